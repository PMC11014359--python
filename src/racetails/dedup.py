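"""UMI-based collapse of PCR duplicates.

Each original molecule carries a random 15-nt UMI from the ligated
adapter; with 4^15 ~ 1.07e9 possible UMIs, collisions are negligible at
library scale, so the default grouping is exact UMI identity.  A
directional single-mismatch mode (merge a UMI into a >= 2x more
abundant neighbour at Hamming distance 1, the standard directional
rule) is provided for error-rich data.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .seq import hamming
from .tailcall import TAIL_CLASS_ORDER, TailCall


class DedupInputError(ValueError):
    """Calls from mixed samples or references were passed to one grouping."""


@dataclass(frozen=True)
class UmiGroup:
    """All calls sharing one (error-corrected) UMI within one sample."""

    sample: str
    umi: str
    member_calls: tuple[TailCall, ...]

    def __post_init__(self) -> None:
        if not self.member_calls:
            raise DedupInputError("UmiGroup requires at least one member call")

    @property
    def consensus(self) -> TailCall:
        return consensus_call(self)


def group_umis(
    calls: Sequence[TailCall], mode: str = "exact"
) -> list[UmiGroup]:
    """Group tail calls by UMI.

    ``exact``: identical UMIs only.  ``directional-1mm``: additionally
    merge a UMI into a neighbour at Hamming distance 1 whose read count
    is at least twice its own (counts compared before merging), seeded
    from the most abundant UMI downward.
    """
    if not calls:
        return []
    samples = {c.sample for c in calls}
    if len(samples) > 1:
        raise DedupInputError(f"calls from multiple samples: {sorted(samples)}")
    references = {c.reference for c in calls}
    if len(references) > 1:
        raise DedupInputError(
            f"calls from multiple references: {sorted(references)}"
        )
    if mode not in ("exact", "directional-1mm"):
        raise ValueError(f"unknown dedup mode {mode!r}")

    by_umi: dict[str, list[TailCall]] = {}
    for call in calls:
        by_umi.setdefault(call.umi, []).append(call)

    if mode == "directional-1mm":
        counts = {u: len(v) for u, v in by_umi.items()}
        # most abundant first; stable order for determinism
        order = sorted(by_umi, key=lambda u: (-counts[u], u))
        parent: dict[str, str] = {}
        for u in order:
            if u in parent:
                continue
            for v in order:
                if v == u or v in parent or len(v) != len(u):
                    continue
                if counts[u] >= 2 * counts[v] and hamming(u, v) == 1:
                    parent[v] = u
        for child, par in parent.items():
            by_umi[par].extend(by_umi.pop(child))

    sample = next(iter(samples))
    return [
        UmiGroup(sample=sample, umi=u, member_calls=tuple(members))
        for u, members in sorted(by_umi.items())
    ]


def consensus_call(group: UmiGroup) -> TailCall:
    """Collapse one UMI group to a single molecule-level call.

    Class by plurality; ties broken toward the class of the member with
    the longest uncensored evidence, then by fixed class order for
    determinism.  Lengths are per-field medians over members of the
    winning class; the consensus is censored only if every winning
    member is.
    """
    members = group.member_calls
    if len(members) == 1:
        call = members[0]
        return replace(call, key=call.umi)

    votes: dict[str, int] = {}
    for call in members:
        votes[call.tail_class] = votes.get(call.tail_class, 0) + 1
    top = max(votes.values())
    tied = [c for c, v in votes.items() if v == top]
    if len(tied) == 1:
        winner = tied[0]
    else:
        uncensored = [c for c in members if not c.censored and c.tail_class in tied]
        if uncensored:
            winner = max(uncensored, key=lambda c: c.total_len).tail_class
        else:
            winner = min(tied, key=TAIL_CLASS_ORDER.index)

    winning = [c for c in members if c.tail_class == winner]
    a_len = statistics.median(c.a_len for c in winning)
    u_len = statistics.median(c.u_len for c in winning)
    template = winning[0]
    subfamilies = {c.subfamily for c in winning if c.subfamily}
    return replace(
        template,
        key=group.umi,
        a_len=int(a_len) if float(a_len).is_integer() else a_len,
        u_len=int(u_len) if float(u_len).is_integer() else u_len,
        censored=all(c.censored for c in winning),
        anchor=max(c.anchor for c in winning),
        subfamily=subfamilies.pop() if len(subfamilies) == 1 else template.subfamily,
        flags=frozenset().union(*(c.flags for c in winning)),
    )


def deduplicate(
    calls: Sequence[TailCall], mode: str = "exact"
) -> tuple[list[TailCall], list[UmiGroup]]:
    """Group and collapse; returns (consensus calls, groups).

    Grouping is performed per (sample, reference) partition, so mixed
    inputs are handled by partitioning rather than rejected.
    """
    partitions: dict[tuple[str, str], list[TailCall]] = {}
    for call in calls:
        partitions.setdefault((call.sample, call.reference), []).append(call)
    consensus: list[TailCall] = []
    groups: list[UmiGroup] = []
    for key in sorted(partitions):
        part_groups = group_umis(partitions[key], mode=mode)
        groups.extend(part_groups)
        consensus.extend(g.consensus for g in part_groups)
    return consensus, groups
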