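"""Non-templated addition (NTA) calling with explicit right-censoring.

The templated 3' end is anchored on the reference amplicon; every base
3' of the last reference-matching base is the NTA.  Terminal
reference-matching adenosines are assigned to the template (greedy
templated extension): an A that could be either genomic or tail belongs
to the genome, which avoids inflating A-tail counts.

Two views of the tail exist per read pair:

* the R2 view (``tail_facing``) always contains the molecule's 3'
  terminus; if it also reaches templated sequence the whole tail is
  observed and lengths are exact;
* the R1 view runs from the anchor into the tail and is exact when it
  reaches the ligated adapter.

When neither view spans the tail, its length is right-censored at the
observation ``window`` (default 80 nt) and reported in the
">= window+1" category — but the tail *class* usually survives
censoring, because the terminal bases (the first R2 bases after the
delimiter) still show whether the tail ends in uridines.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .readparse import ParsedReadPair
from .references import DiagnosticTable, ReferenceAmplicon, UNINFORMATIVE, assign_subfamily
from .seq import revcomp

TAIL_CLASS_ORDER = ("A", "AU", "NONE", "OTHER", "U")  # lexicographic


class TailInputError(ValueError):
    """NTA sequence contains characters outside the A/C/G/T/U/N alphabet."""


@dataclass(frozen=True)
class TailCallParams:
    """Tunables for anchoring and classification."""

    window: int = 80
    tolerance: int = 0  # isolated in-tail substitutions corrected if > 0
    max_mismatch_rate: float = 0.05  # over the aligned templated span
    min_anchor: int = 12  # bases; shorter segments cannot anchor
    max_gap: int = 3  # consecutive non-matching bases ending the templated walk
    delimiter: str = "CTGC"  # for locating the adapter in R1


@dataclass(frozen=True)
class TailCall:
    """Per-read (or per-molecule, after dedup) tail call."""

    sample: str
    key: str  # read name before dedup; UMI afterwards
    umi: str
    reference: str
    subfamily: str | None
    tail_class: str  # A | AU | U | NONE | OTHER
    a_len: int
    u_len: int
    censored: bool
    window: int
    anchor: int  # 0-based reference offset of last templated base observed
    flags: frozenset[str] = field(default_factory=frozenset)

    @property
    def total_len(self) -> int:
        return self.a_len + self.u_len


def classify_tail(nta: str, tolerance: int = 0) -> tuple[str, int, int]:
    """Classify an NTA into {A, AU, U, NONE, OTHER} with run lengths.

    The NTA is sense-oriented (3' terminus last); U and T are
    equivalent.  Strict mode (tolerance 0) requires the exact pattern
    ``A+``, ``A+U+``, ``U+`` or empty; anything else is OTHER with zero
    lengths.  With tolerance t > 0, up to t isolated non-conforming
    bases inside a tail of length >= 10 are corrected to the flanking
    run's base before matching.
    """
    s = nta.upper().replace("U", "T")
    if set(s) - set("ACGTN"):
        raise TailInputError(f"NTA contains invalid characters: {nta!r}")
    if tolerance > 0 and len(s) >= 10:
        chars = list(s)
        budget = tolerance
        for i in range(1, len(chars) - 1):
            if budget == 0:
                break
            if chars[i] != chars[i - 1] and chars[i - 1] == chars[i + 1]:
                chars[i] = chars[i - 1]
                budget -= 1
        s = "".join(chars)
    if not s:
        return "NONE", 0, 0
    m = re.fullmatch(r"(A*)(T*)", s)
    if not m:
        return "OTHER", 0, 0
    a_len, u_len = len(m.group(1)), len(m.group(2))
    if u_len == 0:
        return "A", a_len, 0
    if a_len == 0:
        return "U", 0, u_len
    return "AU", a_len, u_len


@dataclass(frozen=True)
class TailView:
    """One read's view of the NTA: the sequence and whether it is complete."""

    seq: str
    complete: bool


def estimate_length(
    r2_view: TailView | None,
    r1_view: TailView | None,
    window: int,
    tolerance: int = 0,
) -> tuple[str, int, int, bool] | str:
    """Combine R1/R2 tail views into (class, a_len, u_len, censored).

    R2 evidence wins when complete (it defines the terminal base); a
    complete R1 view is used otherwise; with only truncated views the
    length is censored at ``window`` while the class is read off the
    observed terminal portion.  Censored calls report
    ``a_len + u_len == window`` exactly, feeding the ">= window+1"
    histogram category.  Returns ``"no_tail_evidence"`` or
    ``"unanchored"`` on failure.
    """
    if r2_view is None and r1_view is None:
        return "no_tail_evidence"

    for view in (r2_view, r1_view):
        if view is not None and view.complete:
            cls, a_len, u_len = classify_tail(view.seq, tolerance)
            if a_len + u_len <= window:
                return cls, a_len, u_len, False
            # fully observed but beyond the reporting window: capped
            u_len = min(u_len, window)
            return cls, window - u_len, u_len, True

    # Only truncated views: censor.  Prefer R2 — it holds the terminus.
    view = r2_view if r2_view is not None else r1_view
    cls, a_len, u_len = classify_tail(view.seq, tolerance)
    if cls in ("NONE", "OTHER"):
        # a truncated view that is not tail-like cannot be interpreted
        return "unanchored"
    if view is r1_view:
        # R1 prefix lacks the terminus: class beyond A is unknowable
        return "A", window, 0, True
    if cls == "AU":
        u_len = min(u_len, window)
        return "AU", window - u_len, u_len, True
    if cls == "U":
        return "U", 0, window, True
    return "A", window, 0, True


# ---------------------------------------------------------------------------
# anchoring


def _extend_templated(seq: str, ref_seq: str, p0: int, max_gap: int) -> tuple[int, int]:
    """Greedy templated walk of ``seq`` along ``ref_seq`` from offset p0.

    Returns (boundary, mismatches): ``seq[:boundary]`` is templated and
    ``boundary - 1`` maps to the last reference-matching base.  The walk
    ends at the reference 3' terminus or after ``max_gap`` consecutive
    non-matching bases, whichever comes first.
    """
    limit = min(len(seq), len(ref_seq) - p0)
    boundary = 0
    mismatches = 0
    gap = 0
    for i in range(limit):
        if seq[i] == ref_seq[p0 + i]:
            mismatches += gap
            gap = 0
            boundary = i + 1
        else:
            gap += 1
            if gap > max_gap:
                break
    return boundary, mismatches


_SEED_CACHE: dict[str, np.ndarray] = {}


def _ref_array(ref_seq: str) -> np.ndarray:
    arr = _SEED_CACHE.get(ref_seq)
    if arr is None:
        arr = np.frombuffer(ref_seq.encode(), dtype=np.uint8)
        _SEED_CACHE[ref_seq] = arr
    return arr


def _seed_offset(seed: str, ref_seq: str, max_mismatch: int) -> int | None:
    """Unique best placement of ``seed`` in ``ref_seq`` within max_mismatch."""
    if len(seed) > len(ref_seq):
        return None
    pos = ref_seq.find(seed)
    if pos >= 0 and ref_seq.find(seed, pos + 1) < 0:
        return pos
    if pos >= 0:
        return None  # multiple exact placements: ambiguous
    if max_mismatch == 0:
        return None
    ref_arr = _ref_array(ref_seq)
    seed_arr = np.frombuffer(seed.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(ref_arr, len(seed))
    mm = (windows != seed_arr).sum(axis=1)
    best = int(mm.min())
    if best > max_mismatch or (mm == best).sum() != 1:
        return None
    return int(mm.argmin())


def anchor_templated_end(
    template_facing: str,
    tail_facing: str,
    ref: ReferenceAmplicon,
    params: TailCallParams = TailCallParams(),
) -> tuple[int, TailView | None, TailView | None] | str:
    """Anchor both read segments on the reference and extract tail views.

    Returns ``(anchor, r2_view, r1_view)`` where ``anchor`` is the
    0-based reference offset of the last templated base observed, or a
    rejection reason (``"short_anchor"`` / ``"unanchored"``).
    """
    if len(template_facing) < params.min_anchor:
        return "short_anchor"

    # --- R1: prefix-anchored at the forward primer site
    b1, mm1 = _extend_templated(
        template_facing, ref.sequence, ref.primer_offset, params.max_gap
    )
    if b1 < params.min_anchor or mm1 / b1 > params.max_mismatch_rate:
        return "unanchored"
    anchor = ref.primer_offset + b1 - 1
    r1_rest = template_facing[b1:]
    r1_view = None
    if r1_rest:
        probe = revcomp(params.delimiter)
        j = r1_rest.find(probe)
        if j >= 0:
            r1_view = TailView(r1_rest[:j], complete=True)
        else:
            r1_view = TailView(r1_rest, complete=False)
    else:
        # R1 truncated inside the templated region; says nothing of the tail
        r1_view = None

    # --- R2: seed the leading bases, then walk toward the 3' terminus
    r2_view = None
    if len(tail_facing) >= params.min_anchor:
        seed = tail_facing[: params.min_anchor]
        p0 = _seed_offset(seed, ref.sequence, max_mismatch=1)
        if p0 is not None:
            b2, mm2 = _extend_templated(
                tail_facing, ref.sequence, p0, params.max_gap
            )
            if b2 >= params.min_anchor and mm2 / b2 <= params.max_mismatch_rate:
                anchor = max(anchor, p0 + b2 - 1)
                r2_view = TailView(tail_facing[b2:], complete=True)
    if r2_view is None and tail_facing:
        # view may be pure tail (template never reached): usable for
        # class and censored length, not for exact length
        if set(tail_facing) <= set("AT"):
            r2_view = TailView(tail_facing, complete=False)

    if r2_view is None and r1_view is None:
        return "unanchored"
    return anchor, r2_view, r1_view


def pick_reference(
    template_facing: str,
    refs: Sequence[ReferenceAmplicon],
    min_identity: float = 0.8,
    probe_len: int = 24,
) -> ReferenceAmplicon | None:
    """Choose the reference whose primer-proximal bases best match R1."""
    best_ref, best_score = None, -1
    for ref in refs:
        probe = ref.sequence[ref.primer_offset : ref.primer_offset + probe_len]
        k = min(len(probe), len(template_facing))
        if k == 0:
            continue
        score = sum(
            template_facing[i] == probe[i] for i in range(k)
        ) / k
        if score > best_score:
            best_ref, best_score = ref, score
    if best_ref is None or best_score < min_identity:
        return None
    return best_ref


def call_pair(
    pair: ParsedReadPair,
    refs: Sequence[ReferenceAmplicon],
    params: TailCallParams = TailCallParams(),
    diagnostics: Mapping[str, DiagnosticTable] | None = None,
) -> TailCall | str:
    """Full tail call for one parsed read pair, or a rejection reason."""
    diagnostics = diagnostics or {}
    ref = pick_reference(pair.template_facing, refs)
    if ref is None:
        return "unanchored"
    anchored = anchor_templated_end(
        pair.template_facing, pair.tail_facing, ref, params
    )
    if isinstance(anchored, str):
        return anchored
    anchor, r2_view, r1_view = anchored

    est = estimate_length(r2_view, r1_view, params.window, params.tolerance)
    if isinstance(est, str):
        return est
    tail_class, a_len, u_len, censored = est

    flags = set(pair.qc_flags)
    if (
        r2_view is not None
        and r1_view is not None
        and r2_view.complete
        and r1_view.complete
        and r2_view.seq != r1_view.seq
    ):
        flags.add("r1_r2_conflict")

    subfamily = None
    table = diagnostics.get(ref.name)
    if table is not None:
        b1 = anchor - ref.primer_offset + 1
        seg = pair.template_facing[: max(b1, 0)]
        subfamily = assign_subfamily(seg, ref.primer_offset, table)
        if subfamily == UNINFORMATIVE and r2_view is not None and r2_view.complete:
            # the R2 templated prefix may cover positions R1 does not
            templated_r2 = pair.tail_facing[: len(pair.tail_facing) - len(r2_view.seq)]
            start = anchor - len(templated_r2) + 1
            if start >= 0 and templated_r2:
                subfamily = assign_subfamily(templated_r2, start, table)

    return TailCall(
        sample=pair.sample,
        key=pair.name,
        umi=pair.umi,
        reference=ref.name,
        subfamily=subfamily,
        tail_class=tail_class,
        a_len=a_len,
        u_len=u_len,
        censored=censored,
        window=params.window,
        anchor=anchor,
        flags=frozenset(flags),
    )


def call_pairs(
    pairs: Iterable[ParsedReadPair],
    refs: Sequence[ReferenceAmplicon],
    params: TailCallParams = TailCallParams(),
    diagnostics: Mapping[str, DiagnosticTable] | None = None,
) -> tuple[list[TailCall], dict[str, int]]:
    """Call every pair; returns calls plus per-fate rejection counts."""
    calls: list[TailCall] = []
    fates: dict[str, int] = {}
    for pair in pairs:
        result = call_pair(pair, refs, params, diagnostics)
        if isinstance(result, str):
            fates[result] = fates.get(result, 0) + 1
        else:
            calls.append(result)
            fates["called"] = fates.get("called", 0) + 1
    return calls, fates
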