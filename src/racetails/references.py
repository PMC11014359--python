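"""Reference amplicon 3'-end sequences and LINE-1 subfamily diagnostics.

A reference amplicon is the templated sense-strand sequence between the
nested forward primer and the annotated 3' terminus of the targeted
transcript (L1 reporter, GAPDH, PABPC4, or an endogenous-L1 consensus
window).  By convention the last base of ``sequence`` is the annotated
3' terminus: everything a read carries beyond a match to this sequence
is a non-templated addition.

LINE-1 subfamilies (L1-HS vs the older L1-PA2..PA5) differ at a handful
of diagnostic nucleotides inside the amplified window.  Those positions
and expected bases are experiment-specific and must be supplied by
configuration (TSV); the package ships only a synthetic example table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .seq import check_alphabet

logger = logging.getLogger(__name__)

#: Sentinel labels returned by :func:`assign_subfamily`.
AMBIGUOUS = "ambiguous"
UNINFORMATIVE = "uninformative"


class ReferenceError(ValueError):
    """A reference FASTA or its sidecar configuration is invalid."""


@dataclass(frozen=True)
class ReferenceAmplicon:
    """A targeted transcript's templated 3'-end sequence.

    Parameters
    ----------
    name : str
        Record identifier, matching the FASTA header and sample config.
    sequence : str
        Sense strand, 5'->3', ending at the annotated templated 3'
        terminus.  Alphabet A/C/G/T/N.
    primer_offset : int
        0-based position where the nested forward primer binds; R1 reads
        start here.
    notes : str
        Free text (e.g. cross-priming caveats).
    """

    name: str
    sequence: str
    primer_offset: int = 0
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ReferenceError(f"reference {self.name!r}: empty sequence")
        check_alphabet(self.sequence, f"reference {self.name!r}")
        if not 0 <= self.primer_offset < len(self.sequence):
            raise ReferenceError(
                f"reference {self.name!r}: primer_offset {self.primer_offset} "
                f"outside sequence of length {len(self.sequence)}"
            )
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def terminus(self) -> int:
        """0-based index of the annotated templated 3'-terminal base."""
        return len(self.sequence) - 1


@dataclass(frozen=True)
class DiagnosticTable:
    """Subfamily-diagnostic positions within one reference amplicon.

    ``entries`` maps a 0-based reference position to the expected base
    per subfamily; every subfamily must have a base at every position.
    """

    reference: str
    subfamilies: tuple[str, ...]
    entries: tuple[tuple[int, Mapping[str, str]], ...] = field(default=())

    def __post_init__(self) -> None:
        for pos, by_subfam in self.entries:
            if pos < 0:
                raise ReferenceError(
                    f"diagnostic position {pos} is negative ({self.reference})"
                )
            missing = set(self.subfamilies) - set(by_subfam)
            if missing:
                raise ReferenceError(
                    f"diagnostic position {pos}: no base for {sorted(missing)}"
                )

    def validate_against(self, ref: ReferenceAmplicon) -> None:
        for pos, _ in self.entries:
            if pos >= len(ref):
                raise ReferenceError(
                    f"diagnostic position {pos} outside reference "
                    f"{ref.name!r} of length {len(ref)}"
                )

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(pos for pos, _ in self.entries)


def load_references(
    fasta_source: str | IO[str],
    sidecar_config: Mapping[str, Mapping[str, object]],
) -> list[ReferenceAmplicon]:
    """Load and validate reference amplicons from FASTA plus sidecar config.

    ``sidecar_config`` maps record name -> {"primer_offset": int,
    "notes": str}.  Every configured record must exist in the FASTA;
    FASTA records missing from the config are an error too, since a
    silent extra reference usually means a typo in one of the names.
    """
    try:
        records = list(SeqIO.parse(fasta_source, "fasta"))
    except Exception as exc:  # Biopython raises bare ValueError
        raise ReferenceError(f"malformed FASTA: {exc}") from exc

    if not records:
        logger.warning("reference FASTA contains no records")
        return []

    by_name = {}
    for rec in records:
        if rec.id in by_name:
            raise ReferenceError(f"duplicate FASTA record {rec.id!r}")
        by_name[rec.id] = str(rec.seq)

    missing = set(sidecar_config) - set(by_name)
    if missing:
        raise ReferenceError(
            f"config names records absent from FASTA: {sorted(missing)}"
        )
    unconfigured = set(by_name) - set(sidecar_config)
    if unconfigured:
        raise ReferenceError(
            f"FASTA records missing from config: {sorted(unconfigured)}"
        )

    amplicons = []
    for name, seq in by_name.items():
        cfg = sidecar_config[name]
        try:
            check_alphabet(seq, f"record {name!r}")
        except ValueError as exc:
            raise ReferenceError(str(exc)) from exc
        amplicons.append(
            ReferenceAmplicon(
                name=name,
                sequence=seq,
                primer_offset=int(cfg.get("primer_offset", 0)),
                notes=str(cfg.get("notes", "")),
            )
        )
    return amplicons


def load_diagnostics(
    tsv_source: str | IO[str],
    references: Iterable[ReferenceAmplicon] = (),
) -> dict[str, DiagnosticTable]:
    """Read diagnostic tables from TSV.

    Columns: reference, position (1-based in the file), subfamily, base.
    Returns one table per reference named in the file; positions are
    converted to 0-based internally.
    """
    df = pd.read_csv(tsv_source, sep="\t", dtype=str)
    required = {"reference", "position", "subfamily", "base"}
    if not required <= set(df.columns):
        raise ReferenceError(
            f"diagnostic TSV needs columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    refs_by_name = {r.name: r for r in references}
    tables: dict[str, DiagnosticTable] = {}
    for ref_name, sub in df.groupby("reference", sort=True):
        subfamilies = tuple(dict.fromkeys(sub["subfamily"]))
        entries = []
        for pos_str, at_pos in sub.groupby("position", sort=True):
            pos = int(pos_str) - 1  # file is 1-based
            by_subfam = dict(zip(at_pos["subfamily"], at_pos["base"].str.upper()))
            entries.append((pos, by_subfam))
        entries.sort(key=lambda e: e[0])
        table = DiagnosticTable(
            reference=str(ref_name),
            subfamilies=subfamilies,
            entries=tuple(entries),
        )
        if ref_name in refs_by_name:
            table.validate_against(refs_by_name[ref_name])
        tables[str(ref_name)] = table
    return tables


def assign_subfamily(
    templated_segment: str,
    alignment_start: int,
    table: DiagnosticTable,
) -> str:
    """Assign an L1 subfamily to a templated read segment.

    The segment is sense-oriented and aligned to the reference starting
    at ``alignment_start`` (0-based).  The unique subfamily whose
    expected bases match at ALL diagnostic positions covered by the
    segment is returned.  With no covered position the call is
    ``"uninformative"``; with more than one consistent subfamily — or
    with none, which indicates a sequencing error or an unlisted allele
    — it is ``"ambiguous"``.
    """
    segment = templated_segment.upper()
    end = alignment_start + len(segment)
    covered = [
        (pos, by_subfam)
        for pos, by_subfam in table.entries
        if alignment_start <= pos < end
    ]
    if not covered:
        return UNINFORMATIVE

    consistent = set(table.subfamilies)
    for pos, by_subfam in covered:
        base = segment[pos - alignment_start]
        consistent &= {s for s in table.subfamilies if by_subfam[s] == base}
        if not consistent:
            logger.debug(
                "subfamily mismatch at reference position %d (base %r)",
                pos,
                base,
            )
            return AMBIGUOUS
    if len(consistent) == 1:
        return next(iter(consistent))
    return AMBIGUOUS
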