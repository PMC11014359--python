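"""Demultiplexing and structural parsing of raw read pairs.

Each pair is assigned exactly one fate: a successfully parsed
:class:`ParsedReadPair` for one sample, or a single rejection reason.
The per-fate counts always sum to the input count; that conservation is
asserted per run and reported in the demultiplexing report.

R2 carries the adapter-side structure ``[UMI][delimiter][payload]``
(optionally preceded by an in-line 6-nt index).  The payload is the
reverse complement of ``templated + tail``, so its first base is the
complement of the molecule's 3'-terminal nucleotide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import IO, Iterable, Iterator

import gzip

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .seq import hamming, mean_quality, revcomp

UNDETERMINED = "undetermined"


class SampleSheetError(ValueError):
    """Invalid sample sheet (duplicate or insufficiently separated indices)."""


@dataclass(frozen=True)
class ReadLayout:
    """Structural layout of R2 and demultiplexing tolerances."""

    umi_len: int = 15
    delimiter: str = "CTGC"
    index_len: int = 6
    index_in_r2: bool = False
    max_index_mismatch: int = 1
    max_delim_mismatch: int = 1
    min_mean_q: float = 20.0


@dataclass(frozen=True)
class ParsedReadPair:
    """One demultiplexed, structurally parsed read pair."""

    name: str
    sample: str
    umi: str
    tail_facing: str  # sense 5'->3', revcomp of R2 payload; 3' terminus last
    template_facing: str  # R1 payload from the forward-primer site onward
    r2_terminal_base: str  # first base after the delimiter, raw R2 orientation
    qc_flags: frozenset[str] = field(default_factory=frozenset)


def load_sample_sheet(
    source: str | IO[str], max_index_mismatch: int = 1
) -> dict[str, str]:
    """Read a TSV with columns ``sample`` and ``index``; returns index->sample.

    Indices must be unique and pairwise separated by Hamming distance
    greater than ``2 * max_index_mismatch`` so nearest-index assignment
    is unambiguous.
    """
    df = pd.read_csv(source, sep="\t", dtype=str)
    if not {"sample", "index"} <= set(df.columns):
        raise SampleSheetError(
            f"sample sheet needs columns sample, index; got {list(df.columns)}"
        )
    sheet: dict[str, str] = {}
    for _, row in df.iterrows():
        idx = row["index"].upper()
        if idx in sheet:
            raise SampleSheetError(f"duplicate index {idx!r} in sample sheet")
        sheet[idx] = row["sample"]
    for a, b in combinations(sheet, 2):
        if hamming(a, b) <= 2 * max_index_mismatch:
            raise SampleSheetError(
                f"indices {a!r} and {b!r} are closer than required "
                f"(Hamming must exceed {2 * max_index_mismatch})"
            )
    return sheet


def demultiplex(
    index_seq: str, sample_sheet: dict[str, str], max_index_mismatch: int = 1
) -> str:
    """Assign a read's index sequence to a sample, or ``"undetermined"``.

    The unique nearest index within ``max_index_mismatch`` wins; ties or
    distant indices are undetermined.
    """
    index_seq = index_seq.upper()
    best, best_d, tied = None, None, False
    for idx, sample in sample_sheet.items():
        if len(idx) != len(index_seq):
            continue
        d = hamming(idx, index_seq)
        if best_d is None or d < best_d:
            best, best_d, tied = sample, d, False
        elif d == best_d:
            tied = True
    if best is None or best_d > max_index_mismatch or tied:
        return UNDETERMINED
    return best


def parse_r2(
    r2_seq: str, layout: ReadLayout
) -> tuple[str, str, str] | str:
    """Extract (umi, payload, terminal base) from R2, or a rejection reason.

    The UMI is the first ``umi_len`` bases; the delimiter must follow
    immediately, within ``max_delim_mismatch`` substitutions.  Returns
    the tuple on success, else ``"too_short"`` or ``"no_delimiter"``.
    """
    start = layout.index_len if layout.index_in_r2 else 0
    need = start + layout.umi_len + len(layout.delimiter) + 1
    if len(r2_seq) < need:
        return "too_short"
    umi = r2_seq[start : start + layout.umi_len]
    delim_at = start + layout.umi_len
    observed = r2_seq[delim_at : delim_at + len(layout.delimiter)]
    if hamming(observed.upper(), layout.delimiter.upper()) > layout.max_delim_mismatch:
        return "no_delimiter"
    payload = r2_seq[delim_at + len(layout.delimiter) :]
    return umi.upper(), payload.upper(), payload[0].upper()


def orient(
    name: str,
    sample: str,
    umi: str,
    payload: str,
    r1_seq: str,
    qc_flags: Iterable[str] = (),
) -> ParsedReadPair:
    """Build a sense-oriented :class:`ParsedReadPair` from raw segments.

    ``tail_facing`` is the reverse complement of the R2 payload, so it
    runs 5'->3' with the molecule's 3' terminus as its last base.
    """
    return ParsedReadPair(
        name=name,
        sample=sample,
        umi=umi,
        tail_facing=revcomp(payload),
        template_facing=r1_seq.upper(),
        r2_terminal_base=payload[0].upper() if payload else "N",
        qc_flags=frozenset(qc_flags),
    )


def _header_index(title: str) -> str:
    """Index sequence from an Illumina-style header comment ``1:N:0:ACGTAC``."""
    parts = title.split()
    if len(parts) < 2:
        return ""
    fields = parts[1].split(":")
    return fields[-1].upper() if fields else ""


def open_maybe_gzip(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def iter_read_pairs(
    r1_path: str | Path, r2_path: str | Path
) -> Iterator[tuple[str, str, str, str, str]]:
    """Iterate (title, r1_seq, r1_qual, r2_seq, r2_qual) over paired FASTQ."""
    with open_maybe_gzip(r1_path) as f1, open_maybe_gzip(r2_path) as f2:
        for (t1, s1, q1), (t2, s2, q2) in zip(
            FastqGeneralIterator(f1), FastqGeneralIterator(f2), strict=True
        ):
            if t1.split()[0] != t2.split()[0]:
                raise ValueError(
                    f"paired FASTQ out of sync: {t1.split()[0]} vs {t2.split()[0]}"
                )
            yield t1, s1, q1, s2, q2


@dataclass
class ParseReport:
    """Per-fate read counts; ``total`` equals their sum by construction."""

    total: int = 0
    parsed: dict[str, int] = field(default_factory=dict)  # per sample
    rejected: dict[str, int] = field(default_factory=dict)  # per reason

    def as_frame(self) -> pd.DataFrame:
        rows = [("parsed", k, v) for k, v in sorted(self.parsed.items())]
        rows += [("rejected", k, v) for k, v in sorted(self.rejected.items())]
        df = pd.DataFrame(rows, columns=["fate", "label", "count"])
        assert df["count"].sum() == self.total, "read-conservation violated"
        return df


def parse_pairs(
    read_pairs: Iterable[tuple[str, str, str, str, str]],
    sample_sheet: dict[str, str],
    layout: ReadLayout,
) -> tuple[list[ParsedReadPair], ParseReport]:
    """Demultiplex and structurally parse raw pairs.

    Every input pair lands in exactly one bucket: a parsed pair for one
    sample, or one rejection reason among ``undetermined``,
    ``too_short``, ``no_delimiter``.  Low mean-quality pairs are parsed
    but flagged ``low_q`` (excluded from summaries downstream).
    """
    parsed: list[ParsedReadPair] = []
    report = ParseReport()

    for title, r1_seq, r1_qual, r2_seq, r2_qual in read_pairs:
        report.total += 1
        if layout.index_in_r2:
            index_seq = r2_seq[: layout.index_len].upper()
        else:
            index_seq = _header_index(title)
        sample = demultiplex(index_seq, sample_sheet, layout.max_index_mismatch)
        if sample == UNDETERMINED:
            report.rejected[UNDETERMINED] = report.rejected.get(UNDETERMINED, 0) + 1
            continue
        result = parse_r2(r2_seq, layout)
        if isinstance(result, str):
            report.rejected[result] = report.rejected.get(result, 0) + 1
            continue
        umi, payload, _terminal = result
        flags = []
        if min(mean_quality(r1_qual), mean_quality(r2_qual)) < layout.min_mean_q:
            flags.append("low_q")
        pair = orient(title.split()[0], sample, umi, payload, r1_seq, flags)
        parsed.append(pair)
        report.parsed[sample] = report.parsed.get(sample, 0) + 1

    assert (
        sum(report.parsed.values()) + sum(report.rejected.values()) == report.total
    ), "read-conservation violated"
    return parsed, report
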