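"""End-to-end orchestration: parse -> tail-call -> dedup -> summarize.

Every stage reports per-fate counts; the run manifest carries a
read-conservation ledger in which each input pair is accounted for by
exactly one fate, along with the config echo, package version and input
checksums, so a rerun with the same config and inputs is byte-checkable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from itertools import combinations
from pathlib import Path
from typing import Sequence

from . import __version__
from .config import RunConfig
from .dedup import deduplicate
from .readparse import iter_read_pairs, load_sample_sheet, parse_pairs
from .references import load_diagnostics, load_references
from .summarize import (
    SampleSummary,
    compare_class_fractions,
    compare_length_distributions,
    export,
    summarize_by,
)
from .tables import write_calls
from .tailcall import TailCall, call_pairs

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _pairwise_comparisons(
    summaries: Sequence[SampleSummary],
    calls: Sequence[TailCall],
) -> list[dict]:
    """Chi-square on class composition and Mann-Whitney on A/AU lengths
    for every pair of samples within each stratum."""
    by_stratum: dict[str, list[SampleSummary]] = {}
    for s in summaries:
        by_stratum.setdefault(s.stratum, []).append(s)
    lengths: dict[tuple[str, str, str], list[float]] = {}
    for c in calls:
        if c.tail_class in ("A", "AU") and "low_q" not in c.flags:
            key = (c.sample, c.reference, c.tail_class)
            length = c.a_len if c.tail_class == "A" else c.total_len
            lengths.setdefault(key, []).append(min(length, c.window))

    rows = []
    for stratum, group in sorted(by_stratum.items()):
        for sa, sb in combinations(sorted(group, key=lambda s: s.sample), 2):
            if sa.n_molecules == 0 or sb.n_molecules == 0:
                continue
            try:
                stat, p, _ = compare_class_fractions(
                    sa.class_counts, sb.class_counts
                )
                rows.append(
                    dict(sample_a=sa.sample, sample_b=sb.sample, stratum=stratum,
                         test="chi2_classes", statistic=stat, p_value=p)
                )
            except Exception as exc:  # zero columns etc.: report, don't abort
                logger.warning("chi-square skipped for %s: %s", stratum, exc)
            for cls in ("A", "AU"):
                la = lengths.get((sa.sample, stratum, cls), [])
                lb = lengths.get((sb.sample, stratum, cls), [])
                if la and lb:
                    u, p = compare_length_distributions(la, lb)
                    rows.append(
                        dict(sample_a=sa.sample, sample_b=sb.sample,
                             stratum=stratum, test=f"mannwhitney_{cls}_len",
                             statistic=u, p_value=p)
                    )
    return rows


def run_pipeline(
    config: RunConfig,
    fastq_pairs: Sequence[tuple[str | Path, str | Path]],
) -> Path:
    """Run the full analysis; returns the result directory.

    ``fastq_pairs`` is a list of (R1, R2) paths (optionally gzipped).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    refs = load_references(str(config.references), config.reference_meta)
    diagnostics = (
        load_diagnostics(str(config.diagnostics), refs)
        if config.diagnostics
        else {}
    )
    sheet = load_sample_sheet(
        str(config.sample_sheet), config.layout.max_index_mismatch
    )

    conservation: dict[str, dict] = {}
    parsed_all = []
    total_pairs = 0
    for r1_path, r2_path in fastq_pairs:
        parsed, report = parse_pairs(
            iter_read_pairs(r1_path, r2_path), sheet, config.layout
        )
        parsed_all.extend(parsed)
        total_pairs += report.total
        conservation[Path(r1_path).name] = {
            "total": report.total,
            "parsed": dict(sorted(report.parsed.items())),
            "rejected": dict(sorted(report.rejected.items())),
        }
    logger.info("parsed %d/%d read pairs", len(parsed_all), total_pairs)

    calls, call_fates = call_pairs(
        parsed_all, refs, config.tailcall, diagnostics
    )
    assert sum(call_fates.values()) == len(parsed_all), "call-stage conservation"
    write_calls(calls, out_dir / "calls.tsv")

    consensus, groups = deduplicate(calls, mode=config.dedup_mode)
    write_calls(
        consensus,
        out_dir / "calls_dedup.tsv",
        group_sizes=[len(g.member_calls) for g in groups],
    )

    summaries = summarize_by(
        consensus, window=config.tailcall.window, stratify=config.stratify
    )
    comparisons = _pairwise_comparisons(summaries, consensus)
    export(summaries, out_dir, comparisons, figures=config.figures)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "window": config.tailcall.window,
        "dedup_mode": config.dedup_mode,
        "inputs": {
            str(Path(p).name): _sha256(Path(p))
            for pair in fastq_pairs
            for p in pair
        },
        "references": str(config.references),
        "n_read_pairs": total_pairs,
        "n_parsed": len(parsed_all),
        "call_fates": dict(sorted(call_fates.items())),
        "n_calls": len(calls),
        "n_molecules": len(consensus),
        "conservation": conservation,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    if total_pairs == 0:
        logger.warning("no input read pairs; summaries are empty")
    return out_dir
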