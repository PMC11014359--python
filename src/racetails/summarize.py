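"""Per-sample summaries of tail classes and lengths, plus comparisons.

Produces the table shapes behind the study's figure panels: four-class
composition (A / AU / U / no tail, with OTHER tallied separately and
excluded from the four-class denominators), per-length histograms from
1 to ">= window+1", the three A-tail length classes (1-32, 33-64, > 64
nt), 10-nt total-length bins with no-tail molecules excluded, U-length
by total-length joint bins, per-class medians, and between-sample
statistics (Pearson chi-square for composition, two-sided Mann-Whitney
for lengths).
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats as sps

from .tailcall import TailCall

FOUR_CLASSES = ("A", "AU", "U", "NONE")


class SummaryError(ValueError):
    pass


def _top_category(window: int) -> int:
    """Histogram key for the right-censored ">= window+1" category."""
    return window + 1


@dataclass
class SampleSummary:
    """Counts, fractions, histograms, and medians for one (sample, stratum)."""

    sample: str
    stratum: str
    window: int
    n_molecules: int  # four-class molecules; OTHER excluded
    n_other: int
    class_counts: dict[str, int]
    class_fractions: dict[str, float]
    uridylated_fraction: float | None
    a_len_hist: dict[int, int]  # keys 1..window, window+1 == ">= window+1"
    au_len_hist: dict[int, int]  # over total length
    length_class_counts: dict[str, dict[str, int]]  # class -> {short,mid,long}
    ten_nt_bins: dict[str, dict[str, int]]  # class -> bin label -> count
    u_by_total: dict[tuple[str, int], int]  # (total-length bin, u_len) -> count
    medians: dict[str, float | None]
    flags: list[str] = field(default_factory=list)


def length_classes(
    lengths_censored: Iterable[tuple[float, bool]],
) -> tuple[int, int, int]:
    """Counts in the three length classes (1-32, 33-64, >= 65 nt).

    Censored lengths belong to the top class regardless of value.
    """
    short = mid = long_ = 0
    for length, censored in lengths_censored:
        if censored or length >= 65:
            long_ += 1
        elif length <= 32:
            short += 1
        else:
            mid += 1
    return short, mid, long_


def median_length(lengths: Sequence[float]) -> float | None:
    """Median reported length (censored values enter at the window cap).

    Returns None on empty input; integer medians come back as ints.
    """
    if not lengths:
        return None
    med = statistics.median(lengths)
    return int(med) if float(med).is_integer() else med


def _bin_label(total: float, window: int, censored: bool) -> str:
    if censored or total > window:
        return f">={window + 1}"
    lo = (int(total) - 1) // 10 * 10 + 1
    return f"{lo}-{lo + 9}"


def ten_nt_bin_labels(window: int) -> list[str]:
    labels = [f"{lo}-{lo + 9}" for lo in range(1, window, 10)]
    labels.append(f">={window + 1}")
    return labels


def summarize_calls(
    calls: Sequence[TailCall],
    sample: str,
    stratum: str,
    window: int = 80,
) -> SampleSummary:
    """Build a :class:`SampleSummary` from deduplicated calls.

    ``calls`` should already be restricted to one (sample, stratum);
    low-quality-flagged calls are excluded here.
    """
    usable = [c for c in calls if "low_q" not in c.flags]
    counts = {cls: 0 for cls in FOUR_CLASSES}
    n_other = 0
    top = _top_category(window)
    a_hist = {k: 0 for k in range(1, top + 1)}
    au_hist = {k: 0 for k in range(1, top + 1)}
    lcc: dict[str, dict[str, int]] = {
        cls: {"short": 0, "mid": 0, "long": 0} for cls in ("A", "AU", "U")
    }
    bins: dict[str, dict[str, int]] = {
        cls: {lab: 0 for lab in ten_nt_bin_labels(window)}
        for cls in ("A", "AU", "U")
    }
    u_by_total: dict[tuple[str, int], int] = {}
    lengths: dict[str, list[float]] = {cls: [] for cls in ("A", "AU", "U")}

    for call in usable:
        cls = call.tail_class
        if cls == "OTHER":
            n_other += 1
            continue
        counts[cls] += 1
        if cls == "NONE":
            continue
        total = call.total_len
        hist_key = top if (call.censored or total > window) else int(total)
        if cls == "A":
            a_hist[hist_key] += 1
            lengths["A"].append(min(call.a_len, window))
        elif cls == "AU":
            au_hist[hist_key] += 1
            lengths["AU"].append(min(total, window))
        else:
            lengths["U"].append(min(call.u_len, window))
        s, m, l = length_classes([(total, call.censored)])
        lc = lcc[cls]
        lc["short"] += s
        lc["mid"] += m
        lc["long"] += l
        lab = _bin_label(total, window, call.censored)
        bins[cls][lab] += 1
        if call.u_len > 0:
            key = (lab, int(min(call.u_len, window)))
            u_by_total[key] = u_by_total.get(key, 0) + 1

    n = sum(counts.values())
    flags = []
    if n == 0:
        fractions = {cls: float("nan") for cls in FOUR_CLASSES}
        uridylated = None
        flags.append("no_molecules")
    else:
        fractions = {cls: counts[cls] / n for cls in FOUR_CLASSES}
        uridylated = fractions["AU"] + fractions["U"]

    medians = {cls: median_length(v) for cls, v in lengths.items()}
    return SampleSummary(
        sample=sample,
        stratum=stratum,
        window=window,
        n_molecules=n,
        n_other=n_other,
        class_counts=counts,
        class_fractions=fractions,
        uridylated_fraction=uridylated,
        a_len_hist=a_hist,
        au_len_hist=au_hist,
        length_class_counts=lcc,
        ten_nt_bins=bins,
        u_by_total=u_by_total,
        medians=medians,
        flags=flags,
    )


def summarize_by(
    calls: Sequence[TailCall],
    window: int = 80,
    stratify: str = "reference",
) -> list[SampleSummary]:
    """One summary per (sample, stratum); stratify by reference or subfamily."""
    if stratify not in ("reference", "subfamily"):
        raise SummaryError(f"unknown stratification {stratify!r}")
    groups: dict[tuple[str, str], list[TailCall]] = {}
    for call in calls:
        stratum = call.reference if stratify == "reference" else (
            call.subfamily or "unassigned"
        )
        groups.setdefault((call.sample, stratum), []).append(call)
    return [
        summarize_calls(groups[key], key[0], key[1], window)
        for key in sorted(groups)
    ]


# ---------------------------------------------------------------------------
# between-sample statistics


def compare_class_fractions(
    counts_a: Mapping[str, int] | Sequence[int],
    counts_b: Mapping[str, int] | Sequence[int],
) -> tuple[float, float, int]:
    """Pearson chi-square (no continuity correction) on a 2 x k table.

    Returns (statistic, p-value, degrees of freedom = k - 1).
    """
    if isinstance(counts_a, Mapping):
        keys = [k for k in counts_a if counts_a[k] + counts_b.get(k, 0) >= 0]
        row_a = [counts_a[k] for k in keys]
        row_b = [counts_b.get(k, 0) for k in keys]
    else:
        row_a, row_b = list(counts_a), list(counts_b)
    if len(row_a) != len(row_b) or not 2 <= len(row_a) <= 4:
        raise SummaryError("need matching 2 x k counts with k in 2..4")
    if any(v < 0 for v in row_a + row_b):
        raise SummaryError("counts must be non-negative")
    for j, (a, b) in enumerate(zip(row_a, row_b)):
        if a + b == 0:
            raise SummaryError(
                f"column {j} has zero total; pool sparse categories first"
            )
    if sum(row_a) == 0 or sum(row_b) == 0:
        raise SummaryError("each sample needs at least one molecule")
    stat, p, dof, _ = sps.chi2_contingency([row_a, row_b], correction=False)
    return float(stat), float(p), int(dof)


def compare_length_distributions(
    lengths_a: Sequence[float], lengths_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with tie correction.

    Exact null distribution when min(n1, n2) <= 8, normal approximation
    otherwise.  Returns (U statistic for the first sample, p-value).
    """
    if len(lengths_a) == 0 or len(lengths_b) == 0:
        raise SummaryError("both length samples must be non-empty")
    method = "exact" if min(len(lengths_a), len(lengths_b)) <= 8 else "asymptotic"
    res = sps.mannwhitneyu(
        lengths_a, lengths_b, alternative="two-sided", method=method
    )
    return float(res.statistic), float(res.pvalue)


def benjamini_hochberg(pvalues: Sequence[float]) -> list[float]:
    """BH-adjusted p-values (optional; per-comparison p is the default)."""
    adjusted = sps.false_discovery_control(pvalues, method="bh")
    return [float(p) for p in adjusted]


# ---------------------------------------------------------------------------
# export


def _classes_frame(summaries: Sequence[SampleSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        for cls in FOUR_CLASSES:
            frac = s.class_fractions[cls]
            rows.append(
                (s.sample, s.stratum, cls, s.class_counts[cls], round(frac, 6))
            )
        rows.append((s.sample, s.stratum, "OTHER", s.n_other, ""))
    return pd.DataFrame(
        rows, columns=["sample", "stratum", "class", "count", "fraction"]
    )


def _hist_frame(summaries: Sequence[SampleSummary], attr: str) -> pd.DataFrame:
    rows = []
    for s in summaries:
        hist = getattr(s, attr)
        top = _top_category(s.window)
        for length in sorted(hist):
            label = f">={top}" if length == top else str(length)
            rows.append((s.sample, s.stratum, label, hist[length]))
    return pd.DataFrame(rows, columns=["sample", "stratum", "length", "count"])


def _length_class_frame(summaries: Sequence[SampleSummary]) -> pd.DataFrame:
    rows = []
    labels = {"short": "1-32", "mid": "33-64", "long": ">=65"}
    for s in summaries:
        for cls, lc in s.length_class_counts.items():
            for key in ("short", "mid", "long"):
                rows.append((s.sample, s.stratum, cls, labels[key], lc[key]))
    return pd.DataFrame(
        rows, columns=["sample", "stratum", "class", "length_class", "count"]
    )


def _bins_frame(summaries: Sequence[SampleSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        denom = sum(sum(b.values()) for b in s.ten_nt_bins.values())
        for cls, by_bin in s.ten_nt_bins.items():
            for lab in ten_nt_bin_labels(s.window):
                count = by_bin[lab]
                pct = 100.0 * count / denom if denom else ""
                rows.append((s.sample, s.stratum, cls, lab, count, pct))
    return pd.DataFrame(
        rows,
        columns=["sample", "stratum", "class", "total_len_bin", "count", "pct"],
    )


def _u_by_total_frame(summaries: Sequence[SampleSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        for (lab, u_len), count in sorted(s.u_by_total.items()):
            rows.append((s.sample, s.stratum, lab, u_len, count))
    return pd.DataFrame(
        rows, columns=["sample", "stratum", "total_len_bin", "u_len", "count"]
    )


def _medians_frame(summaries: Sequence[SampleSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        for cls in ("A", "AU", "U"):
            med = s.medians[cls]
            rows.append(
                (s.sample, s.stratum, cls, "" if med is None else med)
            )
    return pd.DataFrame(rows, columns=["sample", "stratum", "class", "median"])


def comparisons_frame(comparisons: Sequence[Mapping[str, object]]) -> pd.DataFrame:
    return pd.DataFrame(
        comparisons,
        columns=["sample_a", "sample_b", "stratum", "test", "statistic", "p_value"],
    )


def export(
    summaries: Sequence[SampleSummary],
    out_dir: str | Path,
    comparisons: Sequence[Mapping[str, object]] = (),
    figures: bool = False,
) -> dict[str, Path]:
    """Write one tidy TSV per figure-style output; optionally figures.

    Count conservation is asserted on every export: histogram totals
    must equal their class counts.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for s in summaries:
        assert sum(s.a_len_hist.values()) == s.class_counts["A"], (
            f"A histogram loses molecules for {s.sample}/{s.stratum}"
        )
        assert sum(s.au_len_hist.values()) == s.class_counts["AU"], (
            f"AU histogram loses molecules for {s.sample}/{s.stratum}"
        )

    outputs = {
        "classes": _classes_frame(summaries),
        "length_classes": _length_class_frame(summaries),
        "a_len_hist": _hist_frame(summaries, "a_len_hist"),
        "au_len_hist": _hist_frame(summaries, "au_len_hist"),
        "ten_nt_bins": _bins_frame(summaries),
        "u_by_total": _u_by_total_frame(summaries),
        "medians": _medians_frame(summaries),
    }
    if comparisons:
        outputs["tests"] = comparisons_frame(comparisons)

    paths: dict[str, Path] = {}
    for name, frame in outputs.items():
        path = out_dir / f"{name}.tsv"
        frame.to_csv(path, sep="\t", index=False)
        paths[name] = path

    if figures:
        paths.update(_export_figures(summaries, out_dir))
    return paths


def _export_figures(
    summaries: Sequence[SampleSummary], out_dir: Path
) -> dict[str, Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = {}
    fig, ax = plt.subplots(figsize=(1.2 + 0.8 * len(summaries), 4))
    bottoms = [0.0] * len(summaries)
    xlabels = [f"{s.sample}\n{s.stratum}" for s in summaries]
    for cls in FOUR_CLASSES:
        vals = [
            0.0 if s.n_molecules == 0 else 100.0 * s.class_fractions[cls]
            for s in summaries
        ]
        ax.bar(xlabels, vals, bottom=bottoms, label=cls)
        bottoms = [b + v for b, v in zip(bottoms, vals)]
    ax.set_ylabel("% of molecules")
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = out_dir / "classes.svg"
    fig.savefig(path)
    plt.close(fig)
    paths["classes_figure"] = path

    fig, ax = plt.subplots(figsize=(7, 4))
    for s in summaries:
        keys = sorted(s.a_len_hist)
        ax.plot(keys, [s.a_len_hist[k] for k in keys],
                label=f"{s.sample}/{s.stratum}", lw=1)
    ax.set_xlabel("A-tail length (last bin right-censored)")
    ax.set_ylabel("molecules")
    ax.legend(fontsize=7)
    fig.tight_layout()
    path = out_dir / "a_len_hist.svg"
    fig.savefig(path)
    plt.close(fig)
    paths["a_len_hist_figure"] = path
    return paths
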