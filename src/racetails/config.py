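"""Run configuration: one YAML file drives the whole pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .readparse import ReadLayout
from .tailcall import TailCallParams


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    ``references`` points to a FASTA of amplicon 3'-end windows;
    ``reference_meta`` is the sidecar mapping record name to
    primer_offset/notes.  ``diagnostics`` (optional TSV) supplies the
    L1 subfamily diagnostic positions — these are experiment-specific
    and never hard-coded.
    """

    references: Path
    sample_sheet: Path
    reference_meta: dict[str, dict[str, Any]] = field(default_factory=dict)
    diagnostics: Path | None = None
    layout: ReadLayout = field(default_factory=ReadLayout)
    tailcall: TailCallParams = field(default_factory=TailCallParams)
    dedup_mode: str = "exact"
    stratify: str = "reference"
    out_dir: Path = Path("racetails_out")
    seed: int = 0
    figures: bool = False

    def __post_init__(self) -> None:
        if self.tailcall.window < 1:
            raise ConfigError("window must be >= 1")
        if self.dedup_mode not in ("exact", "directional-1mm"):
            raise ConfigError(f"unknown dedup mode {self.dedup_mode!r}")
        for path in (self.references, self.sample_sheet, self.diagnostics):
            if path is not None and not Path(path).exists():
                raise ConfigError(f"configured path does not exist: {path}")


def load_config(path: str | Path, **overrides: Any) -> RunConfig:
    """Load YAML config; keyword overrides win over file values."""
    with open(path) as fh:
        raw: Mapping[str, Any] = yaml.safe_load(fh) or {}
    raw = {**raw, **{k: v for k, v in overrides.items() if v is not None}}
    base = Path(path).parent

    def _resolve(p: Any) -> Path | None:
        if p is None:
            return None
        p = Path(p)
        return p if p.is_absolute() else base / p

    layout_kwargs = dict(raw.get("layout", {}))
    tolerances = dict(raw.get("tolerances", {}))
    layout = ReadLayout(
        umi_len=int(layout_kwargs.get("umi_len", 15)),
        delimiter=str(layout_kwargs.get("delimiter", "CTGC")).upper(),
        index_len=int(layout_kwargs.get("index_len", 6)),
        index_in_r2=bool(layout_kwargs.get("index_in_r2", False)),
        max_index_mismatch=int(tolerances.get("index", 1)),
        max_delim_mismatch=int(tolerances.get("delimiter", 1)),
        min_mean_q=float(tolerances.get("min_mean_q", 20.0)),
    )
    tailcall = TailCallParams(
        window=int(raw.get("window", 80)),
        tolerance=int(tolerances.get("tail", 0)),
        max_mismatch_rate=float(tolerances.get("anchor_mismatch_rate", 0.05)),
        min_anchor=int(tolerances.get("min_anchor", 12)),
        max_gap=int(tolerances.get("max_gap", 3)),
        delimiter=layout.delimiter,
    )
    try:
        return RunConfig(
            references=_resolve(raw["references"]),
            sample_sheet=_resolve(raw["sample_sheet"]),
            reference_meta=dict(raw.get("reference_meta", {})),
            diagnostics=_resolve(raw.get("diagnostics")),
            layout=layout,
            tailcall=tailcall,
            dedup_mode=str(raw.get("dedup_mode", "exact")),
            stratify=str(raw.get("stratify", "reference")),
            out_dir=Path(raw.get("out_dir", "racetails_out")),
            seed=int(raw.get("seed", 0)),
            figures=bool(raw.get("figures", False)),
        )
    except KeyError as exc:
        raise ConfigError(f"missing required config key: {exc}") from exc
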