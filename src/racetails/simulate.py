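"""Ground-truth simulator for targeted 3' RACE-seq libraries.

Emulates the library chemistry end to end: molecules with templated 3'
ends drawn from reference amplicons, non-templated tails from the four
classes {A, AU, U, NONE}, ligation of a preadenylated adapter carrying a
15-nt random UMI and a fixed delimiter, a 6-nt sample index, PCR
duplication with a configurable copy distribution, and i.i.d. per-base
substitution errors in paired reads.

Read layout (all sequences DNA, U rendered as T):

* R1 (sense, from the nested forward primer):
  ``templated | A^a | T^u | revcomp(delimiter) | revcomp(UMI) | revcomp(adapter)``
* R2 (from the adapter side):
  ``UMI | delimiter | revcomp(tail) | revcomp(templated ...)``

so the first sequenced R2 base after the delimiter is the complement of
the molecule's 3'-terminal nucleotide — the base that identifies
terminal uridylation even when the tail is longer than the read.

The sample index is written into the Illumina-style header comment
(``1:N:0:INDEX``) by default, or in-line at the start of R2 when
``index_in_r2`` is set.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .references import DiagnosticTable, ReferenceAmplicon
from .seq import revcomp

#: Illumina TruSeq small-RNA 3' adapter (RA3); the constant part read
#: by R1 after the UMI.  Configurable, like every layout element.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

#: Placeholder delimiter separating UMI from payload.  The real
#: experiment-specific delimiter must be supplied via config.
DEFAULT_DELIMITER = "CTGC"

TAIL_CLASSES = ("A", "AU", "U", "NONE")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimulationError(ValueError):
    """Invalid simulator configuration."""


@dataclass(frozen=True)
class Molecule:
    """A simulated ground-truth RNA 3' end."""

    molecule_id: str
    reference: str
    subfamily: str | None
    templated_end: int  # 0-based offset of last templated base used
    a_len: int
    u_len: int
    pcr_copies: int
    umi: str

    @property
    def true_class(self) -> str:
        if self.a_len > 0:
            return "AU" if self.u_len > 0 else "A"
        return "U" if self.u_len > 0 else "NONE"


@dataclass
class LibraryParams:
    """Library-prep and sequencing parameters.

    Defaults emulate the study conditions: a 15-nt UMI, 6-nt index,
    negative-binomial poly(A) lengths with a wild-type-like median near
    47 nt, short geometric U tails, modest PCR duplication from a
    21+21-cycle nested PCR, and a typical Illumina substitution rate.
    """

    class_probs: Mapping[str, float] = field(
        default_factory=lambda: {"A": 0.70, "AU": 0.15, "U": 0.02, "NONE": 0.13}
    )
    a_len_dist: Mapping[str, float] = field(
        default_factory=lambda: {"name": "nbinom", "mean": 45.0, "dispersion": 5.0}
    )
    u_len_dist: Mapping[str, float] = field(
        default_factory=lambda: {"name": "geometric", "mean": 2.0}
    )
    copy_dist: Mapping[str, float] = field(
        default_factory=lambda: {"name": "shifted_poisson", "mean": 3.0}
    )
    error_rate: float = 0.001
    read_len_r1: int = 150
    read_len_r2: int = 100
    umi_len: int = 15
    index: str = "ACGTAC"
    delimiter: str = DEFAULT_DELIMITER
    adapter: str = DEFAULT_ADAPTER
    index_in_r2: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_probs.get(c, 0.0) for c in TAIL_CLASSES)
        if abs(total - 1.0) > 1e-9:
            raise SimulationError(
                f"class_probs must sum to 1 over {TAIL_CLASSES}, got {total}"
            )
        if any(p < 0 for p in self.class_probs.values()):
            raise SimulationError("class_probs must be non-negative")
        if not 0.0 <= self.error_rate < 1.0:
            raise SimulationError(f"error_rate {self.error_rate} outside [0, 1)")
        if len(self.index) != 6:
            raise SimulationError(
                f"sample index must be 6 nt, got {self.index!r}"
            )
        if self.umi_len < 1:
            raise SimulationError("umi_len must be >= 1")


def _draw_lengths(dist: Mapping[str, float], size: int, rng: np.random.Generator,
                  minimum: int) -> np.ndarray:
    """Draw tail lengths >= ``minimum`` from a named distribution."""
    name = dist.get("name")
    if name == "nbinom":
        mean = float(dist["mean"])
        r = float(dist["dispersion"])
        if mean <= 0 or r <= 0:
            raise SimulationError(f"nbinom needs positive mean/dispersion: {dist}")
        p = r / (r + mean)
        draw = lambda k: rng.negative_binomial(r, p, size=k)
    elif name == "geometric":
        mean = float(dist["mean"])
        if mean < 1:
            raise SimulationError(f"geometric mean must be >= 1: {dist}")
        draw = lambda k: rng.geometric(1.0 / mean, size=k)  # support >= 1
    elif name == "fixed":
        k0 = int(dist["k"])
        if k0 < minimum:
            raise SimulationError(f"fixed length {k0} below minimum {minimum}")
        draw = lambda k: np.full(k, k0, dtype=np.int64)
    elif name == "uniform":
        lo, hi = int(dist["low"]), int(dist["high"])
        if lo < minimum or hi < lo:
            raise SimulationError(f"bad uniform bounds: {dist}")
        draw = lambda k: rng.integers(lo, hi + 1, size=k)
    else:
        raise SimulationError(f"unknown length distribution {name!r}")

    out = draw(size)
    # zero-truncate by redrawing, preserving the conditional distribution
    while minimum > 0:
        low = out < minimum
        if not low.any():
            break
        out[low] = draw(int(low.sum()))
    return out.astype(np.int64)


def _draw_copies(dist: Mapping[str, float], size: int,
                 rng: np.random.Generator) -> np.ndarray:
    name = dist.get("name")
    if name == "shifted_poisson":
        mean = float(dist["mean"])
        if mean < 1:
            raise SimulationError(f"shifted_poisson mean must be >= 1: {dist}")
        return 1 + rng.poisson(mean - 1.0, size=size)
    if name == "fixed":
        k = int(dist["k"])
        if k < 1:
            raise SimulationError(f"pcr copy count must be >= 1, got {k}")
        return np.full(size, k, dtype=np.int64)
    if name == "geometric":
        mean = float(dist["mean"])
        if mean < 1:
            raise SimulationError(f"geometric mean must be >= 1: {dist}")
        return rng.geometric(1.0 / mean, size=size)
    raise SimulationError(f"unknown copy distribution {name!r}")


def _random_kmers(n: int, k: int, rng: np.random.Generator,
                  distinct: bool = False) -> list[str]:
    arr = _BASES[rng.integers(0, 4, size=(n, k))]
    kmers = [bytes(row).decode() for row in arr]
    if distinct:
        # molecule UMIs are drawn without replacement: at library scale
        # (n << 4^k) this is indistinguishable from i.i.d. draws and
        # keeps one UMI == one molecule, so dedup counts molecules
        seen: set[str] = set()
        for i, umi in enumerate(kmers):
            while umi in seen:
                umi = bytes(_BASES[rng.integers(0, 4, size=k)]).decode()
            seen.add(umi)
            kmers[i] = umi
    return kmers


def simulate_molecules(
    n: int,
    params: LibraryParams,
    refs: Sequence[ReferenceAmplicon],
    diagnostics: Mapping[str, DiagnosticTable] | None = None,
    subfamily_probs: Mapping[str, float] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[Molecule], pd.DataFrame]:
    """Draw ``n`` ground-truth molecules.

    References are chosen uniformly.  When a reference has a diagnostic
    table, each molecule is assigned a subfamily (uniformly, or per
    ``subfamily_probs``) whose diagnostic bases are later patched into
    the templated sequence during rendering.

    Returns the molecules and a tidy ground-truth table with one row
    per molecule.
    """
    if n < 1:
        raise SimulationError(f"n must be >= 1, got {n}")
    if not refs:
        raise SimulationError("at least one reference amplicon is required")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    diagnostics = diagnostics or {}

    probs = np.array([params.class_probs.get(c, 0.0) for c in TAIL_CLASSES])
    classes = rng.choice(len(TAIL_CLASSES), size=n, p=probs / probs.sum())
    ref_idx = rng.integers(0, len(refs), size=n)
    a_lens = _draw_lengths(params.a_len_dist, n, rng, minimum=1)
    u_lens = _draw_lengths(params.u_len_dist, n, rng, minimum=1)
    copies = _draw_copies(params.copy_dist, n, rng)
    umis = _random_kmers(n, params.umi_len, rng, distinct=True)

    molecules = []
    for i in range(n):
        cls = TAIL_CLASSES[classes[i]]
        ref = refs[ref_idx[i]]
        table = diagnostics.get(ref.name)
        subfamily = None
        if table is not None and table.subfamilies:
            names = list(table.subfamilies)
            if subfamily_probs:
                w = np.array([subfamily_probs.get(s, 0.0) for s in names])
                subfamily = names[rng.choice(len(names), p=w / w.sum())]
            else:
                subfamily = names[rng.integers(0, len(names))]
        molecules.append(
            Molecule(
                molecule_id=f"m{i:07d}",
                reference=ref.name,
                subfamily=subfamily,
                templated_end=ref.terminus,
                a_len=int(a_lens[i]) if cls in ("A", "AU") else 0,
                u_len=int(u_lens[i]) if cls in ("AU", "U") else 0,
                pcr_copies=int(copies[i]),
                umi=umis[i],
            )
        )

    truth = pd.DataFrame(
        {
            "molecule_id": [m.molecule_id for m in molecules],
            "reference": [m.reference for m in molecules],
            "subfamily": [m.subfamily or "" for m in molecules],
            "templated_end": [m.templated_end for m in molecules],
            "true_class": [m.true_class for m in molecules],
            "a_len": [m.a_len for m in molecules],
            "u_len": [m.u_len for m in molecules],
            "pcr_copies": [m.pcr_copies for m in molecules],
            "umi": [m.umi for m in molecules],
        }
    )
    return molecules, truth


def _variant_sequence(
    ref: ReferenceAmplicon,
    subfamily: str | None,
    diagnostics: Mapping[str, DiagnosticTable],
    cache: dict,
) -> str:
    """Reference sequence with the subfamily's diagnostic bases patched in."""
    key = (ref.name, subfamily)
    if key in cache:
        return cache[key]
    seq = ref.sequence
    if subfamily is not None:
        table = diagnostics.get(ref.name)
        if table is not None:
            chars = list(seq)
            for pos, by_subfam in table.entries:
                chars[pos] = by_subfam[subfamily]
            seq = "".join(chars)
    cache[key] = seq
    return seq


def _apply_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0.0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < error_rate)[0]
    if hits.size == 0:
        return seq
    # substitute with a uniformly chosen *different* base
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return bytes(arr).decode()


def render_reads(
    molecules: Iterable[Molecule],
    params: LibraryParams,
    refs: Sequence[ReferenceAmplicon],
    diagnostics: Mapping[str, DiagnosticTable] | None = None,
    rng: np.random.Generator | None = None,
) -> Iterator[tuple[str, str, str, str, str]]:
    """Render paired reads: yields (name, r1_seq, r1_qual, r2_seq, r2_qual).

    One read pair per PCR copy.  Read names encode the molecule id and
    copy number for test-only traceability; the sample index is placed
    in the header comment unless ``index_in_r2`` is set.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed + 1)
    diagnostics = diagnostics or {}
    refs_by_name = {r.name: r for r in refs}
    cache: dict = {}

    for mol in molecules:
        ref = refs_by_name[mol.reference]
        variant = _variant_sequence(ref, mol.subfamily, diagnostics, cache)
        templated = variant[: mol.templated_end + 1]
        tail = "A" * mol.a_len + "T" * mol.u_len
        r1_full = (
            templated[ref.primer_offset:]
            + tail
            + revcomp(params.delimiter)
            + revcomp(mol.umi)
            + revcomp(params.adapter)
        )
        r2_prefix = (params.index if params.index_in_r2 else "") + mol.umi
        r2_full = r2_prefix + params.delimiter + revcomp(templated + tail)
        r1 = r1_full[: params.read_len_r1]
        r2 = r2_full[: params.read_len_r2]
        for copy in range(mol.pcr_copies):
            r1_err = _apply_errors(r1, params.error_rate, rng)
            r2_err = _apply_errors(r2, params.error_rate, rng)
            name = f"{mol.molecule_id}:{copy}"
            yield name, r1_err, "I" * len(r1_err), r2_err, "I" * len(r2_err)


def _open_out(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "wt")
    return open(path, "w")


def write_paired_fastq(
    read_pairs: Iterable[tuple[str, str, str, str, str]],
    r1_path: str | Path,
    r2_path: str | Path,
    index: str,
) -> int:
    """Write rendered pairs to FASTQ(.gz); returns the pair count."""
    n = 0
    with _open_out(r1_path) as f1, _open_out(r2_path) as f2:
        for name, r1, q1, r2, q2 in read_pairs:
            f1.write(f"@{name} 1:N:0:{index}\n{r1}\n+\n{q1}\n")
            f2.write(f"@{name} 2:N:0:{index}\n{r2}\n+\n{q2}\n")
            n += 1
    return n


def simulate_sample(
    sample: str,
    n: int,
    params: LibraryParams,
    refs: Sequence[ReferenceAmplicon],
    out_dir: str | Path,
    diagnostics: Mapping[str, DiagnosticTable] | None = None,
    subfamily_probs: Mapping[str, float] | None = None,
    gzip_output: bool = False,
) -> dict:
    """Simulate one sample end to end and write FASTQ + ground truth.

    Returns a manifest dict (also written as JSON next to the outputs).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(params.seed)
    molecules, truth = simulate_molecules(
        n, params, refs, diagnostics, subfamily_probs, rng
    )
    ext = ".fastq.gz" if gzip_output else ".fastq"
    r1_path = out_dir / f"{sample}_R1{ext}"
    r2_path = out_dir / f"{sample}_R2{ext}"
    pairs = render_reads(molecules, params, refs, diagnostics, rng)
    n_pairs = write_paired_fastq(pairs, r1_path, r2_path, params.index)
    truth_path = out_dir / f"{sample}_truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    manifest = {
        "sample": sample,
        "n_molecules": n,
        "n_read_pairs": n_pairs,
        "params": _params_to_jsonable(params),
        "r1": r1_path.name,
        "r2": r2_path.name,
        "truth": truth_path.name,
    }
    with open(out_dir / f"{sample}_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _params_to_jsonable(params: LibraryParams) -> dict:
    out = asdict(params)
    for key, val in out.items():
        if isinstance(val, Mapping):
            out[key] = dict(val)
    return out
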