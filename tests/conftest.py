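import importlib.resources as ir

import numpy as np
import pytest
import yaml
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from racetails.readparse import ReadLayout, parse_pairs
from racetails.references import load_diagnostics, load_references
from racetails.simulate import LibraryParams, render_reads, simulate_molecules

DATA = ir.files("racetails") / "data"


@pytest.fixture(scope="session")
def reference_meta():
    cfg = yaml.safe_load((DATA / "example_config.yaml").read_text())
    return cfg["reference_meta"]


@pytest.fixture(scope="session")
def refs(reference_meta):
    return load_references(str(DATA / "synthetic_references.fasta"), reference_meta)


@pytest.fixture(scope="session")
def diagnostics(refs):
    return load_diagnostics(str(DATA / "synthetic_diagnostics.tsv"), refs)


@pytest.fixture(scope="session")
def l1_table(diagnostics):
    return diagnostics["L1_consensus"]


def simulate_parsed(
    refs,
    n,
    seed,
    diagnostics=None,
    sample="sample1",
    index="ACGTAC",
    layout=None,
    **param_overrides,
):
    """Simulate n molecules and return (molecules, parsed read pairs)."""
    params = LibraryParams(index=index, seed=seed, **param_overrides)
    rng = np.random.default_rng(seed)
    molecules, _ = simulate_molecules(n, params, refs, diagnostics, rng=rng)
    rendered = render_reads(molecules, params, refs, diagnostics, rng)
    raw = [
        (f"{name} 1:N:0:{index}", r1, q1, r2, q2)
        for name, r1, q1, r2, q2 in rendered
    ]
    parsed, report = parse_pairs(raw, {index: sample}, layout or ReadLayout())
    assert report.total == sum(m.pcr_copies for m in molecules)
    return molecules, parsed
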