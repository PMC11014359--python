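"""Small sequence utilities shared across the pipeline.

All sequences are plain Python strings over A/C/G/T/N, sense strand,
5'->3' unless a function says otherwise. U is represented as T on the
DNA level; classification treats them as equivalent.
"""

from __future__ import annotations

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement. An involution: revcomp(revcomp(s)) == s."""
    return seq.translate(_COMP)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"hamming: unequal lengths {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def check_alphabet(seq: str, context: str = "sequence") -> None:
    """Raise ValueError if seq contains characters outside A/C/G/T/N."""
    bad = set(seq.upper()) - VALID_BASES
    if bad:
        raise ValueError(
            f"{context} contains characters outside A/C/G/T/N: {sorted(bad)}"
        )


def mean_quality(qual: str) -> float:
    """Mean Phred quality of a Sanger-encoded (offset 33) quality string."""
    if not qual:
        return 0.0
    return sum(ord(c) - 33 for c in qual) / len(qual)
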