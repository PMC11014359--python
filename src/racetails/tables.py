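"""Serialization of tail calls to/from tidy TSV.

Internal coordinates are 0-based half-open; the ``anchor`` column in
files is 1-based inclusive, per the human convention used in every
user-facing report.
"""

from __future__ import annotations

from pathlib import Path
from typing import IO, Sequence

import pandas as pd

from .tailcall import TailCall

CALL_COLUMNS = [
    "sample",
    "key",
    "umi",
    "reference",
    "subfamily",
    "class",
    "a_len",
    "u_len",
    "total_len",
    "censored",
    "window",
    "anchor",
    "flags",
]


def calls_to_frame(calls: Sequence[TailCall]) -> pd.DataFrame:
    rows = [
        (
            c.sample,
            c.key,
            c.umi,
            c.reference,
            c.subfamily or "",
            c.tail_class,
            c.a_len,
            c.u_len,
            c.total_len,
            c.censored,
            c.window,
            c.anchor + 1,  # 1-based in files
            ";".join(sorted(c.flags)),
        )
        for c in calls
    ]
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def write_calls(
    calls: Sequence[TailCall],
    path: str | Path,
    group_sizes: Sequence[int] | None = None,
) -> Path:
    frame = calls_to_frame(calls)
    if group_sizes is not None:
        frame["group_size"] = list(group_sizes)
    path = Path(path)
    frame.to_csv(path, sep="\t", index=False)
    return path


def read_calls(source: str | Path | IO[str]) -> list[TailCall]:
    df = pd.read_csv(source, sep="\t", dtype={"flags": str, "subfamily": str})
    df = df.rename(columns={"class": "tail_class"})
    calls = []
    for row in df.itertuples(index=False):
        flags = getattr(row, "flags", "")
        flags = frozenset(str(flags).split(";")) - {"", "nan"} if pd.notna(flags) else frozenset()
        subfamily = getattr(row, "subfamily", "")
        calls.append(
            TailCall(
                sample=row.sample,
                key=str(row.key),
                umi=row.umi,
                reference=row.reference,
                subfamily=None if pd.isna(subfamily) or subfamily == "" else subfamily,
                tail_class=row.tail_class,
                a_len=row.a_len,
                u_len=row.u_len,
                censored=bool(row.censored),
                window=int(row.window),
                anchor=int(row.anchor) - 1,
                flags=flags,
            )
        )
    return calls
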