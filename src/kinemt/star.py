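"""Minimal STAR file reader/writer for the Relion particle dialect.

Handles ``data_`` blocks containing either a ``loop_`` table or simple
key-value pairs. Columns are returned as a :class:`pandas.DataFrame` with
``rln``-prefixed names preserved. This is deliberately a small, dependency-
free subset of the format: quoted strings and multi-line semicolon blocks
are not supported (Relion particle tables do not use them).
"""

from __future__ import annotations

import io
from pathlib import Path

import pandas as pd


def read_star(path) -> dict[str, pd.DataFrame]:
    """Parse a STAR file into ``{block_name: DataFrame}``.

    Key-value blocks are returned as single-row DataFrames.
    """
    text = Path(path).read_text()
    blocks: dict[str, pd.DataFrame] = {}
    current_name = None
    pending_kv: dict[str, str] = {}

    def flush_kv():
        nonlocal pending_kv
        if current_name is not None and pending_kv:
            blocks[current_name] = pd.DataFrame([pending_kv])
        pending_kv = {}

    line_iter = list(text.splitlines())
    i = 0
    while i < len(line_iter):
        line = line_iter[i].strip()
        i += 1
        if not line or line.startswith("#"):
            continue
        if line.startswith("data_"):
            flush_kv()
            current_name = line[len("data_"):]
            continue
        if line == "loop_":
            columns = []
            while i < len(line_iter):
                nxt = line_iter[i].strip()
                if nxt.startswith("_"):
                    columns.append(nxt.split()[0].lstrip("_"))
                    i += 1
                else:
                    break
            rows = []
            while i < len(line_iter):
                nxt = line_iter[i].strip()
                if not nxt or nxt.startswith(("data_", "loop_", "_", "#")):
                    break
                rows.append(nxt.split())
                i += 1
            blocks[current_name or ""] = _coerce_numeric(
                pd.DataFrame(rows, columns=columns)
            )
            continue
        if line.startswith("_"):
            parts = line.split(None, 1)
            key = parts[0].lstrip("_")
            pending_kv[key] = parts[1] if len(parts) > 1 else ""
            continue
    flush_kv()
    return blocks


def _coerce_numeric(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        converted = pd.to_numeric(out[col], errors="coerce")
        if not converted.isna().any():
            out[col] = converted
    return out


def write_star(blocks: dict[str, pd.DataFrame], path) -> None:
    """Write ``{block_name: DataFrame}`` as a loop_-style STAR file."""
    buf = io.StringIO()
    for name, df in blocks.items():
        buf.write(f"\ndata_{name}\n\nloop_\n")
        for j, col in enumerate(df.columns, start=1):
            buf.write(f"_{col} #{j}\n")
        for row in df.itertuples(index=False):  # preserves per-column dtypes
            buf.write(" ".join(_format_value(v) for v in row) + "\n")
        buf.write("\n")
    Path(path).write_text(buf.getvalue())


def _format_value(v) -> str:
    if isinstance(v, float):
        return f"{v:.6f}"
    return str(v)
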