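"""Text-format input/output: per-cytosine reports, calls, BED, expression.

The per-cytosine report is a plain TSV with columns
``contig  pos(1-based)  strand  context  m  n`` — the common cytosine-report
dialect. All BED output is 0-based half-open.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def write_counts_tsv(sites: pd.DataFrame, counts: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "contig": sites["contig"].to_numpy(),
            "pos": sites["pos"].to_numpy() + 1,
            "strand": sites["strand"].to_numpy(),
            "context": sites["context"].to_numpy(),
            "m": counts["m"].to_numpy(),
            "n": counts["n"].to_numpy(),
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Returns (sites, counts) with 0-based positions."""
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    sites = df[["contig", "strand", "context"]].copy()
    sites["pos"] = df["pos"].to_numpy() - 1
    sites = sites[["contig", "pos", "strand", "context"]]
    counts = df[["m", "n"]].astype(np.int64)
    return sites, counts


def write_calls_tsv(calls: pd.DataFrame, path: str | Path) -> None:
    out = calls.copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", index=False)


def write_bed(intervals: pd.DataFrame, path: str | Path, extra_cols: list[str] | None = None) -> None:
    """BED6+ from a frame with contig/start/end (+ optional label and extras)."""
    cols = ["contig", "start", "end"]
    df = intervals.copy()
    if "label" not in df.columns:
        df["label"] = "."
    df["score"] = 0
    df["strand"] = "."
    out = df[cols + ["label", "score", "strand"] + (extra_cols or [])]
    out.to_csv(path, sep="\t", index=False, header=False)


def write_expression_tsv(expression: pd.Series | pd.DataFrame, path: str | Path) -> None:
    expression.to_csv(path, sep="\t")


def read_expression_tsv(path: str | Path, value_col: str | None = None) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    col = value_col or df.columns[0]
    return df[col]


def read_grouping_tsv(path: str | Path) -> pd.Series:
    """gene_id → group label (two-column TSV, with or without header)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.iloc[0, 0] in ("gene_id", "gene"):
        df = df.iloc[1:]
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].to_numpy(), name="group")
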