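"""Small shared helpers: sequence encoding, interval arithmetic, site slicing."""

from __future__ import annotations

import numpy as np
import pandas as pd

# uint8 codes for DNA bases (ASCII)
A, C, G, T, N = 65, 67, 71, 84, 78

_COMP = np.zeros(256, dtype=np.uint8)
_COMP[A], _COMP[C], _COMP[G], _COMP[T], _COMP[N] = T, G, C, A, N

_TRANS_RC = bytes.maketrans(b"ACGTN", b"TGCAN")


def seq_to_array(seq: str) -> np.ndarray:
    """Encode an uppercase DNA string as a uint8 array of ASCII codes."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_TRANS_RC)[::-1]


def revcomp_array(arr: np.ndarray) -> np.ndarray:
    return _COMP[arr][::-1]


def contig_bounds(sites: pd.DataFrame) -> dict[str, tuple[int, int]]:
    """Row-index [start, end) per contig of a contig-sorted site table."""
    out: dict[str, tuple[int, int]] = {}
    if len(sites) == 0:
        return out
    contigs = sites["contig"].to_numpy()
    change = np.nonzero(contigs[1:] != contigs[:-1])[0] + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(sites)]))
    for s, e in zip(starts, ends):
        out[contigs[s]] = (int(s), int(e))
    return out


def sites_in_interval(
    sites: pd.DataFrame,
    bounds: dict[str, tuple[int, int]],
    contig: str,
    start: int,
    end: int,
) -> np.ndarray:
    """Positional row indices of sites with start <= pos < end on contig.

    ``sites`` must be sorted by (contig, pos); ``bounds`` from contig_bounds.
    """
    if contig not in bounds:
        return np.empty(0, dtype=np.int64)
    lo, hi = bounds[contig]
    pos = sites["pos"].to_numpy()[lo:hi]
    i = np.searchsorted(pos, start, side="left")
    j = np.searchsorted(pos, end, side="left")
    return np.arange(lo + i, lo + j, dtype=np.int64)


def merge_intervals(iv: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or book-ended half-open intervals."""
    if not iv:
        return []
    iv = sorted(iv)
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]
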