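"""CpG-island detection, methylation classification, and genomic assignment.

An island is a maximal interval with (G+C) content above 55%, observed/
expected CpG ratio of at least 65% and length above 500 bp, where
obs/exp = (#CpG × L) / (#C × #G). Detection is a Takai–Jones-style scan:
mark every qualifying 501-bp window, merge overlapping marked windows, then
trim each merged region to its longest qualifying sub-interval (leftmost on
ties). An island is *methylated* when at least 70% of its CpG dinucleotides
carry a methylcytosine call on either strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GeneModel, GenomeSequence, cg_dyads
from .util import C, G, N, seq_to_array

logger = logging.getLogger(__name__)

WINDOW = 501
MIN_GC = 0.55  # exclusive
MIN_OBS_EXP = 0.65  # inclusive
MIN_LEN = 501  # "more than 500 bp"
METHYLATED_FRACTION = 0.70  # inclusive


@dataclass
class CpGIsland:
    contig: str
    start: int
    end: int
    gc_fraction: float
    obs_exp_cpg: float
    cpg_count: int
    methylated_cpg_fraction: float | None = None
    methylation_class: str | None = None
    region_class: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class _SeqStats:
    """O(1) interval GC / CpG / N statistics via prefix sums."""

    def __init__(self, seq: str):
        arr = seq_to_array(seq)
        self.L = len(arr)
        self.c = np.concatenate(([0], np.cumsum(arr == C)))
        self.g = np.concatenate(([0], np.cumsum(arr == G)))
        self.n = np.concatenate(([0], np.cumsum(arr == N)))
        cpg = (arr[:-1] == C) & (arr[1:] == G) if self.L > 1 else np.zeros(0, bool)
        self.cpg = np.concatenate(([0], np.cumsum(cpg), [np.sum(cpg)]))  # len L+1

    def stats(self, s: int, e: int) -> tuple[float, float, int, bool]:
        """(gc_fraction, obs_exp, cpg_count, has_n) for [s, e)."""
        L = e - s
        nc = int(self.c[e] - self.c[s])
        ng = int(self.g[e] - self.g[s])
        ncpg = int(self.cpg[e - 1] - self.cpg[s]) if e - 1 > s else 0
        has_n = bool(self.n[e] - self.n[s])
        gc = (nc + ng) / L
        oe = (ncpg * L) / (nc * ng) if nc and ng else 0.0
        return gc, oe, ncpg, has_n

    def qualifies(self, s: int, e: int) -> bool:
        gc, oe, _, has_n = self.stats(s, e)
        return (not has_n) and gc > MIN_GC and oe >= MIN_OBS_EXP


def _qualifying_window_starts(st: _SeqStats) -> np.ndarray:
    L = st.L
    if L < WINDOW:
        return np.empty(0, dtype=np.int64)
    s = np.arange(L - WINDOW + 1)
    e = s + WINDOW
    nc = st.c[e] - st.c[s]
    ng = st.g[e] - st.g[s]
    ncpg = st.cpg[e - 1] - st.cpg[s]
    has_n = (st.n[e] - st.n[s]) > 0
    gc_ok = (nc + ng) / WINDOW > MIN_GC
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where((nc > 0) & (ng > 0), ncpg * WINDOW / np.maximum(nc * ng, 1), 0.0)
    return np.flatnonzero(~has_n & gc_ok & (oe >= MIN_OBS_EXP))


def _trim_longest(st: _SeqStats, lo: int, hi: int) -> tuple[int, int] | None:
    """Longest (leftmost on ties) qualifying sub-interval of [lo, hi)."""
    span = hi - lo
    for length in range(span, MIN_LEN - 1, -1):
        for s in range(lo, hi - length + 1):
            if st.qualifies(s, s + length):
                return s, s + length
    return None


def find_cpg_islands(genome: GenomeSequence) -> list[CpGIsland]:
    """Scan every contig; returns non-overlapping islands sorted by position."""
    if len(genome) == 0:
        raise ValueError("empty genome")
    islands: list[CpGIsland] = []
    for contig, seq in genome.contigs.items():
        st = _SeqStats(seq)
        starts = _qualifying_window_starts(st)
        if len(starts) == 0:
            continue
        # merge windows that overlap or are book-ended (gap between starts <= WINDOW)
        breaks = np.flatnonzero(np.diff(starts) > WINDOW) + 1
        for chunk in np.split(starts, breaks):
            lo, hi = int(chunk[0]), int(chunk[-1]) + WINDOW
            trimmed = _trim_longest(st, lo, hi)
            if trimmed is None:
                continue
            s, e = trimmed
            gc, oe, ncpg, _ = st.stats(s, e)
            islands.append(CpGIsland(contig, s, e, gc, oe, ncpg))
    # self-validation: every reported island re-checks the criteria
    for isl in islands:
        assert isl.length > 500 and isl.gc_fraction > MIN_GC and isl.obs_exp_cpg >= MIN_OBS_EXP
    logger.info("find_cpg_islands: %d islands", len(islands))
    return islands


def islands_frame(islands: list[CpGIsland]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "contig": [i.contig for i in islands],
            "start": [i.start for i in islands],
            "end": [i.end for i in islands],
            "gc_fraction": [i.gc_fraction for i in islands],
            "obs_exp_cpg": [i.obs_exp_cpg for i in islands],
            "cpg_count": [i.cpg_count for i in islands],
            "methylation_class": [i.methylation_class for i in islands],
            "region_class": [i.region_class for i in islands],
        }
    )


def classify_cgi_methylation(
    island: CpGIsland,
    sites: pd.DataFrame,
    called: np.ndarray,
    counts: pd.DataFrame | None = None,
    dyads: pd.DataFrame | None = None,
) -> CpGIsland:
    """Set ``methylated_cpg_fraction`` and ``methylation_class`` in place.

    A CpG dyad counts as methylated when the cytosine on either strand is a
    called methylcytosine; the denominator is all CpG dinucleotides of the
    island. Islands with zero read-covered dyads get class ``unknown``.
    """
    if dyads is None:
        dyads = cg_dyads(sites)
    sel = dyads[
        (dyads["contig"] == island.contig)
        & (dyads["pos"] >= island.start)
        & (dyads["pos"] + 2 <= island.end)
    ]
    total = len(sel)
    called = np.asarray(called)

    def strand_flag(idx: np.ndarray, values: np.ndarray) -> np.ndarray:
        out = np.zeros(len(idx), dtype=bool)
        ok = idx >= 0
        out[ok] = values[idx[ok]]
        return out

    ip = sel["idx_plus"].to_numpy()
    im = sel["idx_minus"].to_numpy()
    meth = strand_flag(ip, called) | strand_flag(im, called)
    if counts is not None:
        nvals = counts["n"].to_numpy() >= 1
        covered = strand_flag(ip, nvals) | strand_flag(im, nvals)
        if total and not covered.any():
            island.methylation_class = "unknown"
            island.methylated_cpg_fraction = None
            logger.info("island %s:%d-%d has no covered dyads", island.contig, island.start, island.end)
            return island
    frac = float(meth.sum() / total) if total else 0.0
    island.methylated_cpg_fraction = frac
    island.methylation_class = "methylated" if frac >= METHYLATED_FRACTION else "unmethylated"
    return island


def assign_cgi_regions(
    islands: list[CpGIsland],
    genes: list[GeneModel],
    flank_bp: int = 2000,
) -> pd.DataFrame:
    """Assign each island (by midpoint) to gene_body/upstream/downstream/
    intergenic with that precedence; ties within a class resolve to the
    nearest TSS. Returns the proportions table; islands are annotated in
    place."""
    precedence = {"gene_body": 0, "upstream": 1, "downstream": 2}
    for isl in islands:
        mid = isl.midpoint
        best: tuple[int, int] | None = None  # (precedence, |mid - tss|)
        best_class = "intergenic"
        for gene in genes:
            if gene.contig != isl.contig:
                continue
            gs, ge = gene.start, gene.end
            if gs <= mid < ge:
                cls = "gene_body"
            elif gene.strand == "+" and gs - flank_bp <= mid < gs:
                cls = "upstream"
            elif gene.strand == "-" and ge <= mid < ge + flank_bp:
                cls = "upstream"
            elif gene.strand == "+" and ge <= mid < ge + flank_bp:
                cls = "downstream"
            elif gene.strand == "-" and gs - flank_bp <= mid < gs:
                cls = "downstream"
            else:
                continue
            key = (precedence[cls], abs(mid - gene.tss))
            if best is None or key < best:
                best = key
                best_class = cls
        isl.region_class = best_class
    classes = ("upstream", "gene_body", "downstream", "intergenic")
    n = max(len(islands), 1)
    props = pd.DataFrame(
        {
            "region_class": classes,
            "count": [sum(i.region_class == c for i in islands) for c in classes],
        }
    )
    props["proportion"] = props["count"] / n
    return props
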