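"""Differential methylation between two lines: per-CG Fisher tests with
Benjamini–Hochberg FDR and a two-fold level filter, then seed-extend-merge
DMR calling (1 kb windows, 100 bp steps, ≥4 differential mCGs to seed/extend,
≥5 sites and ≥1 kb to report), and association of DMRs with genes and
expression differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .genome import GeneModel

logger = logging.getLogger(__name__)


@dataclass
class DMRConfig:
    window_bp: int = 1000
    step_bp: int = 100
    seed_min_sites: int = 4
    final_min_sites: int = 5
    min_length_bp: int = 1000
    fdr: float = 0.05
    fold: float = 2.0
    #: pseudocount added to both levels before the fold ratio; 0 means a zero
    #: level with a non-zero partner always satisfies the fold criterion
    fold_pseudocount: float = 0.0

    def __post_init__(self) -> None:
        if self.step_bp > self.window_bp:
            raise ValueError("step must not exceed window")
        if min(self.window_bp, self.step_bp, self.seed_min_sites, self.final_min_sites,
               self.min_length_bp) <= 0 or not 0 < self.fdr < 1:
            raise ValueError("invalid DMR configuration")


def _fisher_cached(cache: dict, table: tuple[int, int, int, int]) -> float:
    p = cache.get(table)
    if p is None:
        a, b, c, d = table
        p = float(fisher_exact([[a, b], [c, d]])[1])
        cache[table] = p
    return p


def test_differential_sites(
    sites: pd.DataFrame,
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    config: DMRConfig | None = None,
) -> pd.DataFrame:
    """Two-sided Fisher's exact test per CG site covered in both lines.

    Returns one row per tested site: counts, levels, fisher_p, BH q_value,
    fold_satisfied and significant (= q ≤ fdr AND fold). The fold is the
    ratio of the larger to the smaller level; a zero level paired with a
    non-zero one satisfies the criterion (configurable pseudocount).
    """
    config = config or DMRConfig()
    cg = (sites["context"] == "CG").to_numpy()
    na = counts_a["n"].to_numpy()
    nb = counts_b["n"].to_numpy()
    ma = counts_a["m"].to_numpy()
    mb = counts_b["m"].to_numpy()
    tested = cg & (na >= 1) & (nb >= 1)
    skipped = int((cg & ~tested).sum())
    if skipped:
        logger.info("test_differential_sites: %d CG sites lack coverage in one line", skipped)
    idx = np.flatnonzero(tested)
    cache: dict[tuple[int, int, int, int], float] = {}
    pvals = np.array(
        [
            _fisher_cached(cache, (int(ma[i]), int(na[i] - ma[i]), int(mb[i]), int(nb[i] - mb[i])))
            for i in idx
        ]
    )
    if len(pvals):
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    else:
        qvals = pvals
    la = ma[idx] / na[idx]
    lb = mb[idx] / nb[idx]
    eps = config.fold_pseudocount
    hi = np.maximum(la, lb) + eps
    lo = np.minimum(la, lb) + eps
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(lo > 0, hi / lo, np.where(hi > 0, np.inf, 1.0))
    fold_ok = fold >= config.fold
    out = sites.iloc[idx][["contig", "pos", "strand"]].copy()
    out["m_a"], out["n_a"] = ma[idx], na[idx]
    out["m_b"], out["n_b"] = mb[idx], nb[idx]
    out["level_a"], out["level_b"] = la, lb
    out["fisher_p"] = pvals
    out["q_value"] = qvals
    out["fold_satisfied"] = fold_ok
    out["significant"] = (qvals <= config.fdr) & fold_ok
    return out.reset_index(drop=True)


@dataclass
class DMR:
    contig: str
    start: int  # merged window span
    end: int
    n_diff_sites: int
    direction: str  # hyper_in_A / hyper_in_B / mixed
    core_start: int  # span of member significant sites
    core_end: int
    associated_genes: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


def _candidate_runs(pos: np.ndarray, config: DMRConfig, contig_len: int | None) -> list[tuple[int, int]]:
    """Maximal runs of consecutive step-aligned qualifying windows.

    A window [s, s+window) qualifies when it holds >= seed_min_sites
    significant sites; growing a seed in step increments while the trailing
    window at the moving edge still qualifies is exactly the run of
    consecutive qualifying windows containing the seed.
    """
    w, step, k = config.window_bp, config.step_bp, config.seed_min_sites
    if len(pos) == 0:
        return []
    first = max((int(pos[0]) - w) // step, 0)
    last = int(pos[-1]) // step
    starts = np.arange(first, last + 1) * step
    counts = np.searchsorted(pos, starts + w, side="left") - np.searchsorted(pos, starts, side="left")
    ok = counts >= k
    if not ok.any():
        return []
    runs = []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], ok.view(np.int8), [0]))))
    for i, j in zip(edges[::2], edges[1::2]):
        s = int(starts[i])
        e = int(starts[j - 1]) + w
        if contig_len is not None:
            e = min(e, contig_len)
        runs.append((s, e))
    return runs


def find_dmrs(
    diff_sites: pd.DataFrame,
    config: DMRConfig | None = None,
    contig_lengths: dict[str, int] | None = None,
) -> list[DMR]:
    """Seed-extend-merge DMR calling over significant differential CG sites.

    Candidates (maximal grown window spans) are kept when they hold at least
    ``final_min_sites`` significant sites and span at least ``min_length_bp``,
    then overlapping or book-ended candidates are merged per contig. The
    direction is the majority sign of (level_a − level_b) over member sites;
    ``core_start``/``core_end`` record the span of the member sites.
    """
    config = config or DMRConfig()
    sig = diff_sites[diff_sites["significant"]]
    dmrs: list[DMR] = []
    for contig, grp in sig.groupby("contig", sort=False, observed=True):
        pos = np.sort(grp["pos"].to_numpy())
        clen = contig_lengths.get(contig) if contig_lengths else None
        runs = _candidate_runs(pos, config, clen)
        kept = []
        for s, e in runs:
            inside = (pos >= s) & (pos < e)
            if inside.sum() >= config.final_min_sites and e - s >= config.min_length_bp:
                kept.append([s, e])
        kept.sort()
        merged: list[list[int]] = []
        for s, e in kept:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        levels = grp.sort_values("pos")
        lpos = levels["pos"].to_numpy()
        delta = (levels["level_a"] - levels["level_b"]).to_numpy()
        for s, e in merged:
            sel = (lpos >= s) & (lpos < e)
            d = delta[sel]
            pos_in = lpos[sel]
            up = int((d > 0).sum())
            down = int((d < 0).sum())
            direction = "hyper_in_A" if up > down else ("hyper_in_B" if down > up else "mixed")
            dmrs.append(
                DMR(
                    contig=contig, start=int(s), end=int(e),
                    n_diff_sites=int(sel.sum()), direction=direction,
                    core_start=int(pos_in.min()), core_end=int(pos_in.max()) + 1,
                )
            )
    # re-check the defining thresholds
    for d in dmrs:
        assert d.n_diff_sites >= config.final_min_sites and d.length >= config.min_length_bp
    logger.info("find_dmrs: %d DMRs", len(dmrs))
    return dmrs


def dmrs_frame(dmrs: list[DMR]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "contig": [d.contig for d in dmrs],
            "start": [d.start for d in dmrs],
            "end": [d.end for d in dmrs],
            "n_diff_sites": [d.n_diff_sites for d in dmrs],
            "direction": [d.direction for d in dmrs],
            "core_start": [d.core_start for d in dmrs],
            "core_end": [d.core_end for d in dmrs],
            "associated_genes": [",".join(d.associated_genes) for d in dmrs],
        }
    )


def associate_dmrs_with_genes(
    dmrs: list[DMR],
    genes: list[GeneModel],
    flank_bp: int = 2000,
) -> pd.DataFrame:
    """A DMR associates with every gene whose span ±flank overlaps it by ≥1 bp."""
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for gene in genes:
        trees.setdefault(gene.contig, IntervalTree()).addi(
            gene.start - flank_bp, gene.end + flank_bp, gene.gene_id
        )
    rows = []
    for i, d in enumerate(dmrs):
        d.associated_genes = []
        for hit in sorted(trees.get(d.contig, IntervalTree()).overlap(d.start, d.end)):
            d.associated_genes.append(hit.data)
            rows.append((hit.data, i, d.contig, d.start, d.end, d.direction))
    return pd.DataFrame(
        rows, columns=["gene_id", "dmr_index", "contig", "start", "end", "direction"]
    )


def integrate_expression_differences(
    dmr_genes: pd.DataFrame,
    expression_a: pd.Series | dict,
    expression_b: pd.Series | dict,
    min_reads: int = 10,
    fold: float = 2.0,
) -> pd.DataFrame:
    """Flag DMR-associated genes by expression difference.

    Genes with both lines below ``min_reads`` are flagged not-expressed (the
    low-read removal); the fold is max/min of the two values and the two_fold
    flag requires a strict ``> fold`` change. Missing genes are retained and
    flagged.
    """
    ea = pd.Series(expression_a, dtype=float)
    eb = pd.Series(expression_b, dtype=float)
    rows = []
    for gene_id in pd.unique(dmr_genes["gene_id"]):
        a = float(ea[gene_id]) if gene_id in ea.index else np.nan
        b = float(eb[gene_id]) if gene_id in eb.index else np.nan
        if np.isnan(a) or np.isnan(b):
            rows.append((gene_id, a, b, "missing", np.nan, False, None))
            continue
        if a < min_reads and b < min_reads:
            rows.append((gene_id, a, b, "not_expressed", np.nan, False, None))
            continue
        lo, hi = min(a, b), max(a, b)
        fc = np.inf if lo == 0 else hi / lo
        higher = "A" if a > b else ("B" if b > a else "equal")
        rows.append((gene_id, a, b, "expressed", fc, bool(fc > fold), higher))
    return pd.DataFrame(
        rows,
        columns=["gene_id", "expr_a", "expr_b", "status", "fold_change", "two_fold", "higher_line"],
    )
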