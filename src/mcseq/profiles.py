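"""Region-level methylation metrics and comparative analyses.

Three region metrics are used throughout, following the field's conventions:

* relative level (mC/CG) — called methylcytosines over read-covered CG sites;
* absolute level (mC/Length) — called methylcytosines (all contexts) per bp;
* methylation degree — the mean of per-site m/n over covered CG sites.

On top of these: strand-aware promoter windows (−1.5 kb..+0.5 kb around the
TSS), metagene profiles over upstream / first exon / first intron / internal
exons / internal introns / last exon / downstream segments, repeat-element
profiles with flanks, matched random-region sampling, hyper/hypo gene
classification (≥70% / ≤30%), expression quintiles, pairwise Welch t-tests
between gene groups, and per-gene χ² divergence between two lines.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome import GeneModel, GenomeSequence
from .util import contig_bounds, sites_in_interval

logger = logging.getLogger(__name__)

SEGMENT_ORDER = (
    "upstream",
    "first_exon",
    "first_intron",
    "internal_exons",
    "internal_introns",
    "last_exon",
    "downstream",
)


@dataclass
class RegionMethylation:
    relative_level: float | None
    absolute_level: float
    mean_degree: float | None
    n_cg_covered: int
    n_cg_called: int
    n_called_total: int
    length: int


class MethylomeView:
    """Bundle of sites, counts and a call mask with fast interval slicing."""

    def __init__(self, sites: pd.DataFrame, counts: pd.DataFrame, called: np.ndarray):
        self.sites = sites
        self.counts = counts
        self.called = np.asarray(called, dtype=bool)
        self.bounds = contig_bounds(sites)
        self.pos = sites["pos"].to_numpy()
        self.is_cg = (sites["context"] == "CG").to_numpy()
        self.n = counts["n"].to_numpy()
        self.m = counts["m"].to_numpy()

    def idx(self, contig: str, start: int, end: int) -> np.ndarray:
        return sites_in_interval(self.sites, self.bounds, contig, start, end)


def region_methylation(
    view: MethylomeView, contig: str, start: int, end: int
) -> RegionMethylation:
    """All three metrics for [start, end); CG-only metrics are None when the
    region holds no covered CG site."""
    idx = view.idx(contig, start, end)
    cg = idx[view.is_cg[idx]]
    covered = cg[view.n[cg] >= 1]
    called_cg = cg[view.called[cg]]
    called_all = int(view.called[idx].sum())
    length = end - start
    if len(covered) == 0:
        rel = deg = None
    else:
        rel = float(len(called_cg) / len(covered))
        deg = float((view.m[covered] / view.n[covered]).mean())
    return RegionMethylation(
        relative_level=rel,
        absolute_level=called_all / length if length else 0.0,
        mean_degree=deg,
        n_cg_covered=len(covered),
        n_cg_called=len(called_cg),
        n_called_total=called_all,
        length=length,
    )


def promoter_region(
    gene: GeneModel, up: int = 1500, down: int = 500, contig_length: int | None = None
) -> tuple[int, int]:
    """Strand-aware promoter window −up..+down around the TSS, clipped."""
    if gene.strand == "+":
        s, e = gene.tss - up, gene.tss + down
    else:
        s, e = gene.tss - down, gene.tss + up
    s = max(s, 0)
    if contig_length is not None:
        e = min(e, contig_length)
    return s, e


# ---------------------------------------------------------------------------
# metagene profile


def _gene_segments(gene: GeneModel, flank_bp: int) -> dict[str, list[tuple[int, int]]]:
    """Genomic intervals per segment, listed 5'→3'. Single-exon genes carry
    the whole exon as first_exon (first/last merged); absent segments are
    empty lists."""
    ex = gene.exons  # already 5'→3'
    k = len(ex)
    if gene.strand == "+":
        up = [(gene.start - flank_bp, gene.start)]
        down = [(gene.end, gene.end + flank_bp)]
    else:
        up = [(gene.end, gene.end + flank_bp)]
        down = [(gene.start - flank_bp, gene.start)]
    introns: list[tuple[int, int]] = []
    genomic = sorted(ex)
    for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
        introns.append((e1, s2))
    if gene.strand == "-":
        introns = introns[::-1]
    seg = {name: [] for name in SEGMENT_ORDER}
    seg["upstream"] = up
    seg["downstream"] = down
    seg["first_exon"] = [ex[0]]
    if k >= 2:
        seg["last_exon"] = [ex[-1]]
        seg["first_intron"] = [introns[0]]
        seg["internal_introns"] = introns[1:]
    if k >= 3:
        seg["internal_exons"] = ex[1:-1]
    return seg


def _bin_metric(
    view: MethylomeView,
    gene: GeneModel,
    intervals: list[tuple[int, int]],
    bins: int,
    metric: str,
) -> np.ndarray:
    """Per-bin metric across a length-normalized concatenation of intervals
    (5'→3'; minus-strand coordinates reversed). NaN where undefined."""
    total = sum(e - s for s, e in intervals)
    out = np.full(bins, np.nan)
    if total <= 0:
        return out
    num = np.zeros(bins)
    den = np.zeros(bins)
    offset = 0
    for s, e in intervals:
        s_c, e_c = max(s, 0), e
        idx = view.idx(gene.contig, s_c, e_c)
        if metric != "absolute":
            idx = idx[view.is_cg[idx]]
        if len(idx):
            pos = view.pos[idx]
            if gene.strand == "+":
                off = offset + (pos - s)
            else:
                off = offset + (e - 1 - pos)
            b = np.minimum((off * bins) // total, bins - 1).astype(np.int64)
            if metric == "relative":
                cov = view.n[idx] >= 1
                np.add.at(den, b[cov], 1)
                np.add.at(num, b[cov & view.called[idx]], 1)
            elif metric == "degree":
                cov = view.n[idx] >= 1
                np.add.at(den, b[cov], 1)
                np.add.at(num, b[cov], (view.m[idx][cov] / view.n[idx][cov]))
            elif metric == "absolute":
                np.add.at(num, b[view.called[idx]], 1)
            else:
                raise ValueError(f"unknown metric {metric!r}")
        offset += e - s
    if metric == "absolute":
        den[:] = total / bins
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / den, np.nan)
    return out


@dataclass
class MetageneProfile:
    segments: tuple[str, ...]
    bins_per_segment: int
    metric: str
    #: (n_genes × bins) per segment; NaN where a gene lacks the segment/coverage
    per_gene: dict[str, np.ndarray]

    def table(self) -> pd.DataFrame:
        rows = []
        for seg in self.segments:
            mat = self.per_gene[seg]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                mean = np.nanmean(mat, axis=0)
                sd = np.nanstd(mat, axis=0, ddof=1)
            n = np.sum(~np.isnan(mat), axis=0)
            se = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), np.nan)
            for b in range(mat.shape[1]):
                rows.append((seg, b, mean[b], se[b], int(n[b])))
        return pd.DataFrame(rows, columns=["segment", "bin", "mean", "se", "n_genes"])


def metagene_profile(
    genes: list[GeneModel],
    view: MethylomeView,
    bins_per_segment: int = 20,
    flank_bp: int = 2000,
    metric: str = "relative",
) -> MetageneProfile:
    """Average metric per bin across genes for the seven canonical segments."""
    per_gene = {seg: np.full((len(genes), bins_per_segment), np.nan) for seg in SEGMENT_ORDER}
    for gi, gene in enumerate(genes):
        for seg, intervals in _gene_segments(gene, flank_bp).items():
            if intervals:
                per_gene[seg][gi] = _bin_metric(view, gene, intervals, bins_per_segment, metric)
    return MetageneProfile(SEGMENT_ORDER, bins_per_segment, metric, per_gene)


# ---------------------------------------------------------------------------
# element (repeat) profiles


@dataclass
class ElementProfile:
    bins_body: int
    bins_flank: int
    flank_bp: int
    #: matrices (n_elements × (bins_flank + bins_body + bins_flank))
    relative: np.ndarray
    absolute: np.ndarray

    def table(self) -> pd.DataFrame:
        segs = (
            ["upstream_flank"] * self.bins_flank
            + ["body"] * self.bins_body
            + ["downstream_flank"] * self.bins_flank
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            rel = np.nanmean(self.relative, axis=0)
            ab = np.nanmean(self.absolute, axis=0)
        n = np.sum(~np.isnan(self.absolute), axis=0)
        return pd.DataFrame(
            {"segment": segs, "bin": range(len(segs)), "relative_mean": rel,
             "absolute_mean": ab, "n_elements": n}
        )


def element_profile(
    intervals: pd.DataFrame,
    view: MethylomeView,
    genome: GenomeSequence,
    flank_bp: int = 2000,
    bins: int = 20,
) -> ElementProfile:
    """Absolute and relative levels across element bodies (length-normalized)
    and fixed-width flanks; flank bins off the contig stay NaN."""
    if len(intervals) == 0:
        raise ValueError("no intervals")
    nb = 2 * bins + bins
    rel = np.full((len(intervals), nb), np.nan)
    ab = np.full((len(intervals), nb), np.nan)
    fb = flank_bp // bins
    for i, row in enumerate(intervals.itertuples(index=False)):
        clen = genome.length(row.contig)
        pieces: list[tuple[int, int, int]] = []  # (bin_index, start, end)
        for b in range(bins):  # upstream flank
            s = row.start - flank_bp + b * fb
            pieces.append((b, s, s + fb))
        body_len = row.end - row.start
        for b in range(bins):  # body
            s = row.start + (b * body_len) // bins
            e = row.start + ((b + 1) * body_len) // bins
            pieces.append((bins + b, s, max(e, s + 1)))
        for b in range(bins):  # downstream flank
            s = row.end + b * fb
            pieces.append((2 * bins + b, s, s + fb))
        for b, s, e in pieces:
            if s < 0 or e > clen:
                continue
            r = region_methylation(view, row.contig, s, e)
            ab[i, b] = r.absolute_level
            if r.relative_level is not None:
                rel[i, b] = r.relative_level
    return ElementProfile(bins, bins, flank_bp, rel, ab)


# ---------------------------------------------------------------------------
# matched random regions


def sample_random_regions(
    genome: GenomeSequence,
    repeats: pd.DataFrame,
    genes: list[GeneModel],
    template_lengths: list[int],
    rng: np.random.Generator,
    genic_flank_bp: int = 2000,
) -> pd.DataFrame:
    """One random region per template length, uniformly placed outside
    repeats and genic regions (gene span ±flank), mutually non-overlapping."""
    excl: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.contigs}
    if genome.mito_contig is not None:
        excl[genome.mito_contig].append((0, genome.length(genome.mito_contig)))
    for r in repeats.itertuples(index=False):
        excl[r.contig].append((int(r.start), int(r.end)))
    for gene in genes:
        excl[gene.contig].append((gene.start - genic_flank_bp, gene.end + genic_flank_bp))
    gaps: list[list] = []  # [contig, start, end]
    from .util import merge_intervals

    for contig in genome.contigs:
        L = genome.length(contig)
        merged = merge_intervals([(max(s, 0), min(e, L)) for s, e in excl[contig]])
        prev = 0
        for s, e in merged:
            if s > prev:
                gaps.append([contig, prev, s])
            prev = e
        if prev < L:
            gaps.append([contig, prev, L])
    placed = []
    for length in sorted(template_lengths, reverse=True):
        weights = np.array([max(g[2] - g[1] - length + 1, 0) for g in gaps], dtype=float)
        total = weights.sum()
        if total <= 0:
            raise ValueError(
                f"cannot place a {length} bp region; {len(template_lengths) - len(placed)} "
                "template(s) unplaced"
            )
        gi = int(rng.choice(len(gaps), p=weights / total))
        contig, gs, ge = gaps[gi]
        start = int(rng.integers(gs, ge - length + 1))
        placed.append((contig, start, start + length))
        gaps[gi] = [contig, gs, start]
        gaps.append([contig, start + length, ge])
    out = pd.DataFrame(placed, columns=["contig", "start", "end"])
    out["label"] = "random"
    return out.sort_values(["contig", "start"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# gene classification & expression


def classify_hyper_hypo(
    genes: list[GeneModel],
    view: MethylomeView,
    compartment: str = "promoter",
    hyper_threshold: float = 0.70,
    hypo_threshold: float = 0.30,
    metric: str = "relative",
) -> pd.DataFrame:
    """Per-gene level in the chosen compartment with hyper/hypo/neither class.

    Hyper: level ≥ 70% (inclusive); hypo: level ≤ 30% (inclusive); genes with
    undefined level are labelled ``undefined`` and excluded from both lists.
    """
    if compartment not in ("promoter", "gene_body"):
        raise ValueError(f"unknown compartment {compartment!r}")
    rows = []
    for gene in genes:
        if compartment == "promoter":
            s, e = promoter_region(gene)
        else:
            s, e = gene.start, gene.end
        r = region_methylation(view, gene.contig, s, e)
        level = r.relative_level if metric == "relative" else r.mean_degree
        if level is None:
            cls = "undefined"
        elif level >= hyper_threshold:
            cls = "hyper"
        elif level <= hypo_threshold:
            cls = "hypo"
        else:
            cls = "neither"
        rows.append((gene.gene_id, level, cls))
    out = pd.DataFrame(rows, columns=["gene_id", "level", "class"])
    n_undef = int((out["class"] == "undefined").sum())
    if n_undef:
        logger.info("classify_hyper_hypo: %d gene(s) with undefined level excluded", n_undef)
    return out


def assign_quintiles(expression: pd.Series) -> pd.Series:
    """Expression quintiles 1 (lowest) .. 5 (highest); sizes differ by ≤1;
    ties broken by gene_id for determinism."""
    order = expression.reset_index()
    order.columns = ["gene_id", "expr"]
    order = order.sort_values(["expr", "gene_id"], kind="mergesort")
    parts = np.array_split(np.arange(len(order)), 5)
    q = np.empty(len(order), dtype=np.int64)
    for i, part in enumerate(parts, start=1):
        q[part] = i
    return pd.Series(q, index=order["gene_id"].to_numpy(), name="quintile")


@dataclass
class QuintileAnalysis:
    assignment: pd.Series
    summary: pd.DataFrame
    spearman_rho: float
    spearman_p: float
    profiles: dict[int, "MetageneProfile"] = field(default_factory=dict)


def expression_quintile_analysis(
    genes: list[GeneModel],
    expression: pd.Series,
    view: MethylomeView,
    bins_per_segment: int = 10,
    flank_bp: int = 2000,
    compute_profiles: bool = True,
) -> QuintileAnalysis:
    """Quintile-stratified promoter/gene-body methylation and the Spearman
    correlation between promoter methylation degree and expression."""
    if len(expression) < 5:
        raise ValueError("need expression for at least 5 genes")
    genes = [g for g in genes if g.gene_id in expression.index]
    quint = assign_quintiles(expression[[g.gene_id for g in genes]])
    prom = {}
    body = {}
    for gene in genes:
        s, e = promoter_region(gene)
        prom[gene.gene_id] = region_methylation(view, gene.contig, s, e).mean_degree
        body[gene.gene_id] = region_methylation(view, gene.contig, gene.start, gene.end).mean_degree
    df = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "quintile": [quint[g.gene_id] for g in genes],
            "expr": [float(expression[g.gene_id]) for g in genes],
            "promoter_degree": [prom[g.gene_id] for g in genes],
            "body_degree": [body[g.gene_id] for g in genes],
        }
    )
    ok = df["promoter_degree"].notna()
    rho, p = sps.spearmanr(df.loc[ok, "promoter_degree"], df.loc[ok, "expr"])
    summary = (
        df.groupby("quintile")
        .agg(
            n=("gene_id", "size"),
            promoter_degree=("promoter_degree", "mean"),
            body_degree=("body_degree", "mean"),
            expr_mean=("expr", "mean"),
        )
        .reset_index()
    )
    profiles = {}
    if compute_profiles:
        for q in range(1, 6):
            sub = [g for g in genes if quint[g.gene_id] == q]
            if sub:
                profiles[q] = metagene_profile(
                    sub, view, bins_per_segment=bins_per_segment,
                    flank_bp=flank_bp, metric="degree",
                )
    return QuintileAnalysis(quint, summary, float(rho), float(p), profiles)


# ---------------------------------------------------------------------------
# group comparison & divergence


@dataclass
class GroupComparison:
    groups: list[str]
    t_matrix: pd.DataFrame
    p_matrix: pd.DataFrame
    summary: pd.DataFrame


def compare_methylation_between_groups(
    group_assignment: pd.Series,
    per_gene_levels: pd.Series,
) -> GroupComparison:
    """Pairwise Welch two-sample t-tests between gene groups on per-gene
    levels; groups of size < 2 are excluded with a warning."""
    df = pd.DataFrame({"group": group_assignment, "level": per_gene_levels}).dropna()
    sizes = df.groupby("group").size()
    small = sizes[sizes < 2].index.tolist()
    if small:
        warnings.warn(f"excluding group(s) with < 2 genes: {small}", stacklevel=2)
        df = df[~df["group"].isin(small)]
    groups = sorted(df["group"].unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups with >= 2 genes")
    t = pd.DataFrame(np.nan, index=groups, columns=groups)
    p = pd.DataFrame(np.nan, index=groups, columns=groups)
    for i, g1 in enumerate(groups):
        for g2 in groups[i:]:
            if g1 == g2:
                t.loc[g1, g2], p.loc[g1, g2] = 0.0, 1.0
                continue
            res = sps.ttest_ind(
                df.loc[df["group"] == g1, "level"],
                df.loc[df["group"] == g2, "level"],
                equal_var=False,
            )
            t.loc[g1, g2] = t.loc[g2, g1] = float(res.statistic)
            p.loc[g1, g2] = p.loc[g2, g1] = float(res.pvalue)
    summary = (
        df.groupby("group")["level"].agg(["size", "mean", "std"]).reset_index()
    )
    return GroupComparison(groups, t, p, summary)


def _chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float, bool]:
    """(statistic, p, fisher_fallback) for [[a,b],[c,d]], no continuity
    correction; Fisher's exact test when any expected cell < 1."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if table.sum() == 0 or (table.sum(0) == 0).any() or (table.sum(1) == 0).any():
        return 0.0, 1.0, False
    expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
    if (expected < 1).any():
        return np.nan, float(sps.fisher_exact(table.astype(int))[1]), True
    stat, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(stat), float(p), False


def per_gene_divergence(
    genes: list[GeneModel],
    view_a: MethylomeView,
    view_b: MethylomeView,
    expression_a: pd.Series,
    expression_b: pd.Series,
) -> pd.DataFrame:
    """Per-gene χ² p-values for methylation and expression between two lines.

    Methylation: 2×2 of (methylated, unmethylated) read bases summed over the
    gene span's CG sites. Expression: the gene's reads against the remaining
    library total per line.
    """
    tot_a = float(expression_a.sum())
    tot_b = float(expression_b.sum())
    rows = []
    for gene in genes:
        idx = view_a.idx(gene.contig, gene.start, gene.end)
        cg = idx[view_a.is_cg[idx]]
        ma, na = int(view_a.m[cg].sum()), int(view_a.n[cg].sum())
        mb, nb = int(view_b.m[cg].sum()), int(view_b.n[cg].sum())
        if na == 0 or nb == 0:
            continue
        mstat, mp, mfisher = _chi2_2x2(ma, na - ma, mb, nb - mb)
        ep = np.nan
        if gene.gene_id in expression_a.index and gene.gene_id in expression_b.index:
            ra, rb = float(expression_a[gene.gene_id]), float(expression_b[gene.gene_id])
            _, ep, _ = _chi2_2x2(int(ra), int(tot_a - ra), int(rb), int(tot_b - rb))
        rows.append((gene.gene_id, mstat, mp, mfisher, ep))
    return pd.DataFrame(
        rows,
        columns=["gene_id", "meth_chi2", "meth_p", "meth_fisher_fallback", "expr_p"],
    )
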