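"""Synthetic MethylC-seq data with known truth.

The generator emulates the statistical structure a vertebrate lung methylome
analysis assumes: a CpG-depleted background genome with planted CpG islands,
genes and repeats; an unmethylated mitochondrion-like control contig; bimodal
CpG methylation (one mode near 0, one in 0.7–1.0) with trace CHG/CHH
methylation; two "lines" differing only inside planted DMRs; bisulfite reads
at ~14x per strand with a combined non-conversion/sequencing error near 0.7%;
and gene expression rank-anticorrelated with promoter methylation.

All randomness flows from one integer seed through ``numpy.random.Generator``;
identical configs give byte-identical FASTQ and count tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GeneModel, GenomeSequence, annotate_contexts, cg_dyads
from .util import A, C, G, T, contig_bounds, revcomp_array, seq_to_array, sites_in_interval

_BASES = np.array([A, C, G, T], dtype=np.uint8)


@dataclass
class GenomeParams:
    n_contigs: int = 2
    contig_length_bp: int = 500_000
    gc_fraction: float = 0.42
    #: ratio of island CpG observed/expected to the depleted background's
    cpg_enrichment_factor: float = 4.0
    n_islands: int = 8
    island_length_bp: int = 4000
    island_gc_fraction: float = 0.60
    n_genes: int = 40
    exons_per_gene: int = 4
    n_repeats: int = 30
    repeat_length_bp: int = 800
    mito_length_bp: int = 16_000


@dataclass
class MethylomeParams:
    cg_high_fraction: float = 0.62
    cg_high_level_range: tuple[float, float] = (0.7, 1.0)
    cg_low_level_range: tuple[float, float] = (0.0, 0.1)
    non_cg_rate: float = 0.0012
    n_dmrs: int = 8
    dmr_length_bp: int = 2000
    dmr_delta_level: float = 0.5


@dataclass
class ReadParams:
    read_length_bp: int = 80
    mean_depth_per_strand: float = 14.0
    error_rate_nonconversion: float = 0.007
    error_rate_sequencing: float = 0.001
    clonal_fraction: float = 0.1


@dataclass
class ExpressionParams:
    coupling_rho: float = 0.6
    noise_sd: float = 0.1


@dataclass
class SimulationConfig:
    seed: int = 1
    genome: GenomeParams = field(default_factory=GenomeParams)
    methylome: MethylomeParams = field(default_factory=MethylomeParams)
    reads: ReadParams = field(default_factory=ReadParams)
    expression: ExpressionParams = field(default_factory=ExpressionParams)

    def __post_init__(self) -> None:
        m = self.methylome
        for frac in (
            self.genome.gc_fraction,
            m.cg_high_fraction,
            m.non_cg_rate,
            self.reads.clonal_fraction,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction out of [0,1]: {frac}")
        if not 0.0 < m.dmr_delta_level <= 1.0:
            raise ValueError("dmr_delta_level must be in (0,1]")
        if self.reads.mean_depth_per_strand <= 0:
            raise ValueError("depth must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        kw = dict(d)
        for name, sub in (
            ("genome", GenomeParams),
            ("methylome", MethylomeParams),
            ("reads", ReadParams),
            ("expression", ExpressionParams),
        ):
            if name in kw and isinstance(kw[name], dict):
                sec = dict(kw[name])
                if "cg_high_level_range" in sec:
                    sec["cg_high_level_range"] = tuple(sec["cg_high_level_range"])
                if "cg_low_level_range" in sec:
                    sec["cg_low_level_range"] = tuple(sec["cg_low_level_range"])
                kw[name] = sub(**sec)
        return cls(**kw)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        """Load a config from TOML or YAML."""
        path = Path(path)
        if path.suffix == ".toml":
            import tomllib

            with open(path, "rb") as fh:
                return cls.from_dict(tomllib.load(fh))
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class MethylomeTruth:
    """Ground truth: per-site methylation probability per line, planted DMRs
    (with the line carrying the higher level), and per-line expression."""

    levels: dict[str, np.ndarray]
    planted_dmrs: pd.DataFrame
    expression: pd.DataFrame | None = None

    @property
    def lines(self) -> list[str]:
        return list(self.levels)


MITO_NAME = "chrM"


def _background(rng: np.random.Generator, length: int, gc: float, cpg_retention: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = rng.choice(_BASES, size=length, p=p)
    # deplete CpG dinucleotides to vertebrate-like observed/expected
    is_cpg_c = (arr[:-1] == C) & (arr[1:] == G)
    idx = np.flatnonzero(is_cpg_c)
    kill = idx[rng.random(len(idx)) >= cpg_retention] + 1
    arr[kill] = np.where(rng.random(len(kill)) < 0.5, A, T)
    return arr


def _island_seq(rng: np.random.Generator, length: int, gc: float = 0.60) -> np.ndarray:
    # GC-rich, no CpG depletion: observed/expected CpG ~ 1
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p)


def _place_intervals(
    rng: np.random.Generator,
    contig_lengths: dict[str, int],
    n: int,
    length: int,
    occupied: dict[str, list[tuple[int, int]]],
    margin: int = 2500,
    max_tries: int = 20_000,
) -> list[tuple[str, int, int]]:
    names = list(contig_lengths)
    weights = np.array([contig_lengths[c] for c in names], dtype=float)
    weights /= weights.sum()
    placed: list[tuple[str, int, int]] = []
    tries = 0
    while len(placed) < n:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"could not place {n} intervals of {length} bp (placed {len(placed)}); "
                "requested features exceed contig capacity"
            )
        contig = names[rng.choice(len(names), p=weights)]
        hi = contig_lengths[contig] - length - margin
        if hi <= margin:
            continue
        start = int(rng.integers(margin, hi))
        end = start + length
        clash = any(start - margin < e and s < end + margin for s, e in occupied.get(contig, []))
        if clash:
            continue
        occupied.setdefault(contig, []).append((start, end))
        placed.append((contig, start, end))
    return placed


def simulate_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[GenomeSequence, list[GeneModel], pd.DataFrame, pd.DataFrame]:
    """Generate a genome with planted CpG islands, genes, repeats and a mito contig.

    Returns ``(genome, genes, repeats, islands)``; repeats and islands are
    truth BED-like frames (contig/start/end/label).
    """
    g = config.genome
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    retention = 1.0 / g.cpg_enrichment_factor
    contigs: dict[str, np.ndarray] = {}
    for i in range(g.n_contigs):
        contigs[f"chr{i + 1}"] = _background(rng, g.contig_length_bp, g.gc_fraction, retention)
    lengths = {name: len(a) for name, a in contigs.items()}

    occupied: dict[str, list[tuple[int, int]]] = {}
    island_iv = _place_intervals(rng, lengths, g.n_islands, g.island_length_bp, occupied)
    for contig, s, e in island_iv:
        contigs[contig][s:e] = _island_seq(rng, e - s, g.island_gc_fraction)
    islands = pd.DataFrame(island_iv, columns=["contig", "start", "end"])
    islands["label"] = "CGI"

    genes: list[GeneModel] = []
    if g.n_genes:
        k = max(1, g.exons_per_gene)
        exon_lens = rng.integers(150, 451, size=(g.n_genes, k))
        intron_lens = rng.integers(400, 1001, size=(g.n_genes, max(k - 1, 1)))
        spans = exon_lens.sum(axis=1) + (intron_lens.sum(axis=1) if k > 1 else 0)
        for j in range(g.n_genes):
            span = int(spans[j])
            (contig, s, e), = _place_intervals(rng, lengths, 1, span, occupied)
            exons = []
            pos = s
            for x in range(k):
                exons.append((pos, pos + int(exon_lens[j, x])))
                pos = exons[-1][1] + (int(intron_lens[j, x]) if x < k - 1 else 0)
            strand = "+" if rng.random() < 0.5 else "-"
            tss, tts = (s, e) if strand == "+" else (e, s)
            genes.append(GeneModel(f"gene{j + 1:04d}", contig, strand, exons, tss, tts))

    repeat_iv = _place_intervals(rng, lengths, g.n_repeats, g.repeat_length_bp, occupied, margin=500)
    repeats = pd.DataFrame(repeat_iv, columns=["contig", "start", "end"])
    repeats["label"] = [("SINE", "LINE", "LTR")[i % 3] for i in range(len(repeats))]

    if g.mito_length_bp:
        contigs[MITO_NAME] = _background(rng, g.mito_length_bp, g.gc_fraction, retention)
    genome = GenomeSequence(
        contigs={name: a.tobytes().decode("ascii") for name, a in contigs.items()},
        mito_contig=MITO_NAME if g.mito_length_bp else None,
    )
    return genome, genes, repeats, islands


def promoter_span(gene: GeneModel, up: int = 1500, down: int = 500) -> tuple[int, int]:
    if gene.strand == "+":
        return gene.tss - up, gene.tss + down
    return gene.tss - down, gene.tss + up


def simulate_methylome(
    genome: GenomeSequence,
    sites: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    genes: list[GeneModel] | None = None,
    islands: pd.DataFrame | None = None,
) -> MethylomeTruth:
    """Draw per-site truth methylation levels for two lines A and B.

    CpG dyads share one level (the two strands are symmetric); levels come
    from the configured bimodal mixture, overridden inside planted islands
    (mostly unmethylated) and gene promoters (a continuous per-gene level that
    drives the expression coupling). Line B differs from line A only inside
    ``n_dmrs`` planted disjoint intervals shifted by ``dmr_delta_level``. The
    mito contig is fully unmethylated in both lines.
    """
    m = config.methylome
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    n_sites = len(sites)
    levels = np.zeros(n_sites, dtype=np.float64)
    ctx = sites["context"].to_numpy()
    is_cg = ctx == "CG"

    # per-dyad bimodal CG levels, copied to both strand sites
    dyads = cg_dyads(sites)
    n_dy = len(dyads)
    high = rng.random(n_dy) < m.cg_high_fraction
    dy_levels = np.where(
        high,
        rng.uniform(*m.cg_high_level_range, size=n_dy),
        rng.uniform(*m.cg_low_level_range, size=n_dy),
    )
    ip = dyads["idx_plus"].to_numpy()
    im = dyads["idx_minus"].to_numpy()
    levels[ip[ip >= 0]] = dy_levels[ip >= 0]
    levels[im[im >= 0]] = dy_levels[im >= 0]

    # trace non-CG methylation
    non_cg = np.flatnonzero(~is_cg)
    hit = non_cg[rng.random(len(non_cg)) < m.non_cg_rate]
    levels[hit] = rng.uniform(0.3, 1.0, size=len(hit))

    bounds = contig_bounds(sites)

    def set_interval(contig: str, start: int, end: int, arr: np.ndarray, value_fn) -> None:
        idx = sites_in_interval(sites, bounds, contig, start, end)
        idx = idx[is_cg[idx]]
        if len(idx):
            arr[idx] = value_fn(idx)

    island_state: list[bool] = []
    if islands is not None:
        for _, row in islands.iterrows():
            meth = rng.random() < 0.2
            island_state.append(meth)
            lo, hi_ = (0.85, 1.0) if meth else (0.0, 0.08)
            set_interval(row.contig, row.start, row.end, levels, lambda idx: rng.uniform(lo, hi_, len(idx)))

    gene_prom_level: dict[str, float] = {}
    if genes is not None:
        for gene in genes:
            base = rng.uniform(0.03, 0.95)
            gene_prom_level[gene.gene_id] = base
            s, e = promoter_span(gene)
            set_interval(
                gene.contig, s, e, levels,
                lambda idx: np.clip(base + rng.normal(0, 0.04, len(idx)), 0, 1),
            )

    levels_b = levels.copy()

    # planted DMRs: disjoint, away from mito, require >= 4 CG sites per kb
    hi_level = min(1.0, 0.7 + m.dmr_delta_level / 2)
    lo_level = hi_level - m.dmr_delta_level
    non_mito = {c: genome.length(c) for c in genome.contigs if c != genome.mito_contig}
    dmr_rows = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    tries = 0
    while len(dmr_rows) < m.n_dmrs:
        tries += 1
        if tries > 200 * max(m.n_dmrs, 1):
            raise ValueError(f"could not place {m.n_dmrs} disjoint DMR intervals")
        placed = _place_intervals(rng, non_mito, 1, m.dmr_length_bp, occupied, margin=1500)
        contig, s, e = placed[0]
        idx = sites_in_interval(sites, bounds, contig, s, e)
        idx = idx[is_cg[idx]]
        if len(idx) < 4 * (e - s) / 1000:
            occupied[contig].remove((s, e))
            continue
        hyper_line = "A" if len(dmr_rows) % 2 == 0 else "B"
        hi_arr, lo_arr = (levels, levels_b) if hyper_line == "A" else (levels_b, levels)
        hi_arr[idx] = hi_level
        lo_arr[idx] = lo_level
        dmr_rows.append((contig, s, e, hyper_line))
    planted = pd.DataFrame(dmr_rows, columns=["contig", "start", "end", "hyper_line"])
    planted = planted.sort_values(["contig", "start"]).reset_index(drop=True)

    # mito contig: unmethylated control
    if genome.mito_contig is not None:
        lo_m, hi_m = bounds.get(genome.mito_contig, (0, 0))
        levels[lo_m:hi_m] = 0.0
        levels_b[lo_m:hi_m] = 0.0

    truth = MethylomeTruth(levels={"A": levels, "B": levels_b}, planted_dmrs=planted)
    if genes is not None:
        truth.expression = _simulate_expression(
            genes, sites, bounds, truth, config, rng
        )
    return truth


def _promoter_mean_level(
    gene: GeneModel,
    sites: pd.DataFrame,
    bounds: dict,
    levels: np.ndarray,
    is_cg: np.ndarray,
) -> float:
    s, e = promoter_span(gene)
    idx = sites_in_interval(sites, bounds, gene.contig, s, e)
    idx = idx[is_cg[idx]]
    return float(levels[idx].mean()) if len(idx) else np.nan


def _simulate_expression(
    genes: list[GeneModel],
    sites: pd.DataFrame,
    bounds: dict,
    truth: MethylomeTruth,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Gaussian-copula coupling: Spearman(expression, promoter level) ~ -rho."""
    ep = config.expression
    is_cg = (sites["context"] == "CG").to_numpy()
    prom_a = np.array(
        [_promoter_mean_level(g, sites, bounds, truth.levels["A"], is_cg) for g in genes]
    )
    prom_b = np.array(
        [_promoter_mean_level(g, sites, bounds, truth.levels["B"], is_cg) for g in genes]
    )
    n = len(genes)
    from scipy.stats import norm, rankdata

    u = (rankdata(np.nan_to_num(prom_a, nan=0.5), method="average") - 0.5) / n
    z_m = norm.ppf(u)
    rho_p = 2 * np.sin(np.pi * ep.coupling_rho / 6)  # Pearson giving target Spearman
    z_e = -rho_p * z_m + np.sqrt(max(0.0, 1 - rho_p**2)) * rng.normal(size=n)
    z_e += rng.normal(0, ep.noise_sd, size=n)
    expr_a = np.round(np.exp(np.log(200) + 1.1 * z_e)).astype(np.int64)
    delta = np.nan_to_num(prom_b - prom_a, nan=0.0)
    expr_b = np.round(
        expr_a * np.power(2.0, -3.0 * delta) * np.exp(rng.normal(0, 0.05, size=n))
    ).astype(np.int64)
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "A": expr_a,
            "B": expr_b,
            "promoter_truth_A": prom_a,
            "promoter_truth_B": prom_b,
        }
    )


def make_two_state_truth(
    sites: pd.DataFrame,
    mito_contig: str | None,
    cg_methylated_fraction: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """All-or-nothing truth: a random fraction of CG sites at level 1.0,
    everything else (all non-CG sites and the mito contig) at 0.0."""
    levels = np.zeros(len(sites))
    cg = np.flatnonzero((sites["context"] == "CG").to_numpy())
    on = cg[rng.random(len(cg)) < cg_methylated_fraction]
    levels[on] = 1.0
    if mito_contig is not None:
        levels[(sites["contig"] == mito_contig).to_numpy()] = 0.0
    return levels


def simulate_counts_for_levels(
    levels: np.ndarray,
    depth: float,
    error_rate: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-site counts: n ~ Poisson(depth), m ~ Binomial(n, p + err*(1-p))."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    n = rng.poisson(depth, size=len(levels))
    p_eff = levels + error_rate * (1.0 - levels)
    m = rng.binomial(n, p_eff)
    return pd.DataFrame({"m": m.astype(np.int64), "n": n.astype(np.int64)})


def simulate_counts(
    truth: MethylomeTruth,
    sites: pd.DataFrame,
    depth: float,
    error_rate: float,
    rng: np.random.Generator,
) -> dict[str, pd.DataFrame]:
    """Count tables for every line in the truth (fast path bypassing reads)."""
    return {
        line: simulate_counts_for_levels(lv, depth, error_rate, rng)
        for line, lv in truth.levels.items()
    }


# ---------------------------------------------------------------------------
# bisulfite read simulation


def simulate_reads(
    genome: GenomeSequence,
    truth: MethylomeTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    line: str = "A",
    library_id: str = "L1",
    sites: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate single-end directional bisulfite reads for one line.

    Fragments are placed uniformly on both strands at ``mean_depth_per_strand``;
    each cytosine on the sequenced strand reads C with probability
    ``p_site + nonconversion*(1-p_site)`` and T otherwise, then uniform
    substitution errors are applied; a ``clonal_fraction`` of reads are exact
    PCR copies of earlier fragments. Directional chemistry: every read is
    T-rich in its own orientation (Crick fragments are reported 5'->3' on the
    Crick strand).

    Returns ``(reads, truth_alignments)``: reads have read_id/sequence/
    library/richness; truth alignments carry contig, leftmost Watson ``start``,
    target_strand (Watson/Crick), the 5' position and an ``is_clone`` flag.
    """
    rp = config.reads
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    if sites is None:
        sites = annotate_contexts(genome)
    levels = truth.levels[line]
    bounds = contig_bounds(sites)

    # per-contig effective C-emission probability on each strand
    p_watson: dict[str, np.ndarray] = {}
    p_crick: dict[str, np.ndarray] = {}
    arrs: dict[str, np.ndarray] = {}
    for contig in genome.contigs:
        L = genome.length(contig)
        if rp.read_length_bp > L:
            raise ValueError(f"read length {rp.read_length_bp} exceeds contig {contig} ({L} bp)")
        arrs[contig] = seq_to_array(genome.contigs[contig])
        pw = np.zeros(L)
        pc = np.zeros(L)
        lo, hi = bounds.get(contig, (0, 0))
        sub = sites.iloc[lo:hi]
        pos = sub["pos"].to_numpy()
        strand = sub["strand"].to_numpy()
        p_eff = levels[lo:hi] + rp.error_rate_nonconversion * (1.0 - levels[lo:hi])
        pw[pos[strand == "+"]] = p_eff[strand == "+"]
        pc[pos[strand == "-"]] = p_eff[strand == "-"]
        p_watson[contig] = pw
        p_crick[contig] = pc

    rl = rp.read_length_bp
    rows_reads = []
    rows_aln = []
    ridx = 0
    for contig in genome.contigs:
        arr = arrs[contig]
        L = len(arr)
        for strand_name in ("Watson", "Crick"):
            n_total = int(round(rp.mean_depth_per_strand * L / rl))
            n_clone = int(round(rp.clonal_fraction * n_total))
            n_uniq = max(n_total - n_clone, 0)
            starts = rng.integers(0, L - rl + 1, size=n_uniq)
            uniq_records = []
            for s in starts:
                s = int(s)
                frag = arr[s : s + rl].copy()
                if strand_name == "Watson":
                    cpos = np.flatnonzero(frag == C)
                    meth = rng.random(len(cpos)) < p_watson[contig][s + cpos]
                    frag[cpos[~meth]] = T
                    seq = frag
                    five_prime = s
                else:
                    rc = revcomp_array(frag)  # Crick 5'->3'
                    # Crick cytosines sit where Watson has G; in rc coordinates
                    cpos = np.flatnonzero(rc == C)
                    watson_pos = s + rl - 1 - cpos
                    meth = rng.random(len(cpos)) < p_crick[contig][watson_pos]
                    rc[cpos[~meth]] = T
                    seq = rc
                    five_prime = s + rl - 1
                if rp.error_rate_sequencing > 0:
                    err = np.flatnonzero(rng.random(rl) < rp.error_rate_sequencing)
                    if len(err):
                        seq = seq.copy()
                        shift = rng.integers(1, 4, size=len(err))
                        cur = np.searchsorted(_BASES, seq[err])
                        seq[err] = _BASES[(cur + shift) % 4]
                    uniq_records.append((s, five_prime, seq))
                else:
                    uniq_records.append((s, five_prime, seq))
            clone_src = rng.integers(0, n_uniq, size=n_clone) if n_uniq else np.empty(0, int)
            order = list(range(n_uniq)) + [-1 - int(i) for i in clone_src]
            perm = rng.permutation(len(order))
            for k in perm:
                tag = order[k]
                is_clone = tag < 0
                s, five_prime, seq = uniq_records[tag if not is_clone else -1 - tag]
                read_id = f"r{ridx:07d}"
                ridx += 1
                rows_reads.append(
                    (read_id, seq.tobytes().decode("ascii"), library_id, "T-rich")
                )
                rows_aln.append((read_id, contig, s, strand_name, five_prime, is_clone))
    reads = pd.DataFrame(rows_reads, columns=["read_id", "sequence", "library_id", "richness"])
    aln = pd.DataFrame(
        rows_aln, columns=["read_id", "contig", "start", "target_strand", "five_prime", "is_clone"]
    )
    return reads, aln


def write_fastq(reads: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in reads.itertuples(index=False):
            fh.write(f"@{row.read_id} lib={row.library_id} richness={row.richness}\n")
            fh.write(row.sequence + "\n+\n" + "I" * len(row.sequence) + "\n")
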