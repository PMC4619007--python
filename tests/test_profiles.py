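"""Region metrics, metagene/element profiles, quintiles, group tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mcseq.genome import GeneModel, GenomeSequence, annotate_contexts
from mcseq.profiles import (
    MethylomeView,
    assign_quintiles,
    classify_hyper_hypo,
    compare_methylation_between_groups,
    element_profile,
    expression_quintile_analysis,
    metagene_profile,
    per_gene_divergence,
    promoter_region,
    region_methylation,
    sample_random_regions,
)
from mcseq.simulate import simulate_counts_for_levels


def _view_from_levels(genome, sites, levels, depth=30, error=0.0, called_threshold=0.5, seed=0):
    rng = np.random.default_rng(seed)
    counts = simulate_counts_for_levels(levels, depth, error, rng)
    called = (counts["m"] / counts["n"].clip(lower=1) >= called_threshold).to_numpy() & (
        counts["n"].to_numpy() > 0
    )
    return MethylomeView(sites, counts, called)


class TestRegionMethylation:
    def test_arithmetic(self):
        # 10 CG dyad sites on + strand; 6 called CG; 2 extra non-CG calls
        sites = pd.DataFrame(
            {
                "contig": "c",
                "pos": np.arange(12) * 80,
                "strand": "+",
                "context": pd.Categorical(
                    ["CG"] * 10 + ["CHH"] * 2, categories=["CG", "CHG", "CHH", "CNN"]
                ),
            }
        )
        counts = pd.DataFrame({"m": [5] * 12, "n": [10] * 12})
        called = np.array([True] * 6 + [False] * 4 + [True] * 2)
        view = MethylomeView(sites, counts, called)
        r = region_methylation(view, "c", 0, 1000)
        assert r.relative_level == pytest.approx(0.6)
        assert r.absolute_level == pytest.approx(8 / 1000)
        assert r.mean_degree == pytest.approx(0.5)

    def test_no_reads_flagged_undefined(self):
        sites = pd.DataFrame(
            {"contig": "c", "pos": [10], "strand": "+",
             "context": pd.Categorical(["CG"], categories=["CG", "CHG", "CHH", "CNN"])}
        )
        counts = pd.DataFrame({"m": [0], "n": [0]})
        view = MethylomeView(sites, counts, np.array([False]))
        r = region_methylation(view, "c", 0, 100)
        assert r.relative_level is None and r.mean_degree is None
        assert r.absolute_level == 0.0

    def test_high_depth_degree_concentrates(self, small_sim):
        genome, *_, sites, truth, _ = small_sim
        rng = np.random.default_rng(9)
        counts = simulate_counts_for_levels(truth.levels["A"], 200, 0.0, rng)
        view = MethylomeView(sites, counts, np.zeros(len(sites), bool))
        contig = "chr1"
        r = region_methylation(view, contig, 0, 80_000)
        cg = (sites["context"] == "CG").to_numpy() & (sites["contig"] == contig).to_numpy()
        assert r.mean_degree == pytest.approx(truth.levels["A"][cg].mean(), abs=0.01)


class TestPromoter:
    def _gene(self, strand, tss):
        if strand == "+":
            return GeneModel("g", "c", "+", [(tss, tss + 2000)], tss, tss + 2000)
        return GeneModel("g", "c", "-", [(tss - 2000, tss)], tss, tss - 2000)

    def test_plus_strand(self):
        assert promoter_region(self._gene("+", 10_000)) == (8500, 10_500)

    def test_minus_strand(self):
        assert promoter_region(self._gene("-", 10_000)) == (9500, 11_500)

    def test_clipping(self):
        assert promoter_region(self._gene("+", 1000)) == (0, 1500)
        assert promoter_region(self._gene("-", 1000), contig_length=2000) == (500, 2000)


def _uniform_genome(seed=17, n_genes=30, length=400_000):
    from mcseq.simulate import GenomeParams, SimulationConfig, simulate_genome

    cfg = SimulationConfig(
        seed=seed,
        genome=GenomeParams(
            n_contigs=1, contig_length_bp=length, n_islands=0, n_genes=n_genes,
            n_repeats=6, mito_length_bp=0,
        ),
    )
    return simulate_genome(cfg, np.random.default_rng(seed))


class TestMetagene:
    def test_step_profile_promoter_low_body_high(self):
        genome, genes, *_ = _uniform_genome()
        sites = annotate_contexts(genome)
        cg = (sites["context"] == "CG").to_numpy()
        pos = sites["pos"].to_numpy()
        levels = np.zeros(len(sites))
        for g in genes:
            inside = (pos >= g.start) & (pos < g.end)
            levels[inside & cg] = 0.9
        view = _view_from_levels(genome, sites, levels, seed=3)
        prof = metagene_profile(genes, view, bins_per_segment=5, metric="relative")
        tab = prof.table()
        up = tab[tab.segment == "upstream"]["mean"].mean()
        body = tab[tab.segment == "internal_exons"]["mean"].mean()
        assert up < 0.2 < 0.7 < body

    def test_single_exon_gene_segments(self):
        genome, _, *_ = _uniform_genome(n_genes=0)
        sites = annotate_contexts(genome)
        gene = GeneModel("solo", "chr1", "+", [(50_000, 51_000)], 50_000, 51_000)
        view = _view_from_levels(genome, sites, np.zeros(len(sites)), seed=1)
        prof = metagene_profile([gene], view, bins_per_segment=4)
        assert not np.isnan(prof.per_gene["first_exon"]).all()
        for seg in ("first_intron", "internal_exons", "internal_introns", "last_exon"):
            assert np.isnan(prof.per_gene[seg]).all()

    def test_uniform_truth_flat(self):
        genome, genes, *_ = _uniform_genome(seed=23)
        sites = annotate_contexts(genome)
        cg = (sites["context"] == "CG").to_numpy()
        levels = np.where(cg, 0.7, 0.0)
        view = _view_from_levels(genome, sites, levels, depth=30, seed=5)
        prof = metagene_profile(genes, view, bins_per_segment=5, metric="degree")
        tab = prof.table().dropna(subset=["mean"])
        grand = np.average(tab["mean"], weights=tab["n_genes"])
        off = np.abs(tab["mean"] - grand) / tab["se"]
        assert (off[tab["n_genes"] >= 10] <= 3).all()


class TestElementProfile:
    def test_low_inside_high_outside(self):
        genome, genes, repeats, _ = _uniform_genome(seed=29)
        sites = annotate_contexts(genome)
        cg = (sites["context"] == "CG").to_numpy()
        pos = sites["pos"].to_numpy()
        levels = np.where(cg, 0.8, 0.0)
        for r in repeats.itertuples(index=False):
            inside = (pos >= r.start) & (pos < r.end)
            levels[inside] = 0.0
        view = _view_from_levels(genome, sites, levels, seed=2)
        prof = element_profile(repeats, view, genome, flank_bp=1000, bins=5)
        tab = prof.table()
        body = tab[tab.segment == "body"]
        flank = tab[tab.segment != "body"]
        assert body["relative_mean"].mean() < 0.2 < 0.6 < flank["relative_mean"].mean()
        assert body["absolute_mean"].mean() < flank["absolute_mean"].mean()

    def test_profile_linearity(self):
        genome, genes, repeats, _ = _uniform_genome(seed=29)
        sites = annotate_contexts(genome)
        levels = np.where((sites["context"] == "CG").to_numpy(), 0.8, 0.0)
        view = _view_from_levels(genome, sites, levels, seed=2)
        full = element_profile(repeats, view, genome, flank_bp=1000, bins=3)
        singles = [
            element_profile(repeats.iloc[[i]], view, genome, flank_bp=1000, bins=3)
            for i in range(len(repeats))
        ]
        stacked = np.vstack([s.absolute for s in singles])
        np.testing.assert_allclose(full.absolute, stacked, equal_nan=True)


class TestRandomRegions:
    def test_reproducible_and_valid(self):
        genome, genes, repeats, _ = _uniform_genome(seed=37)
        lengths = [500, 800, 1000, 1500]
        r1 = sample_random_regions(genome, repeats, genes, lengths, np.random.default_rng(4))
        r2 = sample_random_regions(genome, repeats, genes, lengths, np.random.default_rng(4))
        pd.testing.assert_frame_equal(r1, r2)
        assert sorted(r1["end"] - r1["start"]) == sorted(lengths)
        # exclusion: no overlap with repeats or genic +/- 2 kb, nor among samples
        excl = [(r.start, r.end) for r in repeats.itertuples(index=False)]
        excl += [(g.start - 2000, g.end + 2000) for g in genes]
        placed = list(zip(r1["start"], r1["end"]))
        for s, e in placed:
            assert all(e <= s2 or s >= e2 for s2, e2 in excl)
        for i, (s, e) in enumerate(placed):
            for s2, e2 in placed[i + 1 :]:
                assert e <= s2 or s >= e2

    def test_impossible_placement_raises(self):
        genome, genes, repeats, _ = _uniform_genome(seed=37)
        with pytest.raises(ValueError, match="cannot place"):
            sample_random_regions(genome, repeats, genes, [10_000_000], np.random.default_rng(0))


class TestHyperHypo:
    def _view(self, level):
        genome, genes, *_ = _uniform_genome(seed=41, n_genes=5)
        sites = annotate_contexts(genome)
        cg = (sites["context"] == "CG").to_numpy()
        levels = np.where(cg, level, 0.0)
        return genes, _view_from_levels(genome, sites, levels, depth=60, seed=6)

    def test_thresholds_inclusive(self):
        sites = pd.DataFrame(
            {"contig": "c", "pos": np.arange(10) * 10, "strand": "+",
             "context": pd.Categorical(["CG"] * 10, categories=["CG", "CHG", "CHH", "CNN"])}
        )
        counts = pd.DataFrame({"m": [5] * 10, "n": [10] * 10})
        gene = GeneModel("g", "c", "+", [(0, 100)], 0, 100)
        for n_called, expected in [(7, "hyper"), (5, "neither"), (3, "hypo")]:
            called = np.array([True] * n_called + [False] * (10 - n_called))
            view = MethylomeView(sites, counts, called)
            out = classify_hyper_hypo([gene], view, compartment="gene_body")
            assert out.iloc[0]["class"] == expected

    def test_high_level_genes_hyper(self):
        genes, view = self._view(0.95)
        out = classify_hyper_hypo(genes, view, compartment="gene_body")
        assert (out["class"] == "hyper").all()


class TestQuintiles:
    def test_partition_sizes_and_determinism(self):
        expr = pd.Series(np.arange(10.0), index=[f"g{i}" for i in range(10)])
        q = assign_quintiles(expr)
        assert sorted(q.value_counts()) == [2, 2, 2, 2, 2]
        shuffled = expr.sample(frac=1, random_state=1)
        q2 = assign_quintiles(shuffled)
        assert q.sort_index().equals(q2.sort_index())

    def test_requires_five_genes(self, small_sim):
        genome, genes, *_ , sites, truth, counts = small_sim
        view = MethylomeView(sites, counts["A"], np.zeros(len(sites), bool))
        with pytest.raises(ValueError):
            expression_quintile_analysis(genes, pd.Series({"g": 1.0}), view)

    def test_anticorrelation_recovered(self, small_sim):
        genome, genes, repeats, islands, sites, truth, counts = small_sim
        called = (counts["A"]["m"] / counts["A"]["n"].clip(lower=1) >= 0.5).to_numpy()
        view = MethylomeView(sites, counts["A"], called)
        expr = pd.Series(truth.expression["A"].to_numpy(), index=truth.expression["gene_id"].to_numpy())
        qa = expression_quintile_analysis(genes, expr, view, compute_profiles=False)
        assert qa.spearman_rho < 0
        assert set(qa.assignment.unique()) <= {1, 2, 3, 4, 5}


class TestGroupComparison:
    def test_identical_groups(self):
        levels = pd.Series([0.5, 0.6, 0.5, 0.6], index=list("abcd"))
        groups = pd.Series(["g1", "g1", "g2", "g2"], index=list("abcd"))
        gc = compare_methylation_between_groups(groups, levels)
        assert gc.p_matrix.loc["g1", "g2"] == pytest.approx(1.0)
        assert gc.p_matrix.equals(gc.p_matrix.T)

    def test_shifted_means_detected(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.5, 0.1, 100)
        b = rng.normal(0.7, 0.1, 100)
        levels = pd.Series(np.concatenate([a, b]))
        groups = pd.Series(["old"] * 100 + ["new"] * 100)
        gc = compare_methylation_between_groups(groups, levels)
        assert gc.p_matrix.loc["old", "new"] < 1e-6

    def test_small_group_excluded(self):
        levels = pd.Series([0.1, 0.2, 0.3, 0.4, 0.5])
        groups = pd.Series(["a", "a", "b", "b", "c"])
        with pytest.warns(UserWarning, match="excluding"):
            gc = compare_methylation_between_groups(groups, levels)
        assert gc.groups == ["a", "b"]

    def test_single_group_errors(self):
        levels = pd.Series([0.1, 0.2, 0.3])
        groups = pd.Series(["a", "a", "b"])
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="2 groups"):
                compare_methylation_between_groups(groups, levels)


class TestPerGeneDivergence:
    def _views(self, levels_a, levels_b, genome, sites, seed=0):
        va = _view_from_levels(genome, sites, levels_a, seed=seed)
        vb = _view_from_levels(genome, sites, levels_b, seed=seed + 1)
        return va, vb

    def test_identical_counts_p_one(self):
        sites = pd.DataFrame(
            {"contig": "c", "pos": [10, 20], "strand": "+",
             "context": pd.Categorical(["CG", "CG"], categories=["CG", "CHG", "CHH", "CNN"])}
        )
        counts = pd.DataFrame({"m": [5, 5], "n": [10, 10]})
        view = MethylomeView(sites, counts, np.zeros(2, bool))
        gene = GeneModel("g", "c", "+", [(0, 100)], 0, 100)
        expr = pd.Series({"g": 50.0, "other": 50.0})
        out = per_gene_divergence([gene], view, view, expr, expr)
        assert out.iloc[0]["meth_p"] == pytest.approx(1.0)
        assert out.iloc[0]["expr_p"] == pytest.approx(1.0)

    def test_chi2_matches_closed_form(self):
        from mcseq.profiles import _chi2_2x2

        stat, p, fallback = _chi2_2x2(50, 50, 10, 90)
        table = np.array([[50, 50], [10, 90]], float)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        by_hand = ((table - expected) ** 2 / expected).sum()
        assert not fallback
        assert stat == pytest.approx(by_hand)
        assert p == pytest.approx(sps.chi2.sf(by_hand, 1))

    def test_fisher_fallback_on_tiny_expectation(self):
        from mcseq.profiles import _chi2_2x2

        stat, p, fallback = _chi2_2x2(1, 0, 0, 30)
        assert fallback and 0 <= p <= 1

    def test_null_pvalues_roughly_uniform(self):
        genome, genes, *_ = _uniform_genome(seed=43, n_genes=40, length=600_000)
        sites = annotate_contexts(genome)
        cg = (sites["context"] == "CG").to_numpy()
        levels = np.where(cg, 0.5, 0.0)
        va = _view_from_levels(genome, sites, levels, depth=30, seed=1)
        vb = _view_from_levels(genome, sites, levels, depth=30, seed=2)
        expr = pd.Series(1000.0, index=[g.gene_id for g in genes])
        out = per_gene_divergence(genes, va, vb, expr, expr)
        ks = sps.kstest(out["meth_p"], "uniform")
        assert ks.pvalue > 0.01
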