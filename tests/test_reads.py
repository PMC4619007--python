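"""Read processing: non-conversion filter, conversion, alignment, dedup, pileup."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mcseq.genome import GenomeSequence, annotate_contexts
from mcseq.reads import (
    align_bisulfite_reads,
    convert_three_letter,
    count_non_cg_cytosines,
    deduplicate_clonal,
    filter_nonconverted,
    library_stats,
    pileup_counts,
    read_fastq,
)
from mcseq.simulate import (
    GenomeParams,
    MethylomeParams,
    ReadParams,
    SimulationConfig,
    simulate_counts_for_levels,
    simulate_genome,
    simulate_methylome,
    simulate_reads,
    write_fastq,
)
from mcseq.util import revcomp

dna = st.text(alphabet="ACGT", min_size=0, max_size=50)


class TestNonConversionFilter:
    @pytest.mark.parametrize(
        "seq,keep",
        [
            ("TTTTCGTT", True),   # 0 non-CG cytosines
            ("CACACACA", False),  # 4 — strictly more than three
            ("CACACGCA", True),   # 3 — threshold inclusive
            ("TTTC", True),       # trailing C counts as 1 non-CG
            ("CCCC", False),      # 4: three CC pairs + trailing
        ],
    )
    def test_examples(self, seq, keep):
        assert filter_nonconverted(seq) is keep

    def test_a_rich_uses_reverse_complement(self):
        seq = "TGTGTGTG"  # revcomp = CACACACA -> 4 non-CG cytosines
        assert filter_nonconverted(seq, richness="T-rich")
        assert not filter_nonconverted(seq, richness="A-rich")

    @given(dna)
    def test_count_matches_positional_definition(self, seq):
        naive = sum(
            1
            for i, ch in enumerate(seq)
            if ch == "C" and (i + 1 >= len(seq) or seq[i + 1] != "G")
        )
        assert count_non_cg_cytosines(seq) == naive


class TestConversion:
    @pytest.mark.parametrize(
        "seq,mode,out",
        [("ACGT", "C2T", "ATGT"), ("ACGT", "G2A", "ACAT"), ("TTTT", "C2T", "TTTT"), ("TTTT", "G2A", "TTTT")],
    )
    def test_examples(self, seq, mode, out):
        assert convert_three_letter(seq, mode) == out

    @given(dna)
    def test_length_preserved_and_idempotent(self, seq):
        c = convert_three_letter(seq, "C2T")
        assert len(c) == len(seq)
        assert convert_three_letter(c, "C2T") == c
        assert "C" not in c


def _toy_genome(rng_seed=0, length=4000):
    rng = np.random.default_rng(rng_seed)
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return GenomeSequence({"c": seq})


class TestAligner:
    def test_unique_watson_placement(self):
        g = _toy_genome()
        frag = convert_three_letter(g.contigs["c"][100:140], "C2T")
        reads = pd.DataFrame(
            [("r1", frag, "L1", "T-rich")],
            columns=["read_id", "sequence", "library_id", "richness"],
        )
        aln = align_bisulfite_reads(reads, g)
        assert len(aln) == 1
        assert aln.iloc[0]["start"] == 100
        assert aln.iloc[0]["target_strand"] == "Watson"
        assert aln.iloc[0]["five_prime"] == 100

    def test_crick_placement_and_five_prime(self):
        g = _toy_genome()
        crick = revcomp(g.contigs["c"][200:240])
        frag = convert_three_letter(crick, "C2T")
        reads = pd.DataFrame(
            [("r1", frag, "L1", "T-rich")],
            columns=["read_id", "sequence", "library_id", "richness"],
        )
        aln = align_bisulfite_reads(reads, g)
        assert len(aln) == 1
        assert aln.iloc[0]["target_strand"] == "Crick"
        assert aln.iloc[0]["start"] == 200
        assert aln.iloc[0]["five_prime"] == 239

    def test_repeated_sequence_is_ambiguous(self):
        core = "ATGATTTGATTGGATTAGCTGGATAGTTGAAT"
        g = GenomeSequence({"c": "TTTT" + core + "AAAA" + core + "TTTT"})
        reads = pd.DataFrame(
            [("r1", core, "L1", "T-rich")],
            columns=["read_id", "sequence", "library_id", "richness"],
        )
        aln = align_bisulfite_reads(reads, g)
        assert len(aln) == 0
        assert aln.attrs["drops"]["ambiguous"] == 1

    def test_mismatch_tolerance(self):
        g = _toy_genome()
        frag = list(convert_three_letter(g.contigs["c"][300:340], "C2T"))
        frag[20] = "A" if frag[20] != "A" else "G"
        reads = pd.DataFrame(
            [("r1", "".join(frag), "L1", "T-rich")],
            columns=["read_id", "sequence", "library_id", "richness"],
        )
        aln = align_bisulfite_reads(reads, g)
        assert len(aln) == 1 and aln.iloc[0]["n_mismatches"] == 1

    def test_simulated_reads_recover_truth_positions(self):
        cfg = SimulationConfig(
            seed=13,
            genome=GenomeParams(n_contigs=1, contig_length_bp=30_000, n_islands=1, n_genes=2, n_repeats=2, mito_length_bp=0),
            methylome=MethylomeParams(n_dmrs=0),
            reads=ReadParams(mean_depth_per_strand=2, error_rate_sequencing=0.0, clonal_fraction=0.0),
        )
        rng = np.random.default_rng(cfg.seed)
        genome, genes, repeats, islands = simulate_genome(cfg, rng)
        sites = annotate_contexts(genome)
        truth = simulate_methylome(genome, sites, cfg, rng, genes=genes, islands=islands)
        reads, aln_truth = simulate_reads(genome, truth, cfg, rng, sites=sites)
        aln = align_bisulfite_reads(reads, genome)
        mg = aln.merge(aln_truth, on="read_id", suffixes=("", "_t"))
        assert len(mg) / len(reads) > 0.98
        assert (mg["start"] == mg["start_t"]).all()
        assert (mg["target_strand"] == mg["target_strand_t"]).all()


class TestDedup:
    def _aln(self, rows):
        return pd.DataFrame(
            rows,
            columns=["read_id", "library_id", "contig", "start", "target_strand", "five_prime", "n_mismatches", "watson_seq"],
        )

    def test_same_library_same_start_one_survives(self):
        a = self._aln([("r1", "L1", "c", 5, "Watson", 5, 0, "AA"), ("r2", "L1", "c", 5, "Watson", 5, 0, "AA")])
        out = deduplicate_clonal(a)
        assert list(out["read_id"]) == ["r1"]

    def test_different_libraries_both_survive(self):
        a = self._aln([("r1", "L1", "c", 5, "Watson", 5, 0, "AA"), ("r2", "L2", "c", 5, "Watson", 5, 0, "AA")])
        assert len(deduplicate_clonal(a)) == 2

    def test_idempotent(self):
        a = self._aln(
            [("r1", "L1", "c", 5, "Watson", 5, 0, "AA"),
             ("r2", "L1", "c", 5, "Watson", 5, 0, "AA"),
             ("r3", "L1", "c", 9, "Crick", 10, 0, "AA")]
        )
        once = deduplicate_clonal(a)
        twice = deduplicate_clonal(once)
        pd.testing.assert_frame_equal(once, twice)


class TestPileup:
    def _setup(self):
        g = GenomeSequence({"c": "TTACGTTT"})
        sites = annotate_contexts(g)  # (+,3,CG), (-,4,CG)
        return g, sites

    def _aln(self, rows):
        return pd.DataFrame(
            rows,
            columns=["read_id", "library_id", "contig", "start", "target_strand", "five_prime", "n_mismatches", "watson_seq"],
        )

    def test_all_c_reads(self):
        g, sites = self._setup()
        rows = [(f"r{i}", "L1", "c", 0, "Watson", 0, 0, "TTACGTTT") for i in range(5)]
        counts = pileup_counts(self._aln(rows), g, sites)
        plus = sites.index[(sites.strand == "+") & (sites.pos == 3)][0]
        assert counts.loc[plus, "m"] == 5 and counts.loc[plus, "n"] == 5

    def test_mixed_c_t(self):
        g, sites = self._setup()
        rows = [(f"r{i}", "L1", "c", 0, "Watson", 0, 0, "TTACGTTT") for i in range(4)]
        rows += [(f"s{i}", "L1", "c", 0, "Watson", 0, 0, "TTATGTTT") for i in range(6)]
        counts = pileup_counts(self._aln(rows), g, sites)
        plus = sites.index[(sites.strand == "+") & (sites.pos == 3)][0]
        assert counts.loc[plus, "n"] == 10 and counts.loc[plus, "m"] == 4

    def test_non_informative_base_excluded(self):
        g, sites = self._setup()
        rows = [("r1", "L1", "c", 0, "Watson", 0, 0, "TTAGGTTT")]  # G at the Watson C site
        counts = pileup_counts(self._aln(rows), g, sites)
        plus = sites.index[(sites.strand == "+") & (sites.pos == 3)][0]
        assert counts.loc[plus, "n"] == 0

    def test_crick_site_counts_g_and_a(self):
        g, sites = self._setup()
        rows = [("r1", "L1", "c", 0, "Crick", 7, 0, "TTACGTTT"),
                ("r2", "L1", "c", 0, "Crick", 7, 0, "TTACATTT")]
        counts = pileup_counts(self._aln(rows), g, sites)
        minus = sites.index[(sites.strand == "-") & (sites.pos == 4)][0]
        assert counts.loc[minus, "n"] == 2 and counts.loc[minus, "m"] == 1

    def test_overhang_ignored(self):
        g, sites = self._setup()
        rows = [("r1", "L1", "c", 4, "Watson", 4, 0, "GTTTAAAA")]  # extends past the contig
        counts = pileup_counts(self._aln(rows), g, sites)
        assert counts["n"].sum() == 0  # no Watson C site in [4,8)


class TestLibraryStats:
    def test_conversion_rate_recovered(self, small_sim):
        genome, *_, sites, truth, counts = small_sim
        stats = library_stats(counts["A"], sites, genome)
        assert stats.conversion_rate == pytest.approx(0.993, abs=0.001)
        assert stats.cpg_coverage_fraction > 0.99

    def test_empty_counts(self, small_sim):
        genome, *_, sites, truth, counts = small_sim
        empty = pd.DataFrame({"m": np.zeros(len(sites), int), "n": np.zeros(len(sites), int)})
        stats = library_stats(empty, sites, genome)
        assert stats.cpg_coverage_fraction == 0.0
        assert stats.conversion_rate is None

    def test_chain_monotonicity_enforced(self, small_sim):
        genome, *_, sites, truth, counts = small_sim
        with pytest.raises(ValueError, match="non-increasing"):
            library_stats(counts["A"], sites, genome, {"reads_in": 10, "reads_after_filter": 20})


class TestFastqIO:
    def test_round_trip_with_richness(self, tmp_path, small_sim):
        reads = pd.DataFrame(
            [("r1", "ACGT", "L2", "T-rich"), ("r2", "TTTT", "L2", "A-rich")],
            columns=["read_id", "sequence", "library_id", "richness"],
        )
        p = tmp_path / "r.fq"
        write_fastq(reads, p)
        back = read_fastq(p)
        pd.testing.assert_frame_equal(back, reads)
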