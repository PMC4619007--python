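import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from mcseq.genome import annotate_contexts
from mcseq.simulate import (
    GenomeParams,
    MethylomeParams,
    SimulationConfig,
    simulate_counts,
    simulate_genome,
    simulate_methylome,
)


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """A compact two-line simulation: 1×80 kb contig + 8 kb mito."""
    return SimulationConfig(
        seed=11,
        genome=GenomeParams(
            n_contigs=1, contig_length_bp=80_000, n_islands=2, n_genes=6,
            n_repeats=4, mito_length_bp=8000,
        ),
        methylome=MethylomeParams(n_dmrs=2),
    )


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    """(genome, genes, repeats, islands, sites, truth, counts-per-line)."""
    rng = np.random.default_rng(small_cfg.seed)
    genome, genes, repeats, islands = simulate_genome(small_cfg, rng)
    sites = annotate_contexts(genome)
    truth = simulate_methylome(genome, sites, small_cfg, rng, genes=genes, islands=islands)
    counts = simulate_counts(truth, sites, 28.0, 0.007, rng)
    return genome, genes, repeats, islands, sites, truth, counts
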