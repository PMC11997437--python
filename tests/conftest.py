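import numpy as np
import pytest

import panelsmith as ps


@pytest.fixture(scope="session")
def small_genome():
    g, _ = ps.simulate_genome(
        ps.GenomeConfig(n_chroms=2, lengths=(30_000, 20_000), gc=0.45), seed=11
    )
    return g


@pytest.fixture(scope="session")
def pop_matrix(small_genome):
    g, pops, truth = ps.simulate_population(
        ps.PopulationConfig(
            n_pops=2, samples_per_pop=20, n_snps=300, divergence_F=0.1, maf_floor=0.1
        ),
        small_genome,
        seed=12,
    )
    return g, pops, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_matrix(calls, chrom="chr1", start_pos=100, spacing=100):
    """Build a GenotypeMatrix from a (samples x sites) array of codes."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    sites = [
        ps.SiteRecord(chrom, start_pos + i * spacing, "A", "G") for i in range(m)
    ]
    return ps.GenotypeMatrix([f"s{i}" for i in range(n)], sites, calls)
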