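import numpy as np
import pytest

from dairyopt.genome import GenomeSpec, sample_qtl_effects, simulate_founders


@pytest.fixture(scope="session")
def small_genome_spec() -> GenomeSpec:
    """Two small chromosomes; enough loci for LD and TBV checks."""
    return GenomeSpec(
        n_chromosomes=2,
        bp_per_chromosome=2e7,
        n_causal_per_chromosome=60,
        n_marker_per_chromosome=120,
    )


@pytest.fixture(scope="session")
def small_founders(small_genome_spec):
    return simulate_founders(small_genome_spec, n_founders=120, seed=42)


@pytest.fixture(scope="session")
def small_qtl(small_genome_spec, small_founders):
    return sample_qtl_effects(small_genome_spec, small_founders, seed=43)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
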