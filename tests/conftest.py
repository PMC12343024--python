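import numpy as np
import pytest

from caverelax.codon_evolution import TreeSpec
from caverelax.synthetic_data import SimulationConfig, simulate_codon_alignment


@pytest.fixture(scope="session")
def star_tree() -> TreeSpec:
    return TreeSpec(
        branch_lengths={"cave": 0.09, "surface": 0.09, "outgroup": 0.7}
    )


@pytest.fixture(scope="session")
def small_alignment(star_tree):
    """A 300-codon simulated alignment with distinct branch omegas."""
    cfg = SimulationConfig(
        n_codons=300,
        branch_omegas={"cave": 0.5, "surface": 0.2, "outgroup": 1.0},
        branch_lengths=dict(star_tree.branch_lengths),
        seed=11,
    )
    return simulate_codon_alignment(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
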