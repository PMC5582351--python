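import dataclasses

import pytest

from polysyn.simulate import SimulationConfig, build_event_tree, evolve_genomes


CLEAN = SimulationConfig(
    n_ancestral_genes=120,
    loss_rate_per_copy=0.0,
    tandem_rate=0.0,
    inversion_rate=0.0,
    translocation_rate=0.0,
    identity_noise_sd=0.0,
    spurious_fraction=0.0,
    seed=11,
)


@pytest.fixture(scope="session")
def poaceae_tree():
    return build_event_tree("poaceae9")


@pytest.fixture(scope="session")
def clean_sim(poaceae_tree):
    """Noise-free, loss-free, rearrangement-free nine-genome simulation."""
    return evolve_genomes(poaceae_tree, CLEAN)


@pytest.fixture(scope="session")
def noisy_sim(poaceae_tree):
    """Default study conditions at a reduced gene count."""
    cfg = dataclasses.replace(SimulationConfig(), n_ancestral_genes=200, seed=5)
    return evolve_genomes(poaceae_tree, cfg)
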