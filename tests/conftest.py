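import numpy as np
import pytest

from mitocarrier import (
    AnalysisConfig,
    CarrierTopology,
    SyntheticBundleSpec,
    make_gated_pore,
    make_pseudo_c3_bundle,
    make_state_pair,
)


@pytest.fixture(scope="session")
def bundle():
    """Deterministic pseudo-C3 bundle with one planted salt bridge."""
    spec = SyntheticBundleSpec(
        planted_pairs=[(20, 90, 3.0, "salt_bridge")], seed=7
    )
    model, topology = make_pseudo_c3_bundle(spec)
    return model, topology, spec


@pytest.fixture(scope="session")
def clean_bundle():
    """Pseudo-C3 bundle with no planted features (exact symmetry)."""
    model, topology = make_pseudo_c3_bundle(SyntheticBundleSpec(seed=3))
    return model, topology


@pytest.fixture(scope="session")
def state_pair():
    """Synthetic c-like/m-like state pair with planted inter-state motions."""
    state_a, state_b, topology, truth = make_state_pair(seed=11)
    return state_a, state_b, topology, truth


@pytest.fixture(scope="session")
def pair_config(state_pair):
    _, _, topology, _ = state_pair
    return AnalysisConfig(topology_m=topology, topology_c=topology, frame="none")


@pytest.fixture(scope="session")
def pore_topology():
    """Minimal topology for the gated-pore occlusion fixtures."""
    return CarrierTopology(
        domain_spans={1: (1, 1), 2: (2, 2), 3: (3, 4)},
        binding_site={1},
        chain="A",
    )


@pytest.fixture(scope="session")
def occluded_pore():
    return make_gated_pore(0.0, 0.0)


@pytest.fixture(scope="session")
def top_open_pore():
    return make_gated_pore(15.0, 0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
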