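import numpy as np
import pytest

from npbind.conformation import ReferencePair
from npbind.energetics import EnergyModelConfig, mmpbsa
from npbind.synthetic import (TrajectorySpec, TwoStateSpec, make_complex,
                              make_trajectory, make_two_state_references,
                              merge_structures, particle_as_structure)


@pytest.fixture(scope="session")
def refs() -> ReferencePair:
    return make_two_state_references(TwoStateSpec(seed=1))


@pytest.fixture(scope="session")
def noisy_traj(refs):
    return make_trajectory(refs, TrajectorySpec(lambda_target=0.4,
                                                positional_noise_sd=0.5,
                                                n_frames=40, seed=11))


@pytest.fixture(scope="session")
def complex_fixture():
    protein, particle, table = make_complex(seed=0)
    comp = merge_structures(protein, particle_as_structure(particle))
    return protein, particle, table, comp


@pytest.fixture(scope="session")
def coarse_cfg() -> EnergyModelConfig:
    """Energy model with a coarse PB grid; decomposition identities are exact
    at any spacing."""
    return EnergyModelConfig(pb_grid_spacing=1.0)


@pytest.fixture(scope="session")
def wt_binding(complex_fixture, coarse_cfg):
    _, _, _, comp = complex_fixture
    return mmpbsa(comp, "chain:A", "chain:X", cfg=coarse_cfg)
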