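import numpy as np
import pytest

from allonet.cg_system import NonbondedTable
from allonet.synthetic_data import SyntheticSpec, default_selection, make_toy_pentamer


@pytest.fixture
def plain_table():
    return NonbondedTable(
        pairs={("C1", "C1"): (3.5, 0.47)},
        dialect="plain",
        use_coulomb=False,
    )


@pytest.fixture
def shift_table():
    return NonbondedTable(
        pairs={("C1", "C1"): (3.5, 0.47), ("BB", "BB"): (4.0, 0.47), ("BB", "C1"): (3.7, 0.47)},
        dialect="gromacs_shift",
        r_shift=0.9,
        r_cut=1.2,
    )


@pytest.fixture
def quiet_pentamer():
    """Zero-noise pentamer: element axes realize the schedule exactly."""
    spec = SyntheticSpec(noise_sigma=0.0, n_frames=4, seed=1)
    topo, traj = make_toy_pentamer(spec)
    return spec, topo, traj, default_selection(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
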