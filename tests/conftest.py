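import numpy as np
import pytest

from hingedyn.hinge_model import HingeState, hinge_topology, state_to_frame
from hingedyn.model_io import Atom, Topology, Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def hinge_top():
    return hinge_topology()


@pytest.fixture
def hinge_frame():
    """One embedded hinge frame at theta=95 deg, w=1.4 nm."""
    return state_to_frame(HingeState(theta=95.0, w=1.4))


@pytest.fixture
def hinge_traj(hinge_top):
    """Short embedded trajectory sweeping theta at fixed twist."""
    thetas = np.linspace(60.0, 120.0, 7)
    frames = np.stack(
        [state_to_frame(HingeState(theta=t, w=1.5)) for t in thetas]
    )
    return Trajectory(topology=hinge_top, coords=frames,
                      times=np.arange(7, dtype=float))


@pytest.fixture
def toy_topology():
    """Minimal 4-atom, 2-residue, single-chain topology."""
    atoms = [
        Atom("N", "N", "GLY", 1, "A"),
        Atom("CA", "C", "GLY", 1, "A"),
        Atom("CA", "C", "ALA", 2, "A"),
        Atom("CB", "C", "ALA", 2, "A"),
    ]
    return Topology(atoms=atoms)


def random_rotation(rng):
    """Uniform random proper rotation matrix."""
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(
        rng.integers(0, 2**31))).as_matrix()
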