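import numpy as np
import pytest

from lamtraj.model import AtomRecord, TopologyRoleMap, Trajectory
from lamtraj.synth import LamellarSpec, make_lamellar_trajectory


@pytest.fixture(scope="session")
def small_system():
    """A compact double bilayer (4 x 16 lipids, 20 frames) with ground truth."""
    spec = LamellarSpec(
        lipids_per_leaflet=16, n_frames=20, gauche_p=0.2, seed=11
    )
    traj, role_map, truth = make_lamellar_trajectory(spec)
    return traj, role_map, truth, spec


@pytest.fixture()
def three_atom_traj():
    """Two frames, three atoms, cubic 10 Å box."""
    coords = np.array(
        [
            [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0]],
            [[1.5, 2.5, 3.5], [4.5, 5.5, 6.5], [7.5, 8.5, 9.5]],
        ]
    )
    box = np.full((2, 3), 10.0)
    return Trajectory(coords, box, np.array([0.0, 5.0]), ["C71", "C72", "C73"])


def slab_role_map(n_lipids: int) -> TopologyRoleMap:
    """One headgroup atom per lipid -- enough for leaflet assignment."""
    return TopologyRoleMap(
        n_lipids, [AtomRecord(l, "O1", "headgroup_atom") for l in range(n_lipids)]
    )
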