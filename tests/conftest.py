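import numpy as np
import pytest

from mdflow import fixtures as fx


@pytest.fixture(scope="session")
def droplet():
    """Scripted droplet trajectory with known cluster membership."""
    return fx.gen_lj_droplet(n_atoms=60, n_frames=20, merge_frame=10,
                             cutoff=3.0, seed=7)


@pytest.fixture(scope="session")
def cage_pair():
    return fx.gen_cage_pair()


@pytest.fixture(scope="session")
def dodecahedron():
    return fx.gen_dodecahedral_cage()


@pytest.fixture(scope="session")
def bulk_water():
    return fx.gen_bulk_water(n_molecules=20, box_length=30.0, seed=0)


@pytest.fixture()
def mixed_water_methane():
    """Tiny system with 2 waters and 1 methane for selection tests."""
    from mdflow.datamodel import AtomTable, Box, Frame, Trajectory

    atoms = AtomTable(
        name=["OW", "HW1", "HW2", "OW", "HW1", "HW2", "C"],
        element=["O", "H", "H", "O", "H", "H", "C"],
        residue_name=["SOL"] * 3 + ["SOL"] * 3 + ["MET"],
        residue_id=[1, 1, 1, 2, 2, 2, 3],
        molecule_id=[1, 1, 1, 2, 2, 2, 3],
    )
    rng = np.random.default_rng(1)
    frame = Frame(index=0, positions=rng.uniform(0, 20, (7, 3)),
                  box=Box.cubic(20.0))
    return Trajectory(atoms=atoms, frames=[frame])
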