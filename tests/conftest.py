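import numpy as np
import pytest

from clampscreen.structio import Atom, Structure, Trajectory


def make_atom(serial, name, element, resid, chain="A", coords=(0.0, 0.0, 0.0),
              resname="ALA", occupancy=1.0):
    return Atom(serial, name, element, resname, resid, chain,
                np.asarray(coords, dtype=float), occupancy=occupancy)


@pytest.fixture
def toy_peptide():
    """Five heavy atoms over two residues on one chain."""
    atoms = [
        make_atom(1, "N", "N", 1, coords=(0.0, 0.0, 0.0)),
        make_atom(2, "CA", "C", 1, coords=(1.5, 0.0, 0.0)),
        make_atom(3, "C", "C", 1, coords=(2.2, 1.3, 0.0)),
        make_atom(4, "O", "O", 1, coords=(1.7, 2.4, 0.2)),
        make_atom(5, "CB", "C", 2, coords=(3.7, 1.2, 0.1)),
    ]
    return Structure(atoms, "toy")


@pytest.fixture
def toy_trajectory(toy_peptide):
    base = toy_peptide.coords()
    frames = [base, base + np.array([0.1, 0.0, 0.0]), base + np.array([0.0, 0.2, 0.0])]
    return Trajectory(toy_peptide, frames, dt=10.0)


def random_rotation(rng):
    """A uniformly random proper rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
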