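import numpy as np
import pytest

from lamella.io import Box, Frame
from lamella.topology import default_topologies


@pytest.fixture(scope="session")
def topos():
    return default_topologies()


def build_frame(records, box_lengths, time=0.0):
    """Assemble a Frame from (residue_index, residue_name, atom_name, xyz)."""
    return Frame(
        residue_index=[r[0] for r in records],
        residue_name=[r[1] for r in records],
        atom_name=[r[2] for r in records],
        positions=np.array([r[3] for r in records], dtype=float).reshape(-1, 3),
        box=Box(np.asarray(box_lengths, dtype=float)),
        time=time,
    )


def random_frame(rng, n_atoms=30, box_lengths=(5.0, 6.0, 7.0)):
    """Random mixed frame for round-trip and geometry properties."""
    box = np.asarray(box_lengths, dtype=float)
    names = rng.choice(["P", "N", "C32", "H2X", "MW", "K"], size=n_atoms)
    res = np.arange(1, n_atoms + 1)
    species = rng.choice(["POPC", "POPS", "SOL"], size=n_atoms)
    pos = rng.uniform(0.0, box, size=(n_atoms, 3))
    return Frame(res, species, names, pos, Box(box))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
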