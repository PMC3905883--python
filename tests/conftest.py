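import numpy as np
import pytest

from metafes.system import Atom
from metafes.synthetic import MockComplexSpec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_mock_spec():
    """A minimal 3-state mock complex: one ligand acceptor, one donor
    residue, bases at -1/+1 on both strands."""
    atoms = [
        Atom("L1", "C", 12.011, 0, "LIG", kind="ligand"),
        Atom("LO", "O", 15.999, 0, "LIG", kind="ligand"),
        Atom("ND", "N", 14.007, 1, "LYS", kind="residue"),
        Atom("NC", "C", 12.011, 1, "LYS", kind="residue"),
        Atom("Bm1i", "C", 12.011, 2, "DB", kind="base", base_position=-1,
             strand="intact"),
        Atom("Bm1s", "N", 14.007, 3, "DB", kind="base", base_position=-1,
             strand="scissile"),
        Atom("Bp1i", "C", 12.011, 4, "DB", kind="base", base_position=1,
             strand="intact"),
        Atom("Bp1s", "O", 15.999, 5, "DB", kind="base", base_position=1,
             strand="scissile"),
    ]
    return MockComplexSpec(
        atoms=atoms,
        states=["B", "Ts", "I"],
        occupancy={
            ("ND", "LO", "B"): 0.49,
            ("ND", "LO", "Ts"): 0.0,
            ("ND", "LO", "I"): 0.0,
        },
        sigma={a.name: 0.02 for a in atoms},
        state_sequence=["B"] * 400 + ["Ts"] * 20 + ["I"] * 80,
        seed=7,
    )
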