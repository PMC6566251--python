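import numpy as np
import pytest

import pycomsia as pc


@pytest.fixture(scope="session")
def table4():
    """Packaged 90-compound prediction table (73 train / 17 test)."""
    frame = pc.load_fixture("table4")
    return pc.PredictionTable(frame)


@pytest.fixture(scope="session")
def synthetic_set():
    """A planted electrostatic-signal compound set, shared across tests."""
    spec = pc.GeneratorSpec(n_compounds=50, seed=7)
    return pc.generate_set(spec)


@pytest.fixture
def water():
    """Explicit-geometry water: one O, two H, bonds present."""
    mol = pc.Molecule(
        id="water",
        atoms=[
            pc.Atom("O", [0.0, 0.0, 0.0], partial_charge=-0.8),
            pc.Atom("H", [0.96, 0.0, 0.0], partial_charge=0.4),
            pc.Atom("H", [-0.24, 0.93, 0.0], partial_charge=0.4),
        ],
        bonds=[(0, 1), (0, 2)],
    )
    return mol


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
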