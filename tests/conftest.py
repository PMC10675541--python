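import numpy as np
import pytest

from espqsar.chemio import Atom, Molecule
from espqsar.fields import GridSpec


@pytest.fixture
def water():
    return Molecule(
        id="water",
        atoms=[
            Atom("O", np.array([0.0, 0.0, 0.0]), -0.8),
            Atom("H", np.array([0.9572, 0.0, 0.0]), 0.4),
            Atom("H", np.array([-0.2400, 0.9266, 0.0]), 0.4),
        ],
    )


@pytest.fixture
def small_grid():
    """Cubic 16-node grid centred on the origin, 0.5 Å spacing."""
    n, h = 16, 0.5
    return GridSpec(origin=(-(n - 1) * h / 2,) * 3, spacing=h, npoints=(n,) * 3)


@pytest.fixture
def toy_molecule():
    from espqsar.synthdata import make_toy_molecule

    return make_toy_molecule(seed=11, n_atoms=12, mw_target=280.0)
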