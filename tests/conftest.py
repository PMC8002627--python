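import numpy as np
import pytest

from crebind import Ensemble, Structure


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_structure(rng, n_atoms=8, energy=0.0, symbols=None):
    if symbols is None:
        symbols = tuple(["C", "N", "O", "H"][i % 4] for i in range(n_atoms))
    return Structure(symbols, rng.normal(scale=2.0, size=(n_atoms, 3)), energy)


def make_ensemble(rng, n_structures=5, n_atoms=6):
    symbols = tuple(["C", "N", "O", "H"][i % 4] for i in range(n_atoms))
    return Ensemble(
        [
            make_structure(rng, n_atoms, energy=float(rng.normal(scale=3.0)), symbols=symbols)
            for _ in range(n_structures)
        ]
    )


def random_rotation(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(rng=rng).as_matrix()
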