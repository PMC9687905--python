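import numpy as np
import pytest

from hbgraph import (
    make_ideal_helix,
    make_random_structure,
    parse_pdb,
    place_hydrogens,
    strip_nonprotein,
)


@pytest.fixture(scope="session")
def helix20():
    """Protonated 20-residue ideal poly-Ala helix."""
    s = parse_pdb(make_ideal_helix(n_residues=20))
    return place_hydrogens(strip_nonprotein(s, "A"))


def protonated_random(n_residues: int, seed: int):
    s = parse_pdb(make_random_structure(n_residues, seed=seed))
    return place_hydrogens(strip_nonprotein(s))


@pytest.fixture(scope="session")
def small_family():
    """Small, quickly trainable two-class graph family for model tests."""
    from hbgraph import two_density_family

    return two_density_family(p_low=0.04, p_high=0.2, n_graphs=12, seed=7, n_nodes=(15, 25))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
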