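import numpy as np
import pytest

from pocketdiff.chem import ComplexRecord, LigandStructure, PocketStructure, lookup_radii
from pocketdiff.synth import SynthConfig, make_training_set


@pytest.fixture(scope="session")
def small_benchmark():
    """Ten clash-free synthetic complexes (seeded), shared across tests."""
    cfg = SynthConfig(seed=7, n_complexes=10)
    complexes, size_dist = make_training_set(cfg)
    return complexes, size_dist


@pytest.fixture
def carbon():
    return lookup_radii("C")


@pytest.fixture
def simple_ligand():
    """Three carbons on a line, 1.6 A apart (internally clash-free)."""
    C = lookup_radii("C")
    coords = np.array([[0.0, 0.0, 0.0], [1.6, 0.0, 0.0], [3.2, 0.0, 0.0]])
    return LigandStructure([C, C, C], coords, bonds=[(0, 1), (1, 2)])


@pytest.fixture
def box_pocket():
    """Eight pocket carbons at cube corners, side 10 A, centered at origin."""
    C = lookup_radii("C")
    corners = np.array([[sx * 5.0, sy * 5.0, sz * 5.0]
                        for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)])
    return PocketStructure([C] * 8, corners)
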