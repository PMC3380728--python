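import numpy as np
import pytest

from plow import (
    AMWStyleModel,
    FixtureSpec,
    SearchConfig,
    make_polyala,
    make_synthetic_library,
    make_toy_landscape,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def chain10():
    return make_polyala(10)


@pytest.fixture
def synthetic_library():
    """Small synthetic torsion library over a 12-residue poly-alanine."""
    return make_synthetic_library(FixtureSpec(n_residues=12, configs_per_position=4, seed=7))


@pytest.fixture
def toy3():
    """Enumerable 3-basin staircase landscape (16 states)."""
    return make_toy_landscape(FixtureSpec(n_residues=12, n_basins=3, seed=1))


@pytest.fixture
def toy6():
    """Enumerable 6-basin staircase landscape (64 states)."""
    return make_toy_landscape(FixtureSpec(n_residues=18, n_basins=6, seed=1))


@pytest.fixture
def amw_model():
    return AMWStyleModel()
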