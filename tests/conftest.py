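import numpy as np
import pytest

from semipop import (
    IndependentEnergy,
    Nonlinearity,
    PairwiseEnergy,
    PopulationModel,
    SpikeRaster,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_symmetric_j(rng, n, coupling_sd=0.15, bias_mean=-1.5, bias_sd=0.5):
    j = rng.normal(0.0, coupling_sd, (n, n))
    j = np.triu(j, 1)
    j = j + j.T
    j[np.diag_indices(n)] = rng.normal(bias_mean, bias_sd, n)
    return j


def random_semiparam_model(rng, n, q_bins=8, curvature=-0.08):
    """Small semiparametric pairwise model with a gently concave V."""
    en = PairwiseEnergy(random_symmetric_j(rng, n))
    lo, hi = en.energy_bounds()
    nl = Nonlinearity(0.0, 1.2, np.full(q_bins, curvature), lo, hi)
    return PopulationModel(en, nl)


@pytest.fixture
def small_pairwise_model(rng):
    return PopulationModel(PairwiseEnergy(random_symmetric_j(rng, 8)))


@pytest.fixture
def small_semiparam_model(rng):
    return random_semiparam_model(rng, 8)


@pytest.fixture
def small_independent_model(rng):
    return PopulationModel(IndependentEnergy(rng.normal(-1.5, 0.7, 10)))


@pytest.fixture
def labeled_raster(rng):
    """Raster with 12 stimulus repeats of 25 bins each."""
    activity = (rng.random((300, 6)) < 0.15).astype(np.int8)
    labels = np.repeat(np.arange(12), 25)
    return SpikeRaster(activity, 0.02, labels)
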