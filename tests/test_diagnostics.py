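"""Zipf curves, criticality statistic, moment comparisons, V-vs-DOS."""

import numpy as np
import pytest
from scipy.stats import binom

from semipop import (
    DensityOfStates,
    IndependentEnergy,
    Nonlinearity,
    PopulationModel,
    SpikeRaster,
    criticality_sigma,
    curvature_statistic,
    enumerate_log_z,
    extrapolate_nonlinearity,
    fit_zipf_slope,
    response_statistics,
    sample_model,
    v_vs_dos_distance,
    zipf_curve,
)

from conftest import random_semiparam_model


class TestZipf:
    def test_identical_rows_give_single_point(self):
        act = np.tile([1, 0, 1, 0], (50, 1)).astype(np.int8)
        curve = zipf_curve(SpikeRaster(act), n_bootstrap=10)
        assert curve.frequencies.size == 1
        assert curve.frequencies[0] == 1.0

    def test_frequencies_sorted_and_normalized(self, rng):
        act = (rng.random((5000, 8)) < 0.3).astype(np.int8)
        curve = zipf_curve(SpikeRaster(act), n_bootstrap=0)
        assert (np.diff(curve.frequencies) <= 0).all()
        assert curve.frequencies.sum() == pytest.approx(1.0)

    def test_identical_neurons_follow_binomial_closed_form(self):
        """Ranked probabilities of i.i.d. neurons group patterns by K."""
        n, q = 10, 0.25
        rng = np.random.default_rng(42)
        act = (rng.random((400_000, n)) < q).astype(np.int8)
        curve = zipf_curve(SpikeRaster(act), n_bootstrap=0)
        # closed form: each pattern with K ones has probability q^K (1-q)^(N-K),
        # and there are C(N, K) of them; K=0..N ordered by decreasing probability
        probs = np.array([q**k * (1 - q) ** (n - k) for k in range(n + 1)])
        mult = np.rint(binom.pmf(np.arange(n + 1), n, q) / probs).astype(int)
        order = np.argsort(probs)[::-1]
        expected = np.repeat(probs[order], mult[order])
        # compare on the interior of each constant-probability block (sampling
        # noise reorders patterns across block boundaries)
        start = 0
        for k in order[:4]:
            end = start + mult[k]
            interior = slice(start + 2, end - 2) if mult[k] > 4 else slice(start, end)
            assert np.allclose(curve.frequencies[interior], expected[interior],
                               rtol=0.2)
            start = end

    def test_bootstrap_sd_scales_with_frequency(self, rng):
        act = (rng.random((2000, 6)) < 0.3).astype(np.int8)
        curve = zipf_curve(SpikeRaster(act), n_bootstrap=200, seed=1)
        sd_expected = np.sqrt(curve.frequencies * (1 - curve.frequencies) / 2000)
        # top-rank SDs should be near multinomial noise (rank-sorting shrinks them)
        assert curve.bootstrap_sd[0] == pytest.approx(sd_expected[0], rel=0.5)


class TestCriticalitySigma:
    def test_half_rate_neurons_give_zero(self):
        m = PopulationModel(IndependentEnergy(np.zeros(8)))
        assert criticality_sigma(m) == pytest.approx(0.0, abs=1e-12)

    def test_identical_neurons_closed_form(self):
        # sqrt(q(1-q)) |log(q/(1-q))| independent of N
        q = 0.2
        a = np.full(12, np.log(q / (1 - q)))
        m = PopulationModel(IndependentEnergy(a))
        expected = np.sqrt(q * (1 - q)) * abs(np.log(q / (1 - q)))
        assert criticality_sigma(m) == pytest.approx(expected, rel=1e-12)
        # and the same closed form at a different size
        a5 = np.full(5, np.log(q / (1 - q)))
        assert criticality_sigma(PopulationModel(IndependentEnergy(a5))) == \
            pytest.approx(expected, rel=1e-12)

    def test_sample_estimate_matches_exact(self, rng):
        m = random_semiparam_model(rng, 10, q_bins=5, curvature=-0.05)
        exact = criticality_sigma(m)
        samples = sample_model(m, 200_000, seed=21)
        log_z = enumerate_log_z(m)
        est = criticality_sigma(m, samples, log_z)
        # SE of a sample SD ~ sigma / sqrt(2M)
        assert est == pytest.approx(exact, abs=0.01)

    def test_missing_log_z_raises(self, rng, small_pairwise_model):
        samples = sample_model(small_pairwise_model, 100, seed=22)
        with pytest.raises(ValueError, match="log Z"):
            criticality_sigma(small_pairwise_model, samples)


class TestResponseStatistics:
    def test_identical_inputs_give_identical_columns(self, rng):
        act = (rng.random((3000, 7)) < 0.2).astype(np.int8)
        r = SpikeRaster(act)
        tables = response_statistics(r, r, n_triplets=20, n_bootstrap=20, seed=3)
        for name, df in tables.items():
            assert np.allclose(df["data"], df["model"]), name

    def test_matches_enumeration_within_bootstrap_error(self, rng):
        from semipop import enumerate_statistics

        m = random_semiparam_model(rng, 9, q_bins=5, curvature=-0.08)
        exact = enumerate_statistics(m)
        data = sample_model(m, 60_000, seed=23)
        model_samples = sample_model(m, 60_000, seed=24)
        tables = response_statistics(data, model_samples,
                                     n_triplets=40, n_bootstrap=100, seed=4)
        rates = tables["rates"]
        resid = np.abs(rates["model"] - exact["mean"])
        assert (resid <= 3 * rates["model_sd"] + 1e-3).all()
        pk = tables["p_k"]
        assert (np.abs(pk["model"] - exact["p_k"]) <= 3 * pk["model_sd"] + 1e-3).all()
        tm = tables["third_moments"]
        expected = [exact["third_moments"][(i, j, k)]
                    for i, j, k in zip(tm["i"], tm["j"], tm["k"])]
        assert (np.abs(tm["model"] - expected) <= 3 * tm["model_sd"] + 1e-3).all()

    def test_size_mismatch_rejected(self, rng):
        a = SpikeRaster((rng.random((10, 4)) < 0.5).astype(np.int8))
        b = SpikeRaster((rng.random((10, 5)) < 0.5).astype(np.int8))
        with pytest.raises(ValueError, match="4.*5"):
            response_statistics(a, b)


class TestVvsDos:
    def _dos(self, centers, log_rho):
        half = (centers[1] - centers[0]) / 2
        edges = np.concatenate([centers - half, [centers[-1] + half]])
        return DensityOfStates(edges, log_rho, 5)

    def test_exact_match_gives_zero(self):
        centers = np.linspace(0, 2, 3)
        log_rho = np.array([0.5, 1.0, 2.0])
        # piecewise-linear V through the same values
        nl = Nonlinearity(0.5, 0.75, np.log([2.0]) / 2 * np.ones(1), 0.0, 2.0)
        dos = self._dos(centers, log_rho)
        # instead of engineering V = log rho exactly, use the offset property:
        d0, _ = v_vs_dos_distance(nl, dos)
        shifted = DensityOfStates(dos.bin_edges, dos.log_density + 7.0, 5)
        d7, _ = v_vs_dos_distance(nl, shifted)
        assert d0 == pytest.approx(d7, abs=1e-12)

    def test_linear_residual_gives_variance(self):
        # V - log rho = E on grid {0, 1, 2}: offset-minimized msd = var = 2/3
        centers = np.array([0.0, 1.0, 2.0])
        log_rho = np.zeros(3)
        nl = Nonlinearity(0.0, 1.0, np.zeros(2), 0.0, 2.0)  # V(E) = E
        dist, offset = v_vs_dos_distance(nl, self._dos(centers, log_rho))
        assert dist == pytest.approx(2.0 / 3.0)
        assert offset == pytest.approx(-1.0)

    def test_empty_overlap_raises(self):
        nl = Nonlinearity(0.0, 1.0, np.zeros(2), 0.0, 2.0)
        dos = self._dos(np.array([0.0, 1.0, 2.0]), np.zeros(3))
        with pytest.raises(ValueError, match="range"):
            v_vs_dos_distance(nl, dos, energy_range=(10.0, 20.0))


class TestCurvature:
    def test_linear_v_has_zero_curvature(self):
        nl = Nonlinearity(0.0, 1.0, np.zeros(10), -1.0, 4.0)
        assert curvature_statistic(nl) == 0.0

    def test_single_bin_exponential_closed_form(self):
        # V' = gamma2 e^{c(E - E0)}: mean |V''| = c(e^{c L} - 1)/(c L), L = E1-E0
        c, e0, e1 = 0.7, 0.0, 2.0
        nl = Nonlinearity(0.0, 1.0, [c], e0, e1)
        expected = c * (np.exp(c * (e1 - e0)) - 1) / (c * (e1 - e0))
        assert curvature_statistic(nl, n_grid=400_000) == pytest.approx(expected, rel=1e-4)

    def test_agrees_with_finite_differences(self, rng):
        nl = Nonlinearity(0.0, 1.0, rng.normal(0, 0.5, 8), 0.0, 4.0)
        e = np.linspace(0.05, 3.95, 200)
        # keep clear of bin edges where W jumps
        delta = nl.delta
        off = np.abs((e - nl.e0) / delta - np.round((e - nl.e0) / delta))
        e = e[off > 0.1]
        h = 1e-5
        fd = (nl.value(e + h) - 2 * nl.value(e) + nl.value(e - h)) / h**2
        assert np.abs(nl.second_deriv(e) - fd).max() < 1e-4


class TestExtrapolation:
    def test_identical_curves_extrapolate_to_themselves(self):
        grid = np.linspace(-1, 1, 11)
        v = np.sin(grid)
        out = extrapolate_nonlinearity([(80, v), (100, v), (120, v)], grid=None)
        assert np.allclose(out, v)

    def test_exact_one_over_n_family_recovers_intercept(self):
        grid = np.linspace(0, 1, 21)
        a = grid**2
        b = 3.0 * grid + 1.0
        curves = [(n, a + b / n) for n in (80, 100, 120, 140)]
        out = extrapolate_nonlinearity(curves, grid=None)
        assert np.allclose(out, a, atol=1e-12)

    def test_noisy_recovery_within_tolerance(self, rng):
        grid = np.linspace(0, 1, 15)
        a = np.cos(grid)
        b = -2.0 * grid
        curves = [(n, a + b / n + rng.normal(0, 0.01, grid.size))
                  for n in (80, 100, 120, 140, 160)]
        out = extrapolate_nonlinearity(curves, grid=None)
        assert np.abs(out - a).max() < 0.05

    def test_small_n_curves_excluded(self):
        grid = np.linspace(0, 1, 5)
        curves = [(40, grid), (60, grid)]
        with pytest.raises(ValueError, match="80"):
            extrapolate_nonlinearity(curves, grid=None)


def test_criticality_grows_with_size_for_latent_but_not_independent():
    """sigma(log p)/sqrt(N) rises with N under global coupling only.

    For the latent-mixture population the statistic grows with N; for
    independent populations at matched rates it stays of constant order
    (for identical independent neurons it is exactly N-independent).
    The mixture's log p(s) is computed exactly per sample via its
    energy: log p = logsumexp_k [log w_k - h_k E(s) - log Z(h_k)].
    """
    from scipy.special import logsumexp

    from semipop import (broad_latent_weights, default_alpha,
                         generate_latent_population, independent_log_z_curve)

    h, w = broad_latent_weights()
    keep = w > 0
    sig_latent, sig_indep = [], []
    for n in (20, 80):
        alpha = default_alpha(n, seed=0)
        raster, _ = generate_latent_population((h, w), alpha, 100_000, seed=7)
        e = IndependentEnergy(alpha).energy(raster.activity.astype(float))
        log_z = independent_log_z_curve(alpha, h[keep])
        logp = logsumexp(np.log(w[keep])[:, None]
                         - h[keep][:, None] * e[None, :]
                         - log_z[:, None], axis=0)
        sig_latent.append(logp.std(ddof=1) / np.sqrt(n))
        rates = raster.firing_rates().clip(1e-4, 1 - 1e-4)
        rng2 = np.random.default_rng(8)
        ind = (rng2.random((100_000, n)) < rates).astype(float)
        logp_ind = ind @ np.log(rates) + (1 - ind) @ np.log(1 - rates)
        sig_indep.append(logp_ind.std(ddof=1) / np.sqrt(n))
    assert sig_latent[1] > sig_latent[0] * 1.2
    assert sig_indep[1] < sig_indep[0] * 1.2


def test_latent_zipf_steeper_than_matched_independent():
    """Over the same mid ranks the independent curve is > 0.2 shallower."""
    from semipop import broad_latent_weights, default_alpha, generate_latent_population

    alpha = default_alpha(60, seed=0)
    raster, _ = generate_latent_population(broad_latent_weights(), alpha,
                                           300_000, seed=38)
    rng = np.random.default_rng(39)
    rates = raster.firing_rates().clip(1e-6, 1 - 1e-6)
    ind = SpikeRaster((rng.random((300_000, 60)) < rates).astype(np.int8))
    ranks = (10, 200)
    s_lat = fit_zipf_slope(zipf_curve(raster, n_bootstrap=0), ranks)
    s_ind = fit_zipf_slope(zipf_curve(ind, n_bootstrap=0), ranks)
    assert s_ind - s_lat > 0.2  # latent slope is more negative
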