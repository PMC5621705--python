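"""Gibbs sampling, Persistent Contrastive Divergence, and conditional
single-neuron prediction.

Training follows stochastic approximate gradient ascent on the data
log-likelihood: parameters move along the difference between model
expectations (estimated from a bank of persistent Gibbs chains that is
advanced a few single-site updates per iteration) and data expectations.
For the maximum-entropy baselines the gradients are plain moment
differences; for the semiparametric families the energy-parameter
gradients are weighted by V'(E) and the nonlinearity parameters follow
their own analytic gradients with a separate (much smaller) rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np

from .models import (
    IndependentEnergy,
    Nonlinearity,
    PairwiseEnergy,
    PopulationModel,
)
from .raster import SpikeRaster

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "gibbs_update", "pcd_fit", "predict_single_neuron"]

FAMILIES = (
    "independent",
    "pairwise",
    "k_pairwise",
    "semiparam_independent",
    "semiparam_pairwise",
)


@dataclass
class TrainConfig:
    """Hyperparameters of the PCD optimizer.

    Defaults are the large-recording settings: learning rate 1 for
    energy parameters and 5e-5 for the nonlinearity parameters, n = 2N
    single-site Gibbs updates of every persistent chain per iteration,
    Q = 20 nonlinearity bins, and a two-stage schedule for the
    maximum-entropy baselines (10^4 iterations at 3x10^4 chains, then
    10^4 at 3x10^5).  All fields are overridable for small problems.

    ``average_last`` > 0 replaces the returned parameters with their
    average over the final fraction of iterations, which suppresses the
    stationary stochastic-gradient fluctuations at small chain counts.
    """

    eta_energy: float = 1.0
    eta_nonlinearity: float = 5e-5
    n_iterations: int = 10_000
    n_chains: int = 30_000
    n_gibbs: int | None = None          # default 2N
    seed: int = 0
    n_bins_nonlinearity: int = 20       # Q
    baseline_schedule: list[tuple[int, int]] | None = None
    grid_pad: float = 0.2               # widening of [E0, E1] per side
    init_sd: float = 0.1
    average_last: float = 0.0
    log_every: int = 200

    def resolved_baseline_schedule(self) -> list[tuple[int, int]]:
        if self.baseline_schedule is not None:
            return list(self.baseline_schedule)
        return [(self.n_iterations, self.n_chains),
                (self.n_iterations, 10 * self.n_chains)]


# ---------------------------------------------------------------------------
# Gibbs sampling

def _delta_energy(model: PopulationModel, S: np.ndarray, sites: np.ndarray):
    """E(s_i=1) - E(s_i=0) at the chosen site of each chain."""
    en = model.energy
    if isinstance(en, IndependentEnergy):
        return -en.alpha[sites]
    J = en.J
    rows = J[sites]                        # (M, N)
    tot = np.einsum("mn,mn->m", rows, S)   # includes the j = i term
    diag = np.diagonal(J)[sites]
    cur = S[np.arange(S.shape[0]), sites]
    field = tot - diag * cur               # sum_{j != i} J_ij s_j
    return -(diag + 2.0 * field)


def _site_logit(model: PopulationModel, S, E, K, sites):
    """log p(s_i=1|s_-i) - log p(s_i=0|s_-i) and bookkeeping pieces."""
    cur = S[np.arange(S.shape[0]), sites]
    dE = _delta_energy(model, S, sites)
    e_off = E - cur * dE
    if model.nonlinearity is None:
        logit = -dE
    else:
        v0 = model.nonlinearity.value(e_off)
        v1 = model.nonlinearity.value(e_off + dE)
        logit = -(v1 - v0)
    if model.k_potential is not None:
        k_off = (K - cur).astype(np.int64)
        logit = logit + model.k_potential[k_off + 1] - model.k_potential[k_off]
    return logit, dE, e_off, cur


def _gibbs_sweep(model, S, E, K, rng, n_updates):
    """n_updates vectorized single-site heat-bath updates (in place)."""
    m = S.shape[0]
    n = S.shape[1]
    rows = np.arange(m)
    for _ in range(n_updates):
        sites = rng.integers(0, n, size=m)
        logit, dE, e_off, cur = _site_logit(model, S, E, K, sites)
        p1 = 1.0 / (1.0 + np.exp(-logit))
        new = (rng.random(m) < p1).astype(S.dtype)
        S[rows, sites] = new
        E[:] = e_off + new * dE
        if K is not None:
            K[:] = K - cur + new
    return S, E, K


def gibbs_update(
    state: np.ndarray,
    model: PopulationModel,
    rng: np.random.Generator,
    n_updates: int,
) -> np.ndarray:
    """Apply single-site heat-bath updates to a state (or a batch).

    Each update picks one site uniformly at random (independently per
    chain for batched input) and resamples it from the exact conditional
    p(s_i | s_-i).  Deterministic given the generator state.
    """
    single = np.asarray(state).ndim == 1
    S = np.atleast_2d(np.asarray(state)).astype(np.float64).copy()
    if S.shape[1] != model.n_neurons:
        raise ValueError(
            f"state dimension {S.shape[1]} does not match model "
            f"dimension {model.n_neurons}"
        )
    E = np.asarray(model.energy.energy(S), dtype=float).copy()
    K = S.sum(axis=1).astype(np.int64) if model.k_potential is not None else None
    _gibbs_sweep(model, S, E, K, rng, n_updates)
    out = S.astype(np.int8)
    return out[0] if single else out


# ---------------------------------------------------------------------------
# PCD training

def _energy_of(family: str, params: dict):
    if "independent" in family:
        return IndependentEnergy(params["alpha"])
    return PairwiseEnergy(params["J"])


def _weighted_moments(family, S, w):
    """E_w[grad_theta E(s)] with energy-parameter sign folded in.

    Returns d log-lik contribution: for independent energies the
    per-neuron weighted mean, for pairwise the weighted second-moment
    matrix (ordered-pair convention keeps the result symmetric).
    """
    wm = w.mean()
    if "independent" in family:
        return (S * w[:, None]).mean(axis=0), wm
    return (S * w[:, None]).T @ S / S.shape[0], wm


def pcd_fit(
    data: SpikeRaster,
    model_spec: str,
    config: TrainConfig | None = None,
) -> PopulationModel:
    """Fit one of the five model families by Persistent CD.

    model_spec is one of 'independent', 'pairwise', 'k_pairwise',
    'semiparam_independent', 'semiparam_pairwise'.  Semiparametric fits
    are initialized from the corresponding fitted baseline with a linear
    nonlinearity whose grid covers the initial data-energy range widened
    by ``config.grid_pad`` on each side.
    """
    if model_spec not in FAMILIES:
        raise ValueError(f"unknown model_spec {model_spec!r}; choose from {FAMILIES}")
    config = config or TrainConfig()
    rng = np.random.default_rng(config.seed)
    X = data.activity.astype(np.float64)
    t, n = X.shape
    n_gibbs = config.n_gibbs if config.n_gibbs is not None else 2 * n

    semiparam = model_spec.startswith("semiparam")
    if semiparam:
        baseline_spec = "independent" if "independent" in model_spec else "pairwise"
        base_cfg = replace(config, seed=config.seed + 1)
        baseline = pcd_fit(data, baseline_spec, base_cfg)
        params = (
            {"alpha": baseline.energy.alpha.copy()}
            if baseline_spec == "independent"
            else {"J": baseline.energy.J.copy()}
        )
        e_data = _energy_of(model_spec, params).energy(X)
        span = e_data.max() - e_data.min()
        span = span if span > 0 else 1.0
        e0 = e_data.min() - config.grid_pad * span
        e1 = e_data.max() + config.grid_pad * span
        nl = Nonlinearity.linear(e0, e1, config.n_bins_nonlinearity)
        stages = [(config.n_iterations, config.n_chains)]
    else:
        if model_spec == "independent":
            params = {"alpha": rng.normal(0.0, config.init_sd, n)}
        else:
            A = rng.normal(0.0, config.init_sd, (n, n))
            J = np.triu(A)
            params = {"J": J + np.triu(J, 1).T}
        nl = None
        stages = config.resolved_baseline_schedule()
    phi = np.zeros(n + 1) if model_spec == "k_pairwise" else None

    rates = np.clip(X.mean(axis=0), 1e-4, 1 - 1e-4)
    # data moments of the baseline families are constant across iterations
    data_mean = X.mean(axis=0)
    data_second = X.T @ X / t
    data_pk = np.bincount(data.population_counts(), minlength=n + 1) / t

    train_log: list[dict] = []
    it_global = 0
    for stage_idx, (n_iter, n_chains) in enumerate(stages):
        S = (rng.random((n_chains, n)) < rates[None, :]).astype(np.float64)
        energy = _energy_of(model_spec, params)
        model = PopulationModel(energy, nl, phi)
        E = np.asarray(energy.energy(S), dtype=float)
        K = S.sum(axis=1).astype(np.int64) if phi is not None else None

        avg_from = n_iter - int(np.floor(config.average_last * n_iter)) \
            if (config.average_last > 0 and stage_idx == len(stages) - 1) else n_iter
        avg_acc: dict = {}
        n_avg = 0

        for it in range(n_iter):
            it_global += 1
            if semiparam:
                e_data = energy.energy(X)
                _, vp_data = nl.value_and_deriv(e_data)
                _, vp_chain = nl.value_and_deriv(E)
                stat_data, _ = _weighted_moments(model_spec, X, vp_data)
                stat_chain, _ = _weighted_moments(model_spec, S, vp_chain)
            else:
                stat_data = data_mean if model_spec == "independent" else data_second
                if model_spec == "independent":
                    stat_chain = S.mean(axis=0)
                else:
                    stat_chain = S.T @ S / n_chains

            grad_energy = stat_data - stat_chain  # ascent direction
            if not np.isfinite(grad_energy).all():
                raise FloatingPointError(
                    f"non-finite energy gradient at iteration {it_global}"
                )
            key = "alpha" if "independent" in model_spec else "J"
            params[key] = params[key] + config.eta_energy * grad_energy

            if phi is not None:
                chain_pk = np.bincount(K, minlength=n + 1) / n_chains
                phi = phi + config.eta_energy * (data_pk - chain_pk)

            if semiparam:
                g1d, g2d, gbd = nl.grad_params(e_data)
                g1c, g2c, gbc = nl.grad_params(E)
                dgam1 = g1c.mean() - g1d.mean()
                dgam2 = g2c.mean() - g2d.mean()
                dbeta = gbc.mean(axis=0) - gbd.mean(axis=0)
                if not (np.isfinite(dgam2) and np.isfinite(dbeta).all()):
                    raise FloatingPointError(
                        f"non-finite nonlinearity gradient at iteration {it_global}"
                    )
                # sign: d log-lik / d theta = E_chain[dV] - E_data[dV]... the
                # unnormalized log-prob is -V, so ascent moves theta by
                # eta * (E_chain[dV] - E_data[dV]) with the conventions above
                nl = Nonlinearity(
                    nl.gamma1 + config.eta_nonlinearity * dgam1,
                    nl.gamma2 + config.eta_nonlinearity * dgam2,
                    nl.beta + config.eta_nonlinearity * dbeta,
                    nl.e0, nl.e1,
                )

            energy = _energy_of(model_spec, params)
            model = PopulationModel(energy, nl, phi)
            E = np.asarray(energy.energy(S), dtype=float)
            _gibbs_sweep(model, S, E, K, rng, n_gibbs)

            if it >= avg_from:
                n_avg += 1
                for k, v in params.items():
                    avg_acc[k] = avg_acc.get(k, 0.0) + v
                if semiparam:
                    avg_acc["_nl"] = avg_acc.get("_nl", np.zeros(nl.beta.size + 2)) + \
                        np.concatenate(([nl.gamma1, nl.gamma2], nl.beta))
                if phi is not None:
                    avg_acc["_phi"] = avg_acc.get("_phi", 0.0) + phi

            if (it + 1) % config.log_every == 0 or it == n_iter - 1:
                gap = float(np.max(np.abs(grad_energy)))
                train_log.append(
                    {"iteration": it_global, "stage": stage_idx,
                     "max_moment_gap": gap}
                )

        if n_avg > 0:
            for k in list(params):
                params[k] = avg_acc[k] / n_avg
            if semiparam:
                g1, g2, *b = avg_acc["_nl"] / n_avg
                nl = Nonlinearity(g1, g2, np.array(b), nl.e0, nl.e1)
            if phi is not None:
                phi = avg_acc["_phi"] / n_avg

    energy = _energy_of(model_spec, params)
    out_frac = 0.0
    if semiparam:
        if nl.gamma2 <= 0:
            logger.warning(
                "fitted nonlinearity has non-positive slope gamma2=%g; the "
                "model is not increasing in energy", nl.gamma2,
            )
        e_data = energy.energy(X)
        out_frac = float(np.mean((e_data < nl.e0) | (e_data > nl.e1)))
        if out_frac > 0.05:
            logger.warning(
                "%.1f%% of data energies fall outside the nonlinearity grid "
                "[%g, %g]; the linear tails are extrapolating", 100 * out_frac,
                nl.e0, nl.e1,
            )
    provenance = {
        "family": model_spec,
        "seed": config.seed,
        "config": {
            "eta_energy": config.eta_energy,
            "eta_nonlinearity": config.eta_nonlinearity,
            "n_iterations": config.n_iterations,
            "n_chains": config.n_chains,
            "n_gibbs": n_gibbs,
            "n_bins_nonlinearity": config.n_bins_nonlinearity,
            "average_last": config.average_last,
        },
        "n_iterations_run": it_global,
        "train_log": train_log,
        "out_of_grid_fraction": out_frac,
    }
    return PopulationModel(energy, nl, phi, provenance=provenance)


# ---------------------------------------------------------------------------
# single-neuron prediction

class PredictionResult(NamedTuple):
    p_spike: np.ndarray       # p(s_i = 1 | s_-i) per time bin
    prediction: np.ndarray    # argmax prediction per time bin
    error_rate: float         # fraction of mispredicted bins
    errors_per_second: float


def predict_single_neuron(
    data: SpikeRaster, model: PopulationModel, neuron: int
) -> PredictionResult:
    """Predict one neuron from the rest of the population.

    Uses Bayes' rule on the two unnormalized probabilities (no Z
    needed): p(s_i|s_-i) = p(s_i, s_-i) / sum_{s_i} p(s_i, s_-i), then
    predicts the more likely state.  Ties predict silence.
    """
    n = model.n_neurons
    if not 0 <= neuron < n:
        raise IndexError(f"neuron index {neuron} out of range for N={n}")
    if data.n_neurons != n:
        raise ValueError(
            f"raster has {data.n_neurons} neurons, model has {n}"
        )
    S0 = data.activity.astype(np.float64)
    S1 = S0.copy()
    S0[:, neuron] = 0.0
    S1[:, neuron] = 1.0
    lp0 = model.log_prob_unnorm(S0)
    lp1 = model.log_prob_unnorm(S1)
    p1 = 1.0 / (1.0 + np.exp(lp0 - lp1))
    pred = (lp1 > lp0).astype(np.int8)
    err = float(np.mean(pred != data.activity[:, neuron]))
    return PredictionResult(p1, pred, err, err / data.bin_width)
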