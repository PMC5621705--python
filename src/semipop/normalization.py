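"""Stochastic normalization: annealed importance sampling for log Z and
the Wang-Landau flat-histogram estimate of the density of states.

Both estimators target quantities that the exact enumeration oracle can
also compute for N <= 20; beyond that they are the only route to
normalized probabilities and to the density of states.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.special import logsumexp

from .exact import DensityOfStates
from .models import (
    IndependentEnergy,
    PairwiseEnergy,
    PopulationModel,
)

logger = logging.getLogger(__name__)

__all__ = ["ais_log_z", "ais_standard_error", "WangLandauConfig", "wang_landau"]


def _base_alpha(model: PopulationModel, base) -> np.ndarray:
    """Field vector of the independent base distribution for AIS."""
    n = model.n_neurons
    if base is None:
        return np.zeros(n)
    if isinstance(base, PopulationModel):
        if not isinstance(base.energy, IndependentEnergy) or base.nonlinearity is not None:
            raise ValueError("AIS base must be an independent identity-V model")
        return base.energy.alpha.copy()
    rates = np.asarray(base, dtype=float).ravel()
    if rates.size != n:
        raise ValueError(f"base rates have length {rates.size}, model N={n}")
    if ((rates <= 0) | (rates >= 1)).any():
        logger.warning("AIS base rates clipped to [1e-6, 1 - 1e-6]")
        rates = np.clip(rates, 1e-6, 1 - 1e-6)
    return np.log(rates / (1 - rates))


def ais_log_z(
    model: PopulationModel,
    n_steps: int = 10_000,
    n_samples: int = 10_000,
    seed: int = 0,
    base=None,
) -> tuple[float, np.ndarray]:
    """Estimate log Z by annealed importance sampling.

    The path interpolates geometrically (uniform schedule on the
    exponent) from an independent base model -- given as a fitted
    independent ``PopulationModel``, a vector of firing rates, or None
    for the uniform distribution -- to the target.  One systematic
    Gibbs sweep (one update per site) is applied per intermediate
    distribution.  Returns the log-mean-exp estimate together with the
    per-sample log weights, whose spread yields a standard error.
    """
    rng = np.random.default_rng(seed)
    n = model.n_neurons
    alpha = _base_alpha(model, base)
    log_z_base = float(np.sum(np.logaddexp(0.0, alpha)))

    p_base = 1.0 / (1.0 + np.exp(-alpha))
    S = (rng.random((n_samples, n)) < p_base[None, :]).astype(np.float64)

    def log_p_base(S):
        return S @ alpha

    log_w = np.zeros(n_samples)
    betas = np.linspace(0.0, 1.0, n_steps + 1)
    lp_t = model.log_prob_unnorm(S)
    lp_b = log_p_base(S)
    rows = np.arange(n_samples)
    is_pairwise = isinstance(model.energy, PairwiseEnergy)
    E = np.asarray(model.energy.energy(S), dtype=float)
    K = S.sum(axis=1).astype(np.int64) if model.k_potential is not None else None

    for t in range(1, n_steps + 1):
        db = betas[t] - betas[t - 1]
        log_w += db * (lp_t - lp_b)
        b = betas[t]
        # one heat-bath update per site at inverse temperature b
        for i in range(n):
            cur = S[:, i].copy()
            if is_pairwise:
                J = model.energy.J
                tot = S @ J[:, i]
                dE = -(J[i, i] + 2.0 * (tot - J[i, i] * cur))
            else:
                dE = np.full(n_samples, -model.energy.alpha[i])
            e_off = E - cur * dE
            if model.nonlinearity is None:
                logit_t = -dE
            else:
                logit_t = -(model.nonlinearity.value(e_off + dE)
                            - model.nonlinearity.value(e_off))
            if model.k_potential is not None:
                k_off = K - cur.astype(np.int64)
                logit_t = logit_t + model.k_potential[k_off + 1] - model.k_potential[k_off]
            logit = (1.0 - b) * alpha[i] + b * logit_t
            new = (rng.random(n_samples) < 1.0 / (1.0 + np.exp(-logit))).astype(float)
            S[rows, i] = new
            E = e_off + new * dE
            if K is not None:
                K = K - cur.astype(np.int64) + new.astype(np.int64)
        lp_t = model.log_prob_unnorm(S)
        lp_b = log_p_base(S)

    estimate = log_z_base + logsumexp(log_w) - np.log(n_samples)
    return float(estimate), log_w


def ais_standard_error(log_weights: np.ndarray) -> float:
    """Delta-method standard error of the log Z estimate."""
    w = np.asarray(log_weights, dtype=float)
    m = w.max()
    lin = np.exp(w - m)
    return float(lin.std(ddof=1) / (lin.mean() * np.sqrt(lin.size)))


# ---------------------------------------------------------------------------
# Wang-Landau

@dataclass
class WangLandauConfig:
    """Schedule of the flat-histogram walk.

    The log-density increment starts at ``initial_increment`` and is
    halved after every ``steps_per_level`` proposed moves until it falls
    below ``final_increment`` (a fixed-iteration schedule; histogram
    flatness is not checked because inaccessible bins make it
    ill-defined).  ``bin_edges`` overrides the automatic energy range,
    which is otherwise taken from rigorous interval bounds on the energy
    so that no state can fall outside the binned range.
    """

    n_bins: int = 1000
    final_increment: float = 1e-7
    steps_per_level: int = 1_000_000
    initial_increment: float = 1.0
    seed: int = 0
    bin_edges: np.ndarray | None = None
    trap_limit: int = 10_000_000


@njit(cache=True)
def _wl_kernel(J, e_lo, bin_width, n_bins, levels, steps_per_level, seed, trap_limit):
    n = J.shape[0]
    np.random.seed(seed)
    log_g = np.zeros(n_bins)
    visited = np.zeros(n_bins, dtype=np.bool_)
    s = (np.random.random(n) < 0.5).astype(np.float64)
    e = 0.0
    for i in range(n):
        for j in range(n):
            e -= J[i, j] * s[i] * s[j]
    cur = int((e - e_lo) / bin_width)
    if cur >= n_bins:
        cur = n_bins - 1
    f = 0.0
    since_accept = 0
    for lev in range(levels.shape[0]):
        f = levels[lev]
        for _ in range(steps_per_level):
            i = np.random.randint(0, n)
            field = 0.0
            for j in range(n):
                field += J[i, j] * s[j]
            field -= J[i, i] * s[i]
            d_e = -(J[i, i] + 2.0 * field)   # E(s_i=1) - E(s_i=0)
            if s[i] == 1.0:
                e_new = e - d_e
            else:
                e_new = e + d_e
            new = int((e_new - e_lo) / bin_width)
            if new >= n_bins:
                new = n_bins - 1
            if new < 0:
                new = 0
            if np.log(np.random.random()) < log_g[cur] - log_g[new]:
                s[i] = 1.0 - s[i]
                e = e_new
                cur = new
                since_accept = 0
            else:
                since_accept += 1
                if since_accept > trap_limit:
                    return log_g, visited, cur, -1
            log_g[cur] += f
            visited[cur] = True
    return log_g, visited, cur, 0


def wang_landau(energy, config: WangLandauConfig | None = None) -> DensityOfStates:
    """Estimate the binned density of states of an energy function.

    Runs a single-site-flip flat-histogram walk with multiplicative
    log-density increments halved on a fixed schedule.  The result is
    normalized so that the occupied bins sum to 2^N states; bins never
    visited are flagged (NaN log-density) rather than zero-filled,
    since the walk cannot distinguish "no states" from "not reached".
    """
    config = config or WangLandauConfig()
    if isinstance(energy, IndependentEnergy):
        J = np.diag(energy.alpha)
    elif isinstance(energy, PairwiseEnergy):
        J = energy.J.copy()
    else:
        raise TypeError(f"unsupported energy type {type(energy).__name__}")
    n = J.shape[0]

    if config.bin_edges is not None:
        edges = np.asarray(config.bin_edges, dtype=float)
        n_bins = edges.size - 1
        if not np.allclose(np.diff(edges), edges[1] - edges[0]):
            raise ValueError("wang_landau requires uniform bin edges")
        bin_width = edges[1] - edges[0]
        e_lo = edges[0]
    else:
        lo, hi = energy.energy_bounds()
        span = max(hi - lo, 1e-12)
        pad = 1e-9 * span
        e_lo, e_hi = lo - pad, hi + pad
        n_bins = config.n_bins
        bin_width = (e_hi - e_lo) / n_bins
        edges = e_lo + bin_width * np.arange(n_bins + 1)

    levels = []
    f = config.initial_increment
    while True:
        levels.append(f)
        if f <= config.final_increment:
            break
        f = max(f / 2.0, config.final_increment)
    levels = np.asarray(levels)

    log_g, visited, cur, status = _wl_kernel(
        J, e_lo, bin_width, n_bins, levels,
        int(config.steps_per_level), int(config.seed) % (2**31),
        int(config.trap_limit),
    )
    if status == -1:
        raise RuntimeError(
            f"Wang-Landau walker trapped: no accepted move in "
            f"{config.trap_limit} steps while in bin {cur} "
            f"(energy ~ {e_lo + (cur + 0.5) * bin_width:.6g})"
        )
    log_density = np.full(n_bins, np.nan)
    occ = visited
    # impose sum over occupied bins of rho * width = 2^N
    norm = logsumexp(log_g[occ])
    log_density[occ] = log_g[occ] - norm + n * np.log(2.0) - np.log(bin_width)
    return DensityOfStates(edges, log_density, n)
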