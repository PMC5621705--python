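"""Latent-variable view of the nonlinearity.

A one-dimensional latent variable h with density q(h), mixed over
exponential tilts of a fixed energy function,

    p(s) = int q(h) exp(-h E(s)) / Z(h) dh,

is mathematically equivalent to a semiparametric model exp(-V(E(s)))/Z:
the Laplace transform of q determines V.  This module provides the
forward synthesis (q -> V), the maximum-likelihood inversion of the
mixture weights on a fixed h grid (V -> q, via EM over mixing
proportions with the component family frozen), the per-sample MAP
readout h*, and the entropy of q.  Z(h) comes from a density of states
(one estimate serves every h) or from the closed form available for
independent energies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .exact import DensityOfStates

logger = logging.getLogger(__name__)

__all__ = [
    "LatentDensity",
    "make_h_grid",
    "latent_log_z_curve",
    "independent_log_z_curve",
    "infer_latent_density",
    "nonlinearity_from_latent",
    "map_h_star",
]


def make_h_grid(h_min: float = 0.0, h_max: float = 5.0, n_bins: int = 400):
    """Midpoints and width of a uniform latent grid (default [0, 5] x 400)."""
    edges = np.linspace(h_min, h_max, n_bins + 1)
    return 0.5 * (edges[:-1] + edges[1:]), edges[1] - edges[0]


@dataclass
class LatentDensity:
    """Gridded latent density q(h) with its log Z(h) curve.

    ``q`` are nonnegative densities on uniform bins of width ``dh``
    centered at ``h_grid``; sum(q) * dh = 1.  ``log_z_curve`` holds
    log Z(h) of the tilted component at each grid point.
    """

    h_grid: np.ndarray
    q: np.ndarray
    dh: float
    log_z_curve: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.h_grid = np.asarray(self.h_grid, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        self.log_z_curve = np.asarray(self.log_z_curve, dtype=float)
        if (self.q < 0).any():
            raise ValueError("q must be nonnegative")
        if not (np.diff(self.h_grid) > 0).all():
            raise ValueError("h_grid must be strictly increasing")
        total = float(self.q.sum() * self.dh)
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"q must integrate to 1, got {total}")

    def entropy(self) -> float:
        """Discrete entropy -sum q dh log q over occupied bins (nats)."""
        w = self.q[self.q > 0]
        return float(-np.sum(w * self.dh * np.log(w)))


def latent_log_z_curve(dos: DensityOfStates, h_grid: np.ndarray) -> np.ndarray:
    """log Z(h) = log sum_bins rho(E) dE exp(-h E) from a density of states."""
    ok = dos.accessible
    if not ok.any():
        raise ValueError("density of states has no occupied bins")
    log_mass = dos.log_density[ok] + np.log(dos.bin_widths[ok])
    e = dos.bin_centers[ok]
    h = np.asarray(h_grid, dtype=float)
    return logsumexp(log_mass[None, :] - h[:, None] * e[None, :], axis=1)


def independent_log_z_curve(alpha: np.ndarray, h_grid: np.ndarray) -> np.ndarray:
    """Closed form log Z(h) = sum_i log(1 + e^{h alpha_i}) for E = -sum alpha_i s_i."""
    a = np.asarray(alpha, dtype=float).ravel()
    h = np.asarray(h_grid, dtype=float)
    return np.logaddexp(0.0, h[:, None] * a[None, :]).sum(axis=1)


def infer_latent_density(
    sample_energies: np.ndarray,
    dos: DensityOfStates | None = None,
    h_grid: np.ndarray | None = None,
    dh: float | None = None,
    log_z_curve: np.ndarray | None = None,
    n_energy_bins: int = 1024,
    tol: float = 1e-9,
    max_iter: int = 50_000,
    smoothing: float = 0.0,
) -> LatentDensity:
    """Maximum-likelihood latent density on a fixed grid, by EM.

    The model is a finite mixture over the grid points h_k with frozen
    component family p(E | h_k) = exp(-h_k E - log Z(h_k)); only the
    mixing proportions are optimized, so EM increases the likelihood
    monotonically and stays on the simplex.  Sample energies (computed
    under the fixed, previously fitted energy parameters) are binned
    before the E-step, which makes the cost independent of the sample
    count.  Converged when the relative log-likelihood change drops
    below ``tol``.

    ``smoothing`` > 0 switches to smoothed EM (EMS): after every M-step
    the mixing weights are convolved with a Gaussian of that standard
    deviation (in h units, edge mass reflected).  The energy only
    resolves latent structure down to a finite scale, and along the
    unresolved directions plain EM drifts indefinitely at negligible
    likelihood gain; a resolution-scale bandwidth removes that drift.
    Use 0 (pure maximum likelihood) when q is expected to be discrete.
    """
    if h_grid is None:
        h_grid, dh = make_h_grid()
    else:
        h_grid = np.asarray(h_grid, dtype=float)
        if dh is None:
            steps = np.diff(h_grid)
            if not np.allclose(steps, steps[0]):
                raise ValueError("h_grid must be uniform")
            dh = float(steps[0])
    if log_z_curve is None:
        if dos is None:
            raise ValueError("provide either a DensityOfStates or a log_z_curve")
        log_z_curve = latent_log_z_curve(dos, h_grid)
    log_z_curve = np.asarray(log_z_curve, dtype=float)

    e = np.asarray(sample_energies, dtype=float).ravel()
    m = e.size
    lo, hi = e.min(), e.max()
    span = max(hi - lo, 1e-12)
    edges = np.linspace(lo - 1e-9 * span, hi + 1e-9 * span, n_energy_bins + 1)
    counts, _ = np.histogram(e, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    occ = counts > 0
    counts = counts[occ].astype(float)
    centers = centers[occ]

    kernel = None
    if smoothing > 0:
        nb = max(1, int(round(3 * smoothing / dh)))
        x = np.arange(-nb, nb + 1) * dh
        kernel = np.exp(-0.5 * (x / smoothing) ** 2)
        kernel /= kernel.sum()

    # (B, J): log-likelihood of each occupied energy bin under component k
    log_f = -h_grid[:, None] * centers[None, :] - log_z_curve[:, None]
    log_pi = np.full(h_grid.size, -np.log(h_grid.size))
    prev_ll = -np.inf
    for it in range(max_iter):
        scored = log_pi[:, None] + log_f
        ll_j = logsumexp(scored, axis=0)
        if not np.isfinite(ll_j).all():
            bad = centers[~np.isfinite(ll_j)][0]
            raise ValueError(
                f"sample with energy {bad:.6g} has zero likelihood under "
                "every latent grid point; the h grid is too narrow"
            )
        ll = float(counts @ ll_j) / m
        resp = np.exp(scored - ll_j[None, :])
        weights = resp @ counts / m
        if kernel is not None:
            nb = (kernel.size - 1) // 2
            full = np.convolve(weights, kernel, mode="full")
            weights = full[nb:-nb].copy()
            weights[:nb] += full[:nb][::-1]     # reflect edge mass back in
            weights[-nb:] += full[-nb:][::-1]
            weights /= weights.sum()
        log_pi = np.log(np.maximum(weights, 1e-300))
        if it > 0 and abs(ll - prev_ll) <= tol * max(1.0, abs(ll)):
            break
        prev_ll = ll
    q = np.exp(log_pi) / dh
    q /= q.sum() * dh
    return LatentDensity(
        h_grid, q, dh, log_z_curve,
        provenance={"n_samples": int(m), "em_iterations": it + 1,
                    "log_likelihood": ll},
    )


def nonlinearity_from_latent(q: LatentDensity, energy_grid: np.ndarray) -> np.ndarray:
    """Synthesize V(E) on a grid from a latent density (V(0) = 0 gauge).

    V(E) = -log sum_k q_k dh exp(-h_k E - log Z(h_k)), shifted so that
    V(0) = 0.  Exact for mixtures supported on the grid; for a narrow
    q the curvature of V near the mean energy is proportional to the
    latent variance.
    """
    e = np.asarray(energy_grid, dtype=float)
    log_w = np.log(np.maximum(q.q * q.dh, 1e-300)) - q.log_z_curve
    full = np.concatenate((e, [0.0]))
    v = -logsumexp(log_w[:, None] - q.h_grid[:, None] * full[None, :], axis=0)
    return v[:-1] - v[-1]


def map_h_star(
    sample_energies: np.ndarray, q: LatentDensity
) -> tuple[np.ndarray, float]:
    """MAP latent value per sample and the entropy of q.

    h*(s) = argmax_h [log q(h) - h E(s) - log Z(h)] over the grid; ties
    resolve to the smaller h.  Also returns the discrete entropy of q,
    the natural summary of its dynamic range when q is multimodal.
    """
    e = np.asarray(sample_energies, dtype=float).ravel()
    with np.errstate(divide="ignore"):
        log_q = np.where(q.q > 0, np.log(np.maximum(q.q, 1e-300)), -np.inf)
    scores = log_q[:, None] - q.h_grid[:, None] * e[None, :] - q.log_z_curve[:, None]
    idx = np.argmax(scores, axis=0)  # first maximum = smallest h on ties
    return q.h_grid[idx], q.entropy()
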