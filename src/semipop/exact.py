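"""Brute-force enumeration over all 2^N patterns (N <= 20).

Ground truth for every stochastic estimator in the package: exact
normalizers, the density of states, low-order response statistics, and
gauge-invariant KL divergences between small models.  Enumeration is
done in vectorized chunks of patterns (bit-matrix expansion), which
keeps N = 20 tractable without per-pattern Python loops.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
from scipy.special import logsumexp

from .models import EnergyParams, PopulationModel

__all__ = [
    "DensityOfStates",
    "EnergyHistogram",
    "iter_patterns",
    "enumerate_log_z",
    "enumerate_probabilities",
    "enumerate_density_of_states",
    "enumerate_statistics",
    "exact_kl",
]

MAX_EXACT_N = 20
_CHUNK = 1 << 16


@dataclass
class DensityOfStates:
    """Binned log density of states: states per unit energy.

    ``log_density[b]`` is log(count in bin b / bin width); -inf (or the
    ``accessible`` mask) marks bins containing no state.  After
    normalization, logsumexp(log_density + log dE) = N log 2.
    """

    bin_edges: np.ndarray
    log_density: np.ndarray
    n_neurons: int

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.log_density = np.asarray(self.log_density, dtype=float)
        if not (np.diff(self.bin_edges) > 0).all():
            raise ValueError("bin_edges must be strictly increasing")
        if self.log_density.size != self.bin_edges.size - 1:
            raise ValueError("log_density must have one entry per bin")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)

    @property
    def accessible(self) -> np.ndarray:
        return np.isfinite(self.log_density)

    def total_log_states(self) -> float:
        """logsumexp of log_density + log(bin width); N log 2 if normalized."""
        ok = self.accessible
        return float(logsumexp(self.log_density[ok] + np.log(self.bin_widths[ok])))


@dataclass
class EnergyHistogram:
    """Empirical probability density of the energy over data samples."""

    bin_edges: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        total = float(np.sum(self.density * np.diff(self.bin_edges)))
        if not np.isclose(total, 1.0, atol=1e-8):
            raise ValueError(f"density must integrate to 1, got {total}")

    @classmethod
    def from_energies(cls, energies: np.ndarray, bin_edges: np.ndarray) -> "EnergyHistogram":
        counts, edges = np.histogram(energies, bins=bin_edges)
        if counts.sum() != np.asarray(energies).size:
            raise ValueError("some energies fall outside the bin range")
        dens = counts / (counts.sum() * np.diff(edges))
        return cls(edges, dens)


def _check_n(n: int, cap: int = MAX_EXACT_N) -> None:
    if n > cap:
        raise ValueError(
            f"exact enumeration is limited to N <= {cap} (got N={n}); "
            "use AIS / Wang-Landau for larger populations"
        )


def iter_patterns(n: int, chunk: int = _CHUNK) -> Iterator[np.ndarray]:
    """Yield all 2^n binary patterns in index order, in chunks of rows."""
    _check_n(n)
    total = 1 << n
    bits = np.arange(n, dtype=np.uint32)
    for start in range(0, total, chunk):
        idx = np.arange(start, min(start + chunk, total), dtype=np.uint32)
        yield ((idx[:, None] >> bits[None, :]) & 1).astype(np.int8)


def enumerate_log_z(model: PopulationModel, cap: int = MAX_EXACT_N) -> float:
    """log Z by streaming log-sum-exp over all 2^N patterns."""
    _check_n(model.n_neurons, cap)
    parts = [logsumexp(model.log_prob_unnorm(s)) for s in iter_patterns(model.n_neurons)]
    return float(logsumexp(parts))


def enumerate_probabilities(model: PopulationModel) -> np.ndarray:
    """Normalized probabilities of all 2^N patterns (index order)."""
    _check_n(model.n_neurons)
    lp = np.concatenate([model.log_prob_unnorm(s) for s in iter_patterns(model.n_neurons)])
    return np.exp(lp - logsumexp(lp))


def enumerate_density_of_states(
    energy: EnergyParams, bin_edges: np.ndarray
) -> DensityOfStates:
    """Exact binned density of states rho(E): state count per unit energy."""
    n = energy.n_neurons
    _check_n(n)
    edges = np.asarray(bin_edges, dtype=float)
    counts = np.zeros(edges.size - 1, dtype=np.int64)
    for s in iter_patterns(n):
        e = energy.energy(s)
        if e.min() < edges[0] or e.max() > edges[-1]:
            raise ValueError(
                f"energies span [{e.min():.6g}, {e.max():.6g}], outside the "
                f"bin range [{edges[0]:.6g}, {edges[-1]:.6g}]"
            )
        counts += np.histogram(e, bins=edges)[0]
    # states exactly at the right edge belong to the last bin (numpy does this)
    with np.errstate(divide="ignore"):
        log_density = np.where(
            counts > 0, np.log(np.maximum(counts, 1)) - np.log(np.diff(edges)), -np.inf
        )
    return DensityOfStates(edges, log_density, n)


def enumerate_statistics(model: PopulationModel) -> dict:
    """Exact means, covariances, distinct-triplet third moments, and P(K)."""
    from itertools import combinations

    n = model.n_neurons
    _check_n(n)
    lp = np.concatenate([model.log_prob_unnorm(s) for s in iter_patterns(n)])
    w = np.exp(lp - logsumexp(lp))
    mean = np.zeros(n)
    second = np.zeros((n, n))
    third = np.zeros((n, n, n))
    pk = np.zeros(n + 1)
    off = 0
    for s in iter_patterns(n):
        ws = w[off:off + s.shape[0]]
        sf = s.astype(float)
        wsf = sf * ws[:, None]
        mean += ws @ sf
        second += wsf.T @ sf
        third += np.einsum("mi,mj,mk->ijk", wsf, sf, sf, optimize=True)
        np.add.at(pk, s.sum(axis=1), ws)
        off += s.shape[0]
    cov = second - np.outer(mean, mean)
    tri_idx = list(combinations(range(n), 3))
    triplets = {(i, j, k): third[i, j, k] for (i, j, k) in tri_idx}
    return {"mean": mean, "cov": cov, "third_moments": triplets, "p_k": pk}


def exact_kl(model_a: PopulationModel, model_b: PopulationModel) -> float:
    """KL(p_a || p_b) in nats by exact enumeration (gauge-invariant)."""
    if model_a.n_neurons != model_b.n_neurons:
        raise ValueError(
            f"models differ in size: {model_a.n_neurons} vs {model_b.n_neurons}"
        )
    _check_n(model_a.n_neurons)
    lpa, lpb = [], []
    for s in iter_patterns(model_a.n_neurons):
        lpa.append(model_a.log_prob_unnorm(s))
        lpb.append(model_b.log_prob_unnorm(s))
    lpa = np.concatenate(lpa)
    lpb = np.concatenate(lpb)
    lpa -= logsumexp(lpa)
    lpb -= logsumexp(lpb)
    pa = np.exp(lpa)
    return float(np.sum(pa * (lpa - lpb)))
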