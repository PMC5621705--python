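"""Energy functions, the monotone nonlinearity, and the composed model.

A population pattern ``s`` in {0,1}^N is assigned an energy ``E(s)`` by a
parametric energy function (independent or pairwise), and a probability

    p(s) = exp(-V(E(s))) / Z,

where ``V`` is a strictly monotone, twice differentiable nonlinearity.
With the identity nonlinearity the model reduces to the familiar
maximum-entropy (Ising-like) baselines; an optional potential on the
summed activity K(s) turns the pairwise baseline into a K-pairwise model.

The nonlinearity is parametrized through a piecewise-constant function
``W`` on an energy grid via V'' = W V', which guarantees monotonicity for
any unconstrained coefficient vector ``beta``:

    V(E) = gamma1 + gamma2 * f(E; beta),
    f(E) = int_{E0}^{E} exp( int_{E0}^{E'} W(E'') dE'' ) dE'.

Both integrals are carried out in closed form (W is constant on each of
the Q bins of [E0, E1]); V extends linearly below E0 and above E1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

__all__ = [
    "IndependentEnergy",
    "PairwiseEnergy",
    "Nonlinearity",
    "PopulationModel",
    "compute_energy",
    "eval_nonlinearity",
    "grad_nonlinearity_params",
    "model_log_prob_unnorm",
]


def _check_pattern(patterns: np.ndarray, n: int) -> np.ndarray:
    s = np.atleast_2d(np.asarray(patterns))
    if s.shape[-1] != n:
        raise ValueError(
            f"pattern dimension {s.shape[-1]} does not match "
            f"energy dimension {n}"
        )
    return s


@dataclass
class IndependentEnergy:
    """E(s) = -sum_i alpha_i s_i (single-neuron biases only)."""

    alpha: np.ndarray

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float).ravel()
        if self.alpha.size < 1:
            raise ValueError("alpha must be non-empty")

    @property
    def n_neurons(self) -> int:
        return self.alpha.size

    def energy(self, patterns: np.ndarray) -> np.ndarray:
        s = _check_pattern(patterns, self.n_neurons)
        e = -(s @ self.alpha)
        return e if np.asarray(patterns).ndim > 1 else float(e[0])

    def energy_bounds(self) -> tuple[float, float]:
        """Rigorous [min, max] of E over all 2^N patterns."""
        a = self.alpha
        return float(-a[a > 0].sum()), float(-a[a < 0].sum())


@dataclass
class PairwiseEnergy:
    """E(s) = -sum_{i,j} J_ij s_i s_j over ordered pairs.

    J is symmetric; the sum runs over all ordered pairs, so off-diagonal
    interactions count twice and the diagonal J_ii (counted once, since
    s_i^2 = s_i) acts as a single-neuron bias.
    """

    J: np.ndarray

    def __post_init__(self) -> None:
        self.J = np.asarray(self.J, dtype=float)
        if self.J.ndim != 2 or self.J.shape[0] != self.J.shape[1]:
            raise ValueError(f"J must be square, got shape {self.J.shape}")
        if not np.allclose(self.J, self.J.T, atol=1e-12, rtol=0):
            raise ValueError("J must be symmetric to within 1e-12")

    @property
    def n_neurons(self) -> int:
        return self.J.shape[0]

    def energy(self, patterns: np.ndarray) -> np.ndarray:
        s = _check_pattern(patterns, self.n_neurons).astype(float)
        e = -np.einsum("mi,ij,mj->m", s, self.J, s)
        return e if np.asarray(patterns).ndim > 1 else float(e[0])

    def energy_bounds(self) -> tuple[float, float]:
        """Rigorous [min, max] of E over all 2^N patterns.

        Every ordered-pair term -J_ij s_i s_j lies in [-J_ij^+, J_ij^-],
        so the interval below provably contains all attainable energies.
        """
        pos = self.J[self.J > 0].sum()
        neg = self.J[self.J < 0].sum()
        return float(-pos), float(-neg)


EnergyParams = Union[IndependentEnergy, PairwiseEnergy]


# --- numerically guarded primitives for the closed-form V -----------------
# phi(u) = (e^u - 1)/u           -> 1 as u -> 0
# psi(u) = (e^u (u - 1) + 1)/u^2 -> 1/2 as u -> 0

_SMALL = 1e-8


def _phi(u: np.ndarray) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    small = np.abs(u) < _SMALL
    safe = np.where(small, 1.0, u)
    return np.where(small, 1.0 + u / 2.0, np.expm1(safe) / safe)


def _psi(u: np.ndarray) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    small = np.abs(u) < 1e-5
    safe = np.where(small, 1.0, u)
    exact = (np.exp(safe) * (safe - 1.0) + 1.0) / safe**2
    return np.where(small, 0.5 + u / 3.0 + u**2 / 8.0, exact)


@dataclass
class Nonlinearity:
    """Monotone nonlinearity V(E) with piecewise-constant W on [e0, e1].

    Parameters
    ----------
    gamma1, gamma2 : float
        V(e0) and V'(e0).  For an increasing V, gamma2 > 0.
    beta : (Q,) array
        Levels of W on the Q equal-width bins of [e0, e1]; unconstrained.
    e0, e1 : float
        Endpoints of the energy grid (e1 > e0).  Outside the grid V
        continues linearly with slope V'(e0) below and V'(e1) above.
    """

    gamma1: float
    gamma2: float
    beta: np.ndarray
    e0: float
    e1: float

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float).ravel()
        if self.beta.size < 1:
            raise ValueError("beta must have at least one bin")
        if not self.e1 > self.e0:
            raise ValueError(f"require e1 > e0, got e0={self.e0}, e1={self.e1}")
        self._refresh()

    def _refresh(self) -> None:
        q = self.beta.size
        self._delta = (self.e1 - self.e0) / q
        d = self._delta
        # cum[i] = Delta * sum_{j<=i} beta_j, i = 0..Q
        self._cum = np.concatenate(([0.0], np.cumsum(self.beta) * d))
        # t_i = exp(cum[i-1]) * Delta * phi(Delta beta_i): full-bin increments of f
        self._t = np.exp(self._cum[:-1]) * d * _phi(d * self.beta)
        # F[i] = sum_{j<=i} t_j, i = 0..Q
        self._F = np.concatenate(([0.0], np.cumsum(self._t)))

    @property
    def n_bins(self) -> int:
        return self.beta.size

    @property
    def delta(self) -> float:
        return self._delta

    def _locate(self, energy):
        """Bin index k (1-based; Q+1 above the grid), offset x, and beta_k."""
        e = np.asarray(energy, dtype=float)
        if not np.isfinite(e).all():
            raise ValueError("non-finite energy passed to nonlinearity")
        r = e - self.e0
        q = self.beta.size
        k = np.clip(np.floor(r / self._delta).astype(np.intp) + 1, 1, q + 1)
        x = r - (k - 1) * self._delta
        beta_k = np.where(k <= q, self.beta[np.minimum(k, q) - 1], 0.0)
        return r, k, x, beta_k

    def f(self, energy):
        """The integral f(E; beta); f is V with gamma1=0, gamma2=1."""
        e = np.asarray(energy, dtype=float)
        r, k, x, beta_k = self._locate(e)
        inside = self._F[k - 1] + np.exp(self._cum[k - 1]) * x * _phi(beta_k * x)
        out = np.where(r < 0, r, inside)
        return out if e.ndim else float(out)

    def value(self, energy):
        """V(E)."""
        f = self.f(energy)
        return self.gamma1 + self.gamma2 * f

    def value_and_deriv(self, energy):
        """(V(E), V'(E)) from the same running products."""
        e = np.asarray(energy, dtype=float)
        r, k, x, beta_k = self._locate(e)
        f = self._F[k - 1] + np.exp(self._cum[k - 1]) * x * _phi(beta_k * x)
        f = np.where(r < 0, r, f)
        deriv = self.gamma2 * np.where(r < 0, 1.0, np.exp(self._cum[k - 1] + beta_k * x))
        v = self.gamma1 + self.gamma2 * f
        if e.ndim:
            return v, deriv
        return float(v), float(deriv)

    def second_deriv(self, energy):
        """V''(E) = W(E) V'(E); zero on the linear tails."""
        e = np.asarray(energy, dtype=float)
        r, k, x, beta_k = self._locate(e)
        _, vp = self.value_and_deriv(e)
        w = np.where((r < 0) | (k > self.beta.size), 0.0, beta_k)
        out = w * vp
        return out if e.ndim else float(out)

    def grad_params(self, energy):
        """Gradients of V w.r.t. (gamma1, gamma2, beta).

        Returns ``(d_gamma1, d_gamma2, d_beta)`` with shapes (M,), (M,),
        (M, Q) for an array input (scalars/(Q,) for a scalar input).
        The three beta cases are: bins above the energy's bin contribute
        zero; the energy's own bin contributes through the partial-bin
        integral; lower bins contribute both directly and through the
        running exponential of every later term.
        """
        e = np.asarray(energy, dtype=float)
        e2 = np.atleast_1d(e)
        r, k, x, beta_k = self._locate(e2)
        f = self._F[k - 1] + np.exp(self._cum[k - 1]) * x * _phi(beta_k * x)
        f = np.where(r < 0, r, f)

        q = self.beta.size
        m = np.arange(1, q + 1)
        k_col = k[:, None]
        below = m[None, :] < k_col  # m < [E]
        at = m[None, :] == k_col    # m = [E] (never true when k = Q+1 tail... k<=Q only)
        # direct term of the energy's own (partial) bin
        d_at = (np.exp(self._cum[k - 1]) * x**2 * _psi(beta_k * x))[:, None]
        # full-bin direct terms, precomputed per bin
        d_full = np.exp(self._cum[:-1]) * self._delta**2 * _psi(self._delta * self.beta)
        d_beta = np.where(
            below,
            d_full[None, :] + self._delta * (f[:, None] - self._F[1:][None, :]),
            np.where(at, d_at, 0.0),
        )
        # below the grid V is linear in (gamma1, gamma2) only
        d_beta = np.where((r < 0)[:, None], 0.0, d_beta)
        d_g2 = f
        d_g1 = np.ones_like(f)
        d_beta = self.gamma2 * d_beta
        if e.ndim:
            return d_g1, d_g2, d_beta
        return 1.0, float(d_g2[0]), d_beta[0]

    @classmethod
    def linear(cls, e0: float, e1: float, n_bins: int = 20) -> "Nonlinearity":
        """Identity-like start: V(E) = E - e0 (gamma1=0, gamma2=1, beta=0)."""
        return cls(0.0, 1.0, np.zeros(n_bins), e0, e1)


@dataclass
class PopulationModel:
    """Energy function composed with a nonlinearity (or identity).

    ``nonlinearity=None`` marks a maximum-entropy baseline with identity
    V; only then may a K-potential ``phi`` (length N+1) be attached,
    giving the K-pairwise family.  ``log_z`` caches a normalizer along
    with the method that produced it ("exact" or "ais").
    """

    energy: EnergyParams
    nonlinearity: Nonlinearity | None = None
    k_potential: np.ndarray | None = None
    log_z: float | None = None
    log_z_method: str | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k_potential is not None:
            if self.nonlinearity is not None:
                raise ValueError(
                    "a K-potential is only supported with the identity "
                    "nonlinearity (maximum-entropy baseline)"
                )
            self.k_potential = np.asarray(self.k_potential, dtype=float).ravel()
            if self.k_potential.size != self.energy.n_neurons + 1:
                raise ValueError(
                    f"k_potential must have length N+1={self.energy.n_neurons + 1}, "
                    f"got {self.k_potential.size}"
                )

    @property
    def n_neurons(self) -> int:
        return self.energy.n_neurons

    def log_prob_unnorm(self, patterns: np.ndarray) -> np.ndarray:
        """log p(s) + log Z, i.e. -V(E(s)) (+ phi_K for K-pairwise)."""
        e = self.energy.energy(patterns)
        if self.nonlinearity is None:
            out = -np.asarray(e, dtype=float)
        else:
            out = -np.asarray(self.nonlinearity.value(e), dtype=float)
        if self.k_potential is not None:
            s = _check_pattern(patterns, self.n_neurons)
            out = out + self.k_potential[s.sum(axis=1)]
        if np.asarray(patterns).ndim == 1:
            return float(np.atleast_1d(out)[0])
        return out

    def log_prob(self, patterns: np.ndarray) -> np.ndarray:
        if self.log_z is None:
            raise ValueError("model has no cached log_z; compute it first "
                             "(exact enumeration or AIS)")
        return self.log_prob_unnorm(patterns) - self.log_z


# ---------------------------------------------------------------------------
# thin functional facade

def compute_energy(pattern: np.ndarray, energy: EnergyParams):
    """Energy of one pattern (or a batch) under the given parameters."""
    return energy.energy(pattern)


def eval_nonlinearity(energy, nl: Nonlinearity):
    """(V(E), V'(E)) at the given energy (scalar or array)."""
    return nl.value_and_deriv(energy)


def grad_nonlinearity_params(energy, nl: Nonlinearity):
    """(dV/dgamma1, dV/dgamma2, dV/dbeta) at the given energy."""
    return nl.grad_params(energy)


def model_log_prob_unnorm(pattern: np.ndarray, model: PopulationModel):
    """Unnormalized log probability log p(s) + log Z."""
    return model.log_prob_unnorm(pattern)
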