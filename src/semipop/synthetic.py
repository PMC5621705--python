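"""Synthetic rasters with known ground truth.

Provides exact and Gibbs sampling from any population model, the
latent-variable generator of near-critical populations (a scalar h drawn
from a broad density, then a conditionally independent population tilted
by h), and the subsetting / repeat-splitting protocols used for scaling
analyses.  Defaults emulate a retinal recording binned at 20 ms: low,
heterogeneous firing rates and a broad unit-order latent dispersion.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .exact import MAX_EXACT_N, enumerate_probabilities
from .inference import gibbs_update
from .latent import LatentDensity, make_h_grid
from .models import IndependentEnergy, PairwiseEnergy, PopulationModel
from .raster import SpikeRaster

__all__ = [
    "sample_model",
    "generate_latent_population",
    "nested_subpopulations",
    "split_by_repeats",
    "default_alpha",
    "broad_latent_weights",
    "bimodal_latent_weights",
    "Subpopulation",
]


def _index_to_patterns(idx: np.ndarray, n: int) -> np.ndarray:
    bits = np.arange(n, dtype=np.uint32)
    return ((idx[:, None].astype(np.uint32) >> bits[None, :]) & 1).astype(np.int8)


def sample_model(
    model: PopulationModel,
    n_samples: int,
    seed: int = 0,
    method: str = "exact",
    burn_in_sweeps: int = 200,
    thin_sweeps: int = 5,
    n_chains: int = 100,
    bin_width: float = 0.02,
) -> SpikeRaster:
    """Draw samples from a population model.

    ``method="exact"`` enumerates all 2^N probabilities (N <= 20) and
    draws categorically; ``method="gibbs"`` runs ``n_chains`` parallel
    chains, discards ``burn_in_sweeps`` full sweeps (N single-site
    updates each) and keeps one state per chain every ``thin_sweeps``
    sweeps.  Both are deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    n = model.n_neurons
    if method == "exact":
        if n > MAX_EXACT_N:
            raise ValueError(
                f"exact sampling requires N <= {MAX_EXACT_N} (got {n}); "
                "use method='gibbs'"
            )
        p = enumerate_probabilities(model)
        idx = rng.choice(p.size, size=n_samples, p=p)
        return SpikeRaster(_index_to_patterns(idx, n), bin_width)
    if method != "gibbs":
        raise ValueError(f"unknown sampling method {method!r}")
    state = (rng.random((n_chains, n)) < 0.5).astype(np.int8)
    state = gibbs_update(state, model, rng, burn_in_sweeps * n)
    chunks = []
    collected = 0
    while collected < n_samples:
        state = gibbs_update(state, model, rng, thin_sweeps * n)
        take = min(n_chains, n_samples - collected)
        chunks.append(state[:take].copy())
        collected += take
    return SpikeRaster(np.concatenate(chunks, axis=0), bin_width)


def default_alpha(
    n: int, seed: int = 0, mean: float = -3.0, sd: float = 1.0
) -> np.ndarray:
    """Heterogeneous low-rate biases, drawn once per fixture.

    At the latent midpoint h = 1 a neuron with bias a fires with
    probability 1/(1 + e^{-a}); the default N(-3, 1) draw gives rates of
    a few percent per 20 ms bin, spread over an order of magnitude, as
    in retinal recordings.
    """
    return np.random.default_rng(seed).normal(mean, sd, n)


def broad_latent_weights(
    n_bins: int = 400,
    h_max: float = 5.0,
    log_mean: float = 0.0,
    log_sd: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Broad latent density: lognormal truncated to [0, h_max].

    Unit-order dispersion (sd of log h = 1 by default) is the "broad q"
    regime in which the latent mixture produces near-Zipf rank-frequency
    curves.  Returns (grid midpoints, probability per grid point).
    """
    h, dh = make_h_grid(0.0, h_max, n_bins)
    with np.errstate(divide="ignore"):
        logpdf = np.where(
            h > 0,
            -((np.log(np.maximum(h, 1e-300)) - log_mean) ** 2) / (2 * log_sd**2)
            - np.log(np.maximum(h, 1e-300)),
            -np.inf,
        )
    w = np.exp(logpdf - logpdf.max())
    return h, w / w.sum()


def bimodal_latent_weights(
    n_bins: int = 400,
    h_max: float = 5.0,
    modes: tuple[float, float] = (0.7, 1.3),
    sd: float = 0.08,
) -> tuple[np.ndarray, np.ndarray]:
    """Two well-separated latent modes (for active/silent state tests)."""
    h, dh = make_h_grid(0.0, h_max, n_bins)
    w = np.zeros_like(h)
    for m in modes:
        w += np.exp(-((h - m) ** 2) / (2 * sd**2))
    return h, w / w.sum()


def _latent_weights(q) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(q, LatentDensity):
        w = q.q * q.dh
        return q.h_grid, w / w.sum()
    h, w = q
    h = np.asarray(h, dtype=float)
    w = np.asarray(w, dtype=float)
    if (w < 0).any() or not np.isclose(w.sum(), 1.0):
        raise ValueError("latent weights must be a normalized distribution")
    return h, w


def generate_latent_population(
    q,
    alpha,
    n_samples: int,
    seed: int = 0,
    bin_width: float = 0.02,
) -> tuple[SpikeRaster, np.ndarray]:
    """Sample a latent-mixture population: h ~ q, then s | h.

    ``q`` is a LatentDensity or a (h_grid, weights) pair; ``alpha`` is
    an independent-energy bias vector (the conditional then factorizes
    into Bernoulli(1/(1 + e^{-h a_i})) per neuron, exact for any N) or
    a PairwiseEnergy (exact conditional sampling, N <= 20).  Returns the
    raster together with the per-sample latent draws.
    """
    rng = np.random.default_rng(seed)
    h_grid, w = _latent_weights(q)
    h_idx = rng.choice(h_grid.size, size=n_samples, p=w)
    h = h_grid[h_idx]
    if isinstance(alpha, PairwiseEnergy):
        n = alpha.n_neurons
        if n > MAX_EXACT_N:
            raise ValueError(
                f"pairwise latent generation requires N <= {MAX_EXACT_N} (got {n})"
            )
        activity = np.empty((n_samples, n), dtype=np.int8)
        for k in np.unique(h_idx):
            rows = np.where(h_idx == k)[0]
            tilted = PopulationModel(PairwiseEnergy(h_grid[k] * alpha.J))
            p = enumerate_probabilities(tilted)
            idx = rng.choice(p.size, size=rows.size, p=p)
            activity[rows] = _index_to_patterns(idx, n)
    else:
        a = alpha.alpha if isinstance(alpha, IndependentEnergy) else np.asarray(alpha, dtype=float)
        activity = np.empty((n_samples, a.size), dtype=np.int8)
        for start in range(0, n_samples, 65536):  # chunked: keeps memory flat
            hb = h[start:start + 65536]
            p_spike = 1.0 / (1.0 + np.exp(-hb[:, None] * a[None, :]))
            activity[start:start + 65536] = rng.random(p_spike.shape) < p_spike
    return SpikeRaster(activity, bin_width), h


class Subpopulation(NamedTuple):
    repeat: int
    indices: np.ndarray
    raster: SpikeRaster


def nested_subpopulations(
    raster: SpikeRaster,
    start: int = 40,
    step: int = 20,
    stop: int = 140,
    n_repeats: int = 5,
    seed: int = 0,
) -> list[Subpopulation]:
    """Nested chains of random neuron subsets for scaling analyses.

    Per repeat: a random subset of ``start`` neurons, then repeatedly
    augmented by ``step`` further random neurons up to ``stop``, so that
    smaller subsets are contained in larger ones within a chain.  The
    defaults (40, 20, 140, 5 repeats) on a 160-neuron raster yield 30
    datasets.
    """
    n = raster.n_neurons
    if stop > n:
        raise ValueError(f"stop={stop} exceeds the raster's {n} neurons")
    rng = np.random.default_rng(seed)
    out = []
    sizes = list(range(start, stop + 1, step))
    for rep in range(n_repeats):
        order = rng.permutation(n)
        for size in sizes:
            idx = np.sort(order[:size])
            out.append(Subpopulation(rep, idx, raster.subset(idx)))
    return out


def split_by_repeats(
    raster: SpikeRaster, n_test_repeats: int, seed: int = 0
) -> tuple[SpikeRaster, SpikeRaster]:
    """Disjoint train/test split by stimulus-repeat label."""
    if raster.repeat_labels is None:
        raise ValueError("raster has no repeat labels to split by")
    labels = np.unique(raster.repeat_labels)
    if n_test_repeats >= labels.size:
        raise ValueError(
            f"n_test_repeats={n_test_repeats} must be below the "
            f"{labels.size} distinct repeats"
        )
    rng = np.random.default_rng(seed)
    test_labels = rng.choice(labels, size=n_test_repeats, replace=False)
    is_test = np.isin(raster.repeat_labels, test_labels)

    def take(mask):
        return SpikeRaster(
            raster.activity[mask], raster.bin_width, raster.repeat_labels[mask]
        )

    return take(~is_test), take(is_test)
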