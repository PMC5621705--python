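"""Population-level analyses: Zipf curves, the criticality statistic,
moment comparisons, nonlinearity-vs-density-of-states matching,
curvature, and large-N extrapolation of the nonlinearity."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exact import DensityOfStates, enumerate_probabilities
from .models import Nonlinearity, PopulationModel
from .raster import SpikeRaster

__all__ = [
    "RankFrequencyCurve",
    "zipf_curve",
    "fit_zipf_slope",
    "criticality_sigma",
    "response_statistics",
    "v_vs_dos_distance",
    "curvature_statistic",
    "extrapolate_nonlinearity",
]


def _pattern_counts(activity: np.ndarray) -> np.ndarray:
    """Occurrence count of every distinct row, by hashing packed rows."""
    packed = np.packbits(activity.astype(np.uint8), axis=1)
    view = np.ascontiguousarray(packed).view(
        np.dtype((np.void, packed.shape[1]))
    ).ravel()
    _, counts = np.unique(view, return_counts=True)
    return counts


@dataclass
class RankFrequencyCurve:
    """Sorted pattern frequencies with ranks and bootstrap SDs.

    ``frequencies`` are non-increasing and sum to 1 over the distinct
    patterns observed; ``counts`` are the raw occurrence counts;
    ``bootstrap_sd`` (if computed) gives the per-rank SD under row
    resampling.
    """

    frequencies: np.ndarray
    counts: np.ndarray
    n_samples: int
    bootstrap_sd: np.ndarray | None = None

    @property
    def ranks(self) -> np.ndarray:
        return np.arange(1, self.frequencies.size + 1)


def zipf_curve(
    samples: SpikeRaster | np.ndarray,
    n_bootstrap: int = 100,
    seed: int = 0,
) -> RankFrequencyCurve:
    """Rank-frequency (Zipf) curve of exact pattern occurrences.

    Patterns are counted by hashing full rows; frequencies are sorted in
    non-increasing order.  With ``n_bootstrap`` > 0, per-rank standard
    deviations are estimated by resampling time bins with replacement
    (multinomially over the observed pattern counts).
    """
    activity = samples.activity if isinstance(samples, SpikeRaster) else np.asarray(samples)
    if activity.size == 0:
        raise ValueError("cannot build a Zipf curve from an empty raster")
    counts = np.sort(_pattern_counts(activity))[::-1]
    t = activity.shape[0]
    freqs = counts / t
    sd = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        reps = np.empty((n_bootstrap, counts.size))
        for b in range(n_bootstrap):
            resampled = rng.multinomial(t, freqs)
            reps[b] = np.sort(resampled)[::-1] / t
        sd = reps.std(axis=0, ddof=1)
    return RankFrequencyCurve(freqs, counts, t, sd)


def fit_zipf_slope(
    curve: RankFrequencyCurve,
    rank_range: tuple[int, int] = (10, 1000),
    min_count: int = 2,
) -> float:
    """Least-squares slope of log10 frequency vs log10 rank over mid ranks.

    Restricted to ranks in ``rank_range`` (inclusive) and to patterns
    observed at least ``min_count`` times; a slope near -1 is the Zipf
    signature of criticality.
    """
    r = curve.ranks
    sel = (r >= rank_range[0]) & (r <= rank_range[1]) & (curve.counts >= min_count)
    if sel.sum() < 2:
        raise ValueError("fewer than two eligible ranks for the slope fit")
    x = np.log10(r[sel])
    y = np.log10(curve.frequencies[sel])
    return float(np.polyfit(x, y, 1)[0])


def criticality_sigma(
    model: PopulationModel | None = None,
    samples: SpikeRaster | np.ndarray | None = None,
    log_z: float | None = None,
) -> float:
    """sigma(log p(s)) / sqrt(N), the criticality statistic.

    With a model alone the statistic is exact (enumeration, N <= 20);
    with a model plus samples it is estimated as the sample SD of
    log p over the rows, which requires a normalizer (``log_z``, or the
    model's cached value).  It vanishes as N grows for independent-like
    populations and stays finite for critical ones.
    """
    if model is None:
        raise ValueError("criticality_sigma requires a model")
    n = model.n_neurons
    if samples is None:
        p = enumerate_probabilities(model)
        keep = p > 0
        logp = np.log(p[keep])
        mean = np.sum(p[keep] * logp)
        var = np.sum(p[keep] * (logp - mean) ** 2)
        return float(np.sqrt(var) / np.sqrt(n))
    if log_z is None:
        log_z = model.log_z
    if log_z is None:
        raise ValueError(
            "sample-based criticality_sigma needs log Z (exact or AIS)"
        )
    activity = samples.activity if isinstance(samples, SpikeRaster) else np.asarray(samples)
    logp = model.log_prob_unnorm(activity.astype(float)) - log_z
    return float(logp.std(ddof=1) / np.sqrt(n))


def _bootstrap_weights(rng, t, n_bootstrap):
    """Row-resampling weights: each replicate is a multinomial over rows."""
    return rng.multinomial(t, np.full(t, 1.0 / t), size=n_bootstrap) / t


def response_statistics(
    data: SpikeRaster,
    model_samples: SpikeRaster,
    n_triplets: int = 10_000,
    n_bootstrap: int = 100,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Paired data/model statistics with bootstrap SDs.

    Compares firing rates, pairwise covariances, ``n_triplets`` randomly
    sampled (without replacement) distinct third moments E[s_i s_j s_k],
    and the distribution of the summed activity K.  Bootstrap resamples
    time bins with replacement (100 replicates by default; figures
    typically display 3 SD).
    """
    if data.n_neurons != model_samples.n_neurons:
        raise ValueError(
            f"neuron count mismatch: data has {data.n_neurons}, "
            f"model samples have {model_samples.n_neurons}"
        )
    n = data.n_neurons
    rng = np.random.default_rng(seed)
    out: dict[str, pd.DataFrame] = {}

    def rate_stats(raster):
        x = raster.activity.astype(float)
        w = _bootstrap_weights(rng, x.shape[0], n_bootstrap)
        boot = w @ x
        return x.mean(axis=0), boot.std(axis=0, ddof=1)

    r_d, sd_d = rate_stats(data)
    r_m, sd_m = rate_stats(model_samples)
    out["rates"] = pd.DataFrame(
        {"neuron": np.arange(n), "data": r_d, "data_sd": sd_d,
         "model": r_m, "model_sd": sd_m}
    )

    iu = np.triu_indices(n, k=1)

    def cov_stats(raster):
        x = raster.activity.astype(float)
        t = x.shape[0]
        cov = np.cov(x, rowvar=False, ddof=0)
        w = _bootstrap_weights(rng, t, n_bootstrap)
        boot = np.empty((n_bootstrap, iu[0].size))
        for b in range(n_bootstrap):
            mu = w[b] @ x
            second = (x * w[b][:, None]).T @ x
            boot[b] = (second - np.outer(mu, mu))[iu]
        return np.atleast_2d(cov)[iu], boot.std(axis=0, ddof=1)

    c_d, csd_d = cov_stats(data)
    c_m, csd_m = cov_stats(model_samples)
    out["covariances"] = pd.DataFrame(
        {"i": iu[0], "j": iu[1], "data": c_d, "data_sd": csd_d,
         "model": c_m, "model_sd": csd_m}
    )

    n_all = n * (n - 1) * (n - 2) // 6
    n_tri = min(n_triplets, n_all)
    chosen = rng.choice(n_all, size=n_tri, replace=False)
    # unrank combinations i<j<k lexicographically
    from itertools import combinations
    all_tri = np.array(list(combinations(range(n), 3)))
    tri = all_tri[np.sort(chosen)]

    def tri_stats(raster):
        x = raster.activity.astype(float)
        t = x.shape[0]
        w = _bootstrap_weights(rng, t, n_bootstrap)
        means = np.empty(n_tri)
        sds = np.empty(n_tri)
        for start in range(0, n_tri, 512):
            blk = tri[start:start + 512]
            prod = x[:, blk[:, 0]] * x[:, blk[:, 1]] * x[:, blk[:, 2]]
            means[start:start + 512] = prod.mean(axis=0)
            sds[start:start + 512] = (w @ prod).std(axis=0, ddof=1)
        return means, sds

    t_d, tsd_d = tri_stats(data)
    t_m, tsd_m = tri_stats(model_samples)
    out["third_moments"] = pd.DataFrame(
        {"i": tri[:, 0], "j": tri[:, 1], "k": tri[:, 2],
         "data": t_d, "data_sd": tsd_d, "model": t_m, "model_sd": tsd_m}
    )

    def pk_stats(raster):
        k = raster.population_counts()
        t = k.size
        pk = np.bincount(k, minlength=n + 1) / t
        w = _bootstrap_weights(rng, t, n_bootstrap)
        onehot = np.zeros((t, n + 1))
        onehot[np.arange(t), k] = 1.0
        boot = w @ onehot
        return pk, boot.std(axis=0, ddof=1)

    k_d, ksd_d = pk_stats(data)
    k_m, ksd_m = pk_stats(model_samples)
    out["p_k"] = pd.DataFrame(
        {"k": np.arange(n + 1), "data": k_d, "data_sd": ksd_d,
         "model": k_m, "model_sd": ksd_m}
    )
    return out


def v_vs_dos_distance(
    nl: Nonlinearity,
    dos: DensityOfStates,
    energy_range: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Offset-minimized mean squared distance between V and log rho.

    Evaluated at the occupied density-of-states bin centers inside
    ``energy_range`` (defaults to the full occupied range).  Since V is
    only defined up to an additive constant, the distance is minimized
    over that constant; the minimizer is the mean difference, so the
    result is the variance of V(E) - log rho(E) over the grid.  Returns
    ``(distance, offset)``.
    """
    centers = dos.bin_centers
    ok = dos.accessible
    if energy_range is not None:
        lo, hi = energy_range
        ok = ok & (centers >= lo) & (centers <= hi)
    if not ok.any():
        raise ValueError("no occupied density-of-states bins in the requested range")
    diff = nl.value(centers[ok]) - dos.log_density[ok]
    offset = -float(diff.mean())
    return float(np.mean((diff + offset) ** 2)), offset


def curvature_statistic(nl: Nonlinearity, n_grid: int = 4001) -> float:
    """Mean |V''| over [E0, E1] (V'' = W V' under the representation)."""
    e = np.linspace(nl.e0, nl.e1, n_grid + 1)
    mid = 0.5 * (e[:-1] + e[1:])  # midpoints avoid the bin-edge jumps of W
    return float(np.mean(np.abs(nl.second_deriv(mid))))


def extrapolate_nonlinearity(
    curves: list[tuple[int, np.ndarray]],
    grid: np.ndarray | None = None,
    n_min: int = 80,
) -> np.ndarray:
    """Extrapolate nonlinearities to infinite population size.

    ``curves`` holds (N, V values) on a shared (normalized) energy grid.
    Each curve is offset so that V = 0 at grid point 0 (when ``grid``
    is given and spans zero), then a least-squares line in 1/N is fitted
    per grid point over the curves with N >= ``n_min``; the 1/N = 0
    intercepts are returned.
    """
    eligible = [(n, np.asarray(v, dtype=float)) for n, v in curves if n >= n_min]
    if len(eligible) < 2:
        raise ValueError(
            f"need at least 2 curves with N >= {n_min}, got {len(eligible)}"
        )
    vals = []
    for n, v in eligible:
        if grid is not None and grid.min() <= 0 <= grid.max():
            v = v - np.interp(0.0, np.asarray(grid, dtype=float), v)
        vals.append(v)
    vals = np.asarray(vals)
    inv_n = 1.0 / np.array([n for n, _ in eligible], dtype=float)
    x = np.column_stack([inv_n, np.ones_like(inv_n)])
    coef, *_ = np.linalg.lstsq(x, vals, rcond=None)
    return coef[1]
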