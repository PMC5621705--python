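# Methods

## Model class

The package models the stationary distribution of binary population
activity patterns `s ∈ {0,1}^N` (rows of a binned spike raster, default
bin width 20 ms) as a *semiparametric energy-based model*

    p(s) = exp(−V(E(s))) / Z,

where `E` is a parametric energy with local structure — independent,
`E(s) = −Σ_i α_i s_i`, or pairwise, `E(s) = −Σ_{i,j} J_ij s_i s_j` over
ordered pairs (off-diagonal couplings count twice; the diagonal acts as
a bias because `s_i² = s_i`) — and `V` is a strictly increasing, twice
differentiable nonlinearity estimated nonparametrically.  With the
identity `V` the class reduces to the maximum-entropy baselines
(independent, pairwise, and, with an extra potential `φ_K` on the summed
activity `K(s) = Σ_i s_i`, K-pairwise).  The role of `V` is to match the
model's distribution of the energy to the empirical one: for fixed
energy parameters the optimal piecewise-constant nonlinearity is
`V(E) = log ρ̄(E) − log p̂̄(E) + const`, where `ρ̄` is the density of
states (configurations per unit energy) and `p̂̄` the empirical energy
density on the same bins.

Two exact gauge freedoms matter throughout: adding a constant to `V`
(absorbed by `Z`), and jointly rescaling `J → cJ` while dilating the
energy axis of `V` by `1/c`.  Neither changes any probability, so
comparisons across fits must use gauge-invariant quantities (KL
divergences, probabilities, `h*` assignments) or fix the gauge
explicitly.

## Monotone nonlinearity

`V` is parametrized through `V'' = W·V'` with `W` piecewise constant on
`Q` equal bins of a grid `[E0, E1]` (default `Q = 20`).  Integrating
twice gives a closed form for `V` and `V'` in terms of `(γ1, γ2, β)`
with `γ1 = V(E0)`, `γ2 = V'(E0)`; monotonicity holds for any
unconstrained `β`, which is what makes unconstrained gradient ascent
possible.  Terms of the form `(e^{Δβ}−1)/β` are evaluated by series for
`|Δβ| < 1e−8` (the singularity at `β = 0` is removable).  Outside the
grid `V` continues linearly with the boundary slopes.  The parameter
gradients implement the three-case structure (bins above the energy's
bin contribute nothing; the energy's own bin through the partial-bin
integral; lower bins both directly and through the running
exponential); all are validated against central finite differences.
The grid is set once when a semiparametric fit starts, as the data
energy range under the initial parameters widened by 20% per side; the
fraction of energies ending up outside the grid is tracked and warned
about above 5%.

## Training (Persistent Contrastive Divergence)

All five families are trained by stochastic gradient ascent in which
model expectations come from a bank of persistent Gibbs chains advanced
`n = 2N` single-site heat-bath updates per iteration ("one application
of the Gibbs operator" = one uniformly chosen site resampled from its
exact conditional; `2N ≈ two sweeps`).  Defaults mirror the
large-recording settings: `η = 1` for energy parameters, `η = 5e−5` for
`(γ1, γ2, β)`, `L = 10^4` iterations, and a two-stage schedule for the
baselines (`M_s = 3×10^4` then `3×10^5` chains); semiparametric models
are initialized from their fitted baseline with a linear `V` and train
for one stage.  Chains initialize as independent Bernoulli draws at the
data rates (unstated upstream; reduces burn-in versus uniform).

Two desk-scale adaptations are config switches, not new defaults:

- `average_last`: averaging parameters over the final fraction of
  iterations.  With small chain banks the stationary fluctuation of the
  stochastic gradient dominates the error; tail averaging removes it at
  no cost.  Off by default.
- The nonlinearity learning rate should scale with the problem: the
  `(γ2, β)` gradients are of order the integral `f(E)`, which grows with
  the energy range (roughly with `N`).  The printed `5e−5` is
  appropriate for 100+-neuron recordings; small-population fits in the
  tests use `5e−4` so that the `V` scale can actually relax within a
  short run.  With `V` effectively frozen the energy parameters absorb
  the scale mismatch, which distorts downstream latent inversions.

Gradient NaNs abort with the iteration index; `γ2 ≤ 0` after training
logs a warning (the class is meant to be increasing, but gradients are
unconstrained).

## Exact oracle

Everything stochastic is validated against brute-force enumeration for
`N ≤ 20`: log-normalizers, binned density of states, means/covariances/
third moments/`P(K)`, and exact KL divergences between models (the
gauge-invariant recovery metric).  Enumeration iterates all `2^N`
patterns in vectorized chunks of 2^16 rows (a bit-matrix expansion of
the pattern index); this is orders of magnitude faster in numpy than
per-pattern incremental schemes and makes `N = 20` a few seconds.

## Normalization estimators

**AIS / thermodynamic integration.**  `log Z` is estimated along a
geometric path `p_t ∝ p_base^{1−t/T} p_target^{t/T}` with a uniform
schedule (default `T = 10^4` intermediate distributions, `10^4`
samples), one heat-bath sweep per temperature, starting from an
independent base (a fitted independent model, rate-matched Bernoulli
rates — clipped to `[1e−6, 1−1e−6]` if degenerate — or the uniform
distribution) whose normalizer is in closed form.  The estimator of
`Z/Z_base` is unbiased; the function returns per-sample log weights so
callers can attach a delta-method standard error.

**Wang–Landau.**  The density of states of an energy function is
estimated by a single-site-flip flat-histogram walk whose log-density
increment starts at 1 and halves on a fixed iteration schedule (default
`10^6` proposals per level at desk scale) down to a final increment
(default `10^−7`).  Histogram flatness is deliberately not checked:
inaccessible bins make it ill-defined.  The energy range is taken from
rigorous interval bounds (`E ∈ [−ΣJ⁺, −ΣJ⁻]`), which provably contain
every configuration, so the imposed normalization `Σ ρ̄·Δ = 2^N` cannot
silently miss support; bins never visited are flagged as inaccessible
(NaN) rather than zero-filled.  An explicit `bin_edges` override exists
for oracle comparisons.  A walker that accepts no move in `10^7` steps
raises, reporting the stuck bin.

## Latent-variable equivalence

A one-dimensional latent variable `h ~ q(h)` mixing exponential tilts
`p(s|h) = e^{−hE(s)}/Z(h)` is equivalent to a nonlinearity via a Laplace
transform; `Z(h)` is evaluated for all `h` from one density-of-states
estimate, `log Z(h) = log Σ_bins ρ̄ Δ e^{−hE}` (closed form available
for independent energies).  The inverse problem — recovering `q` from
sample energies under the fitted parameters — is posed as
maximum-likelihood estimation of mixing proportions on a fixed grid
(default `[0, 5]` in 400 bins) by EM, which is monotone and respects
the simplex; sample energies are binned (1024 bins) first so the
E-step cost is independent of sample size.  Convergence: relative
log-likelihood change below `1e−9`, or `max_iter`.

This deconvolution is ill-posed: components at neighboring `h` produce
nearly identical energy distributions (the energy resolves `h` only to
roughly `σ(E|h)/|dμ/dh|`, a few tenths here), and beyond the `h` where
the population is essentially silent all components coincide.  Plain EM
therefore first approaches the truth and then drifts indefinitely along
likelihood-flat ridges toward spiky solutions, gaining nats at noise
level.  The `smoothing` option implements smoothed EM (EMS): after each
M-step the weights are convolved with a Gaussian of the given standard
deviation in `h` units (edge mass reflected), which makes the iteration
stationary at a smooth solution.  `smoothing = 0` (default) is the pure
MLE and appropriate for discrete mixtures; continuous-density analyses
in the tests use `0.1`, at or below the identifiability resolution
(robust over 0.05–0.2 in validation).  `h*` readout takes the grid
argmax of `log q(h) − hE − log Z(h)` per sample (ties to the smaller
`h`), and the dynamic range of `q` is summarized by its discrete
entropy.

## Synthetic populations

The generator defines the study conditions.  Near-critical populations
are latent mixtures with independent energies: biases drawn once from
`N(−3, 1)` (marginal spike probabilities of a few to ~10 percent per
20 ms bin, spread over an order of magnitude, emulating retinal
recordings) and `h` from a lognormal(0, 1) truncated to `[0, 5]`
("broad, unit-order dispersion"; a bimodal option exists for
active/silent-state tests).  The conditional factorizes into
`Bernoulli(σ(hα_i))`, exact at any `N`; generation is chunked to keep
memory flat at 10^6+ samples.  Under these conditions the mid-rank
(10–1000) Zipf slope of 10^6-sample simulations at `N = 100` measures
≈ −1.06–−1.07, stable across seeds (±0.005), sample counts
(2.5×10^5–4×10^6), population sizes (50–200), and rate levels; the
strict −1 is the infinite-size limit, and finite mixtures over-steepen
slightly.  Matched-rate independent populations are far shallower over
the same ranks.  What the generator does *not* emulate: stimulus drive,
temporal correlations across bins, refractoriness, and pairwise fine
structure beyond what the global tilt induces — so passing tests show
correct inference under the model's own assumptions, not retinal
realism.

Exact sampling (categorical over all `2^N` probabilities) is available
to `N = 20`; beyond that, thinned parallel Gibbs chains.  The
subsetting protocol draws, per repeat, a random nested chain of neuron
subsets (default sizes 40, 60, …, 140 from 160, 5 repeats → 30
datasets); train/test splits cut by stimulus-repeat label.

## Diagnostics

Zipf curves count exact pattern occurrences (packed-row hashing), with
multinomial bootstrap over time bins (100 replicates; figures
conventionally show 3 SD).  The automated slope convention is least
squares of `log10 f` vs `log10 r` over ranks 10–1000 restricted to
patterns seen ≥ twice.  The criticality statistic is
`σ(log p(s))/√N` — exact by enumeration for `N ≤ 20`, or the sample SD
given a normalizer; for identical independent neurons it equals
`√(q(1−q))·|log(q/(1−q))|` at any `N`.  Model-vs-data response
statistics (rates, covariances, randomly sampled distinct third
moments, `P(K)`) carry row-bootstrap SDs.  The match between `V` and
`log ρ̄` is the offset-minimized mean squared distance over occupied
density-of-states bins (the optimal offset is the mean difference, so
the distance is the variance of `V − log ρ̄`); for cross-`N`
comparisons both axes are normalized by `N`.  Mean `|V''|` uses
`V'' = W·V'`, exact under the representation, averaged on a dense
midpoint grid.  Large-`N` extrapolation offsets each curve to `V(0)=0`
and fits a straight line in `1/N` per grid point over curves with
`N ≥ 80` (the linearity threshold), reading off the `1/N → 0`
intercept.

## Problem sizes in the test suite

The suite exercises the full stack at sizes chosen for a laptop-class
run: enumeration oracles at `N = 3–12`, PCD recovery at `N = 12` with
5×10^4 samples (exact KL against the generating model), the latent
round trip at `N = 40` with 10^5 samples, Zipf/criticality simulations
at `N = 60–100` with up to 10^6 samples, and Wang–Landau/AIS at desk
schedules (10^5–10^6 proposals per level; hundreds of intermediate
distributions).  Printed defaults remain at recording scale; every test
overrides them through `TrainConfig`/estimator configs.

## Known limitations

- The latent scale gauge means absolute `h` units of an inverted `q`
  are set by where the optimizer lands on the `J → cJ` ridge, not by
  the data; only gauge-aligned or gauge-invariant comparisons are
  meaningful (see the round-trip analysis above).
- The latent tail beyond the silence point is not identifiable; EMS
  keeps it smooth but cannot recover its true shape.
- PCD with constant step size reaches a stationary distribution around
  the MLE rather than the MLE itself; tail averaging mitigates but the
  residual depends on the chain count.
- Exact oracles stop at `N = 20`; above that all ground truth is
  itself Monte Carlo.
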