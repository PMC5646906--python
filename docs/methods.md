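# Methods

This document records the mathematical model implemented by `caspike`, the
numerical choices made, and the scope and limits of the synthetic
experiments bundled with the package.

## Model

### Observations

A cell's activity is a spike sequence y = {y₁ < … < y_N} in an observation
window [0, T], recorded with frame interval Δ, with y₀ = 0 by convention.
Intensities are discretized on the uniform grid tᵢ = iΔ, i = 0…n, T = nΔ,
as non-negative values xᵢ (events/second).

### ISI densities conditioned on an intensity

The time-rescaling integral X(a, b) = ∫ₐᵇ x(u) du maps real time to
rescaled (operational) time. Conditioned on x, the inter-spike interval
densities for an interval (y_{k−1}, y_k] with X = X(y_{k−1}, y_k) are:

- IP: p = x(y_k) · e^{−X}
- IG (shape γ > 0): p = γ x(y_k) (γX)^{γ−1} e^{−γX} / Γ(γ)
- IIG (location α > 0): p = x(y_k) (2πX³)^{−1/2} exp(−(X − α)² / (2α²X))

Equivalently, rescaled intervals are Exp(1), Gamma(γ, scale 1/γ), and
inverse-Gaussian(mean α, λ = 1) respectively. IG with γ = 1 is exactly IP.
The conditional intensity (hazard) is q(t | y_k, x) = x(t) f(X) / S(X) with
f, S the rescaled-time density and survival; for IP this reduces to x(t).
Where S underflows, the hazard uses the family's asymptote (1 for IP, γ for
IG, 1/(2α²) for IIG), and the event is logged.

### Sequence likelihood

The sequence log-density is the sum of the interior ISI log-densities plus
Poisson-form boundary terms for the first spike, p₁ = x(y₁) e^{−X(0, y₁)},
and the terminal survival, p_T = e^{−X(y_N, T)}, for all three families
(the boundary intervals condition on events that are not renewals). An
empty sequence has log-density −X(0, T).

### Prior, MAP and marginalization

The prior on the grid values x₀…x_n is a Gaussian process with mean μ and
squared-exponential covariance Σ(t, t′) = σ_f² e^{−κ(t−t′)²/2} + δ_{tt′}σ_v²,
with the nugget fixed at σ_v² = 10⁻⁴. The default prior mean is the
empirical rate N/T.

The MAP intensity maximizes log p(y | x) − ½(x−μ)ᵀΣ⁻¹(x−μ) subject to
x ≥ 0, found by a projected Newton method: bins with x = 0 and inward
gradient are frozen, the reduced Newton system is solved by Cholesky
(with escalating jitter if indefinite), and a step-halving line search
guarantees ascent. Convergence requires projected-gradient norm < 10⁻⁶ or
relative improvement < 10⁻⁸ (max 200 iterations).

Hyperparameters θ = (shape, κ, σ_f) vary over a small log-spaced grid with
μ fixed at N/T and a uniform prior p(θ). Each grid point receives the
Laplace-approximated log evidence

log F(θ) = log p(θ) + log p(y | x*) − ½(x*−μ)ᵀΣ⁻¹(x*−μ) − ½log|Σ| − ½log|Λ* + Σ⁻¹|,

where Λ* = −∇² log p(y | x*); the (2π)^{n/2} factors cancel exactly.
Weights w(θ) ∝ exp(log F) are normalized by log-sum-exp; grid points whose
Newton solve fails are dropped with a warning. The reported intensity is
the weighted mixture mean x̄ = Σ w(θ) x*_θ, and the 95% band is
x̄ ± 1.96 √v with v the mixture second moment around x̄ using the Laplace
covariance diag((Λ* + Σ⁻¹)⁻¹) per θ, clipped below at 0. Pooled fits sum
the sequence log-likelihoods of all cells under one shared intensity.

### Goodness of fit

Rescaled intervals τ_k = −log S(X̂_k) for k = 2…N (the interval (0, y₁] is
excluded — the renewal hazard conditions on a previous spike that did not
occur at y₀ = 0), and u_k = 1 − e^{−τ_k}. The KS construction plots ordered
u against s_n = (n − ½)/K; the Q–Q construction plots ordered τ against
−log(1 − s_n). Slopes are zero-intercept ordinary least squares (the
reference line is the 45° diagonal through the origin). Model selection
fits each candidate family per cell, rescales through that cell's fitted
intensity and best-evidence shape, and ranks families by |median slope − 1|
across cells; no data are pooled.

### Rate baselines, population tools, preprocessing

Kernel smoothing averages Gaussian kernels over cells,
r(t) = (1/m) Σᵢⱼ φ(t − y_{ij}; σ); the bandwidth σ̂ minimizes the
closed-form least-squares cross-validation cost of the pooled-spike
density over a log-spaced candidate grid. The PSTH pools counts in bins
anchored at t = 0 (final partial bin normalised by its true width); the
bin width minimizes the Shimazaki–Shinomoto cost (2k̄ − v)/(m w)². Accuracy
is the normalised L₂ error ‖r̂ − r‖₂ / ∫r dt on the common grid (left-rule
quadrature). Stimulus time courses are summarized by the weights of their
leading principal components (uncentered SVD by default) and clustered by
k-means (scikit-learn, best of restarts); count histograms are compared by
the overlap distance H(R, S) = Σ min(Rᵢ, Sᵢ) / max(ΣR, ΣS) ∈ [0, 1] and
error samples by two-sided Mann–Whitney rank sums. Fluorescence traces are
normalised as F/F₀ with F₀ the mean of the minimum-variance sliding window
(25 s, searched in the first 120 s); a threshold-crossing peak extractor
with a refractory period converts traces to spike sequences.

## Numerical choices

- **Quadrature.** All rescaling integrals use the left rule on the grid,
  X̂(aΔ, bΔ) = Δ Σ_{k=a}^{b−1} x_k, which makes X̂ exactly additive over
  abutting intervals and consistent between the likelihood, the hazard and
  the GoF rescaling.
- **Grid snapping.** Spike times are snapped to the nearest grid index;
  moving a time by ≥ Δ/2 or colliding two spikes on one index is an error
  at the likelihood layer. Pipelines bin continuous-time surrogate draws
  with `snap_sequence`, which drops in-bin duplicates and logs the count.
- **Surrogate generators.** Three samplers share one interface:
  time-rescaling (renewal draw in rescaled time, inverted through the
  piecewise-linear cumulative intensity), inverse-CDF (bisection of the
  conditional ISI CDF to Δ/10), and per-frame Bernoulli with
  p = min(q·Δ, 1) (a warning is raised when max p > 0.1, i.e. when the
  grid is too coarse for the hazard). The first spike always uses the
  Poisson form; sequences truncate at T. Ensembles draw per-cell seeds
  from a spawned `SeedSequence`, so results are reproducible and cells are
  independent.
- **Desk-scale study sizes.** The bundled experiments run on one CPU in
  minutes: observation windows of 40–120 s, simulation grid Δ = 0.02 s,
  inference grids of n = 160 bins, and reduced hyperparameter grids
  (`FAST_CONFIG`). These sizes are the package's own choices for fast,
  reproducible synthetic studies; all are overridable.

## Scope and limitations

- **Per-cell GoF needs a slowly varying intensity.** The model-selection
  protocol rescales ISIs through an intensity fitted from the same ~40
  spikes. When the intensity fluctuates on the timescale of single ISIs,
  the per-cell fit oversmooths and biases all slopes toward a common
  value, destroying discrimination. The bundled `isi-selection` experiment
  therefore uses a gently oscillating intensity (one swing per ~20 ISIs),
  the regime that recorded Ca²⁺ spike sequences occupy. In that regime IP
  and IIG fits deviate clearly from slope 1 while IG concentrates near 1.
- **Zero-intercept slope is a scale diagnostic.** Symmetric S-shaped
  deviations of the KS curve can leave the slope near 1; the slope ranks
  families but is not a formal test. Uniformity KS tests on u are
  available for sharper checks.
- **Laplace evidence is approximate.** Weights are exact only for
  log-concave posteriors well approximated by a Gaussian at the MAP; the
  package validates the approximation against numeric quadrature on small
  problems (within 0.05 nats) but makes no claim for large n.
- **Non-negativity by projection.** The GP prior is Gaussian and can
  produce negative sampled intensities; sampling clips at 0 (fraction
  logged) and inference projects the MAP onto x ≥ 0. This is a rectified
  GP, not a log-GP; credible bands are likewise clipped at 0.
- **Bernoulli generator resolution.** Per-frame Bernoulli sampling is
  first-order in Δ; at hazards with q·Δ > 0.1 it visibly distorts short
  ISIs (hence the warning). The other two generators are exact up to the
  piecewise-constant intensity interpolation.
- **Preprocessing is a convenience.** Spike detection from raw
  fluorescence is acquisition-specific; the threshold extractor is a
  simple front end, and the package's primary input remains spike tables.
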