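# caspike

Bayesian point-process modelling of heterogeneous calcium (Ca²⁺) spike
sequences.

Cells challenged with an agonist emit trains of all-or-nothing Ca²⁺ spikes
whose timing varies strongly from cell to cell. `caspike` treats each cell's
spike sequence as an inhomogeneous renewal process conditioned on a latent,
time-varying **intensity function** x(t):

- **ISI families.** Inter-spike intervals follow an inhomogeneous Poisson
  (IP), Gamma (IG, shape γ) or inverse-Gaussian (IIG, location α) renewal
  density, all conditioned on x(t) through the time-rescaling integral
  X(a, b) = ∫ₐᵇ x(u) du. IG with γ = 1 reduces exactly to IP.
- **Bayesian rate inference.** A Gaussian-process prior (squared-exponential
  kernel; hyperparameters μ, σ_f, κ plus the ISI shape) is placed on the
  discretized intensity. The MAP intensity is found by a projected Newton
  method, hyperparameters are marginalized over a grid with Laplace-
  approximated evidence weights, and a pointwise 95% credible band is
  reported.
- **Goodness of fit.** The time-rescaling theorem maps correctly modelled
  ISIs to unit-mean exponentials; Kolmogorov–Smirnov and Q–Q constructions
  with zero-intercept slopes select the ISI family per cell.
- **Baselines and population tools.** Kernel smoothing with least-squares
  cross-validated bandwidth, PSTHs with cost-optimized bin width, normalised
  L₂ error, surrogate-sequence generators (time-rescaling, inverse-CDF,
  per-frame Bernoulli), PCA + k-means clustering of stimulus time courses,
  histogram overlap distance, and rank-sum comparisons.

## Worked example

Simulate five cells from the oscillating reference intensity
x_det(t) = 0.5 cos t + 0.5 cos(t/2) + 1 under an IG(γ = 5.9) model, then
recover the rate and check the fit:

```python
from caspike import ISIModel
from caspike.estimators import GPRateEstimator
from caspike.experiments import FAST_CONFIG
from caspike.gof import cell_slope
from caspike.gp import reference_intensity
from caspike.rates import l2_error
from caspike.surrogate import simulate_ensemble, snap_sequence

x_true = reference_intensity("x_det", 2000, 0.02)        # [0, 40] s
model = ISIModel("IG", 5.9)
cells = [snap_sequence(s, 0.25)
         for s in simulate_ensemble(x_true, model, "rescaling", m=5, seed=11)]
print("spikes per cell:", [len(c) for c in cells])

est = GPRateEstimator(family="IG", config=FAST_CONFIG, n=160, delta=0.25).fit(cells)
post = est.posterior_
print("best hyperparameters:", post.best_theta)
x_ref = reference_intensity("x_det", 160, 0.25)
print("normalised L2 error vs truth: %.3f" % l2_error(est.intensity_, x_ref))

slope = cell_slope(cells[0], post.x_star, ISIModel("IG", post.best_theta.shape))
print("KS slope, cell 0: %.3f" % slope)
```

Output:

```
spikes per cell: [37, 39, 46, 37, 42]
best hyperparameters: GPHyperparams(mu=1.005, sigma_f=0.5, kappa=np.float64(1.0), sigma_v2=0.0001, shape=np.float64(6.3496042078727974))
normalised L2 error vs truth: 0.023
KS slope, cell 0: 1.010
```

The generating shape γ = 5.9 sits between the evidence grid points and is
recovered as 6.35; the pooled five-cell estimate is within 2.3% normalised
L₂ of the truth, and the rescaled ISIs of a single cell fall on the KS
diagonal (slope ≈ 1).

## Command line

The `caspike` entry point wraps the library:

```sh
caspike simulate --family IG --shape 5.9 -m 10 --seed 1 -o spikes.csv
caspike fit spikes.csv --family IG -o posterior.csv
caspike gof spikes.csv -o slopes.csv
caspike rate spikes.csv --method ks -o rate.csv
caspike cluster stimuli.csv -k 4 --seed 0 -o labels.csv
caspike compare errors_a.txt errors_b.txt
caspike experiment rate-benchmark --seed 0 -o results/
```

Spike tables are long-format CSV (`cell_id,spike_time`) with the observation
window and frame interval carried as `# t_end=` / `# delta=` header comments.

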