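"""Classical spike-rate estimators and the normalised L2 error metric.

Kernel smoothing places a Gaussian of bandwidth sigma on every spike and
averages over the m sequences,

    r(t) = (1/m) sum_j sum_i f(t - y_ij, sigma),
    f(t, sigma) = exp(-t^2 / (2 sigma^2)) / sqrt(2 pi sigma^2),

so the estimate integrates (over the whole real line) to the mean spike
count per sequence.  The PSTH is the pooled count per bin divided by
m * bin_width.  Data-driven selection of sigma and of the PSTH bin width
is provided: least-squares cross-validation on the pooled spikes for the
kernel bandwidth, and the Shimazaki-Shinomoto (2 k_bar - v)/(m w)^2 cost
for the bin width, both minimised over log-spaced candidate grids.

Neither estimator applies boundary corrections at 0 or T; kernel mass
leaking outside the window biases the estimate downward within about one
bandwidth of the edges.
"""

from __future__ import annotations

import numpy as np

from .point_process import IntensityGrid, SpikeSequence


def _pooled(sequences) -> tuple[np.ndarray, int]:
    seqs = list(sequences)
    if not seqs:
        raise ValueError("need at least one sequence")
    spikes = np.concatenate([s.times for s in seqs]) if seqs else np.empty(0)
    return spikes, len(seqs)


def kernel_rate(sequences, sigma: float, n: int, delta: float) -> IntensityGrid:
    """Gaussian kernel-smoothed rate on a uniform grid of n+1 points."""
    if not (sigma > 0):
        raise ValueError("bandwidth sigma must be positive")
    spikes, m = _pooled(sequences)
    t = np.arange(n + 1) * delta
    if len(spikes) == 0:
        return IntensityGrid(np.zeros(n + 1), delta)
    d = t[:, None] - spikes[None, :]
    r = np.exp(-(d**2) / (2 * sigma**2)).sum(axis=1) / (m * np.sqrt(2 * np.pi) * sigma)
    return IntensityGrid(r, delta)


def psth_rate(sequences, bin_width: float, n: int, delta: float) -> IntensityGrid:
    """Piecewise-constant pooled-count rate; bins anchored at t = 0.

    The final partial bin is normalised by its true width.
    """
    spikes, m = _pooled(sequences)
    T = n * delta
    if not (0 < bin_width <= T):
        raise ValueError("bin_width must be in (0, T]")
    edges = np.arange(0.0, T, bin_width)
    edges = np.append(edges, T)
    counts, _ = np.histogram(spikes, bins=edges)
    widths = np.diff(edges)
    rate_per_bin = counts / (m * widths)
    t = np.arange(n + 1) * delta
    idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(rate_per_bin) - 1)
    return IntensityGrid(rate_per_bin[idx], delta)


def _lscv_cost(spikes: np.ndarray, sigma: float) -> float:
    """Least-squares cross-validation cost for a Gaussian kernel density
    on the pooled spikes (closed form)."""
    K = len(spikes)
    d2 = (spikes[:, None] - spikes[None, :]) ** 2
    term1 = np.exp(-d2 / (4 * sigma**2)).sum() / (K**2 * 2 * sigma * np.sqrt(np.pi))
    off = np.exp(-d2 / (2 * sigma**2)).sum() - K  # exclude i == j
    term2 = 2 * off / (K * (K - 1) * sigma * np.sqrt(2 * np.pi))
    return float(term1 - term2)


def bandwidth_candidates(sequences, num: int = 30) -> np.ndarray:
    """Log-spaced candidate bandwidths spanning the spike-time geometry."""
    spikes, _ = _pooled(sequences)
    spikes = np.sort(spikes)
    span = float(spikes[-1] - spikes[0]) if len(spikes) > 1 else 1.0
    gaps = np.diff(spikes)
    lo = max(float(gaps[gaps > 0].min()) / 2 if np.any(gaps > 0) else span / 100, 1e-6)
    hi = max(span / 2, lo * 10)
    return np.geomspace(lo, hi, num)


def optimal_bandwidth(sequences, candidates=None) -> float:
    """Cross-validated kernel bandwidth sigma-hat.

    Minimises the least-squares CV cost of the pooled-spike density over a
    log-spaced grid; because the cost depends on the pooled spike count,
    sigma-hat shifts with the number of sequences m.
    """
    spikes, _ = _pooled(sequences)
    if len(spikes) < 2:
        raise ValueError("need at least 2 pooled spikes to select a bandwidth")
    cand = np.asarray(candidates) if candidates is not None else bandwidth_candidates(sequences)
    costs = np.array([_lscv_cost(spikes, s) for s in cand])
    return float(cand[int(np.argmin(costs))])


def _psth_cost(spikes: np.ndarray, m: int, width: float, T: float) -> float:
    """Shimazaki-Shinomoto histogram cost (2 k_bar - v) / (m w)^2."""
    edges = np.arange(0.0, T + width, width)
    counts, _ = np.histogram(spikes, bins=edges)
    kbar = counts.mean()
    v = counts.var()
    return float((2 * kbar - v) / (m * width) ** 2)


def optimal_bin_width(sequences, candidates=None) -> float:
    """Cost-minimising PSTH bin width over a log-spaced candidate grid."""
    spikes, m = _pooled(sequences)
    if len(spikes) < 2:
        raise ValueError("need at least 2 pooled spikes to select a bin width")
    T = max(s.t_end for s in sequences)
    cand = np.asarray(candidates) if candidates is not None else np.geomspace(T / 200, T / 2, 30)
    costs = np.array([_psth_cost(spikes, m, w, T) for w in cand])
    return float(cand[int(np.argmin(costs))])


def l2_error(estimate: IntensityGrid, truth: IntensityGrid) -> float:
    """Normalised L2 norm [int (r_hat - r_true)^2 dt]^(1/2) / int r_true dt."""
    if estimate.n != truth.n or abs(estimate.delta - truth.delta) > 1e-12:
        raise ValueError("estimate and truth must share one grid")
    d = estimate.values[:-1] - truth.values[:-1]  # left rule, consistent with X-hat
    num = np.sqrt(np.sum(d**2) * truth.delta)
    den = np.sum(truth.values[:-1]) * truth.delta
    if den <= 0:
        raise ValueError("truth integrates to zero")
    return float(num / den)
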