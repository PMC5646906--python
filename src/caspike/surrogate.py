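"""Surrogate spike-sequence generation from an intensity function.

Three interchangeable algorithms draw from the same renewal model
conditioned on a gridded intensity x(t):

- ``rescaling``: draw the ISI in rescaled time from the renewal density
  (Exp(1) for IP, Gamma(gamma, 1/gamma) for IG, inverse Gaussian with mean
  alpha for IIG) and map it back through the inverse of the cumulative
  intensity;
- ``inverse``: draw u ~ U(0,1) and invert the conditional ISI CDF
  1 - S(X(y_prev, t)) by bisection on the grid (delta/10 resolution);
- ``bernoulli``: walk the grid with per-bin spike probability
  min(q(t|y_last) * delta, 1) based on the conditional intensity.

The first spike is drawn from the Poisson form p1 for every family
(consistent with the likelihood's boundary terms) and sequences are
truncated at T, matching the censoring term pT.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from .point_process import (
    ISIModel,
    IntensityGrid,
    SpikeSequence,
    _hazard_asymptote,
    _renewal_logpdf,
    _renewal_logsf,
    _renewal_sf,
)

logger = logging.getLogger(__name__)

METHODS = ("inverse", "bernoulli", "rescaling")


def _cum(x: IntensityGrid) -> np.ndarray:
    return x.cumulative()


def _cum_at(x: IntensityGrid, C: np.ndarray, t: float) -> float:
    """Integral of the piecewise-constant intensity from 0 to t."""
    k = min(int(t / x.delta), x.n - 1)
    return float(C[k] + (t - k * x.delta) * x.values[k])


def _invert_cum(x: IntensityGrid, C: np.ndarray, a: float, v: float) -> float | None:
    """Smallest t > a with int_a^t x(u) du = v, or None if beyond T."""
    target = _cum_at(x, C, a) + v
    if target > C[-1]:
        return None
    j = int(np.searchsorted(C, target, side="right") - 1)
    j = min(max(j, 0), x.n - 1)
    while x.values[j] == 0 and C[j + 1] <= target and j < x.n - 1:
        j += 1
    if x.values[j] == 0:
        return None
    t = j * x.delta + (target - C[j]) / x.values[j]
    return t if t <= x.t_end else None


def _rescaled_draw(model: ISIModel, rng: np.random.Generator) -> float:
    if model.family == "IP":
        return float(rng.exponential())
    if model.family == "IG":
        return float(rng.gamma(model.shape, 1.0 / model.shape))
    return float(rng.wald(model.shape, 1.0))  # inverse Gaussian, mean alpha, lambda 1


def _bisect_isi(x: IntensityGrid, C: np.ndarray, model: ISIModel, y_prev: float, u: float) -> float | None:
    """Invert the conditional ISI CDF F(t) = 1 - S(X(y_prev, t)) at u."""

    def F(t):
        X = _cum_at(x, C, t) - _cum_at(x, C, y_prev)
        return 1.0 - float(_renewal_sf(model, X))

    if F(x.t_end) < u:
        return None
    lo, hi = y_prev, x.t_end
    tol = x.delta / 10
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if F(mid) < u:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _first_spike(x: IntensityGrid, C: np.ndarray, rng) -> float | None:
    return _invert_cum(x, C, 0.0, float(rng.exponential()))


def simulate_sequence(
    x: IntensityGrid,
    model: ISIModel,
    method: str = "rescaling",
    seed=None,
    cell_id: str = "",
) -> SpikeSequence:
    """Generate one spike sequence from intensity ``x`` under ``model``.

    Reproducible under a fixed seed; ``seed`` may be an int or a
    ``numpy.random.SeedSequence``.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    rng = np.random.default_rng(seed)
    C = _cum(x)
    times: list[float] = []

    if method == "bernoulli":
        X = 0.0  # rescaled time since last spike
        last_bin = None
        max_p = 0.0
        for k in range(x.n):
            if last_bin is None:
                q = x.values[k]  # Poisson hazard before the first spike
            else:
                logsf = _renewal_logsf(model, X)
                if np.isfinite(logsf):
                    q = x.values[k] * float(np.exp(_renewal_logpdf(model, X) - logsf))
                else:
                    q = x.values[k] * _hazard_asymptote(model)
            p = min(q * x.delta, 1.0)
            max_p = max(max_p, p)
            if rng.random() < p:
                times.append((k + 1) * x.delta)
                last_bin = k + 1
                X = 0.0
            elif last_bin is not None:
                X += x.values[k] * x.delta
        if max_p > 0.1:
            warnings.warn(
                f"bernoulli generator: max per-bin probability {max_p:.3f} > 0.1; "
                "the grid step is coarse for this hazard",
                stacklevel=2,
            )
    else:
        y = _first_spike(x, C, rng)
        while y is not None:
            times.append(y)
            if method == "rescaling":
                y = _invert_cum(x, C, y, _rescaled_draw(model, rng))
            else:
                y = _bisect_isi(x, C, model, y, float(rng.random()))
            if y is not None and y <= times[-1]:
                y = times[-1] + 1e-9  # numeric guard: keep strictly increasing

    return SpikeSequence(np.asarray(times), t_end=x.t_end, delta=x.delta, cell_id=cell_id)


def simulate_ensemble(
    x: IntensityGrid,
    model: ISIModel,
    method: str = "rescaling",
    m: int = 1,
    seed=None,
    cell_prefix: str = "cell",
) -> list[SpikeSequence]:
    """m independent sequences with per-sequence seeds spawned from ``seed``."""
    if m < 1:
        raise ValueError("m must be at least 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(m)
    return [
        simulate_sequence(x, model, method, seed=children[j], cell_id=f"{cell_prefix}{j:03d}")
        for j in range(m)
    ]


def snap_sequence(seq: SpikeSequence, delta: float, t_end: float | None = None) -> SpikeSequence:
    """Bin spike times onto the frame grid, dropping in-bin duplicates.

    Continuous-time surrogate draws occasionally land two spikes in one
    frame; the gridded likelihood requires distinct indices, so the later
    one is dropped (with a log record of how many).
    """
    t_end = seq.t_end if t_end is None else t_end
    n = int(round(t_end / delta))
    idx = np.unique(np.clip(np.rint(seq.times / delta).astype(int), 1, n))
    dropped = len(seq.times) - len(idx)
    if dropped:
        logger.info("snap_sequence %s: dropped %d in-bin duplicate spikes", seq.cell_id, dropped)
    return SpikeSequence(idx * delta, t_end=n * delta, delta=delta, cell_id=seq.cell_id)
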