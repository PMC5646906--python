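"""Renewal-process building blocks for calcium spike sequences.

A cell's spiking record is an ordered set of event times observed on a
window [0, T] sampled at frame interval delta.  Inter-spike-interval (ISI)
statistics are made time-homogeneous by rescaling time through a latent,
non-negative intensity function x(t): the rescaled interval between spikes
y_{i-1} and y_i is X(y_{i-1}, y_i) = int x(u) du.  Conditioned on x, three
renewal families are supported for the rescaled ISIs:

- ``IP``  inhomogeneous Poisson, unit-rate exponential in rescaled time;
- ``IG``  inhomogeneous Gamma with shape gamma (Gamma(gamma, scale 1/gamma),
  mean one; gamma = 1 recovers IP exactly);
- ``IIG`` inhomogeneous inverse Gaussian with location alpha
  (inverse Gaussian with mean alpha and shape parameter one).

All likelihood computation is gridded: time is discretised with step delta
so that T = n*delta, spike times snap to grid indices, and the rescaling
integral uses a left-rule half-open quadrature
X(a, b) = delta * sum_{k=l_a}^{l_b - 1} x_k, which is exactly additive over
adjacent intervals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

logger = logging.getLogger(__name__)

_FAMILIES = ("IP", "IG", "IIG")


class ParameterError(ValueError):
    """Invalid model or hyperparameter value."""


class DomainError(ValueError):
    """Time argument outside the observation window or off the grid."""


@dataclass(frozen=True)
class ISIModel:
    """Renewal family tag plus its shape/location parameter.

    ``shape`` is the Gamma shape gamma for ``IG``, the inverse-Gaussian
    location alpha for ``IIG``, and must be omitted for ``IP``.
    """

    family: str
    shape: float | None = None

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ParameterError(f"unknown ISI family {self.family!r}; choose from {_FAMILIES}")
        if self.family == "IP":
            if self.shape is not None:
                raise ParameterError("IP model takes no shape parameter")
        else:
            if self.shape is None or not np.isfinite(self.shape) or self.shape <= 0:
                raise ParameterError(f"{self.family} requires a strictly positive shape, got {self.shape}")


@dataclass(frozen=True)
class IntensityGrid:
    """Non-negative rate x_i = x(i*delta) on a uniform grid i = 0..n."""

    values: np.ndarray
    delta: float

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or len(vals) < 2:
            raise ValueError("intensity grid needs at least two points (n >= 1)")
        if not np.all(np.isfinite(vals)):
            raise ValueError("intensity values must be finite")
        if np.any(vals < 0):
            raise ValueError("intensity values must be non-negative")
        if not (self.delta > 0):
            raise ValueError("grid step delta must be positive")

    @property
    def n(self) -> int:
        return len(self.values) - 1

    @property
    def t_end(self) -> float:
        return self.n * self.delta

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n + 1) * self.delta

    def __call__(self, t):
        """Value at time t under the piecewise-constant (left) convention."""
        idx = np.clip((np.asarray(t) / self.delta).astype(int), 0, self.n)
        return self.values[idx]

    def cumulative(self) -> np.ndarray:
        """Left-rule cumulative integral at grid points, length n+1."""
        out = np.empty(self.n + 1)
        out[0] = 0.0
        np.cumsum(self.values[:-1] * self.delta, out=out[1:])
        return out


@dataclass(frozen=True)
class SpikeSequence:
    """Ordered spike times of one cell on an observation window [0, T]."""

    times: np.ndarray
    t_end: float
    delta: float
    cell_id: str = ""

    def __post_init__(self):
        t = np.atleast_1d(np.asarray(self.times, dtype=float))
        object.__setattr__(self, "times", t)
        if not (self.t_end > 0 and self.delta > 0):
            raise ValueError("t_end and delta must be positive")
        if len(t):
            if t[0] <= 0 or t[-1] > self.t_end + 1e-9:
                raise ValueError("spike times must satisfy 0 < y_1 <= ... <= y_N <= T")
            gaps = np.diff(t)
            if len(gaps) and gaps.min() <= 0:
                raise ValueError("spike times must be strictly increasing")

    def validate_frame_spacing(self) -> None:
        """Raise if two spikes are closer than the frame interval delta.

        Continuous-time surrogate draws may violate this; recorded data and
        grid-snapped sequences must satisfy it.
        """
        gaps = np.diff(self.times)
        if len(gaps) and gaps.min() < self.delta - 1e-9:
            raise ValueError("duplicate spikes closer than the frame interval delta")

    def __len__(self) -> int:
        return len(self.times)


def snap_to_grid(times, delta: float, n: int) -> np.ndarray:
    """Snap spike times to nearest grid indices l_i (y_i = l_i * delta).

    Emits a warning when snapping moves a time; moving by delta/2 or more
    is a grid mismatch and raises.
    """
    t = np.asarray(times, dtype=float)
    idx = np.rint(t / delta).astype(int)
    offset = np.abs(t - idx * delta)
    if np.any(offset >= delta / 2 + 1e-12):
        raise DomainError("spike times are more than delta/2 off the intensity grid")
    if np.any(offset > 1e-9 * delta):
        warnings.warn("spike times snapped to the intensity grid", stacklevel=2)
    if np.any(idx < 0) or np.any(idx > n):
        raise DomainError("spike time outside the observation window")
    if len(idx) > 1 and np.any(np.diff(idx) <= 0):
        raise DomainError("spikes collide on the grid after snapping")
    return idx


def rescale_integral(x: IntensityGrid, a: float, b: float) -> float:
    """Rescaled duration X(a, b) = delta * sum_{k=l_a}^{l_b - 1} x_k.

    Left-rule half-open quadrature: exactly additive over adjacent
    intervals, X(a, c) = X(a, b) + X(b, c).
    """
    if not (0 <= a <= b <= x.t_end + 1e-9):
        raise DomainError("need 0 <= a <= b <= T")
    la, lb = (int(np.rint(v / x.delta)) for v in (a, b))
    for v, l in ((a, la), (b, lb)):
        if abs(v - l * x.delta) >= x.delta / 2 + 1e-12:
            raise DomainError("endpoint more than delta/2 off the grid")
    return float(np.sum(x.values[la:lb]) * x.delta)


# -- renewal family in rescaled time ---------------------------------------
#
# The ISI density factorises as p(y_i, y_{i-1} | x) = x(y_i) * f(X_i) where
# f is the renewal density of the rescaled interval.  The helpers below give
# log f, its survival function, and first/second derivatives of log f needed
# by the Newton optimiser.

def _renewal_logpdf(model: ISIModel, X):
    X = np.asarray(X, dtype=float)
    if model.family == "IP":
        return -X
    if model.family == "IG":
        g = model.shape
        with np.errstate(divide="ignore"):
            return g * np.log(g) - special.gammaln(g) + (g - 1) * np.log(X) - g * X
    a = model.shape
    with np.errstate(divide="ignore", invalid="ignore"):
        out = -0.5 * np.log(2 * np.pi * X**3) - (X - a) ** 2 / (2 * a**2 * X)
    return np.where(X > 0, out, -np.inf)


def _renewal_logsf(model: ISIModel, X):
    X = np.asarray(X, dtype=float)
    if model.family == "IP":
        return -X
    if model.family == "IG":
        return stats.gamma.logsf(X, model.shape, scale=1.0 / model.shape)
    return stats.invgauss.logsf(X, model.shape)


def _renewal_sf(model: ISIModel, X):
    return np.exp(_renewal_logsf(model, X))


def _dlogf(model: ISIModel, X):
    """d log f / dX for the renewal density."""
    X = np.asarray(X, dtype=float)
    if model.family == "IP":
        return -np.ones_like(X)
    if model.family == "IG":
        g = model.shape
        return (g - 1) / X - g
    a = model.shape
    return -1.5 / X + 0.5 / X**2 - 0.5 / a**2


def _d2logf(model: ISIModel, X):
    """d^2 log f / dX^2 for the renewal density."""
    X = np.asarray(X, dtype=float)
    if model.family == "IP":
        return np.zeros_like(X)
    if model.family == "IG":
        return -(model.shape - 1) / X**2
    return 1.5 / X**2 - 1.0 / X**3


def _hazard_asymptote(model: ISIModel) -> float:
    """Large-interval limit of the renewal hazard in rescaled time."""
    if model.family == "IP":
        return 1.0
    if model.family == "IG":
        return float(model.shape)
    return 1.0 / (2 * model.shape**2)


def isi_density(model: ISIModel, x: IntensityGrid, y_prev: float, y_curr: float) -> float:
    """ISI probability density p(y_curr, y_prev | x) (per second)."""
    if not (y_prev < y_curr):
        raise DomainError("need y_prev < y_curr")
    X = rescale_integral(x, y_prev, y_curr)
    xt = x.values[min(int(np.rint(y_curr / x.delta)), x.n)]
    return float(xt * np.exp(_renewal_logpdf(model, X)))


def conditional_intensity(model: ISIModel, x: IntensityGrid, t: float, y_last: float) -> float:
    """Hazard q(t | y_last, x) = x(t) * f(X) / S(X) of the next spike at t.

    Falls back to the analytic large-interval hazard asymptote when the
    survival function underflows (deep tail), with a log record.
    """
    if not (t > y_last):
        raise DomainError("need t > y_last")
    X = rescale_integral(x, y_last, t)
    xt = x.values[min(int(np.rint(t / x.delta)), x.n)]
    logsf = _renewal_logsf(model, X)
    if not np.isfinite(logsf):
        logger.warning("survival underflow at rescaled interval %.3g; using tail hazard asymptote", X)
        return float(xt * _hazard_asymptote(model))
    return float(xt * np.exp(_renewal_logpdf(model, X) - logsf))


def _segments(l: np.ndarray, n: int):
    """(start, stop, interior?) index segments partitioning [0, n).

    Half-open grid-cell ranges [l_{i-1}, l_i); the first segment (before
    spike 1) and the censored tail [l_N, n) carry Poisson boundary terms.
    """
    bounds = np.concatenate(([0], l, [n]))
    out = []
    for i in range(len(bounds) - 1):
        interior = 1 <= i <= len(l) - 1
        out.append((int(bounds[i]), int(bounds[i + 1]), interior))
    return out


def sequence_log_density(y: SpikeSequence, x: IntensityGrid, model: ISIModel) -> float:
    """Log joint density of a spike sequence given the gridded intensity.

    log p1(y_1|x) + log pT(T, y_N|x) + sum_i log p(y_i, y_{i-1}|x), with
    Poisson-form boundary terms; for an empty sequence this is the no-spike
    survival -X(0, T).
    """
    if abs(y.t_end - x.t_end) > x.delta / 2:
        raise DomainError("sequence window and intensity grid disagree on T")
    l = snap_to_grid(y.times, x.delta, x.n)
    delta = x.delta
    if len(l) == 0:
        return -float(np.sum(x.values[:-1]) * delta)
    with np.errstate(divide="ignore"):
        total = float(np.sum(np.log(x.values[l])))
    for start, stop, interior in _segments(l, x.n):
        X = float(np.sum(x.values[start:stop]) * delta)
        total += float(_renewal_logpdf(model, X)) if interior else -X
    return total
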