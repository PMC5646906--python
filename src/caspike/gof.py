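"""Time-rescaling goodness-of-fit and ISI model selection.

If the spike sequence really is a realisation of the renewal model with
conditional intensity q(t|y_k, x), the rescaled intervals

    tau_k = int_{y_{k-1}}^{y_k} q(s | y_{k-1}, x) ds

are i.i.d. unit-mean exponential, and u_k = 1 - exp(-tau_k) are uniform on
[0, 1).  The Kolmogorov-Smirnov construction plots the ordered u_k against
the uniform quantiles s_n = (n - 0.5)/K; the quantile-quantile construction
plots the ordered tau against the exponential quantiles -ln(1 - s_n).  A
correctly specified model puts the points on the 45-degree diagonal, which
is summarised per cell by a zero-intercept least-squares slope.

The hazard integral is evaluated exactly under the discretised intensity by
the change of variables v = X(y_{k-1}, s): tau_k = -log S(X_k), with X_k
the same left-rule quadrature used by the likelihood.  For the Poisson
family this reduces to tau_k = X_k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inference import FitConfig, GPPosterior, fit_cell
from .point_process import (
    ISIModel,
    IntensityGrid,
    SpikeSequence,
    _renewal_logsf,
    snap_to_grid,
)


@dataclass(frozen=True)
class RescaledISIs:
    """Rescaled intervals tau_k > 0 and their uniformized transforms u_k."""

    tau: np.ndarray
    u: np.ndarray

    @property
    def K(self) -> int:
        return len(self.tau)


@dataclass(frozen=True)
class GofResult:
    """Per-candidate goodness-of-fit summary across cells."""

    model: ISIModel
    slope: float                 # median per-cell KS slope
    per_cell: np.ndarray         # slope per analysed cell
    box: dict                    # quartile/whisker summary of per-cell slopes
    posteriors: tuple = ()


def rescale_isis(y: SpikeSequence, x: IntensityGrid, model: ISIModel) -> RescaledISIs:
    """Rescaled intervals for ISIs k = 2..N.

    The interval (0, y_1] is excluded: the hazard of the renewal family
    conditions on a previous spike, which did not occur at y_0 = 0.
    """
    if len(y) < 2:
        raise ValueError("need at least 2 spikes to rescale ISIs")
    l = snap_to_grid(y.times, x.delta, x.n)
    cum = x.cumulative()
    X = np.diff(cum[l])  # left-rule X(y_{k-1}, y_k)
    logsf = np.asarray(_renewal_logsf(model, X), dtype=float)
    bad = ~np.isfinite(logsf)
    if np.any(bad):
        import warnings

        warnings.warn("survival underflow in rescaling; tail-capped tau", stacklevel=2)
        logsf[bad] = np.log(np.finfo(float).tiny)
    tau = -logsf
    tau = np.maximum(tau, np.finfo(float).tiny)
    u = np.minimum(-np.expm1(-tau), np.nextafter(1.0, 0.0))
    return RescaledISIs(tau=tau, u=u)


def ks_points(r: RescaledISIs):
    """(s_n, ordered u) pairs: uniform CDF quantiles vs ordered u_k."""
    if r.K < 1:
        raise ValueError("need at least one rescaled ISI")
    s = (np.arange(1, r.K + 1) - 0.5) / r.K
    return s, np.sort(r.u)


def qq_points(r: RescaledISIs):
    """(theoretical, empirical) exponential quantile pairs."""
    if r.K < 1:
        raise ValueError("need at least one rescaled ISI")
    s = (np.arange(1, r.K + 1) - 0.5) / r.K
    return -np.log1p(-s), np.sort(r.tau)


def fit_slope(points) -> float:
    """Zero-intercept least-squares slope through (abscissa, ordinate)."""
    a, b = (np.asarray(v, dtype=float) for v in points)
    if len(a) < 2:
        raise ValueError("need at least 2 points")
    denom = float(a @ a)
    if denom == 0:
        raise ValueError("degenerate abscissa: all zero")
    return float(a @ b) / denom


def box_stats(values) -> dict:
    """Quartiles and 1.5*IQR whiskers: the lower whisker is the smallest
    data point above Q1 - 1.5*IQR, the upper the largest below Q3 + 1.5*IQR."""
    v = np.sort(np.asarray(values, dtype=float))
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo = v[v >= q1 - 1.5 * iqr][0]
    hi = v[v <= q3 + 1.5 * iqr][-1]
    return {"q1": float(q1), "median": float(med), "q3": float(q3),
            "whisker_low": float(lo), "whisker_high": float(hi)}


def cell_slope(y: SpikeSequence, x: IntensityGrid, model: ISIModel, which: str = "ks") -> float:
    """KS (default) or Q-Q slope of one cell rescaled under (x, model)."""
    r = rescale_isis(y, x, model)
    pts = ks_points(r) if which == "ks" else qq_points(r)
    return fit_slope(pts)


def select_isi_model(
    sequences,
    candidates=("IP", "IG", "IIG"),
    config: FitConfig = FitConfig(),
    which: str = "ks",
    keep_posteriors: bool = False,
) -> dict[str, GofResult]:
    """Per-cell ISI model-selection protocol.

    For every candidate family and every cell: infer x* by the full
    Bayesian fit, rescale the cell's ISIs through the fitted conditional
    intensity, and summarise the KS (or Q-Q) slope.  Candidates are ranked
    by the median |slope - 1| across cells; no data amalgamation takes
    place -- each cell is treated individually.
    """
    if not candidates:
        raise ValueError("need at least one candidate family")
    results: dict[str, GofResult] = {}
    for family in candidates:
        slopes, posts = [], []
        for seq in sequences:
            post = fit_cell(seq, family=family, config=config)
            model = _posterior_model(post, family)
            slopes.append(cell_slope(seq, post.x_star, model, which=which))
            if keep_posteriors:
                posts.append(post)
        slopes = np.asarray(slopes)
        results[family] = GofResult(
            model=_family_tag(family),
            slope=float(np.median(slopes)),
            per_cell=slopes,
            box=box_stats(slopes),
            posteriors=tuple(posts),
        )
    return results


def rank_candidates(results: dict[str, GofResult]) -> list[str]:
    """Families ordered by |median slope - 1|, best first."""
    return sorted(results, key=lambda f: abs(results[f].slope - 1.0))


def _posterior_model(post: GPPosterior, family: str) -> ISIModel:
    """Candidate model with its shape set to the highest-weight grid point."""
    shape = post.best_theta.shape
    return ISIModel(family, None if family == "IP" else shape)


def _family_tag(family: str) -> ISIModel:
    return ISIModel(family, None if family == "IP" else 1.0)
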