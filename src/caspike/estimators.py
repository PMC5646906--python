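"""scikit-learn-style rate estimators.

Each estimator consumes a list of :class:`~caspike.point_process.SpikeSequence`
objects (the observations for one stimulus condition) in ``fit`` and
exposes the estimated intensity on the common time grid through the fitted
attribute ``intensity_``; ``predict(t)`` evaluates it at arbitrary times.
They are ordinary ``BaseEstimator`` subclasses, so ``get_params`` /
``set_params``, cloning and pipeline composition behave as usual.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import rates
from .inference import FitConfig, fit_cell
from .point_process import SpikeSequence


def _grid_from(sequences, n, delta):
    seqs = [sequences] if isinstance(sequences, SpikeSequence) else list(sequences)
    if not seqs:
        raise ValueError("need at least one spike sequence")
    if delta is None:
        delta = seqs[0].delta
    if n is None:
        n = int(round(seqs[0].t_end / delta))
    return seqs, n, delta


class _RateEstimatorMixin:
    def predict(self, t):
        """Evaluate the fitted intensity at times ``t`` (events/second)."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "intensity_")
        return self.intensity_(np.asarray(t, dtype=float))

    def score(self, truth):
        """Negative normalised L2 error against a known intensity grid."""
        return -rates.l2_error(self.intensity_, truth)


class GPRateEstimator(BaseEstimator, _RateEstimatorMixin):
    """Bayesian intensity estimator: GP prior, renewal likelihood, Laplace
    marginalisation over a hyperparameter grid.

    Parameters
    ----------
    family : {"IP", "IG", "IIG"}
        Renewal family of the ISI likelihood.
    config : FitConfig
        Hyperparameter grids, GP mean handling and optimiser tolerances.
    n, delta : optional grid overrides (defaults come from the data).

    Attributes
    ----------
    intensity_ : IntensityGrid       marginalised MAP estimate x*
    ci_lower_, ci_upper_ : ndarray   pointwise 95% credible band
    posterior_ : GPPosterior         full per-theta record
    """

    def __init__(self, family: str = "IG", config: FitConfig = FitConfig(),
                 n: int | None = None, delta: float | None = None):
        self.family = family
        self.config = config
        self.n = n
        self.delta = delta

    def fit(self, sequences, y=None):
        seqs, n, delta = _grid_from(sequences, self.n, self.delta)
        post = fit_cell(seqs, family=self.family, config=self.config, n=n, delta=delta)
        self.posterior_ = post
        self.intensity_ = post.x_star
        self.ci_lower_ = post.ci_lower
        self.ci_upper_ = post.ci_upper
        return self


class KernelRateEstimator(BaseEstimator, _RateEstimatorMixin):
    """Gaussian kernel-smoothing rate estimator.

    ``sigma`` is the bandwidth in seconds, or ``"auto"`` for least-squares
    cross-validation on the pooled spikes.  The selected value is stored in
    ``sigma_``.
    """

    def __init__(self, sigma="auto", n: int | None = None, delta: float | None = None):
        self.sigma = sigma
        self.n = n
        self.delta = delta

    def fit(self, sequences, y=None):
        seqs, n, delta = _grid_from(sequences, self.n, self.delta)
        self.sigma_ = (
            rates.optimal_bandwidth(seqs) if self.sigma == "auto" else float(self.sigma)
        )
        self.intensity_ = rates.kernel_rate(seqs, self.sigma_, n, delta)
        return self


class PSTHRateEstimator(BaseEstimator, _RateEstimatorMixin):
    """Peri-stimulus time histogram rate estimator.

    ``bin_width`` in seconds, or ``"auto"`` for the cost-minimising
    Shimazaki-Shinomoto selection; stored in ``bin_width_``.
    """

    def __init__(self, bin_width="auto", n: int | None = None, delta: float | None = None):
        self.bin_width = bin_width
        self.n = n
        self.delta = delta

    def fit(self, sequences, y=None):
        seqs, n, delta = _grid_from(sequences, self.n, self.delta)
        self.bin_width_ = (
            rates.optimal_bin_width(seqs) if self.bin_width == "auto" else float(self.bin_width)
        )
        self.intensity_ = rates.psth_rate(seqs, self.bin_width_, n, delta)
        return self
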