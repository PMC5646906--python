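"""MAP intensity estimation under a GP prior with Laplace-weighted
hyperparameter marginalisation.

For a fixed hyperparameter set theta = (shape, kappa, sigma_f) the most
probable intensity x_theta* maximises log p(y|x, theta) + log p(x|theta)
subject to x >= 0; the constraint is handled by a projected Newton method
(negative coordinates truncated, Newton step solved on the free set) so the
Laplace algebra stays exact in the interior.  The evidence of each theta is
approximated by Laplace's method,

    log F = log p(theta) + log p(y|x*, theta) - (x*-mu)' Sigma^-1 (x*-mu)/2
            - log|Sigma|/2 - log|Lambda* + Sigma^-1|/2,

with Lambda* the negative Hessian of the log-likelihood at x*.  The final
estimate is the F-weighted average of the per-theta MAP intensities over a
finite hyperparameter grid, with a pointwise 95% credible band assembled
from the per-theta Laplace covariances (mixture second moment) and clipped
at zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg
from scipy.special import logsumexp

from .gp import SIGMA_V2, GPHyperparams, gram_matrix
from .point_process import (
    ISIModel,
    IntensityGrid,
    SpikeSequence,
    _d2logf,
    _dlogf,
    _renewal_logpdf,
    _segments,
    snap_to_grid,
)

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """Newton iteration failed; carries the last iterate and gradient norm."""

    def __init__(self, msg, last_x=None, grad_norm=None):
        super().__init__(msg)
        self.last_x = last_x
        self.grad_norm = grad_norm


@dataclass(frozen=True)
class FitConfig:
    """Hyperparameter grids, prior, and optimiser tolerances.

    The prior p(theta) is independent uniform over the (log-spaced) grid
    points.  ``mu`` of the GP mean defaults to the pooled empirical rate
    N/T when left as None.  Cells with at most ``min_spikes`` spikes
    trigger an inclusion warning (population analyses kept cells that
    spiked more than 10 times).
    """

    gamma_grid: tuple = tuple(np.geomspace(1.0, 20.0, 6))
    alpha_grid: tuple = tuple(np.geomspace(0.2, 5.0, 6))
    kappa_grid: tuple = tuple(np.geomspace(1e-3, 10.0, 4))
    sigma_f_grid: tuple = tuple(np.geomspace(0.1, 5.0, 3))
    mu: float | None = None
    sigma_v2: float = SIGMA_V2
    max_iter: int = 200
    grad_tol: float = 1e-6
    rel_tol: float = 1e-8
    min_spikes: int = 10


@dataclass(frozen=True)
class HyperGrid:
    """Finite hyperparameter grid with a normalised log-prior."""

    points: tuple
    log_prior: np.ndarray

    def __post_init__(self):
        lp = np.asarray(self.log_prior, dtype=float)
        object.__setattr__(self, "log_prior", lp)
        if len(lp) != len(self.points) or len(lp) == 0:
            raise ValueError("log_prior must match points and be non-empty")
        if abs(logsumexp(lp)) > 1e-8:
            raise ValueError("log-prior must normalise over the grid")

    @classmethod
    def uniform(cls, points) -> "HyperGrid":
        points = tuple(points)
        return cls(points, np.full(len(points), -np.log(len(points))))


@dataclass(frozen=True)
class GPPosterior:
    """Marginalised MAP intensity with pointwise 95% credible band."""

    x_star: IntensityGrid
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    per_theta: tuple          # (GPHyperparams, x_theta* array, log F) records
    weights: np.ndarray       # normalised exp(log F - log Z)
    log_Z: float

    @property
    def best_theta(self) -> GPHyperparams:
        return self.per_theta[int(np.argmax(self.weights))][0]


# -- likelihood internals ---------------------------------------------------

class _PooledLikelihood:
    """Gridded log-likelihood of one or more sequences sharing one x."""

    def __init__(self, sequences, n: int, delta: float, model: ISIModel):
        self.n, self.delta, self.model = n, delta, model
        self.spike_idx = []
        self.segments = []  # (start, stop, interior) across all sequences
        for seq in sequences:
            l = snap_to_grid(seq.times, delta, n)
            self.spike_idx.append(l)
            self.segments.extend(_segments(l, n))
        self.all_spikes = (
            np.concatenate(self.spike_idx) if self.spike_idx else np.empty(0, dtype=int)
        )

    def _seg_X(self, x):
        return [float(np.sum(x[a:b]) * self.delta) for a, b, _ in self.segments]

    def value(self, x) -> float:
        if len(self.all_spikes) and np.any(x[self.all_spikes] <= 0):
            return -np.inf
        total = float(np.sum(np.log(x[self.all_spikes]))) if len(self.all_spikes) else 0.0
        for (a, b, interior), X in zip(self.segments, self._seg_X(x)):
            if interior:
                if X <= 0:
                    return -np.inf
                total += float(_renewal_logpdf(self.model, X))
            else:
                total -= X
        return total

    def grad(self, x) -> np.ndarray:
        g = np.zeros(self.n + 1)
        np.add.at(g, self.all_spikes, 1.0 / x[self.all_spikes])
        for (a, b, interior), X in zip(self.segments, self._seg_X(x)):
            w = float(_dlogf(self.model, X)) if interior else -1.0
            g[a:b] += self.delta * w
        return g

    def neg_hessian(self, x) -> np.ndarray:
        """Lambda(x) = -d^2 loglik / dx^2 (dense)."""
        lam = np.zeros((self.n + 1, self.n + 1))
        d = np.zeros(self.n + 1)
        np.add.at(d, self.all_spikes, 1.0 / x[self.all_spikes] ** 2)
        lam[np.diag_indices_from(lam)] += d
        for (a, b, interior), X in zip(self.segments, self._seg_X(x)):
            if interior:
                c = -float(_d2logf(self.model, X)) * self.delta**2
                lam[a:b, a:b] += c
        return lam


def _chol_logdet(A):
    c = linalg.cho_factor(A, lower=True)
    return c, 2.0 * float(np.sum(np.log(np.diag(c[0]))))


def _newton_map(lik: _PooledLikelihood, mu: float, prec: np.ndarray, config: FitConfig):
    """Projected Newton ascent of the log posterior; returns (x*, psi*)."""
    n1 = lik.n + 1
    x = np.full(n1, max(mu, 1e-2))

    def psi(v):
        r = v - mu
        return lik.value(v) - 0.5 * float(r @ prec @ r)

    cur = psi(x)
    for it in range(config.max_iter):
        grad = lik.grad(x) - prec @ (x - mu)
        pg = grad.copy()
        pg[(x <= 0) & (grad < 0)] = 0.0
        if np.max(np.abs(pg)) < config.grad_tol:
            return x, cur
        A = lik.neg_hessian(x) + prec
        free = (x > 0) | (grad > 0)
        if not np.any(free):
            return x, cur
        Af = A[np.ix_(free, free)]
        d = np.zeros(n1)
        tau = 0.0
        for _ in range(6):
            try:
                c = linalg.cho_factor(Af + tau * np.eye(Af.shape[0]), lower=True)
                d[free] = linalg.cho_solve(c, grad[free])
                break
            except linalg.LinAlgError:
                tau = 1e-6 if tau == 0 else tau * 100
        else:
            raise ConvergenceError("Newton system not positive definite", x, float(np.max(np.abs(pg))))
        step, improved = 1.0, False
        while step > 1e-12:
            xn = np.maximum(x + step * d, 0.0)
            new = psi(xn)
            if new > cur:
                improved = True
                break
            step /= 2
        if not improved:
            return x, cur  # stationary up to line-search resolution
        rel = abs(new - cur) / (abs(cur) + 1.0)
        x, cur = xn, new
        if rel < config.rel_tol:
            return x, cur
    grad = lik.grad(x) - prec @ (x - mu)
    pg = grad.copy()
    pg[(x <= 0) & (grad < 0)] = 0.0
    gn = float(np.max(np.abs(pg)))
    if gn < 1e-3:  # loose but stationary enough to be usable downstream
        logger.warning("MAP Newton hit max_iter with projected gradient %.2e", gn)
        return x, cur
    raise ConvergenceError("MAP Newton did not converge", x, gn)


def _as_sequences(y):
    return [y] if isinstance(y, SpikeSequence) else list(y)


def _grid_shape(sequences, n=None, delta=None):
    seqs = _as_sequences(sequences)
    if not seqs and (n is None or delta is None):
        raise ValueError("with no sequences, n and delta must be given explicitly")
    if delta is None:
        delta = seqs[0].delta
    if n is None:
        n = int(round(seqs[0].t_end / delta))
    return n, delta


def map_intensity(y, h: GPHyperparams, model: ISIModel, config: FitConfig = FitConfig(),
                  n: int | None = None, delta: float | None = None) -> IntensityGrid:
    """MAP intensity x_theta* for fixed hyperparameters (Eq-13-style argmax).

    ``y`` may be a single sequence or a list of sequences pooled under a
    shared intensity (summed log-likelihoods).
    """
    seqs = _as_sequences(y)
    n, delta = _grid_shape(seqs, n, delta)
    times = np.arange(n + 1) * delta
    Sigma = gram_matrix(times, h)
    c, _ = _chol_logdet(Sigma)
    prec = linalg.cho_solve(c, np.eye(n + 1))
    lik = _PooledLikelihood(seqs, n, delta, model)
    x, _ = _newton_map(lik, h.mu, prec, config)
    return IntensityGrid(np.maximum(x, 0.0), delta)


def laplace_log_evidence(loglik_value: float, lam: np.ndarray, x_star: np.ndarray,
                         mu: float, Sigma: np.ndarray) -> float:
    """log of Laplace's approximation to the prior-weighted evidence
    integral int p(y|x) N(x; mu, Sigma) dx around the MAP x_star."""
    _, logdet_sigma = _chol_logdet(Sigma)
    prec = linalg.cho_solve(linalg.cho_factor(Sigma, lower=True), np.eye(len(x_star)))
    r = x_star - mu
    _, logdet_post = _chol_logdet(lam + prec)
    return loglik_value - 0.5 * float(r @ prec @ r) - 0.5 * logdet_sigma - 0.5 * logdet_post


def laplace_log_weight(y, x_theta_star: IntensityGrid, h: GPHyperparams,
                       model: ISIModel, log_prior: float) -> float:
    """log F(y, x_theta*, theta): Laplace evidence plus the log-prior of theta.

    Raises on an indefinite curvature matrix (signals a non-MAP input).
    """
    seqs = _as_sequences(y)
    n, delta = x_theta_star.n, x_theta_star.delta
    lik = _PooledLikelihood(seqs, n, delta, model)
    x = x_theta_star.values
    Sigma = gram_matrix(np.arange(n + 1) * delta, h)
    return log_prior + laplace_log_evidence(lik.value(x), lik.neg_hessian(x), x, h.mu, Sigma)


def marginalize_hyperparameters(y, grid: HyperGrid, model_family: str,
                                config: FitConfig = FitConfig(),
                                n: int | None = None, delta: float | None = None) -> GPPosterior:
    """Discrete-sum marginalisation x* = sum_theta w_theta x_theta* with
    Laplace weights w proportional to exp(log F)."""
    seqs = _as_sequences(y)
    n, delta = _grid_shape(seqs, n, delta)
    times = np.arange(n + 1) * delta

    # Gram factors depend only on (kappa, sigma_f, sigma_v2); cache them.
    gram_cache: dict = {}

    def gram(h):
        key = (h.kappa, h.sigma_f, h.sigma_v2)
        if key not in gram_cache:
            Sigma = gram_matrix(times, h)
            c, logdet = _chol_logdet(Sigma)
            prec = linalg.cho_solve(c, np.eye(n + 1))
            gram_cache[key] = (prec, logdet)
        return gram_cache[key]

    records, log_F, variances = [], [], []
    for h, lp in zip(grid.points, grid.log_prior):
        model = ISIModel(model_family, h.shape if model_family != "IP" else None)
        prec, logdet_sigma = gram(h)
        lik = _PooledLikelihood(seqs, n, delta, model)
        try:
            x, _ = _newton_map(lik, h.mu, prec, config)
        except ConvergenceError as err:
            logger.warning("dropping grid point %s: %s", h, err)
            continue
        lam = lik.neg_hessian(x)
        A = lam + prec
        try:
            c, logdet_post = _chol_logdet(A)
        except linalg.LinAlgError:
            logger.warning("dropping grid point %s: indefinite curvature", h)
            continue
        r = x - h.mu
        lf = float(lp + lik.value(x) - 0.5 * (r @ prec @ r) - 0.5 * logdet_sigma - 0.5 * logdet_post)
        cov_diag = np.diag(linalg.cho_solve(c, np.eye(n + 1)))
        records.append((h, x, lf))
        log_F.append(lf)
        variances.append(cov_diag)

    if not records:
        raise ConvergenceError("no hyperparameter grid point produced a usable fit")
    log_F = np.asarray(log_F)
    if not np.any(np.isfinite(log_F)):
        raise ConvergenceError("all Laplace weights underflowed; re-centre the hyperparameter grid")
    log_Z = float(logsumexp(log_F))
    w = np.exp(log_F - log_Z)
    X = np.stack([r[1] for r in records])
    V = np.stack(variances)
    x_star = w @ X
    second = w @ (V + X**2)
    var_mix = np.maximum(second - x_star**2, 0.0)
    band = 1.96 * np.sqrt(var_mix)
    return GPPosterior(
        x_star=IntensityGrid(np.maximum(x_star, 0.0), delta),
        ci_lower=np.maximum(x_star - band, 0.0),
        ci_upper=x_star + band,
        per_theta=tuple(records),
        weights=w,
        log_Z=log_Z,
    )


def build_hyper_grid(family: str, mu: float, config: FitConfig) -> HyperGrid:
    """Independent uniform prior over the log-spaced grids of the config."""
    if family == "IP":
        shapes = [None]
    elif family == "IG":
        shapes = list(config.gamma_grid)
    elif family == "IIG":
        shapes = list(config.alpha_grid)
    else:
        raise ValueError(f"unknown family {family!r}")
    points = [
        GPHyperparams(mu=mu, sigma_f=sf, kappa=k, sigma_v2=config.sigma_v2, shape=s)
        for s in shapes
        for k in config.kappa_grid
        for sf in config.sigma_f_grid
    ]
    return HyperGrid.uniform(points)


def fit_cell(y, family: str = "IG", config: FitConfig = FitConfig(),
             n: int | None = None, delta: float | None = None) -> GPPosterior:
    """Full Bayesian fit of one cell (or pooled sequences sharing one x).

    Deterministic given the config: grid construction, per-theta MAP fits,
    Laplace weighting and marginalisation involve no randomness.
    """
    seqs = _as_sequences(y)
    n, delta = _grid_shape(seqs, n, delta)
    n_spikes = sum(len(s) for s in seqs)
    for s in seqs:
        if len(s) <= config.min_spikes:
            warnings.warn(
                f"sequence {s.cell_id or '<unnamed>'} has {len(s)} spikes "
                f"(inclusion filter requires more than {config.min_spikes})",
                stacklevel=2,
            )
    t_total = sum(s.t_end for s in seqs)
    mu = config.mu if config.mu is not None else max(n_spikes / t_total, 1e-3)
    grid = build_hyper_grid(family, mu, config)
    logger.info(
        "fit_cell: family=%s, %d grid points, mu=%.3g, n=%d, delta=%.3g",
        family, len(grid.points), mu, n, delta,
    )
    return marginalize_hyperparameters(seqs, grid, family, config, n=n, delta=delta)
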