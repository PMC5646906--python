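"""Squared-exponential Gaussian-process prior over intensity functions.

The latent spike rate x(t) is modelled a priori as a GP with constant mean
mu and squared-exponential covariance

    Sigma(t1, t2) = sigma_f^2 * exp(-kappa * (t1 - t2)^2 / 2) + delta_{t1 t2} * sigma_v^2,

where kappa (1/s^2) sets the smoothness, sigma_f (events/s) the signal
scale, and the nugget sigma_v^2 (fixed at 1e-4 by default) guarantees a
well-conditioned Gram matrix.  The module also provides the two reference
intensities used throughout the simulation studies: the deterministic
oscillation x_det(t) = 0.5 cos(t) + 0.5 cos(0.5 t) + 1 and GP draws x_GP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .point_process import IntensityGrid, ParameterError

logger = logging.getLogger(__name__)

#: Default nugget variance; excluded from hyperparameter optimisation.
SIGMA_V2 = 1e-4


@dataclass(frozen=True)
class GPHyperparams:
    """GP prior parameters, optionally bundling the ISI shape parameter."""

    mu: float
    sigma_f: float
    kappa: float
    sigma_v2: float = SIGMA_V2
    shape: float | None = None

    def __post_init__(self):
        if not (self.sigma_f > 0):
            raise ParameterError("sigma_f must be positive")
        if not (self.kappa > 0):
            raise ParameterError("kappa must be positive")
        if not (self.sigma_v2 >= 0):
            raise ParameterError("sigma_v2 must be non-negative")


def se_covariance(t1, t2, h: GPHyperparams):
    """Squared-exponential kernel value(s); nugget added where t1 == t2."""
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    d = t1 - t2
    return h.sigma_f**2 * np.exp(-h.kappa * d**2 / 2) + np.where(d == 0, h.sigma_v2, 0.0)


def gram_matrix(times, h: GPHyperparams) -> np.ndarray:
    """Dense SE Gram matrix over grid times; checked positive definite.

    On a Cholesky failure the jitter is escalated once (10x nugget) before
    giving up.
    """
    t = np.asarray(times, dtype=float)
    d = t[:, None] - t[None, :]
    K = h.sigma_f**2 * np.exp(-h.kappa * d**2 / 2)
    K[np.diag_indices_from(K)] += h.sigma_v2
    try:
        linalg.cholesky(K, lower=True)
    except linalg.LinAlgError:
        logger.warning("Gram matrix not PD at nugget %.1e; escalating jitter once", h.sigma_v2)
        K[np.diag_indices_from(K)] += 10 * h.sigma_v2
        linalg.cholesky(K, lower=True)  # raises if still indefinite
    return K


def sample_intensity(
    h: GPHyperparams,
    n: int,
    delta: float,
    n_samples: int = 1,
    seed: int | None = None,
    clip: bool = True,
) -> list[IntensityGrid]:
    """Draw GP realisations on the grid and rectify them into intensities.

    Negative excursions are clipped at zero (an intensity is a rate); the
    clipped fraction is logged so heavily-clipped draws can be rejected by
    the caller.  With ``clip=False`` the raw (possibly negative) draws are
    returned as plain arrays for diagnostic use.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(n + 1) * delta
    K = gram_matrix(t, h)
    L = linalg.cholesky(K, lower=True)
    draws = h.mu + L @ rng.standard_normal((n + 1, n_samples))
    out = []
    for j in range(n_samples):
        v = draws[:, j]
        if not clip:
            out.append(v)
            continue
        frac = float(np.mean(v < 0))
        if frac > 0:
            logger.info("clipped %.1f%% of GP sample %d at zero", 100 * frac, j)
            v = np.maximum(v, 0.0)
        out.append(IntensityGrid(v, delta))
    return out


def x_det(t):
    """Regularly oscillating reference intensity 0.5 cos(t) + 0.5 cos(t/2) + 1."""
    t = np.asarray(t, dtype=float)
    return 0.5 * np.cos(t) + 0.5 * np.cos(0.5 * t) + 1.0


#: Hyperparameters of the x_GP reference draw (and its IG shape companion).
XGP_HYPERPARAMS = GPHyperparams(mu=2.1, sigma_f=1.5, kappa=0.5, shape=6.2)

#: IG shape used with x_det in the simulation studies.
XDET_SHAPE = 5.9


def reference_intensity(
    name: str,
    n: int,
    delta: float,
    seed: int | None = None,
    h: GPHyperparams | None = None,
) -> IntensityGrid:
    """Reference intensities of the simulation studies: ``x_det`` or ``x_GP``."""
    if name == "x_det":
        return IntensityGrid(x_det(np.arange(n + 1) * delta), delta)
    if name == "x_GP":
        if seed is None:
            raise ValueError("x_GP requires an explicit seed")
        return sample_intensity(h or XGP_HYPERPARAMS, n, delta, 1, seed)[0]
    raise ValueError(f"unknown reference intensity {name!r}; choose x_det or x_GP")
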