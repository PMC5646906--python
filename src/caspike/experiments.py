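"""Reproducible synthetic experiments tying the modules together.

Three named experiments mirror the package's simulation studies at desk
scale (problem sizes are deliberately modest so a run stays interactive;
all sizes are overridable):

- ``isi-selection``   generate cells from a known IG model and check that
  the per-cell goodness-of-fit protocol ranks IG above IP and IIG;
- ``rate-benchmark``  compare the GP estimator against kernel smoothing at
  the cross-validated bandwidth over growing numbers of pooled sequences;
- ``population-pipeline``  planted stimulus groups -> PCA weights ->
  k-means -> per-cluster mean intensities -> surrogate regeneration ->
  histogram distance.

Every random quantity derives from the single ``seed`` argument, and the
summary is a plain dict serialisable as JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import io as cio
from .gof import rank_candidates, select_isi_model
from .gp import XDET_SHAPE, reference_intensity
from .inference import FitConfig
from .estimators import GPRateEstimator, KernelRateEstimator, PSTHRateEstimator
from .point_process import ISIModel, IntensityGrid
from .population import cluster_mean_rate, histogram_distance, kmeans_cluster, pca_weights
from .rates import l2_error, optimal_bin_width
from .surrogate import simulate_ensemble, snap_sequence

logger = logging.getLogger(__name__)

EXPERIMENTS = ("isi-selection", "rate-benchmark", "population-pipeline")

#: Reduced hyperparameter grids used by the experiment fits.
FAST_CONFIG = FitConfig(
    gamma_grid=tuple(np.geomspace(1.0, 16.0, 4)),
    alpha_grid=tuple(np.geomspace(0.3, 4.0, 4)),
    kappa_grid=tuple(np.geomspace(0.01, 1.0, 3)),
    sigma_f_grid=(0.5, 1.5),
)


def _seeds(seed: int, k: int):
    return np.random.SeedSequence(seed).spawn(k)


def slow_intensity(t_end: float, delta: float, mean_rate: float = 1.0 / 3.0,
                   period: float = 60.0, depth: float = 0.4) -> IntensityGrid:
    """Gently oscillating intensity for the per-cell GoF studies.

    The per-cell model-selection protocol rescales ISIs through an
    intensity fitted from the same ~40 spikes, so it is calibrated in the
    regime the paper's recordings occupy: intensity variation slow
    compared with the inter-spike interval.  One oscillation per
    ``period`` seconds around ``mean_rate`` keeps roughly 20 ISIs per
    swing at the defaults.
    """
    t = np.arange(int(round(t_end / delta)) + 1) * delta
    return IntensityGrid(mean_rate * (1.0 + depth * np.sin(2 * np.pi * t / period)), delta)


def isi_selection_experiment(seed: int = 0, n_cells: int = 20, t_end: float = 120.0,
                             sim_delta: float = 0.02, fit_delta: float = 0.75,
                             gamma: float = 6.0, mean_rate: float = 1.0 / 3.0,
                             config: FitConfig = FAST_CONFIG) -> dict:
    """Model-selection recovery on synthetic IG cells (~40 spikes each)."""
    x = slow_intensity(t_end, sim_delta, mean_rate)
    model = ISIModel("IG", gamma)
    cells = [
        snap_sequence(s, fit_delta)
        for s in simulate_ensemble(x, model, "rescaling", m=n_cells, seed=seed)
    ]
    results = select_isi_model(cells, ("IP", "IG", "IIG"), config=config)
    ranking = rank_candidates(results)
    return {
        "experiment": "isi-selection",
        "seed": seed,
        "n_cells": n_cells,
        "generating_family": "IG",
        "generating_shape": gamma,
        "ranking": ranking,
        "median_slope": {f: results[f].slope for f in results},
        "box": {f: results[f].box for f in results},
        "recovered": ranking[0] == "IG",
    }


def rate_benchmark_experiment(seed: int = 0, group_sizes=(1, 2, 4, 7), n_replicates: int = 20,
                              t_end: float = 40.0, sim_delta: float = 0.02,
                              fit_delta: float = 0.25, gamma: float = XDET_SHAPE,
                              config: FitConfig = FAST_CONFIG) -> dict:
    """Normalised L2 error of GP vs kernel-smoothing estimates as the
    number of pooled sequences grows."""
    n_fit = int(round(t_end / fit_delta))
    x_true_fine = reference_intensity("x_det", int(round(t_end / sim_delta)), sim_delta)
    x_true = reference_intensity("x_det", n_fit, fit_delta)
    model = ISIModel("IG", gamma)
    rep_seeds = _seeds(seed, n_replicates)
    errors = {m: {"gp": [], "ks_sigma_hat": [], "psth": []} for m in group_sizes}
    for r in range(n_replicates):
        pool = simulate_ensemble(x_true_fine, model, "rescaling",
                                 m=max(group_sizes), seed=rep_seeds[r])
        for m in group_sizes:
            seqs = [snap_sequence(s, fit_delta) for s in pool[:m]]
            gp = GPRateEstimator(family="IG", config=config, n=n_fit, delta=fit_delta).fit(seqs)
            ks = KernelRateEstimator(sigma="auto", n=n_fit, delta=fit_delta).fit(seqs)
            ph = PSTHRateEstimator(bin_width="auto", n=n_fit, delta=fit_delta).fit(seqs)
            errors[m]["gp"].append(l2_error(gp.intensity_, x_true))
            errors[m]["ks_sigma_hat"].append(l2_error(ks.intensity_, x_true))
            errors[m]["psth"].append(l2_error(ph.intensity_, x_true))
    medians = {
        str(m): {k: float(np.median(v)) for k, v in errors[m].items()} for m in group_sizes
    }
    return {
        "experiment": "rate-benchmark",
        "seed": seed,
        "group_sizes": list(group_sizes),
        "n_replicates": n_replicates,
        "median_l2": medians,
        "l2_samples": {
            str(m): {k: [float(x) for x in v] for k, v in errors[m].items()} for m in group_sizes
        },
    }


def _planted_stimuli(seed, n_cells, n_groups, t_grid):
    """Per-cell stimulus traces with planted group structure."""
    rng = np.random.default_rng(seed)
    amplitudes = np.linspace(0.6, 2.0, n_groups)
    centers = np.linspace(0.3, 0.6, n_groups) * t_grid[-1]
    labels = np.repeat(np.arange(n_groups), int(np.ceil(n_cells / n_groups)))[:n_cells]
    X = np.empty((n_cells, len(t_grid)))
    for i, g in enumerate(labels):
        a = amplitudes[g] * (1 + 0.05 * rng.standard_normal())
        bump = a * np.exp(-((t_grid - centers[g]) ** 2) / (2 * (t_grid[-1] / 8) ** 2))
        X[i] = bump + 0.02 * rng.standard_normal(len(t_grid))
    return X, labels


def population_pipeline_experiment(seed: int = 0, n_cells: int = 24, n_groups: int = 4,
                                   t_end: float = 40.0, delta: float = 0.25,
                                   gamma: float = 6.0, min_spikes: int = 10,
                                   config: FitConfig = FAST_CONFIG) -> dict:
    """End-to-end population analysis on planted stimulus groups."""
    n = int(round(t_end / delta))
    t_grid = np.arange(n + 1) * delta
    s_stim, s_spk, s_surr = _seeds(seed, 3)
    X, planted = _planted_stimuli(s_stim, n_cells, n_groups, t_grid)

    # stimulus drives the rate: baseline plus a gain on the trace
    cell_seeds = s_spk.spawn(n_cells)
    model = ISIModel("IG", gamma)
    cells, kept = [], []
    for i in range(n_cells):
        x_i = IntensityGrid(np.maximum(0.3 + 1.6 * X[i], 0.0), delta)
        seq = snap_sequence(
            simulate_ensemble(x_i, model, "rescaling", m=1, seed=cell_seeds[i],
                              cell_prefix=f"cell{i:03d}_")[0],
            delta,
        )
        if len(seq) > min_spikes:
            cells.append(seq)
            kept.append(i)
    kept = np.asarray(kept)

    W = pca_weights(X[kept], n_components=3)
    clu = kmeans_cluster(W, k=n_groups, seed=int(np.random.default_rng(seed).integers(2**31)))
    posts = [
        GPRateEstimator(family="IG", config=config, n=n, delta=delta).fit(c).posterior_
        for c in cells
    ]
    means = cluster_mean_rate(posts, clu.labels)

    bin_width = optimal_bin_width(cells)
    edges = np.arange(0.0, t_end + bin_width, bin_width)
    h_per_cluster = {}
    surr_seeds = s_surr.spawn(len(means))
    for j, (lab, x_mean) in enumerate(sorted(means.items())):
        members = [c for c, l in zip(cells, clu.labels) if l == lab]
        rec = np.histogram(np.concatenate([c.times for c in members]), bins=edges)[0]
        surr = simulate_ensemble(x_mean, model, "rescaling", m=len(members), seed=surr_seeds[j])
        sim = np.histogram(np.concatenate([s.times for s in surr]), bins=edges)[0]
        h_per_cluster[str(lab)] = histogram_distance(rec, sim)

    return {
        "experiment": "population-pipeline",
        "seed": seed,
        "n_cells": n_cells,
        "kept_cells": int(len(kept)),
        "k": n_groups,
        "cluster_sizes": np.bincount(clu.labels, minlength=n_groups).tolist(),
        "planted_labels": planted[kept].tolist(),
        "labels": clu.labels.tolist(),
        "kmeans_error": clu.error,
        "bin_width": float(bin_width),
        "histogram_distance": h_per_cluster,
    }


def run_experiment(name: str, seed: int = 0, outdir=None, **kwargs) -> dict:
    """Run a named experiment; optionally write its summary bundle."""
    runners = {
        "isi-selection": isi_selection_experiment,
        "rate-benchmark": rate_benchmark_experiment,
        "population-pipeline": population_pipeline_experiment,
    }
    if name not in runners:
        raise ValueError(f"unknown experiment {name!r}; choose from {EXPERIMENTS}")
    summary = runners[name](seed=seed, **kwargs)
    summary["config"] = {"name": name, "seed": seed, **{k: repr(v) for k, v in kwargs.items()}}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / f"{name}-summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
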