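"""Fluorescence-trace normalisation and threshold spike extraction.

Recorded traces are normalised as F/F0 where the baseline F0 is the mean
over the sliding window (default 25 s long, searched within the first
120 s) with minimum standard deviation -- i.e. the quietest pre-stimulus
stretch.  A simple threshold-crossing extractor is provided as a
convenience front end; the primary input of the package remains spike
tables, since raw-trace spike detection is acquisition-specific.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .point_process import SpikeSequence


def _check_uniform(time: np.ndarray) -> float:
    dt = np.diff(time)
    if len(dt) == 0 or np.any(dt <= 0) or np.ptp(dt) > 1e-6 * dt[0]:
        raise ValueError("time column must be strictly increasing and uniform")
    return float(dt[0])


def normalize_trace(time, values, baseline_len: float = 25.0, search_end: float = 120.0):
    """F/F0 normalisation with automatic baseline-window selection.

    Returns ``(normalized, window_start)`` where ``window_start`` is the
    left edge (seconds) of the selected minimum-variance baseline window.
    """
    time = np.asarray(time, dtype=float)
    values = np.asarray(values, dtype=float)
    dt = _check_uniform(time)
    if time[-1] - time[0] < search_end:
        raise ValueError(f"trace must cover at least the search range 0-{search_end} s")
    w = max(int(round(baseline_len / dt)), 1)
    last_start = int(round((search_end - baseline_len) / dt))
    roll = pd.Series(values).rolling(w)
    stds = roll.std(ddof=0).to_numpy()[w - 1:]       # std of window starting at i
    means = roll.mean().to_numpy()[w - 1:]
    stds = stds[: last_start + 1]
    i = int(np.nanargmin(stds))
    f0 = means[i]
    if f0 == 0:
        raise ValueError("baseline mean is zero; cannot normalise")
    return values / f0, float(time[0] + i * dt)


def extract_spikes(time, values, threshold: float, refractory: float, cell_id: str = "") -> SpikeSequence:
    """Threshold-crossing spike extraction from a normalised trace.

    A spike is the time of the local maximum within each super-threshold
    excursion; peaks closer than ``refractory`` seconds to the previous
    accepted spike are discarded.  Deterministic.
    """
    if not threshold > 1:
        raise ValueError("threshold must exceed 1 (F/F0 units)")
    time = np.asarray(time, dtype=float)
    values = np.asarray(values, dtype=float)
    dt = _check_uniform(time)
    above = values > threshold
    spikes = []
    i = 0
    while i < len(values):
        if above[i]:
            j = i
            while j < len(values) and above[j]:
                j += 1
            peak = i + int(np.argmax(values[i:j]))
            t = float(time[peak])
            if t > 0 and (not spikes or t - spikes[-1] >= refractory):
                spikes.append(t)
            i = j
        else:
            i += 1
    return SpikeSequence(np.asarray(spikes), t_end=float(time[-1]), delta=dt, cell_id=cell_id)
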