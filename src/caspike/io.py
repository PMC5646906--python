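"""Delimited-text input/output for spike tables, intensity grids and
posterior summaries.

Spike data travel in a long-format table (``cell_id,spike_time``) with the
observation window T and frame interval delta carried as commented header
metadata -- never inferred silently::

    # t_end=180.0
    # delta=1.0
    cell_id,spike_time
    c000,12.0
    ...

Intensity grids and rate estimates use a two-column ``time,rate`` table;
posteriors add the credible band (``time,x_star,ci_lower,ci_upper``).
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import GPPosterior
from .point_process import IntensityGrid, SpikeSequence


def write_spike_table(sequences, path) -> None:
    seqs = list(sequences)
    if not seqs:
        raise ValueError("no sequences to write")
    t_end, delta = seqs[0].t_end, seqs[0].delta
    if any(abs(s.t_end - t_end) > 1e-9 or abs(s.delta - delta) > 1e-12 for s in seqs):
        raise ValueError("all sequences in one table must share t_end and delta")
    with open(path, "w", newline="\n") as fh:
        fh.write(f"# t_end={float(t_end)!r}\n# delta={float(delta)!r}\n")
        fh.write("cell_id,spike_time\n")
        for s in seqs:
            cid = s.cell_id or "cell"
            for t in s.times:
                fh.write(f"{cid},{float(t)!r}\n")


def read_spike_table(path) -> list[SpikeSequence]:
    """Parse a long-format spike table; invalid rows are reported with
    their line numbers."""
    text = Path(path).read_text()
    meta = {}
    header_lines = 0
    for line in text.splitlines():
        if line.startswith("#"):
            header_lines += 1
            if "=" in line:
                k, v = line.lstrip("# ").split("=", 1)
                meta[k.strip()] = float(v)
        else:
            break
    if "t_end" not in meta or "delta" not in meta:
        raise ValueError("spike table must carry '# t_end=' and '# delta=' header metadata")
    df = pd.read_csv(_io.StringIO(text), comment="#")
    if list(df.columns) != ["cell_id", "spike_time"]:
        raise ValueError("expected columns cell_id,spike_time")
    # +2: header metadata lines precede the column row, rows are 0-based
    line_no = np.arange(len(df)) + header_lines + 2
    bad = df.index[(df["spike_time"] <= 0) | (df["spike_time"] > meta["t_end"] + 1e-9)]
    if len(bad):
        raise ValueError(f"invalid spike times at line(s) {sorted(line_no[bad].tolist())}")
    out = []
    for cid, grp in df.groupby("cell_id", sort=False):
        t = grp["spike_time"].to_numpy()
        diffs = np.diff(t)
        offenders = grp.index[1:][diffs <= 0] if len(t) > 1 else []
        if len(offenders):
            raise ValueError(
                f"unsorted or duplicate times for cell {cid!r} at line(s) "
                f"{sorted(line_no[offenders].tolist())}"
            )
        close = grp.index[1:][diffs < meta["delta"] - 1e-9] if len(t) > 1 else []
        if len(close):
            raise ValueError(
                f"spikes closer than delta for cell {cid!r} at line(s) "
                f"{sorted(line_no[close].tolist())}"
            )
        out.append(SpikeSequence(t, t_end=meta["t_end"], delta=meta["delta"], cell_id=str(cid)))
    return out


def write_intensity(x: IntensityGrid, path) -> None:
    pd.DataFrame({"time": x.times, "rate": x.values}).to_csv(path, index=False)


def read_intensity(path) -> IntensityGrid:
    df = pd.read_csv(path)
    t = df["time"].to_numpy()
    dt = np.diff(t)
    if len(dt) == 0 or np.ptp(dt) > 1e-9 * dt[0]:
        raise ValueError("intensity table must have a uniform time grid")
    return IntensityGrid(df["rate"].to_numpy(), float(dt[0]))


def write_posterior(post: GPPosterior, path, weights_path=None) -> None:
    pd.DataFrame(
        {
            "time": post.x_star.times,
            "x_star": post.x_star.values,
            "ci_lower": post.ci_lower,
            "ci_upper": post.ci_upper,
        }
    ).to_csv(path, index=False)
    if weights_path is not None:
        rows = [
            {
                "shape": h.shape if h.shape is not None else np.nan,
                "kappa": h.kappa,
                "sigma_f": h.sigma_f,
                "mu": h.mu,
                "log_F": lf,
                "weight": w,
            }
            for (h, _, lf), w in zip(post.per_theta, post.weights)
        ]
        pd.DataFrame(rows).to_csv(weights_path, index=False)
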