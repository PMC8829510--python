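"""Time-series and snapshot file output, and run logging.

CSV schema for time series: header
``tick,n_vsmc,n_ecm,ratio,plaque_burden,lumen_area,wall_area,mean_damage``,
one row per tick including tick 0. Snapshots are integer occupancy
matrices (0 empty/lumen, 1 VSMC, 2 ECM) written as compressed ``.npz``
with an optional PNG rendering (lumen white, VSMC red, ECM blue).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import SimulationConfig, config_hash, save_config
from .model import TIMESERIES_COLUMNS, ReplicateResult, SimulationResult

__all__ = [
    "write_timeseries",
    "read_timeseries",
    "write_snapshots",
    "write_run",
    "write_replicates",
]

logger = logging.getLogger("vesselabm")


def write_timeseries(ts: pd.DataFrame, path) -> None:
    """Write a per-tick time series as CSV with the canonical header."""
    missing = [c for c in TIMESERIES_COLUMNS if c not in ts.columns]
    if missing:
        raise ValueError(f"time series is missing column(s) {missing}")
    ts[TIMESERIES_COLUMNS].to_csv(path, index=False)


def read_timeseries(path) -> pd.DataFrame:
    """Read a time-series CSV, validating the header."""
    df = pd.read_csv(path)
    missing = [c for c in TIMESERIES_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"malformed time-series file {path!s}: missing column(s) {missing}"
        )
    return df[TIMESERIES_COLUMNS]


def write_snapshots(snapshots: dict, out_dir, png: bool = False) -> None:
    """Write each snapshot as ``tick_XXXX.npz`` (and optionally ``.png``)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for tick, snap in sorted(snapshots.items()):
        np.savez_compressed(out / f"tick_{tick:04d}.npz", occupancy=snap)
        if png:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt
            from matplotlib.colors import ListedColormap

            fig, ax = plt.subplots(figsize=(4, 4))
            cmap = ListedColormap(["white", "crimson", "steelblue"])
            ax.imshow(snap.T, origin="lower", cmap=cmap, vmin=0, vmax=2)
            ax.set_title(f"t = {tick} h")
            ax.set_xticks([])
            ax.set_yticks([])
            fig.savefig(out / f"tick_{tick:04d}.png", dpi=120)
            plt.close(fig)


def _write_log(path, config: SimulationConfig, seeds) -> None:
    with open(path, "w") as fh:
        fh.write(f"vesselabm {__version__}\n")
        fh.write(f"config hash: {config_hash(config)}\n")
        fh.write(f"seeds: {list(seeds)}\n")


def write_run(result: SimulationResult, out_dir, png: bool = False) -> Path:
    """Write one run: timeseries.csv, snapshots/, config.yaml, run.log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_timeseries(result.timeseries, out / "timeseries.csv")
    write_snapshots(result.snapshots, out / "snapshots", png=png)
    save_config(result.config, out / "config.yaml")
    _write_log(out / "run.log", result.config, [result.seed])
    logger.info("wrote run output to %s", out)
    return out


def write_replicates(reps: ReplicateResult, out_dir) -> Path:
    """Write a replicate batch: per-seed timeseries, mean/sd summary, log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for run in reps.runs:
        write_timeseries(run.timeseries, out / f"timeseries_seed{run.seed}.csv")
    summary = reps.mean.add_suffix("_mean").join(reps.sd.add_suffix("_sd"))
    summary = summary.rename(columns={"tick_mean": "tick"}).drop(columns=["tick_sd"])
    summary.to_csv(out / "summary.csv", index=False)
    _write_log(
        out / "run.log",
        reps.runs[0].config,
        [r.seed for r in reps.runs],
    )
    logger.info("wrote %d replicates to %s", reps.n_replicates, out)
    return out
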