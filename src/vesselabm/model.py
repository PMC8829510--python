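"""Model and results objects: the user-facing simulation surface.

:class:`RemodelingModel` binds a :class:`~vesselabm.config.SimulationConfig`
(and, optionally, an explicit WSS profile overriding the configured
source) and runs the lattice model. A single run returns a
:class:`SimulationResult` holding the per-tick time series, periodic
snapshots and the final grid; :meth:`RemodelingModel.run_replicates`
returns a :class:`ReplicateResult` with per-tick mean and standard
deviation across seeds. Both results offer ``summary()`` tables and
matplotlib plots.

Example
-------
>>> from vesselabm import RemodelingModel
>>> model = RemodelingModel()          # shipped calibrated defaults
>>> res = model.run(seed=1)
>>> print(res.summary())
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import __version__
from .config import SimulationConfig, config_hash, default_config
from .core import (
    ECM,
    VSMC,
    Grid,
    StepParams,
    assign_damage,
    biochem_modifier_fields,
    init_geometry,
    plaque_burden,
    step,
)
from .hemodynamics import (
    ML_PER_MIN,
    TubeSpec,
    WSSProfile,
    load_wss_profile,
    make_sector_profile,
    poiseuille_wss,
)

__all__ = [
    "RemodelingModel",
    "SimulationResult",
    "ReplicateResult",
    "run_simulation",
    "run_replicates",
    "build_profile",
]

logger = logging.getLogger("vesselabm")

TIMESERIES_COLUMNS = [
    "tick",
    "n_vsmc",
    "n_ecm",
    "ratio",
    "plaque_burden",
    "lumen_area",
    "wall_area",
    "mean_damage",
]


def build_profile(config: SimulationConfig) -> WSSProfile:
    """Construct the angular WSS profile described by ``config.wss_source``."""
    src = config.wss_source
    if src.type == "sector":
        return make_sector_profile(
            src.tau_base, src.tau_min, src.center_deg, src.width_deg, src.n_samples
        )
    if src.type == "poiseuille":
        tube = TubeSpec(
            radius=src.radius_m,
            viscosity=src.viscosity_pa_s,
            density=src.density_kg_m3,
            flow_rate=src.flow_ml_min * ML_PER_MIN,
        )
        tau = poiseuille_wss(tube)
        n = max(src.n_samples, 4)
        return WSSProfile(
            angles=np.arange(n) * (360.0 / n), tau=np.full(n, tau)
        )
    return load_wss_profile(src.path)


@dataclass
class SimulationResult:
    """Outcome of one seeded run.

    ``timeseries`` has one row per tick (tick 0 = initial state) with the
    counts, VSMC/ECM ratio, plaque burden, areas and mean damage;
    ``snapshots`` maps tick -> occupancy matrix (0 empty, 1 VSMC, 2 ECM).
    """

    timeseries: pd.DataFrame
    snapshots: dict
    final_grid: Grid
    config: SimulationConfig
    seed: int

    def _window(self, t0: int = 700, t1: int = 800) -> pd.DataFrame:
        ts = self.timeseries
        return ts[(ts["tick"] >= t0) & (ts["tick"] <= t1)]

    @property
    def final(self) -> pd.Series:
        return self.timeseries.iloc[-1]

    def summary(self) -> str:
        f = self.final
        lines = [
            "Vessel-wall remodeling simulation",
            "=" * 49,
            f"seed                     {self.seed}",
            f"config hash              {config_hash(self.config)}",
            f"ticks simulated          {int(f['tick'])} (1 h each)",
            f"initial wall area        {self.final_grid.baseline_wall_area} sites",
            f"final VSMC count         {int(f['n_vsmc'])}",
            f"final ECM count          {int(f['n_ecm'])}",
            f"final VSMC/ECM ratio     {f['ratio']:.4f}",
            f"final plaque burden      {100 * f['plaque_burden']:.2f} %",
            f"final lumen area         {int(f['lumen_area'])} sites",
            f"final mean damage        {f['mean_damage']:.4g}",
        ]
        return "\n".join(lines)

    def plot_timeseries(self, ax=None):
        """Counts, ratio and plaque burden against time on twin axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        ts = self.timeseries
        ax.plot(ts["tick"], ts["n_vsmc"], color="crimson", label="VSMC")
        ax.plot(ts["tick"], ts["n_ecm"], color="steelblue", label="ECM")
        ax.set_xlabel("tick (h)")
        ax.set_ylabel("agent count")
        ax2 = ax.twinx()
        ax2.plot(
            ts["tick"], 100 * ts["plaque_burden"], color="black", label="plaque burden"
        )
        ax2.set_ylabel("plaque burden (%)")
        ax.legend(loc="lower right")
        return ax

    def plot_snapshot(self, tick: int, ax=None):
        """Cross-section occupancy: lumen white, VSMC red, ECM blue."""
        import matplotlib.pyplot as plt
        from matplotlib.colors import ListedColormap

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        snap = self.snapshots[tick]
        cmap = ListedColormap(["white", "crimson", "steelblue"])
        ax.imshow(snap.T, origin="lower", cmap=cmap, vmin=0, vmax=2)
        ax.set_title(f"t = {tick} h")
        ax.set_xticks([])
        ax.set_yticks([])
        return ax


@dataclass
class ReplicateResult:
    """Per-tick mean/sd over replicate runs, plus the individual runs."""

    runs: list
    mean: pd.DataFrame
    sd: pd.DataFrame
    base_seed: int

    @property
    def n_replicates(self) -> int:
        return len(self.runs)

    def window_mean(self, column: str, t0: int = 700, t1: int = 800) -> float:
        """Replicate-and-time average of a column over [t0, t1]."""
        m = self.mean
        sel = (m["tick"] >= t0) & (m["tick"] <= t1)
        return float(m.loc[sel, column].mean())

    def summary(self, t0: int = 700, t1: int = 800) -> str:
        lines = [
            f"Replicate summary over {self.n_replicates} runs "
            f"(seeds {self.base_seed}..{self.base_seed + self.n_replicates - 1})",
            "=" * 58,
            f"window for stabilized means: ticks {t0}-{t1}",
            f"mean VSMC count          {self.window_mean('n_vsmc', t0, t1):.1f}",
            f"mean ECM count           {self.window_mean('n_ecm', t0, t1):.1f}",
            f"mean VSMC/ECM ratio      {self.window_mean('ratio', t0, t1):.4f}",
            f"mean plaque burden       {100 * self.window_mean('plaque_burden', t0, t1):.2f} %",
            f"mean lumen area          {self.window_mean('lumen_area', t0, t1):.1f} sites",
        ]
        return "\n".join(lines)


def run_simulation(
    config: SimulationConfig,
    seed: int | None = None,
    profile: WSSProfile | None = None,
    tick_callback=None,
) -> SimulationResult:
    """Run one seeded simulation described by ``config``.

    ``tick_callback(grid, stats)``, if given, is invoked after every tick
    (used by invariant-checking tests). Deterministic for a given seed.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    if profile is None:
        profile = build_profile(config)
    logger.info(
        "run start: seed=%s config=%s version=%s", seed, config_hash(config), __version__
    )
    grid = init_geometry(config.geometry, config.clocks, config.vsmc_fraction, rng)
    assign_damage(grid, profile, config.damage)
    bio = config.biochem
    p_et, p_no, p_mmp9 = biochem_modifier_fields(
        grid,
        profile,
        bio.et,
        bio.no,
        bio.mmp9,
        bio.conversion,
        n_ec=bio.n_ec_per_site,
        dt=config.clocks.dt,
    )
    params = StepParams(
        clocks=config.clocks,
        probabilities=config.probabilities,
        state=config.remodeling_state(),
        p_et=p_et,
        p_no=p_no,
        p_mmp9=p_mmp9,
        decay=float(np.exp(-config.damage.recovery_rate * config.clocks.dt)),
    )
    occ = grid.occupied
    rows = [
        {
            "tick": 0,
            "n_vsmc": grid.n_vsmc,
            "n_ecm": grid.n_ecm,
            "ratio": grid.n_vsmc / grid.n_ecm if grid.n_ecm else np.nan,
            "plaque_burden": plaque_burden(grid),
            "lumen_area": grid.lumen_area,
            "wall_area": grid.wall_area,
            "mean_damage": float(grid.damage[occ].mean()),
        }
    ]
    snapshots = {}
    for t in range(1, config.clocks.total_ticks + 1):
        try:
            stats = step(grid, t, params, rng)
        except Exception as exc:
            raise RuntimeError(f"simulation failed at tick {t}: {exc}") from exc
        if tick_callback is not None:
            tick_callback(grid, stats)
        rows.append({k: stats[k] for k in TIMESERIES_COLUMNS})
        if t % config.snapshot_every == 0:
            snapshots[t] = grid.kind.copy()
    ts = pd.DataFrame(rows, columns=TIMESERIES_COLUMNS)
    logger.info("run done: seed=%s final_pb=%.4f", seed, ts["plaque_burden"].iloc[-1])
    return SimulationResult(
        timeseries=ts, snapshots=snapshots, final_grid=grid, config=config, seed=seed
    )


def run_replicates(
    config: SimulationConfig,
    n: int = 10,
    base_seed: int | None = None,
    profile: WSSProfile | None = None,
) -> ReplicateResult:
    """Run seeds ``base_seed .. base_seed+n-1`` and aggregate per tick."""
    if n < 2:
        raise ValueError("need at least 2 replicates")
    if base_seed is None:
        base_seed = config.seed
    runs = []
    for i in range(n):
        seed = base_seed + i
        try:
            runs.append(run_simulation(config, seed=seed, profile=profile))
        except Exception as exc:
            raise RuntimeError(f"replicate with seed {seed} failed: {exc}") from exc
    stack = np.stack([r.timeseries.to_numpy(dtype=float) for r in runs])
    mean = pd.DataFrame(stack.mean(axis=0), columns=TIMESERIES_COLUMNS)
    sd = pd.DataFrame(stack.std(axis=0, ddof=1), columns=TIMESERIES_COLUMNS)
    mean["tick"] = runs[0].timeseries["tick"]
    sd["tick"] = runs[0].timeseries["tick"]
    return ReplicateResult(runs=runs, mean=mean, sd=sd, base_seed=base_seed)


class RemodelingModel:
    """WSS-driven vessel-wall remodeling model.

    Parameters
    ----------
    config : SimulationConfig, optional
        Full parameterization; defaults to the shipped calibrated
        configuration.
    wss_profile : WSSProfile, optional
        Explicit angular WSS profile; overrides ``config.wss_source``.
    """

    def __init__(
        self,
        config: SimulationConfig | None = None,
        wss_profile: WSSProfile | None = None,
    ):
        self.config = config if config is not None else default_config()
        self.wss_profile = wss_profile

    @classmethod
    def from_yaml(cls, path, wss_profile: WSSProfile | None = None) -> "RemodelingModel":
        from .config import load_config

        return cls(load_config(path), wss_profile=wss_profile)

    def run(self, seed: int | None = None, tick_callback=None) -> SimulationResult:
        return run_simulation(
            self.config, seed=seed, profile=self.wss_profile, tick_callback=tick_callback
        )

    def run_replicates(
        self, n: int = 10, base_seed: int | None = None
    ) -> ReplicateResult:
        return run_replicates(
            self.config, n=n, base_seed=base_seed, profile=self.wss_profile
        )
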