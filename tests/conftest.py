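"""Shared fixtures: configurations and the expensive reference runs.

The two session-scoped simulation fixtures (the monitored seed-1 run and
the 10-replicate batch) are computed once and shared by the invariant
and reproduction tests.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import settings
from scipy import ndimage

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from vesselabm import default_config
from vesselabm.model import run_replicates, run_simulation


@pytest.fixture(scope="session")
def default_cfg():
    return default_config()


@pytest.fixture(scope="session")
def short_cfg(default_cfg):
    """Default physics, shortened horizon, for cheap integration tests."""
    return replace(
        default_cfg,
        clocks=replace(default_cfg.clocks, total_ticks=240),
        snapshot_every=120,
    )


def _check_occupancy(grid):
    """Exactly one agent per occupied site; id bookkeeping consistent."""
    occ = grid.kind > 0
    ids_ok = np.array_equal(occ, grid.ids >= 0)
    n_ok = int(occ.sum()) == len(grid.pos)
    pos_ok = all(grid.ids[x, y] == aid for aid, (x, y) in grid.pos.items())
    return ids_ok and n_ok and pos_ok


@pytest.fixture(scope="session")
def monitored_run(default_cfg):
    """Seed-1 default run with per-tick invariant observations recorded."""
    record = {
        "occupancy_ok": [],
        "wall_components": [],
        "lumen_area": [],
        "plaque_burden": [],
        "births": [],
        "deaths": [],
        "n_agents": [],
    }

    def cb(grid, stats):
        record["occupancy_ok"].append(_check_occupancy(grid))
        _, ncomp = ndimage.label(grid.kind > 0)
        record["wall_components"].append(ncomp)
        record["lumen_area"].append(grid.lumen_area)
        record["plaque_burden"].append(stats["plaque_burden"])
        record["births"].append(stats["births"])
        record["deaths"].append(stats["deaths"])
        record["n_agents"].append(grid.wall_area)

    result = run_simulation(default_cfg, seed=1, tick_callback=cb)
    return result, record


@pytest.fixture(scope="session")
def replicate_batch(default_cfg):
    """The 10-replicate reference batch, seeds 1..10, frozen defaults."""
    return run_replicates(default_cfg, n=10, base_seed=1)
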