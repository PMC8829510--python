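"""Calibration of the event-probability coefficients.

The probability coefficients (``alpha_div``, ``alpha_apop``, ``alpha_gen``,
``alpha_deg``) are free parameters of the model. ``calibrate_defaults``
searches a candidate list for the parameter set whose replicate-mean
stabilized endpoints come closest (in summed squared relative error) to a
set of target endpoints — by default the reference stabilized counts of
1282 VSMC and 1313 ECM agents. The winning set is what ships in the
default configuration.

VSMC and ECM count dynamics are mutually independent in this model
(events of one kind never change counts of the other), so candidate
grids for the two pairs of coefficients can be explored jointly in the
same runs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .biochem import ProbabilityParams
from .config import SimulationConfig
from .model import run_replicates

__all__ = [
    "DEFAULT_TARGETS",
    "CalibrationResult",
    "endpoint_objective",
    "simulated_endpoints",
    "calibrate_defaults",
]

#: reference stabilized endpoints used to freeze the shipped defaults
DEFAULT_TARGETS = {"n_vsmc": 1282.0, "n_ecm": 1313.0}


@dataclass
class CalibrationResult:
    best_params: dict
    best_objective: float
    best_endpoints: dict
    table: list  # one dict per evaluated candidate


def endpoint_objective(endpoints: dict, targets: dict) -> float:
    """Summed squared relative distance of endpoints to targets.

    Zero iff every targeted endpoint equals its target exactly.
    """
    if not targets:
        raise ValueError("targets must be non-empty")
    obj = 0.0
    for key, target in targets.items():
        if key not in endpoints:
            raise KeyError(f"endpoint {key!r} missing from candidate evaluation")
        obj += ((endpoints[key] - target) / target) ** 2
    return obj


def simulated_endpoints(
    config: SimulationConfig,
    n_seeds: int,
    base_seed: int,
    t0: int = 700,
    t1: int = 800,
) -> dict:
    """Replicate-mean stabilized endpoints of the configured model."""
    reps = run_replicates(config, n=n_seeds, base_seed=base_seed)
    return {
        "n_vsmc": reps.window_mean("n_vsmc", t0, t1),
        "n_ecm": reps.window_mean("n_ecm", t0, t1),
        "ratio": reps.window_mean("ratio", t0, t1),
        "plaque_burden": reps.window_mean("plaque_burden", t0, t1),
    }


def calibrate_defaults(
    targets: dict,
    search_space: list,
    n_seeds_per_point: int,
    base_config: SimulationConfig,
    base_seed: int = 1,
    endpoint_fn=None,
    progress=None,
) -> CalibrationResult:
    """Pick the candidate probability coefficients best matching the targets.

    Parameters
    ----------
    targets : dict
        Endpoint name -> target value (e.g. ``{"n_vsmc": 1282, "n_ecm": 1313}``).
    search_space : list of dict
        Explicit candidates; each dict holds ``ProbabilityParams`` field
        overrides (grids or Latin-hypercube designs are expressed by
        enumerating their points).
    n_seeds_per_point : int
        Replicates per candidate (seeds ``base_seed..``).
    base_config : SimulationConfig
        Configuration the candidates are grafted onto.
    endpoint_fn : callable, optional
        ``endpoint_fn(config, n_seeds, base_seed) -> dict``; defaults to
        :func:`simulated_endpoints`. Injectable for cheap surrogate tests.
    """
    if not search_space:
        raise ValueError("search_space must contain at least one candidate")
    if endpoint_fn is None:
        endpoint_fn = simulated_endpoints
    table = []
    best = None
    for cand in search_space:
        probs = replace(base_config.probabilities, **cand)
        config = replace(base_config, probabilities=probs)
        endpoints = endpoint_fn(config, n_seeds_per_point, base_seed)
        obj = endpoint_objective(endpoints, targets)
        row = {"params": dict(cand), "endpoints": dict(endpoints), "objective": obj}
        table.append(row)
        if progress is not None:
            progress(row)
        if best is None or obj < best["objective"]:
            best = row
    return CalibrationResult(
        best_params=best["params"],
        best_objective=best["objective"],
        best_endpoints=best["endpoints"],
        table=table,
    )
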