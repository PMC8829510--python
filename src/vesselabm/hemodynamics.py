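"""Angular wall-shear-stress (WSS) profiles on a vessel cross-section.

The agent-based wall model consumes a single hemodynamic input: the WSS
(in Pa) as a function of angular position around the lumen perimeter.
This module provides three ways to obtain such a profile:

* :func:`poiseuille_wss` — the analytic steady laminar WSS of a straight
  circular tube, ``tau = 4 mu Q / (pi R^3)``, useful as a uniform baseline;
* :func:`make_sector_profile` — a parametric profile that is constant at a
  base level except for a smooth (raised-cosine) low-WSS sector, emulating
  the focal low-shear region produced by disturbed flow;
* :func:`load_wss_profile` — CSV import (``angle_deg,wss_pa``) for profiles
  computed elsewhere, e.g. by a CFD solver.

Profiles are periodic; :func:`sample_wss` evaluates them at arbitrary
angles by periodic linear interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TubeSpec",
    "WSSProfile",
    "poiseuille_wss",
    "make_sector_profile",
    "load_wss_profile",
    "write_wss_profile",
    "sample_wss",
    "ML_PER_MIN",
]

#: volumetric flow conversion, 1 ml/min in m^3/s
ML_PER_MIN = 1e-6 / 60.0

WSS_CSV_COLUMNS = ("angle_deg", "wss_pa")


@dataclass(frozen=True)
class TubeSpec:
    """Geometry and fluid parameters of a straight circular tube.

    Parameters
    ----------
    radius : float
        Inner radius in m.
    length : float
        Tube length in m (not used by the wall-shear formula itself but part
        of the vessel description).
    viscosity : float
        Dynamic viscosity in Pa*s.
    density : float
        Fluid mass density in kg/m^3.
    flow_rate : float
        Volumetric flow rate in m^3/s.
    """

    radius: float = 1.535e-3
    length: float = 19.253e-3
    viscosity: float = 3.5e-3
    density: float = 1060.0
    flow_rate: float = 50.0 * ML_PER_MIN

    def __post_init__(self) -> None:
        for name in ("radius", "length", "viscosity", "density"):
            if not getattr(self, name) > 0:
                raise ValueError(f"TubeSpec.{name} must be strictly positive")
        if self.flow_rate < 0:
            raise ValueError("TubeSpec.flow_rate must be non-negative")


@dataclass(frozen=True)
class WSSProfile:
    """Periodic angular samples of wall shear stress on the perimeter.

    ``angles`` are degrees, strictly ascending within [0, 360); ``tau`` are
    the corresponding WSS values in Pa (non-negative). The profile is
    understood as periodic with period 360 degrees.
    """

    angles: np.ndarray
    tau: np.ndarray

    def __post_init__(self) -> None:
        angles = np.asarray(self.angles, dtype=float)
        tau = np.asarray(self.tau, dtype=float)
        object.__setattr__(self, "angles", angles)
        object.__setattr__(self, "tau", tau)
        if angles.ndim != 1 or tau.ndim != 1 or angles.size != tau.size:
            raise ValueError("angles and tau must be 1-d arrays of equal length")
        if angles.size < 4:
            raise ValueError("a WSS profile needs at least 4 angular samples")
        if np.any(angles < 0) or np.any(angles >= 360):
            raise ValueError("angles must lie in [0, 360)")
        if np.any(np.diff(angles) <= 0):
            raise ValueError("angles must be strictly ascending")
        if np.any(tau < 0):
            raise ValueError("WSS must be non-negative everywhere")

    def __len__(self) -> int:
        return int(self.angles.size)


def poiseuille_wss(tube: TubeSpec) -> float:
    """Steady laminar Newtonian wall shear stress of a straight tube, in Pa.

    ``tau = 4 mu Q / (pi R^3)``, equivalent to ``(R/2) * dP/L`` with the
    Hagen-Poiseuille pressure drop.
    """
    return 4.0 * tube.viscosity * tube.flow_rate / (np.pi * tube.radius**3)


def make_sector_profile(
    tau_base: float,
    tau_min: float,
    center: float,
    width: float,
    n_samples: int = 360,
) -> WSSProfile:
    """Uniform profile with a smooth low-WSS sector.

    The profile equals ``tau_base`` everywhere except within an angular
    sector of the given ``width`` (degrees) centred on ``center``, where it
    dips along a raised-cosine bump reaching ``tau_min`` exactly at the
    sector centre.

    Parameters
    ----------
    tau_base, tau_min : float
        WSS plateau and sector minimum, Pa, with ``0 <= tau_min <= tau_base``.
    center : float
        Angular position of the sector centre, degrees.
    width : float
        Full angular width of the sector, degrees, in [0, 360].
    n_samples : int
        Number of evenly spaced samples (>= 4).
    """
    if not 0 <= tau_min <= tau_base:
        raise ValueError("require 0 <= tau_min <= tau_base")
    if not 0 <= width <= 360:
        raise ValueError("width must lie in [0, 360] degrees")
    if n_samples < 4:
        raise ValueError("n_samples must be >= 4")
    angles = np.arange(n_samples) * (360.0 / n_samples)
    # circular distance to the sector centre, in [-180, 180)
    dist = np.abs((angles - center + 180.0) % 360.0 - 180.0)
    tau = np.full(n_samples, float(tau_base))
    if width > 0:
        inside = dist <= width / 2.0
        bump = 0.5 * (1.0 + np.cos(2.0 * np.pi * dist[inside] / width))
        tau[inside] = tau_base - (tau_base - tau_min) * bump
    return WSSProfile(angles=angles, tau=tau)


def write_wss_profile(profile: WSSProfile, path) -> None:
    """Write a profile as CSV with header ``angle_deg,wss_pa``."""
    pd.DataFrame(
        {"angle_deg": profile.angles, "wss_pa": profile.tau}
    ).to_csv(path, index=False)


def load_wss_profile(path) -> WSSProfile:
    """Load an angular WSS profile from CSV.

    The file must have header columns ``angle_deg`` and ``wss_pa``. Rows are
    sorted by angle, duplicate angles are collapsed by their mean, and
    angles outside [0, 360) are normalized modulo 360 (with a warning).
    """
    df = pd.read_csv(path)
    missing = [c for c in WSS_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"WSS profile CSV {path!s} is missing column(s) {missing}; "
            f"expected header {','.join(WSS_CSV_COLUMNS)}"
        )
    neg = df.index[df["wss_pa"] < 0]
    if len(neg):
        raise ValueError(
            f"negative WSS in {path!s} at data row {int(neg[0])} "
            f"(wss_pa={df.loc[neg[0], 'wss_pa']})"
        )
    if len(df) < 4:
        raise ValueError("a WSS profile needs at least 4 rows")
    angles = df["angle_deg"].to_numpy(dtype=float)
    if np.any((angles < 0) | (angles >= 360)):
        warnings.warn(
            f"angles outside [0, 360) in {path!s}; normalizing modulo 360",
            stacklevel=2,
        )
        angles = angles % 360.0
    tidy = (
        pd.DataFrame({"angle_deg": angles, "wss_pa": df["wss_pa"].to_numpy(float)})
        .groupby("angle_deg", sort=True)
        .mean()
        .reset_index()
    )
    if len(tidy) < 4:
        raise ValueError("fewer than 4 distinct angles after collapsing duplicates")
    return WSSProfile(
        angles=tidy["angle_deg"].to_numpy(), tau=tidy["wss_pa"].to_numpy()
    )


def sample_wss(profile: WSSProfile, theta) -> float | np.ndarray:
    """Evaluate a profile at angle(s) ``theta`` (degrees).

    Periodic linear interpolation between the bracketing samples; ``theta``
    is normalized modulo 360, and interpolation wraps across 360 -> 0.
    """
    theta = np.asarray(theta, dtype=float) % 360.0
    # extend by one period on each side so np.interp handles the wrap
    ang = np.concatenate(
        ([profile.angles[-1] - 360.0], profile.angles, [profile.angles[0] + 360.0])
    )
    tau = np.concatenate(([profile.tau[-1]], profile.tau, [profile.tau[0]]))
    out = np.interp(theta, ang, tau)
    return float(out) if out.ndim == 0 else out
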