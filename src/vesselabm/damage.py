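"""The WSS damage index: mapping, radial attenuation, temporal recovery.

The damage index ``D`` couples hemodynamics to cell kinetics. It is the
relative shortfall of wall shear stress below a low-WSS threshold
``wss0`` (1 Pa by convention):

    D = (wss0 - tau) / wss0   for tau < wss0,   else 0

so D = 1 at stagnant flow and D = 0 at or above physiological shear.
Innermost wall agents take D from the WSS at their angle; deeper layers
receive the innermost value attenuated geometrically per layer. Each
simulated hour every agent's stored D is multiplied by ``exp(-lambda)``,
mimicking the recovery of WSS as remodeling proceeds (the simulator does
not recompute WSS from the evolving geometry).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DamageParams", "damage_index", "attenuate_radial", "recover_damage"]


@dataclass(frozen=True)
class DamageParams:
    """Constants of the damage model.

    wss0 : damage threshold, Pa (> 0); shear below it is damaging.
    recovery_rate : per-hour decay exponent lambda (>= 0); damage is
        multiplied by ``exp(-lambda)`` once per one-hour tick.
    attenuation : per-layer coefficient kappa in (0, 1]; layer ``l`` of the
        wall carries ``kappa**l`` of the innermost damage at its angle.
    """

    wss0: float = 1.0
    recovery_rate: float = 0.0075
    attenuation: float = 0.9

    def __post_init__(self) -> None:
        if not self.wss0 > 0:
            raise ValueError("wss0 must be strictly positive")
        if self.recovery_rate < 0:
            raise ValueError("recovery_rate must be non-negative")
        if not 0 < self.attenuation <= 1:
            raise ValueError("attenuation must lie in (0, 1]")


def damage_index(tau, params: DamageParams = DamageParams()):
    """Damage index of a WSS value (Pa); scalar or array, result in [0, 1]."""
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("WSS must be non-negative")
    d = np.clip((params.wss0 - tau) / params.wss0, 0.0, 1.0)
    return float(d) if d.ndim == 0 else d


def attenuate_radial(d_inner, layer, params: DamageParams = DamageParams()):
    """Damage at wall layer ``layer`` given innermost damage ``d_inner``.

    Layer 0 is the innermost (lumen-facing) layer; attenuation is
    geometric, ``D = d_inner * kappa**layer``.
    """
    d_inner = np.asarray(d_inner, dtype=float)
    layer = np.asarray(layer)
    if np.any(layer < 0):
        raise ValueError("layer index must be >= 0")
    out = d_inner * params.attenuation ** np.asarray(layer, dtype=float)
    return float(out) if out.ndim == 0 else out


def recover_damage(d, n_steps, params: DamageParams = DamageParams()):
    """Damage after ``n_steps`` one-hour recovery steps: ``d*exp(-lambda*n)``."""
    d = np.asarray(d, dtype=float)
    n_steps = np.asarray(n_steps)
    if np.any(n_steps < 0):
        raise ValueError("n_steps must be >= 0")
    out = d * np.exp(-params.recovery_rate * np.asarray(n_steps, dtype=float))
    return float(out) if out.ndim == 0 else out
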