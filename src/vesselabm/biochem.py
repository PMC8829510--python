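"""Endothelium-derived biochemical factors and event probabilities.

Virtual endothelial cells lining the lumen synthesize three vasoactive
factors at WSS-dependent rates (pg per cell per hour):

* endothelin (ET), a VSMC proliferation promoter — saturating exponential
  rise with shear, ``C_ET = M (delta + alpha (1 - exp(-k tau^n)))``;
* nitric oxide (NO), a proliferation inhibitor — empirical quartic in
  shear, clamped below at zero;
* MMP-9, an ECM-degrading protease — affine in shear.

Per-tick factor content of an angular sector converts to a small
probability modifier through a saturating map ``p = s C / (C + K)``, and
the modifiers combine with the damage-driven probabilities:

    P_div  = clamp(alpha_div*D + p_ET - p_NO)
    P_apop = alpha_apop*D                      (not modified)
    P_gen  = alpha_gen*D                       (not modified)
    P_deg  = clamp(alpha_deg*D + p_MMP9)

Biochemical modifiers act only on damaged tissue (D > 0); the undamaged
wall stays in homeostasis regardless of baseline factor production.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ETParams",
    "NOParams",
    "MMP9Params",
    "ConversionParams",
    "ProbabilityParams",
    "EventProbabilities",
    "et_rate",
    "no_rate",
    "mmp9_rate",
    "sector_content",
    "factor_probability",
    "wss_event_probabilities",
    "combine_event_probabilities",
]


def _check_tau(tau):
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("WSS must be non-negative")
    return tau


def _ret(x):
    return float(x) if x.ndim == 0 else x


@dataclass(frozen=True)
class ETParams:
    """Endothelin synthesis-rate constants: ``M (delta + alpha(1-e^(-k tau^n)))``."""

    M: float = 8e-4  # pg/cell/h
    delta: float = 0.6
    alpha: float = 0.4
    k: float = 3.63  # Pa^-n
    n: float = 1.68

    def __post_init__(self) -> None:
        if not (self.M > 0 and self.k > 0 and self.n > 0):
            raise ValueError("M, k, n must be strictly positive")
        if self.delta < 0 or self.alpha < 0:
            raise ValueError("delta and alpha must be non-negative")


@dataclass(frozen=True)
class NOParams:
    """Nitric-oxide quartic coefficients, pg/cell/h per Pa^i."""

    a: float = 4.365e-7
    b: float = -9.399e-7
    c: float = 6.348e-7
    d: float = -9.939e-8
    e: float = 9.333e-9


@dataclass(frozen=True)
class MMP9Params:
    """MMP-9 synthesis-rate constants: ``beta*tau + gamma``."""

    beta: float = 4.939e-8  # pg/cell/h/Pa
    gamma: float = 2.218e-7  # pg/cell/h

    def __post_init__(self) -> None:
        if self.beta < 0 or self.gamma < 0:
            raise ValueError("beta and gamma must be non-negative")


@dataclass(frozen=True)
class ConversionParams:
    """Content-to-probability conversion ``p = scale * C / (C + half_content)``.

    ``scale`` caps the modifier per eligibility check; ``half_content`` (pg)
    is the content at which the modifier reaches half its cap.
    ``printed_constants`` records the literature constants verbatim for
    traceability; they are not used directly by the saturating map.
    """

    scale: float = 0.005
    half_content: float = 8e4  # pg
    printed_constants: tuple = (16.67, 1.45e-9, 8e4)

    def __post_init__(self) -> None:
        if not 0 <= self.scale <= 1:
            raise ValueError("scale must lie in [0, 1]")
        if not self.half_content > 0:
            raise ValueError("half_content must be strictly positive")


@dataclass(frozen=True)
class ProbabilityParams:
    """Per-check damage-to-probability coefficients for the four events."""

    alpha_div: float = 0.5
    alpha_apop: float = 0.125
    alpha_gen: float = 0.16
    alpha_deg: float = 0.04

    def __post_init__(self) -> None:
        for name in ("alpha_div", "alpha_apop", "alpha_gen", "alpha_deg"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class EventProbabilities:
    """Per-agent event probabilities after WSS and biochemical modification."""

    p_div: float
    p_apop: float
    p_gen: float
    p_deg: float

    def __post_init__(self) -> None:
        for name in ("p_div", "p_apop", "p_gen", "p_deg"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be a probability in [0, 1]")


def et_rate(tau, params: ETParams = ETParams()):
    """ET synthesized by one endothelial cell per hour (pg/cell/h)."""
    tau = _check_tau(tau)
    return _ret(params.M * (params.delta + params.alpha * (1.0 - np.exp(-params.k * tau**params.n))))


def no_rate(tau, params: NOParams = NOParams()):
    """NO synthesized by one endothelial cell per hour (pg/cell/h).

    Quartic polynomial in tau, clamped below at 0: negative synthesis is
    unphysical outside the fitted shear range.
    """
    tau = _check_tau(tau)
    p = params
    val = ((((p.a * tau + p.b) * tau + p.c) * tau + p.d) * tau) + p.e
    return _ret(np.maximum(val, 0.0))


def mmp9_rate(tau, params: MMP9Params = MMP9Params()):
    """MMP-9 synthesized by one endothelial cell per hour (pg/cell/h)."""
    tau = _check_tau(tau)
    return _ret(params.beta * tau + params.gamma)


def sector_content(rate, n_ec, dt: float = 1.0):
    """Instantaneous factor content (pg) of a sector over one tick.

    ``rate * n_ec * dt``: the hourly production of the sector's ``n_ec``
    virtual endothelial cells; content does not accumulate between ticks.
    """
    rate = np.asarray(rate, dtype=float)
    if np.any(rate < 0) or np.any(np.asarray(n_ec) < 0) or dt < 0:
        raise ValueError("rate, n_ec and dt must be non-negative")
    return _ret(rate * n_ec * dt)


def factor_probability(content, params: ConversionParams = ConversionParams()):
    """Probability modifier of a factor content (pg): ``s*C/(C+K)`` in [0, s)."""
    content = np.asarray(content, dtype=float)
    if np.any(content < 0):
        raise ValueError("content must be non-negative")
    return _ret(params.scale * content / (content + params.half_content))


def wss_event_probabilities(d, params: ProbabilityParams):
    """Damage-driven probabilities ``alpha_x * D`` for the four events."""
    d = np.asarray(d, dtype=float)
    if np.any((d < 0) | (d > 1)):
        raise ValueError("damage index must lie in [0, 1]")
    out = tuple(
        _ret(alpha * d)
        for alpha in (
            params.alpha_div,
            params.alpha_apop,
            params.alpha_gen,
            params.alpha_deg,
        )
    )
    return out


def combine_event_probabilities(
    wss_probs, p_et=0.0, p_no=0.0, p_mmp9=0.0
) -> EventProbabilities:
    """Combine damage-driven probabilities with biochemical modifiers.

    ET promotes and NO inhibits VSMC division; MMP-9 promotes ECM
    degradation; apoptosis and generation are unmodified. Results are
    clamped into [0, 1].
    """
    p_div_wss, p_apop_wss, p_gen_wss, p_deg_wss = wss_probs
    for name, p in (("p_et", p_et), ("p_no", p_no), ("p_mmp9", p_mmp9)):
        if not 0 <= p <= 1:
            raise ValueError(f"{name} must lie in [0, 1]")
    return EventProbabilities(
        p_div=float(np.clip(p_div_wss + p_et - p_no, 0.0, 1.0)),
        p_apop=float(p_apop_wss),
        p_gen=float(p_gen_wss),
        p_deg=float(np.clip(p_deg_wss + p_mmp9, 0.0, 1.0)),
    )
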