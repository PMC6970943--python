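"""Two-resistor lumped-parameter model of a stenosed coronary branch.

The coronary circulation is reduced to a serial circuit between the mean
aortic pressure ``P_A`` and the mean venous pressure ``P_V``: a stenotic
arterial resistance ``R_S`` followed by a capillary-venous resistance
``R_C``.  The stenosis is a uniform narrowing of the lumen from area ``A_0``
to ``A_S`` over the vessel length, so Poiseuille's law gives
``R_S(alpha) = R_0 / alpha**2`` with ``alpha = A_S/A_0`` the fractional
area narrowing (alpha = 1: healthy vessel, alpha = 0: total occlusion).

All closed-form relations between stenosis degree, resistances, pressures,
flow and the fractional flow reserve (FFR = P_D/P_A) live here, together
with the inverse maps (alpha from FFR, alpha from measured pressures).

Units: pressures in mmHg, flows in ml/s, resistances in mmHg·s/ml,
lengths in cm, areas in cm², viscosity in mmHg·s/cm².  No unit conversion
is performed; dimensional bookkeeping is the caller's concern.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "StenosisGeometry",
    "CircuitParameters",
    "HemodynamicState",
    "alpha_from_S",
    "S_from_alpha",
    "alpha_from_diameters",
    "stenotic_resistance",
    "solve_circuit",
    "ffr_of_alpha",
    "alpha_of_ffr",
    "alpha_from_pressures",
    "flow_definition_ffr",
    "baseline_vs_hyperemic_ffr",
]


def _as_float_or_array(x):
    """Return a python float for scalar input, ndarray otherwise."""
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 0:
        return float(arr)
    return arr


@dataclass(frozen=True)
class StenosisGeometry:
    """Geometry of a uniformly narrowed vessel segment.

    Parameters
    ----------
    A0 : float
        Healthy lumen cross-sectional area (cm²), > 0.
    AS : float
        Stenotic lumen area (cm²), 0 ≤ AS ≤ A0.
    L : float
        Vessel length (cm), > 0.
    eta : float
        Blood viscosity (mmHg·s/cm²), > 0.
    """

    A0: float
    AS: float
    L: float
    eta: float

    def __post_init__(self) -> None:
        if not self.A0 > 0:
            raise ValueError(f"A0 must be positive, got {self.A0}")
        if not 0 <= self.AS <= self.A0:
            raise ValueError(f"AS must lie in [0, A0={self.A0}], got {self.AS}")
        if not self.L > 0:
            raise ValueError(f"L must be positive, got {self.L}")
        if not self.eta > 0:
            raise ValueError(f"eta must be positive, got {self.eta}")

    @classmethod
    def from_diameters(cls, d0: float, dS: float, L: float, eta: float) -> "StenosisGeometry":
        if not 0 <= dS <= d0:
            raise ValueError(f"need 0 <= dS <= d0, got dS={dS}, d0={d0}")
        return cls(A0=math.pi * d0**2 / 4, AS=math.pi * dS**2 / 4, L=L, eta=eta)

    @property
    def d0(self) -> float:
        """Healthy lumen diameter (cm)."""
        return math.sqrt(4 * self.A0 / math.pi)

    @property
    def dS(self) -> float:
        """Stenotic lumen diameter (cm)."""
        return math.sqrt(4 * self.AS / math.pi)

    @property
    def alpha(self) -> float:
        """Fractional area narrowing AS/A0 = (dS/d0)² ∈ [0, 1]."""
        return self.AS / self.A0

    @property
    def S(self) -> float:
        """Fractional diameter stenosis 1 − dS/d0 ∈ [0, 1]."""
        return 1.0 - self.dS / self.d0

    @property
    def R0(self) -> float:
        """Poiseuille resistance of the healthy segment, 8πηL/A0² (mmHg·s/ml)."""
        return 8 * math.pi * self.eta * self.L / self.A0**2


@dataclass(frozen=True)
class CircuitParameters:
    """Pressure sources and resistances of the serial two-resistor circuit.

    ``RS`` is the stenotic arterial resistance, ``RC`` the capillary-venous
    resistance; hyperemia is represented by lowering ``RC`` to ``RCmin``.
    ``R0`` (optional) is the non-stenotic arterial resistance, needed only
    to form the dimensionless ratio ``r = R0/RC``.
    """

    PA: float
    PV: float
    RC: float
    RS: float = 0.0
    RCmin: float | None = None
    R0: float | None = None

    def __post_init__(self) -> None:
        if not self.PA > self.PV >= 0:
            raise ValueError(f"need PA > PV >= 0, got PA={self.PA}, PV={self.PV}")
        if not self.RC > 0:
            raise ValueError(f"RC must be positive, got {self.RC}")
        if self.RS < 0:
            raise ValueError(f"RS must be non-negative, got {self.RS}")
        if self.RCmin is not None and not 0 < self.RCmin <= self.RC:
            raise ValueError(f"need 0 < RCmin <= RC, got RCmin={self.RCmin}, RC={self.RC}")
        if self.R0 is not None and not self.R0 > 0:
            raise ValueError(f"R0 must be positive, got {self.R0}")

    @property
    def v(self) -> float:
        """Venous-to-aortic pressure ratio PV/PA ∈ [0, 1)."""
        return self.PV / self.PA

    @property
    def r(self) -> float:
        """Resistance ratio R0/RC (requires R0)."""
        if self.R0 is None:
            raise ValueError("R0 is not set; cannot form r = R0/RC")
        return self.R0 / self.RC


@dataclass(frozen=True)
class HemodynamicState:
    """Solved pressures and flow of the serial circuit."""

    PD: float
    F: float
    dPS: float
    dPC: float
    FSmax: float | None = field(default=None)
    FNmax: float | None = field(default=None)


def alpha_from_S(S):
    """Area narrowing from diameter stenosis: alpha = (1 − S)²."""
    S = _as_float_or_array(S)
    if np.any(np.asarray(S) < 0) or np.any(np.asarray(S) > 1):
        raise ValueError(f"S must lie in [0, 1], got {S}")
    return (1.0 - S) ** 2


def S_from_alpha(alpha):
    """Diameter stenosis from area narrowing: S = 1 − √alpha."""
    alpha = _as_float_or_array(alpha)
    if np.any(np.asarray(alpha) < 0) or np.any(np.asarray(alpha) > 1):
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    return 1.0 - np.sqrt(alpha)


def alpha_from_diameters(dS, d0):
    """alpha = (dS/d0)² for raw diameter measurements."""
    dS = _as_float_or_array(dS)
    d0 = _as_float_or_array(d0)
    if np.any(np.asarray(d0) <= 0):
        raise ValueError("d0 must be positive")
    if np.any(np.asarray(dS) < 0) or np.any(np.asarray(dS) > np.asarray(d0)):
        raise ValueError("need 0 <= dS <= d0")
    return (dS / d0) ** 2


def stenotic_resistance(alpha, R0):
    """Poiseuille resistance of the narrowed segment, R_S = R0/alpha².

    Monotonically decreasing in alpha; equals R0 at alpha = 1.  alpha = 0
    would be an infinite resistance and is rejected — the ratio-form
    :func:`ffr_of_alpha` handles total occlusion without it.
    """
    alpha = _as_float_or_array(alpha)
    if np.any(np.asarray(alpha) <= 0):
        raise ValueError(
            "alpha = 0 gives unbounded stenotic resistance; "
            "use ffr_of_alpha for the occlusion limit"
        )
    if np.any(np.asarray(alpha) > 1):
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    if np.any(np.asarray(R0) <= 0):
        raise ValueError(f"R0 must be positive, got {R0}")
    return R0 / alpha**2


def solve_circuit(params: CircuitParameters) -> HemodynamicState:
    """Solve the serial circuit for flow and distal pressure.

    F = (PA − PV)/(RC + RS); PD = PA − RS·F.  The pressure drops over the
    stenosis and the capillary bed sum to the total perfusion pressure
    exactly (series conservation).
    """
    total = params.RC + params.RS
    if total <= 0:
        raise ValueError("RC + RS must be positive (no load)")
    F = (params.PA - params.PV) / total
    dPS = params.RS * F
    dPC = params.RC * F
    PD = params.PA - dPS
    return HemodynamicState(PD=PD, F=F, dPS=dPS, dPC=dPC)


def ffr_of_alpha(alpha, r, v=0.0):
    """FFR as a function of the degree of narrowing alpha.

    Evaluates the rational form

        FFR = (alpha² + r·v) / (alpha² + r)

    which is algebraically identical to the 1/alpha² divider form
    FFR = 1/(1 + (r/alpha²)) + (r/alpha²)/(1 + r/alpha²)·v for alpha > 0
    (multiply numerator and denominator by alpha²), but stays finite at
    alpha = 0 where it correctly returns the occlusion limit v = PV/PA.

    Parameters
    ----------
    alpha : float or array
        Fractional area narrowing ∈ [0, 1].
    r : float
        Resistance ratio R0/RC > 0 (hyperemia raises r by lowering RC).
    v : float
        Venous-to-aortic pressure ratio PV/PA ∈ [0, 1).

    Returns
    -------
    float or ndarray — strictly increasing in alpha, range
    [v, (1 + r·v)/(1 + r)].
    """
    alpha = _as_float_or_array(alpha)
    if np.any(np.asarray(alpha) < 0) or np.any(np.asarray(alpha) > 1):
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    if not np.all(np.asarray(r) > 0):
        raise ValueError(f"r must be positive, got {r}")
    if np.any(np.asarray(v) < 0) or np.any(np.asarray(v) >= 1):
        raise ValueError(f"v must lie in [0, 1), got {v}")
    a2 = alpha**2
    return (a2 + r * v) / (a2 + r)


def alpha_of_ffr(ffr, r, v=0.0):
    """Invert the FFR(alpha) relation: alpha = √( r·(FFR − v)/(1 − FFR) ).

    Valid for v ≤ ffr < 1; raises if the requested FFR would need
    alpha > 1 (i.e. ffr above the no-stenosis ceiling (1 + r·v)/(1 + r)).
    """
    ffr = _as_float_or_array(ffr)
    if not np.all(np.asarray(r) > 0):
        raise ValueError(f"r must be positive, got {r}")
    if np.any(np.asarray(ffr) < v) or np.any(np.asarray(ffr) >= 1):
        raise ValueError(f"ffr must lie in [v={v}, 1), got {ffr}")
    a2 = r * (ffr - v) / (1.0 - ffr)
    if np.any(np.asarray(a2) > 1.0 + 1e-12):
        raise ValueError(
            f"FFR {ffr} not attainable at alpha <= 1 for r={r}, v={v} "
            f"(ceiling {(1 + r * v) / (1 + r):.6f})"
        )
    return np.sqrt(np.clip(a2, 0.0, 1.0)) if np.ndim(a2) else math.sqrt(min(a2, 1.0))


def alpha_from_pressures(PA, PD, PV, r):
    """Estimate the degree of narrowing from measured pressures.

    alpha = √( r·(PD − PV)/(PA − PD) ): the stenotic and capillary
    pressure drops share the same flow, so their ratio isolates
    R_S/R_C = r/alpha².  Recovers the generating alpha exactly on
    noiseless forward-model data; on noisy data the estimate may
    exceed 1 and is returned uncapped.
    """
    PA = _as_float_or_array(PA)
    PD = _as_float_or_array(PD)
    if not np.all(np.asarray(r) > 0):
        raise ValueError(f"r must be positive, got {r}")
    if np.any(np.asarray(PA) <= np.asarray(PD)):
        raise ValueError("PA must exceed PD: no measurable stenotic drop")
    if np.any(np.asarray(PD) < np.asarray(PV)):
        raise ValueError("PD must not fall below PV")
    return np.sqrt(r * (PD - PV) / (PA - PD))


class FlowDefinitionFFR(NamedTuple):
    FSmax: float
    FNmax: float
    ffr_exact: float
    ffr_approx: float


def flow_definition_ffr(PD_H, PA_H, PV, RCmin) -> FlowDefinitionFFR:
    """FFR from its flow definition: maximal stenotic over maximal normal flow.

    Both maximal flows are perfusion pressure over the hyperemic capillary
    resistance, so the ratio is (PD_H − PV)/(PA_H − PV) independently of
    RCmin; neglecting PV yields the clinical pressure-ratio approximation
    PD_H/PA_H, which overestimates whenever PV > 0.
    """
    if not RCmin > 0:
        raise ValueError(f"RCmin must be positive, got {RCmin}")
    if not PA_H > PD_H > PV >= 0:
        raise ValueError(
            f"need PA_H > PD_H > PV >= 0, got PA_H={PA_H}, PD_H={PD_H}, PV={PV}"
        )
    FSmax = (PD_H - PV) / RCmin
    FNmax = (PA_H - PV) / RCmin
    return FlowDefinitionFFR(
        FSmax=FSmax,
        FNmax=FNmax,
        ffr_exact=(PD_H - PV) / (PA_H - PV),
        ffr_approx=PD_H / PA_H,
    )


def baseline_vs_hyperemic_ffr(alpha, r_base, r_hyper, v=0.0):
    """FFR at baseline and during hyperemia for the same stenosis.

    Hyperemia lowers the capillary resistance, raising r = R0/RC, which
    lowers the FFR: the returned pair always satisfies FFR_H ≤ FFR_B.
    """
    if not 0 < r_base < r_hyper:
        raise ValueError(
            f"need 0 < r_base < r_hyper (hyperemia raises R0/RC), "
            f"got r_base={r_base}, r_hyper={r_hyper}"
        )
    return ffr_of_alpha(alpha, r_base, v), ffr_of_alpha(alpha, r_hyper, v)
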