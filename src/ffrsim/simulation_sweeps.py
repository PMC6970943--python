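"""In-silico parameter sweeps of the stenosis model.

FFR, FFR_C and P_D as functions of the degree of narrowing alpha for the
four standard settings
r = R0/RC ∈ {0.04, 0.1} × v = PV/PA ∈ {0, 0.1} at P_A = 100 mmHg; the
equal-FFR-step construction that exposes the ordinal-scale behaviour of
the FFR; and the P_D-vs-P_A dot clouds with iso-FFR reference lines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .companion_metrics import companion_exact
from .stenosis_model import S_from_alpha, alpha_of_ffr, ffr_of_alpha

__all__ = [
    "SweepSetting",
    "SweepCurve",
    "DotCloud",
    "DEFAULT_SETTINGS",
    "DEFAULT_ALPHA_GRID_SIZE",
    "default_settings",
    "run_sweep",
    "run_default_sweeps",
    "equal_ffr_steps",
    "build_dot_cloud",
    "ffr_alpha_derivative",
]

#: grid density giving smooth curves at negligible cost, endpoints included
DEFAULT_ALPHA_GRID_SIZE = 201

#: iso-FFR reference lines drawn in the dot-cloud figure
ISO_FFR_LEVELS = (1.0, 0.75, 0.5, 0.25)


def _default_grid() -> np.ndarray:
    return np.linspace(0.0, 1.0, DEFAULT_ALPHA_GRID_SIZE)


@dataclass(frozen=True)
class SweepSetting:
    """One parameter setting of the sweep: resistance ratio r = R0/RC,
    pressure ratio v = PV/PA, aortic pressure (mmHg) and the alpha grid."""

    r: float
    v: float = 0.0
    PA: float = 100.0
    alpha_grid: np.ndarray = field(default_factory=_default_grid)

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValueError(f"r must be positive, got {self.r}")
        if not 0 <= self.v < 1:
            raise ValueError(f"v must lie in [0, 1), got {self.v}")
        if not self.PA > 0:
            raise ValueError(f"PA must be positive, got {self.PA}")
        grid = np.asarray(self.alpha_grid, dtype=float)
        if grid.ndim != 1 or len(grid) < 2 or np.any(np.diff(grid) <= 0):
            raise ValueError("alpha_grid must be a strictly increasing 1-D array")
        if grid[0] < 0 or grid[-1] > 1:
            raise ValueError("alpha_grid must lie within [0, 1]")
        object.__setattr__(self, "alpha_grid", grid)

    @property
    def label(self) -> str:
        return f"r={self.r:g}_v={self.v:g}"


@dataclass(frozen=True)
class SweepCurve:
    """One sweep: per-alpha rows of (alpha, S, FFR, FFR_C, PD)."""

    setting: SweepSetting
    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass(frozen=True)
class DotCloud:
    """P_D vs P_A points for a grid of stenosis degrees, plus the slopes of
    the iso-FFR reference lines PD = FFR·PA."""

    points: pd.DataFrame
    iso_ffr_lines: tuple[float, ...]
    r: float
    v: float


def default_settings(PA: float = 100.0) -> list[SweepSetting]:
    """The four printed sweep settings: r ∈ {0.04, 0.1} × v ∈ {0, 0.1}."""
    return [SweepSetting(r=r, v=v, PA=PA) for r in (0.04, 0.1) for v in (0.0, 0.1)]


DEFAULT_SETTINGS = default_settings()


def run_sweep(setting: SweepSetting) -> SweepCurve:
    """Evaluate FFR, FFR_C and P_D over the alpha grid of one setting.

    Endpoints obey the closed-form limits FFR(0) = v and
    FFR(1) = (1 + r·v)/(1 + r).
    """
    alpha = setting.alpha_grid
    ffr = ffr_of_alpha(alpha, setting.r, setting.v)
    table = pd.DataFrame(
        {
            "alpha": alpha,
            "S": S_from_alpha(alpha),
            "FFR": ffr,
            "FFR_C": companion_exact(setting.PA, ffr),
            "PD": setting.PA * ffr,
        }
    )
    return SweepCurve(setting=setting, table=table)


def run_default_sweeps(PA: float = 100.0) -> list[SweepCurve]:
    return [run_sweep(s) for s in default_settings(PA)]


def equal_ffr_steps(setting: SweepSetting, n_steps: int) -> pd.DataFrame:
    """Equally spaced FFR values and the alpha each one requires.

    The FFR axis is divided into equal steps between the occlusion value
    FFR(0) and the no-stenosis ceiling FFR(1); inverting the model gives
    the corresponding alpha values, whose spacing is *unequal* — equal
    changes in FFR do not represent equal changes in stenosis degree,
    which is what makes the FFR an ordinal-scale metric.
    """
    if n_steps < 2:
        raise ValueError(f"n_steps must be >= 2, got {n_steps}")
    lo = ffr_of_alpha(0.0, setting.r, setting.v)
    hi = ffr_of_alpha(1.0, setting.r, setting.v)
    ffr_grid = np.linspace(lo, hi, n_steps)
    alpha = np.empty_like(ffr_grid)
    alpha[:-1] = [alpha_of_ffr(f, setting.r, setting.v) for f in ffr_grid[:-1]]
    alpha[-1] = 1.0  # ceiling value maps to alpha=1 exactly
    return pd.DataFrame({"FFR": ffr_grid, "alpha": alpha})


def build_dot_cloud(
    r: float,
    v: float,
    alpha_values=None,
    PA_samples=None,
) -> DotCloud:
    """P_D as a function of P_A for a family of stenosis degrees.

    Each (PA, alpha) pair yields one point PD = PA·FFR(alpha); points of a
    common alpha fall on a line through the origin.  The vertical spacing
    between consecutive alpha lines shrinks as alpha decreases (dFFR/dalpha
    → 0 at the occlusion end), so the cloud thins out for severe stenoses.
    """
    if alpha_values is None:
        alpha_values = np.r_[np.arange(1.0, 0.05, -0.1), 0.05]
    if PA_samples is None:
        PA_samples = np.linspace(55.0, 115.0, 13)
    alpha_values = np.asarray(alpha_values, dtype=float)
    PA_samples = np.asarray(PA_samples, dtype=float)
    if np.any(alpha_values < 0) or np.any(alpha_values > 1):
        raise ValueError("alpha_values must lie in [0, 1]")
    if np.any(PA_samples <= 0):
        raise ValueError("PA_samples must be positive")

    rows = []
    for a in alpha_values:
        ffr = ffr_of_alpha(float(a), r, v)
        for PA in PA_samples:
            rows.append((PA, PA * ffr, a, ffr))
    points = pd.DataFrame(rows, columns=["PA", "PD", "alpha", "FFR"])
    return DotCloud(points=points, iso_ffr_lines=ISO_FFR_LEVELS, r=r, v=v)


def ffr_alpha_derivative(alpha, r, v=0.0, h: float = 1e-5):
    """Central-difference dFFR/dalpha, clipped to the domain at the ends.

    The closed form is 2·alpha·r·(1 − v)/(alpha² + r)²; the numerical route
    is kept so sweep diagnostics stay independent of the algebra they probe.
    """
    alpha = np.asarray(alpha, dtype=float)
    lo = np.clip(alpha - h, 0.0, 1.0)
    hi = np.clip(alpha + h, 0.0, 1.0)
    out = (ffr_of_alpha(hi, r, v) - ffr_of_alpha(lo, r, v)) / (hi - lo)
    return float(out) if out.ndim == 0 else out
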