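"""The FFR ratio and its Pythagorean companion metric.

A pressure pair (P_A, P_D) is a point in the plane; its polar coordinates
are the slope P_D/P_A — the FFR — and the radius √(P_A² + P_D²), here
called FFR_C.  The FFR alone identifies only the ray through the origin
the point lies on; FFR_C is the discarded second coordinate.  Together
they determine the pressures uniquely, which is why a proportional change
of both pressures leaves the FFR unchanged while scaling FFR_C.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "PressurePair",
    "MetricPair",
    "AmbiguityCase",
    "Verdict",
    "NonPhysiologicalPressureWarning",
    "to_polar",
    "from_polar",
    "companion_exact",
    "companion_approx",
    "classify_ambiguity",
]


class NonPhysiologicalPressureWarning(UserWarning):
    """P_D exceeds P_A (FFR > 1): impossible for a passive stenosis, but
    tolerated arithmetically so noisy measured data does not crash the
    pipeline."""


@dataclass(frozen=True)
class PressurePair:
    """Mean aortic and distal pressures (mmHg), the Cartesian view."""

    PA: float
    PD: float

    def __post_init__(self) -> None:
        if not self.PA > 0:
            raise ValueError(f"PA must be positive, got {self.PA}")
        if self.PD < 0:
            raise ValueError(f"PD must be non-negative, got {self.PD}")


@dataclass(frozen=True)
class MetricPair:
    """FFR (dimensionless slope) and FFR_C (mmHg radius), the polar view."""

    ffr: float
    ffr_c: float

    def __post_init__(self) -> None:
        if self.ffr < 0:
            raise ValueError(f"ffr must be non-negative, got {self.ffr}")
        if not self.ffr_c > 0:
            raise ValueError(f"ffr_c must be positive, got {self.ffr_c}")


class Verdict(str, Enum):
    DECREASE = "decrease"
    UNCHANGED = "unchanged"
    INCREASE = "increase"


@dataclass(frozen=True)
class AmbiguityCase:
    """Outcome of multiplying PD by gamma and PA by beta: FFR scales by
    gamma/beta, so the same stenosis event can move the FFR either way."""

    gamma: float
    beta: float
    verdict: Verdict
    multiplier: float


def to_polar(p: PressurePair) -> MetricPair:
    """Map (PA, PD) to (FFR, FFR_C) = (PD/PA, √(PA² + PD²))."""
    if p.PD > p.PA:
        warnings.warn(
            f"PD={p.PD} > PA={p.PA} gives FFR > 1 (non-physiological)",
            NonPhysiologicalPressureWarning,
            stacklevel=2,
        )
    return MetricPair(ffr=p.PD / p.PA, ffr_c=math.hypot(p.PA, p.PD))


def from_polar(m: MetricPair) -> PressurePair:
    """Recover the pressures: PA = FFR_C/√(1 + FFR²), PD = PA·FFR."""
    PA = m.ffr_c / math.sqrt(1.0 + m.ffr**2)
    return PressurePair(PA=PA, PD=PA * m.ffr)


def companion_exact(PA, ffr):
    """FFR_C expressed through FFR: PA·√(1 + FFR²)."""
    PA = np.asarray(PA, dtype=float)
    if np.any(PA <= 0):
        raise ValueError("PA must be positive")
    out = PA * np.sqrt(1.0 + np.asarray(ffr, dtype=float) ** 2)
    return float(out) if out.ndim == 0 else out


def companion_approx(PA, ffr):
    """Binomial (first-order) approximation of the companion metric.

    √(1 + x) ≈ 1 + x/2 at x = FFR² gives FFR_C ≈ PA·(1 + FFR²/2); the
    truncation error is bounded by the next series term, PA·FFR⁴/8, and
    shrinks as the FFR decreases.
    """
    PA = np.asarray(PA, dtype=float)
    ffr = np.asarray(ffr, dtype=float)
    if np.any(PA <= 0):
        raise ValueError("PA must be positive")
    if np.any(ffr < 0) or np.any(ffr > 1):
        raise ValueError("ffr must lie in [0, 1]")
    out = PA * (1.0 + 0.5 * ffr**2)
    return float(out) if out.ndim == 0 else out


def classify_ambiguity(gamma: float, beta: float) -> AmbiguityCase:
    """Classify the FFR response to PD → gamma·PD, PA → beta·PA.

    The FFR is multiplied by gamma/beta: it decreases iff gamma < beta,
    is unchanged iff gamma = beta, increases iff gamma > beta — even
    though each case may describe a worsening stenosis.
    """
    if not (gamma > 0 and beta > 0):
        raise ValueError(f"gamma and beta must be positive, got {gamma}, {beta}")
    if gamma < beta:
        verdict = Verdict.DECREASE
    elif gamma == beta:
        verdict = Verdict.UNCHANGED
    else:
        verdict = Verdict.INCREASE
    return AmbiguityCase(gamma=gamma, beta=beta, verdict=verdict, multiplier=gamma / beta)
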