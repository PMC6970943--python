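"""Statistical analysis of (synthetic or measured) pressure cohorts.

Four fits and two classification utilities:

* ordinary least squares of hyperemic P_D on P_A (the cohort scatter line);
* the constrained rational fit FFR = P_D/(c1 + c2·P_D), which vanishes at
  P_D = 0 and saturates at 1/c2 for large P_D;
* the Pearson correlation of the companion metric FFR_C with P_D;
* the logarithmic decomposition ln(FFR) = A·ln(P_D) − B·ln(P_A) + C, whose
  coefficients weigh the relative contribution of each pressure to the FFR;
* dual-criterion classification (FFR cut-off plus a distal-pressure or
  companion cut-off) with gray-zone accounting.

Boundary conventions: "clinically significant" means FFR < 0.80 strictly
(an FFR of exactly 0.80 is not abnormal), and the gray zone is the
half-open interval [0.75, 0.80).  No p-values are computed by default —
the FFR is an ordinal-scale metric, so parametric tests on it are suspect;
permutation p-values are available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .synthetic_cohort import cohort_to_frame

__all__ = [
    "FitResult",
    "ClassificationResult",
    "RankDeficientDesignWarning",
    "fit_linear_pd_pa",
    "fit_rational_ffr_pd",
    "correlate_ffrc_pd",
    "fit_log_decomposition",
    "classify_dual_criterion",
    "gray_zone_fraction",
    "GrayZoneReport",
    "permutation_pvalue",
]


class RankDeficientDesignWarning(UserWarning):
    """The regression design matrix is rank deficient; a pseudo-inverse
    solution is reported and some coefficients are not identifiable."""


@dataclass(frozen=True)
class FitResult:
    """Common container for regression output."""

    model_name: str
    coefficients: dict
    correlation: float
    r_squared: float
    n: int
    residual_sd: float
    stderr: dict | None = None

    def to_row(self) -> dict:
        row = {"model_name": self.model_name, "n": self.n,
               "R": self.correlation, "R2": self.r_squared,
               "residual_sd": self.residual_sd}
        row.update(self.coefficients)
        return row


@dataclass(frozen=True)
class ClassificationResult:
    """Per-record flags and cohort counts of the dual-criterion rule."""

    flags: pd.DataFrame
    counts: dict
    ffr_cut: float
    pd_cut: float
    ffrc_cut: float | None = None


def _pearson(x, y) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(stats.pearsonr(x, y)[0])


def fit_linear_pd_pa(cohort) -> FitResult:
    """OLS of hyperemic distal pressure on aortic pressure."""
    frame = cohort_to_frame(cohort)
    if len(frame) < 3:
        raise ValueError(f"need at least 3 records, got {len(frame)}")
    PA = frame["PA"].to_numpy(dtype=float)
    PD = frame["PD_hyper"].to_numpy(dtype=float)
    if np.ptp(PA) == 0:
        raise ValueError("constant PA: slope not identifiable")
    model = sm.OLS(PD, sm.add_constant(PA)).fit()
    intercept, slope = model.params
    resid = PD - model.fittedvalues
    return FitResult(
        model_name="linear_pd_pa",
        coefficients={"slope": float(slope), "intercept": float(intercept)},
        correlation=_pearson(PA, PD),
        r_squared=float(model.rsquared),
        n=len(frame),
        residual_sd=float(np.sqrt(np.mean(resid**2))),
        stderr={"slope": float(model.bse[1]), "intercept": float(model.bse[0])},
    )


def _rational(pd_, c1, c2):
    return pd_ / (c1 + c2 * pd_)


def fit_rational_ffr_pd(cohort) -> FitResult:
    """Constrained rational fit FFR = P_D/(c1 + c2·P_D).

    The curve passes through the origin by construction and approaches
    1/c2 as P_D grows.  Initial values come from the linearisation
    1/FFR = c2 + c1/P_D; the final coefficients minimise squared error on
    the FFR scale (where the quality of fit is reported).
    """
    frame = cohort_to_frame(cohort)
    usable = frame[(frame["FFR"] > 0) & (frame["PD_hyper"] > 0)]
    n_excluded = len(frame) - len(usable)
    if n_excluded:
        warnings.warn(f"excluded {n_excluded} records with non-positive FFR or PD")
    if len(usable) < 3:
        raise ValueError(f"need at least 3 usable records, got {len(usable)}")
    PD = usable["PD_hyper"].to_numpy(dtype=float)
    FFR = usable["FFR"].to_numpy(dtype=float)

    # linearised initialisation: 1/FFR = c2 + c1 * (1/PD)
    X = sm.add_constant(1.0 / PD)
    c2_0, c1_0 = sm.OLS(1.0 / FFR, X).fit().params
    try:
        popt, _ = optimize.curve_fit(_rational, PD, FFR, p0=[max(c1_0, 1e-6), c2_0], maxfev=10000)
    except RuntimeError:
        popt = np.array([c1_0, c2_0])
    c1, c2 = (float(popt[0]), float(popt[1]))
    pred = _rational(PD, c1, c2)
    resid = FFR - pred
    ss_tot = float(np.sum((FFR - FFR.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    corr = _pearson(pred, FFR) if np.std(pred) > 0 and np.std(FFR) > 0 else 1.0
    return FitResult(
        model_name="rational_ffr_pd",
        coefficients={"c1": c1, "c2": c2},
        correlation=corr,
        r_squared=r2,
        n=len(usable),
        residual_sd=float(np.sqrt(np.mean(resid**2))),
    )


def correlate_ffrc_pd(cohort) -> FitResult:
    """Pearson correlation of the companion metric FFR_C with hyperemic P_D."""
    frame = cohort_to_frame(cohort)
    if len(frame) < 3:
        raise ValueError(f"need at least 3 records, got {len(frame)}")
    PD = frame["PD_hyper"].to_numpy(dtype=float)
    FC = frame["FFR_C"].to_numpy(dtype=float)
    R = _pearson(PD, FC)
    slope, intercept = np.polyfit(PD, FC, 1)
    resid = FC - (slope * PD + intercept)
    return FitResult(
        model_name="ffrc_pd_correlation",
        coefficients={"slope": float(slope), "intercept": float(intercept)},
        correlation=R,
        r_squared=R**2,
        n=len(frame),
        residual_sd=float(np.sqrt(np.mean(resid**2))),
    )


def fit_log_decomposition(cohort) -> FitResult:
    """Multiple regression ln(FFR) = A·ln(P_D) − B·ln(P_A) + C.

    For exact ratio data (FFR = P_D/P_A with independently varying
    pressures) the identity forces A = 1, B = 1, C = 0; departures measure
    the relative weight each pressure carries in the observed FFR.  The
    sign convention stores B as the coefficient multiplying −ln(P_A).
    """
    frame = cohort_to_frame(cohort)
    usable = frame[(frame["FFR"] > 0) & (frame["PD_hyper"] > 0) & (frame["PA"] > 0)]
    n_excluded = len(frame) - len(usable)
    if n_excluded:
        warnings.warn(f"excluded {n_excluded} records with non-positive values")
    if len(usable) < 4:
        raise ValueError(f"need at least 4 usable records, got {len(usable)}")
    lpd = np.log(usable["PD_hyper"].to_numpy(dtype=float))
    lpa = np.log(usable["PA"].to_numpy(dtype=float))
    lffr = np.log(usable["FFR"].to_numpy(dtype=float))
    X = sm.add_constant(np.column_stack([lpd, lpa]), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn(
            "ln(PD) and ln(PA) are collinear with the intercept; "
            "reporting the minimum-norm pseudo-inverse solution",
            RankDeficientDesignWarning,
        )
    model = sm.OLS(lffr, X).fit()
    C, A, negB = model.params
    pred = model.fittedvalues
    resid = lffr - pred
    corr = _pearson(pred, lffr) if np.std(pred) > 0 and np.std(lffr) > 0 else 1.0
    return FitResult(
        model_name="log_decomposition",
        coefficients={"A": float(A), "B": float(-negB), "C": float(C)},
        correlation=corr,
        r_squared=float(model.rsquared) if np.std(lffr) > 0 else 1.0,
        n=len(usable),
        residual_sd=float(np.sqrt(np.mean(resid**2))),
        stderr={"A": float(model.bse[1]), "B": float(model.bse[2]), "C": float(model.bse[0])},
    )


def classify_dual_criterion(
    cohort,
    ffr_cut: float = 0.80,
    pd_cut: float = 50.0,
    ffrc_cut: float | None = None,
) -> ClassificationResult:
    """Flag each record against the FFR cut-off and a complementary one.

    ``below_ffr_cut`` uses the strict inequality FFR < ffr_cut (an FFR of
    exactly 0.80 is not abnormal).  ``jeopardy`` marks records that pass
    the FFR criterion yet have an inadequate driving pressure — distal
    pressure below ``pd_cut`` or, when given, companion metric below
    ``ffrc_cut`` — the cases an FFR-only reading would miss.
    """
    frame = cohort_to_frame(cohort)
    ffr = frame["FFR"].to_numpy(dtype=float)
    pd_h = frame["PD_hyper"].to_numpy(dtype=float)
    below_ffr = ffr < ffr_cut
    below_pd = pd_h < pd_cut
    flags = pd.DataFrame(
        {
            "id": frame["id"] if "id" in frame else np.arange(len(frame)),
            "below_ffr_cut": below_ffr,
            "below_pd_cut": below_pd,
            "in_gray_zone": (ffr >= 0.75) & (ffr < 0.80),
        }
    )
    fails_companion = below_pd
    if ffrc_cut is not None:
        below_ffrc = frame["FFR_C"].to_numpy(dtype=float) < ffrc_cut
        flags["below_ffrc_cut"] = below_ffrc
        fails_companion = fails_companion | below_ffrc
    flags["jeopardy"] = ~below_ffr & fails_companion
    counts = {c: int(flags[c].sum()) for c in flags.columns if c != "id"}
    return ClassificationResult(
        flags=flags, counts=counts, ffr_cut=ffr_cut, pd_cut=pd_cut, ffrc_cut=ffrc_cut
    )


@dataclass(frozen=True)
class GrayZoneReport:
    fraction: float
    zone_width: float
    n_in_zone: int
    n: int


def gray_zone_fraction(cohort, lo: float = 0.75, hi: float = 0.80) -> GrayZoneReport:
    """Fraction of records with lo ≤ FFR < hi, plus the zone's width as a
    fraction of the theoretical FFR range [0, 1] (default zone: 5%)."""
    if not 0 <= lo < hi <= 1:
        raise ValueError(f"need 0 <= lo < hi <= 1, got lo={lo}, hi={hi}")
    frame = cohort_to_frame(cohort)
    if len(frame) == 0:
        raise ValueError("empty cohort")
    ffr = frame["FFR"].to_numpy(dtype=float)
    in_zone = (ffr >= lo) & (ffr < hi)
    return GrayZoneReport(
        fraction=float(in_zone.mean()),
        zone_width=float(hi - lo),
        n_in_zone=int(in_zone.sum()),
        n=len(frame),
    )


def permutation_pvalue(x, y, n_perm: int = 9999, seed: int = 0) -> float:
    """Two-sided permutation p-value for a Pearson correlation.

    Offered instead of the parametric test because ordinal-scale metrics
    violate the assumptions behind t-based inference.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    obs = abs(_pearson(x, y))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if abs(_pearson(x, rng.permutation(y))) >= obs:
            hits += 1
    return (hits + 1) / (n_perm + 1)
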