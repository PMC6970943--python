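"""Synthetic patient cohorts with the structure of the RCA pressure study.

The clinical records behind the 22-patient right-coronary-artery analysis
are not published; this module generates cohorts whose distributional
structure matches what is printed about them: aortic pressures spanning
roughly 55–115 mmHg, stenosis locations proximal/medial/distal in 8:12:4
proportion, a near-linear hyperemic P_D–P_A relation (slope ≈ 0.87,
R ≈ 0.73), and FFR values mostly above 0.6 with a few below the 0.80
cut-off.

Each patient is drawn independently: aortic pressure from a truncated
normal, stenosis degree alpha from a Beta law weighted toward mild and
moderate narrowings, location labels from a categorical with the study's
8/12/4 proportions.  Distal pressures come from the forward two-resistor
model at the hyperemic (and baseline) resistance ratio, then receive
additive Gaussian measurement noise and are clipped to the physiological
band [P_V, P_A].
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .companion_metrics import companion_exact
from .stenosis_model import S_from_alpha, ffr_of_alpha

__all__ = [
    "CohortConfig",
    "CohortRecord",
    "LOCATIONS",
    "generate_cohort",
    "cohort_to_frame",
    "frame_to_records",
    "cohort_summary",
]

LOCATIONS = ("p", "m", "d")


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; the defaults are the emulated study conditions.

    Attributes
    ----------
    n : int
        Number of patients (study: 22).
    seed : int
        Seed of the generator; same config + seed reproduces the cohort
        bit for bit.
    PA_mean, PA_sd : float
        Mean and sd (mmHg) of the truncated-normal aortic pressure.
    PA_bounds : tuple
        Truncation interval (mmHg); default the printed 55–115 range.
    PV : float
        Venous pressure (mmHg), common to all patients.
    r_hyper, r_base : float
        Hyperemic and baseline resistance ratios R0/RC; hyperemia lowers
        the capillary resistance, so r_hyper > r_base.
    alpha_beta_a, alpha_beta_b : float
        Beta-law shape for the stenosis degree; (5, 2) puts most mass
        above alpha = 0.3 (mild/moderate stenoses dominate the cohort).
    noise_sd : float
        Additive Gaussian measurement noise on distal pressures (mmHg).
    location_probs : tuple
        Probabilities of proximal/medial/distal labels, default the
        study's 8:12:4 proportions (normalised).
    """

    n: int = 22
    seed: int = 0
    PA_mean: float = 90.0
    PA_sd: float = 12.0
    PA_bounds: tuple[float, float] = (55.0, 115.0)
    PV: float = 5.0
    r_hyper: float = 0.1
    r_base: float = 0.04
    alpha_beta_a: float = 5.0
    alpha_beta_b: float = 2.0
    noise_sd: float = 3.0
    location_probs: tuple[float, float, float] = (8 / 24, 12 / 24, 4 / 24)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        lo, hi = self.PA_bounds
        if not self.PV < lo < hi:
            raise ValueError(f"PA_bounds must satisfy PV < lo < hi, got {self.PA_bounds}")
        if not 0 < self.r_base < self.r_hyper:
            raise ValueError("need 0 < r_base < r_hyper")
        if self.PA_sd <= 0 or self.noise_sd < 0:
            raise ValueError("PA_sd must be positive and noise_sd non-negative")
        if self.alpha_beta_a <= 0 or self.alpha_beta_b <= 0:
            raise ValueError("Beta shape parameters must be positive")
        p = np.asarray(self.location_probs, dtype=float)
        if p.shape != (3,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("location_probs must be 3 non-negative values summing to 1")
        if self.PV < 0:
            raise ValueError("PV must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["PA_bounds"] = list(self.PA_bounds)
        d["location_probs"] = list(self.location_probs)
        return d


@dataclass(frozen=True)
class CohortRecord:
    """One synthetic patient row."""

    id: str
    location: str
    alpha_true: float
    S_pct: float
    PA: float
    PD_base: float
    PD_hyper: float
    FFR: float
    FFR_C: float
    clipped: bool = False


def generate_cohort(config: CohortConfig) -> list[CohortRecord]:
    """Draw a cohort; deterministic for a given config.

    With ``noise_sd = 0`` the records are exact forward-model solutions:
    the stenosis degree is recoverable from the pressures to machine
    precision and the baseline FFR strictly exceeds the hyperemic FFR for
    every incomplete stenosis.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.PA_bounds
    a = (lo - config.PA_mean) / config.PA_sd
    b = (hi - config.PA_mean) / config.PA_sd
    PA = stats.truncnorm.rvs(
        a, b, loc=config.PA_mean, scale=config.PA_sd, size=config.n, random_state=rng
    )
    alpha = rng.beta(config.alpha_beta_a, config.alpha_beta_b, size=config.n)
    location = rng.choice(LOCATIONS, size=config.n, p=config.location_probs)
    noise_h = rng.normal(0.0, config.noise_sd, size=config.n) if config.noise_sd > 0 else np.zeros(config.n)
    noise_b = rng.normal(0.0, config.noise_sd, size=config.n) if config.noise_sd > 0 else np.zeros(config.n)

    v = config.PV / PA
    PD_hyper_clean = PA * ffr_of_alpha(alpha, config.r_hyper, v)
    PD_base_clean = PA * ffr_of_alpha(alpha, config.r_base, v)
    PD_hyper = PD_hyper_clean + noise_h
    PD_base = PD_base_clean + noise_b
    clipped = (PD_hyper < config.PV) | (PD_hyper > PA) | (PD_base < config.PV) | (PD_base > PA)
    PD_hyper = np.clip(PD_hyper, config.PV, PA)
    PD_base = np.clip(PD_base, config.PV, PA)

    records = []
    for i in range(config.n):
        records.append(
            CohortRecord(
                id=f"pt{i + 1:03d}",
                location=str(location[i]),
                alpha_true=float(alpha[i]),
                S_pct=float(100.0 * S_from_alpha(alpha[i])),
                PA=float(PA[i]),
                PD_base=float(PD_base[i]),
                PD_hyper=float(PD_hyper[i]),
                FFR=float(PD_hyper[i] / PA[i]),
                FFR_C=float(companion_exact(PA[i], PD_hyper[i] / PA[i])),
                clipped=bool(clipped[i]),
            )
        )
    return records


def cohort_to_frame(records) -> pd.DataFrame:
    """Cohort as a DataFrame (accepts a record list or passes one through)."""
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame([asdict(r) for r in records])


def frame_to_records(frame: pd.DataFrame) -> list[CohortRecord]:
    return [CohortRecord(**row) for row in frame.to_dict(orient="records")]


def cohort_summary(records) -> dict:
    """Counts, ranges and cut-off fractions of a cohort.

    Reports location counts, min/max of PA, PD_hyper and FFR, the fraction
    of patients below the clinical FFR cut-off 0.80 (strict) and the
    fraction inside the diagnostic gray zone [0.75, 0.80).
    """
    frame = cohort_to_frame(records)
    if len(frame) == 0:
        raise ValueError("empty cohort")
    ffr = frame["FFR"].to_numpy()
    return {
        "n": int(len(frame)),
        "location_counts": {
            loc: int((frame["location"] == loc).sum()) for loc in LOCATIONS
        },
        "PA_range": (float(frame["PA"].min()), float(frame["PA"].max())),
        "PD_hyper_range": (float(frame["PD_hyper"].min()), float(frame["PD_hyper"].max())),
        "FFR_range": (float(ffr.min()), float(ffr.max())),
        "frac_below_cutoff": float(np.mean(ffr < 0.80)),
        "frac_gray_zone": float(np.mean((ffr >= 0.75) & (ffr < 0.80))),
        "n_clipped": int(frame["clipped"].sum()),
    }
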