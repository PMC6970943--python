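# Methods

## Model

The coronary branch is a serial two-resistor circuit between a constant
mean aortic pressure `P_A` and a constant mean venous pressure `P_V`.
The arterial segment, uniformly narrowed from lumen area `A_0` to
`A_S = α·A_0` over its full length `L`, has the Poiseuille resistance

```
R_S(α) = 8πηL / A_S² = R_0 / α²,     R_0 = 8πηL / A_0²
```

and feeds a capillary-venous bed of resistance `R_C`.  Hyperemia is
modelled purely as a drop of `R_C` to `R_Cmin`, i.e. an increase of the
dimensionless ratio `r = R_0/R_C`; there are no flow-dependent,
time-dependent or autoregulatory effects, no compliance or inertance, and
no Bernoulli entrance losses (the narrowing is treated as uniform, not
local).  Solving the divider:

```
F    = (P_A − P_V) / (R_C + R_S(α))
P_D  = P_A − R_S(α)·F
FFR  = P_D/P_A = (α² + r·v) / (α² + r),     v = P_V/P_A
```

The rational form of the FFR is used everywhere instead of the
literal `1/α²` divider expression.  The two are algebraically identical
for `α > 0` (multiply through by `α²`), but the rational form is finite
at `α = 0`, where it returns the correct occlusion limit `v` without a
special case.  `stenotic_resistance` by contrast refuses `α = 0`, which
would be an infinite resistance: resistances stay finite-valued, and
callers who need the occlusion limit use the ratio form.

Two inverse maps close the loop: `alpha_of_ffr` inverts FFR(α)
analytically (`α = √(r(FFR−v)/(1−FFR))`), and `alpha_from_pressures`
estimates the stenosis degree from a measured triple
(`α = √(r(P_D−P_V)/(P_A−P_D))`) — exact on noiseless forward-model data,
uncapped (and possibly > 1) on noisy data.

Units follow the circuit convention: mmHg, ml/s, mmHg·s/ml, cm, cm², and
viscosity in mmHg·s/cm².  The viscosity unit is dimensionally unusual but
is carried as-is; no unit validation or conversion is attempted.

## Companion metric

A pressure pair `(P_A, P_D)` in Cartesian coordinates has polar
coordinates `(FFR, FFR_C)` with `FFR_C = √(P_A² + P_D²) =
P_A·√(1+FFR²)`.  For `P_D ∈ [0, P_A]` the radius ranges between `P_A`
and `P_A·√2`.  The binomial (first-order) approximation
`FFR_C ≈ P_A(1 + FFR²/2)` has truncation error at most `P_A·FFR⁴/8`
(the next series term) and improves as the FFR decreases.  `P_D > P_A`
(FFR > 1) is non-physiological for a passive stenosis but occurs in noisy
measurements; it is accepted arithmetically with a
`NonPhysiologicalPressureWarning` rather than an exception, so cohort
pipelines do not crash on noise.  FFR values are carried unrounded; any
two-decimal rounding happens only in report formatting.

## Sweeps

Default sweep conditions are the four standard settings r ∈ {0.04, 0.1}
× v ∈ {0, 0.1} at `P_A = 100` mmHg on 201 equally spaced α values in
[0, 1] — dense enough for smooth curves at negligible cost, endpoints
included.  The exact grids behind the original simulation figures are not
published; these are declared defaults, overridable per setting.  The
dot-cloud sampling uses 13 equally spaced `P_A` values on [55, 115] mmHg
and α ∈ {1.0, 0.9, …, 0.1, 0.05} for the same reason.

Curve-shape diagnostics (the interior maximum of dFFR/dα that makes the
curve S-shaped, at `α* = √(r/3)`; the thinning of the dot cloud toward
occlusion) use central differences with step `h = 1e−5`, accurate to
~1e−10 for this smooth rational function, so the diagnostics stay
numerically independent of the algebra they probe.  Of the four standard
curves, exactly one pair crosses on (0, 1): the start values are set by
`v` and the ceilings by `r`, so the (r=0.04, v=0) curve (low start, high
ceiling) crosses the (r=0.1, v=0.1) curve (high start, low ceiling) once.

## Synthetic cohorts

The generator stands in for an unpublished 22-patient right-coronary
cohort of which only summary statistics are printed (N, location counts,
the P_D–P_A regression line `P_D = 0.873·P_A − 6.836` with R = 0.728,
FFR values mostly above 0.6).  Per patient it draws independently:

* `P_A` ~ truncated normal, mean 90, sd 12 mmHg, bounds [55, 115] mmHg —
  the bounds are the printed pressure range; mean and sd are chosen as
  typical resting aortic pressures since no cohort distribution is
  printed;
* stenosis degree `α` ~ Beta(5, 2) — mass concentrated above 0.3,
  matching a cohort dominated by mild/moderate stenoses with a few below
  the cut-off;
* location label p/m/d with probabilities 1/3, 1/2, 1/6 — the printed
  8:12:4 proportions normalised (as printed they sum to 24, not 22);
* distal pressures from the forward model at `r_hyper = 0.1` (and
  `r_base = 0.04` for the baseline column) with `P_V = 5` mmHg, plus
  additive Gaussian measurement noise (default sd 3 mmHg) on `P_D` only;
  `P_A` is treated as the noise-free reference.  Noisy `P_D` is clipped
  to `[P_V, P_A]` (keeping FFR ≤ 1) and clipped rows carry a flag.

`r_hyper`/`r_base` reuse the two sweep resistance ratios, read as the
hyperemic/baseline pair.  Locations are labels only — the model assigns
them no hemodynamic effect.  The generator is deterministic given
(config, seed).

What passing tests show — and do not show.  The calibration tests check
that across 100 seeds the mean fitted slope lies in [0.70, 1.00] and the
mean correlation in [0.55, 0.90], brackets around the printed 0.873 and
0.728; single 22-patient draws scatter well outside these brackets, as
22-patient samples do.  Because the per-patient records are unpublished,
exact reproduction of the clinical scatter plots is impossible by design;
the synthetic cohort demonstrates that the pipeline behaves correctly on
data *with the printed structure*, not that the generator matches the
real patients' joint distribution (it ignores age, sex, adenosine route
and any PA–α dependence).

## Cohort analysis

* `fit_linear_pd_pa` — OLS of hyperemic `P_D` on `P_A` (statsmodels),
  reporting slope, intercept, Pearson R and standard errors.
* `fit_rational_ffr_pd` — `FFR = P_D/(c₁ + c₂·P_D)`, which vanishes at
  `P_D = 0` and saturates at `1/c₂`.  Initialised from the linearisation
  `1/FFR = c₂ + c₁/P_D`, refined by nonlinear least squares *on the FFR
  scale*, where goodness of fit is reported; the linearised fit is only a
  starting point.  Records with non-positive FFR or P_D are excluded with
  a logged warning.
* `correlate_ffrc_pd` — Pearson correlation of `FFR_C` with hyperemic
  `P_D` (hyperemic is assumed since the measurement state of the printed
  correlation is not stated).
* `fit_log_decomposition` — OLS of `ln FFR` on `ln P_D` and `ln P_A`;
  `B` is stored as the coefficient of `−ln P_A`, so exact ratio data
  gives A = B = 1, C = 0.  A rank-deficient design (e.g. constant `P_A`)
  raises `RankDeficientDesignWarning` and returns the minimum-norm
  pseudo-inverse solution.
* Classification: "clinically significant" is FFR < 0.80 *strictly* — an
  FFR of exactly 0.80 is not abnormal — and the gray zone is the
  half-open [0.75, 0.80), 5% of the theoretical range.  `jeopardy` marks
  records that pass the FFR criterion yet fail the distal-pressure
  criterion (`P_D` < 50 mmHg by default) or, when supplied, an `FFR_C`
  cut-off.  No validated `FFR_C` cut-off exists, so that parameter has no
  default.  Both R and R² are always reported.
* No p-values by default: the FFR is an ordinal-scale metric, so
  parametric tests on it are inappropriate; a permutation p-value
  (`permutation_pvalue`) is available explicitly.

## Numerical policy

Closed-form round trips (α↔S, polar↔Cartesian, FFR↔α) and
circuit-oracle comparisons are asserted at 1e−10 relative tolerance.
The two-node circuit oracle in the tests solves the linear system
`[[1, R_S], [1, −R_C]]·(P_D, F) = (P_A, P_V)` numerically, independent of
the closed forms.  Noiseless regression fixtures are asserted at 1e−8 or
tighter; stochastic properties (α-recovery error monotone in noise sd
over {0, 1, 3, 5} mmHg, cohort calibration bands) average 50–100 seeds of
22-patient cohorts, sizes chosen to make the suite fast while keeping
Monte-Carlo error far below the tested margins.

## Known limitations

Steady Poiseuille flow only — no pulsatility, compliance, inertance,
entrance/exit losses, autoregulation, or neural/hormonal control; the
venous pressure is a fixed sink; hyperemia is a pure resistance drop.
The inverse estimator `alpha_from_pressures` requires the resistance
ratio `r`, which varies between patients and is not measurable from
pressures alone — a limitation of any pressure-only stenosis metric.
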