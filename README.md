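# ffrsim

Lumped-parameter modelling of coronary stenosis hemodynamics: the
fractional flow reserve (FFR), its Pythagorean companion metric, and the
statistical pipeline for pressure-wire cohorts.

## The problem

The fractional flow reserve is the standard invasive index of coronary
stenosis severity: the ratio of mean pressure distal to the stenosis to
mean aortic pressure during drug-induced hyperemia,

```
FFR = P_D / P_A        (0 = occlusion, 1 = no stenosis; cut-off 0.80)
```

`ffrsim` models the stenosed coronary branch as a serial two-resistor
circuit between the aortic and venous pressures: a Poiseuille stenosis
resistance `R_S(α) = R_0/α²` (where `α = A_S/A_0` is the fractional
cross-sectional area of the narrowed lumen) feeding a capillary-venous
bed `R_C`.  Solving the divider gives the closed form

```
FFR(α) = (α² + r·v) / (α² + r),      r = R_0/R_C,   v = P_V/P_A
```

an S-shaped curve in `α` running from `v` at occlusion to `(1+r·v)/(1+r)`
at no stenosis.  The package uses this model to study three properties of
the FFR that matter for its clinical interpretation:

* **Ordinality** — equal steps in FFR correspond to unequal steps in
  stenosis degree, so the FFR is an ordinal-scale metric and means/t-tests
  on it are suspect.
* **Bias** — venous pressure and capillary resistance shift the curve, so
  baseline and hyperemic FFR differ and inter-patient variation partly
  reflects the metric, not the stenosis.
* **The neglected companion** — the pressure pair `(P_A, P_D)` has polar
  coordinates `(FFR, FFR_C)` with `FFR_C = √(P_A² + P_D²)`; the FFR alone
  identifies only a ray through the origin, and the discarded radius
  `FFR_C` carries clinically relevant information (a patient with
  `P_D = 40`, `P_A = 50` mmHg has a reassuring FFR of 0.80 but an
  alarming perfusion pressure).

The package provides the forward/inverse maps between stenosis degree,
pressures and FFR; the in-silico parameter sweeps; a synthetic generator
for 22-patient right-coronary-artery cohorts matching the published
summary statistics of a real cohort (whose per-patient records are not
public); and the cohort analysis suite (P_D–P_A regression, the
constrained rational fit `FFR = P_D/(c₁ + c₂·P_D)`, FFR_C–P_D
correlation, the log decomposition `ln FFR = A·ln P_D − B·ln P_A + C`,
and dual-criterion classification with gray-zone accounting).

## Worked example

```python
>>> from ffrsim import ffr_of_alpha, alpha_of_ffr, to_polar, PressurePair
>>> ffr_of_alpha(0.5, r=0.1)          # 50% residual lumen area, hyperemic r
0.7142857142857143
>>> alpha_of_ffr(0.80, r=0.1)         # lumen fraction at the clinical cut-off
0.632455532033676
>>> m = to_polar(PressurePair(PA=50, PD=40))
>>> m.ffr, m.ffr_c                    # unremarkable ratio, alarming radius
(0.8, 64.03124237432849)
```

A stenosis leaving half the lumen area gives FFR ≈ 0.71 under hyperemia
(r = 0.1): already below the 0.80 cut-off.  Inverting the model shows the
cut-off itself corresponds to α ≈ 0.63, i.e. a 21% diameter reduction —
the steep mid-part of the S-curve.  The polar view of the hypotensive
worked case shows FFR_C = 64 mmHg, far below a healthy radius of
~130 mmHg, which the FFR alone cannot reveal.

The same pipeline from the shell:

```sh
$ ffrsim cohort --n 22 --seed 7 --out run
wrote 22 patients to run/cohort.csv
$ ffrsim analyze run/cohort.csv --out run_analysis
linear_pd_pa: slope=0.9522, intercept=-11.0068 (R=0.866, R2=0.751, n=22)
rational_ffr_pd: c1=31.5669, c2=0.7816 (R=0.742, R2=0.550, n=22)
ffrc_pd_correlation: slope=1.2411, intercept=24.6254 (R=0.963, R2=0.926, n=22)
log_decomposition: A=1.0000, B=1.0000, C=-0.0000 (R=1.000, R2=1.000, n=22)
gray zone: 4/22 records; jeopardy: 0
```

One synthetic 22-patient cohort (seed 7) reproduces the qualitative
structure of the real study: a P_D–P_A regression slope just below 1 with
moderate scatter, a strong FFR_C–P_D correlation, and a handful of
patients inside the 0.75–0.80 gray zone.  The log decomposition recovers
the exact identity A = B = 1, C = 0 because the stored FFR is derived
from the stored pressures.  `ffrsim sweep` writes the four standard
FFR/FFR_C/P_D-versus-α curves (r ∈ {0.04, 0.1} × v ∈ {0, 0.1},
P_A = 100 mmHg) as CSV, and `ffrsim figures RUNDIR` renders the standard
plots from any run directory.

## Layout

| Module | Contents |
| --- | --- |
| `ffrsim.stenosis_model` | circuit solver, FFR(α) and all inverse maps |
| `ffrsim.companion_metrics` | polar/Cartesian maps, binomial approximation, γ/β ambiguity |
| `ffrsim.simulation_sweeps` | sweep curves, equal-FFR-step construction, dot clouds |
| `ffrsim.synthetic_cohort` | cohort generator and summaries |
| `ffrsim.cohort_analysis` | regressions, classification, gray zone |
| `ffrsim.io` / `ffrsim.cli` / `ffrsim.figures` | CSV I/O, command line, plots |

See `docs/methods.md` for the model assumptions, parameter defaults and
numerical choices.
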