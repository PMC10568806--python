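# Methods

This note documents the model, its assumptions, the numerical choices
made where the design was genuinely open, and what the synthetic data
generator does and does not emulate. Units: internal time is **days**
(months convert at 30.4375 d, years at 365.25 d); money is 2022 USD;
utilities are on the 0–1 EQ-5D scale.

## Decision problem and model structure

Two strategies are compared for previously untreated dMMR/MSI-H
metastatic colorectal cancer: pembrolizumab 200 mg IV every 3 weeks
(arm `P`, up to 35 doses ≈ 2 years) and investigator-choice
chemotherapy (arm `C`): mFOLFOX or FOLFIRI ± bevacizumab or cetuximab,
in the observed mix (7.69 / 44.76 / 3.50 / 11.19 / 25.17 / 7.69 %).

The cohort model is a three-state **partitioned survival model**:
state occupancy at cycle boundary t is read directly off the two
survival functions rather than from transition probabilities —
progression-free `min(S_PFS, S_OS)` (the clamp handles crossing
extrapolations; progressed occupancy is then zero at the crossing),
progressed `S_OS − S_PFS`, dead `1 − S_OS`. The cycle is 42 days (the
least common multiple of the two arms' 2- and 3-week schedules). The
horizon is "lifetime": the trace stops at the first cycle with fewer
than 1% of the cohort surviving (threshold 0.01, configurable; a
40-year hard cap guards improper extrapolations). Switching the
threshold to 0.001 moves total QALYs by < 1% on the default fixture,
which is the lifetime-horizon adequacy check in the test suite.

Costs and QALYs are discounted at 5%/year (range 0–8%) with
`(1+r)^(−t/365.25)`. Within a cycle, occupancy × discount factor is
aggregated by the **trapezoid rule** (average of the two boundary
values) by default, configurable to end-of-cycle; the trapezoid choice
minimizes discretization error against the closed-form exponential
oracle (< 0.5% at 42-day cycles) and plays the role of a half-cycle
correction.

### Accrual rules

- **Acquisition** accrues on progression-free occupancy only
  (treat-to-progression), with per-drug caps on total administrations
  enforced by cycle index: 35 q3w doses = 2/cycle exhaust mid-cycle 18
  (cycles 1–17 full, cycle 18 half). Cetuximab's loading dose (400
  then 250 mg/m² weekly) is an extra 150 mg/m² in cycle 1 only.
- **Administration**: attendances/cycle × $310.16; q3w schedules count
  2 attendances per 42-day cycle, q2w 3, weekly cetuximab adds 6.
- **Follow-up**: $31.33/cycle on alive occupancy.
- **Adverse events** (grade ≥ 3 diarrhoea, anaemia, hypokalaemia,
  neutropenia): a one-off burden in cycle 1, undiscounted —
  cost = Σ incidence×cost, QALY loss = Σ incidence×|disutility|.
  Discounting a cycle-1 lump would change nothing material.
- **Subsequent therapy**: a per-cycle cost on progressed occupancy,
  weighted by the per-arm treatment-class mix (pembrolizumab, other
  PD-1/PD-L1 inhibitor, chemotherapy, VEGF inhibitor, EGFR inhibitor).
  Class unit costs come from representative regimens: the chemotherapy
  class is the simple average of CAPIRI / CAPOX / FOLFOX / FOLFIRI
  per-cycle drug costs (CAPIRI/CAPOX doses are the standard ones —
  capecitabine 1000 mg/m² b.i.d. days 1–14 q3w, oxaliplatin 130 mg/m²,
  irinotecan 200 mg/m² — config-overridable); the ICI classes are
  pembrolizumab 200 mg q3w and nivolumab 240 mg q2w. Because a cohort
  PSM cannot track time-in-state per patient, ICI duration limits are
  approximated by a configurable cap of ≈17.4 model cycles (2 years)
  after which the ICI share costs zero — the standard memoryless
  approximation. Best supportive care is costed at 0.
- Doses scale with BSA 1.80 m² or weight 65 kg; no vial rounding.

`ICER = ΔCost/ΔQALY` with dominance classification (dominant /
dominated / interior); a zero QALY difference is flagged undefined and
never divided.

### Patient assistance program (PAP)

The PAP scenario replaces first-line pembrolizumab acquisition with an
annual fee of $11,200 prorated per cycle and capped at $22,400 total
(the monetary cap binds just before the 35-dose cap). It applies to
first-line treatment only; whether crossover pembrolizumab would also
qualify is ambiguous, so post-progression ICI costs keep the ordinary
price under the same duration cap.

## Pseudo-IPD reconstruction

Inputs are digitized (time, survival) coordinates and the printed
number-at-risk table. Coordinates are first normalized (clamped to
[0,1], made non-increasing by pool-adjacent-violators, deduplicated
keeping the lower value at equal times, anchored at (0,1)).

Reconstruction proceeds interval by interval between risk-table
landmarks. Two allocation modes:

1. **Exact drop-ratio inversion** (tried first): with noise-free,
   step-resolution coordinates every KM drop satisfies
   `S_k/S_{k−1} = 1 − d/n` for small integers (d, n), so the at-risk
   set at each step can be recovered exactly (smallest consistent d is
   taken; when multiples are also consistent the event count is not
   identifiable, but the reconstructed KM curve is identical either
   way). Censorings are placed between the steps they separate, and
   the interval must reconcile exactly with both landmark counts —
   otherwise the mode abstains.
2. **Iterative uniform-censoring estimate** (fallback, the published
   algorithm): the number censored per interval is estimated
   iteratively, censor times are spread uniformly within the interval,
   and integer event counts at each step are chosen so the running KM
   product tracks the input, self-correcting via the
   last-event-anchored ratio.

Residual subjects after the last coordinate are censored at last
follow-up. If a risk table implies negative censorings the offending
interval is reported; with no risk table at all the weakest defined
assumption is used (no censoring before last follow-up, cohort size
supplied by the caller, warning logged). An optional total-event count
rescales events in the final interval. Reconstruction is fully
deterministic.

Measured fidelity (test suite): noise-free round trips on 20 seeded
synthetic arms (n=200, ~25–30% censoring, 6-month risk tables) are
exact; with 0.003–0.005 jitter the max |ΔS| is of the order of the
jitter itself.

## Parametric survival families

Right-censored log-likelihood `Σ_events log f + Σ_censored log S`,
maximized by L-BFGS-B from a fixed set of data-driven starts (≥3 per
family; best optimum kept — fits are deterministic). Positive
parameters are optimized on the log scale. Invalid parameter regions
return a large negative sentinel rather than raising.

- **Generalized gamma** uses the Prentice (μ, σ, q) parameterization,
  which nests Weibull (q=1), gamma and log-normal (q→0); the q→0 limit
  is taken analytically for |q| < 1e-5 (the general incomplete-gamma
  path is continuous across the switch to ~1e-3 in log-likelihood on
  50-observation datasets).
- **Gompertz** is S(t) = exp(−(b/a)(e^{at}−1)) with unconstrained
  shape a and the a→0 exponential limit; a < 0 yields an improper
  survival function plateauing at exp(b/a) — legitimate for
  extrapolation, surfaced as a logged warning.
- Model selection ranks converged fits by AIC ascending, ties
  (|ΔAIC| < 0.01) broken by BIC, non-converged fits last. BIC uses
  n = all records (events + censored), the dominant convention. The
  base-case family binding used when curves are taken as given —
  generalized gamma for OS in both arms and pembrolizumab PFS,
  log-normal for chemotherapy PFS — ships as a constant.
- Fit uncertainty is **not** propagated into the PSA; only the
  tabulated parameters are sampled.

## Sensitivity analyses

**DSA**: every registry parameter is swept one-way to its low/high
bound (tabulated range, else ±20%); bars are |ICER_high − ICER_low|,
sorted descending. **PSA**: 500 Monte-Carlo iterations sampling betas
for probabilities/utilities and gammas for costs (method of moments:
beta ν = m(1−m)/se² − 1; gamma shape (m/se)², scale se²/m). Disutility
magnitudes are sampled then negated; mixture weights are renormalized
to sum to one after independent sampling; prices tabulated as fixed
(pembrolizumab, cetuximab, nivolumab) are never sampled. The CEAC is
the fraction of draws with positive net monetary benefit λΔQALY−ΔCost
over a $0–60,000 grid in $500 steps.

Where the shipped table prints both explicit distribution parameters
and (mean, SE), the explicit parameters win and the moment mismatch is
logged (e.g. the PFS-utility row's beta(245.0, 63.2) implies mean
0.795, not the 0.7825 baseline; the bevacizumab gamma implies mean
13.44, not 15). Baselines drive the base case; distributions drive the
PSA, so sampled means are checked against the distribution-implied
means.

## Synthetic trial generator

The generator emulates the statistical structure the analysis assumes,
not any particular dataset: per-subject PFS from a parametric family
per arm, OS = PFS + exponential post-progression survival (so OS ≥ PFS
by construction), uniform accrual, administrative censoring at a fixed
trial end, exponential dropout. Defaults (chosen once as a realistic
emulation of the trial conditions the analysis targets): 300 subjects
per arm; arm-P PFS log-logistic (shape 1.3, median 16.5 months); arm-C
PFS log-normal (median 8.2 months, σ 1.1); post-progression hazard
0.0243/month (median ≈ 28.5 months, putting arm-C median OS near 36.7
months); 18 months accrual + 32 months minimum follow-up; dropout
hazard 0.004/month. Ties at identical times follow the standard KM
convention (events before censorings). Digitization is mimicked by
sampling the step function on a regular grid plus all step locations,
adding truncated-Gaussian reading error, and isotonic cleanup so the
output is a valid survival curve.

What it does **not** emulate: subject covariates (age, BRAF,
sidedness), non-proportional crossover dynamics, informative
censoring, within-figure digitization biases (axis skew, pixel
quantization). Passing tests therefore demonstrate correctness of the
pipeline's algorithms under the stated generative assumptions, not
agreement with any published base case. In particular, the synthetic
base-case ICER is driven by the tabulated pembrolizumab list price of
$179.18/mg (≈ $35.8k per dose, used exactly as printed and flagged in
logs) and therefore sits far above the WTP threshold; the qualitative
conclusions probed by the tests — discounting harder raises the ICER,
the PAP scenario collapses it, tornado leaders are PAP/discount/
subsequent-treatment shares/baseline utility — are price-robust.

## Known input inconsistencies (handled, not imitated)

- The WTP constant $38,142.56 is stored as printed although
  ¥262,500/6.9 = $38,043.48.
- The published base-case "incremental cost per LY gained $8,284.72"
  is inconsistent with the printed ΔCost/ΔLY (≈ $26,095); the ratio
  here is always reported as computed.
- Printed per-arm totals subtract to $78,286.05 vs the printed
  incremental $78,286.04 (cent-level rounding).
- Whether continued post-progression pembrolizumab in arm P is already
  inside its 10% subsequent-treatment share is unstated; assumed yes.

## Problem sizes

Test-suite and acceptance-script sizes were chosen as the smallest
that make the statistical checks sharp: 20 × n=200 arms for
reconstruction fidelity, 2,000 draws per family for parameter
recovery (all six families within 10%), 500 PSA iterations (matching
the tabulated analysis), 1,500 draws for the CEAC median property.
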