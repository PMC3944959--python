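# Methods

## Decision problem and model structure

The package evaluates two eye-care interventions in Zambia against "no
intervention", from a societal perspective, in 2010 US$ per QALY gained.
Each is a cohort state-transition model with three states: treated (T),
deteriorated/untreated (D), and dead (M, absorbing). Cycle length is one
year. The intervention cohort enters T and pays the treatment cost once
at entry (cycle 0, undiscounted); the comparator cohort enters D at zero
cost and keeps baseline utility until death.

Per cycle t = 1, 2, … the engine applies, in order:

1. **Mortality** — each occupant of T or D dies with the life-table
   probability q(a) for the age a held at the cycle start; death applies
   equally from both alive states (no state-specific mortality is
   reported for this population).
2. **Utility accrual** — survivors of the cycle accrue the utility of the
   state they held *during* the cycle, discounted by (1+r)^(−t) with
   r = 3 %/year. Decedents accrue nothing that cycle (a cycle-end
   convention; see "Numerical conventions").
3. **T→D transition** — applied at the end of the cycle: a constant
   4 %/year for cataract (surgery effect lost, utility reverts to
   baseline), and a time-varying spectacle-loss probability for
   refraction.

Cataract runs for the cohort's remaining lifetime from age 63; refraction
runs for five cycles from age 39.

### Spectacle-loss schedule

The loss probability rises from 5 % at the end of cycle 1 to 90 % at the
end of cycle 5. The source description ("increasing exponentially") is
ambiguous between two readings; the default is geometric interpolation of
the *per-cycle* probability through both endpoints,

    p(t) = p1 · (pH/p1)^((t−1)/(H−1)),   p(1) = 0.05, p(5) = 0.90,

because it pins both printed values as per-cycle probabilities. The
alternative — the curve read as a *cumulative* loss fraction, converted
to conditional per-cycle probabilities — is available via
`RefractionParams(cumulative_schedule=True)`. Neither reading reproduces
the original refraction QALY increments (see "Known limitations").

## Life tables and calibration

A life table is a vector of single-year annual death probabilities qx,
padded to a terminal age of 100 where qx = 1 (cohort closure). Abridged
(5-year band) tables are expanded under a constant annual hazard within
each band, annual qx = 1 − (1 − nqx)^(1/n), which preserves each band's
n-year survival exactly. Survival treats death as occurring by cycle end:
S(t) = Π(1 − qx).

The Zambian national life table used originally is not published. Two
stand-ins are provided:

* **Flat calibration (default).** The published no-surgery cataract arm
  implies a discounted survival annuity from age 63 of
  7.519 / 0.782 = 9.615 years. `calibrate_flat_mortality` finds, by
  bisection (tolerance 1e−6; the annuity is strictly decreasing in q, so
  the root is unique), the constant annual death probability reproducing
  it — q ≈ 0.0645. This matches the *total* annuity, not the age
  profile.
* **Gompertz synthetic tables** (`synthetic_life_table`):
  qx = 1 − exp(−level · e^(shape·age)), a standard adult-mortality shape,
  for experiments needing an age gradient.

## Parameters

| Parameter | Default | Units | Source of default |
|---|---|---|---|
| Cataract surgery cost | 92 (SE 3.4) | 2010 US$ | pooled facility micro-costing |
| Spectacles cost | 72 (SE 7.8) | 2010 US$ | pooled facility micro-costing |
| Cataract utility, baseline / post | 0.782 (0.017) / 0.832 (0.015) | utility | cohort EQ-5D |
| Refraction utility, baseline / post | 0.850 (0.022) / 0.925 (0.018) | utility | cohort EQ-5D |
| Deterioration after surgery | 0.04 (0.01) | /year | literature-based |
| Spectacle loss, cycle 1 / cycle 5 | 0.05 (0.01) / 0.90 | /cycle | assumed schedule |
| Discount rate (effects and capital) | 0.03 | /year | standard |
| Cohort entry age, cataract / refraction | 63 / 39 | years | cohort means |
| WTP benchmark | 1,160 | US$/QALY | 2011 GNI per capita |
| Exchange rate | 4,729 | Kwacha/US$ | 2010 |

Costing: capital items are annualised as PV·r/(1 − (1+r)^(−L)) (straight
line at r = 0); overheads are allocated by annual patient volume;
facility totals pool by recruitment weights. Recruitment weights were not
published, so the published pooled means/SEs (92/3.4, 72/7.8) ship as the
canonical model inputs and always take precedence; when an SE must be
estimated from facility totals the default heuristic is range/4, behind
an explicit `se_override`. Tables render to the nearest dollar
(`pandas.DataFrame.round`, banker's rounding — a displayed 20.5 shows as
20 where the original table shows 21); arithmetic is unrounded
throughout.

EQ-5D-3L scoring uses the additive tariff form (constant for any
problem, per-dimension level-2/3 decrements, constant for any level-3).
The Zimbabwean tariff applied originally is not printed anywhere in the
source material, so value-set coefficients are a configuration input; a
clearly-labelled toy tariff backs the tests. Utilities below 0 are
allowed by the scoring contract. The paired baseline/follow-up comparison
uses a two-sided paired t-test (the original test is unnamed; this is the
field default for paired means). With zero variance of differences the
statistic degenerates; the p-value is reported as 0.0 (1.0 when the
difference is also zero).

## Probabilistic sensitivity analysis

Each uncertain parameter gets a distribution fitted by the method of
moments to its mean/SE — gamma (shape = (m/s)², scale = s²/m) for costs,
beta (ν = m(1−m)/s² − 1, α = mν, β = (1−m)ν) for utilities and
probabilities. Infeasible pairs (s² ≥ m(1−m)) fail before any iteration.
Draws are independent across parameters (no correlation structure is
reported) and across 10,000 iterations, from a single
`numpy.random.default_rng(seed)` stream in a fixed order (cost, baseline
utility, post utility, transition probability), making runs bit-identical
under a seed. Only the first-cycle spectacle-loss probability carries an
SE, so each refraction iteration redraws p1 and rescales the geometric
schedule with the final-cycle 90 % pinned.

The CEAC reports, at each threshold λ (default grid 0–2,000 US$/QALY in
steps of 10, always including 1,160), the fraction of iterations with
λ·ΔQALY − ΔCost > 0. The probabilistic ICER is the ratio of mean
increments (matching how the original summary is laid out);
mean-of-ratios is available behind a flag.

## Synthetic cohorts

`synthetic_cohort` generates patient-level stand-ins for the unreleased
study records: baseline utilities from a moment-matched beta; follow-up =
baseline + an independent normal treatment-effect draw, clipped at the
EQ-5D ceiling of 1. Clipping would otherwise drag the realised mean
change below its target, so the raw shift is calibrated numerically
(censored-normal expectation integrated over the baseline beta, solved by
Brent's method) to make the *post-ceiling* mean change equal the target
effect. Default change SD is 0.17, consistent with the observed
baseline/follow-up SDs (a fixture choice, not an estimate). Cost
components draw from gammas around category means (CV 0.3 by default).
Optional loss to follow-up marks records missing at random. Not emulated:
baseline–follow-up correlation, covariates, visual acuities — so passing
closed-loop tests show pipeline correctness at the published moments, not
fidelity to individual-level structure of the real data.

## Numerical conventions

* No half-cycle correction by default (the source is silent); switchable
  via `half_cycle_correction`, which averages start- and end-of-cycle
  survivorship in the accrual.
* Discount factor (1+r)^(−t), t from 1; entry costs at t = 0
  undiscounted.
* Trace invariants enforced by tests: occupancies sum to 1 within 1e−12
  each cycle; the dead state is non-decreasing; the engine agrees with a
  brute-force path-enumeration oracle to 1e−10 on short horizons and with
  the geometric closed form in the no-mortality flat-rate limit to 1e−10.
* ICER dominance labels: "dominant" (ΔC < 0 < ΔQ), "dominated"
  (ΔQ ≤ 0 < ΔC, value NaN), "undefined" (both zero).
* Problem sizes: 10,000 PSA iterations as in the original analysis;
  distribution round-trip checks use 1e5 draws; parameter-recovery checks
  use n = 10,000 synthetic patients; the paired-test power check uses
  1,000 replicates against a noncentral-t closed form.

## Known limitations

* **Absolute lifetime QALYs.** With the flat calibrated table the
  comparator arm reproduces 7.519 by construction, but the intervention
  arm gives 7.871 (increment 0.352, ICER US$261/QALY) versus the
  published 7.874/0.355/259: the deterioration-weighted annuity depends
  on the age *profile* of mortality, which a flat table cannot supply.
  The published deterministic ratios are recovered exactly from the
  printed increments (92/0.355 = 259, 72/0.192 = 375).
* **Refraction arm levels.** The published no-spectacles QALY total
  (3.655 over five discounted cycles from age 39) implies far heavier
  survival weighting than plausible adult mortality at ages 39–43
  provides; with the calibrated table the engine gives 3.214. Neither
  loss-schedule reading reproduces the published incremental 0.192, and
  the published probabilistic refraction row (0.096 QALYs, ICER 748,
  about half the deterministic increment) has no stated mechanism. These
  rows are therefore not matched; the engine is instead held to
  structural invariants and an independent enumeration oracle.
* The highest-facility-cost sensitivity ratio computed from printed
  rounded inputs is 128/0.355 = 360.6, one dollar above the published
  360 (whose unrounded inputs are unavailable).
* No second-eye surgery, complication costs, spectacle repurchase,
  time/productivity costs, or EQ-5D-5L — all outside the original
  analysis.
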