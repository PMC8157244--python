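# Methods

## Scope and design

`tamsim` is a simulation pipeline, not an estimation tool. It takes three
inputs — a per-group CYP2D6 activity-score (AS) frequency table, a
population-PK parameter set for the joint tamoxifen–endoxifen model, and a
pool of age/body-weight values — builds virtual populations, computes each
patient's steady-state troughs in closed form, and summarizes target
attainment against the 5.97 ng/mL endoxifen threshold. Estimating the
nonlinear mixed-effects model itself, modelling individual CYP2D6
diplotypes, enzyme-inhibiting comedication, and outcome (recurrence)
modelling are all out of scope.

## Virtual populations

**Activity-score classes.** Diplotype activity scores are collapsed into
six classes `0, 0.5, 1, 1.5, 2, >2`. Raw frequency sheets may carry
0.25-step labels and a `missing` category; `normalize_frequency_table`
applies three rules: (i) each 0.25 step is folded into the following 0.5
step (0.25→0.5, 0.75→1, 1.25→1.5, 1.75→2); (ii) scores of 2.5 and above —
copy-number variants — are aggregated into `>2`, and 2.25 is routed there
too so the six-class partition stays total; (iii) explicit `missing` mass
and any shortfall of the group total to 1 are assigned to class 2
(missing AS is treated as wildtype), with the moved mass audited in
`missing_assigned`. Totals above 1 by more than 0.002 are rejected; totals
inside that band — an artifact of frequencies printed at three significant
figures — are rescaled proportionally. The bundled table (the published
six-class frequencies for the nine biogeographical groups) is run through
the same normalizer at load time.

**Phenotypes.** AS 0 → gPM, AS 0.5–1 → gIM, AS ≥ 1.5 → gNM (ultrarapid
metabolizers are folded into gNM). The mapping is total and deterministic,
so phenotype frequencies are exact functions of the class frequencies.

**Assignment.** The default is *quota* assignment: class counts are
`freq × n` rounded by the largest-remainder method, ties broken toward the
lowest class. This makes the phenotype summaries deterministic and exactly
equal to the frequency-table sums (to < 1 patient per class), which is why
the package reproduces the reported phenotype percentages digit for digit.
A *multinomial* mode (random counts with expectation `freq × n`) is
available when sampling variability in the AS distribution itself is
wanted.

**Covariates.** Ages and weights are drawn independently, with
replacement, from the covariate pool; no age–weight correlation and no
AS–covariate dependence is imposed (the same pool serves all groups by
design, so that between-group differences reflect CYP2D6 alone). The two
random effects are drawn at population-build time so a population is a
self-contained, reproducible object.

**Seeds.** One master seed per run; each stochastic component uses a child
generator seeded with the entropy pair `[master_seed, stream]` — streams
0–8 for the groups in canonical order, 100 for the covariate pool. Adding
or removing a group never perturbs the draws of another.

## The synthetic covariate pool

The original 1388-patient covariate data are not deposited, so the default
pool emulates their published marginals: truncated log-normal draws with
the scale calibrated so the realized median is within 2% of 55 years /
67 kg and all values lie inside 22–95 years / 39–150 kg. Log-normal was
chosen for positivity and the right skew typical of body weight; σ = 0.28
(age) and 0.22 (weight) give ranges compatible with the published bounds.
Calibration runs a fixed-point loop on a 20,000-draw probe, then refines
against the realized pool median (skipped below n = 200, where the sample
median is noise-dominated). The synthetic pool matches only the published
median and range — not the true shape, and not any age–weight correlation
— so simulation results conditional on covariates inherit that
approximation. A real pool can be supplied as a CSV with columns
`age_years, weight_kg`.

## Pharmacokinetic model and parameters

The structural model is a linear cascade: first-order absorption with lag
(`ka`, `tlag`) into a tamoxifen compartment (`V_TAM/F`), parallel linear
elimination (`CL_20/F`) and formation of endoxifen (`CL_23/F`), and linear
endoxifen elimination (`CL_30/F`, `V_ENDX/F`). Covariates: power models of
age and weight on `CL_20/F` centred at the pool medians (55 y, 67 kg, the
standard centring choice; overridable), and a fractional-change model of
the AS class on `CL_23/F` with reference AS 2 — `CL_23,i = CL_23,typ ·
(1 + Δ_AS)`, `Δ_2 ≡ 0`, `Δ` non-decreasing in AS. Interindividual
variability is log-normal on both tamoxifen clearance pathways and absent
from endoxifen elimination; the two η's are uncorrelated (no correlation
structure is published). No molecular-weight correction is applied between
parent and metabolite amounts: the apparent formation clearance absorbs
the scale.

**Parameter values.** The published estimates are not public; the bundled
`params_placeholder.yaml` is a complete, schema-valid stand-in chosen once
from general tamoxifen clinical pharmacology (apparent tamoxifen half-life
≈ 5 days, endoxifen half-life ≈ 55 h, a small formation fraction at AS 2,
Δ values strictly increasing from −0.85 at AS 0 to +0.2 at >2 so the
typical gNM sits above and the typical gIM below the 5.97 ng/mL target).
Every artifact produced from it carries an `is_placeholder` stamp.
Attainment percentages under the placeholder set are therefore
qualitative; phenotype frequencies are exact regardless, since they do not
touch the PK layer. The parameter loader enforces a strict schema
(unknown or missing keys rejected) so a transcribed published set drops in
without code changes.

**Residual error.** Simulated attainment uses residual-free ("true")
concentrations: the target is defined on underlying exposure, and no
residual magnitude is published. `sigma_resid` exists in the schema for
users who want to overlay log-scale measurement noise.

## Steady-state engine

The trough is defined as the pre-dose concentration at steady state,
evaluated `τ − tlag` hours after the absorption onset of the most recent
dose (the standard therapeutic-drug-monitoring convention; for a slowly
eliminated metabolite the within-interval minimum coincides with the
pre-dose value). For the linear cascade the single-dose solution is a sum
of exponentials in {ka, k_tam, k_endx} (Bateman terms for the parent,
partial-fraction cascade terms for the metabolite); by superposition each
term gains the geometric accumulation factor `1/(1 − e^(−λτ))` at steady
state. Amounts are kept in ng (dose mg × 1e6) and volumes in L, giving
ng/mL as `amount/(V·1e3)`.

Numerical choices: when two rate constants agree to better than 1e−8
relative, the smaller is nudged down by 1e−6 relative (with a warning)
rather than implementing the three confluent limit branches for a
measure-zero case; the nudge is validated against the ODE oracle. `tlag ≥
τ` is rejected. Dose 0 short-circuits to zero concentrations.

The **ODE oracle** integrates the same cascade dose by dose (boluses into
the gut compartment at `k·τ + tlag`, piecewise LSODA at rtol 1e−9 —
strictly tighter than the 1e−4 equivalence bound it certifies) and records
pre-dose concentrations. A 182-day treatment covers ≥ 20 half-lives
whenever the slowest half-life is ≤ ~6 days, which holds for the typical
placeholder individual (≈ 5 days); the test suite checks the 1%
steady-state-attainment premise explicitly rather than assuming it. The
analytic result itself is duration-independent.

## Attainment analysis

A patient is *subtarget* when the endoxifen trough is strictly below the
threshold — the target is "at least 5.97 ng/mL", so equality attains it (a
measure-zero distinction for continuous simulation, fixed for
determinism). Medians use the standard mid-rank convention. Alternative
proposed thresholds (3.36, 5.28 ng/mL) are accepted anywhere a threshold
is taken and by `tamsim summarize`, which re-analyzes saved results
without re-simulation. Cross-group comparison reports the extreme groups
(ties broken by group name), their fold difference, and the count of
groups above the 20% reference line. Displayed values are rounded to three
significant figures; machine-readable outputs keep full precision.

## Problem sizes and determinism

The default run is the full scenario — nine groups × 10,000 patients, 20 mg
every 24 h — and completes in a few seconds on one CPU because each patient
costs one closed-form evaluation. Identical config and master seed yield
byte-identical summary artifacts. Test-suite simulations use the same
sizes except where a smaller population suffices to exercise a code path;
the engine-vs-oracle sweep uses 200 randomized parameter sets with rate
constants bounded so 20 slowest half-lives stay within a few hundred
dosing intervals.

## Known limitations

- Attainment percentages are only as good as the parameter set; the
  bundled placeholder reproduces the direction and ordering of the
  CYP2D6 effect, not published magnitudes.
- The AS-class frequency input collapses diplotype detail; nothing below
  the six classes (allele level, copy-number counts) is modelled.
- One covariate pool serves all groups — real between-group differences in
  age/weight distributions are deliberately not represented.
- The six-class frequencies bundled here are printed at three significant
  figures; group totals deviate from 1 by up to ±0.1% and are renormalized,
  which is also why two groups' phenotype percentages can differ from the
  printed values in the last digit.
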