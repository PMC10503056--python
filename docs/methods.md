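# Methods

`cvdscreen` models a one-year cardiovascular-risk screening program and
follows the screened cohort over its lifetime, comparing program designs
on incremental cost per quality-adjusted life year (QALY). This note
documents the model, its parameters, the synthetic inputs, and the
numerical and design choices a maintainer should know about.

## The decision problem

A national primary-care screening program (modelled on Sri Lanka's
Healthy Lifestyle Centres) screens 672,000 adults in one year
(20 patients/week × 1,000 clinics × 48 weeks at 70% utilisation). A
program *design* fixes five axes:

1. the 10-year CVD risk tool (WHO-ISH, WHO-2019, Framingham or
   Globorisk style, each in an office or laboratory version),
2. the age rule (35+, 40+, or 40–65),
3. the 10-year risk threshold that defines "high CVD risk" (30%, 20%,
   10%),
4. whether all diabetics receive statins regardless of risk,
5. whether the blood-pressure treatment threshold drops to 130/80 for
   diabetics and high-risk persons.

The default grid crosses 8 tool/mode pairs × 2 age rules × 2 thresholds
× 2 × 2 policy flags and adds the base case (current protocol: WHO-ISH
office chart, 20%, 35+), i.e. 129 designs.

## Treatment and follow-up rules

Every screened person is assessed against:

- **antihypertensives** at BP ≥ 140/90 — interpreted as SBP ≥ 140 *or*
  DBP ≥ 90 (the usual clinical reading of slash notation); with the
  lowered-threshold policy additionally at ≥ 130/80 for diabetics and
  high-risk persons;
- **statins** for high CVD risk, for total cholesterol ≥ 300 mg/dL in
  lab designs, and for all diabetics when that flag is on;
- **hypoglycaemics** at fasting glucose ≥ 126 mg/dL or random glucose
  ≥ 200 mg/dL.

Medication, once started, continues for life. High-risk persons get two
follow-up visits and glucose tests per year (plus a cholesterol test per
visit in lab designs); medicated non-high-risk persons get one visit and
glucose test per year with an extra visit in year 1. Persons qualifying
through the lab cholesterol rule but not classified high-risk follow the
lower (non-high-risk) schedule; the distinction is not observable from
the rules alone, so the two-tier reading was fixed once and kept.

## Risk scoring

Two engine families:

- **Equation tools** implement the sex-specific proportional-hazards
  survival form `risk = 1 − S0^exp(Σ β·g(x) − Σ β·g(x̄))` with 10-year
  baseline survival `S0`, identity or natural-log transforms `g`, and
  reference means `x̄`.
- **Chart tools** bin age × SBP (× total cholesterol in lab charts) by
  sex, smoking and diabetes, and map the cell's risk category to a point
  probability via category midpoints. Bins are half-open `[lo, hi)`
  with the lower edge inclusive; values outside the outermost bins are
  clamped to the nearest bin and logged. Out-of-range equation
  predictors are likewise clamped to the declared validity range.

Tool parameters ship as versioned YAML files under
`src/cvdscreen/data/`. **They are synthetic stand-ins**: structurally
faithful to the published tool families, with plausible gradients, but
not the published coefficients (which live in external references and
differ per publication variant). A scenario's own tool decides only who
counts as high-risk; *event simulation always uses the laboratory
WHO-2019-style equation pair*, treated as the best available estimate of
each person's true CHD and stroke risk. Tools that output only combined
CVD risk are combined as `p = 1 − (1−p_chd)(1−p_stroke)` when needed in
the other direction.

10-year risks convert to annual ones by the constant-hazard identity
`p1 = 1 − (1−p10)^(1/10)`, which recompounds exactly.

## The Markov model

Five states: `NO_CVD`, `POST_CHD`, `POST_STROKE`, `DEAD_CVD`,
`DEAD_OTHER`; both dead states are absorbing. One-year cycles; each
person starts with mass 1 on `NO_CVD` and is propagated as an
expected-value occupancy distribution (no first-order Monte-Carlo noise;
parameter uncertainty is the PSA's job).

During cycles 1–10 (the effect horizon):

- `NO_CVD` faces the annual CHD and stroke probabilities, each split
  into fatal and non-fatal parts by an age/sex case-fatality table.
  Statin and antihypertensive relative risks multiply the corresponding
  parts (composing multiplicatively when both are taken). Natural
  mortality applies to the event-free remainder,
  `p_other = q_age·(1 − p_events)`, avoiding double-counted deaths.
- `POST_CHD` / `POST_STROKE` face the elevated post-event annual death
  probabilities (0.03 and 0.10), floored at natural mortality since the
  life-table value can exceed them at high ages. These deaths are
  attributed to `DEAD_CVD` (attribution does not affect costs or
  QALYs).

From cycle 11 onward all alive states face natural mortality only:
treatment is assumed to confer no risk reduction beyond 10 years of
therapy (a conservative assumption), no new events are generated, and
recurrent events are not modelled at all. Cycles continue until certain
death or age 100, where death is forced (attributed to `DEAD_OTHER`).
If combined event probabilities ever exceeded 1 they would be
renormalised to 1; with realistic inputs this path never triggers.

### Utilities and costs

Annual utility in an alive state is
`baseline_utility + years_since_screening × (−0.0066) + state decrement
(−0.0210 post-CHD, −0.2493 post-stroke) − pill disutility (0 by
default, 0.00384 in sensitivity) for the newly medicated`, clipped to
`[−1, 1]`. The floor keeps additive decrements bounded at extreme ages.

Annual costs (December-2019 USD) comprise medication (atorvastatin
3.98; enalapril 2.21 + nifedipine 0.78 jointly as the antihypertensive
regimen — the source lists both drugs without stating the regimen;
metformin 6.27), follow-up consultations (1.96) and tests (glucose
0.17, cholesterol 0.19) per schedule, usual care (base per-capita
inpatient/outpatient costs multiplied by state-specific inflation
ratios: CHD 2.85/1.95, stroke 1.09/1.97, general 1.00), and event
admissions (MI 318, stroke 241) charged on the incident fatal plus
non-fatal event mass in the event cycle. The screening visit
(consultation + glucose test + cholesterol test in lab designs) is a
one-off year-0 cost.

The base per-capita usual-care levels (inpatient 18, outpatient 22) are
illustrative defaults; only the inflation *ratios* are study
quantities.

### Half-cycle correction and discounting

All recurring flows (utility, medication, follow-up, usual care) are
valued at the average of start- and end-of-cycle occupancy; one-off
flows (screening, event admissions) are not. Cycle-k flows are
discounted by `(1+r)^−k` at `r = 0.03`. With certain survival for `T`
cycles this reduces to the geometric sum `Σ u (1+r)^−k` (plus a
half-cycle term in the forced terminal cycle), which the tests check to
1e−10.

### Program-attributable totals

Program totals are computed from *attributable* outcomes: for every
screened person the model also simulates the counterfactual in which
they are never screened (no visit, no medication, no follow-up) and
takes the difference before scaling the survey-weighted mean to the
672,000-person throughput. Without this, comparisons between designs
that screen different age ranges would be dominated by cohort
composition (younger cohorts carry millions more baseline QALYs),
swamping treatment effects that are three orders of magnitude smaller.
Attributable totals make a pure tool switch show up as what it is — a
small cost saving with a small QALY change — rather than a composition
artifact.

## Cost-effectiveness analysis

Increments are taken against the base case. Quadrant conventions: more
QALYs at higher cost gives an ICER; cheaper-and-at-least-as-effective is
*cost saving* (no ratio); cheaper-and-less-effective is also reported
as cost saving, with the ratio read as savings per QALY forgone;
ΔQALY = 0 leaves the ICER undefined.

Dominance: a design is **strongly dominated** if another yields at
least as many QALYs at no greater cost (one inequality strict; exact
ties keep the lexicographically smaller id for determinism). **Extended
dominance** then removes designs until pairwise ICERs along the
cost-ordered survivors strictly increase. The survivors are the
cost-effectiveness frontier; each member's ICER is reported against the
closest cheaper frontier member. The tests verify the algorithm against
an independent convex-hull construction on hundreds of random
instances.

ICERs are classified against 0.25×, 0.5× and 1× GDP per capita
($4,083, 2019 USD), boundaries inclusive; cost-saving results are
classified as such before any threshold. Age-subgroup analysis
aggregates the same machinery within half-open 5-year bands.

## Sensitivity analysis

**One-way (deterministic):** named parameter overrides each trigger a
full pipeline re-run. The default set varies the antihypertensive
effect on stroke to a stronger value (RR 0.73, illustrative of the
higher-baseline-SBP estimate), the discount rate to 0% and 6%, the MI
disutility to the stroke value, usual-care costs to 80%/120%, and the
CHD/stroke usual-care ratios to 1 and 3.

**Probabilistic:** each draw realises every varied parameter once and
applies it to all designs (common random parameters), so within a draw
two designs differing only in a policy flag see identical parameters.
Families: uniform on value ± x% for costs/probabilities stated that
way; log-normal with median at the point estimate and
`sdlog = (ln hi − ln lo)/(2 × 1.959964)` for relative risks and
inflation ratios; beta with moments matched to the point estimate and
`sd = (hi − lo)/3.9199` for the post-CHD death probability; gamma with
a 10% SD fraction for unit costs. Utility decrements use a log-normal
on the negated scale; when the CI crosses zero (non-fatal MI:
−0.021, CI −0.066 to 0.024) a deterministic location shift
`shift = hi + 0.1(hi − lo)` keeps the magnitudes positive, and draws
are mapped back as `shift − exp(N(μ, σ))`. Risk-equation coefficients
are not varied (no uncertainty is stated for them), so screening
classification and treatment plans are fixed across draws and
precomputed once per design.

CEAC curves report, per willingness-to-pay value on a default grid of
0–2× GDP per capita in 41 steps, the probability each design maximises
net monetary benefit `NMB = λ·QALYs − cost`; exact ties split the
probability mass equally. A separate summary reports the fraction of
draws in which each design's ICER against the base is at most a stated
threshold, with cost-saving draws counted as below threshold.

**Pill disutility:** re-runs the pipeline with a 0.00384 utility
decrement for everyone newly on daily medication and reports the change
in incremental QALYs and ICERs per design.

## The synthetic population

The generator stands in for restricted survey microdata. It emulates:
age-correlated blood pressure and (negatively) baseline utility, via
both a Gaussian copula over the continuous risk factors and explicit
additive age gradients; sex-specific smoking prevalence (29% male, 1%
female); diabetes flags always consistent with the generated glucose
values plus a 4% diagnosed-but-controlled share; prior-CVD prevalence
rising logistically with age; positive survey weights normalised to a
10-million adult population. Diastolic pressure is a linear regression
on systolic plus noise, capped 5 mmHg below systolic, so the
SBP > DBP invariant holds by construction. The supplied correlation
matrix is applied on the normal-scores scale; for a Gaussian copula the
induced Spearman correlation is `(6/π)·arcsin(ρ/2)`, within 0.02 of ρ
everywhere, which is inside the generator's own Monte-Carlo tolerance.

It does **not** emulate: the sampling design of any real survey
(clustering, stratification, non-response), missing data (cohorts are
generated complete; the original analysis imputed), measurement error,
or secular trends. Defaults are illustrative of a South-Asian adult
population, not estimates of any country's distributions. Passing tests
therefore demonstrate internal correctness and qualitative behaviour
(dominance structure, monotonicities, sensitivity directions) — not
quantitative fidelity to any real population's ICERs, which depend on
the unavailable microdata and published tool coefficients.

The packaged life table (Gompertz–Makeham, sex factor 1.35) and
case-fatality fractions (rising linearly with age from 0.15/0.20 at
ages 30–34) are synthetic stand-ins, labelled as such in their
filenames.

## Problem sizes

The default worked examples and the acceptance script use cohorts of
1,500–10,000 synthetic persons, the full 129-design grid, and a reduced
PSA (100 draws over the three cheapest frontier designs on 1,500
persons). These sizes give stable frontier structure and sub-percent
Monte-Carlo noise on the reported shares while keeping a full run in
minutes on one CPU; they are the package's chosen defaults, and all are
arguments.

## Known limitations

- No recurrent CVD events, no secondary-prevention intensity, no
  microvascular diabetes outcomes (hypoglycaemic costs are counted;
  their health benefits are not).
- Perfect adherence and uptake; no real-world attrition.
- Public health-system perspective only (no travel or productivity
  costs).
- Risk tools are not recalibrated to any population, and the packaged
  coefficients are stand-ins — absolute risk levels are illustrative.
- The post-event death probabilities are age-invariant point values
  (floored at natural mortality) rather than age-specific estimates.
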