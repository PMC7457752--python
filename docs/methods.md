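# Methods

## Scope and data model

The package scores one experimental arm against its control arm. A
`TrialArmRecord` carries the hazard ratio (HR) with its confidence
interval, per-arm median survival (months), landmark survival proportions
(fractions in [0, 1] at timepoints in months), a grade-3/4 adverse-event
incidence table, and the boolean quality-of-life / palliation /
treatment-free-interval / toxic-death flags. All times are months; all
survival proportions and incidences are fractions (printed percentages
divided by 100).

The packaged fixtures transcribe the published initial and updated
assessments of the 18 checkpoint-inhibitor indications. Published tables
print the score *components*, not all of their raw inputs: per-arm AE
tables, medians and landmark survival are mostly absent. The record
therefore supports override fields — `toxicity_points_override`,
`tail_bonus_override` — and transcription flags (`toxicity_reduced`,
`long_term_benefit_reported`) carrying the published values directly.
Scoring prefers raw inputs when present; every override substitution is
written to the run log, because auditability is the point of a value
framework. Fixture-based results are thus reproduction of published
scoring, while the raw-input pathways are exercised by the synthetic
generator and by the arms (the head-and-neck worked example and the two
adjuvant trials) whose effect-size inputs the tables do print.

Two fixture rows carry a published 16-point tail bonus on an OS-evaluated
arm. The derivation rule can only award 16 for PFS, so these values are
representable solely via the override path; the component invariant
(16 ⇔ PFS) is enforced on the derived path only.

## ASCO-VF arithmetic

* Treatment effect: `(1 − HR) · 100 · w`, w = 1.0 for OS and RFS/DFS
  (including the curative setting), 0.8 for PFS. HR > 1 yields negative
  points and is deliberately not floored — a floor would hide data errors.
* Toxicity: the framework's published materials do not fix a single
  arithmetic for multi-event tables, so the package uses the unweighted
  sum of grade-3/4 incidences per arm as the burden B, scored as
  `20 · (B_ctrl − B_exp) / max(B_ctrl, B_exp)` clamped to [−20, 20]:
  bounded, antisymmetric under arm swap, and zero-safe (0 when both
  burdens are 0). Fixtures always use published overrides, so cohort
  reproduction never depends on this choice.
* Tail of the curve: the landmark whose timepoint lies within ±10% of
  twice the control-arm median is evaluated; the bonus (20, or 16 for
  PFS) requires control survival ≥ 0.20 and experimental ≥ 1.5× control.
  A missing landmark is a defined "not available" outcome (0, logged) —
  limited follow-up — distinguished from "not qualified".
* Palliation, QOL and treatment-free interval each add 10 points when the
  corresponding statistically-significant-improvement flag is set.
* Components are reported rounded to one decimal; the NHB is the exact
  sum of unrounded components, rounded only for display.

## ESMO-MCBS grading

Form 1 (curative), 2a (non-curative OS) and 2b (non-curative PFS) are
selected from setting and endpoint; the curative setting accepts RFS/DFS
or OS (updated adjuvant reports are graded on OS).

The preliminary score applies a dual rule driven by a YAML rule table:

* the lower CI limit of the HR must clear a ceiling (default 0.65,
  compared with ≤ at the boundary); the absolute gain in median survival
  then selects a band. With the default table, form 2a with control
  median ≤ 12 months scores 4/3/2 at gains ≥ 3.0/2.0/1.5 months (else 1);
  the > 12-month stratum uses 5.0/3.0/2.0 and a 3-year landmark. When the
  CI clause fails, the band score is capped at 2.
* independently, an absolute survival gain ≥ 0.10 at the stratum landmark
  (2 years for short-median OS strata, 1 year for PFS) confers the form's
  top preliminary score: 4 on form 2a, 3 on form 2b.

These bands are the minimal ones consistent with the published worked
example (lower CI limit < 0.65 + 2.4-month gain → 3; > 10% two-year gain
→ 4); users grading new trials should substitute the full v1.1 scorecard
via `EsmoRuleTable.from_yaml`. The form-2b bands (3/2 at ≥ 1.5/1.0
months) and the form-1 B/C boundary (B at lower CI limit ≤ 0.80) are
likewise defaults, not published values.

Adjustments: any of {QOL improved, toxicity reduced, long-term PFS
plateau} upgrades by exactly one level regardless of how many apply (the
worked example had both QOL and toxicity improvements yet moved only
3 → 4); increased toxic death downgrades one level; the final grade is
clamped to [1, 5] and to ≤ 4 for PFS-graded arms (no published PFS-graded
assessment exceeds 4). Long-term OS benefit — a survival advantage still
observed at 5 years when the control median is ≤ 12 months, 7 years
otherwise — is reported as a flag only, never as a grade change, since no
trial in the cohort meets it. Grades 4/5 and A/B constitute meaningful
benefit.

## Cohort analysis

Multi-arm trials contribute one representative arm per indication: the
higher NHB for every ASCO quantity (ties go to table order), and the
higher ESMO grade for grade counts — each framework's "higher score" rule
applied on its own scale. (These can disagree: one two-arm melanoma trial
has its higher-NHB arm at ESMO grade 3 and the other arm at 4.) Medians
use the standard midpoint convention; the headline cohort median NHB is
an arm-level median over all 23 arms (the indication-level median is
55.15), and the summarizer exposes both levels. Bonus and grade counts
are always per indication.

The phase comparison takes best-arm NHB deltas (updated − initial) per
shared indication; the "improved" subset is the strictly positive deltas
(tolerance 1e−9), whose median and range are the headline change.
Indications assessed in only one phase are excluded and logged.

One published tally — 13 trials with positive and 5 with negative
toxicity scores — does not reconcile with best-arm selection (which gives
14/4) and matches the arm level only for the negative count (5 of 23
arms); the tests assert the reproducible arm-level facts.

## Synthetic data

The generator draws, per trial, a hazard ratio `exp(N(μ, σ))` and builds
mixture-cure exponential survival curves `S(t) = π + (1 − π)·e^(−rt)` for
both arms — the simplest family with the durable plateau the frameworks
reward. The control rate is solved from a uniformly drawn control median
and the control cure fraction; the experimental rate scales the control
rate by the HR with its own cure fraction, so proportional hazards is not
enforced and effect size and tail behaviour are independent dials. Cure
fractions ≥ 0.5 leave the median undefined and are rejected as config
errors. Medians solve the curves in closed form; landmarks tabulate
twice the control median plus the 1/2/3/5/7-year grading timepoints; AE
incidences are Beta(α, β) draws per arm; CI width uses a normal log-HR
approximation with standard error `2/√n` at a nominal pivotal-trial
sample size (default 700, near the cohort's median of 694). Default
conditions emulate a second-line immunotherapy cohort (HR centred at 0.7,
σ = 0.15, control medians 5–15 months, modest experimental plateau).

What the generator does **not** emulate: patient-level event times,
censoring, Kaplan–Meier estimation noise, correlated endpoints, or
digitization error in landmark reads. Passing synthetic tests therefore
demonstrates that the scoring rules are implemented correctly on exact
curve values, not that real-world curve extraction is robust.

Two reference configurations are used by the analysis drivers and tests,
at 500 trials each: an engineered-plateau cohort (control π = 0.25 puts
control survival at twice its median at 1/3 ≥ 20%; experimental π = 0.45
with HR ~ lognormal(ln 0.6, 0.1) keeps experimental survival there above
1.5× control for any plausible draw, so the tail-bonus rate is 100%) and
a null cohort (HR centred at 1, no plateaus, no flags, exchangeable
toxicity draws; median NHB sits within ±3 of 0).

## Numerical and testing choices

All randomness flows through `numpy.random.default_rng(seed)`; identical
configs give identical cohorts. Floating-point comparisons in tests use
absolute tolerances: 0.15 for NHB against published values (published
components are rounded to one decimal, so sums can differ by up to ~0.15)
and exact-to-printed-precision for single components. The grading engine
is cross-checked against a brute-force oracle written directly from the
rule-table YAML on a 320-point grid of (endpoint × control-median stratum
× lower CI limit × median gain × landmark gain), including the 0.65 and
0.10 boundaries.

## Known limitations

* ESMO band edges beyond those pinned by the published worked example are
  configurable defaults; grades for trials far from the fixture regime
  should be computed with the full v1.1 scorecard loaded as a rule table.
* The ASCO toxicity arithmetic for raw AE tables is this package's
  bounded formulation, not a published formula.
* Single-arm trial forms, non-inferiority designs, response-rate fallback
  scoring and drug-cost display are out of scope.
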