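# oncovalue

Clinical-benefit scoring of randomized oncology trials with the two major
value frameworks: the **ASCO Value Framework** (2016 update) net health
benefit (NHB) and the **ESMO Magnitude of Clinical Benefit Scale**
(ESMO-MCBS v1.1) grade. The package ships transcriptions of the published
assessments of the 18 FDA-approved immune-checkpoint-inhibitor indications
supported by randomized trials (23 scored arms in the initial assessments,
18 re-assessed arms with updated survival/QOL data), a cohort-analysis
pipeline that recomputes the published summaries, and a seeded synthetic
trial generator so every scoring rule can be exercised without external
data.

It is written for oncologists, HTA analysts and methods researchers who
want auditable, reproducible framework scores rather than hand-filled
scorecards.

## The scores

**ASCO-VF.** For an experimental arm with hazard ratio HR versus control:

```
NHB = (1 − HR) · 100 · w          treatment-effect points; w = 1.0 (OS, RFS/DFS), 0.8 (PFS)
    + toxicity points             in [−20, 20], from grade-3/4 AE burdens per arm
    + tail-of-the-curve bonus     20 (OS/RFS) or 16 (PFS) if, at 2× the control-arm
                                  median, S_ctrl ≥ 20% and S_exp ≥ 1.5 · S_ctrl
    + 10 · [palliation improved] + 10 · [QOL improved] + 10 · [TFI improved]
```

**ESMO-MCBS.** Non-curative arms are graded 1–5 (4/5 = meaningful benefit)
on form 2a (OS) or 2b (PFS): the lower 95% CI limit of the HR must clear a
ceiling (0.65) while the absolute gain in median survival selects a band,
or a ≥10% absolute survival gain at a prognosis-weighted landmark confers
the top preliminary score; QOL/toxicity improvements (or a long-term PFS
plateau) upgrade by at most one level, excess toxic deaths downgrade by
one. Curative (adjuvant) arms are graded A–C from the CI limit. The
threshold bands are data (`src/oncovalue/data/esmo_rules.yaml`), not code.

## Worked example

The second-line head-and-neck squamous-cell carcinoma approval (OS
HR 0.70, 95% CI 0.52–0.92; medians 7.5 vs 5.1 months; published toxicity
points 7.1; qualifying survival tail; improved QOL and symptom palliation):

```python
from oncovalue import TrialArmRecord, score_asco, score_esmo

rec = TrialArmRecord(
    trial_id="CHECKMATE-141", indication_id="CHECKMATE-141",
    setting="non_curative", endpoint="OS",
    hr=0.70, ci_lower=0.52, ci_upper=0.92,
    median_control=5.1, median_experimental=7.5,
    toxicity_points_override=7.1, tail_bonus_override=20,
    qol="improved", toxicity_reduced=True, palliation_improved=True,
)
print(score_asco(rec).rounded())
a = score_esmo(rec)
print(a.preliminary, a.final_grade, a.meaningful_benefit)
```

prints

```
{'treatment_effect_points': 30.0, 'toxicity_points': 7.1, 'tail_bonus': 20,
 'palliation_bonus': 10, 'qol_bonus': 10, 'tfi_bonus': 0, 'nhb': 77.1}
3 4 True
```

i.e. 30 treatment-effect points (HR 0.70), a 77.1 NHB — the highest of the
initial cohort — and ESMO preliminary score 3 (lower CI limit ≤ 0.65 with a
2.4-month OS gain) upgraded once to grade 4 (meaningful benefit) by the
QOL/toxicity improvements.

## Cohort pipeline

The numbered drivers under `analysis/` run the full reproduction and write
tables to `results/`:

```bash
python analysis/01_score_trials.py      # per-arm scores + audit logs, both phases
python analysis/02_cohort_summary.py    # medians, ranges, bonus/grade counts
python analysis/03_compare_phases.py    # initial-vs-updated best-arm deltas
python analysis/04_synthetic_cohorts.py # engineered-tail and null cohort checks
```

The same pipeline is exposed on the command line: `oncovalue score` (score
any CSV/JSON trial table, with a per-arm audit log of every override and
bonus-gate decision), `oncovalue reproduce`, and `oncovalue simulate`
(seeded synthetic cohorts). `oncovalue reproduce` prints, among others:

```
initial phase: median NHB 55.3 (range 17.4-77.1) over 23 arms / 18 indications
updated comparison: median NHB improvement 10.0 (range 2.0-20.0) over 12 improved indications
```

## Layout

```
src/oncovalue/
  trial_data.py       # record model, validation, CSV/JSON I/O, packaged fixtures
  asco_vf.py          # ASCO-VF components and NHB composition
  esmo_mcbs.py        # ESMO-MCBS forms, rule table, grading engine
  cohort_analysis.py  # best-arm selection, summaries, phase comparison
  synthetic_data.py   # mixture-cure synthetic trial generator
  cli_app.py          # command-line interface
  data/               # fixture tables + default ESMO rule table (YAML)
analysis/             # numbered reproduction drivers
docs/methods.md       # modelling assumptions, defaults, limitations
```

CSV schema: one row per experimental arm, columns named after
`TrialArmRecord` fields; list-valued cells (`landmark_survival`,
`toxicity_table`) are JSON-encoded; unknown columns are preserved as
record metadata. JSON input is a document with a `records` array.
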