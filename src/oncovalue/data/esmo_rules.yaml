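# ESMO-MCBS v1.1 grading thresholds used by the grading engine.
#
# The engine treats these bands as data so users can substitute the full
# scorecard from the framework publication. The defaults below are the
# minimal banding consistent with the published worked example for the
# head-and-neck second-line approval (lower CI limit < 0.65 with a
# 2.4-month OS gain -> preliminary 3; >10% absolute 2-year survival gain
# -> preliminary 4).
version: oncovalue-default-1
lower_ci_ceiling: 0.65          # required lower 95% CI limit of the HR
curative:
  a_max_lower_ci: 0.65          # grade A when lower CI limit <= this
  b_max_lower_ci: 0.80          # grade B when lower CI limit <= this; else C
form2a:                         # non-curative, OS endpoint
  landmark_gain_threshold: 0.10 # absolute survival gain at the stratum timepoint
  landmark_score: 4             # preliminary conferred by a qualifying gain
  strata:
    - max_control_median: 12.0  # months; null = unbounded
      landmark_months: 24
      bands:                    # gain in median OS (months) -> preliminary
        - {min_gain: 3.0, score: 4}
        - {min_gain: 2.0, score: 3}
        - {min_gain: 1.5, score: 2}
    - max_control_median: null
      landmark_months: 36
      bands:
        - {min_gain: 5.0, score: 4}
        - {min_gain: 3.0, score: 3}
        - {min_gain: 2.0, score: 2}
form2b:                         # non-curative, PFS endpoint
  landmark_gain_threshold: 0.10
  landmark_score: 3             # PFS preliminary is capped at 3
  final_cap: 4                  # PFS-graded arms never exceed 4 after upgrades
  strata:
    - max_control_median: null
      landmark_months: 12
      bands:
        - {min_gain: 1.5, score: 3}
        - {min_gain: 1.0, score: 2}
long_term_os:
  landmark_months_short: 60     # control median <= 12 months: advantage at 5 years
  landmark_months_long: 84      # otherwise: advantage at 7 years
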