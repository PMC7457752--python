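"""ESMO-MCBS form selection, preliminary scoring, adjustments, grades.

Includes a brute-force oracle written directly from the rule-table data,
checked against the grading engine on a full input grid.
"""

import itertools

import pytest
import yaml
from importlib import resources

from oncovalue import (
    Endpoint,
    GradingError,
    LandmarkPoint,
    QolStatus,
    Setting,
    TrialArmRecord,
    adjust,
    curative_grade,
    long_term_benefit,
    preliminary_score,
    score_esmo,
    select_form,
    summarize,
)
from oncovalue.esmo_mcbs import Form


def _record(**overrides):
    base = dict(
        trial_id="E-1", indication_id="E", setting="non_curative", endpoint="OS",
        hr=0.70, ci_lower=0.52, ci_upper=0.92,
    )
    base.update(overrides)
    return TrialArmRecord(**base)


def _lm(t, sc, se):
    return LandmarkPoint(timepoint_months=t, surv_control=sc, surv_experimental=se)


class TestFormSelection:
    @pytest.mark.parametrize("setting, endpoint, form", [
        ("curative", "RFS_DFS", Form.CURATIVE),
        ("curative", "OS", Form.CURATIVE),
        ("non_curative", "OS", Form.OS),
        ("non_curative", "PFS", Form.PFS),
    ])
    def test_mapping(self, setting, endpoint, form):
        assert select_form(Setting(setting), Endpoint(endpoint)) == form

    def test_non_curative_rfs_unsupported(self):
        with pytest.raises(GradingError):
            select_form(Setting.NON_CURATIVE, Endpoint.RFS_DFS)


class TestPreliminaryScore:
    def test_os_gain_band(self, rules):
        # short control median, lower CI limit under the ceiling, 2.4-month gain
        rec = _record(median_control=5.0, gain_months=2.4)
        assert preliminary_score(rec, rules) == 3

    def test_two_year_survival_gain_confers_top_score(self, rules):
        rec = _record(median_control=5.0, gain_months=2.4,
                      landmark_survival=[_lm(24, 0.40, 0.52)])
        assert preliminary_score(rec, rules) == 4

    def test_pfs_form_caps_at_three(self, rules):
        rec = _record(endpoint="PFS", median_control=5.0, gain_months=6.0)
        assert preliminary_score(rec, rules) == 3

    def test_ci_ceiling_caps_band_score(self, rules):
        rec = _record(ci_lower=0.70, hr=0.80, ci_upper=0.95,
                      median_control=5.0, gain_months=4.0)
        assert preliminary_score(rec, rules) == 2

    def test_longer_median_stratum_uses_larger_bands(self, rules):
        rec = _record(median_control=20.0, gain_months=3.5)
        assert preliminary_score(rec, rules) == 3  # >= 3.0 in the long stratum

    def test_missing_inputs_raise(self, rules):
        with pytest.raises(GradingError, match="gain_months"):
            preliminary_score(_record(), rules)


class TestAdjust:
    def test_single_upgrade_from_qol_and_toxicity(self):
        # multiple positive adjustments collapse to one level
        assert adjust(3, QolStatus.IMPROVED, True, False, False, Form.OS) == "4"

    def test_plateau_up_and_toxic_death_down_cancel(self):
        assert adjust(3, QolStatus.NOT_REPORTED, False, True, True, Form.PFS) == "3"

    def test_upgrade_to_five(self):
        assert adjust(4, QolStatus.IMPROVED, False, False, False, Form.OS) == "5"

    def test_pfs_final_cap(self):
        assert adjust(4, QolStatus.IMPROVED, True, False, True, Form.PFS) == "4"

    def test_downgrade_floor(self):
        assert adjust(1, QolStatus.NOT_IMPROVED, False, True, False, Form.OS) == "1"

    @pytest.mark.parametrize("prelim", [1, 2, 3, 4])
    @pytest.mark.parametrize("form", [Form.OS, Form.PFS])
    def test_final_within_one_level_and_qol_monotone(self, prelim, form):
        for tox, death, plateau in itertools.product([False, True], repeat=3):
            grades = [int(adjust(prelim, q, tox, death, plateau, form))
                      for q in (QolStatus.NOT_IMPROVED, QolStatus.IMPROVED)]
            for g in grades:
                assert prelim - 1 <= g <= prelim + 1
            assert grades[1] >= grades[0]


class TestCurativeGrade:
    @pytest.mark.parametrize("hr, lo, hi, grade", [
        (0.65, 0.51, 0.83, "A"),
        (0.75, 0.64, 0.90, "A"),
        (0.85, 0.72, 0.99, "B"),
        (0.95, 0.85, 1.05, "C"),
    ])
    def test_lower_ci_bands(self, rules, hr, lo, hi, grade):
        rec = _record(setting="curative", endpoint="RFS_DFS",
                      hr=hr, ci_lower=lo, ci_upper=hi)
        assert curative_grade(rec, rules) == grade


class TestLongTermBenefit:
    def test_pfs_gain_at_one_year(self, rules):
        rec = _record(endpoint="PFS", landmark_survival=[_lm(12, 0.30, 0.42)])
        assert long_term_benefit(rec, rules) is True

    def test_pfs_boundary_ten_percent_qualifies(self, rules):
        rec = _record(endpoint="PFS", landmark_survival=[_lm(12, 0.30, 0.40)])
        assert long_term_benefit(rec, rules) is True

    def test_os_without_late_landmark_fails(self, rules):
        rec = _record(median_control=5.0, landmark_survival=[_lm(24, 0.2, 0.4)])
        assert long_term_benefit(rec, rules) is False

    def test_os_advantage_at_five_years_short_median(self, rules):
        rec = _record(median_control=5.0, landmark_survival=[_lm(60, 0.10, 0.15)])
        assert long_term_benefit(rec, rules) is True

    def test_os_needs_seven_years_with_long_median(self, rules):
        rec = _record(median_control=20.0, landmark_survival=[_lm(60, 0.10, 0.25)])
        assert long_term_benefit(rec, rules) is False

    def test_published_flag_used_when_landmarks_absent(self, rules):
        rec = _record(endpoint="PFS", long_term_benefit_reported=True)
        assert long_term_benefit(rec, rules) is True


class TestWorkedExample:
    """Second-line head-and-neck squamous-cell carcinoma approval."""

    def test_initial_grade_four(self, scored_initial):
        arm = next(a for a in scored_initial if a.arm_id == "CHECKMATE-141")
        assert arm.esmo.source == "engine"
        assert arm.esmo.preliminary == 3
        assert arm.esmo.upgrade_applied
        assert arm.esmo.final_grade == "4"
        assert arm.esmo.meaningful_benefit

    def test_updated_grade_five(self, scored_updated):
        arm = next(a for a in scored_updated if a.arm_id == "CHECKMATE-141")
        assert arm.esmo.source == "engine"
        assert arm.esmo.preliminary == 4
        assert arm.esmo.final_grade == "5"

    def test_adjuvant_trials_grade_a(self, scored_initial):
        for arm_id in ("CHECKMATE-238", "EORTC-18071"):
            arm = next(a for a in scored_initial if a.arm_id == arm_id)
            assert arm.esmo.source == "engine"
            assert arm.esmo.final_grade == "A"
            assert arm.esmo.meaningful_benefit


class TestFixtureGrades:
    def test_grade_counts(self, scored_initial):
        summary = summarize(scored_initial, level="indication")
        assert summary.grade_counts == {"5": 8, "4": 8, "A": 2}
        assert summary.n_meaningful == 18

    def test_every_arm_matches_published_grade(self, scored_initial, initial_fixtures):
        for arm in scored_initial:
            assert arm.esmo is not None
            assert arm.esmo.final_grade == initial_fixtures.expected[arm.arm_id].esmo_grade

    def test_three_initial_trials_meet_long_term_criteria(self, scored_initial):
        summary = summarize(scored_initial, level="indication")
        long_term = {i for i, v in summary.long_term.items() if v}
        assert long_term == {"PACIFIC", "CHECKMATE-067", "KEYNOTE-002"}


def _load_rule_doc():
    with resources.as_file(
        resources.files("oncovalue.data") / "esmo_rules.yaml"
    ) as fp:
        return yaml.safe_load(fp.read_text())


def _oracle(doc, endpoint, control_median, ci_lower, gain, landmark_gain,
            qol_improved, tox_reduced, toxic_death):
    """Literal re-evaluation of the rule-table data, independent of the engine."""
    form = doc["form2a"] if endpoint == "OS" else doc["form2b"]
    stratum = None
    for s in form["strata"]:
        if s["max_control_median"] is None or control_median <= s["max_control_median"]:
            stratum = s
            break
    score = 1
    for band in sorted(stratum["bands"], key=lambda b: -b["min_gain"]):
        if gain >= band["min_gain"]:
            score = band["score"]
            break
    if ci_lower > doc["lower_ci_ceiling"]:
        score = min(score, 2)
    if landmark_gain >= form["landmark_gain_threshold"]:
        score = max(score, form["landmark_score"])
    plateau = endpoint == "PFS" and landmark_gain >= form["landmark_gain_threshold"]
    up = 1 if (qol_improved or tox_reduced or plateau) else 0
    down = 1 if toxic_death else 0
    final = max(1, min(5, score + up - down))
    if endpoint == "PFS":
        final = min(final, form["final_cap"])
    return score, str(final)


class TestOracleEquivalence:
    def test_engine_matches_brute_force_grid(self, rules):
        doc = _load_rule_doc()
        grid = itertools.product(
            ["OS", "PFS"],
            [6.0, 20.0],
            [0.50, 0.65, 0.66, 0.80],
            [0.5, 1.5, 2.4, 3.0, 5.0],
            [0.0, 0.05, 0.10, 0.15],
        )
        flag_sets = [(False, False, False), (True, False, False),
                     (False, False, True)]
        n = 0
        for endpoint, med, lo, gain, lgain in grid:
            stratum_t = (12.0 if endpoint == "PFS"
                         else (24.0 if med <= 12 else 36.0))
            rec = _record(
                endpoint=endpoint, hr=lo + 0.05, ci_lower=lo, ci_upper=lo + 0.5,
                median_control=med, gain_months=gain,
                landmark_survival=[_lm(stratum_t, 0.30, 0.30 + lgain)])
            for qol_imp, tox_red, death in flag_sets:
                rec2 = rec.model_copy(update={
                    "qol": QolStatus.IMPROVED if qol_imp else QolStatus.NOT_IMPROVED,
                    "toxicity_reduced": tox_red,
                    "toxic_death_increased": death,
                })
                got = score_esmo(rec2, rules)
                want_prelim, want_final = _oracle(
                    doc, endpoint, med, lo, gain, lgain, qol_imp, tox_red, death)
                assert (got.preliminary, got.final_grade) == (want_prelim, want_final), (
                    endpoint, med, lo, gain, lgain, qol_imp, tox_red, death)
                n += 1
        assert n >= 320
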