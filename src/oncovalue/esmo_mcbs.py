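"""ESMO-MCBS v1.1 grading: forms, preliminary score, adjustments, grades.

Non-curative arms are graded 1-5 (4/5 = meaningful clinical benefit) on
form 2a (OS endpoint) or form 2b (PFS endpoint); adjuvant/curative arms
are graded A-C (A/B = meaningful) on form 1. The preliminary score comes
from a dual rule - the lower confidence limit of the hazard ratio must
clear a ceiling (default 0.65) while the absolute gain in median survival
selects a band - or, independently, from a qualifying absolute survival
gain at a prognosis-weighted landmark timepoint. Quality-of-life or
toxicity improvements (or, for PFS, a long-term plateau) upgrade the
preliminary score by at most one level; an excess of toxic deaths
downgrades it by one.

The threshold bands live in a packaged, human-editable YAML rule table
(:class:`EsmoRuleTable`) rather than in code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .trial_data import (
    Endpoint,
    LandmarkPoint,
    QolStatus,
    Setting,
    TrialArmRecord,
)


class GradingError(ValueError):
    """Raised when a record lacks the inputs a grading clause requires."""


class Form:
    CURATIVE = "form1_curative"
    OS = "form2a_os"
    PFS = "form2b_pfs"


MEANINGFUL_GRADES = {"4", "5", "A", "B"}

#: Landmark timepoints within +/-10% of the stratum timepoint are accepted,
#: matching the tail-rule tolerance on the ASCO side.
LANDMARK_TIMEPOINT_TOLERANCE = 0.10


@dataclass(frozen=True)
class Band:
    min_gain: float
    score: int


@dataclass(frozen=True)
class Stratum:
    max_control_median: Optional[float]  # months; None = unbounded
    landmark_months: float
    bands: tuple[Band, ...]


@dataclass(frozen=True)
class FormRules:
    strata: tuple[Stratum, ...]
    landmark_gain_threshold: float
    landmark_score: int
    final_cap: Optional[int] = None


@dataclass(frozen=True)
class EsmoRuleTable:
    """Configurable threshold bands driving preliminary scoring."""

    version: str
    lower_ci_ceiling: float
    a_max_lower_ci: float
    b_max_lower_ci: float
    form2a: FormRules
    form2b: FormRules
    long_term_os_short: float
    long_term_os_long: float

    @classmethod
    def from_dict(cls, doc: dict) -> "EsmoRuleTable":
        def form(key: str) -> FormRules:
            raw = doc[key]
            strata = []
            for s in raw["strata"]:
                bands = tuple(
                    Band(b["min_gain"], b["score"])
                    for b in sorted(s["bands"], key=lambda b: -b["min_gain"])
                )
                gains = [b.min_gain for b in bands]
                if any(a <= b for a, b in zip(gains, gains[1:])):
                    raise ValueError("band edges must be strictly decreasing once sorted")
                strata.append(Stratum(s["max_control_median"], s["landmark_months"], bands))
            return FormRules(
                strata=tuple(strata),
                landmark_gain_threshold=raw["landmark_gain_threshold"],
                landmark_score=raw["landmark_score"],
                final_cap=raw.get("final_cap"),
            )

        return cls(
            version=doc.get("version", "unversioned"),
            lower_ci_ceiling=doc["lower_ci_ceiling"],
            a_max_lower_ci=doc["curative"]["a_max_lower_ci"],
            b_max_lower_ci=doc["curative"]["b_max_lower_ci"],
            form2a=form("form2a"),
            form2b=form("form2b"),
            long_term_os_short=doc["long_term_os"]["landmark_months_short"],
            long_term_os_long=doc["long_term_os"]["landmark_months_long"],
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EsmoRuleTable":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "EsmoRuleTable":
        with resources.as_file(
            resources.files("oncovalue.data") / "esmo_rules.yaml"
        ) as fp:
            return cls.from_yaml(fp)


@dataclass(frozen=True)
class EsmoAssessment:
    """Grading outcome for one arm."""

    form: str
    preliminary: Optional[int]  # None for curative form-1 grades
    upgrade_applied: bool
    downgrade_applied: bool
    final_grade: str  # "1".."5" or "A".."C"
    meaningful_benefit: bool
    long_term_benefit: bool
    source: str = "engine"  # "engine" or "transcribed"


def select_form(setting: Setting, endpoint: Endpoint) -> str:
    """Form 1 in the curative setting; 2a/2b for non-curative OS/PFS."""
    setting, endpoint = Setting(setting), Endpoint(endpoint)
    if setting is Setting.CURATIVE:
        return Form.CURATIVE
    if endpoint is Endpoint.OS:
        return Form.OS
    if endpoint is Endpoint.PFS:
        return Form.PFS
    raise GradingError(
        "non-curative RFS/DFS grading is not defined by forms 2a/2b")


def _stratum_for(form_rules: FormRules, control_median: Optional[float]) -> Stratum:
    for stratum in form_rules.strata:
        if stratum.max_control_median is None or (
            control_median is not None
            and control_median <= stratum.max_control_median
        ):
            return stratum
    # control median unknown: use the unbounded stratum's (larger) bands
    return form_rules.strata[-1]


def _landmark_gain_at(landmarks: Sequence[LandmarkPoint],
                      timepoint: float) -> Optional[float]:
    tol = LANDMARK_TIMEPOINT_TOLERANCE * timepoint
    candidates = [p for p in landmarks if abs(p.timepoint_months - timepoint) <= tol]
    if not candidates:
        return None
    point = min(candidates, key=lambda p: abs(p.timepoint_months - timepoint))
    return point.surv_experimental - point.surv_control


def preliminary_score(record: TrialArmRecord, rules: EsmoRuleTable) -> int:
    """Dual-rule preliminary score (1-4; capped at 3 on the PFS form).

    The gain-band clause requires the lower CI limit of the HR to clear the
    rule-table ceiling (<= 0.65 by default; above it the band score is
    capped at 2). Independently, an absolute survival gain at the stratum
    landmark timepoint at or above the table threshold confers the form's
    top preliminary score. A clause whose inputs are missing cannot fire;
    if no clause can fire at all a :class:`GradingError` is raised.
    """
    form = select_form(record.setting, record.endpoint)
    if form == Form.CURATIVE:
        raise GradingError("preliminary_score applies to non-curative forms only")
    form_rules = rules.form2a if form == Form.OS else rules.form2b
    stratum = _stratum_for(form_rules, record.median_control)

    score: Optional[int] = None
    if record.gain_months is not None:
        score = 1
        for band in stratum.bands:  # sorted descending by min_gain
            if record.gain_months >= band.min_gain:
                score = band.score
                break
        if record.ci_lower > rules.lower_ci_ceiling:
            score = min(score, 2)

    gain = _landmark_gain_at(record.landmark_survival, stratum.landmark_months)
    if gain is not None and gain >= form_rules.landmark_gain_threshold:
        score = max(score or 1, form_rules.landmark_score)

    if score is None:
        missing = ["gain_months"]
        if not record.landmark_survival:
            missing.append("landmark_survival")
        raise GradingError(
            f"{record.trial_id}: no usable effect-size inputs "
            f"(missing: {', '.join(missing)})")
    return score


def adjust(preliminary: int, qol: QolStatus, toxicity_reduced: bool,
           toxic_death_increased: bool, plateau: bool,
           form: str = Form.OS) -> str:
    """Apply QOL/toxicity/plateau adjustments to the preliminary score.

    Any number of positive adjustments collapses to a single +1 upgrade;
    an excess of toxic deaths applies a single -1 downgrade. The final
    grade is clamped to [1, 5], and to 4 for PFS-form grades.
    """
    up = 1 if (QolStatus(qol) is QolStatus.IMPROVED or toxicity_reduced or plateau) else 0
    down = 1 if toxic_death_increased else 0
    final = max(1, min(5, preliminary + up - down))
    if form == Form.PFS:
        final = min(final, 4)
    return str(final)


def curative_grade(record: TrialArmRecord, rules: EsmoRuleTable) -> str:
    """Form-1 grade: A/B by lower-CI-limit ceilings, else C."""
    if record.ci_lower is None:
        raise GradingError(f"{record.trial_id}: curative grading needs the HR CI")
    if record.ci_lower <= rules.a_max_lower_ci:
        return "A"
    if record.ci_lower <= rules.b_max_lower_ci:
        return "B"
    return "C"


def long_term_benefit(record: TrialArmRecord, rules: EsmoRuleTable) -> bool:
    """Long-term ("tail of the curve") benefit criterion.

    PFS: absolute PFS gain >= 10% at 1 year. OS: a survival advantage
    still observed at 5 years when the control median is <= 12 months,
    at 7 years otherwise. When the needed landmark is not in the record
    the published qualification flag (if any) is used; otherwise the
    criterion is not met.
    """
    if record.endpoint is Endpoint.PFS:
        gain = _landmark_gain_at(record.landmark_survival,
                                 rules.form2b.strata[0].landmark_months)
        if gain is not None:
            return gain >= rules.form2b.landmark_gain_threshold
    elif record.endpoint is Endpoint.OS:
        timepoint = (
            rules.long_term_os_short
            if record.median_control is not None and record.median_control <= 12.0
            else rules.long_term_os_long
        )
        gain = _landmark_gain_at(record.landmark_survival, timepoint)
        if gain is not None:
            return gain > 0.0
    if record.long_term_benefit_reported is not None:
        return record.long_term_benefit_reported
    return False


def _toxicity_reduced(record: TrialArmRecord) -> bool:
    if record.toxicity_reduced is not None:
        return record.toxicity_reduced
    if record.toxicity_table:
        b_c = sum(r.incidence_control for r in record.toxicity_table)
        b_e = sum(r.incidence_experimental for r in record.toxicity_table)
        return b_e < b_c
    return False


def score_esmo(record: TrialArmRecord,
               rules: Optional[EsmoRuleTable] = None, log=None) -> EsmoAssessment:
    """Full ESMO-MCBS assessment of one arm."""
    rules = rules or EsmoRuleTable.default()
    form = select_form(record.setting, record.endpoint)

    if form == Form.CURATIVE:
        grade = curative_grade(record, rules)
        if log is not None:
            log.note(record.trial_id,
                     f"form 1 grade {grade} from lower CI limit {record.ci_lower}")
        return EsmoAssessment(
            form=form, preliminary=None, upgrade_applied=False,
            downgrade_applied=False, final_grade=grade,
            meaningful_benefit=grade in MEANINGFUL_GRADES,
            long_term_benefit=False,
        )

    prelim = preliminary_score(record, rules)
    ltb = long_term_benefit(record, rules)
    # A long-term PFS plateau is an upgrade; long-term OS benefit is an
    # additional flag only (reported, never a grade change).
    plateau = ltb if form == Form.PFS else False
    tox_reduced = _toxicity_reduced(record)
    final = adjust(prelim, record.qol, tox_reduced,
                   record.toxic_death_increased, plateau, form)
    up = int(final) > prelim
    down = int(final) < prelim
    if log is not None:
        log.note(record.trial_id,
                 f"{form}: preliminary {prelim}, final {final} "
                 f"(qol={record.qol.value}, toxicity_reduced={tox_reduced}, "
                 f"toxic_death={record.toxic_death_increased}, plateau={plateau})")
    return EsmoAssessment(
        form=form, preliminary=prelim, upgrade_applied=up,
        downgrade_applied=down, final_grade=final,
        meaningful_benefit=final in MEANINGFUL_GRADES,
        long_term_benefit=ltb,
    )


def assessment_from_transcription(record: TrialArmRecord, grade: str,
                                  long_term: bool = False) -> EsmoAssessment:
    """Build an assessment from a published grade when engine inputs are absent."""
    form = select_form(record.setting, record.endpoint)
    return EsmoAssessment(
        form=form, preliminary=None, upgrade_applied=False,
        downgrade_applied=False, final_grade=str(grade),
        meaningful_benefit=str(grade) in MEANINGFUL_GRADES,
        long_term_benefit=long_term, source="transcribed",
    )
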