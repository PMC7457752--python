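"""Trial-arm data model, validation, serialization and packaged fixtures.

One :class:`TrialArmRecord` describes a single experimental arm of a
randomized trial compared against its control arm: the hazard-ratio effect
size with its confidence interval, median survival per arm, landmark
(fixed-timepoint) survival proportions, grade-3/4 adverse-event incidences,
and the quality-of-life / palliation / treatment-free-interval flags the
two value frameworks consume.

Packaged fixtures transcribe the published initial and updated assessments
of the 18 FDA-approved immune-checkpoint-inhibitor indications (23 initial
arms, 18 updated arms) together with their published score components, so
cohort results can be recomputed and audited offline.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Optional

import pandas as pd
from pydantic import BaseModel, Field, model_validator


class Setting(str, enum.Enum):
    """Treatment setting: adjuvant/curative versus advanced/non-curative."""

    CURATIVE = "curative"
    NON_CURATIVE = "non_curative"


class Endpoint(str, enum.Enum):
    """Survival endpoint the approval was graded on."""

    OS = "OS"
    PFS = "PFS"
    RFS_DFS = "RFS_DFS"


class QolStatus(str, enum.Enum):
    IMPROVED = "improved"
    NOT_IMPROVED = "not_improved"
    NOT_REPORTED = "not_reported"


class Phase(str, enum.Enum):
    INITIAL = "initial"
    UPDATED = "updated"


class ValidationFailure(Exception):
    """A record violated the schema or an internal-consistency invariant.

    Deliberately not a ValueError so pydantic propagates it unwrapped from
    model validators, keeping the record/field message intact.
    """


class LandmarkPoint(BaseModel):
    """Survival proportions read at a fixed timepoint (months)."""

    timepoint_months: float = Field(gt=0)
    surv_control: float = Field(ge=0.0, le=1.0)
    surv_experimental: float = Field(ge=0.0, le=1.0)


class ToxicityRow(BaseModel):
    """Grade-3/4 adverse-event incidence (fraction of patients) per arm."""

    ae_name: str
    incidence_control: float = Field(ge=0.0, le=1.0)
    incidence_experimental: float = Field(ge=0.0, le=1.0)


class TrialArmRecord(BaseModel):
    """One experimental arm versus control, with everything both frameworks need.

    ``toxicity_points_override`` and ``tail_bonus_override`` carry published
    score components when the underlying raw inputs (adverse-event tables,
    landmark survival at twice the control median) are not available;
    ``toxicity_reduced`` and ``long_term_benefit_reported`` likewise carry
    published ESMO-MCBS input flags that cannot be derived from the other
    fields. Scoring engines always prefer raw inputs when present.
    """

    trial_id: str
    indication_id: str
    drug: str = ""
    cancer_type: str = ""
    year_approved: Optional[int] = None
    setting: Setting = Setting.NON_CURATIVE
    endpoint: Endpoint = Endpoint.OS

    hr: float = Field(gt=0)
    ci_lower: float = Field(gt=0)
    ci_upper: float = Field(gt=0)
    ci_level: float = Field(default=95.0, gt=50.0, lt=100.0)

    median_control: Optional[float] = Field(default=None, gt=0)
    median_experimental: Optional[float] = Field(default=None, gt=0)
    gain_months: Optional[float] = None

    landmark_survival: list[LandmarkPoint] = Field(default_factory=list)
    toxicity_table: list[ToxicityRow] = Field(default_factory=list)
    toxicity_points_override: Optional[float] = Field(default=None, ge=-20.0, le=20.0)
    tail_bonus_override: Optional[int] = None

    qol: QolStatus = QolStatus.NOT_REPORTED
    toxicity_reduced: Optional[bool] = None
    palliation_improved: bool = False
    tfi_improved: bool = False
    toxic_death_increased: bool = False
    long_term_benefit_reported: Optional[bool] = None

    assessment_phase: Phase = Phase.INITIAL
    extra: dict[str, Any] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check_consistency(self) -> "TrialArmRecord":
        if not (self.ci_lower <= self.hr <= self.ci_upper):
            raise ValidationFailure(
                f"{self.trial_id}: CI must bracket HR "
                f"(got {self.ci_lower} <= {self.hr} <= {self.ci_upper})"
            )
        if self.median_control is not None and self.median_experimental is not None:
            derived = self.median_experimental - self.median_control
            if self.gain_months is None:
                self.gain_months = derived
            elif not math.isclose(self.gain_months, derived, abs_tol=1e-6):
                raise ValidationFailure(
                    f"{self.trial_id}: gain_months={self.gain_months} inconsistent "
                    f"with medians (expected {derived:.6g})"
                )
        tps = [p.timepoint_months for p in self.landmark_survival]
        if any(b <= a for a, b in zip(tps, tps[1:])):
            raise ValidationFailure(
                f"{self.trial_id}: landmark timepoints must be strictly increasing"
            )
        if self.tail_bonus_override is not None and self.tail_bonus_override not in (0, 16, 20):
            raise ValidationFailure(
                f"{self.trial_id}: tail_bonus_override must be one of 0/16/20"
            )
        if self.setting is Setting.CURATIVE and self.endpoint is Endpoint.PFS:
            # Adjuvant approvals are graded on recurrence-free survival
            # (or overall survival in updated reports), never PFS.
            raise ValidationFailure(
                f"{self.trial_id}: curative setting cannot be graded on PFS"
            )
        return self


@dataclass
class ExpectedScores:
    """Published per-arm score components, for regression auditing."""

    treatment_effect: float
    toxicity: float
    tail: float
    palliation: float
    qol: float
    tfi: float
    nhb: float
    esmo_grade: str

    def component_sum(self) -> float:
        return (
            self.treatment_effect + self.toxicity + self.tail
            + self.palliation + self.qol + self.tfi
        )


@dataclass
class FixtureSet:
    """Packaged trial records plus the published scores they should reproduce."""

    phase: Phase
    records: list[TrialArmRecord]
    expected: dict[str, ExpectedScores] = field(default_factory=dict)

    @property
    def indication_ids(self) -> list[str]:
        seen: list[str] = []
        for r in self.records:
            if r.indication_id not in seen:
                seen.append(r.indication_id)
        return seen


# CSV cells holding list-valued fields are JSON-encoded.
_LIST_FIELDS = ("landmark_survival", "toxicity_table")
_BOOL_FIELDS = (
    "palliation_improved", "tfi_improved", "toxic_death_increased",
    "toxicity_reduced", "long_term_benefit_reported",
)
_RECORD_FIELDS = [
    f for f in TrialArmRecord.model_fields if f != "extra"
]


def _parse_bool(value: Any) -> Optional[bool]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in ("", "na", "none", "nan"):
        return None
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no"):
        return False
    raise ValidationFailure(f"unparseable boolean value: {value!r}")


def _row_to_record(row: dict[str, Any]) -> TrialArmRecord:
    kwargs: dict[str, Any] = {}
    extra: dict[str, Any] = {}
    for key, value in row.items():
        if isinstance(value, float) and math.isnan(value):
            value = None
        if key not in _RECORD_FIELDS:
            if value is not None:
                extra[key] = value
            continue
        if key in _LIST_FIELDS:
            if value in (None, ""):
                value = []
            elif isinstance(value, str):
                value = json.loads(value)
            if key == "landmark_survival":
                value = [
                    LandmarkPoint(
                        timepoint_months=p[0], surv_control=p[1], surv_experimental=p[2]
                    )
                    if isinstance(p, (list, tuple)) else p
                    for p in value
                ]
            else:
                value = [
                    ToxicityRow(
                        ae_name=p[0], incidence_control=p[1], incidence_experimental=p[2]
                    )
                    if isinstance(p, (list, tuple)) else p
                    for p in value
                ]
        elif key in _BOOL_FIELDS:
            value = _parse_bool(value)
            if value is None and key not in ("toxicity_reduced", "long_term_benefit_reported"):
                value = False
        if value is not None:
            kwargs[key] = value
    missing = [k for k in ("trial_id", "indication_id", "hr", "ci_lower", "ci_upper") if k not in kwargs]
    if missing:
        ident = kwargs.get("trial_id", "<unknown>")
        raise ValidationFailure(f"record {ident}: missing mandatory field(s) {missing}")
    kwargs["extra"] = extra
    return TrialArmRecord(**kwargs)


def _record_to_row(record: TrialArmRecord) -> dict[str, Any]:
    row: dict[str, Any] = {}
    for key in _RECORD_FIELDS:
        value = getattr(record, key)
        if isinstance(value, enum.Enum):
            value = value.value
        elif key == "landmark_survival":
            value = json.dumps(
                [[p.timepoint_months, p.surv_control, p.surv_experimental] for p in value]
            ) if value else ""
        elif key == "toxicity_table":
            value = json.dumps(
                [[p.ae_name, p.incidence_control, p.incidence_experimental] for p in value]
            ) if value else ""
        row[key] = value
    row.update(record.extra)
    return row


def read_trial_table(path: str | Path, format: str = "csv") -> list[TrialArmRecord]:
    """Read trial-arm records from a CSV or JSON table.

    Unknown columns are preserved in each record's ``extra`` metadata dict.
    Raises :class:`ValidationFailure` naming the record and field on any
    schema violation.
    """
    path = Path(path)
    if format == "csv":
        frame = pd.read_csv(path)
        rows = frame.to_dict(orient="records")
    elif format == "json":
        with open(path) as fh:
            doc = json.load(fh)
        rows = doc["records"] if isinstance(doc, dict) else doc
    else:
        raise ValueError(f"unknown format {format!r} (expected 'csv' or 'json')")
    return [_row_to_record(dict(row)) for row in rows]


def write_trial_table(records: list[TrialArmRecord], path: str | Path,
                      format: str = "csv") -> None:
    """Write records to CSV (list fields as JSON strings in cells) or JSON."""
    path = Path(path)
    rows = [_record_to_row(r) for r in records]
    if format == "csv":
        pd.DataFrame(rows).to_csv(path, index=False)
    elif format == "json":
        for row in rows:
            for key in _LIST_FIELDS:
                row[key] = json.loads(row[key]) if row[key] else []
        with open(path, "w") as fh:
            json.dump({"records": rows}, fh, indent=1, default=str)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'csv' or 'json')")


_EXPECTED_COLS = {
    "expected_treatment_effect": "treatment_effect",
    "expected_toxicity": "toxicity",
    "expected_tail": "tail",
    "expected_palliation": "palliation",
    "expected_qol": "qol",
    "expected_tfi": "tfi",
    "expected_nhb": "nhb",
    "expected_esmo_grade": "esmo_grade",
}

_FIXTURE_FILES = {
    Phase.INITIAL: "table_initial_assessments.csv",
    Phase.UPDATED: "table_updated_assessments.csv",
}


def load_fixtures(phase: str | Phase) -> FixtureSet:
    """Load the packaged transcription of the published assessments.

    ``phase='initial'`` returns the 23 arms of the 18 pivotal-trial
    assessments; ``phase='updated'`` the 18 re-assessed arms.
    """
    phase = Phase(phase)
    with resources.as_file(
        resources.files("oncovalue.data") / _FIXTURE_FILES[phase]
    ) as fp:
        records = read_trial_table(fp, format="csv")
    expected: dict[str, ExpectedScores] = {}
    for rec in records:
        vals = {short: rec.extra[col] for col, short in _EXPECTED_COLS.items()}
        vals["esmo_grade"] = str(vals["esmo_grade"])
        expected[rec.trial_id] = ExpectedScores(**vals)
    return FixtureSet(phase=phase, records=records, expected=expected)
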