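"""ASCO Value Framework (2016 update) net-health-benefit scoring.

The NHB of an experimental arm is the sum of six components:

* treatment-effect points, ``(1 - HR) * 100`` weighted 1.0 for overall
  survival and recurrence/disease-free survival, 0.8 for progression-free
  survival;
* toxicity points in [-20, 20], from grade-3/4 adverse-event burdens;
* a tail-of-the-curve bonus (20 points, or 16 for PFS) when survival at
  twice the control-arm median is improved by at least 50% relative and
  control-arm survival there is at least 20%;
* 10-point bonuses each for palliation of cancer-related symptoms,
  improved quality of life, and improved treatment-free interval.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

from .trial_data import Endpoint, LandmarkPoint, Setting, ToxicityRow, TrialArmRecord


class ScoringError(ValueError):
    """Raised when a score component cannot be computed from the inputs."""


#: PFS improvements carry 0.8 of the OS weight throughout the framework.
ENDPOINT_WEIGHT = {Endpoint.OS: 1.0, Endpoint.PFS: 0.8, Endpoint.RFS_DFS: 1.0}

#: Landmark timepoints within +/-10% of twice the control median qualify.
TAIL_TIMEPOINT_TOLERANCE = 0.10
TAIL_CONTROL_FLOOR = 0.20
TAIL_RELATIVE_IMPROVEMENT = 1.5


@dataclass(frozen=True)
class AscoBreakdown:
    """Per-component ASCO-VF score; ``nhb`` is the exact component sum."""

    treatment_effect_points: float
    toxicity_points: float
    tail_bonus: int
    palliation_bonus: int
    qol_bonus: int
    tfi_bonus: int

    @property
    def nhb(self) -> float:
        return (
            self.treatment_effect_points + self.toxicity_points + self.tail_bonus
            + self.palliation_bonus + self.qol_bonus + self.tfi_bonus
        )

    def rounded(self) -> dict[str, float]:
        """Components rounded to one decimal for reporting."""
        return {
            "treatment_effect_points": round(self.treatment_effect_points, 1),
            "toxicity_points": round(self.toxicity_points, 1),
            "tail_bonus": self.tail_bonus,
            "palliation_bonus": self.palliation_bonus,
            "qol_bonus": self.qol_bonus,
            "tfi_bonus": self.tfi_bonus,
            "nhb": round(self.nhb, 1),
        }


def treatment_effect_points(hr: float, endpoint: Endpoint,
                            setting: Setting = Setting.NON_CURATIVE) -> float:
    """Clinical-benefit points from the hazard-ratio point estimate.

    ``(1 - hr) * 100 * w`` with w = 1.0 for OS and RFS/DFS, 0.8 for PFS.
    A null or harmful effect (hr >= 1) yields zero or negative points;
    negative values are deliberately not floored.
    """
    if hr <= 0:
        raise ScoringError(f"hazard ratio must be positive, got {hr}")
    return (1.0 - hr) * 100.0 * ENDPOINT_WEIGHT[Endpoint(endpoint)]


def toxicity_points(toxicity_table: Sequence[ToxicityRow] | None,
                    override: Optional[float] = None) -> float:
    """Toxicity points in [-20, 20] from per-arm grade-3/4 AE burdens.

    With raw incidence tables, the per-arm burden is the unweighted sum of
    incidences; the score is the relative burden difference scaled to the
    +/-20 band: ``20 * (B_control - B_experimental) / max(B_c, B_e)``,
    clamped. Equal burdens (including both zero) score 0. A published
    ``override`` value, when given, is returned unchanged.
    """
    if override is not None:
        if not -20.0 <= override <= 20.0:
            raise ScoringError(f"toxicity override {override} outside [-20, 20]")
        return float(override)
    if not toxicity_table:
        raise ScoringError(
            "toxicity scoring needs a grade-3/4 AE incidence table or an "
            "explicit toxicity_points_override"
        )
    b_control = sum(row.incidence_control for row in toxicity_table)
    b_experimental = sum(row.incidence_experimental for row in toxicity_table)
    denom = max(b_control, b_experimental)
    if denom == 0:
        return 0.0
    score = 20.0 * (b_control - b_experimental) / denom
    return max(-20.0, min(20.0, score))


class TailStatus(str, enum.Enum):
    QUALIFIED = "qualified"
    NOT_QUALIFIED = "not_qualified"
    NOT_AVAILABLE = "not_available"


@dataclass(frozen=True)
class TailOutcome:
    bonus: int
    status: TailStatus
    detail: str


def evaluate_tail(endpoint: Endpoint, median_control: Optional[float],
                  landmark_survival: Sequence[LandmarkPoint] | None) -> TailOutcome:
    """Apply the tail-of-the-curve rule, distinguishing its failure modes.

    ``NOT_AVAILABLE`` covers limited follow-up (no landmark near twice the
    control median) or a missing control median; ``NOT_QUALIFIED`` means the
    landmark exists but the 20%-floor or 50%-improvement condition failed.
    """
    endpoint = Endpoint(endpoint)
    award = 16 if endpoint is Endpoint.PFS else 20
    if median_control is None or not landmark_survival:
        return TailOutcome(0, TailStatus.NOT_AVAILABLE,
                           "no control median or landmark survival data")
    target = 2.0 * median_control
    tol = TAIL_TIMEPOINT_TOLERANCE * target
    candidates = [p for p in landmark_survival
                  if abs(p.timepoint_months - target) <= tol]
    if not candidates:
        return TailOutcome(
            0, TailStatus.NOT_AVAILABLE,
            f"no landmark within 10% of {target:.1f} months (limited follow-up)")
    point = min(candidates, key=lambda p: abs(p.timepoint_months - target))
    if point.surv_control < TAIL_CONTROL_FLOOR:
        return TailOutcome(
            0, TailStatus.NOT_QUALIFIED,
            f"control survival {point.surv_control:.2f} below the 20% floor "
            f"at {point.timepoint_months:.1f} months")
    if point.surv_experimental < TAIL_RELATIVE_IMPROVEMENT * point.surv_control:
        return TailOutcome(
            0, TailStatus.NOT_QUALIFIED,
            f"experimental survival {point.surv_experimental:.2f} below 1.5x "
            f"control ({point.surv_control:.2f}) at {point.timepoint_months:.1f} months")
    return TailOutcome(
        award, TailStatus.QUALIFIED,
        f"survival {point.surv_experimental:.2f} vs {point.surv_control:.2f} "
        f"at {point.timepoint_months:.1f} months")


def tail_of_curve_bonus(endpoint: Endpoint, median_control: Optional[float],
                        landmark_survival: Sequence[LandmarkPoint] | None) -> int:
    """Tail-of-the-curve bonus: 20 for OS/RFS-DFS, 16 for PFS, else 0."""
    return evaluate_tail(endpoint, median_control, landmark_survival).bonus


def flag_bonus(flag: bool) -> int:
    """10 bonus points for a statistically significant improvement flag."""
    return 10 if flag else 0


def score_asco(record: TrialArmRecord, log=None) -> AscoBreakdown:
    """Compose the full ASCO-VF breakdown for one trial arm.

    Published component overrides on the record (toxicity points, tail
    bonus) take precedence over derivation from raw inputs; every
    substitution is noted on ``log`` (any object with ``note(arm, msg)``).
    """
    te = treatment_effect_points(record.hr, record.endpoint, record.setting)
    tox = toxicity_points(record.toxicity_table or None,
                          record.toxicity_points_override)
    if log is not None and record.toxicity_points_override is not None:
        log.note(record.trial_id,
                 f"toxicity points {record.toxicity_points_override} taken from override")
    if record.tail_bonus_override is not None:
        tail = record.tail_bonus_override
        if log is not None:
            log.note(record.trial_id, f"tail bonus {tail} taken from override")
    else:
        outcome = evaluate_tail(record.endpoint, record.median_control,
                                record.landmark_survival)
        tail = outcome.bonus
        if log is not None:
            log.note(record.trial_id,
                     f"tail bonus {tail} ({outcome.status.value}: {outcome.detail})")
    from .trial_data import QolStatus  # local to avoid re-export confusion

    return AscoBreakdown(
        treatment_effect_points=te,
        toxicity_points=tox,
        tail_bonus=tail,
        palliation_bonus=flag_bonus(record.palliation_improved),
        qol_bonus=flag_bonus(record.qol is QolStatus.IMPROVED),
        tfi_bonus=flag_bonus(record.tfi_improved),
    )
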