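"""Patient cohort handling and CIPN phenotyping from FACT-Ntx scores.

The FACT-Ntx neurotoxicity subscale is a patient-reported outcome on a 0-44
integer scale where a *higher* score means *less* neuropathy.  Chemotherapy-
induced peripheral neuropathy (CIPN) is called when a patient's score worsens
(drops) by at least 20% relative to baseline at any follow-up visit
(completion of taxane therapy, 6 months, or 12 months).  Patients are thereby
split into two groups: group 1 (CIPN) and group 2 (no meaningful change).

This module holds the domain types for patients and their score trajectories,
the classification rule, and the descriptive arithmetic used to summarise
baseline demographics per group (counts, percentages, means, SDs).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

FACT_NTX_MIN = 0
FACT_NTX_MAX = 44

#: Fractional worsening from baseline at or above which CIPN is called.
CIPN_WORSENING_THRESHOLD = 0.20


class Timepoint(str, enum.Enum):
    """Assessment visits; serum is drawn at baseline (T0) and month 12 (T12)."""

    BASELINE = "baseline"
    COMPLETION = "completion"
    MONTH6 = "month6"
    MONTH12 = "month12"


FOLLOWUP_TIMEPOINTS: tuple[Timepoint, ...] = (
    Timepoint.COMPLETION,
    Timepoint.MONTH6,
    Timepoint.MONTH12,
)


class GroupLabel(str, enum.Enum):
    GROUP1_CIPN = "group1_cipn"
    GROUP2_STABLE = "group2_stable"


class UndefinedChangeError(ValueError):
    """Raised when a percent change from baseline cannot be expressed."""


def _validate_score(score: int, what: str) -> int:
    if not isinstance(score, (int, np.integer)) or isinstance(score, bool):
        raise ValueError(f"{what} must be an integer, got {score!r}")
    if not FACT_NTX_MIN <= score <= FACT_NTX_MAX:
        raise ValueError(
            f"{what} must lie in [{FACT_NTX_MIN}, {FACT_NTX_MAX}], got {score}"
        )
    return int(score)


@dataclass(frozen=True)
class FactNtxAssessment:
    """One FACT-Ntx score for one patient at one visit."""

    patient_id: str
    timepoint: Timepoint
    score: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "timepoint", Timepoint(self.timepoint))
        object.__setattr__(
            self, "score", _validate_score(self.score, "FACT-Ntx score")
        )


# Demographic fields summarised as categorical variables, in Table-style order.
CATEGORICAL_FIELDS: tuple[str, ...] = (
    "race",
    "ethnicity",
    "smoking",
    "alcohol_per_week",
    "menopause",
    "stage",
    "er_status",
    "pr_status",
    "her2_status",
    "taxane_regimen",
    "prior_chemo",
)

CONTINUOUS_FIELDS: tuple[str, ...] = ("age_years", "bmi")


@dataclass
class PatientRecord:
    """Demographics, clinical characteristics and the FACT-Ntx trajectory."""

    patient_id: str
    age_years: float
    race: str
    ethnicity: str
    smoking: str
    alcohol_per_week: str
    bmi: float
    menopause: str
    stage: str
    er_status: str
    pr_status: str
    her2_status: str
    taxane_regimen: str
    prior_chemo: str
    assessments: list[FactNtxAssessment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be nonempty")
        if not self.age_years >= 18:
            raise ValueError(f"age_years must be >= 18, got {self.age_years}")
        if not self.bmi > 0:
            raise ValueError(f"bmi must be positive, got {self.bmi}")
        seen: set[Timepoint] = set()
        for a in self.assessments:
            if a.patient_id != self.patient_id:
                raise ValueError(
                    f"assessment for {a.patient_id!r} attached to patient "
                    f"{self.patient_id!r}"
                )
            if a.timepoint in seen:
                raise ValueError(
                    f"duplicate assessment at {a.timepoint.value} for patient "
                    f"{self.patient_id!r}"
                )
            seen.add(a.timepoint)

    def score_at(self, timepoint: Timepoint) -> int | None:
        timepoint = Timepoint(timepoint)
        for a in self.assessments:
            if a.timepoint is timepoint:
                return a.score
        return None

    @property
    def baseline_score(self) -> int | None:
        return self.score_at(Timepoint.BASELINE)

    def followup_scores(self) -> dict[Timepoint, int]:
        return {
            tp: s
            for tp in FOLLOWUP_TIMEPOINTS
            if (s := self.score_at(tp)) is not None
        }


def percent_worsening(baseline: int, followup: int) -> float:
    """Fractional worsening from ``baseline`` to ``followup``.

    Positive values mean the score dropped (more neuropathy); negative values
    mean improvement.  A baseline of 0 has no defined percent change and is
    rejected rather than treated as infinite worsening.
    """
    baseline = _validate_score(baseline, "baseline score")
    followup = _validate_score(followup, "follow-up score")
    if baseline == 0:
        raise UndefinedChangeError(
            "percent worsening is undefined for a baseline score of 0"
        )
    return (baseline - followup) / baseline


def classify_cipn(
    patient: PatientRecord,
    threshold: float = CIPN_WORSENING_THRESHOLD,
) -> GroupLabel:
    """Apply the >=20%-worsening rule over all available follow-up visits.

    The rule is inclusive at the boundary: a worst-case worsening of exactly
    ``threshold`` classifies as CIPN.  Missing intermediate visits are
    allowed; a patient with no follow-up at all cannot be classified and is
    rejected rather than silently called stable.
    """
    baseline = patient.baseline_score
    if baseline is None:
        raise ValueError(
            f"patient {patient.patient_id!r} has no baseline assessment"
        )
    followups = patient.followup_scores()
    if not followups:
        raise ValueError(
            f"patient {patient.patient_id!r} has no follow-up assessments"
        )
    worst = max(percent_worsening(baseline, s) for s in followups.values())
    if worst >= threshold:
        return GroupLabel.GROUP1_CIPN
    return GroupLabel.GROUP2_STABLE


def pooled_mean(group_means: Sequence[tuple[float, int]]) -> float:
    """Size-weighted combination of per-group means: sum(n_i m_i) / sum(n_i)."""
    if len(group_means) == 0:
        raise ValueError("pooled_mean requires at least one (mean, n) pair")
    for m, n in group_means:
        if n < 1:
            raise ValueError(f"group size must be >= 1, got {n}")
    total = sum(n for _, n in group_means)
    return sum(m * n for m, n in group_means) / total


def percentage(count: int, total: int, ndigits: int = 2) -> float:
    """Percentage of ``count`` out of ``total``, rounded for reporting."""
    if total <= 0:
        raise ValueError("percentage denominator must be positive")
    return round(100.0 * count / total, ndigits)


SUMMARY_COLUMNS = (
    "variable",
    "level",
    "group1_n",
    "group1_pct",
    "group2_n",
    "group2_pct",
    "total_n",
    "total_pct",
)


def summarize_cohort(
    patients: Sequence[PatientRecord],
    labels: Mapping[str, GroupLabel],
) -> pd.DataFrame:
    """Per-group and overall demographic summary table.

    Categorical rows carry counts and percentages (denominator = group size,
    2 d.p.).  Continuous variables (age, BMI) carry mean, SD, and — because
    prose and tables sometimes disagree on which is meant — the median, in the
    ``*_n`` columns with percentage columns left empty.  Raw (unrounded)
    values are used internally; only percentages are rounded here.
    """
    if not patients:
        raise ValueError("summarize_cohort requires at least one patient")
    for p in patients:
        if p.patient_id not in labels:
            raise ValueError(f"patient {p.patient_id!r} has no group label")

    g1 = [p for p in patients if labels[p.patient_id] is GroupLabel.GROUP1_CIPN]
    g2 = [p for p in patients if labels[p.patient_id] is GroupLabel.GROUP2_STABLE]
    groups = {"group1": g1, "group2": g2, "total": list(patients)}

    rows: list[dict] = []

    def _stat_row(variable: str, stat: str, fn) -> dict:
        row: dict = {"variable": variable, "level": stat}
        for key, members in groups.items():
            vals = [getattr(p, variable) for p in members]
            row[f"{key}_n"] = fn(vals) if vals else math.nan
            row[f"{key}_pct"] = math.nan
        return row

    for var in CONTINUOUS_FIELDS:
        rows.append(_stat_row(var, "mean", lambda v: float(np.mean(v))))
        rows.append(_stat_row(var, "sd", lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else math.nan))
        rows.append(_stat_row(var, "median", lambda v: float(np.median(v))))

    for var in CATEGORICAL_FIELDS:
        levels = sorted({getattr(p, var) for p in patients})
        for level in levels:
            row = {"variable": var, "level": level}
            for key, members in groups.items():
                n = sum(1 for p in members if getattr(p, var) == level)
                row[f"{key}_n"] = n
                row[f"{key}_pct"] = (
                    percentage(n, len(members)) if members else 0.00
                )
            rows.append(row)

    return pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS))


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

_SCORE_COLUMNS = {tp: f"fact_ntx_{tp.value}" for tp in Timepoint}


def write_cohort_csv(patients: Sequence[PatientRecord], path) -> None:
    """One row per patient: demographics plus per-visit FACT-Ntx columns."""
    rows = []
    for p in patients:
        row = {
            "patient_id": p.patient_id,
            "age_years": p.age_years,
            "race": p.race,
            "ethnicity": p.ethnicity,
            "smoking": p.smoking,
            "alcohol_per_week": p.alcohol_per_week,
            "bmi": p.bmi,
            "menopause": p.menopause,
            "stage": p.stage,
            "er_status": p.er_status,
            "pr_status": p.pr_status,
            "her2_status": p.her2_status,
            "taxane_regimen": p.taxane_regimen,
            "prior_chemo": p.prior_chemo,
        }
        for tp, col in _SCORE_COLUMNS.items():
            s = p.score_at(tp)
            row[col] = "" if s is None else s
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cohort_csv(path) -> list[PatientRecord]:
    df = pd.read_csv(path, dtype={"patient_id": str})
    patients = []
    for _, row in df.iterrows():
        assessments = []
        for tp, col in _SCORE_COLUMNS.items():
            if col in row and pd.notna(row[col]) and row[col] != "":
                assessments.append(
                    FactNtxAssessment(
                        patient_id=row["patient_id"],
                        timepoint=tp,
                        score=int(row[col]),
                    )
                )
        patients.append(
            PatientRecord(
                patient_id=row["patient_id"],
                age_years=float(row["age_years"]),
                race=row["race"],
                ethnicity=row["ethnicity"],
                smoking=row["smoking"],
                alcohol_per_week=row["alcohol_per_week"],
                bmi=float(row["bmi"]),
                menopause=row["menopause"],
                stage=str(row["stage"]),
                er_status=row["er_status"],
                pr_status=row["pr_status"],
                her2_status=row["her2_status"],
                taxane_regimen=row["taxane_regimen"],
                prior_chemo=row["prior_chemo"],
                assessments=assessments,
            )
        )
    return patients


def write_summary_csv(summary: pd.DataFrame, path) -> None:
    summary.to_csv(path, index=False)
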