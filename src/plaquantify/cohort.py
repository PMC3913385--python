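"""Subject-level data model, exclusion rules, and per-subject aggregation.

A case-control antenatal cohort: "case" means the pregnancy was clinically
judged at high risk of preterm delivery, "control" not at risk. Each
retained subject contributes the mean plaque coverage and mean red
fluorescence (dR%) over her 10-12 natural anterior teeth (FDI 13-23 and
33-43).

Exclusion rules, applied in a fixed order with each subject logged once
under the first rule that fires:

1. fewer than 10 natural anterior teeth;
2. recent antibiotic use (a supplied boolean; no time-window logic);
3. missing BMI, smoking status or maternal age;
4. withdrawn / no images captured (no tooth measurements).

Only a subject's first visit enters the analysis; repeat visits are
dropped (and logged) to avoid Hawthorne-effect bias from subjects who knew
their plaque was being imaged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import pandas as pd

from .errors import DataError
from .plaque_segmentation import CoverageResult
from .red_fluorescence import DeltaRResult

__all__ = [
    "SubjectRecord",
    "SubjectSummary",
    "apply_exclusions",
    "summarize_subject",
    "classify_delivery",
    "read_cohort_csv",
    "cohort_to_frame",
]

Group = Literal["case", "control"]
Smoking = Literal["nonsmoker", "stopped", "smoker"]

SMOKING_LEVELS: tuple[str, ...] = ("nonsmoker", "stopped", "smoker")
#: ordinal encoding used by the logistic model
SMOKING_CODE = {"nonsmoker": 0, "stopped": 1, "smoker": 2}


def _missing(v) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and math.isnan(v):
        return True
    if isinstance(v, str) and v.strip() == "":
        return True
    return False


@dataclass
class SubjectRecord:
    """One subject-visit row with covariates and per-tooth measurements."""

    subject_id: str
    group: Group
    maternal_age: float | None
    bmi: float | None
    smoking: Smoking | None
    natural_anterior_teeth: int
    antibiotics_recent: bool
    visit_index: int = 1
    delivery_weeks: float | None = None
    tooth_measurements: list[tuple[CoverageResult, DeltaRResult]] = field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        if self.group not in ("case", "control"):
            raise DataError(f"group must be 'case' or 'control', got {self.group!r}")
        if not 0 <= self.natural_anterior_teeth <= 12:
            raise DataError(
                f"natural_anterior_teeth must be 0-12, got {self.natural_anterior_teeth}"
            )
        if self.visit_index < 1:
            raise DataError("visit_index must be >= 1")
        if self.delivery_weeks is not None and not _missing(self.delivery_weeks):
            if not 20 < self.delivery_weeks < 45:
                raise DataError(
                    f"delivery_weeks {self.delivery_weeks} outside plausible (20, 45)"
                )
        if self.smoking is not None and not _missing(self.smoking):
            if self.smoking not in SMOKING_LEVELS:
                raise DataError(f"unknown smoking level {self.smoking!r}")


@dataclass
class SubjectSummary:
    """Per-subject means over measured teeth plus copied covariates."""

    subject_id: str
    group: Group
    mean_coverage_pct: float
    mean_delta_r_pct: float
    n_teeth_measured: int
    maternal_age: float | None = None
    bmi: float | None = None
    smoking: Smoking | None = None
    delivery_weeks: float | None = None


def apply_exclusions(
    records: Sequence[SubjectRecord],
) -> tuple[list[SubjectRecord], list[tuple[str, str]]]:
    """Apply the study's exclusion filters.

    Returns the retained records and a log of ``(subject_id, reason)``
    pairs; reasons are ``repeat_visit``, ``insufficient_teeth``,
    ``antibiotics``, ``missing_covariates`` and ``withdrawn_or_no_images``.
    Retained + excluded counts always equal the input count, and the
    filter is idempotent.
    """
    seen: set[tuple[str, int]] = set()
    for rec in records:
        key = (rec.subject_id, rec.visit_index)
        if key in seen:
            raise DataError(f"duplicate (subject_id, visit_index) row {key}")
        seen.add(key)

    retained: list[SubjectRecord] = []
    log: list[tuple[str, str]] = []
    for rec in records:
        if rec.visit_index != 1:
            log.append((rec.subject_id, "repeat_visit"))
        elif rec.natural_anterior_teeth < 10:
            log.append((rec.subject_id, "insufficient_teeth"))
        elif rec.antibiotics_recent:
            log.append((rec.subject_id, "antibiotics"))
        elif _missing(rec.bmi) or _missing(rec.smoking) or _missing(rec.maternal_age):
            log.append((rec.subject_id, "missing_covariates"))
        elif not rec.tooth_measurements:
            log.append((rec.subject_id, "withdrawn_or_no_images"))
        else:
            retained.append(rec)
    return retained, log


def summarize_subject(record: SubjectRecord) -> SubjectSummary:
    """Arithmetic means of coverage and dR% over the subject's teeth."""
    n = len(record.tooth_measurements)
    if n == 0:
        raise DataError(f"subject {record.subject_id}: no tooth measurements")
    cov = sum(c.coverage_pct for c, _ in record.tooth_measurements) / n
    dr = sum(d.delta_r_pct for _, d in record.tooth_measurements) / n
    return SubjectSummary(
        subject_id=record.subject_id,
        group=record.group,
        mean_coverage_pct=cov,
        mean_delta_r_pct=dr,
        n_teeth_measured=n,
        maternal_age=record.maternal_age,
        bmi=record.bmi,
        smoking=record.smoking,
        delivery_weeks=record.delivery_weeks,
    )


DELIVERY_BINS: tuple[str, ...] = ("extreme", "moderate", "mild", "term")


def classify_delivery(delivery_weeks: float | None) -> str:
    """Bin gestational age at delivery.

    Half-open bins: < 28 weeks ``extreme``, 28 to < 34 ``moderate``,
    34 to < 37 ``mild``, >= 37 ``term``; preterm means < 37 completed
    weeks. A missing value maps to ``"unknown"`` and is left out of
    outcome tabulations.
    """
    if delivery_weeks is None or _missing(delivery_weeks):
        return "unknown"
    w = float(delivery_weeks)
    if w < 28:
        return "extreme"
    if w < 34:
        return "moderate"
    if w < 37:
        return "mild"
    return "term"


# ---------------------------------------------------------------------------
# CSV interface


_COHORT_COLUMNS = [
    "subject_id",
    "group",
    "maternal_age",
    "bmi",
    "smoking",
    "natural_anterior_teeth",
    "antibiotics_recent",
    "visit_index",
    "delivery_weeks",
]


def read_cohort_csv(path) -> list[SubjectRecord]:
    """Read subject rows (without tooth measurements) from CSV.

    Columns: subject_id, group, maternal_age, bmi,
    smoking {nonsmoker|stopped|smoker}, natural_anterior_teeth,
    antibiotics_recent {0|1}, visit_index, delivery_weeks (blank allowed).
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing_cols = set(_COHORT_COLUMNS) - set(df.columns)
    if missing_cols:
        raise DataError(f"cohort CSV missing columns: {sorted(missing_cols)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            SubjectRecord(
                subject_id=str(row.subject_id),
                group=str(row.group),
                maternal_age=None if _missing(row.maternal_age) else float(row.maternal_age),
                bmi=None if _missing(row.bmi) else float(row.bmi),
                smoking=None if _missing(row.smoking) else str(row.smoking),
                natural_anterior_teeth=int(row.natural_anterior_teeth),
                antibiotics_recent=bool(int(row.antibiotics_recent)),
                visit_index=int(row.visit_index),
                delivery_weeks=None
                if _missing(row.delivery_weeks)
                else float(row.delivery_weeks),
            )
        )
    return records


def cohort_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Subject rows as a DataFrame (tooth measurements not included)."""
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "group": [r.group for r in records],
            "maternal_age": [r.maternal_age for r in records],
            "bmi": [r.bmi for r in records],
            "smoking": [r.smoking for r in records],
            "natural_anterior_teeth": [r.natural_anterior_teeth for r in records],
            "antibiotics_recent": [int(r.antibiotics_recent) for r in records],
            "visit_index": [r.visit_index for r in records],
            "delivery_weeks": [r.delivery_weeks for r in records],
        }
    )
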