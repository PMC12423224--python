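"""Cohort inclusion rules applied before subtype classification.

Individuals enter the four-cluster (SIDD/SIRD/MOD/MARD) system only when
(a) all variables needed for centroid assignment are available, (b) fasting
glucose and C-peptide lie inside the acceptable range for HOMA computation
(3.0-25.0 mmol/l and 0.2-3.5 nmol/l, endpoints inclusive), and (c) GAD
autoantibodies are below the positivity cut-off of 2 U/ml — GADA-positive
individuals belong to the autoimmune SAID subtype and are excluded here.

Each record receives a decision listing *every* violated rule; the cohort
summary additionally tallies a single primary reason per excluded record
(missing data > glucose out of range > C-peptide out of range > GADA
positive) so that exclusion counts partition the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Iterable, Mapping, Optional, Sequence

import math

import pandas as pd

__all__ = [
    "CohortRecord",
    "EligibilityDecision",
    "EligibilityThresholds",
    "REASON_PRECEDENCE",
    "apply_eligibility",
    "filter_cohort",
    "records_from_frame",
]

#: Primary-reason order used for the mutually exclusive summary tally.
REASON_PRECEDENCE = (
    "missing_clustering_variable",
    "glucose_out_of_range",
    "c_peptide_out_of_range",
    "gada_positive",
    "hba1c_above_max",
)

_CLUSTERING_FIELDS = ("age_at_diagnosis", "bmi", "hba1c", "homa2_b", "homa2_ir")


def _is_missing(value) -> bool:
    if value is None:
        return True
    try:
        return math.isnan(float(value))
    except (TypeError, ValueError):
        return False


@dataclass(frozen=True)
class CohortRecord:
    """One individual's raw features and optional eligibility/outcome fields.

    Units: age in years, BMI in kg/m^2, HbA1c in mmol/mol, HOMA2-B and
    HOMA2-IR unitless, fasting glucose in mmol/l, fasting C-peptide in
    nmol/l, GADA in U/ml.  The outcome is any user-supplied continuous
    quantity (e.g. a predicted 10-year CVD risk in %).
    """

    id: str
    sex: Optional[str] = None
    age_at_diagnosis: Optional[float] = None
    bmi: Optional[float] = None
    hba1c: Optional[float] = None
    homa2_b: Optional[float] = None
    homa2_ir: Optional[float] = None
    fasting_glucose: Optional[float] = None
    fasting_c_peptide: Optional[float] = None
    gada: Optional[float] = None
    outcome: Optional[float] = None


@dataclass(frozen=True)
class EligibilityThresholds:
    """Inclusion-rule parameters; defaults reproduce the published rules."""

    glucose_range: tuple[float, float] = (3.0, 25.0)
    c_peptide_range: tuple[float, float] = (0.2, 3.5)
    gada_cutoff: float = 2.0
    #: Require fasting glucose / C-peptide / GADA to be present.  When True
    #: (default), a missing value in any of these counts as incomplete
    #: information for cluster assignment.
    require_eligibility_fields: bool = True
    #: Optional recruitment-style HbA1c ceiling in mmol/mol (off by default;
    #: not part of the classification method itself).
    hba1c_max: Optional[float] = None


@dataclass(frozen=True)
class EligibilityDecision:
    id: str
    eligible: bool
    reasons: frozenset[str] = field(default_factory=frozenset)

    @property
    def primary_reason(self) -> Optional[str]:
        """Highest-precedence reason, or None when eligible."""
        for reason in REASON_PRECEDENCE:
            if reason in self.reasons:
                return reason
        return None


def apply_eligibility(
    record: CohortRecord,
    thresholds: EligibilityThresholds | None = None,
) -> EligibilityDecision:
    """Evaluate all inclusion rules for one record (no short-circuiting)."""
    thr = thresholds or EligibilityThresholds()
    reasons: set[str] = set()

    missing = [f for f in _CLUSTERING_FIELDS if _is_missing(getattr(record, f))]
    if _is_missing(record.sex) or record.sex == "":
        missing.append("sex")
    if thr.require_eligibility_fields:
        for f in ("fasting_glucose", "fasting_c_peptide", "gada"):
            if _is_missing(getattr(record, f)):
                missing.append(f)
    if missing:
        reasons.add("missing_clustering_variable")

    g = record.fasting_glucose
    if not _is_missing(g) and not (thr.glucose_range[0] <= g <= thr.glucose_range[1]):
        reasons.add("glucose_out_of_range")
    c = record.fasting_c_peptide
    if not _is_missing(c) and not (
        thr.c_peptide_range[0] <= c <= thr.c_peptide_range[1]
    ):
        reasons.add("c_peptide_out_of_range")
    if not _is_missing(record.gada) and record.gada >= thr.gada_cutoff:
        reasons.add("gada_positive")
    if (
        thr.hba1c_max is not None
        and not _is_missing(record.hba1c)
        and record.hba1c > thr.hba1c_max
    ):
        reasons.add("hba1c_above_max")

    return EligibilityDecision(
        id=record.id, eligible=not reasons, reasons=frozenset(reasons)
    )


def filter_cohort(
    records: Sequence[CohortRecord],
    thresholds: EligibilityThresholds | None = None,
) -> tuple[list[CohortRecord], list[EligibilityDecision], dict[str, int]]:
    """Apply the inclusion rules to a cohort.

    Returns the eligible records, the per-record decisions (all violated
    rules listed), and a summary count of excluded records by primary
    reason (mutually exclusive, following :data:`REASON_PRECEDENCE`).
    """
    if not records:
        raise ValueError("empty record list")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate record id(s): {dupes}")

    eligible: list[CohortRecord] = []
    decisions: list[EligibilityDecision] = []
    counts: dict[str, int] = {}
    for record in records:
        decision = apply_eligibility(record, thresholds)
        decisions.append(decision)
        if decision.eligible:
            eligible.append(record)
        else:
            reason = decision.primary_reason
            counts[reason] = counts.get(reason, 0) + 1
    return eligible, decisions, counts


def records_from_frame(frame: pd.DataFrame) -> list[CohortRecord]:
    """Build records from a cohort table (one row per individual).

    Column names follow the :class:`CohortRecord` fields; missing values
    are empty cells / NaN.  Extra columns are ignored.
    """
    if "id" not in frame.columns:
        raise ValueError("cohort table must have an 'id' column")
    known = {f.name for f in fields(CohortRecord)}
    records = []
    for _, row in frame.iterrows():
        kwargs = {}
        for col in frame.columns:
            if col not in known:
                continue
            value = row[col]
            if col in ("id", "sex"):
                kwargs[col] = None if _is_missing(value) else str(value)
            else:
                kwargs[col] = None if _is_missing(value) else float(value)
        kwargs["id"] = str(row["id"])
        records.append(CohortRecord(**kwargs))
    return records
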