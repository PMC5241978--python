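"""Trial-readiness scoring rubric (0-5 points).

Registered trials are scored on how far their design supports stratified,
multidimensional analysis:

* 1 point for specifying symptoms/features beyond the diagnostic category
  (criterion 2) *or* patient-specific variables such as biomarkers
  (criterion 3); 2 points when both are present;
* 2 points when outcomes are measured at domain level with change measures
  (so individual response and trajectories can be explored); 1 point when
  only total/composite scores are reported; 0 otherwise (criterion 4);
* 1 point when outcomes are analysed against the patient-specific
  variables (criterion 5).

Per-criterion evidence levels modulate the flags: ``insufficient`` reported
information demotes a criterion to absent (conservative, lower score), a
``stated_intent`` in the design promotes it to present (generous, higher
score), and ``reported`` takes the flag at face value.

The diagnostic category itself (criterion 1) carries no points and is kept
as metadata only.  A reviewed-trials table is shipped as a CSV fixture; each
row's encoding judgement is recorded in its ``note`` column.
"""

from __future__ import annotations

from csv import DictReader
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

from .errors import ValidationError

__all__ = [
    "GRANULARITIES",
    "EVIDENCE_LEVELS",
    "TrialRecord",
    "RubricScore",
    "score_trial",
    "score_cohort",
    "load_reviewed_trials",
    "reviewed_trials_path",
]

GRANULARITIES = ("none", "composite_only", "domain_specific_with_change")
EVIDENCE_LEVELS = ("insufficient", "stated_intent", "reported")
_CRITERIA = ("c2", "c3", "c4", "c5")


@dataclass(frozen=True)
class TrialRecord:
    """Encoded stratification-readiness criteria for one registered trial."""

    trial_id: str
    has_specific_symptoms: bool = False
    has_patient_specific_variables: bool = False
    outcome_granularity: str = "none"
    outcome_linked_to_patient_variables: bool = False
    evidence: Mapping[str, str] = field(default_factory=dict)
    diagnosis: str = ""  # criterion 1 — metadata only, carries no points

    def __post_init__(self) -> None:
        if not self.trial_id:
            raise ValidationError("trial_id must be non-empty")
        if self.outcome_granularity not in GRANULARITIES:
            raise ValidationError(
                f"outcome_granularity must be one of {GRANULARITIES}, "
                f"got {self.outcome_granularity!r}"
            )
        ev = {**{c: "reported" for c in _CRITERIA}, **dict(self.evidence)}
        unknown = set(ev) - set(_CRITERIA)
        if unknown:
            raise ValidationError(f"unknown evidence keys {sorted(unknown)}")
        for c, level in ev.items():
            if level not in EVIDENCE_LEVELS:
                raise ValidationError(
                    f"evidence for {c} must be one of {EVIDENCE_LEVELS}, got {level!r}"
                )
        object.__setattr__(self, "evidence", ev)

    def _effective_flag(self, criterion: str, flag: bool) -> bool:
        level = self.evidence[criterion]
        if level == "insufficient":
            return False  # conservative: favour the lower score
        if level == "stated_intent":
            return True  # generous: design intent counts
        return flag

    def effective_granularity(self) -> str:
        if self.evidence["c4"] == "insufficient":
            return "none"
        return self.outcome_granularity


@dataclass(frozen=True)
class RubricScore:
    """Decomposed rubric points for one trial; total is always their sum."""

    trial_id: str
    points_criterion_2_3: int
    points_criterion_4: int
    points_criterion_5: int

    @property
    def total(self) -> int:
        return self.points_criterion_2_3 + self.points_criterion_4 + self.points_criterion_5


def score_trial(record: TrialRecord) -> RubricScore:
    """Apply the rubric to one trial record."""
    c2 = record._effective_flag("c2", record.has_specific_symptoms)
    c3 = record._effective_flag("c3", record.has_patient_specific_variables)
    points_23 = int(c2) + int(c3)

    granularity = record.effective_granularity()
    points_4 = {"none": 0, "composite_only": 1, "domain_specific_with_change": 2}[granularity]

    c5 = record._effective_flag("c5", record.outcome_linked_to_patient_variables)
    points_5 = int(c5)

    return RubricScore(record.trial_id, points_23, points_4, points_5)


def score_cohort(records: Iterable[TrialRecord]) -> dict[int, int]:
    """Histogram of totals (count per score 0..5) over a set of trials."""
    records = list(records)
    if not records:
        raise ValidationError("empty trial list")
    hist = {s: 0 for s in range(6)}
    for rec in records:
        hist[score_trial(rec).total] += 1
    return hist


def reviewed_trials_path():
    """Filesystem path of the shipped reviewed-trials fixture CSV."""
    return resources.files("sigstrat").joinpath("data/table1_trials.csv")


def _parse_bool(s: str) -> bool:
    return str(s).strip().lower() in ("true", "1", "yes")


def records_from_frame(df: pd.DataFrame) -> list[TrialRecord]:
    """Build trial records from a table with the fixture's column layout."""
    required = {
        "trial_id",
        "has_specific_symptoms",
        "has_patient_specific_variables",
        "outcome_granularity",
        "outcome_linked_to_patient_variables",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"trial table is missing column(s) {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        evidence = {
            c: str(row[f"evidence_{c}"])
            for c in _CRITERIA
            if f"evidence_{c}" in df.columns and not pd.isna(row[f"evidence_{c}"])
        }
        records.append(
            TrialRecord(
                trial_id=str(row["trial_id"]),
                has_specific_symptoms=_parse_bool(row["has_specific_symptoms"]),
                has_patient_specific_variables=_parse_bool(row["has_patient_specific_variables"]),
                outcome_granularity=str(row["outcome_granularity"]),
                outcome_linked_to_patient_variables=_parse_bool(
                    row["outcome_linked_to_patient_variables"]
                ),
                evidence=evidence,
                diagnosis=str(row.get("diagnosis", "") or ""),
            )
        )
    return records


def load_reviewed_trials() -> list[tuple[TrialRecord, int]]:
    """The shipped reviewed-trials fixture: (record, tabulated score) pairs."""
    out = []
    with reviewed_trials_path().open() as fh:
        for row in DictReader(fh):
            evidence = {
                c: row[f"evidence_{c}"]
                for c in _CRITERIA
                if row.get(f"evidence_{c}")
            }
            rec = TrialRecord(
                trial_id=row["trial_id"],
                has_specific_symptoms=_parse_bool(row["has_specific_symptoms"]),
                has_patient_specific_variables=_parse_bool(row["has_patient_specific_variables"]),
                outcome_granularity=row["outcome_granularity"],
                outcome_linked_to_patient_variables=_parse_bool(
                    row["outcome_linked_to_patient_variables"]
                ),
                evidence=evidence,
                diagnosis=row.get("diagnosis", ""),
            )
            out.append((rec, int(row["score"])))
    return out
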