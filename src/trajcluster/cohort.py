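"""Cohort inclusion/exclusion logic driven by configurable rule tables.

A patient is included iff, in this fixed order, they (1) have an index
event, (2) are at least ``min_age`` years old, (3) have no earlier index
therapy within the lookback window (incident case), (4) carry at least one
qualifying disease marker, and (5) carry no exclusion marker.  The first
failing rule is recorded as the exclusion reason, so attrition tables are
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .simulate import COPD_MARKER, EXACERBATION, INDEX_EVENT

__all__ = ["SelectionRules", "select_cohort", "attrition_table",
           "REASON_ORDER"]

REASON_ORDER = ("no_index", "age", "not_incident", "no_copd", "excluded_condition")

DEFAULT_QUALIFYING = frozenset({COPD_MARKER, EXACERBATION})
DEFAULT_EXCLUSION = frozenset({"cystic_fibrosis_diagnosis", "neuromuscular_diagnosis"})


@dataclass(frozen=True)
class SelectionRules:
    min_age: float = 40.0
    incident_lookback: int = 1826  # days, ~5 years
    copd_qualifying_event_types: frozenset = DEFAULT_QUALIFYING
    exclusion_event_types: frozenset = DEFAULT_EXCLUSION
    index_event_type: str = INDEX_EVENT
    # Day offsets are anchored so the candidate index falls at day 0; index
    # events earlier than this mark pre-period (prevalent) therapy.
    inclusion_start_day: int = 0

    def __post_init__(self) -> None:
        if self.min_age < 0:
            raise ValueError("min_age must be >= 0")
        if self.incident_lookback <= 0:
            raise ValueError("incident_lookback must be > 0")
        overlap = set(self.copd_qualifying_event_types) & set(self.exclusion_event_types)
        if overlap:
            raise ValueError(f"qualifying and exclusion sets overlap: {sorted(overlap)}")


def select_cohort(events: pd.DataFrame, covariates: pd.DataFrame,
                  rules: SelectionRules | None = None) -> tuple[list, pd.DataFrame]:
    """Apply the selection rules patient by patient.

    Returns ``(included_ids, exclusions)`` where ``exclusions`` has columns
    ``patient_id, reason`` with exactly one row per excluded patient.
    Patients appearing only in ``covariates`` are evaluated too (they fail
    with ``no_index``).
    """
    rules = rules or SelectionRules()
    ev_by_patient = dict(tuple(events.groupby("patient_id", sort=False)))
    ages = covariates.set_index("patient_id")["age"] if "age" in covariates else pd.Series(dtype=float)

    all_ids = sorted(set(events["patient_id"]) | set(covariates["patient_id"]))
    included: list = []
    excl_rows: list[tuple] = []
    for pid in all_ids:
        reason = _evaluate(pid, ev_by_patient.get(pid), ages, rules)
        if reason is None:
            included.append(pid)
        else:
            excl_rows.append((pid, reason))
    exclusions = pd.DataFrame(excl_rows, columns=["patient_id", "reason"])
    return included, exclusions


def _evaluate(pid, ev: pd.DataFrame | None, ages: pd.Series,
              rules: SelectionRules) -> str | None:
    """Return the first failing rule's reason, or None if included."""
    if ev is None:
        return "no_index"
    idx_events = ev.loc[ev["event_type"] == rules.index_event_type, "start_day"]
    in_window = idx_events[idx_events >= rules.inclusion_start_day]
    if in_window.empty:
        return "no_index"
    # Index date = first delivery inside the inclusion period.
    index_day = int(in_window.min())

    age = ages.get(pid)
    if age is None or pd.isna(age) or age < rules.min_age:
        return "age"

    prior = idx_events[(idx_events < index_day)
                       & (idx_events >= index_day - rules.incident_lookback)]
    if len(prior):
        return "not_incident"

    if rules.copd_qualifying_event_types:
        if not ev["event_type"].isin(rules.copd_qualifying_event_types).any():
            return "no_copd"

    if ev["event_type"].isin(rules.exclusion_event_types).any():
        return "excluded_condition"
    return None


def attrition_table(included: list, exclusions: pd.DataFrame) -> pd.DataFrame:
    """Counts per selection outcome, in rule order, including 'included'."""
    rows = [("included", len(included))]
    counts = exclusions["reason"].value_counts()
    rows += [(r, int(counts.get(r, 0))) for r in REASON_ORDER]
    return pd.DataFrame(rows, columns=["outcome", "n"])
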