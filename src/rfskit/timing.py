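"""Recurrence dating rules and recurrence-free survival construction.

A patient flagged by a tree is dated from the indicator that triggered the
call: dated indicators contribute their event date directly; the visit
cluster contributes the midpoint of its time window; for indicators with
no date of their own (death status, cause of death, stage) the fall-back
chain is the earliest evidence date among the patient's present dated
indicators, then the death date, then the midpoint of the landmark-to-last-
contact interval. RFS runs from definitive surgery (diagnosis when there
was none) to the estimated recurrence date, censored at the last known
date for patients called non-recurrent — including those who died without
recurrence.
"""
from __future__ import annotations

import datetime
from dataclasses import dataclass
from typing import Optional

from .cart import DecisionTree, RECURRENT, predict
from .cohort import Cohort, PatientBaseline
from .dateutils import midpoint
from .indicators import (DATED_INDICATORS, IndicatorConfig, IndicatorVector,
                         WINDOW_INDICATORS, build_indicator_matrix)


class DatingError(ValueError):
    """A recurrent call with no usable evidence and no follow-up window."""


@dataclass
class RecurrenceCall:
    patient_id: str
    predicted_recurred: bool
    estimated_recurrence_date: Optional[datetime.date] = None
    triggering_indicator: Optional[str] = None


@dataclass
class SurvivalRecord:
    patient_id: str
    time_days: int
    event: bool
    origin: str  # "surgery" or "diagnosis"


def assign_recurrence_date(call_label: str, triggering_indicator: Optional[str],
                           vector: IndicatorVector) -> datetime.date:
    """Date a recurrent call from its triggering indicator's evidence."""
    if call_label != RECURRENT:
        raise ValueError("only recurrent calls are dated")

    if triggering_indicator is not None:
        ind = vector[triggering_indicator]
        if not ind.present:
            raise ValueError(f"triggering indicator {triggering_indicator!r} "
                             "is not present in the vector")
        if triggering_indicator in DATED_INDICATORS and ind.evidence_date is not None:
            return ind.evidence_date
        if triggering_indicator in WINDOW_INDICATORS and ind.evidence_window is not None:
            return midpoint(*ind.evidence_window)

    # undated trigger (death status / stage) or no "present" node on the path
    dated = [vector[name].evidence_date for name in DATED_INDICATORS
             if name in vector.entries and vector[name].present
             and vector[name].evidence_date is not None]
    if dated:
        return min(dated)
    for name in WINDOW_INDICATORS:
        if name in vector.entries and vector[name].present:
            return midpoint(*vector[name].evidence_window)
    if vector.death_date is not None:
        return vector.death_date
    if vector.last_contact >= vector.landmark:
        return midpoint(vector.landmark, vector.last_contact)
    raise DatingError(f"patient {vector.patient_id}: recurrent call with no "
                      "datable evidence and no post-landmark follow-up")


def build_survival_record(baseline: PatientBaseline, call: RecurrenceCall) -> SurvivalRecord:
    """RFS time in days from the origin date, with event=True for recurrent
    calls and censoring at last contact otherwise (death without recurrence
    is censoring, not an event)."""
    if baseline.patient_id != call.patient_id:
        raise ValueError("baseline and call refer to different patients")
    if baseline.surgery_date is not None:
        origin_name, origin = "surgery", baseline.surgery_date
    else:
        origin_name, origin = "diagnosis", baseline.diagnosis_date
    if call.predicted_recurred:
        if call.estimated_recurrence_date is None:
            raise ValueError(f"patient {call.patient_id}: recurrent call without a date")
        t = (call.estimated_recurrence_date - origin).days
        if t < 0:
            raise ValueError(f"patient {call.patient_id}: estimated recurrence "
                             f"{call.estimated_recurrence_date} precedes {origin_name} {origin}")
        return SurvivalRecord(call.patient_id, t, True, origin_name)
    t = (baseline.last_contact_date - origin).days
    return SurvivalRecord(call.patient_id, t, False, origin_name)


def call_cohort(cohort: Cohort, tree: DecisionTree,
                config: Optional[IndicatorConfig] = None,
                ) -> tuple[list[RecurrenceCall], list[SurvivalRecord]]:
    """Apply one fitted tree to a whole cohort: one recurrence call and one
    survival record per patient, in baseline order."""
    config = config or IndicatorConfig()
    matrix, vectors = build_indicator_matrix(cohort, config)
    calls: list[RecurrenceCall] = []
    records: list[SurvivalRecord] = []
    for baseline in cohort.baselines:
        vec = vectors[baseline.patient_id]
        row = matrix.loc[baseline.patient_id].to_dict()
        label, trigger = predict(tree, row)
        if label == RECURRENT:
            date = assign_recurrence_date(label, trigger, vec)
            call = RecurrenceCall(baseline.patient_id, True, date, trigger)
        else:
            call = RecurrenceCall(baseline.patient_id, False)
        calls.append(call)
        records.append(build_survival_record(baseline, call))
    return calls, records
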