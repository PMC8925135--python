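"""Binary recurrence indicators extracted from each patient's event stream.

The working assumption is that a recurrence shows up in administrative data
as a second wave of care after a landmark date (definitive surgery plus 6,
12 or 18 calendar months): a burst of oncology visits, a new diagnostic
workup (imaging, biopsy), a second local/regional treatment (surgery,
radiation), a new chemotherapy episode, or breast-cancer death. Each
indicator is a yes/no flag carrying either a single evidence date or a
time window, which the dating rules later consume.
"""
from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import Cohort, EventRecord, PatientBaseline
from .dateutils import add_months

#: Fixed indicator column order. CART tie-breaks resolve to the earliest
#: column in this order, so it is part of the classifier contract.
INDICATOR_ORDER = (
    "second_surgery",
    "second_radiation",
    "second_chemo",
    "re_imaging",
    "re_biopsy",
    "visit_cluster",
    "died",
    "died_of_breast_cancer",
    "stage_III",
)

#: Indicators whose evidence is a single event date.
DATED_INDICATORS = ("second_surgery", "second_radiation", "second_chemo",
                    "re_imaging", "re_biopsy", "second_hormone")
#: Indicators whose evidence is a [start, end] time window.
WINDOW_INDICATORS = ("visit_cluster",)
#: Indicators with no post-landmark event evidence of their own.
UNDATED_INDICATORS = ("died", "died_of_breast_cancer", "stage_III")

_TREATMENT_EVENT = {
    "second_surgery": "surgery",
    "second_radiation": "radiation_fraction",
    "second_chemo": "chemo_admin",
    "re_imaging": "imaging",
    "re_biopsy": "biopsy",
    "second_hormone": "hormone_dispense",
}


@dataclass
class IndicatorConfig:
    """Tunable knobs of the indicator definitions.

    landmark_months
        Months after definitive surgery (diagnosis when no surgery) before
        events may count as recurrence evidence; one of 6, 12, 18.
    visit_cluster_min_count / visit_cluster_window_days
        A visit cluster is at least ``min_count`` oncology visits within
        ``window_days`` of each other, starting on/after the landmark.
    second_chemo_min_cycles
        Chemotherapy administrations on/after the landmark needed to call a
        new chemotherapy episode ("more than two cycles" -> 3).
    include_hormone
        Add a ``second_hormone`` indicator (first post-landmark hormone
        dispense); off by default.
    """
    landmark_months: int = 6
    visit_cluster_min_count: int = 3
    visit_cluster_window_days: int = 90
    second_chemo_min_cycles: int = 3
    include_hormone: bool = False

    def __post_init__(self):
        if self.landmark_months not in (6, 12, 18):
            raise ValueError(f"landmark_months must be 6, 12 or 18, got {self.landmark_months}")
        if self.visit_cluster_min_count < 1 or self.second_chemo_min_cycles < 1:
            raise ValueError("count thresholds must be >= 1")
        if self.visit_cluster_window_days <= 0:
            raise ValueError("visit_cluster_window_days must be positive")

    @property
    def indicator_names(self) -> tuple[str, ...]:
        if self.include_hormone:
            return INDICATOR_ORDER[:6] + ("second_hormone",) + INDICATOR_ORDER[6:]
        return INDICATOR_ORDER


@dataclass
class Indicator:
    present: bool
    evidence_date: Optional[datetime.date] = None
    evidence_window: Optional[tuple[datetime.date, datetime.date]] = None


@dataclass
class IndicatorVector:
    """All indicators for one patient, with their date evidence."""
    patient_id: str
    landmark: datetime.date
    last_contact: datetime.date
    death_date: Optional[datetime.date]
    entries: dict[str, Indicator] = field(default_factory=dict)

    def __getitem__(self, name: str) -> Indicator:
        return self.entries[name]

    def presence(self, order: Sequence[str]) -> dict[str, bool]:
        return {name: self.entries[name].present for name in order}


def landmark_date(baseline: PatientBaseline, config: IndicatorConfig) -> datetime.date:
    """Definitive surgery date plus the landmark interval (calendar months,
    day clamped to month end); falls back to the diagnosis date for the few
    patients with no surgery."""
    origin = baseline.surgery_date if baseline.surgery_date is not None else baseline.diagnosis_date
    return add_months(origin, config.landmark_months)


def detect_visit_cluster(visit_dates: Sequence[datetime.date],
                         landmark: datetime.date,
                         config: IndicatorConfig,
                         ) -> Optional[tuple[datetime.date, datetime.date]]:
    """Earliest qualifying burst of oncology visits on/after the landmark.

    Scans windows anchored at each visit ``d_i >= landmark``; a window
    qualifies when at least ``visit_cluster_min_count`` visits fall within
    ``visit_cluster_window_days`` of ``d_i`` (inclusive). Returns
    ``[d_i, last qualifying visit]`` for the earliest anchor, or None.
    """
    dates = [d for d in visit_dates if d >= landmark]
    k = config.visit_cluster_min_count
    span = datetime.timedelta(days=config.visit_cluster_window_days)
    for i, start in enumerate(dates):
        inside = [d for d in dates[i:] if d <= start + span]
        if len(inside) >= k:
            return (start, inside[-1])
    return None


def detect_second_treatment(events: Sequence[EventRecord], event_type: str,
                            landmark: datetime.date, min_count: int = 1,
                            ) -> Optional[datetime.date]:
    """Date evidence for a repeated treatment/diagnostic on/after the landmark.

    For single-event indicators (surgery, radiation, imaging, biopsy,
    hormone) the evidence is the earliest matching event; for chemotherapy
    (``min_count`` > 1) the indicator fires only when at least ``min_count``
    administrations occur on/after the landmark, and the evidence date is the
    first of them.
    """
    dates = sorted(e.event_date for e in events
                   if e.event_type == event_type and e.event_date >= landmark)
    if len(dates) >= min_count:
        return dates[0]
    return None


def extract_indicators(baseline: PatientBaseline, events: Sequence[EventRecord],
                       config: Optional[IndicatorConfig] = None) -> IndicatorVector:
    """Build the full indicator vector for one patient."""
    config = config or IndicatorConfig()
    lm = landmark_date(baseline, config)
    vec = IndicatorVector(patient_id=baseline.patient_id, landmark=lm,
                          last_contact=baseline.last_contact_date,
                          death_date=baseline.death_date)

    for name in config.indicator_names:
        if name in _TREATMENT_EVENT:
            min_count = config.second_chemo_min_cycles if name == "second_chemo" else 1
            date = detect_second_treatment(events, _TREATMENT_EVENT[name], lm, min_count)
            vec.entries[name] = Indicator(present=date is not None, evidence_date=date)
        elif name == "visit_cluster":
            visits = sorted(e.event_date for e in events if e.event_type == "oncology_visit")
            window = detect_visit_cluster(visits, lm, config)
            vec.entries[name] = Indicator(present=window is not None, evidence_window=window)
        elif name == "died":
            vec.entries[name] = Indicator(present=baseline.death_date is not None,
                                          evidence_date=baseline.death_date)
        elif name == "died_of_breast_cancer":
            hit = baseline.death_date is not None and baseline.death_cause == "breast_cancer"
            vec.entries[name] = Indicator(present=hit,
                                          evidence_date=baseline.death_date if hit else None)
        elif name == "stage_III":
            vec.entries[name] = Indicator(present=baseline.stage == "III")
    return vec


def build_indicator_matrix(cohort: Cohort, config: Optional[IndicatorConfig] = None,
                           ) -> tuple[pd.DataFrame, dict[str, IndicatorVector]]:
    """Boolean patients x indicators matrix (baseline order) plus the
    per-patient evidence vectors."""
    config = config or IndicatorConfig()
    by_patient = cohort.events_by_patient()
    vectors: dict[str, IndicatorVector] = {}
    rows = []
    for b in cohort.baselines:
        vec = extract_indicators(b, by_patient.get(b.patient_id, []), config)
        vectors[b.patient_id] = vec
        rows.append(vec.presence(config.indicator_names))
    matrix = pd.DataFrame(rows, index=[b.patient_id for b in cohort.baselines],
                          columns=list(config.indicator_names), dtype=bool)
    return matrix, vectors


class IndicatorExtractor(BaseEstimator, TransformerMixin):
    """Transformer turning a :class:`~rfskit.cohort.Cohort` into the boolean
    indicator matrix.

    Stateless (``fit`` records only the column order); ``transform`` returns
    the matrix and stashes the evidence vectors on ``evidence_`` for the
    dating step. Parameters mirror :class:`IndicatorConfig`.
    """

    def __init__(self, landmark_months: int = 6, visit_cluster_min_count: int = 3,
                 visit_cluster_window_days: int = 90, second_chemo_min_cycles: int = 3,
                 include_hormone: bool = False):
        self.landmark_months = landmark_months
        self.visit_cluster_min_count = visit_cluster_min_count
        self.visit_cluster_window_days = visit_cluster_window_days
        self.second_chemo_min_cycles = second_chemo_min_cycles
        self.include_hormone = include_hormone

    def _config(self) -> IndicatorConfig:
        return IndicatorConfig(
            landmark_months=self.landmark_months,
            visit_cluster_min_count=self.visit_cluster_min_count,
            visit_cluster_window_days=self.visit_cluster_window_days,
            second_chemo_min_cycles=self.second_chemo_min_cycles,
            include_hormone=self.include_hormone,
        )

    def fit(self, cohort: Cohort, y=None) -> "IndicatorExtractor":
        self.feature_names_ = list(self._config().indicator_names)
        return self

    def transform(self, cohort: Cohort) -> pd.DataFrame:
        matrix, vectors = build_indicator_matrix(cohort, self._config())
        self.evidence_ = vectors
        return matrix
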