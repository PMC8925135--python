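"""Domain types and delimited-text I/O for administrative-claims cohorts.

A cohort is three flat tables: one row per clinical event (visits, imaging,
biopsies, surgeries, chemotherapy administrations, radiation fractions,
hormone dispenses, death), one row per patient with baseline/tumour
covariates and follow-up anchors, and optionally one row per patient of
chart-review gold labels (recurrence yes/no and its date).

Files are UTF-8 CSV with a header row; dates are ISO-8601; booleans are
coded ``yes``/``no``; a blank cell is an absent optional value.
"""
from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .dateutils import parse_date

EVENT_TYPES = frozenset({
    "oncology_visit", "imaging", "biopsy", "surgery", "chemo_admin",
    "radiation_fraction", "hormone_dispense", "death",
})
SURGERY_TYPES = frozenset({"none", "BCS", "mastectomy"})
STAGES = frozenset({"0_I", "II", "III"})
GRADES = frozenset({"1", "2", "3"})
RECEPTOR_STATUS = frozenset({"pos", "neg"})
DEATH_CAUSES = frozenset({"breast_cancer", "other"})

#: Minimum days from definitive surgery for an event to count as recurrence.
RECURRENCE_MIN_DAYS = 180


class CohortError(ValueError):
    """Base class for cohort construction problems."""


class SchemaError(CohortError):
    """A required column is missing or a categorical value is out of vocabulary."""


class DateParseError(CohortError):
    """A cell could not be parsed as an ISO-8601 date (carries the file line)."""


class ReferentialError(CohortError):
    """An event or label references a patient absent from the baseline table."""


@dataclass
class EventRecord:
    """One dated clinical event for one patient."""
    patient_id: str
    event_type: str
    event_date: datetime.date
    detail: Optional[str] = None


@dataclass
class PatientBaseline:
    """Index dates, tumour/treatment covariates and vital status for one patient."""
    patient_id: str
    diagnosis_date: datetime.date
    surgery_date: Optional[datetime.date]
    surgery_type: str
    stage: str
    grade: str
    er: str
    pr: str
    her2: str
    age_at_diagnosis: float
    last_contact_date: datetime.date
    death_date: Optional[datetime.date] = None
    death_cause: Optional[str] = None


@dataclass
class GoldLabel:
    """Chart-review recurrence status (and date, when recurred) for one patient."""
    patient_id: str
    recurred: bool
    recurrence_date: Optional[datetime.date] = None


@dataclass
class Cohort:
    baselines: list[PatientBaseline]
    events: list[EventRecord]
    labels: Optional[list[GoldLabel]] = None

    def baseline_index(self) -> dict[str, PatientBaseline]:
        return {b.patient_id: b for b in self.baselines}

    def events_by_patient(self) -> dict[str, list[EventRecord]]:
        by: dict[str, list[EventRecord]] = {b.patient_id: [] for b in self.baselines}
        for ev in self.events:
            by.setdefault(ev.patient_id, []).append(ev)
        for evs in by.values():
            evs.sort(key=lambda e: (e.event_date, e.event_type, e.detail or ""))
        return by

    def label_index(self) -> dict[str, GoldLabel]:
        return {} if self.labels is None else {g.patient_id: g for g in self.labels}

    def __len__(self) -> int:
        return len(self.baselines)


@dataclass
class Violation:
    patient_id: str
    rule: str
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __iter__(self):
        return iter(self.violations)

    def __len__(self) -> int:
        return len(self.violations)


# ---------------------------------------------------------------------------
# reading

_EVENT_COLUMNS = ["patient_id", "event_type", "event_date", "detail"]
_PATIENT_COLUMNS = [
    "patient_id", "diagnosis_date", "surgery_date", "surgery_type", "stage",
    "grade", "er", "pr", "her2", "age_at_diagnosis", "last_contact_date",
    "death_date", "death_cause",
]
_LABEL_COLUMNS = ["patient_id", "recurred", "recurrence_date"]


def _read_table(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column '{col}'")
    return df


def _cell_date(value: str, path, row: int, col: str) -> Optional[datetime.date]:
    if value == "":
        return None
    try:
        return parse_date(value)
    except ValueError as exc:
        # +2: one for the header row, one for 0-based indexing
        raise DateParseError(f"{path}, line {row + 2}, column '{col}': "
                             f"unparseable date {value!r}") from exc


def _cell_enum(value: str, vocab: frozenset, path, row: int, col: str,
               optional: bool = False) -> Optional[str]:
    if value == "" and optional:
        return None
    if value not in vocab:
        raise SchemaError(f"{path}, line {row + 2}, column '{col}': "
                          f"value {value!r} not in {sorted(vocab)}")
    return value


def _cell_bool(value: str, path, row: int, col: str) -> bool:
    if value not in ("yes", "no"):
        raise SchemaError(f"{path}, line {row + 2}, column '{col}': "
                          f"expected 'yes' or 'no', got {value!r}")
    return value == "yes"


def read_cohort(events_path, patients_path, labels_path=None) -> Cohort:
    """Read a cohort from its three CSV tables (labels optional).

    Raises :class:`SchemaError` for missing columns or out-of-vocabulary
    categoricals, :class:`DateParseError` (with file line) for bad dates, and
    :class:`ReferentialError` for events or labels whose patient is not in the
    patients table.
    """
    pdf = _read_table(patients_path, _PATIENT_COLUMNS)
    baselines = []
    for i, row in enumerate(pdf.itertuples(index=False)):
        baselines.append(PatientBaseline(
            patient_id=row.patient_id,
            diagnosis_date=_cell_date(row.diagnosis_date, patients_path, i, "diagnosis_date"),
            surgery_date=_cell_date(row.surgery_date, patients_path, i, "surgery_date"),
            surgery_type=_cell_enum(row.surgery_type, SURGERY_TYPES, patients_path, i, "surgery_type"),
            stage=_cell_enum(row.stage, STAGES, patients_path, i, "stage"),
            grade=_cell_enum(row.grade, GRADES, patients_path, i, "grade"),
            er=_cell_enum(row.er, RECEPTOR_STATUS, patients_path, i, "er"),
            pr=_cell_enum(row.pr, RECEPTOR_STATUS, patients_path, i, "pr"),
            her2=_cell_enum(row.her2, RECEPTOR_STATUS, patients_path, i, "her2"),
            age_at_diagnosis=float(row.age_at_diagnosis),
            last_contact_date=_cell_date(row.last_contact_date, patients_path, i, "last_contact_date"),
            death_date=_cell_date(row.death_date, patients_path, i, "death_date"),
            death_cause=_cell_enum(row.death_cause, DEATH_CAUSES, patients_path, i,
                                   "death_cause", optional=True),
        ))
    known = {b.patient_id for b in baselines}

    edf = _read_table(events_path, _EVENT_COLUMNS)
    events = []
    for i, row in enumerate(edf.itertuples(index=False)):
        if row.patient_id not in known:
            raise ReferentialError(
                f"{events_path}, line {i + 2}: event references unknown patient "
                f"'{row.patient_id}'")
        events.append(EventRecord(
            patient_id=row.patient_id,
            event_type=_cell_enum(row.event_type, EVENT_TYPES, events_path, i, "event_type"),
            event_date=_cell_date(row.event_date, events_path, i, "event_date"),
            detail=row.detail or None,
        ))

    labels = None
    if labels_path is not None:
        ldf = _read_table(labels_path, _LABEL_COLUMNS)
        labels = []
        for i, row in enumerate(ldf.itertuples(index=False)):
            if row.patient_id not in known:
                raise ReferentialError(
                    f"{labels_path}, line {i + 2}: label references unknown patient "
                    f"'{row.patient_id}'")
            labels.append(GoldLabel(
                patient_id=row.patient_id,
                recurred=_cell_bool(row.recurred, labels_path, i, "recurred"),
                recurrence_date=_cell_date(row.recurrence_date, labels_path, i, "recurrence_date"),
            ))
    return Cohort(baselines=baselines, events=events, labels=labels)


# ---------------------------------------------------------------------------
# writing

def _iso(d: Optional[datetime.date]) -> str:
    return "" if d is None else d.isoformat()


def write_cohort(cohort: Cohort, dir_path) -> dict[str, Path]:
    """Write ``events.csv``/``patients.csv`` (and ``labels.csv`` when labels are
    present) under ``dir_path``; returns the written paths.

    ``read_cohort(**write_cohort(c))`` reproduces ``c`` field for field.
    """
    out = Path(dir_path)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    edf = pd.DataFrame(
        [(e.patient_id, e.event_type, _iso(e.event_date), e.detail or "")
         for e in cohort.events],
        columns=_EVENT_COLUMNS)
    paths["events_path"] = out / "events.csv"
    edf.to_csv(paths["events_path"], index=False)

    pdf = pd.DataFrame(
        [(b.patient_id, _iso(b.diagnosis_date), _iso(b.surgery_date), b.surgery_type,
          b.stage, b.grade, b.er, b.pr, b.her2, b.age_at_diagnosis,
          _iso(b.last_contact_date), _iso(b.death_date), b.death_cause or "")
         for b in cohort.baselines],
        columns=_PATIENT_COLUMNS)
    paths["patients_path"] = out / "patients.csv"
    pdf.to_csv(paths["patients_path"], index=False)

    if cohort.labels is not None:
        ldf = pd.DataFrame(
            [(g.patient_id, "yes" if g.recurred else "no", _iso(g.recurrence_date))
             for g in cohort.labels],
            columns=_LABEL_COLUMNS)
        paths["labels_path"] = out / "labels.csv"
        ldf.to_csv(paths["labels_path"], index=False)
    return paths


# ---------------------------------------------------------------------------
# validation

def validate_cohort(cohort: Cohort) -> ValidationReport:
    """Check every structural invariant; the report is empty iff all hold.

    Checks: unique patient ids; events/labels reference known patients; at most
    one death event per patient, agreeing with the baseline death date; surgery
    not before diagnosis; last contact not before diagnosis/surgery and equal
    to the death date when the patient died; labelled recurrences dated and at
    least 180 days after definitive surgery.
    """
    report = ValidationReport()
    add = report.violations.append

    seen: set[str] = set()
    for b in cohort.baselines:
        if b.patient_id in seen:
            add(Violation(b.patient_id, "unique_patient", "duplicate patient_id in baselines"))
        seen.add(b.patient_id)
    index = cohort.baseline_index()

    for b in cohort.baselines:
        if b.surgery_date is not None and b.surgery_date < b.diagnosis_date:
            add(Violation(b.patient_id, "surgery_after_diagnosis",
                          f"surgery {b.surgery_date} precedes diagnosis {b.diagnosis_date}"))
        anchor = max(d for d in (b.diagnosis_date, b.surgery_date) if d is not None)
        if b.last_contact_date < anchor:
            add(Violation(b.patient_id, "last_contact_order",
                          f"last contact {b.last_contact_date} precedes {anchor}"))
        if b.death_date is not None and b.death_date != b.last_contact_date:
            add(Violation(b.patient_id, "death_is_last_contact",
                          f"death {b.death_date} != last contact {b.last_contact_date}"))
        if b.stage not in STAGES:
            add(Violation(b.patient_id, "stage_vocab", f"stage {b.stage!r} (stage IV excluded)"))

    deaths: dict[str, int] = {}
    for ev in cohort.events:
        if ev.patient_id not in index:
            add(Violation(ev.patient_id, "event_patient_known",
                          "event references patient absent from baselines"))
            continue
        if ev.event_type == "death":
            deaths[ev.patient_id] = deaths.get(ev.patient_id, 0) + 1
            bd = index[ev.patient_id].death_date
            if bd is not None and ev.event_date != bd:
                add(Violation(ev.patient_id, "death_date_agreement",
                              f"death event {ev.event_date} != baseline death {bd}"))
    for pid, n in deaths.items():
        if n > 1:
            add(Violation(pid, "single_death", f"{n} death events"))

    if cohort.labels is not None:
        seen_labels: set[str] = set()
        for g in cohort.labels:
            if g.patient_id in seen_labels:
                add(Violation(g.patient_id, "unique_label", "duplicate patient_id in labels"))
            seen_labels.add(g.patient_id)
            if g.patient_id not in index:
                add(Violation(g.patient_id, "label_patient_known",
                              "label references patient absent from baselines"))
                continue
            if g.recurred and g.recurrence_date is None:
                add(Violation(g.patient_id, "recurrence_dated",
                              "recurred=yes without recurrence_date"))
            b = index[g.patient_id]
            if (g.recurrence_date is not None and b.surgery_date is not None
                    and (g.recurrence_date - b.surgery_date).days < RECURRENCE_MIN_DAYS):
                add(Violation(g.patient_id, "recurrence_180d",
                              f"recurrence {g.recurrence_date} only "
                              f"{(g.recurrence_date - b.surgery_date).days} days after surgery"))
    return report
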