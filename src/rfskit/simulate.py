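"""Synthetic administrative-claims cohorts with known recurrence ground truth.

The generator emulates the care trajectory that the indicator/CART pipeline
assumes: a primary-treatment phase (diagnostic workup, definitive surgery,
adjuvant chemotherapy cycles, radiation fractions, hormone dispenses) and a
surveillance phase of sporadic oncology visits and imaging, onto which a
second wave of care is planted for recurrent patients — a burst of visits,
re-imaging, re-biopsy and sometimes second surgery / chemotherapy /
radiation, starting a short administrative lag after the true recurrence
date. Defaults are calibrated to the cohort the method targets: 598
stage 0–III patients, 20.2% recurrence, median follow-up 4 years (IQR
roughly 3–5), 0.8% with no definitive surgery, mastectomy in 72.6%.

Two noise channels keep the classification problem honest: a fraction of
recurrences is administratively silent (no second wave), and a fraction of
non-recurrent patients receives a benign false workup (visit burst plus
imaging, sometimes biopsy, never a second treatment). Recurrence risk
depends on stage, grade and HER2 through a logistic model whose intercept
is re-calibrated per cohort so the mean risk equals ``recurrence_prob``.
"""
from __future__ import annotations

import datetime
from dataclasses import dataclass, field, fields
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import Cohort, EventRecord, GoldLabel, PatientBaseline

DAYS_PER_YEAR = 365.25


@dataclass
class SimParams:
    """All knobs of the cohort generator; every field is a study condition.

    Probabilities are in [0, 1], rates per year, durations in days unless
    the name says years.
    """
    n_patients: int = 598
    recurrence_prob: float = 0.202
    rng_seed: int = 0

    # follow-up from the origin (surgery, or diagnosis when no surgery):
    # shifted gamma, median 4 y, quartile width 2 y
    followup_gamma_shape: float = 6.0
    followup_gamma_scale: float = 0.6243
    followup_shift_years: float = 0.46
    followup_min_years: float = 0.5

    # true recurrence latency from the origin: 180 d + Weibull, scaled so
    # ~80% of recurrences fall within 5 years of surgery
    latency_min_days: int = 180
    latency_weibull_shape: float = 1.3
    latency_weibull_scale_days: float = 1141.0

    # primary phase
    no_surgery_prob: float = 0.008
    mastectomy_prob_given_surgery: float = 0.732  # 72.6% of all patients
    surgery_delay_days: tuple[int, int] = (14, 120)
    chemo_prob: float = 0.915
    chemo_cycles_poisson_mean: float = 4.0  # cycles = 1 + Poisson(mean)
    chemo_cycle_interval_days: int = 21
    chemo_start_delay_days: int = 28
    radiation_prob: float = 0.5
    radiation_fractions: int = 16
    hormone_prob_er_pos: float = 0.8
    hormone_prob_er_neg: float = 0.05
    hormone_dispense_interval_days: int = 90

    # surveillance phase (background noise)
    surveillance_visit_rate_per_year: float = 2.5
    surveillance_imaging_rate_per_year: float = 0.6
    surveillance_biopsy_rate_per_year: float = 0.05

    # recurrence phase (the planted second wave)
    indicator_lag_max_days: int = 60
    cluster_visit_rate_per_year: float = 12.0
    cluster_duration_days: int = 180
    p_re_imaging: float = 0.9
    p_re_biopsy: float = 0.7
    p_second_surgery: float = 0.35
    p_second_chemo: float = 0.5
    second_chemo_extra_cycles_mean: float = 2.0  # admins = 3 + Poisson(mean)
    p_second_radiation: float = 0.3
    second_radiation_fractions: int = 10
    p_silent_recurrence: float = 0.07

    # false benign workup among non-recurrent patients
    p_false_workup: float = 0.05
    false_workup_imaging_prob: float = 0.8
    false_workup_biopsy_prob: float = 0.5

    # death
    cancer_death_hazard_per_year: float = 0.45  # after recurrence
    other_death_hazard_per_year: float = 0.005

    # covariate marginals (entire-cohort column of the target population)
    stage_probs: tuple[float, float, float] = (0.159, 0.520, 0.321)  # 0_I, II, III
    grade_probs: tuple[float, float, float] = (0.075, 0.353, 0.572)
    er_pos_prob: float = 0.734
    pr_pos_prob: float = 0.627
    her2_pos_prob: float = 0.269
    age_shift_years: float = 24.0
    age_gamma_shape: float = 2.0
    age_gamma_scale: float = 9.0

    # recurrence-risk log-odds (intercept calibrated per cohort)
    logodds_stage_II: float = 0.9
    logodds_stage_III: float = 2.0
    logodds_her2_pos: float = -0.7
    logodds_grade_3: float = 0.4

    diagnosis_window: tuple[str, str] = ("2007-01-01", "2014-12-31")

    def validate(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name.startswith("p_") or f.name.endswith("_prob") or f.name.endswith("_pos_prob"):
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"SimParams.{f.name} must be a probability, got {v}")
            if "rate_per_year" in f.name or "hazard" in f.name:
                if v < 0:
                    raise ValueError(f"SimParams.{f.name} must be >= 0, got {v}")
        for name in ("stage_probs", "grade_probs"):
            probs = getattr(self, name)
            if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-6:
                raise ValueError(f"SimParams.{name} must be a probability vector")
        if self.latency_min_days < 180:
            raise ValueError("latency_min_days must be >= 180 (recurrence definition)")
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")


def default_params() -> SimParams:
    """The default study conditions (598 patients, 20.2% recurrence,
    4-year median follow-up, target-population covariate marginals)."""
    return SimParams()


# ---------------------------------------------------------------------------

def _calibrate_intercept(logodds: np.ndarray, target: float) -> float:
    """Intercept b0 such that mean(sigmoid(b0 + logodds)) == target."""
    if target <= 0.0:
        return -np.inf
    if target >= 1.0:
        return np.inf
    lo, hi = -20.0, 20.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if np.mean(1.0 / (1.0 + np.exp(-(mid + logodds)))) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _poisson_dates(rng, rate_per_year: float, start: datetime.date,
                   end: datetime.date) -> list[datetime.date]:
    span_days = (end - start).days
    if span_days <= 0 or rate_per_year <= 0:
        return []
    n = rng.poisson(rate_per_year * span_days / DAYS_PER_YEAR)
    offsets = np.sort(rng.integers(0, span_days + 1, size=n))
    return [start + datetime.timedelta(days=int(o)) for o in offsets]


def simulate_cohort(params: Optional[SimParams] = None,
                    seed: Optional[int] = None) -> Cohort:
    """Draw one cohort (baselines, events, gold labels) from the generator.

    The same ``params`` and ``seed`` give a byte-identical cohort. ``seed``
    overrides ``params.rng_seed`` when given.
    """
    params = params or default_params()
    params.validate()
    rng = np.random.default_rng(params.rng_seed if seed is None else seed)
    n = params.n_patients
    day = datetime.timedelta(days=1)

    # -- pass 1: covariates for the whole cohort (vectorized, fixed order)
    stage = rng.choice(np.array(["0_I", "II", "III"]), size=n, p=params.stage_probs)
    grade = rng.choice(np.array(["1", "2", "3"]), size=n, p=params.grade_probs)
    er = np.where(rng.random(n) < params.er_pos_prob, "pos", "neg")
    pr = np.where(rng.random(n) < params.pr_pos_prob, "pos", "neg")
    her2 = np.where(rng.random(n) < params.her2_pos_prob, "pos", "neg")
    age = np.clip(params.age_shift_years
                  + rng.gamma(params.age_gamma_shape, params.age_gamma_scale, size=n),
                  18.0, 90.0).round(1)

    logodds = (params.logodds_stage_II * (stage == "II")
               + params.logodds_stage_III * (stage == "III")
               + params.logodds_her2_pos * (her2 == "pos")
               + params.logodds_grade_3 * (grade == "3"))
    b0 = _calibrate_intercept(logodds, params.recurrence_prob)
    with np.errstate(over="ignore"):
        p_rec = 1.0 / (1.0 + np.exp(-(b0 + logodds)))
    recurred = rng.random(n) < p_rec

    dx_lo = datetime.date.fromisoformat(params.diagnosis_window[0])
    dx_hi = datetime.date.fromisoformat(params.diagnosis_window[1])
    dx_span = (dx_hi - dx_lo).days

    baselines: list[PatientBaseline] = []
    events: list[EventRecord] = []
    labels: list[GoldLabel] = []

    # -- pass 2: per-patient timelines (fixed draw order for determinism)
    for i in range(n):
        pid = f"P{i:04d}"
        diagnosis = dx_lo + day * int(rng.integers(0, dx_span + 1))
        no_surgery = rng.random() < params.no_surgery_prob
        if no_surgery:
            surgery_date, surgery_type = None, "none"
        else:
            surgery_date = diagnosis + day * int(rng.integers(*params.surgery_delay_days))
            surgery_type = ("mastectomy"
                            if rng.random() < params.mastectomy_prob_given_surgery
                            else "BCS")
        origin = surgery_date if surgery_date is not None else diagnosis

        fy = max(params.followup_shift_years
                 + rng.gamma(params.followup_gamma_shape, params.followup_gamma_scale),
                 params.followup_min_years)
        followup_end = origin + day * int(round(fy * DAYS_PER_YEAR))

        rec_date: Optional[datetime.date] = None
        if recurred[i]:
            latency = params.latency_min_days + rng.weibull(
                params.latency_weibull_shape) * params.latency_weibull_scale_days
            rec_date = origin + day * int(round(latency))
            if rec_date + 90 * day > followup_end:
                # chart review observed the recurrence, so follow-up extends past it
                followup_end = rec_date + day * int(90 + rng.integers(0, 271))

        ev: list[tuple[str, datetime.date, Optional[str]]] = []

        # primary diagnostic workup and treatment
        ev.append(("imaging", diagnosis, None))
        ev.append(("biopsy", diagnosis + 3 * day, None))
        if surgery_date is not None:
            ev.append(("surgery", surgery_date, surgery_type))
        got_chemo = rng.random() < params.chemo_prob
        chemo_end = origin
        if got_chemo:
            n_cycles = 1 + int(rng.poisson(params.chemo_cycles_poisson_mean))
            start = origin + params.chemo_start_delay_days * day
            for c in range(n_cycles):
                ev.append(("chemo_admin", start + c * params.chemo_cycle_interval_days * day, None))
            chemo_end = start + (n_cycles - 1) * params.chemo_cycle_interval_days * day
        if rng.random() < params.radiation_prob:
            start = max(chemo_end, origin + 21 * day) + 14 * day
            for f in range(params.radiation_fractions):
                ev.append(("radiation_fraction", start + f * day, None))
        hp = params.hormone_prob_er_pos if er[i] == "pos" else params.hormone_prob_er_neg
        if rng.random() < hp:
            t = origin + 60 * day
            while t <= followup_end:
                ev.append(("hormone_dispense", t, None))
                t += params.hormone_dispense_interval_days * day

        # surveillance background
        for d in _poisson_dates(rng, params.surveillance_visit_rate_per_year,
                                diagnosis, followup_end):
            ev.append(("oncology_visit", d, None))
        for d in _poisson_dates(rng, params.surveillance_imaging_rate_per_year,
                                origin + 180 * day, followup_end):
            ev.append(("imaging", d, None))
        for d in _poisson_dates(rng, params.surveillance_biopsy_rate_per_year,
                                origin + 180 * day, followup_end):
            ev.append(("biopsy", d, None))

        # the planted second wave of care
        silent = rng.random() < params.p_silent_recurrence
        if rec_date is not None and not silent:
            sig = rec_date + day * int(rng.integers(0, params.indicator_lag_max_days + 1))
            for d in _poisson_dates(rng, params.cluster_visit_rate_per_year,
                                    sig, sig + params.cluster_duration_days * day):
                ev.append(("oncology_visit", d, None))
            if rng.random() < params.p_re_imaging:
                ev.append(("imaging", sig + day * int(rng.integers(0, 15)), None))
            if rng.random() < params.p_re_biopsy:
                ev.append(("biopsy", sig + day * int(rng.integers(7, 22)), None))
            if rng.random() < params.p_second_surgery:
                ev.append(("surgery", sig + day * int(rng.integers(21, 46)), "mastectomy"))
            if rng.random() < params.p_second_chemo:
                n_adm = 3 + int(rng.poisson(params.second_chemo_extra_cycles_mean))
                start = sig + 30 * day
                for c in range(n_adm):
                    ev.append(("chemo_admin", start + c * params.chemo_cycle_interval_days * day, None))
            if rng.random() < params.p_second_radiation:
                start = sig + 60 * day
                for f in range(params.second_radiation_fractions):
                    ev.append(("radiation_fraction", start + f * day, None))
        elif rec_date is None and rng.random() < params.p_false_workup:
            lead = (origin + 210 * day)
            if lead < followup_end - 90 * day:
                anchor_span = (followup_end - 90 * day - lead).days
                anchor = lead + day * int(rng.integers(0, anchor_span + 1))
                for d in _poisson_dates(rng, params.cluster_visit_rate_per_year,
                                        anchor, anchor + 60 * day):
                    ev.append(("oncology_visit", d, None))
                if rng.random() < params.false_workup_imaging_prob:
                    ev.append(("imaging", anchor + day * int(rng.integers(0, 15)), None))
                if rng.random() < params.false_workup_biopsy_prob:
                    ev.append(("biopsy", anchor + day * int(rng.integers(7, 22)), None))

        # death: cancer death only after recurrence; other-cause for anyone
        death_date: Optional[datetime.date] = None
        death_cause: Optional[str] = None
        cancer_death = None
        if rec_date is not None and params.cancer_death_hazard_per_year > 0:
            dt = rng.exponential(1.0 / params.cancer_death_hazard_per_year)
            cancer_death = rec_date + day * max(int(round(dt * DAYS_PER_YEAR)), 7)
        other_death = None
        if params.other_death_hazard_per_year > 0:
            dt = rng.exponential(1.0 / params.other_death_hazard_per_year)
            other_death = origin + day * int(round(dt * DAYS_PER_YEAR))
            if rec_date is not None and other_death <= rec_date + 30 * day:
                other_death = None  # the patient demonstrably survived to recur
        candidates = [(d, c) for d, c in ((cancer_death, "breast_cancer"),
                                          (other_death, "other"))
                      if d is not None and d <= followup_end]
        if candidates:
            death_date, death_cause = min(candidates)

        last_contact = death_date if death_date is not None else followup_end
        kept = [(t, d, det) for t, d, det in ev if diagnosis <= d <= last_contact]
        if death_date is not None:
            kept.append(("death", death_date, death_cause))
        kept.sort(key=lambda r: (r[1], r[0], r[2] or ""))
        events.extend(EventRecord(pid, t, d, det) for t, d, det in kept)

        baselines.append(PatientBaseline(
            patient_id=pid, diagnosis_date=diagnosis, surgery_date=surgery_date,
            surgery_type=surgery_type, stage=str(stage[i]), grade=str(grade[i]),
            er=str(er[i]), pr=str(pr[i]), her2=str(her2[i]),
            age_at_diagnosis=float(age[i]), last_contact_date=last_contact,
            death_date=death_date, death_cause=death_cause))
        labels.append(GoldLabel(patient_id=pid, recurred=bool(recurred[i]),
                                recurrence_date=rec_date))

    return Cohort(baselines=baselines, events=events, labels=labels)


# ---------------------------------------------------------------------------

@dataclass
class CohortSummary:
    n: int
    n_recurred: int
    recurrence_pct: float
    followup_median_years: float
    followup_iqr_years: tuple[float, float]
    table: pd.DataFrame = field(repr=False)


def summarize_cohort(cohort: Cohort) -> CohortSummary:
    """Cohort characteristics: counts/percentages per factor level, receipt
    of chemo/radiation/hormone therapy, recurrence count and follow-up
    median (IQR) in years. Percentages within a factor sum to 100."""
    rows = []
    n = len(cohort)
    received = {pid: {e.event_type for e in evs}
                for pid, evs in cohort.events_by_patient().items()}

    def factor(name, values):
        counts = pd.Series(values).value_counts()
        for level, c in sorted(counts.items()):
            rows.append((name, level, int(c), 100.0 * c / n if n else float("nan")))

    factor("stage", [b.stage for b in cohort.baselines])
    factor("grade", [b.grade for b in cohort.baselines])
    factor("er", [b.er for b in cohort.baselines])
    factor("pr", [b.pr for b in cohort.baselines])
    factor("her2", [b.her2 for b in cohort.baselines])
    factor("surgery_type", [b.surgery_type for b in cohort.baselines])
    for therapy, etype in (("chemotherapy", "chemo_admin"),
                           ("radiotherapy", "radiation_fraction"),
                           ("hormone_therapy", "hormone_dispense")):
        factor(therapy, ["yes" if etype in received.get(b.patient_id, set()) else "no"
                         for b in cohort.baselines])

    n_rec = sum(g.recurred for g in cohort.labels) if cohort.labels else 0
    fy = [((b.last_contact_date - (b.surgery_date or b.diagnosis_date)).days / DAYS_PER_YEAR)
          for b in cohort.baselines]
    q25, med, q75 = (np.percentile(fy, [25, 50, 75]) if fy else (float("nan"),) * 3)
    return CohortSummary(
        n=n, n_recurred=int(n_rec),
        recurrence_pct=100.0 * n_rec / n if n else float("nan"),
        followup_median_years=float(med),
        followup_iqr_years=(float(q25), float(q75)),
        table=pd.DataFrame(rows, columns=["variable", "level", "count", "percent"]))
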