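"""Validation battery comparing algorithm recurrence calls against chart review.

Covers the full comparison protocol: confusion-matrix metrics (sensitivity,
specificity, PPV, NPV, accuracy, reported to one decimal), reconstruction of
a confusion matrix from printed sensitivity/specificity, month-binned
timing-agreement tables, rank-sum comparison of RFS lengths, Kaplan–Meier
curves with log-rank tests, per-covariate Cox hazard-ratio concordance, and
group-characteristics tables with chi-square/Fisher or t/rank-sum tests.

Survival machinery (product-limit estimator, log-rank, Cox PH with Efron
ties) is delegated to lifelines; the comparison logic and reporting
conventions live here.
"""
from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .cart import DecisionTree
from .cohort import Cohort, GoldLabel
from .dateutils import MONTH_DAYS
from .indicators import IndicatorConfig
from .timing import RecurrenceCall, SurvivalRecord, call_cohort

ALPHA = 0.05  # two-sided significance level used throughout


def round1(x: float) -> float:
    """Round to one decimal, half away from zero (reporting convention)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _pct(num: float, den: float) -> float:
    return round1(100.0 * num / den) if den else float("nan")


# ---------------------------------------------------------------------------
# confusion metrics

@dataclass
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def flagged(self) -> int:
        return self.tp + self.fp

    @property
    def censored(self) -> int:
        """Patients called non-recurrent (censored in the survival analysis)."""
        return self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        return _pct(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return _pct(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float:
        return _pct(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float:
        return _pct(self.tn, self.tn + self.fn)

    @property
    def accuracy(self) -> float:
        return _pct(self.tp + self.tn, self.total)

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
                "sensitivity": self.sensitivity, "specificity": self.specificity,
                "ppv": self.ppv, "npv": self.npv, "accuracy": self.accuracy,
                "flagged": self.flagged, "censored": self.censored}


def _call_map(calls) -> dict[str, bool]:
    if isinstance(calls, Mapping):
        return {pid: bool(v) for pid, v in calls.items()}
    return {c.patient_id: bool(c.predicted_recurred) for c in calls}


def _gold_map(gold) -> dict[str, bool]:
    if isinstance(gold, Mapping):
        return {pid: bool(v) for pid, v in gold.items()}
    return {g.patient_id: bool(g.recurred) for g in gold}


def confusion_metrics(calls, gold) -> ConfusionMetrics:
    """Cross-tabulate algorithm calls against chart-review labels.

    ``calls`` and ``gold`` may be sequences of :class:`RecurrenceCall` /
    :class:`GoldLabel` or patient-id -> bool mappings; the patient sets must
    coincide.
    """
    cm = _call_map(calls)
    gm = _gold_map(gold)
    if set(cm) != set(gm):
        only_c = sorted(set(cm) - set(gm))[:3]
        only_g = sorted(set(gm) - set(cm))[:3]
        raise ValueError(f"calls and gold cover different patients "
                         f"(e.g. calls-only {only_c}, gold-only {only_g})")
    tp = sum(1 for pid in cm if cm[pid] and gm[pid])
    fp = sum(1 for pid in cm if cm[pid] and not gm[pid])
    fn = sum(1 for pid in cm if not cm[pid] and gm[pid])
    tn = len(cm) - tp - fp - fn
    return ConfusionMetrics(tp=tp, fp=fp, tn=tn, fn=fn)


def reconstruct_confusion(sensitivity_pct: float, specificity_pct: float,
                          n_pos: int, n_neg: int) -> ConfusionMetrics:
    """Recover the integer confusion matrix behind printed sensitivity and
    specificity, given the gold positive/negative counts; the remaining
    metrics (PPV, NPV, accuracy, flagged/censored counts) then follow
    arithmetically."""
    if not (0 <= sensitivity_pct <= 100 and 0 <= specificity_pct <= 100):
        raise ValueError("percentages must lie in [0, 100]")
    tp = int(Decimal(repr(sensitivity_pct * n_pos / 100.0)).quantize(
        Decimal("1"), rounding=ROUND_HALF_UP))
    tn = int(Decimal(repr(specificity_pct * n_neg / 100.0)).quantize(
        Decimal("1"), rounding=ROUND_HALF_UP))
    return ConfusionMetrics(tp=tp, fp=n_neg - tn, tn=tn, fn=n_pos - tp)


# ---------------------------------------------------------------------------
# timing agreement

AGREEMENT_BIN_LABELS = ("<=1", ">1,<=2", ">2,<=3", ">3,<=6", ">6")
_BIN_EDGES_MONTHS = (1.0, 2.0, 3.0, 6.0)


@dataclass
class AgreementTable:
    """Frequency table of |estimated - gold recurrence date| in months."""
    counts: tuple[int, ...]
    n_total: int
    bin_labels: tuple[str, ...] = AGREEMENT_BIN_LABELS

    @property
    def cumulative(self) -> tuple[int, ...]:
        return tuple(np.cumsum(self.counts).tolist())

    @property
    def percents(self) -> tuple[float, ...]:
        return tuple(_pct(c, self.n_total) for c in self.counts)

    @property
    def cumulative_percents(self) -> tuple[float, ...]:
        return tuple(_pct(c, self.n_total) for c in self.cumulative)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_months": self.bin_labels,
            "count": self.counts,
            "percent": self.percents,
            "cumulative": self.cumulative,
            "cumulative_percent": self.cumulative_percents,
        })


def _bin_index(diff_months: float) -> int:
    for i, edge in enumerate(_BIN_EDGES_MONTHS):
        if diff_months <= edge:
            return i
    return len(_BIN_EDGES_MONTHS)


def timing_agreement(calls, gold: Iterable[GoldLabel],
                     month_len_days: float = MONTH_DAYS) -> AgreementTable:
    """Bin the absolute difference between estimated and chart-review
    recurrence dates over all gold-recurrent patients.

    Gold-recurrent patients the algorithm called non-recurrent contribute to
    the ``>6`` bin (their difference is unbounded), so the table always
    accounts for every gold-recurrent patient.
    """
    if isinstance(calls, Mapping):
        est: dict[str, Optional[datetime.date]] = dict(calls)
    else:
        est = {c.patient_id: c.estimated_recurrence_date for c in calls
               if c.predicted_recurred}
    counts = [0] * 5
    n_total = 0
    for g in gold:
        if not g.recurred:
            continue
        n_total += 1
        date = est.get(g.patient_id)
        if date is None:
            counts[-1] += 1
        else:
            diff = abs((date - g.recurrence_date).days) / month_len_days
            counts[_bin_index(diff)] += 1
    return AgreementTable(counts=tuple(counts), n_total=n_total)


# ---------------------------------------------------------------------------
# RFS length comparison

def _as_times(records) -> np.ndarray:
    arr = [r.time_days if isinstance(r, SurvivalRecord) else r for r in records]
    return np.asarray(arr, dtype=float)


def compare_rfs_lengths(records_a, records_b, paired: bool = False) -> float:
    """Two-sided Wilcoxon comparison of two samples of RFS lengths (days).

    Rank-sum (Mann–Whitney) by default; exact distribution when both groups
    have fewer than 20 observations, normal approximation with tie
    correction otherwise. ``paired=True`` switches to the signed-rank test
    on per-patient differences (samples must then align).
    """
    a, b = _as_times(records_a), _as_times(records_b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison requires aligned samples")
        d = a - b
        if np.all(d == 0):
            return 1.0
        return float(stats.wilcoxon(a, b, alternative="two-sided").pvalue)
    method = "exact" if max(len(a), len(b)) < 20 and not _has_ties(a, b) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def _has_ties(a: np.ndarray, b: np.ndarray) -> bool:
    pooled = np.concatenate([a, b])
    return len(np.unique(pooled)) < len(pooled)


# ---------------------------------------------------------------------------
# Kaplan–Meier and log-rank

@dataclass
class KMResult:
    times: np.ndarray
    survival: np.ndarray
    median_days: float
    fitter: KaplanMeierFitter = field(repr=False)

    def at(self, t: float) -> float:
        return float(self.fitter.predict(t))


def _duration_event(records) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(records, pd.DataFrame):
        return records["time_days"].to_numpy(float), records["event"].to_numpy(bool)
    t = np.asarray([r.time_days for r in records], dtype=float)
    e = np.asarray([r.event for r in records], dtype=bool)
    return t, e


def km_curve(records) -> KMResult:
    """Product-limit estimator of recurrence-free survival."""
    t, e = _duration_event(records)
    if len(t) == 0:
        raise ValueError("need at least one record")
    if (t < 0).any():
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter().fit(t, e)
    sf = kmf.survival_function_
    return KMResult(times=sf.index.to_numpy(float),
                    survival=sf.iloc[:, 0].to_numpy(float),
                    median_days=float(kmf.median_survival_time_),
                    fitter=kmf)


def logrank(records_a, records_b) -> float:
    """Two-group log-rank test p-value."""
    ta, ea = _duration_event(records_a)
    tb, eb = _duration_event(records_b)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be non-empty")
    return float(logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb).p_value)


# ---------------------------------------------------------------------------
# Cox concordance

#: Default covariate set for the Cox comparison (dummy coding, first level
#: is the reference). Histology is not part of the baseline schema and the
#: diagnosis-year grouping is derived from the diagnosis date.
AGE_BINS = ((35, "<=35"), (40, "36-40"), (55, "41-55"), (float("inf"), ">=56"))
DXYEAR_BINS = ((2009, "2007-2009"), (2012, "2010-2012"), (float("inf"), "2013-2015"))


def cohort_covariates(cohort: Cohort) -> pd.DataFrame:
    """Dummy-coded patient covariates for Cox regression, indexed by patient.

    Age group, stage, ER/PR/HER2, grade, diagnosis-year group, and receipt
    of chemo / radiotherapy / hormone therapy derived from the event stream.
    """
    received = {pid: {e.event_type for e in evs}
                for pid, evs in cohort.events_by_patient().items()}
    rows = []
    for b in cohort.baselines:
        age_grp = next(lab for hi, lab in AGE_BINS if b.age_at_diagnosis <= hi)
        yr_grp = next(lab for hi, lab in DXYEAR_BINS if b.diagnosis_date.year <= hi)
        got = received.get(b.patient_id, set())
        rows.append({
            "patient_id": b.patient_id,
            "age_36_40": age_grp == "36-40", "age_41_55": age_grp == "41-55",
            "age_ge56": age_grp == ">=56",
            "stage_II": b.stage == "II", "stage_III": b.stage == "III",
            "er_pos": b.er == "pos", "pr_pos": b.pr == "pos", "her2_pos": b.her2 == "pos",
            "grade_2": b.grade == "2", "grade_3": b.grade == "3",
            "hormone_yes": "hormone_dispense" in got,
            "radiotherapy_yes": "radiation_fraction" in got,
            "chemotherapy_yes": "chemo_admin" in got,
            "dxyear_2010_2012": yr_grp == "2010-2012",
            "dxyear_2013_2015": yr_grp == "2013-2015",
        })
    return pd.DataFrame(rows).set_index("patient_id").astype(float)


@dataclass
class ConcordanceReport:
    rows: pd.DataFrame
    direction_match_fraction: float
    significance_match_fraction: float
    notes: list[str] = field(default_factory=list)


def _fit_cox(df: pd.DataFrame) -> tuple[Optional[pd.DataFrame], Optional[str]]:
    for penalizer in (0.0, 0.05):
        cph = CoxPHFitter(penalizer=penalizer)
        try:
            cph.fit(df, duration_col="time_days", event_col="event")
        except Exception as exc:  # lifelines ConvergenceError and kin
            last = f"{type(exc).__name__}: {exc}"
            continue
        note = None if penalizer == 0.0 else f"fitted with ridge penalizer {penalizer}"
        return cph.summary, note
    return None, last


def cox_concordance(survival_a, survival_b, covariates: pd.DataFrame) -> ConcordanceReport:
    """Fit one Cox PH model (Efron ties) per survival dataset over the same
    covariates and compare, per covariate, the hazard-ratio direction
    (above/below 1) and the significance verdict at the 5% level.

    Datasets that fail to converge even with a small ridge are flagged and
    excluded from the match fractions.
    """
    frames = []
    for records in (survival_a, survival_b):
        t, e = _duration_event(records)
        pids = ([r.patient_id for r in records] if not isinstance(records, pd.DataFrame)
                else list(records.index))
        df = covariates.loc[pids].copy()
        df["time_days"], df["event"] = t, e.astype(int)
        frames.append(df)

    notes: list[str] = []
    summaries = []
    for label, df in zip(("A", "B"), frames):
        summary, note = _fit_cox(df)
        if summary is None:
            notes.append(f"dataset {label}: Cox model failed to converge ({note})")
        elif note:
            notes.append(f"dataset {label}: {note}")
        summaries.append(summary)

    rows = []
    for cov in covariates.columns:
        row = {"covariate": cov}
        ok = all(s is not None and cov in s.index for s in summaries)
        if ok:
            (ca, pa), (cb, pb) = ((s.loc[cov, "coef"], s.loc[cov, "p"]) for s in summaries)
            row.update(hr_a=float(np.exp(ca)), p_a=float(pa),
                       hr_b=float(np.exp(cb)), p_b=float(pb),
                       direction_match=bool((ca > 0) == (cb > 0)),
                       significance_match=bool((pa < ALPHA) == (pb < ALPHA)),
                       converged=True)
        else:
            row.update(hr_a=np.nan, p_a=np.nan, hr_b=np.nan, p_b=np.nan,
                       direction_match=None, significance_match=None, converged=False)
        rows.append(row)
    table = pd.DataFrame(rows).set_index("covariate")
    usable = table[table["converged"]]
    return ConcordanceReport(
        rows=table,
        direction_match_fraction=(float(usable["direction_match"].mean())
                                  if len(usable) else float("nan")),
        significance_match_fraction=(float(usable["significance_match"].mean())
                                     if len(usable) else float("nan")),
        notes=notes)


# ---------------------------------------------------------------------------
# group characteristics

def compare_characteristics(groups: Mapping[str, pd.DataFrame],
                            variables: Mapping[str, str]) -> pd.DataFrame:
    """Compare baseline characteristics between groups, one row per variable.

    ``variables`` maps column name -> 'categorical' | 'continuous'.
    Categorical variables use the chi-square test, replaced by Fisher's
    exact test on 2x2 tables with any expected cell below 5; continuous
    variables (two groups) use the t-test when both groups pass a Shapiro
    normality check, the rank-sum test otherwise. Summaries are count (%)
    per level for categoricals and median (IQR) for continuous variables.
    """
    names = list(groups)
    out = []
    for var, kind in variables.items():
        for g in groups.values():
            if var not in g.columns:
                raise ValueError(f"variable {var!r} absent from a group table")
        row: dict = {"variable": var, "type": kind}
        if kind == "categorical":
            levels = sorted(set().union(*[set(g[var].astype(str)) for g in groups.values()]))
            table = np.array([[int((g[var].astype(str) == lv).sum()) for lv in levels]
                              for g in groups.values()])
            for name, counts in zip(names, table):
                total = counts.sum()
                row[name] = "; ".join(f"{lv}: {c} ({_pct(c, total)}%)"
                                      for lv, c in zip(levels, counts))
            table = table[:, table.sum(axis=0) > 0]
            if table.shape == (2, 2):
                expected = stats.contingency.expected_freq(table)
                if (expected < 5).any():
                    row["test"] = "fisher"
                    row["p_value"] = float(stats.fisher_exact(table)[1])
                else:
                    row["test"] = "chi_square"
                    row["p_value"] = float(stats.chi2_contingency(table)[1])
            elif table.shape[1] < 2 or table.shape[0] < 2:
                row["test"], row["p_value"] = "degenerate", float("nan")
            else:
                row["test"] = "chi_square"
                row["p_value"] = float(stats.chi2_contingency(table)[1])
        elif kind == "continuous":
            if len(names) != 2:
                raise ValueError("continuous comparison supports exactly two groups")
            xs = [groups[name][var].astype(float).to_numpy() for name in names]
            for name, x in zip(names, xs):
                if len(x):
                    q25, med, q75 = np.percentile(x, [25, 50, 75])
                    row[name] = f"{med:g} ({q25:g}-{q75:g})"
                else:
                    row[name] = "-"
            if any(len(x) < 3 for x in xs):
                row["test"], row["p_value"] = "degenerate", float("nan")
                out.append(row)
                continue
            normal = all(np.ptp(x) > 0 and stats.shapiro(x).pvalue >= ALPHA for x in xs)
            if normal:
                row["test"] = "t_test"
                row["p_value"] = float(stats.ttest_ind(*xs).pvalue)
            else:
                row["test"] = "rank_sum"
                row["p_value"] = float(stats.mannwhitneyu(
                    *xs, alternative="two-sided").pvalue)
        else:
            raise ValueError(f"unknown variable type {kind!r} for {var!r}")
        out.append(row)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# end-to-end report

def gold_survival_records(cohort: Cohort) -> list[SurvivalRecord]:
    """Chart-review RFS records: event at the gold recurrence date, censored
    at last contact otherwise."""
    if cohort.labels is None:
        raise ValueError("cohort has no gold labels; cannot validate")
    index = cohort.baseline_index()
    records = []
    for g in cohort.labels:
        b = index[g.patient_id]
        origin_name = "surgery" if b.surgery_date is not None else "diagnosis"
        origin = b.surgery_date if b.surgery_date is not None else b.diagnosis_date
        if g.recurred:
            records.append(SurvivalRecord(g.patient_id,
                                          (g.recurrence_date - origin).days, True,
                                          origin_name))
        else:
            records.append(SurvivalRecord(g.patient_id,
                                          (b.last_contact_date - origin).days, False,
                                          origin_name))
    return records


@dataclass
class OperatingPointReport:
    confusion: ConfusionMetrics
    agreement: AgreementTable
    rfs_wilcoxon_p: float
    logrank_p: float
    km_estimated: KMResult
    concordance: ConcordanceReport
    characteristics: pd.DataFrame
    calls: list[RecurrenceCall] = field(repr=False)
    records: list[SurvivalRecord] = field(repr=False)


@dataclass
class ReportBundle:
    km_gold: KMResult
    by_operating_point: dict[str, OperatingPointReport]

    def write(self, out_dir, plot: bool = True) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        metric_rows, agree_frames, conc_frames, char_frames = [], [], [], []
        lines = ["Validation of algorithm calls against chart review",
                 "=" * 51, ""]
        for name, rep in self.by_operating_point.items():
            cm = rep.confusion
            metric_rows.append({"operating_point": name, **cm.as_dict(),
                                "rfs_wilcoxon_p": rep.rfs_wilcoxon_p,
                                "logrank_p": rep.logrank_p})
            agree_frames.append(rep.agreement.to_frame().assign(operating_point=name))
            conc_frames.append(rep.concordance.rows.reset_index().assign(operating_point=name))
            char_frames.append(rep.characteristics.assign(operating_point=name))
            lines += [
                f"[{name}]",
                f"  flagged {cm.flagged} / censored {cm.censored} of {cm.total}",
                f"  sensitivity {cm.sensitivity}%, specificity {cm.specificity}%, "
                f"PPV {cm.ppv}%, NPV {cm.npv}%, accuracy {cm.accuracy}%",
                f"  within 3 months of gold date: "
                f"{rep.agreement.cumulative[2]} ({rep.agreement.cumulative_percents[2]}%)",
                f"  RFS rank-sum p = {rep.rfs_wilcoxon_p:.3f}, "
                f"log-rank p = {rep.logrank_p:.3f}",
                "  (log-rank compares estimated vs chart-review curves over the "
                "same patients; the two samples are not independent)",
                f"  Cox direction match {rep.concordance.direction_match_fraction:.2f}, "
                f"significance match {rep.concordance.significance_match_fraction:.2f}",
                "",
            ]
        pd.DataFrame(metric_rows).to_csv(out / "metrics.csv", index=False)
        pd.concat(agree_frames).to_csv(out / "agreement.csv", index=False)
        pd.concat(conc_frames).to_csv(out / "concordance.csv", index=False)
        pd.concat(char_frames).to_csv(out / "characteristics.csv", index=False)
        (out / "summary.txt").write_text("\n".join(lines))
        if plot:
            self._plot(out / "km_overlay.png")

    def _plot(self, path) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(7, 5))
        ax.step(self.km_gold.times / DAYS_IN_YEAR, self.km_gold.survival,
                where="post", label="chart review", lw=2, color="black")
        for name, rep in self.by_operating_point.items():
            ax.step(rep.km_estimated.times / DAYS_IN_YEAR, rep.km_estimated.survival,
                    where="post", label=name)
        ax.set_xlabel("years from surgery")
        ax.set_ylabel("recurrence-free survival")
        ax.legend()
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


DAYS_IN_YEAR = 365.25


def validation_report(cohort: Cohort, trees: Mapping[str, DecisionTree],
                      config: Optional[IndicatorConfig] = None) -> ReportBundle:
    """Run the whole battery for every operating point against gold labels."""
    if cohort.labels is None:
        raise ValueError("cohort has no gold labels; cannot validate")
    config = config or IndicatorConfig()
    gold_records = gold_survival_records(cohort)
    covariates = cohort_covariates(cohort)
    km_gold = km_curve(gold_records)

    gold_by_pid = cohort.label_index()
    reports: dict[str, OperatingPointReport] = {}
    for name, tree in trees.items():
        calls, records = call_cohort(cohort, tree, config)
        cm = confusion_metrics(calls, cohort.labels)
        agreement = timing_agreement(calls, cohort.labels)
        # whole-cohort RFS lengths (censored times included), as in the
        # primary comparison; the recurrent-only subset is selection-biased
        wilcoxon_p = compare_rfs_lengths([r.time_days for r in records],
                                         [r.time_days for r in gold_records])
        lr_p = logrank(records, gold_records)
        km_est = km_curve(records)
        concordance = cox_concordance(records, gold_records, covariates)

        base = pd.DataFrame([{
            "patient_id": b.patient_id, "stage": b.stage, "grade": b.grade,
            "er": b.er, "pr": b.pr, "her2": b.her2,
            "surgery_type": b.surgery_type, "age": b.age_at_diagnosis,
        } for b in cohort.baselines]).set_index("patient_id")
        est_rec = base.loc[[c.patient_id for c in calls if c.predicted_recurred]]
        gold_rec = base.loc[[g.patient_id for g in cohort.labels if g.recurred]]
        characteristics = compare_characteristics(
            {"chart_review_recurrent": gold_rec, "algorithm_recurrent": est_rec},
            {"stage": "categorical", "grade": "categorical", "er": "categorical",
             "pr": "categorical", "her2": "categorical",
             "surgery_type": "categorical", "age": "continuous"})

        reports[name] = OperatingPointReport(
            confusion=cm, agreement=agreement, rfs_wilcoxon_p=wilcoxon_p,
            logrank_p=lr_p, km_estimated=km_est, concordance=concordance,
            characteristics=characteristics, calls=calls, records=records)
    return ReportBundle(km_gold=km_gold, by_operating_point=reports)
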