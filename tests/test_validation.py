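"""Validation battery: metrics, agreement tables, survival comparisons."""
import datetime
import itertools

import numpy as np
import pandas as pd
import pytest

from rfskit import (compare_characteristics, compare_rfs_lengths, confusion_metrics,
                    cox_concordance, fit_operating_points, km_curve, logrank,
                    reconstruct_confusion, timing_agreement, validation_report)
from rfskit.cohort import GoldLabel
from rfskit.timing import SurvivalRecord
from rfskit.validation import cohort_covariates, gold_survival_records, round1

from conftest import D


def _maps(tp, fn, fp, tn):
    calls, gold = {}, {}
    i = 0
    for c, g, n in (("y", "y", tp), ("n", "y", fn), ("y", "n", fp), ("n", "n", tn)):
        for _ in range(n):
            calls[f"P{i}"] = c == "y"
            gold[f"P{i}"] = g == "y"
            i += 1
    return calls, gold


class TestConfusion:
    def test_perfect_agreement(self):
        cm = confusion_metrics(*_maps(10, 0, 0, 30))
        assert cm.sensitivity == 100.0 and cm.specificity == 100.0

    def test_high_sensitivity_operating_point_arithmetic(self):
        cm = confusion_metrics(*_maps(tp=114, fn=7, fp=30, tn=447))
        assert cm.sensitivity == 94.2
        assert cm.ppv == 79.2
        assert cm.npv == 98.5

    def test_high_accuracy_operating_point_arithmetic(self):
        cm = confusion_metrics(*_maps(tp=103, fn=18, fp=13, tn=464))
        assert cm.accuracy == 94.8

    def test_patient_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics({"A": True}, {"B": True})


class TestReconstruct:
    def test_flagged_count_follows_from_sens_spec(self):
        cm = reconstruct_confusion(94.2, 93.7, 121, 477)
        assert cm.flagged == 144

    def test_perfect_percentages(self):
        cm = reconstruct_confusion(100, 100, 121, 477)
        assert (cm.tp, cm.tn) == (121, 477)
        assert cm.accuracy == 100.0

    def test_ppv_follows_from_sens_spec(self):
        assert reconstruct_confusion(75.2, 98.3, 121, 477).ppv == 91.9

    @pytest.mark.parametrize("sens, spec", [(94.2, 93.7), (75.2, 98.3), (85.1, 97.3)])
    def test_rounding_roundtrip(self, sens, spec):
        cm = reconstruct_confusion(sens, spec, 121, 477)
        assert abs(cm.sensitivity - sens) <= 0.1
        assert abs(cm.specificity - spec) <= 0.1


def agreement_fixture(per_bin, missed=0):
    """Gold-recurrent patients with estimated dates offset to land in the
    five month bins (offsets 15/45/75/120/250 days), plus missed patients."""
    offsets = (15, 45, 75, 120, 250)
    gold, calls = [], {}
    i = 0
    base = D("2010-01-01")
    for count, off in zip(per_bin, offsets):
        for _ in range(count):
            pid = f"R{i}"
            gold.append(GoldLabel(pid, True, base))
            calls[pid] = base + datetime.timedelta(days=off)
            i += 1
    for _ in range(missed):
        gold.append(GoldLabel(f"R{i}", True, base))
        i += 1
    return calls, gold


class TestTimingAgreement:
    def test_exact_dates_all_in_first_bin(self):
        calls, gold = agreement_fixture((8, 0, 0, 0, 0))
        calls = {p: D("2010-01-01") for p in calls}
        table = timing_agreement(calls, gold)
        assert table.counts == (8, 0, 0, 0, 0)
        assert table.cumulative_percents[0] == 100.0

    def test_high_accuracy_bin_profile(self):
        calls, gold = agreement_fixture((47, 22, 9, 14, 29))
        table = timing_agreement(calls, gold)
        assert table.n_total == 121
        assert table.cumulative[2] == 78
        assert table.cumulative_percents[2] == 64.5

    def test_high_sensitivity_bin_profile(self):
        calls, gold = agreement_fixture((51, 24, 11, 12, 23))
        table = timing_agreement(calls, gold)
        assert table.cumulative[3] == 98
        assert table.cumulative_percents[3] == 81.0

    def test_missed_patients_count_in_last_bin(self):
        calls, gold = agreement_fixture((5, 0, 0, 0, 0), missed=3)
        table = timing_agreement(calls, gold)
        assert table.counts == (5, 0, 0, 0, 3)
        assert table.cumulative[-1] == table.n_total == 8

    def test_cumulative_monotone_and_complete(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            per_bin = tuple(int(x) for x in rng.integers(0, 20, size=5))
            calls, gold = agreement_fixture(per_bin, missed=int(rng.integers(0, 5)))
            table = timing_agreement(calls, gold)
            cum = table.cumulative
            assert all(a <= b for a, b in zip(cum, cum[1:]))
            assert cum[-1] == table.n_total


class TestRfsComparison:
    def test_identical_samples(self):
        x = list(range(10, 200, 13))
        assert compare_rfs_lengths(x, x) >= 0.99

    def test_disjoint_shifted_samples(self):
        rng = np.random.default_rng(0)
        a = rng.normal(100, 5, 50)
        b = rng.normal(1000, 5, 50)
        assert compare_rfs_lengths(a, b) < 0.001

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            compare_rfs_lengths([], [1, 2])

    def test_matches_exact_permutation_at_n8(self):
        """p agrees with full enumeration of the rank-sum null (C(16,8))."""
        rng = np.random.default_rng(21)
        a = rng.normal(0.0, 1.0, 8)
        b = rng.normal(0.8, 1.0, 8)
        p_impl = compare_rfs_lengths(a, b)
        pooled = np.concatenate([a, b])
        ranks = pd.Series(pooled).rank().to_numpy()
        observed = ranks[:8].sum()
        null = [sum(combo) for combo in itertools.combinations(ranks, 8)]
        mean = np.mean(null)
        p_exact = np.mean([abs(s - mean) >= abs(observed - mean) - 1e-9 for s in null])
        assert p_impl == pytest.approx(p_exact, abs=0.01)

    def test_paired_flag_uses_signed_rank(self):
        a = [100, 200, 300, 400, 150, 250, 350]
        assert compare_rfs_lengths(a, a, paired=True) == 1.0


def _records(times, events):
    return [SurvivalRecord(f"P{i}", t, bool(e), "surgery")
            for i, (t, e) in enumerate(zip(times, events))]


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survivor(self):
        times = [30, 60, 90, 120, 150]
        km = km_curve(_records(times, [1] * 5))
        for t in times:
            assert km.at(t) == pytest.approx(np.mean([x > t for x in times]))

    def test_all_censored_stays_at_one(self):
        km = km_curve(_records([10, 20, 30], [0, 0, 0]))
        assert km.at(30) == 1.0

    def test_hand_computed_product_limit(self):
        # events at 2, 5, 5, 9; censored at 4 and 7
        km = km_curve(_records([2, 4, 5, 5, 7, 9], [1, 0, 1, 1, 0, 1]))
        assert km.at(2) == pytest.approx(5 / 6)
        assert km.at(5) == pytest.approx(5 / 6 * 2 / 4)
        assert km.at(9) == pytest.approx(0.0)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            km_curve(_records([-1, 5], [1, 1]))


class TestLogrank:
    def test_identical_groups(self):
        recs = _records([10, 20, 30, 40, 50], [1, 1, 0, 1, 0])
        assert logrank(recs, recs) >= 0.99

    def test_separated_exponentials(self):
        rng = np.random.default_rng(4)
        a = _records(rng.exponential(100, 100).astype(int) + 1, [1] * 100)
        b = _records(rng.exponential(400, 100).astype(int) + 1, [1] * 100)
        assert logrank(a, b) < 0.001

    def test_statistic_matches_textbook_formula(self):
        """(O - E)^2 / V on a 10-record two-group fixture, computed by hand."""
        from lifelines.statistics import logrank_test
        ta, ea = [3, 5, 8, 10, 12], [1, 1, 1, 0, 1]
        tb, eb = [2, 4, 6, 9, 11], [1, 0, 1, 1, 1]
        o_minus_e, var = 0.0, 0.0
        event_times = sorted({t for t, e in zip(ta + tb, ea + eb) if e})
        for t in event_times:
            na = sum(1 for x in ta if x >= t)
            nb = sum(1 for x in tb if x >= t)
            da = sum(1 for x, e in zip(ta, ea) if x == t and e)
            db = sum(1 for x, e in zip(tb, eb) if x == t and e)
            n, d = na + nb, da + db
            o_minus_e += da - d * na / n
            if n > 1:
                var += d * (na / n) * (nb / n) * (n - d) / (n - 1)
        chi2 = o_minus_e ** 2 / var
        res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
        assert res.test_statistic == pytest.approx(chi2, abs=1e-8)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank([], _records([1], [1]))


class TestCoxConcordance:
    def test_identical_datasets_fully_concordant(self):
        rng = np.random.default_rng(8)
        n = 200
        x = rng.random(n) < 0.5
        t = rng.exponential(np.where(x, 200, 400)).astype(int) + 1
        recs = _records(t, [1] * n)
        cov = pd.DataFrame({"x": x.astype(float)},
                           index=[f"P{i}" for i in range(n)])
        rep = cox_concordance(recs, recs, cov)
        assert rep.direction_match_fraction == 1.0
        assert rep.significance_match_fraction == 1.0

    def test_recovers_planted_hazard_ratio(self):
        """A log-2 hazard effect on a binary covariate is recovered within
        20% at n=1000 (exponential survival, light censoring)."""
        rng = np.random.default_rng(15)
        n = 1000
        x = rng.random(n) < 0.5
        rate = 0.001 * np.exp(np.log(2.0) * x)
        t = rng.exponential(1.0 / rate)
        censor = rng.exponential(2000.0, n)
        obs = np.minimum(t, censor)
        event = t <= censor
        recs = _records(obs.astype(int) + 1, event.astype(int))
        cov = pd.DataFrame({"x": x.astype(float)}, index=[f"P{i}" for i in range(n)])
        rep = cox_concordance(recs, recs, cov)
        assert rep.rows.loc["x", "hr_a"] == pytest.approx(2.0, rel=0.2)


class TestCharacteristics:
    def test_identical_groups_not_significant(self):
        g = pd.DataFrame({"stage": ["II"] * 30 + ["III"] * 20})
        out = compare_characteristics({"a": g, "b": g.copy()}, {"stage": "categorical"})
        assert out.loc[0, "p_value"] == pytest.approx(1.0)

    def test_contrasting_2x2_table(self):
        a = pd.DataFrame({"flag": ["yes"] * 20 + ["no"] * 80})
        b = pd.DataFrame({"flag": ["yes"] * 50 + ["no"] * 50})
        out = compare_characteristics({"a": a, "b": b}, {"flag": "categorical"})
        assert out.loc[0, "test"] == "chi_square"
        assert out.loc[0, "p_value"] < 0.001

    def test_sparse_table_switches_to_fisher(self):
        a = pd.DataFrame({"flag": ["yes"] * 2 + ["no"] * 30})
        b = pd.DataFrame({"flag": ["yes"] * 1 + ["no"] * 28})
        out = compare_characteristics({"a": a, "b": b}, {"flag": "categorical"})
        assert out.loc[0, "test"] == "fisher"

    def test_skewed_continuous_uses_rank_sum(self):
        rng = np.random.default_rng(2)
        a = pd.DataFrame({"age": rng.exponential(10, 80)})
        b = pd.DataFrame({"age": rng.exponential(10, 80)})
        out = compare_characteristics({"a": a, "b": b}, {"age": "continuous"})
        assert out.loc[0, "test"] == "rank_sum"

    def test_unknown_variable_rejected(self):
        with pytest.raises(ValueError):
            compare_characteristics({"a": pd.DataFrame({"x": [1]})}, {"y": "continuous"})


class TestRound1:
    @pytest.mark.parametrize("x, expected", [
        (64.46, 64.5), (80.99, 81.0), (79.16, 79.2), (94.0, 94.0), (98.45, 98.5),
    ])
    def test_half_up_reporting(self, x, expected):
        assert round1(x) == expected


@pytest.fixture(scope="module")
def bundle(default_cohort, default_matrix, default_labels):
    matrix, _ = default_matrix
    trees = fit_operating_points(matrix, default_labels)
    return validation_report(default_cohort, trees)


class TestReportBundle:
    def test_all_sections_for_all_operating_points(self, bundle):
        assert set(bundle.by_operating_point) == {
            "high_sensitivity", "high_accuracy", "high_ppv"}
        for rep in bundle.by_operating_point.values():
            assert rep.confusion.total == 598
            assert rep.agreement.cumulative[-1] == rep.agreement.n_total
            assert 0.0 <= rep.rfs_wilcoxon_p <= 1.0
            assert 0.0 <= rep.logrank_p <= 1.0
            assert not rep.concordance.rows.empty
            assert not rep.characteristics.empty

    def test_censored_complements_flagged(self, bundle):
        for rep in bundle.by_operating_point.values():
            assert rep.confusion.censored == 598 - rep.confusion.flagged

    def test_metrics_match_independent_recount(self, bundle, default_cohort):
        gold = default_cohort.label_index()
        for rep in bundle.by_operating_point.values():
            tp = sum(1 for c in rep.calls
                     if c.predicted_recurred and gold[c.patient_id].recurred)
            fp = sum(1 for c in rep.calls
                     if c.predicted_recurred and not gold[c.patient_id].recurred)
            assert (tp, fp) == (rep.confusion.tp, rep.confusion.fp)

    def test_written_report_files(self, bundle, tmp_path):
        bundle.write(tmp_path, plot=False)
        for name in ("metrics.csv", "agreement.csv", "concordance.csv",
                     "characteristics.csv", "summary.txt"):
            assert (tmp_path / name).exists()

    def test_gold_records_match_labels(self, default_cohort):
        recs = gold_survival_records(default_cohort)
        n_rec = sum(g.recurred for g in default_cohort.labels)
        assert sum(r.event for r in recs) == n_rec
        assert len(recs) == 598

    def test_covariate_table_is_complete(self, default_cohort):
        cov = cohort_covariates(default_cohort)
        assert len(cov) == 598
        assert not cov.isna().any().any()
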