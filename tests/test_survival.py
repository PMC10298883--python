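import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orfsub import survival as sv
from orfsub import synthetic_data as synth


def cohort_from(time, event, expr_rows):
    n = len(time)
    patients = [f"P{i}" for i in range(n)]
    expression = pd.DataFrame.from_dict(expr_rows, orient="index", dtype=float)
    expression.columns = patients
    return sv.SurvivalCohort(patient_ids=patients, time=np.asarray(time, float),
                             event=np.asarray(event, int), expression=expression)


class TestSignatureScore:
    def test_single_gene_mean_raw_is_identity(self):
        c = cohort_from([1, 2, 3, 4], [1, 1, 1, 1], {"G1": [5.0, 1.0, 2.0, 9.0]})
        assert np.allclose(sv.signature_score(c, ["G1"], method="mean_raw"), [5, 1, 2, 9])

    def test_opposite_z_scores_cancel(self):
        v = [1.0, 2.0, 3.0, 4.0]
        c = cohort_from([1, 2, 3, 4], [1, 1, 1, 1], {"G1": v, "G2": [-x for x in v]})
        assert np.allclose(sv.signature_score(c, ["G1", "G2"], method="mean_z"), 0.0)

    def test_three_gene_hand_table(self):
        rows = {"A": [1.0, 2.0, 3.0, 4.0], "B": [4.0, 3.0, 2.0, 1.0], "C": [0.0, 0.0, 10.0, 10.0]}
        c = cohort_from([1, 2, 3, 4], [1, 1, 1, 1], rows)
        z = {}
        for g, v in rows.items():
            v = np.array(v)
            z[g] = (v - v.mean()) / v.std()
        expected = (z["A"] + z["B"] + z["C"]) / 3
        assert np.allclose(sv.signature_score(c, ["A", "B", "C"]), expected)

    def test_missing_gene_fatal(self):
        c = cohort_from([1, 2, 3, 4], [1, 1, 1, 1], {"G1": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(KeyError, match="GHOST"):
            sv.signature_score(c, ["GHOST"])


class TestSplit:
    def test_even_split(self):
        labels = sv.split_groups([1, 2, 3, 4])
        assert list(labels) == ["low", "low", "high", "high"]

    def test_median_ties_go_low(self):
        labels = sv.split_groups([1, 1, 1, 2])
        assert list(labels).count("low") == 3 and list(labels).count("high") == 1

    def test_constant_errors(self):
        with pytest.raises(ValueError):
            sv.split_groups([2, 2, 2, 2])


class TestKMCurve:
    def test_three_events(self):
        curve = sv.km_curve([1, 2, 3], [1, 1, 1])
        assert np.allclose(curve.survival, [2 / 3, 1 / 3, 0.0])

    def test_all_censored_flat(self):
        curve = sv.km_curve([5, 6, 7], [0, 0, 0])
        assert curve.event_times.size == 0

    def test_single_subject(self):
        curve = sv.km_curve([5], [1])
        assert curve.survival[-1] == 0.0 and curve.event_times[0] == 5

    def test_censored_at_event_time_at_risk(self):
        # subject censored at t=2 still counts in the risk set of the t=2 event
        curve = sv.km_curve([2, 2, 3], [1, 0, 1])
        assert curve.at_risk[0] == 3

    def test_matches_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(11)
        t = rng.exponential(10, 40)
        curve = sv.km_curve(t, np.ones(40, int))
        for ti, si in zip(curve.event_times, curve.survival):
            assert si == pytest.approx((t > ti).mean())


class TestQuantileSurvival:
    def make_curve(self, times, survival):
        return sv.KMCurve(np.asarray(times, float), np.asarray(survival, float),
                          np.zeros(len(times), int), np.zeros(len(times), int))

    def test_median_crossing(self):
        assert sv.quantile_survival(self.make_curve([10, 20], [0.6, 0.4]), 0.5) == 20

    def test_upper_quartile_undefined(self):
        assert sv.quantile_survival(self.make_curve([10], [0.9]), 0.25) is None

    def test_exact_boundary_inclusive(self):
        assert sv.quantile_survival(self.make_curve([12, 30], [0.5, 0.1]), 0.5) == 12

    def test_monotone_in_q(self):
        curve = self.make_curve([5, 10, 15, 20], [0.8, 0.6, 0.45, 0.2])
        uq = sv.quantile_survival(curve, 0.25)
        med = sv.quantile_survival(curve, 0.5)
        assert uq <= med


class TestLogrank:
    def test_identical_groups_null(self):
        t = [3, 5, 8, 3, 5, 8]
        e = [1, 1, 0, 1, 1, 0]
        labels = ["low"] * 3 + ["high"] * 3
        res = sv.logrank(t, e, labels)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12) and res.p == pytest.approx(1.0)

    def test_label_swap_invariance(self):
        t = [6, 13, 21, 5, 8, 13]
        e = [1, 0, 1, 1, 1, 1]
        labels = np.array(["low"] * 3 + ["high"] * 3)
        swapped = np.where(labels == "low", "high", "low")
        a, b = sv.logrank(t, e, labels), sv.logrank(t, e, swapped)
        assert a.chi2 == pytest.approx(b.chi2) and a.p == pytest.approx(b.p)

    def test_six_subject_hand_ledger(self):
        """Frozen O/E/V ledger: low=(6,1),(13,0),(21,1); high=(5,1),(8,1),(13,1).
        O_low=2, E_low=49/15, V=433/450, chi2=(2-49/15)^2/V."""
        res = sv.logrank([6, 13, 21, 5, 8, 13], [1, 0, 1, 1, 1, 1], ["low"] * 3 + ["high"] * 3)
        assert res.o_low == 2.0
        assert res.e_low == pytest.approx(49 / 15)
        assert res.chi2 == pytest.approx(1.6674364896073903)
        assert res.p == pytest.approx(0.1966022476343343)

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(21)
        t = rng.exponential(12, 60)
        e = (rng.random(60) < 0.8).astype(int)
        labels = np.where(rng.random(60) < 0.5, "low", "high")
        res = sv.logrank(t, e, labels)
        ref = logrank_test(t[labels == "low"], t[labels == "high"],
                           e[labels == "low"], e[labels == "high"])
        assert res.chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert res.p == pytest.approx(ref.p_value, rel=1e-9)

    def test_monotone_time_transform_invariance(self):
        t = np.array([6.0, 13, 21, 5, 8, 13])
        e = [1, 0, 1, 1, 1, 1]
        labels = ["low"] * 3 + ["high"] * 3
        a = sv.logrank(t, e, labels)
        b = sv.logrank(np.exp(t / 10), e, labels)
        assert a.chi2 == pytest.approx(b.chi2)

    def test_one_group_errors(self):
        with pytest.raises(ValueError):
            sv.logrank([1, 2, 3, 4], [1, 1, 1, 1], ["low"] * 4)


class TestHazardRatio:
    def test_null(self):
        hr, lo, hi = sv.hazard_ratio(5, 5, 7, 7)
        assert hr == 1.0 and lo < 1.0 < hi

    def test_reciprocal_on_swap(self):
        hr, *_ = sv.hazard_ratio(4, 6, 9, 5)
        hr_swapped, *_ = sv.hazard_ratio(9, 5, 4, 6)
        assert hr_swapped == pytest.approx(1 / hr)

    def test_zero_expected_errors(self):
        with pytest.raises(ValueError):
            sv.hazard_ratio(1, 0.0, 1, 1)

    def test_recovery_from_ph_simulation(self):
        cohort, ledger = synth.gen_survival_cohort(
            synth.SurvivalCohortConfig(n_patients=500, true_hr=2.0), seed=77
        )
        result = sv.evaluate_signature(cohort, ledger["signature_genes"])
        assert 1.6 <= result.hr <= 2.5

    def test_median_recovery_across_replicates(self):
        """Median O/E estimate over 200 PH cohorts (n=500) within 10% of the
        true HR for HR in {1, 2}; the O/E estimator attenuates larger
        effects, so at HR=3 it sits below the truth but above 2.2."""
        for true_hr, lo, hi in ((1.0, 0.9, 1.1), (2.0, 1.8, 2.2), (3.0, 2.2, 3.0)):
            cfg = synth.SurvivalCohortConfig(n_patients=500, true_hr=true_hr)
            estimates = []
            for i in range(200):
                cohort, ledger = synth.gen_survival_cohort(cfg, seed=5000 + i)
                estimates.append(sv.evaluate_signature(cohort, ledger["signature_genes"]).hr)
            assert lo <= float(np.median(estimates)) <= hi


class TestEvaluateSignature:
    def test_single_gene_consistency(self):
        cohort, _ = synth.gen_survival_cohort(
            synth.SurvivalCohortConfig(n_patients=80, n_noise_genes=1), ["SIG1"], seed=9
        )
        panel = sv.evaluate_signature(cohort, ["SIG1"])
        gene = sv.evaluate_signature(cohort, ["SIG1"], score_method="mean_raw")
        assert panel.hr == pytest.approx(gene.hr)  # z-scoring is monotone per gene

    def test_power_at_hr2(self):
        cfg = synth.SurvivalCohortConfig(n_patients=300, true_hr=2.0)
        wins = 0
        n_reps = 100
        for i in range(n_reps):
            cohort, ledger = synth.gen_survival_cohort(cfg, seed=8000 + i)
            res = sv.evaluate_signature(cohort, ledger["signature_genes"])
            wins += res.hr > 1 and res.p < 0.05
        assert wins / n_reps >= 0.80

    def test_group_sizes_reported(self):
        cohort, ledger = synth.gen_survival_cohort(
            synth.SurvivalCohortConfig(n_patients=100), seed=13
        )
        res = sv.evaluate_signature(cohort, ledger["signature_genes"])
        assert res.n_low + res.n_high == 100
        assert res.hr_ci[0] <= res.hr <= res.hr_ci[1]


class TestAblation:
    def test_single_carrier_found(self):
        """One planted prognostic gene among inert ones: its removal breaks
        the panel, so the decisive subset is exactly that gene."""
        cohort, _ = synth.gen_survival_cohort(
            synth.SurvivalCohortConfig(n_patients=400, true_hr=2.5, group_shift=6.0, n_noise_genes=2),
            signature_genes=["DRIVER"],
            seed=33,
        )
        panel = ["DRIVER", "NOISE1", "NOISE2"]
        result = sv.ablation(cohort, panel, strategy="greedy")
        assert result.status == "found" and "DRIVER" in result.decisive

    def test_exhaustive_matches_greedy_on_single_carrier(self):
        cohort, _ = synth.gen_survival_cohort(
            synth.SurvivalCohortConfig(n_patients=400, true_hr=2.5, n_noise_genes=3),
            signature_genes=["DRIVER"],
            seed=34,
        )
        panel = ["DRIVER", "NOISE1", "NOISE2", "NOISE3"]
        result = sv.ablation(cohort, panel, strategy="exhaustive_k")
        assert result.status == "found" and result.decisive == ["DRIVER"]

    def test_nonsignificant_panel_rejected(self):
        cohort, _ = synth.gen_survival_cohort(
            synth.SurvivalCohortConfig(n_patients=200, true_hr=1.0, group_shift=0.0, n_noise_genes=2),
            signature_genes=["SIG1"],
            seed=35,
        )
        with pytest.raises(ValueError):
            sv.ablation(cohort, ["SIG1", "NOISE1", "NOISE2"], alpha=1e-12)
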