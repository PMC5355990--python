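import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as ll_logrank

import histotype as ht
from histotype.exceptions import GroupingError, JoinError, ValidationError


def calls_frame(sample_ids, plain, strict, cohort="c1"):
    return pd.DataFrame({"sample_id": sample_ids, "cohort": cohort,
                         "score": 0.0, "call_plain": plain,
                         "call_strict": strict})


def clinical_frame(sample_ids, histology, **extra):
    return pd.DataFrame({"sample_id": sample_ids, "histology": histology,
                         "grade": extra.pop("grade", "2"), **extra})


class TestConcordance:
    def test_all_correct(self):
        ids = [f"s{i}" for i in range(4)]
        hist = ["ductal", "ductal", "lobular", "lobular"]
        rep = ht.concordance_report(calls_frame(ids, hist, hist),
                                    clinical_frame(ids, hist))
        assert rep.plain_concordance == 1.0
        assert rep.strict_concordance == 1.0
        assert rep.indeterminacy_rate == 0.0

    def test_hand_counted_mixed_case(self):
        # 10 samples: 1 discordant plain call; 2 would-be discordant samples
        # are indeterminate under strict -> plain 9/10, strict 8/8
        ids = [f"s{i}" for i in range(10)]
        hist = ["ductal"] * 7 + ["lobular"] * 3
        plain = ["ductal"] * 7 + ["lobular", "lobular", "ductal"]
        strict = plain.copy()
        strict[6] = "indeterminate"   # would have been correct? no: make the
        strict[9] = "indeterminate"   # wrong one and one right one abstain
        plain[6] = "lobular"          # second discordant in plain mode
        rep = ht.concordance_report(
            calls_frame(ids, plain, strict), clinical_frame(ids, hist))
        assert rep.plain_concordance == pytest.approx(8 / 10)
        assert rep.strict_concordance == pytest.approx(8 / 8)
        assert rep.indeterminacy_rate == pytest.approx(2 / 10)
        assert rep.reclassification_rate == pytest.approx(2 / 10)

    def test_ambiguous_histology_excluded_but_counted(self):
        ids = [f"s{i}" for i in range(5)]
        hist = ["ductal", "lobular", "mixed", "other", "ductal"]
        calls = calls_frame(ids, ["ductal"] * 5, ["ductal"] * 5)
        rep = ht.concordance_report(calls, clinical_frame(ids, hist))
        assert rep.n == 3
        assert rep.n_excluded_histology == 2

    def test_orphan_sample_ids_raise(self):
        calls = calls_frame(["a", "zzz"], ["ductal"] * 2, ["ductal"] * 2)
        clin = clinical_frame(["a", "b"], ["ductal", "ductal"])
        with pytest.raises(JoinError):
            ht.concordance_report(calls, clin)


class TestGradeCrosstab:
    def test_single_sample_single_cell(self):
        calls = calls_frame(["s0"], ["lobular"], ["lobular"])
        clin = clinical_frame(["s0"], ["lobular"], grade="2")
        tab = ht.grade_crosstab(calls, clin)
        assert tab.loc[("lobular", "lobular"), "2"] == 1
        assert tab.loc[("lobular", "lobular"), "total"] == 1

    def test_totals_match_input_n(self):
        rng = np.random.default_rng(0)
        n = 40
        ids = [f"s{i}" for i in range(n)]
        hist = rng.choice(["ductal", "lobular"], n)
        grade = rng.choice(["1", "2", "3", "NA"], n)
        calls = calls_frame(ids, rng.choice(["ductal", "lobular"], n),
                            rng.choice(["ductal", "lobular",
                                        "indeterminate"], n))
        clin = clinical_frame(ids, hist, grade=grade)
        tab = ht.grade_crosstab(calls, clin)
        assert tab.loc[("total", ""), "total"] == n

    def test_lobular_calls_enriched_for_grade_two(self):
        wins = 0
        for seed in range(5):
            spec = ht.SimulationSpec(n_cohorts=2, n_per_cohort=150,
                                     n_genes=400, n_informative=50,
                                     grade_na_prob=0.0, seed=seed)
            X, clinical, _ = ht.simulate_cohorts(spec)
            art = ht.train_classifier(X, clinical["histology"].to_numpy(),
                                      ht.RunConfig(seed=seed, cv_folds=5))
            df = art.discovery_scores.merge(clinical, on="sample_id")
            lob = df[df["call_plain"] == "lobular"]["grade"].astype(int)
            duc = df[df["call_plain"] == "ductal"]["grade"].astype(int)
            odds_lob = (lob == 2).mean() / max((lob != 2).mean(), 1e-9)
            odds_duc = (duc == 2).mean() / max((duc != 2).mean(), 1e-9)
            wins += odds_lob > odds_duc
        assert wins >= 4


class TestKaplanMeier:
    def test_no_events_flat_curve(self):
        res = ht.km_estimate([5, 10, 15], [0, 0, 0])
        assert (res.curves["all"]["survival"] == 1.0).all()

    def test_all_events_closed_form(self):
        res = ht.km_estimate([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(res.curves["all"]["survival"],
                                   [1.0, 2 / 3, 1 / 3, 0.0], atol=1e-12)

    def test_censored_at_start_does_not_change_curve(self):
        base = ht.km_estimate([5.0, 10.0], [1, 1]).curves["all"]
        # a sample censored at time 0 drops out before any event
        padded = ht.km_estimate([0.0, 5.0, 10.0], [0, 1, 1]).curves["all"]
        merged = padded[padded["time"].isin(base["time"])]
        np.testing.assert_allclose(merged["survival"].to_numpy(),
                                   base["survival"].to_numpy(), atol=1e-12)

    def test_matches_lifelines_on_random_fixtures(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 50
            times = rng.exponential(60, n)
            events = (rng.random(n) < 0.7).astype(int)
            res = ht.km_estimate(times, events, horizon=120.0)
            t = np.minimum(times, 120.0)
            e = np.where(times > 120.0, 0, events)
            kmf = KaplanMeierFitter().fit(t, e)
            ours = res.curves["all"].set_index("time")["survival"]
            ref = kmf.survival_function_.iloc[:, 0]
            for time in ours.index:
                assert abs(ours.loc[time]
                           - ref[ref.index <= time].iloc[-1]) < 1e-10

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            ht.km_estimate([-1.0, 2.0], [1, 1])


class TestLogrank:
    def test_identical_groups_give_null_statistic(self):
        times = [1, 2, 3, 1, 2, 3]
        events = [1, 1, 0, 1, 1, 0]
        res = ht.logrank_test(times, events, list("AAABBB"))
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_logrank == pytest.approx(1.0)

    def test_hand_computed_toy_tally(self):
        # A: events at 2 and 4; B: event at 1, censored at 5
        res = ht.logrank_test([2, 4, 1, 5], [1, 1, 1, 0], list("AABB"))
        # hand tally: E_A = 1/2 + 2/3 + 1/2 = 5/3, V = 1/4 + 2/9 + 1/4 = 13/18
        assert res.observed["A"] == 2.0
        assert res.expected["A"] == pytest.approx(5 / 3)
        assert res.chi2 == pytest.approx((2 - 5 / 3) ** 2 / (13 / 18))
        # totals of O and E agree
        assert sum(res.observed.values()) == pytest.approx(
            sum(res.expected.values()))

    def test_matches_lifelines_statistic(self):
        rng = np.random.default_rng(12)
        n = 60
        times = rng.exponential(50, n)
        events = (rng.random(n) < 0.8).astype(int)
        group = np.where(rng.random(n) < 0.4, "A", "B")
        res = ht.logrank_test(times, events, group, horizon=1e9)
        ref = ll_logrank(times[group == "A"], times[group == "B"],
                         events[group == "A"], events[group == "B"])
        assert res.chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert res.p_logrank == pytest.approx(ref.p_value, rel=1e-9)

    def test_invariant_under_group_relabeling(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(40, 30)
        events = (rng.random(30) < 0.6).astype(int)
        group = np.where(rng.random(30) < 0.5, "A", "B")
        a = ht.logrank_test(times, events, group)
        b = ht.logrank_test(times, events,
                            np.where(group == "A", "B", "A"))
        assert a.chi2 == pytest.approx(b.chi2, abs=1e-12)

    def test_p_matches_permutation_null(self):
        rng = np.random.default_rng(17)
        n = 40
        group = np.array(["A"] * 20 + ["B"] * 20)
        times = rng.exponential(np.where(group == "A", 40, 70))
        events = (rng.random(n) < 0.8).astype(int)
        res = ht.logrank_test(times, events, group, horizon=1e9)

        # vectorized permutation null of the same O/E/V tally
        B = 20000
        perm = np.stack([rng.permutation(n) for _ in range(B)])
        gmat = (group[perm] == "A")                     # B x n
        O1 = np.zeros(B)
        E1 = np.zeros(B)
        V = np.zeros(B)
        for t in np.unique(times[events == 1]):
            at_risk = times >= t
            dead = (times == t) & (events == 1)
            nn = at_risk.sum()
            d = dead.sum()
            n1 = gmat[:, at_risk].sum(axis=1)
            d1 = gmat[:, dead].sum(axis=1)
            O1 += d1
            E1 += d * n1 / nn
            if nn > 1:
                V += d * (n1 / nn) * (1 - n1 / nn) * (nn - d) / (nn - 1)
        chi2_perm = np.where(V > 0, (O1 - E1) ** 2 / np.maximum(V, 1e-12), 0.0)
        p_perm = (chi2_perm >= res.chi2 - 1e-12).mean()
        mc_err = 3 * np.sqrt(max(p_perm * (1 - p_perm), 1e-6) / B)
        assert abs(res.p_logrank - p_perm) < mc_err + 0.01

    def test_single_group_rejected(self):
        with pytest.raises(GroupingError):
            ht.logrank_test([1, 2], [1, 1], ["A", "A"])


class TestCoxReporting:
    def test_hazard_ratio_direction_on_simulated_classes(self):
        spec = ht.SimulationSpec(n_cohorts=2, n_per_cohort=400, seed=19)
        _, clinical, _ = ht.simulate_cohorts(spec)
        res = ht.cox_hazard_ratio(clinical["surv_time"],
                                  clinical["surv_event"],
                                  clinical["histology"], reference="ductal")
        # generator gives ductal a hazard ratio of 2 vs lobular
        assert res.hazard_ratio < 1.0
        assert res.p_cox_lrt < 0.05
        assert res.hr_ci[0] < res.hazard_ratio < res.hr_ci[1]
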