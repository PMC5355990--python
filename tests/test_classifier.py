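import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import histotype as ht
from histotype.classifier import _candidate_cutoffs
from histotype.exceptions import CalibrationError, ConfigurationError

from conftest import make_matrix


def make_clf(pattern, cutoff=None, band=None):
    g = len(pattern)
    return ht.HistotypeClassifier(
        genes=[f"g{i}" for i in range(g)], pattern=np.asarray(pattern, float),
        gene_means=np.zeros(g), gene_sds=np.ones(g),
        cutoff=cutoff, band=band)


class TestScoring:
    def test_sample_equal_to_pattern_scores_one(self):
        pattern = np.array([1.0, -0.5, 2.0, 0.3])
        clf = make_clf(pattern)
        X = make_matrix(np.column_stack([pattern, -pattern]),
                        sample_ids=["pos", "neg"])
        s = ht.score_samples(clf, X)
        assert s.loc[s.sample_id == "pos", "score"].iloc[0] == pytest.approx(1.0)
        assert s.loc[s.sample_id == "neg", "score"].iloc[0] == pytest.approx(-1.0)

    def test_scores_match_brute_force_pearson(self, rng):
        g = 12
        pattern = rng.normal(size=g)
        means, sds = rng.normal(size=g), rng.uniform(0.5, 2, g)
        clf = ht.HistotypeClassifier(genes=[f"g{i}" for i in range(g)],
                                     pattern=pattern, gene_means=means,
                                     gene_sds=sds)
        vals = rng.normal(size=(g, 10))
        s = ht.score_samples(clf, make_matrix(vals))
        for j in range(10):
            z = (vals[:, j] - means) / sds
            expected = np.corrcoef(z, pattern)[0, 1]
            assert s["score"].iloc[j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_sample_flagged_and_excluded(self, rng):
        clf = make_clf(rng.normal(size=5))
        vals = rng.normal(size=(5, 3))
        vals[:, 1] = 7.0  # constant sub-vector
        with pytest.warns(UserWarning, match="zero-variance"):
            s = ht.score_samples(clf, make_matrix(vals))
        assert len(s) == 2
        assert s.attrs["excluded"] == ["s1"]

    @settings(deadline=None, max_examples=50)
    @given(st.floats(0.1, 10), st.floats(-5, 5))
    def test_score_invariant_to_affine_transform_of_sample(self, a, b):
        rng = np.random.default_rng(3)
        pattern = rng.normal(size=8)
        clf = make_clf(pattern)
        v = rng.normal(size=(8, 1))
        base = ht.score_samples(clf, make_matrix(v))["score"].iloc[0]
        moved = ht.score_samples(clf, make_matrix(a * v + b))["score"].iloc[0]
        assert moved == pytest.approx(base, abs=1e-9)

    def test_pattern_needs_two_genes(self):
        with pytest.raises(ConfigurationError):
            ht.HistotypeClassifier(genes=["only"], pattern=[1.0],
                                   gene_means=[0.0], gene_sds=[1.0])

    def test_json_round_trip(self, tmp_path, rng):
        clf = make_clf(rng.normal(size=4), cutoff=0.2, band=(0.1, 0.35))
        clf.to_json(tmp_path / "clf.json")
        back = ht.HistotypeClassifier.from_json(tmp_path / "clf.json")
        np.testing.assert_array_equal(back.pattern, clf.pattern)
        assert back.cutoff == clf.cutoff and back.band == clf.band


class TestCutoffCalibration:
    def test_perfect_separation_zero_errors(self):
        scores = np.array([-0.8, -0.6, -0.5, 0.4, 0.6])
        labels = ["ductal"] * 3 + ["lobular"] * 2
        c = ht.calibrate_cutoff(scores, labels)
        assert -0.5 < c < 0.4
        calls = np.where(scores > c, "lobular", "ductal")
        assert (calls == labels).all()

    def test_three_score_toy_brute_force(self):
        scores = np.array([0.1, 0.2, 0.15])
        labels = np.array(["ductal", "ductal", "lobular"])
        c = ht.calibrate_cutoff(scores, labels)
        # exhaustive search over every cutoff shows minimum 1 error
        best = min(int((np.where(scores > x, "lobular", "ductal") != labels).sum())
                   for x in np.linspace(-1, 1, 4001))
        achieved = int((np.where(scores > c, "lobular", "ductal") != labels).sum())
        assert best == achieved == 1

    def test_translation_equivariance(self, rng):
        scores = rng.normal(0, 0.3, 40).clip(-0.9, 0.9)
        labels = np.where(rng.random(40) < 0.3, "lobular", "ductal")
        c = ht.calibrate_cutoff(scores, labels)
        shift = 0.05
        c2 = ht.calibrate_cutoff(scores + shift, labels)
        err = int((np.where(scores > c, "lobular", "ductal") != labels).sum())
        err2 = int((np.where(scores + shift > c2, "lobular", "ductal")
                    != labels).sum())
        assert c2 == pytest.approx(c + shift, abs=1e-12)
        assert err == err2

    def test_identical_scores_rejected(self):
        with pytest.raises(CalibrationError):
            ht.calibrate_cutoff([0.5] * 5, ["ductal", "ductal", "ductal",
                                            "lobular", "lobular"])

    def test_candidates_include_sentinels(self):
        c = _candidate_cutoffs(np.array([0.0, 0.5]))
        np.testing.assert_allclose(c, [-1.0, 0.25, 1.0])


class TestStrictBand:
    def test_perfect_separation_band_spans_gap(self):
        rng = np.random.default_rng(2)
        scores = np.concatenate([rng.uniform(-0.9, -0.3, 50),
                                 rng.uniform(0.3, 0.9, 20)])
        labels = ["ductal"] * 50 + ["lobular"] * 20
        c = ht.calibrate_cutoff(scores, labels)
        lo, hi = ht.calibrate_strict_band(scores, labels, c, alpha=0.05)
        assert lo <= -0.3 + 1e-9 and hi >= 0.3 - 1e-9
        # nobody scores inside the empty-interior band
        assert not ((scores > lo) & (scores < hi)).any()

    def test_overlapping_scores_give_partial_indeterminacy(self):
        rng = np.random.default_rng(5)
        n = 300
        y = rng.random(n) < 0.3
        scores = np.clip(rng.normal(np.where(y, 0.25, -0.25), 0.25), -1, 1)
        labels = np.where(y, "lobular", "ductal")
        c = ht.calibrate_cutoff(scores, labels)
        lo, hi = ht.calibrate_strict_band(scores, labels, c, alpha=0.05)
        frac = ((scores > lo) & (scores < hi)).mean()
        assert 0.0 < frac < 1.0
        # reference reimplementation of the same pooled-Z rule
        from scipy import stats as ss

        def errs(x):
            return (np.where(scores > x, "lobular", "ductal") != labels).sum()

        e_star = errs(c) / n
        u = np.unique(scores)
        cands = np.concatenate(([-1], (u[:-1] + u[1:]) / 2, [1]))
        ok = []
        for x in cands:
            e = errs(x) / n
            pbar = (e + e_star) / 2
            z = 0.0 if pbar in (0, 1) else \
                (e - e_star) / np.sqrt(pbar * (1 - pbar) * 2 / n)
            ok.append(2 * ss.norm.sf(abs(z)) > 0.05)
        i = int(np.argmin(np.abs(cands - c)))
        j = i
        while j > 0 and ok[j - 1]:
            j -= 1
        k = i
        while k < len(cands) - 1 and ok[k + 1]:
            k += 1
        ref_lo = -1.0 if j == 0 else u[j - 1]
        ref_hi = 1.0 if k == len(cands) - 1 else u[k]
        assert (lo, hi) == (pytest.approx(ref_lo), pytest.approx(ref_hi))

    def test_band_shrinks_toward_cutoff_as_alpha_grows(self):
        rng = np.random.default_rng(8)
        n = 200
        y = rng.random(n) < 0.3
        scores = np.clip(rng.normal(np.where(y, 0.3, -0.3), 0.3), -1, 1)
        labels = np.where(y, "lobular", "ductal")
        c = ht.calibrate_cutoff(scores, labels)
        widths = []
        for alpha in (0.05, 0.5, 0.999999):
            lo, hi = ht.calibrate_strict_band(scores, labels, c, alpha=alpha)
            widths.append(hi - lo)
        assert widths[0] >= widths[1] >= widths[2]
        assert widths[2] < 0.05


class TestCalls:
    def test_boundary_rules(self):
        clf = make_clf([1.0, -1.0], cutoff=0.2, band=(0.1, 0.4))
        scores = pd.DataFrame({"sample_id": list("abcd"), "cohort": "x",
                               "score": [0.2, 0.21, 0.4, 0.1]})
        plain = ht.call_samples(clf, scores, "plain")
        assert plain["call"].tolist() == ["ductal", "lobular", "lobular",
                                          "ductal"]
        strict = ht.call_samples(clf, scores, "strict")
        assert strict["call"].tolist() == ["indeterminate", "indeterminate",
                                           "lobular", "ductal"]

    def test_plain_equals_strict_when_band_interior_empty(self):
        clf = make_clf([1.0, -1.0], cutoff=0.0, band=(-0.2, 0.2))
        scores = pd.DataFrame({"sample_id": list("ab"), "cohort": "x",
                               "score": [-0.5, 0.5]})
        both = ht.annotate_calls(clf, scores)
        assert (both["call_plain"] == both["call_strict"]).all()

    def test_uncalibrated_classifier_cannot_call(self):
        clf = make_clf([1.0, -1.0])
        scores = pd.DataFrame({"sample_id": ["a"], "cohort": "x",
                               "score": [0.0]})
        with pytest.raises(ConfigurationError):
            ht.call_samples(clf, scores, "plain")


class TestPipelineProperties:
    def test_strict_concordance_at_least_plain(self):
        """Excluding indeterminates should not hurt agreement (strict mode
        abstains exactly where the score is least decisive)."""
        wins = 0
        for seed in range(10):
            spec = ht.SimulationSpec(n_cohorts=2, n_per_cohort=150,
                                     n_genes=400, n_informative=50, seed=seed)
            X, clinical, _ = ht.simulate_cohorts(spec)
            art = ht.train_classifier(X, clinical["histology"].to_numpy(),
                                      ht.RunConfig(seed=seed, cv_folds=5))
            rep = ht.concordance_report(art.discovery_scores, clinical)
            if np.isnan(rep.strict_concordance) or \
                    rep.strict_concordance >= rep.plain_concordance:
                wins += 1
        assert wins >= 9

    def test_cross_platform_call_agreement(self, trained):
        art, X, clinical, truth = trained
        spec = ht.SimulationSpec(**truth["spec"])
        agree = []
        for seed in range(5):
            Xr = ht.rnaseq_like_transform(X, spec, seed=seed)
            calls_a = ht.score_cohorts(art.classifier, X)
            calls_r = ht.score_cohorts(art.classifier, Xr)
            merged = calls_a.merge(calls_r, on="sample_id",
                                   suffixes=("_array", "_rnaseq"))
            agree.append((merged["call_plain_array"]
                          == merged["call_plain_rnaseq"]).mean())
        assert sum(a >= 0.9 for a in agree) >= 4
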