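"""Predictor scores, ROC/AUC, DeLong comparison, Youden cut-points."""

import numpy as np
import pandas as pd
import pytest

import amyscreen as amy


def _pair_auc_oracle(scores, labels):
    """O(n^2) AUC: fraction of (pos, neg) pairs ordered correctly, ties = 1/2."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestLcmsComposite:
    def test_hand_computed_five_rows(self):
        t = pd.DataFrame(
            {
                "lcms_ab40": [280.0, 300.0, 260.0, 310.0, 290.0],
                "lcms_ab42": [30.0, 25.0, 28.0, 22.0, 31.0],
                "lcms_abm3_40": [31.0, 29.0, 33.0, 27.0, 30.0],
            }
        )
        r1 = t["lcms_abm3_40"] / t["lcms_ab42"]
        r2 = t["lcms_ab40"] / t["lcms_ab42"]
        z1 = (r1 - r1.mean()) / r1.std(ddof=1)
        z2 = (r2 - r2.mean()) / r2.std(ddof=1)
        expected = (z1 + z2) / 2
        np.testing.assert_allclose(amy.lcms_composite(t), expected, atol=1e-12)

    def test_sample_mean_zero(self, analysis_table):
        assert amy.lcms_composite(analysis_table).mean() == pytest.approx(0.0, abs=1e-12)

    def test_mean_ratio_participant_scores_zero(self):
        # a row whose both ratios sit at the sample mean gets composite 0
        base = pd.DataFrame(
            {
                "lcms_ab40": [200.0, 300.0],
                "lcms_ab42": [25.0, 25.0],
                "lcms_abm3_40": [20.0, 40.0],
            }
        )
        mid = pd.DataFrame(
            {"lcms_ab40": [250.0], "lcms_ab42": [25.0], "lcms_abm3_40": [30.0]}
        )
        t = pd.concat([base, mid], ignore_index=True)
        comp = amy.lcms_composite(t)
        assert comp.iloc[2] == pytest.approx(0.0, abs=1e-12)

    def test_group_means_ordered(self, default_cohort):
        comp = amy.lcms_composite(default_cohort)
        pos = comp[default_cohort["pet_status"] == "positive"].mean()
        neg = comp[default_cohort["pet_status"] == "negative"].mean()
        assert pos > neg  # more cerebral amyloid -> higher composite

    def test_nonpositive_ab42_names_row(self, default_cohort):
        bad = default_cohort.copy()
        bad.loc[17, "lcms_ab42"] = 0.0
        with pytest.raises(amy.InvalidRecordError, match="17"):
            amy.lcms_composite(bad)


class TestFitLogistic:
    def test_intercept_only_equals_logit_prevalence(self):
        y = np.zeros(441, dtype=int)
        y[:82] = 1
        model = amy.fit_logistic(y, pd.DataFrame(index=np.arange(441)))
        assert model.converged
        assert model.coefficients[0] == pytest.approx(np.log(82 / 359), abs=1e-6)

    def test_binary_predictor_equals_log_odds_ratio(self):
        # 2x2 table: exposed 30/70 events, unexposed 10/90
        y = np.r_[np.ones(30), np.zeros(70), np.ones(10), np.zeros(90)]
        x = np.r_[np.ones(100), np.zeros(100)]
        model = amy.fit_logistic(y, pd.DataFrame({"x": x}))
        log_or = np.log((30 / 70) / (10 / 90))
        assert model.coefficients[1] == pytest.approx(log_or, abs=1e-6)
        assert model.coefficients[0] == pytest.approx(np.log(10 / 90), abs=1e-6)

    def test_perfect_separation_flagged(self):
        y = np.r_[np.ones(20), np.zeros(20)]
        x = np.r_[np.ones(20), -np.ones(20)]
        with pytest.warns(RuntimeWarning, match="separation"):
            model = amy.fit_logistic(y, pd.DataFrame({"x": x}))
        assert model.separation
        assert not model.converged

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            amy.fit_logistic(np.ones(10), pd.DataFrame({"x": np.arange(10.0)}))


class TestRocCurve:
    def test_perfect_and_tied_scores(self):
        y = np.r_[np.ones(5), np.zeros(5)]
        assert amy.roc_curve(np.r_[np.ones(5), np.zeros(5)], y).auc == 1.0
        assert amy.roc_curve(np.ones(10), y).auc == 0.5

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        y = (rng.random(50) < 0.4).astype(int)
        y[:2] = [0, 1]  # both classes present
        scores = rng.integers(0, 12, size=50).astype(float)  # many ties
        roc = amy.roc_curve(scores, y)
        assert roc.auc == pytest.approx(_pair_auc_oracle(scores, y), abs=1e-12)

    def test_matches_sklearn(self, rng):
        sk = pytest.importorskip("sklearn.metrics")
        y = (rng.random(120) < 0.3).astype(int)
        y[:2] = [0, 1]
        scores = rng.normal(size=120) + y
        roc = amy.roc_curve(scores, y)
        assert roc.auc == pytest.approx(sk.roc_auc_score(y, scores), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        y = (rng.random(80) < 0.3).astype(int)
        y[:2] = [0, 1]
        scores = rng.normal(size=80)
        a = amy.roc_curve(scores, y).auc
        b = amy.roc_curve(np.exp(scores), y).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_lower_orientation_mirrors_negated_scores(self, rng):
        y = (rng.random(60) < 0.4).astype(int)
        y[:2] = [0, 1]
        scores = rng.normal(size=60)
        lo = amy.roc_curve(scores, y, orientation="lower")
        hi = amy.roc_curve(-scores, y, orientation="higher")
        assert lo.auc == pytest.approx(hi.auc, abs=1e-15)
        np.testing.assert_allclose(lo.sensitivity, hi.sensitivity)

    def test_sensitivity_monotone_along_thresholds(self, rng):
        y = (rng.random(70) < 0.3).astype(int)
        y[:2] = [0, 1]
        roc = amy.roc_curve(rng.normal(size=70), y)
        assert np.all(np.diff(roc.sensitivity) <= 0)
        assert np.all(np.diff(roc.specificity) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(amy.UndefinedRocError):
            amy.roc_curve(np.arange(5.0), np.ones(5))


class TestDelong:
    def test_identical_scores_p_one(self, rng):
        y = (rng.random(50) < 0.4).astype(int)
        y[:2] = [0, 1]
        s = rng.normal(size=50)
        cmp_ = amy.delong_test(s, s.copy(), y)
        assert cmp_.degenerate
        assert cmp_.p_value == 1.0
        assert cmp_.auc_a == cmp_.auc_b

    def test_monotone_transform_gives_zero_difference(self, rng):
        y = (rng.random(50) < 0.4).astype(int)
        y[:2] = [0, 1]
        s = rng.normal(size=50)
        cmp_ = amy.delong_test(s, np.tanh(s) * 3 + 1, y)
        assert cmp_.auc_a == pytest.approx(cmp_.auc_b, abs=1e-12)
        assert cmp_.p_value == 1.0

    def test_variance_nonnegative_and_z_sign(self, rng):
        for _ in range(20):
            y = (rng.random(60) < 0.4).astype(int)
            y[:2] = [0, 1]
            a = rng.normal(size=60) + y
            b = rng.normal(size=60) + 0.3 * y
            cmp_ = amy.delong_test(a, b, y)
            assert cmp_.variance >= 0
            assert 0 <= cmp_.p_value <= 1
            if not cmp_.degenerate and cmp_.auc_a != cmp_.auc_b:
                assert np.sign(cmp_.z) == np.sign(cmp_.auc_a - cmp_.auc_b)


class TestYoudenCutpoint:
    def test_perfect_scores(self):
        y = np.r_[np.ones(5), np.zeros(5)]
        cp = amy.youden_cutpoint(amy.roc_curve(np.r_[np.ones(5), np.zeros(5)], y))
        assert cp.youden_j == pytest.approx(1.0)
        assert cp.sensitivity == 1.0 and cp.specificity == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        y = (rng.random(20) < 0.5).astype(int)
        y[:2] = [0, 1]
        scores = rng.normal(size=20)
        roc = amy.roc_curve(scores, y)
        cp = amy.youden_cutpoint(roc)
        # brute force over all candidate thresholds, recomputing from data
        best = -np.inf
        for t in roc.thresholds:
            pred = scores >= t
            sens = (pred & (y == 1)).sum() / (y == 1).sum()
            spec = (~pred & (y == 0)).sum() / (y == 0).sum()
            best = max(best, sens + spec - 1)
        assert cp.youden_j == pytest.approx(best, abs=1e-12)

    def test_accuracy_closed_form(self):
        # published base-model operating point at 82/441 prevalence
        roc = amy.RocCurve(
            thresholds=np.array([-np.inf, 0.5, np.inf]),
            sensitivity=np.array([1.0, 0.573, 0.0]),
            specificity=np.array([0.0, 0.783, 1.0]),
            auc=0.7,
            n_pos=82,
            n_neg=359,
        )
        cp = amy.youden_cutpoint(roc)
        assert cp.sensitivity == pytest.approx(0.573)
        assert cp.accuracy == pytest.approx(0.744, abs=5e-4)

    def test_youden_identity(self, rng):
        y = (rng.random(40) < 0.4).astype(int)
        y[:2] = [0, 1]
        cp = amy.youden_cutpoint(amy.roc_curve(rng.normal(size=40), y))
        assert cp.youden_j == cp.sensitivity + cp.specificity - 1.0


class TestModelScoreInvariants:
    def test_single_predictor_probability_auc_equals_raw_auc(self, analysis_table):
        t = analysis_table
        y = t["pet_status"] == "positive"
        model = amy.fit_logistic(y, t[["lcms_ab4240"]])
        probs = model.predict_proba(t)
        auc_prob = amy.roc_curve(probs, y).auc
        auc_raw = amy.roc_curve(t["lcms_ab4240"].to_numpy(), y, orientation="lower").auc
        assert auc_prob == pytest.approx(auc_raw, abs=1e-12)

    def test_probability_and_biomarker_thresholds_partition_identically(self, analysis_table):
        t = analysis_table
        y = (t["pet_status"] == "positive").to_numpy()
        model = amy.fit_logistic(y, t[["lcms_ab4240"]])
        probs = model.predict_proba(t)
        cp_prob = amy.youden_cutpoint(amy.roc_curve(probs, y))
        cp_bio = amy.youden_cutpoint(
            amy.roc_curve(t["lcms_ab4240"].to_numpy(), y, orientation="lower")
        )
        part_prob = probs >= cp_prob.threshold
        part_bio = t["lcms_ab4240"].to_numpy() <= cp_bio.threshold
        np.testing.assert_array_equal(part_prob, part_bio)

    def test_nested_models_never_lose_in_sample_auc(self, analysis_table):
        t = analysis_table
        y = (t["pet_status"] == "positive").to_numpy()
        small = amy.fit_logistic(y, t[["lcms_ab4240"]])
        big = amy.fit_logistic(y, t[["lcms_ab4240", "age", "sex_female", "apoe4"]])
        auc_small = amy.roc_curve(small.predict_proba(t), y).auc
        auc_big = amy.roc_curve(big.predict_proba(t), y).auc
        assert auc_big >= auc_small - 1e-10


class TestLogPearsonCorrelations:
    def test_self_correlation_is_one(self, analysis_table):
        out = amy.log_pearson_correlations(
            analysis_table, [("lcms_ab42", "lcms_ab42")]
        )
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_matches_textbook_formula(self, rng):
        t = pd.DataFrame(
            {"a": np.exp(rng.normal(size=10)), "b": np.exp(rng.normal(size=10))}
        )
        out = amy.log_pearson_correlations(t, [("a", "b")])
        x, y = np.log(t["a"]), np.log(t["b"])
        xc, yc = x - x.mean(), y - y.mean()
        r_direct = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert out["r"].iloc[0] == pytest.approx(r_direct, abs=1e-12)

    def test_bonferroni_clamp(self, analysis_table):
        pairs = [
            ("simoa_ab42", "lcms_ab42"),
            ("simoa_ab40", "lcms_ab40"),
            ("simoa_ptau181", "lcms_composite"),
        ]
        out = amy.log_pearson_correlations(analysis_table, pairs)
        np.testing.assert_allclose(
            out["p_bonferroni"], np.minimum(1.0, out["p"] * len(pairs))
        )

    def test_composite_used_untransformed(self, analysis_table):
        # composite contains negative values; must not raise under log rule
        out = amy.log_pearson_correlations(
            analysis_table, [("lcms_composite", "lcms_ab4240")]
        )
        assert -1 <= out["r"].iloc[0] <= 1

    def test_nonpositive_under_log_rejected(self):
        t = pd.DataFrame({"a": [1.0, -2.0, 3.0, 4.0], "b": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(amy.InvalidRecordError):
            amy.log_pearson_correlations(t, [("a", "b")])
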