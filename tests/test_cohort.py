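"""RECIST calls, ROC/AUC, Youden, table reconstruction, logistic fits, DeLong."""

import numpy as np
import pytest
from scipy.stats import rankdata
from scipy.special import expit

from hiskit import presets
from hiskit.cohort import (
    ContingencyTable2x2,
    ConvergenceError,
    JointTable2x2x2,
    LogisticModel,
    delong_test,
    empirical_roc,
    fit_bivariate,
    fit_logistic,
    predict_probability,
    recist_classify,
    reconstruct_joint_table,
    reconstruct_tps_table,
    sens_spec_at,
    youden_cutoff,
)


def mw_auc(scores, labels):
    """Independent tie-corrected Mann-Whitney AUC oracle."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRecist:
    def test_durable_shrinkage_responds(self):
        assert recist_classify(100, [(6, 65), (12, 64), (26, 66)])

    def test_enlargement_within_window_fails(self):
        assert not recist_classify(100, [(6, 65), (16, 120)])

    def test_never_shrinking_fails(self):
        assert not recist_classify(100, [(6, 95), (24, 92)])

    def test_shrink_boundary_inclusive_at_70_percent(self):
        assert recist_classify(100, [(6, 70)])
        assert not recist_classify(100, [(6, 70.5)])

    def test_progression_after_window_still_responds(self):
        assert recist_classify(100, [(6, 60), (30, 200)])

    def test_negative_burden_errors(self):
        with pytest.raises(ValueError):
            recist_classify(100, [(6, -1)])


class TestROC:
    def test_perfect_separation(self):
        roc = empirical_roc([3, 4, 5, 0, 1, 2], [1, 1, 1, 0, 0, 0])
        assert roc.auc == 1.0

    def test_all_ties_give_half(self):
        roc = empirical_roc([5.0] * 6, [1, 1, 1, 0, 0, 0])
        assert roc.auc == 0.5

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            empirical_roc([1, 2, 3], [1, 1, 1])

    def test_binary_tps50_indicator_reproduces_published_auc(self, tables_by_cut):
        table, _ = tables_by_cut[50]
        scores, labels = table.scores_labels()
        assert round(empirical_roc(scores, labels).auc, 2) == 0.71

    def test_auc_matches_pairwise_oracle(self, rng):
        scores = rng.integers(0, 5, size=40).astype(float)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        assert empirical_roc(scores, labels).auc == pytest.approx(
            mw_auc(scores, labels))

    def test_binary_auc_equals_mean_sens_spec(self, rng):
        for _ in range(50):
            t = ContingencyTable2x2(*[int(x) for x in rng.integers(1, 30, 4)])
            scores, labels = t.scores_labels()
            assert empirical_roc(scores, labels).auc == pytest.approx(t.auc)

    def test_negation_and_monotone_invariance(self, rng):
        scores = rng.normal(size=30)
        labels = (rng.random(30) < 0.4).astype(int)
        labels[:2] = [0, 1]
        auc = empirical_roc(scores, labels).auc
        assert empirical_roc(-scores, labels).auc == pytest.approx(1 - auc)
        assert empirical_roc(np.exp(2 * scores), labels).auc == pytest.approx(auc)

    def test_sensitivity_nonincreasing_in_threshold(self, rng):
        scores = rng.normal(size=50)
        labels = (rng.random(50) < 0.5).astype(int)
        labels[:2] = [0, 1]
        roc = empirical_roc(scores, labels)
        # thresholds descend, so sensitivity must be non-decreasing along the array
        assert np.all(np.diff(roc.sensitivity) >= 0)


class TestYouden:
    def test_recovers_planted_bimodal_cutoff(self):
        rng = np.random.default_rng(11)
        scores = np.concatenate([rng.normal(5, 1, 250), rng.normal(9, 1, 250)])
        labels = np.array([0] * 250 + [1] * 250)
        roc = empirical_roc(scores, labels)
        cut = youden_cutoff(roc)
        # brute-force J maximization over all observed thresholds
        best_j, best_t = -1.0, None
        for t in np.unique(scores):
            s, p = sens_spec_at(scores, labels, t)
            if s + p - 1 > best_j + 1e-12:
                best_j, best_t = s + p - 1, t
        assert cut == pytest.approx(best_t)
        assert abs(cut - 7.0) < 0.5

    def test_perfectly_separated_returns_smallest_gap_threshold(self):
        roc = empirical_roc([1, 2, 10, 11], [0, 0, 1, 1])
        assert youden_cutoff(roc) == 10

    def test_reversed_labels_symmetric_j(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=60)
        labels = (rng.random(60) < 0.5).astype(int)
        labels[:2] = [0, 1]
        j1 = empirical_roc(scores, labels).youden.max()
        j2 = empirical_roc(-scores, 1 - labels).youden.max()
        assert j1 == pytest.approx(j2)


class TestSensSpecAt:
    def test_perfect_split(self):
        assert sens_spec_at([1, 1, 0, 0], [1, 1, 0, 0], 0.5) == (1.0, 1.0)

    def test_threshold_below_everything(self):
        assert sens_spec_at([1, 2, 3, 4], [1, 1, 0, 0], -10) == (1.0, 0.0)

    def test_reconstructed_tps50_boundary(self, tables_by_cut):
        table, _ = tables_by_cut[50]
        scores, labels = table.scores_labels()
        sens, spec = sens_spec_at(scores, labels, 1.0)
        assert round(sens, 3) == 0.558
        assert round(spec, 3) == 0.865


class TestReconstructTpsTable:
    def test_tps50_cells_and_positive_margin(self):
        t = reconstruct_tps_table(77, 52, 55.8, 86.5, expected_positive_total=50)
        assert (t.resp_pos, t.resp_neg, t.nonresp_pos, t.nonresp_neg) == (43, 34, 7, 45)

    def test_tps25_positive_margin(self):
        t = reconstruct_tps_table(77, 52, 64.9, 75.0)
        assert t.n_pos == 63

    def test_perfect_classifier(self):
        t = reconstruct_tps_table(10, 10, 100, 100)
        assert (t.resp_pos, t.resp_neg, t.nonresp_pos, t.nonresp_neg) == (10, 0, 0, 10)

    def test_margin_mismatch_errors(self):
        with pytest.raises(ValueError, match="does not match"):
            reconstruct_tps_table(77, 52, 55.8, 86.5, expected_positive_total=51)

    def test_percentage_out_of_range_errors(self):
        with pytest.raises(ValueError):
            reconstruct_tps_table(10, 10, 120, 50)


class TestReconstructJointTable:
    def test_tps50_cells(self, tables_by_cut):
        _, joint = tables_by_cut[50]
        assert joint.cell(True, True) == (9, 0)
        assert joint.cell(True, False) == (17, 11)
        assert joint.cell(False, True) == (34, 7)
        assert joint.cell(False, False) == (17, 34)

    def test_tps75_cells(self, tables_by_cut):
        _, joint = tables_by_cut[75]
        assert joint.cell(True, True) == (4, 0)
        assert joint.cell(True, False) == (22, 11)
        assert joint.cell(False, True) == (26, 4)
        assert joint.cell(False, False) == (25, 37)

    @pytest.mark.parametrize("cut", [25, 50, 75])
    def test_collapses_to_all_supplied_margins(self, tables_by_cut, cut):
        tps_table, joint = tables_by_cut[cut]
        m = presets.TABLE1_MARGINS
        assert joint.stratum(True).n_total == 37
        assert joint.stratum(False).n_total == 92
        assert joint.collapse_tps().n_resp == 77
        assert joint.collapse_tps().n_nonresp == 52
        assert joint.collapse_tps().n_pos == m.tps_positive_total(cut)
        assert joint.collapse_tps() == tps_table

    def test_inconsistent_margins_error(self, tables_by_cut):
        tps_table, _ = tables_by_cut[50]
        bad = ContingencyTable2x2(tps_table.resp_pos + 1, tps_table.resp_neg - 1,
                                  tps_table.nonresp_pos, tps_table.nonresp_neg)
        with pytest.raises(ValueError):
            reconstruct_joint_table(presets.TABLE1_MARGINS, 50, bad, 77.9, 60.0)


class TestFitLogistic:
    def test_balanced_null_table_gives_zero_coefficients(self):
        X = np.array([[1.0, 0.0], [1.0, 1.0]])
        beta, se, _ = fit_logistic(X, np.array([10, 10]), np.array([20, 20]))
        np.testing.assert_allclose(beta, 0.0, atol=1e-10)

    def test_single_predictor_slope_is_log_odds_ratio(self):
        X = np.array([[1.0, 1.0], [1.0, 0.0]])
        beta, _, _ = fit_logistic(X, np.array([8, 2]), np.array([10, 10]))
        assert beta[1] == pytest.approx(np.log(16), abs=1e-8)

    def test_reconstructed_tps50_reproduces_published_equation(self, tables_by_cut):
        _, joint = tables_by_cut[50]
        model = fit_bivariate(joint, tps_cut=50)
        assert round(model.intercept, 4) == -0.7347
        assert round(model.coef_btv, 3) == 1.241
        assert round(model.coef_tps, 3) == 2.398

    def test_matches_statsmodels_glm(self, rng):
        import statsmodels.api as sm

        X = np.column_stack([np.ones(4), [0, 0, 1, 1], [0, 1, 0, 1]])
        tot = rng.integers(20, 60, size=4)
        p_true = expit(X @ np.array([-0.5, 1.0, 0.8]))
        succ = rng.binomial(tot, p_true)
        succ = np.clip(succ, 1, tot - 1)  # keep away from separation
        beta, se, _ = fit_logistic(X, succ, tot)
        ref = sm.GLM(np.column_stack([succ, tot - succ]), X,
                     family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(beta, ref.params, atol=1e-6)
        np.testing.assert_allclose(se, ref.bse, rtol=1e-4)

    def test_score_equations_hold_at_optimum(self, tables_by_cut):
        _, joint = tables_by_cut[50]
        model = fit_bivariate(joint)
        X, succ, tot = [], [], []
        for (b, t), (r, n) in joint.cells.items():
            X.append([1.0, float(b), float(t)])
            succ.append(r)
            tot.append(r + n)
        X, succ, tot = np.array(X), np.array(succ), np.array(tot)
        p = expit(X @ [model.intercept, model.coef_btv, model.coef_tps])
        resid = X.T @ (succ - tot * p)
        assert np.max(np.abs(resid)) < 1e-6

    def test_separation_raises(self):
        X = np.array([[1.0, 0.0], [1.0, 1.0]])
        with pytest.raises(ConvergenceError):
            fit_logistic(X, np.array([0, 10]), np.array([10, 10]))

    def test_recovers_generating_coefficients_within_3se(self, rng):
        truth = np.array([-0.7, 1.2, 2.4])
        X = np.column_stack([np.ones(4), [1, 1, 0, 0], [1, 0, 1, 0]])
        tot = np.array([1250, 1250, 1250, 1250])
        succ = rng.binomial(tot, expit(X @ truth))
        beta, se, _ = fit_logistic(X, succ, tot)
        assert np.all(np.abs(beta - truth) < 3 * se)


class TestPredictProbability:
    def test_intercept_only(self):
        m = LogisticModel(intercept=0.4, coef_btv=1.0, coef_tps=2.0)
        assert predict_probability(m, False, False) == pytest.approx(expit(0.4))

    def test_published_tps50_model_values(self):
        m = presets.REFERENCE_MODELS[50]
        assert predict_probability(m, True, True) == pytest.approx(
            expit(2.9043), abs=1e-4)
        assert predict_probability(m, False, False) == pytest.approx(0.324, abs=5e-4)


class TestDeLong:
    def test_identical_scores_degenerate(self):
        s = np.array([3.0, 1.0, 2.0, 0.5, 0.1, 0.7])
        labels = np.array([1, 1, 1, 0, 0, 0])
        res = delong_test(s, s, labels)
        assert res.z == 0.0 and res.p == 1.0 and res.degenerate

    def test_argument_order_flips_z_sign(self, rng):
        labels = np.array([1] * 10 + [0] * 10)
        sa = labels + rng.normal(0, 1, 20)
        sb = rng.normal(0, 1, 20)
        r1 = delong_test(sa, sb, labels)
        r2 = delong_test(sb, sa, labels)
        assert r1.z == pytest.approx(-r2.z)
        assert r1.p == pytest.approx(r2.p)

    def test_small_sample_matches_permutation_oracle(self):
        """Asymptotic p agrees with a sign-flip permutation test at n=12."""
        rng = np.random.default_rng(42)
        labels = np.array([1] * 6 + [0] * 6)
        truth = labels.astype(float)
        sa = truth * 1.2 + rng.normal(0, 1.0, 12)
        sb = truth * 0.5 + rng.normal(0, 1.0, 12)
        res = delong_test(sa, sb, labels)

        obs = abs(mw_auc(sa, labels) - mw_auc(sb, labels))
        prng = np.random.default_rng(7)
        hits = 0
        n_perm = 10_000
        for _ in range(n_perm):
            flip = prng.random(12) < 0.5
            pa = np.where(flip, sb, sa)
            pb = np.where(flip, sa, sb)
            if abs(mw_auc(pa, labels) - mw_auc(pb, labels)) >= obs - 1e-12:
                hits += 1
        p_perm = hits / n_perm
        assert res.p == pytest.approx(p_perm, abs=0.1)

    def test_paired_auc_values_match_empirical(self, tables_by_cut):
        _, joint = tables_by_cut[50]
        b, t, labels = joint.patients()
        tps_scores = t.astype(float)
        biv_scores = presets.REFERENCE_MODELS[50].logit(b, t)
        res = delong_test(biv_scores, tps_scores, labels)
        assert res.auc_a == pytest.approx(mw_auc(biv_scores, labels))
        assert res.auc_b == pytest.approx(mw_auc(tps_scores, labels))
        assert res.auc_a > res.auc_b  # the bivariate model dominates
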