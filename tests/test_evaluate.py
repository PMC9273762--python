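import numpy as np
import pandas as pd
import pytest
from scipy import stats

import wardflag as wf
from wardflag import evaluate
from conftest import make_feature_table


def auc_roc_pairwise(probs, labels):
    """O(n^2) Mann-Whitney AUC with half-credit for ties."""
    pos = probs[labels == 1]
    neg = probs[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def auc_prc_stepsum(probs, labels):
    """Step-integrated PR curve: sum of (R_i - R_{i-1}) * P_i over thresholds."""
    order = np.argsort(-probs, kind="mergesort")
    p, y = probs[order], labels[order]
    n_pos = y.sum()
    ap, tp, fp = 0.0, 0, 0
    prev_recall = 0.0
    i = 0
    while i < len(p):
        j = i
        while j < len(p) and p[j] == p[i]:  # group tied scores
            tp += y[j]
            fp += 1 - y[j]
            j += 1
        recall = tp / n_pos
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return ap


class TestMetricOracles:
    def test_auc_matches_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(5, 25))
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                y[0], y[-1] = 1, 0
            p = np.round(rng.uniform(0, 1, n), 1)  # coarse grid forces ties
            rep = wf.compute_metrics(p, y)
            assert rep.auc_roc == pytest.approx(auc_roc_pairwise(p, y), abs=1e-12)
            assert rep.auc_prc == pytest.approx(auc_prc_stepsum(p, y), abs=1e-12)

    def test_perfect_predictions(self):
        y = np.array([0, 1, 0, 1, 1, 0])
        rep = wf.compute_metrics(y.astype(float), y)
        assert rep.auc_roc == 1 and rep.auc_prc == 1 and rep.f1 == 1

    def test_null_predictions_approach_chance(self):
        rng = np.random.default_rng(2)
        y = (rng.uniform(size=20000) < 0.1).astype(int)
        p = rng.uniform(size=20000)
        rep = wf.compute_metrics(p, y)
        assert rep.auc_roc == pytest.approx(0.5, abs=0.02)
        assert rep.auc_prc == pytest.approx(0.1, abs=0.02)

    def test_confusion_matrix_arithmetic(self):
        p = np.array([0.9, 0.8, 0.6, 0.4, 0.3, 0.2])
        y = np.array([1, 0, 1, 1, 0, 0])
        rep = wf.compute_metrics(p, y, threshold=0.5)
        # predicted positive: first three -> TP=2 FP=1; negatives: TN=2 FN=1
        assert rep.precision == pytest.approx(2 / 3)
        assert rep.recall == pytest.approx(2 / 3)
        assert rep.npv == pytest.approx(2 / 3)
        assert rep.f1 == pytest.approx(2 / 3)

    def test_complement_identities(self):
        """NPV + false-omission rate = 1 and PPV + false-discovery rate = 1."""
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(20, 60))
            y = rng.integers(0, 2, n)
            p = rng.uniform(size=n)
            rep = wf.compute_metrics(p, y, threshold=0.5)
            pred = p > 0.5
            if pred.sum() and (~pred).sum():
                fdr = np.sum(pred & (y == 0)) / pred.sum()
                fomr = np.sum(~pred & (y == 1)) / (~pred).sum()
                assert rep.precision + fdr == pytest.approx(1.0)
                assert rep.npv + fomr == pytest.approx(1.0)

    def test_single_class_labels(self):
        rep = wf.compute_metrics(np.array([0.2, 0.8]), np.array([1, 1]))
        assert np.isnan(rep.auc_roc) and np.isnan(rep.auc_prc)
        assert rep.recall == 0.5  # threshold metrics still defined


class TestStratifiedBootstrap:
    def test_resamples_preserve_prevalence_exactly(self):
        rng = np.random.default_rng(0)
        y = (rng.uniform(size=400) < 0.13).astype(int)
        for _ in range(50):
            idx = evaluate.stratified_resample_indices(y, rng)
            assert len(idx) == len(y)
            assert y[idx].mean() == y.mean()

    def test_degenerate_metric_zero_width_ci(self):
        y = np.array([0, 0, 1, 1] * 10)
        ci = wf.stratified_bootstrap_ci(y.astype(float), y, R=2, seed=0)
        roc = ci[ci.metric == "auc_roc"].iloc[0]
        assert roc["ci_lo"] == roc["mean"] == roc["ci_hi"] == 1.0

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(1)
        y = (rng.uniform(size=200) < 0.2).astype(int)
        p = np.clip(y * 0.5 + rng.uniform(size=200) * 0.5, 0, 1)
        a = wf.stratified_bootstrap_ci(p, y, R=50, seed=9)
        b = wf.stratified_bootstrap_ci(p, y, R=50, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_percentile_ci_coverage_on_known_auc(self):
        """Binormal scores with closed-form AUC = Phi(delta/sqrt(2)): the 95%
        percentile bootstrap CI should cover the truth in >= 90% of seeded
        replications.  (The t-based construction quantifies the precision of
        the bootstrap mean, not coverage of the truth, so it is not the
        object of this check.)"""
        delta = 1.0
        truth = stats.norm.cdf(delta / np.sqrt(2))
        rng = np.random.default_rng(0)
        hits = 0
        n_rep = 60
        for _ in range(n_rep):
            y = np.r_[np.ones(60, dtype=int), np.zeros(340, dtype=int)]
            p = np.r_[rng.normal(delta, 1, 60), rng.normal(0, 1, 340)]
            ci = wf.stratified_bootstrap_ci(
                p, y, R=120, seed=int(rng.integers(1 << 30)), method="percentile"
            )
            roc = ci[ci.metric == "auc_roc"].iloc[0]
            hits += roc.ci_lo <= truth <= roc.ci_hi
        assert hits >= int(0.9 * n_rep)


class TestCovariateBalance:
    def test_identical_samples_zero_smd(self):
        df = pd.DataFrame({"age": np.arange(50, 90, 0.5), "sex": ["male", "female"] * 40})
        out = wf.covariate_balance(df, df)
        assert (out["smd"].abs() < 1e-12).all()

    def test_direct_formula(self):
        a = pd.DataFrame({"x": np.random.default_rng(0).normal(10, 2, 4000)})
        b = pd.DataFrame({"x": np.random.default_rng(1).normal(12, 2, 4000)})
        out = wf.covariate_balance(a, b)
        assert out.loc[0, "smd"] == pytest.approx(1.0, abs=0.06)

    def test_null_distribution_smd_small(self):
        rng = np.random.default_rng(3)
        a = pd.DataFrame({"x": rng.normal(size=4000), "g": rng.choice(["a", "b"], 4000)})
        b = pd.DataFrame({"x": rng.normal(size=4000), "g": rng.choice(["a", "b"], 4000)})
        out = wf.covariate_balance(a, b)
        assert (out["smd"].abs() < 0.1).all()


class TestBaselines:
    def test_empty_model_set(self, small_cohort):
        out = wf.run_baselines(
            small_cohort["table"], small_cohort["table"], "label_8h",
            small_cohort["config"], models=(), n_bootstrap=2,
        )
        assert len(out) == 0

    def test_deterministic_and_comparable_to_ef_on_separable_data(self):
        rng = np.random.default_rng(0)
        n = 800
        X = rng.normal(size=(n, 3))
        y = (X[:, 0] + X[:, 1] > 0).astype(int)
        train, test = make_feature_table(X[:500], y[:500]), make_feature_table(X[500:], y[500:])
        cfg = wf.RunConfig(random_seed=0)
        out1 = wf.run_baselines(train, test, "label_8h", cfg, models=("DT",), n_bootstrap=8)
        out2 = wf.run_baselines(train, test, "label_8h", cfg, models=("DT",), n_bootstrap=8)
        pd.testing.assert_frame_equal(out1, out2)
        ef = wf.fit_ef(train, cfg, wf.TreeSpec(max_depth=8, min_samples_leaf=5),
                       "label_8h", n_bootstrap=8)
        ef_prc = wf.compute_metrics(wf.predict_proba(ef, test), y[500:]).auc_prc
        dt_prc = out1.iloc[0]["auc_prc"]
        assert abs(ef_prc - dt_prc) < 0.05
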