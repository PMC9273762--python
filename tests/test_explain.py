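import numpy as np
import pandas as pd
import pytest
from sklearn.tree import DecisionTreeClassifier

import wardflag as wf
from wardflag import explain
from conftest import make_feature_table


def random_tree(rng, n_features=5, max_depth=3, n=60, with_nan=False):
    X = rng.normal(size=(n, n_features))
    if with_nan:
        X[rng.uniform(size=X.shape) < 0.2] = np.nan
    y = (rng.uniform(size=n) < 0.5).astype(int)
    tree = DecisionTreeClassifier(max_depth=max_depth, random_state=int(rng.integers(1 << 30)))
    return tree.fit(X, y), X


class TestTreeShapley:
    def test_single_leaf_tree_constant_game(self):
        X = np.zeros((10, 3))
        y = np.ones(10, dtype=int)
        tree = DecisionTreeClassifier().fit(X, y)
        phi, phi0 = wf.tree_shapley(tree, X[0])
        assert np.allclose(phi, 0)
        assert phi0 == 1.0

    def test_single_split_tree_single_player_game(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, 4))
        y = (X[:, 2] > 0).astype(int)
        tree = DecisionTreeClassifier(max_depth=1, random_state=0).fit(X, y)
        x = X[0]
        phi, phi0 = wf.tree_shapley(tree, x)
        fx = explain.tree_predict_p1(tree, x)
        assert np.allclose(np.delete(phi, 2), 0)
        assert phi[2] == pytest.approx(fx - phi0, abs=1e-12)

    @pytest.mark.parametrize("with_nan", [False, True])
    def test_matches_exhaustive_enumeration(self, with_nan):
        """Polynomial path-dependent algorithm vs full 2^M coalition sum."""
        rng = np.random.default_rng(99 if with_nan else 7)
        for _ in range(25):
            tree, X = random_tree(rng, n_features=int(rng.integers(2, 7)),
                                  max_depth=3, with_nan=with_nan)
            for _ in range(2):
                x = X[int(rng.integers(len(X)))]
                phi, phi0 = wf.tree_shapley(tree, x)
                phe, phe0 = wf.exhaustive_shapley(tree, x)
                np.testing.assert_allclose(phi, phe, atol=1e-8)
                assert phi0 == pytest.approx(phe0, abs=1e-8)

    def test_local_accuracy_per_tree(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            tree, X = random_tree(rng, max_depth=4, with_nan=True)
            for x in X[:5]:
                phi, phi0 = wf.tree_shapley(tree, x)
                fx = explain.tree_predict_p1(tree, x)
                assert abs(phi0 + phi.sum() - fx) < 1e-6

    def test_dummy_feature_has_zero_phi(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            tree, X = random_tree(rng, n_features=6, max_depth=3)
            used = {int(f) for f in tree.tree_.feature if f >= 0}
            unused = set(range(6)) - used
            phi, _ = wf.tree_shapley(tree, X[0])
            for j in unused:
                assert phi[j] == 0.0

    def test_custom_background_changes_base_value(self):
        rng = np.random.default_rng(12)
        tree, X = random_tree(rng, max_depth=3)
        phi_a, base_a = wf.tree_shapley(tree, X[0], background=X[:20])
        # a background concentrated in one leaf shifts the expectation
        leafish = np.tile(X[0], (15, 1))
        phi_b, base_b = wf.tree_shapley(tree, X[0], background=leafish)
        fx = explain.tree_predict_p1(tree, X[0])
        assert base_b == pytest.approx(fx, abs=1e-12)  # all mass on x's leaf
        assert abs(base_a + phi_a.sum() - fx) < 1e-9


class TestEnsembleExplain:
    def test_b1_equals_single_tree(self, small_cohort):
        cfg = small_cohort["config"]
        tbl = small_cohort["table"]
        model = wf.fit_ef(tbl, cfg, wf.TreeSpec(max_depth=4), "label_8h", n_bootstrap=1)
        row = tbl.iloc[10]
        expl = wf.ensemble_explain(model, row)
        x = row[model.feature_names].to_numpy(dtype=float)
        phi, phi0 = wf.tree_shapley(model.trees[0], x, n_features=len(model.feature_names))
        np.testing.assert_allclose(expl.contributions, phi, atol=1e-12)
        assert expl.base_value == pytest.approx(phi0, abs=1e-12)

    def test_duplicated_tree_equals_single(self, small_cohort):
        cfg = small_cohort["config"]
        tbl = small_cohort["table"]
        m1 = wf.fit_ef(tbl, cfg, wf.TreeSpec(max_depth=4), "label_8h", n_bootstrap=1)
        m2 = wf.EFModel(
            trees=[m1.trees[0], m1.trees[0]], seeds=[0, 0],
            feature_names=m1.feature_names, label_col=m1.label_col,
            tree_spec=m1.tree_spec,
        )
        row = tbl.iloc[3]
        e1, e2 = wf.ensemble_explain(m1, row), wf.ensemble_explain(m2, row)
        np.testing.assert_allclose(e1.contributions, e2.contributions, atol=1e-12)

    def test_ensemble_local_accuracy(self, small_model, small_cohort):
        rows = small_cohort["table"].sample(30, random_state=1)
        probs = wf.predict_proba(small_model, rows)
        for (_, row), fx in zip(rows.iterrows(), probs):
            expl = wf.ensemble_explain(small_model, row)
            assert abs(expl.base_value + expl.contributions.sum() - fx) < 1e-6
            assert expl.model_output == pytest.approx(fx, abs=1e-12)

    def test_duplicated_features_share_importance(self):
        # two identical columns: ensemble mean importance must be comparable
        rng = np.random.default_rng(0)
        n = 500
        a = rng.normal(size=n)
        X = np.column_stack([a, a, rng.normal(size=n)])
        y = (a + 0.3 * rng.normal(size=n) > 0).astype(int)
        tbl = make_feature_table(X, y)
        cfg = wf.RunConfig(random_seed=0)
        model = wf.fit_ef(tbl, cfg, wf.TreeSpec(max_depth=3), "label_8h", n_bootstrap=60)
        imp = wf.global_importance(model, tbl.sample(100, random_state=2))
        i0 = imp[wf.FEATURE_COLUMNS[0]]
        i1 = imp[wf.FEATURE_COLUMNS[1]]
        assert i0 > 0 and i1 > 0
        assert 0.25 < i0 / (i0 + i1) < 0.75


class TestReports:
    def _expl(self, phis, names=None):
        names = names or [f"f{i}" for i in range(len(phis))]
        return explain.Explanation(
            feature_names=names,
            contributions=np.asarray(phis, dtype=float),
            base_value=0.1,
            model_output=0.1 + float(np.sum(phis)),
            feature_values=np.arange(len(phis), dtype=float),
        )

    def test_top_contributors_sorted_by_abs_phi(self):
        top = wf.top_contributors(self._expl([0.3, -0.4, 0.1]), k=2)
        assert [t[0] for t in top] == ["f1", "f0"]
        assert top[0][1] == -0.4

    def test_all_zero_falls_back_to_schema_order(self):
        top = wf.top_contributors(self._expl([0.0, 0.0, 0.0]), k=3)
        assert [t[0] for t in top] == ["f0", "f1", "f2"]

    def test_k_larger_than_feature_count_returns_all(self):
        assert len(wf.top_contributors(self._expl([0.1, 0.2]), k=10)) == 2

    def test_constant_model_zero_importance(self):
        X = np.zeros((20, 3))
        y = np.zeros(20, dtype=int)
        tbl = make_feature_table(X, y)
        cfg = wf.RunConfig(random_seed=0, balance="off")
        model = wf.fit_ef(tbl, cfg, wf.TreeSpec(), "label_8h", n_bootstrap=3)
        imp = wf.global_importance(model, tbl)
        assert (imp == 0).all()

    def test_single_row_population_importance_is_abs_phi(self, small_model, small_cohort):
        row = small_cohort["table"].iloc[[5]]
        imp = wf.global_importance(small_model, row)
        expl = wf.ensemble_explain(small_model, row.iloc[0])
        expected = pd.Series(np.abs(expl.contributions), index=expl.feature_names)
        np.testing.assert_allclose(
            imp.sort_index().to_numpy(), expected.sort_index().to_numpy(), atol=1e-10
        )
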