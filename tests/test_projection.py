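import numpy as np
import pandas as pd
import pytest

from blineage.projection import (
    ReferenceProjector,
    assign,
    fit_knn,
    fit_projection,
    project,
    select_mvg,
)


def _frame(X, features=None):
    """features x cells DataFrame from a cells x features array."""
    X = np.asarray(X, dtype=float)
    features = features or [f"g{j}" for j in range(X.shape[1])]
    return pd.DataFrame(X.T, index=features)


class TestSelectMVG:
    def test_ranking_by_variance(self):
        rng = np.random.default_rng(0)
        scales = [0.0, 1.0, 4.0, 2.0, 3.0]
        X = rng.normal(size=(200, 5)) * np.sqrt(scales)
        got = select_mvg(_frame(X), n=2)
        assert got == ["g2", "g4"]

    def test_clamp_with_warning(self):
        X = np.random.default_rng(1).normal(size=(50, 3))
        with pytest.warns(UserWarning, match="only 3"):
            got = select_mvg(_frame(X), n=10)
        assert sorted(got) == ["g0", "g1", "g2"]

    def test_zero_variance_gene_ranks_last(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([np.full(100, 7.0), rng.normal(size=(100, 2))])
        got = select_mvg(_frame(X), n=3)
        assert got[-1] == "g0"

    def test_deterministic_tie_break_by_id(self):
        X = np.tile(np.array([[0.0], [1.0]]), (1, 3))
        got = select_mvg(_frame(X), n=2)
        assert got == ["g0", "g1"]


class TestFitProjection:
    def test_closed_form_first_component(self):
        # covariance [[2,1],[1,2]] -> leading eigenvector (1,1)/sqrt 2
        rng = np.random.default_rng(3)
        Z = rng.multivariate_normal([0, 0], [[2, 1], [1, 2]], size=20000)
        model = fit_projection(_frame(Z), labels=np.zeros(20000), n_pc=2)
        pc1 = model.loadings[:, 0]
        np.testing.assert_allclose(np.abs(pc1), np.full(2, 1 / np.sqrt(2)), atol=0.02)

    def test_refit_is_deterministic(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(100, 12))
        labels = np.zeros(100)
        m1 = fit_projection(_frame(X), labels, n_pc=5)
        m2 = fit_projection(_frame(X), labels, n_pc=5)
        np.testing.assert_array_equal(m1.loadings, m2.loadings)

    def test_orthonormal_loadings_and_variance_identity(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(200, 40))
        model = fit_projection(_frame(X), np.zeros(200), n_pc=30)
        np.testing.assert_allclose(
            model.loadings.T @ model.loadings, np.eye(30), atol=1e-8
        )
        score_var = model.healthy_scores.var(axis=0, ddof=1).sum()
        assert score_var == pytest.approx(model.explained_variance.sum(), rel=1e-8)

    def test_too_few_features(self):
        X = np.random.default_rng(6).normal(size=(100, 5))
        with pytest.raises(ValueError, match="features"):
            fit_projection(_frame(X), np.zeros(100), n_pc=30)


class TestProject:
    def _model(self, n=100, p=12, n_pc=5, seed=7):
        X = np.random.default_rng(seed).normal(size=(n, p))
        return _frame(X), fit_projection(_frame(X), np.zeros(n), n_pc=n_pc)

    def test_self_consistency(self):
        healthy, model = self._model()
        np.testing.assert_allclose(
            project(healthy, model), model.healthy_scores, atol=1e-8
        )

    def test_mean_profile_maps_to_origin(self):
        healthy, model = self._model()
        q = pd.DataFrame(model.center[:, None], index=model.features)
        np.testing.assert_allclose(project(q, model), 0.0, atol=1e-10)

    def test_hand_matrix_product(self):
        _, model = self._model(p=6, n_pc=3)
        rng = np.random.default_rng(8)
        Q = rng.normal(size=(3, 6))  # 3 cells
        scores = project(_frame(Q, features=model.features), model)
        np.testing.assert_allclose(scores, (Q - model.center) @ model.loadings)

    def test_missing_features_imputed_as_mean(self):
        healthy, model = self._model(p=12)
        q = healthy.iloc[:8, :3]  # drop 4 of 12 features
        with pytest.warns(UserWarning, match="imputed"):
            scores = project(q, model)
        full = healthy.iloc[:, :3].copy()
        full.iloc[8:] = model.center[8:, None]  # explicit mean imputation
        np.testing.assert_allclose(scores, project(full, model), atol=1e-10)

    def test_too_many_missing_features(self):
        healthy, model = self._model(p=12)
        with pytest.raises(ValueError, match="missing"):
            project(healthy.iloc[:4], model)


class TestKNN:
    def _separated_model(self, n=200, seed=9):
        rng = np.random.default_rng(seed)
        X = np.vstack(
            [rng.normal(0, 1, (n, 8)), rng.normal(20, 1, (n, 8))]
        )
        labels = np.array(["near"] * n + ["far"] * n, dtype=object)
        return fit_projection(_frame(X), labels, n_pc=5)

    def test_separable_clusters_reach_perfect_cv(self):
        model = fit_knn(self._separated_model(), seed=0)
        assert model.cv_accuracy == 1.0

    def test_cv_accuracy_matches_brute_force_oracle(self):
        from sklearn.model_selection import StratifiedKFold

        rng = np.random.default_rng(10)
        X = np.vstack([rng.normal(0, 2, (60, 6)), rng.normal(2, 2, (60, 6))])
        labels = np.array(["a"] * 60 + ["b"] * 60, dtype=object)
        model = fit_projection(_frame(X), labels, n_pc=4)
        fit_knn(model, k=10, n_folds=5, seed=3)

        # independent leave-fold-out reimplementation with plain argsort votes
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=3)
        correct = 0
        S = model.healthy_scores
        for train, test in skf.split(S, labels):
            for i in test:
                d = np.linalg.norm(S[train] - S[i], axis=1)
                votes = pd.Series(labels[train][np.argsort(d, kind="stable")[:10]])
                top = votes.value_counts()
                win = sorted(top.index[top == top.max()])[0]
                if win == labels[i]:
                    correct += 1
        assert model.cv_accuracy == pytest.approx(correct / len(labels))

    def test_neighbor_sets_match_all_pairs_search(self):
        model = fit_knn(self._separated_model(n=150), seed=1)
        rng = np.random.default_rng(11)
        Q = rng.normal(5, 5, size=(40, model.n_pc))
        _, idx = model._nn.kneighbors(Q)
        for i in range(40):
            d = np.linalg.norm(model.healthy_scores - Q[i], axis=1)
            brute = set(np.argsort(d, kind="stable")[:10])
            assert set(idx[i]) == brute

    def test_fold_reduction_warning(self):
        rng = np.random.default_rng(12)
        X = np.vstack([rng.normal(0, 1, (5, 6)), rng.normal(9, 1, (50, 6))])
        labels = np.array(["rare"] * 5 + ["common"] * 50, dtype=object)
        model = fit_projection(_frame(X), labels, n_pc=3)
        with pytest.warns(UserWarning, match="reducing CV folds"):
            fit_knn(model, k=3, n_folds=10, seed=0)


class TestAssign:
    def _model_from_scores(self, scores, labels, k=10):
        model = fit_projection(
            _frame(np.hstack([scores, np.zeros((len(scores), 30 - scores.shape[1]))])),
            np.asarray(labels, dtype=object),
            n_pc=scores.shape[1],
        )
        # overwrite with the constructed geometry for exact control
        model.healthy_scores = np.asarray(scores, dtype=float)
        model.healthy_labels = np.asarray(labels, dtype=object)
        return fit_knn(model, k=k, n_folds=2, seed=0)

    def test_single_label_neighborhood(self):
        rng = np.random.default_rng(13)
        scores = np.vstack([rng.normal(0, 0.1, (30, 2)), rng.normal(10, 0.1, (30, 2))])
        labels = ["here"] * 30 + ["there"] * 30
        model = self._model_from_scores(scores, labels)
        res = assign(np.array([[0.0, 0.0]]), model)
        assert res.assignments[0] == "here"
        assert res.vote_counts.iloc[0].sum() == 10

    def test_constructed_seven_vs_three_vote(self):
        scores = np.array([[i * 0.1, 0.0] for i in range(7)] +
                          [[0.05, 0.1 * i] for i in range(1, 4)] +
                          [[50.0, 50.0]] * 5)
        labels = ["maj"] * 7 + ["min"] * 3 + ["bg"] * 5
        model = self._model_from_scores(scores, labels)
        res = assign(np.array([[0.0, 0.0]]), model)
        assert res.assignments[0] == "maj"
        assert res.vote_counts.loc[0, "maj"] == 7
        assert res.vote_counts.loc[0, "min"] == 3

    def test_five_vs_five_tie_broken_by_mean_distance(self):
        near = [[0.1 * (i + 1), 0.0] for i in range(5)]       # closer on average
        far = [[0.0, 0.2 * (i + 1)] for i in range(5)]
        scores = np.array(near + far + [[99.0, 99.0]] * 3)
        labels = ["znear"] * 5 + ["afar"] * 5 + ["bg"] * 3
        model = self._model_from_scores(scores, labels)
        res = assign(np.array([[0.0, 0.0]]), model)
        # "znear" sorts after "afar" alphabetically, so only the distance rule
        # can pick it
        assert res.assignments[0] == "znear"

    def test_fewer_healthy_cells_than_neighbors(self):
        rng = np.random.default_rng(14)
        scores = rng.normal(size=(6, 2))
        model = self._model_from_scores(scores, ["a", "b"] * 3, k=6)
        model.k = 10
        with pytest.raises(ValueError, match="fewer healthy cells"):
            assign(np.zeros((1, 2)), model)


class TestReferenceProjector:
    def test_end_to_end_concentrates_on_matching_population(self):
        import blineage as bl
        from blineage.expression import normalize

        def program(i0, n=20, fold=4.0):
            return {f"G{j:04d}": fold for j in range(i0, i0 + n)}

        pops = {
            "popA": (150, program(10)),
            "popB": (150, program(40)),
            "popC": (150, program(70)),
        }
        healthy, _ = bl.generate_population_counts(pops, n_genes=300, seed=0)
        proj = ReferenceProjector(n_mvg=200, n_pc=30, seed=0).fit(
            normalize(healthy), healthy.groups
        )
        query, _ = bl.generate_population_counts(
            {"tumor": (100, program(10))}, n_genes=300, seed=99
        )
        res = proj.assign(normalize(query))
        assert (res.assignments == "popA").mean() >= 0.80

    def test_model_save_load_roundtrip(self, tmp_path):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(80, 10))
        labels = np.array(["a", "b"] * 40, dtype=object)
        model = fit_projection(_frame(X), labels, n_pc=4)
        fit_knn(model, k=5, n_folds=3, seed=1)
        model.save(tmp_path / "proj")
        from blineage.projection import ProjectionModel

        loaded = ProjectionModel.load(tmp_path / "proj")
        np.testing.assert_allclose(loaded.loadings, model.loadings)
        np.testing.assert_allclose(loaded.healthy_scores, model.healthy_scores, atol=1e-12)
        assert loaded.cv_accuracy == model.cv_accuracy
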