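import numpy as np
import pandas as pd
import pytest

import jipflux as jf
from jipflux.cap import _canonical_eig, _gower_center, _LooEngine, _pcoa_eig
from jipflux.exceptions import ValidationError
from scipy.spatial.distance import pdist, squareform


def two_cluster_data(rng, n_per=10, sep=6.0, dim=4):
    means = np.zeros((2, dim))
    means[1, 0] = sep
    X = np.vstack([rng.normal(mu, 1.0, size=(n_per, dim)) for mu in means])
    y = np.repeat(["a", "b"], n_per)
    return X, y


class TestNormalizeMatrix:
    def test_zscore_definition(self, rng):
        X = rng.normal(3, 5, size=(30, 6))
        Z = jf.normalize_matrix(X)
        np.testing.assert_allclose(Z.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(Z.std(axis=0), 1, atol=1e-10)

    def test_constant_column_dropped(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=10), "b": np.ones(10)})
        with pytest.warns(UserWarning, match="zero-variance"):
            Z = jf.normalize_matrix(X)
        assert list(Z.columns) == ["a"]

    def test_none_mode_identity(self, rng):
        X = rng.normal(size=(5, 3))
        np.testing.assert_array_equal(jf.normalize_matrix(X, mode="none"), X)

    def test_all_constant_errors(self):
        with pytest.raises(ValidationError):
            jf.normalize_matrix(np.ones((5, 3)))

    def test_missing_rows_dropped(self, rng):
        X = rng.normal(size=(10, 3))
        X[2, 1] = np.nan
        with pytest.warns(UserWarning, match="missing"):
            Z = jf.normalize_matrix(X)
        assert Z.shape == (9, 3)


class TestPcoa:
    @pytest.mark.parametrize("n,p", [(5, 3), (10, 4), (20, 5), (50, 10)])
    def test_matches_pca_on_euclidean_distances(self, rng, n, p):
        X = rng.normal(size=(n, p))
        D = squareform(pdist(X))
        vals, scores = jf.pcoa(D)
        Xc = X - X.mean(axis=0)
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        pca_scores = U * s
        k = scores.shape[1]
        for j in range(k):
            r = np.corrcoef(scores[:, j], pca_scores[:, j])[0, 1]
            assert abs(abs(r) - 1) < 1e-8

    def test_identical_points_zero_eigenvalues(self):
        D = np.zeros((6, 6))
        vals, scores = jf.pcoa(D)
        np.testing.assert_allclose(vals, 0, atol=1e-12)
        assert scores.shape[1] == 0

    def test_two_points_single_positive_axis(self):
        D = np.array([[0.0, 2.0], [2.0, 0.0]])
        vals, scores = jf.pcoa(D)
        assert (vals > 1e-12).sum() == 1

    @pytest.mark.parametrize("bad", [
        np.array([[0.0, 1.0], [2.0, 0.0]]),          # asymmetric
        np.array([[0.5, 1.0], [1.0, 0.0]]),          # nonzero diagonal
        np.array([[0.0, -1.0], [-1.0, 0.0]]),        # negative distance
    ])
    def test_invalid_matrices_rejected(self, bad):
        with pytest.raises(ValidationError):
            jf.pcoa(bad)


class TestCapOrdination:
    def test_separable_clusters_fully_allocated(self, rng):
        X, y = two_cluster_data(rng)
        res = jf.cap_fit(X, y, jf.CapConfig(seed=0, n_permutations=999))
        assert res.n_correct == 20
        assert res.p_perm <= 0.01

    def test_determinism_same_seed(self, rng):
        X, y = two_cluster_data(rng)
        r1 = jf.cap_fit(X, y, jf.CapConfig(seed=3))
        r2 = jf.cap_fit(X, y, jf.CapConfig(seed=3))
        assert r1.p_perm == r2.p_perm and r1.m_used == r2.m_used
        pd.testing.assert_frame_equal(r1.canonical_scores, r2.canonical_scores)
        pd.testing.assert_frame_equal(r1.allocation, r2.allocation)

    def test_sample_order_and_label_name_invariance(self, rng):
        X, y = two_cluster_data(rng, sep=4.0)
        res = jf.cap_fit(X, y, jf.CapConfig(seed=1, n_permutations=99))
        perm = rng.permutation(len(y))
        relabel = {"a": "zzz", "b": "qqq"}
        res2 = jf.cap_fit(X[perm], np.array([relabel[v] for v in y[perm]]),
                          jf.CapConfig(seed=1, n_permutations=99))
        assert res2.n_correct == res.n_correct
        assert res2.m_used == res.m_used

    def test_trace_bounded_by_axes_and_groups(self, rng):
        X = rng.normal(size=(24, 6))
        y = np.repeat(["a", "b", "c"], 8)
        for m in (1, 2, 5):
            res = jf.cap_fit(X, y, jf.CapConfig(m=m, n_permutations=49, seed=0))
            assert res.trace_statistic <= min(m, 2) + 1e-10
            assert np.all((res.squared_correlations >= -1e-12)
                          & (res.squared_correlations <= 1 + 1e-12))

    def test_small_group_rejected(self, rng):
        X = rng.normal(size=(5, 3))
        y = np.array(["a", "a", "a", "a", "b"])
        with pytest.raises(ValidationError, match="fewer than 2"):
            jf.CapOrdination().fit(X, y)

    def test_m_beyond_rank_rejected(self, rng):
        X = rng.normal(size=(8, 2))
        y = np.repeat(["a", "b"], 4)
        with pytest.raises(ValidationError):
            jf.CapOrdination(m=5).fit(X, y)

    def test_predict_recovers_training_groups(self, rng):
        X, y = two_cluster_data(rng)
        est = jf.CapOrdination(n_permutations=49, random_state=0).fit(X, y)
        assert (est.predict(X) == y).mean() == 1.0

    def test_loo_engine_matches_explicit_canonical_classification(self, rng):
        """Nearest-centroid in canonical space equals nearest-centroid in the
        retained orthonormal PCoA coordinates (the engine's shortcut)."""
        X = rng.normal(size=(15, 4))
        X[5:10] += 2.0
        X[10:] -= 2.0
        y_idx = np.repeat([0, 1, 2], 5)
        D2 = squareform(pdist((X - X.mean(0)) / X.std(0))) ** 2
        engine = _LooEngine(D2, m_max=4)
        preds = engine.loo_predictions(y_idx, 3)
        for i in range(15):
            mask = np.arange(15) != i
            G = _gower_center(D2[np.ix_(mask, mask)])
            vals, vecs, positive = _pcoa_eig(G)
            r = int(positive.sum())
            V, lam = vecs[:, :r], vals[:r]
            from jipflux.cap import _project_holdout
            v_new = (V.T @ _project_holdout(G, D2[i, mask])) / lam
            for m in range(1, 5):
                mm = min(m, r)
                Q = V[:, :mm]
                corr, U, n_axes = _canonical_eig(Q, y_idx[mask], 3)
                W = U[:, :n_axes]
                scores = Q @ W
                cents = np.stack([scores[y_idx[mask] == k].mean(axis=0)
                                  for k in range(3)])
                z = W.T @ v_new[:mm]
                expected = int(np.argmin(((cents - z) ** 2).sum(axis=1)))
                assert preds[i, m - 1] == expected


class TestPlot:
    def _result(self, rng, dim=4):
        design = jf.paper_like_design(seed=2, n_replicates=3)
        transients, metadata, _ = jf.simulate_experiment(design)
        params, _ = jf.analyze_transients(transients)
        groups = (metadata["population"] + "/" + metadata["season"]
                  + "/" + metadata["period"]).loc[params.index].to_numpy()
        res = jf.cap_fit(params, groups, jf.CapConfig(seed=0, n_permutations=19))
        return res, metadata

    def test_figure_written(self, tmp_path, rng):
        res, metadata = self._result(rng)
        out = tmp_path / "cap.png"
        jf.cap.plot_cap(res, metadata, out)
        assert out.exists() and out.stat().st_size > 0

    def test_one_axis_fallback(self, tmp_path, rng):
        X, y = two_cluster_data(rng, dim=3)
        res = jf.cap_fit(pd.DataFrame(X, index=[f"s{i}" for i in range(20)]),
                         y, jf.CapConfig(m=1, n_permutations=19, seed=0))
        meta = pd.DataFrame({"population": ["p"] * 20, "season": ["summer"] * 20,
                             "period": np.repeat(["day", "night"], 10)},
                            index=res.canonical_scores.index)
        out = tmp_path / "strip.png"
        jf.cap.plot_cap(res, meta, out)
        assert out.exists() and out.stat().st_size > 0

    def test_missing_metadata_named(self, tmp_path, rng):
        res, metadata = self._result(rng)
        with pytest.raises(ValidationError, match="NO_su_da_01"):
            jf.cap.plot_cap(res, metadata.drop(index="NO_su_da_01"), tmp_path / "x.png")
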