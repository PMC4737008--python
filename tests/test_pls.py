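"""SIMPLS decomposition and VIP feature scoring."""

import numpy as np
import pytest

from eegconn.connectivity import build_feature_table
from eegconn.montage import pair_to_index
from eegconn.pls import (
    center,
    predict,
    rank_features,
    select_top,
    simpls_fit,
    sweep_k,
    vip_scores,
)

from conftest import PLANTED_OVERALL


def binary_y(n, rng):
    y = np.zeros(n)
    y[rng.permutation(n)[: n // 2]] = 1.0
    return y


class TestCenter:
    def test_removes_column_means(self, rng):
        X = rng.standard_normal((20, 5)) + 3.0
        Xc, mean = center(X)
        np.testing.assert_allclose(Xc.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(mean, X.mean(axis=0))

    def test_already_centred_unchanged(self, rng):
        X = rng.standard_normal((20, 5))
        X -= X.mean(axis=0)
        Xc, _ = center(X)
        np.testing.assert_allclose(Xc, X, atol=1e-12)

    def test_simple_column(self):
        Xc, _ = center(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(Xc.ravel(), [-1.0, 0.0, 1.0])


class TestSimpls:
    def test_first_weight_is_cross_product_direction(self, rng):
        """Closed form: w1 proportional to X'y; cross-checked by brute-force
        maximization of cov(Xw, y) over random unit vectors."""
        X = rng.standard_normal((40, 8))
        y = binary_y(40, rng)
        m = simpls_fit(X, y, 1)
        Xc, _ = center(X)
        yc = y - y.mean()
        w_cf = Xc.T @ yc
        w_cf /= np.linalg.norm(w_cf)
        if w_cf[np.argmax(np.abs(w_cf))] < 0:
            w_cf = -w_cf
        np.testing.assert_allclose(m.W[:, 0], w_cf, atol=1e-12)
        # no random unit vector achieves higher covariance with y
        best = abs(np.cov(Xc @ w_cf, yc)[0, 1])
        for _ in range(500):
            w = rng.standard_normal(8)
            w /= np.linalg.norm(w)
            assert abs(np.cov(Xc @ w, yc)[0, 1]) <= best + 1e-12

    def test_rank_one_problem_solved_exactly(self, rng):
        a = rng.standard_normal(6)
        y = binary_y(30, rng)
        X = np.outer(y, a)
        m = simpls_fit(X, y, 1)
        assert np.linalg.norm(m.E) < 1e-8
        assert np.linalg.norm(m.F) < 1e-8

    def test_score_orthogonality(self, rng):
        X = rng.standard_normal((50, 12))
        m = simpls_fit(X, binary_y(50, rng), 3)
        G = m.T.T @ m.T
        np.testing.assert_allclose(G, np.diag(np.diag(G)), atol=1e-8)

    def test_decomposition_reconstructs_inputs(self, rng):
        X = rng.standard_normal((50, 12))
        y = binary_y(50, rng)
        m = simpls_fit(X, y, 3)
        Xc, _ = center(X)
        np.testing.assert_allclose(m.T @ m.P.T + m.E, Xc, atol=1e-10)
        np.testing.assert_allclose(m.T @ m.Q[0] + m.F, y - y.mean(), atol=1e-10)

    def test_matches_sklearn_pls1(self, rng):
        """Independent oracle: for a single response, SIMPLS coincides with
        NIPALS PLS1 (sklearn) — identical predictions and rotation vectors."""
        from sklearn.cross_decomposition import PLSRegression

        X = rng.standard_normal((60, 25))
        y = binary_y(60, rng)
        m = simpls_fit(X, y, 5)
        sk = PLSRegression(n_components=5, scale=False).fit(X, y)
        np.testing.assert_allclose(predict(m, X), sk.predict(X).ravel(), atol=1e-10)
        R = sk.x_rotations_ / np.linalg.norm(sk.x_rotations_, axis=0)
        for k in range(5):
            w_sk = R[:, k]
            if w_sk[np.argmax(np.abs(w_sk))] < 0:
                w_sk = -w_sk
            np.testing.assert_allclose(m.W[:, k], w_sk, atol=1e-10)

    def test_excess_components_truncated_with_warning(self, rng):
        X = rng.standard_normal((6, 3))
        with pytest.warns(UserWarning, match="truncat"):
            m = simpls_fit(X, binary_y(6, rng), 10)
        assert m.n_components <= 3

    def test_deterministic_sign_convention(self, rng):
        X = rng.standard_normal((40, 8))
        y = binary_y(40, rng)
        m = simpls_fit(X, y, 3)
        for k in range(3):
            assert m.W[np.argmax(np.abs(m.W[:, k])), k] > 0

    def test_feature_permutation_equivariance(self, rng):
        X = rng.standard_normal((40, 10))
        y = binary_y(40, rng)
        perm = rng.permutation(10)
        m = simpls_fit(X, y, 3)
        mp = simpls_fit(X[:, perm], y, 3)
        np.testing.assert_allclose(mp.W, m.W[perm], atol=1e-10)
        np.testing.assert_allclose(vip_scores(mp).scores,
                                   vip_scores(m).scores[perm], atol=1e-10)


class TestVip:
    def test_single_component_collapses_to_weight_magnitude(self, rng):
        X = rng.standard_normal((40, 8))
        m = simpls_fit(X, binary_y(40, rng), 1)
        v = vip_scores(m)
        np.testing.assert_allclose(v.scores, np.sqrt(8) * np.abs(m.W[:, 0]),
                                   atol=1e-12)
        assert list(v.order) == list(np.argsort(-np.abs(m.W[:, 0]), kind="stable"))

    def test_equal_weights_give_unit_vip(self, rng):
        m = simpls_fit(rng.standard_normal((30, 4)), binary_y(30, rng), 1)
        m.W = np.full((4, 1), 0.5)  # 1/sqrt(d), unit norm
        np.testing.assert_allclose(vip_scores(m).scores, 1.0, atol=1e-12)

    def test_sum_of_squares_equals_feature_count(self, rng):
        X = rng.standard_normal((60, 37))
        m = simpls_fit(X, binary_y(60, rng), 5)
        s = vip_scores(m).scores
        assert s @ s == pytest.approx(37.0, abs=1e-8)

    def test_ranking_invariant_to_monotone_form(self, rng):
        """Dropping the square root and the factor d must not change the order."""
        X = rng.standard_normal((60, 20))
        m = simpls_fit(X, binary_y(60, rng), 4)
        v = vip_scores(m)
        rho2 = m.rho ** 2
        raw = (m.W ** 2 @ rho2) / rho2.sum()  # no sqrt, no d
        np.testing.assert_array_equal(np.argsort(-v.scores, kind="stable"),
                                      np.argsort(-raw, kind="stable"))

    def test_orthogonal_response_warns_and_zeroes(self):
        X = np.array([[1.0, 0.0], [-1.0, 0.0], [1.0, 0.0], [-1.0, 0.0]])
        y = np.array([0.0, 0.0, 1.0, 1.0])  # X'y = 0
        with pytest.warns(UserWarning):
            m = simpls_fit(X, y, 1)
            v = vip_scores(m)
        assert np.all(v.scores == 0)


class TestSelection:
    def test_select_top_k(self, rng):
        v = rank_features(rng.standard_normal((40, 30)), binary_y(40, rng), 3)
        sel = select_top(v, 10)
        assert len(sel) == 10
        assert list(sel["rank"]) == list(range(1, 11))
        assert np.all(np.diff(v.scores[sel["position"]]) <= 1e-12)

    def test_k_beyond_d_rejected(self, rng):
        v = rank_features(rng.standard_normal((20, 5)), binary_y(20, rng), 2)
        with pytest.raises(ValueError):
            v.top(6)

    def test_full_permutation_at_k_equals_d(self, rng):
        v = rank_features(rng.standard_normal((20, 5)), binary_y(20, rng), 2)
        assert sorted(v.top(5)) == [0, 1, 2, 3, 4]

    def test_planted_pairs_reach_top_ranks(self, study_epochs):
        """The three planted differential couplings dominate the VIP ranking."""
        table = build_feature_table(study_epochs, "overall")
        ranking = rank_features(table.X, table.labels, 5)
        planted = {pair_to_index(i, j) - 1 for _, (i, j), _, _ in PLANTED_OVERALL}
        assert planted <= set(ranking.top(10))

    def test_annotations_carried(self, study_epochs):
        table = build_feature_table(study_epochs, "overall")
        ranking = rank_features(table.X, table.labels, 5)
        sel = select_top(ranking, 5, annotations=table.annotations)
        assert "lead_pair" in sel.columns
        assert (sel["feature_index"] == sel["position"] + 1).all()


def test_sweep_k_structure_and_selection_of_everything(study_epochs):
    table = build_feature_table(study_epochs, "overall")
    sweep = sweep_k(table.X, table.labels, ks=[10, 171], folds=5, seed=0)
    assert list(sweep["k"]) == [10, 171]
    # selecting all features must match the plain full-feature run
    from eegconn.classify import train_eval

    full = train_eval(table.X, table.labels, folds=5, seed=0)
    assert sweep.loc[1, "mean_accuracy_pct"] == pytest.approx(full.mean_pct, abs=1e-9)
    # planted signal lives in few features: top-10 within 5 points of all 171
    assert abs(sweep.loc[0, "mean_accuracy_pct"]
               - sweep.loc[1, "mean_accuracy_pct"]) <= 5.0
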