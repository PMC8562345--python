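import itertools

import numpy as np
import pandas as pd
import pytest

from behavdyn.features import FeatureTable
from behavdyn.ml import (
    chi2_score,
    cluster_purity,
    discretize_equal_frequency,
    gini_gain,
    information_gain,
    kmeans_cluster,
    pca_projection,
    rank_variables,
    tsne_embed,
)


def expand(table):
    """Turn a 2x2 contingency table into (x, y) label arrays."""
    x, y = [], []
    for i, row in enumerate(table):
        for j, count in enumerate(row):
            x += [i] * count
            y += [j] * count
    return np.array(x), np.array(y)


def oracle_scores(table):
    """Brute-force contingency evaluation of all three filter scores."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    py = table.sum(axis=0) / n

    def h(p):
        p = p[p > 0]
        return -(p * np.log2(p)).sum()

    ig = h(py) - sum(row.sum() / n * h(row / row.sum()) for row in table)
    gini = (1 - (py**2).sum()) - sum(
        row.sum() / n * (1 - ((row / row.sum()) ** 2).sum()) for row in table
    )
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    chi2 = ((table - expected) ** 2 / expected).sum()
    return ig, gini, chi2


def make_table(frame, feature_names, target="condition"):
    frame = frame.copy()
    frame["subject"] = "R1"
    frame["session_number"] = np.arange(1, len(frame) + 1)
    frame["sequence"] = None
    return FeatureTable(data=frame, feature_names=tuple(feature_names), target=target)


class TestDiscretize:
    def test_quartiles_of_1_to_8(self):
        codes = discretize_equal_frequency(np.arange(1.0, 9.0), k=4)
        np.testing.assert_array_equal(codes, [0, 0, 1, 1, 2, 2, 3, 3])

    def test_constant_input_single_bin(self):
        assert set(discretize_equal_frequency(np.full(10, 2.0), k=4)) == {0}

    def test_bins_collapse_to_distinct_values(self):
        codes = discretize_equal_frequency(np.array([1.0, 1.0, 2.0, 2.0]), k=4)
        assert len(set(codes)) == 2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            discretize_equal_frequency([])


class TestFilterScores:
    def test_perfect_split_saturates_information_and_gini(self):
        x, y = expand([[8, 0], [0, 8]])
        assert information_gain(x, y) == pytest.approx(1.0)
        assert gini_gain(x, y) == pytest.approx(0.5)

    def test_constant_feature_scores_zero(self):
        x = np.zeros(16, dtype=int)
        y = np.array([0, 1] * 8)
        assert information_gain(x, y) == pytest.approx(0.0)
        assert gini_gain(x, y) == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "table,expected_ig,expected_gini,expected_chi2",
        [
            ([[6, 2], [2, 6]], 0.18872, 0.125, 4.0),
            ([[10, 0], [0, 10]], 1.0, 0.5, 20.0),
        ],
    )
    def test_hand_checked_contingency_tables(self, table, expected_ig, expected_gini, expected_chi2):
        ig_o, gini_o, chi2_o = oracle_scores(table)
        assert ig_o == pytest.approx(expected_ig, abs=1e-5)
        assert gini_o == pytest.approx(expected_gini, abs=1e-12)
        assert chi2_o == pytest.approx(expected_chi2, abs=1e-12)
        x, y = expand(table)
        assert information_gain(x, y) == pytest.approx(ig_o, abs=1e-12)
        assert gini_gain(x, y) == pytest.approx(gini_o, abs=1e-12)
        assert chi2_score(x, y) == pytest.approx(chi2_o, abs=1e-12)

    def test_proportional_table_chi2_zero(self):
        x, y = expand([[6, 3], [4, 2]])
        assert chi2_score(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_information_gain_is_symmetric_mutual_information(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 3, 200)
        y = rng.integers(0, 2, 200)
        assert information_gain(x, y) == pytest.approx(information_gain(y, x), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            information_gain([0, 1], [0, 1, 0])


class TestRankVariables:
    def _table(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        y = np.array(["FT", "VT"] * (n // 2))
        frame = pd.DataFrame(
            {
                "condition": y,
                "oracle_like": np.where(y == "FT", 1.0, 0.0) + rng.normal(0, 0.01, n),
                "noisy": np.where(y == "FT", 1.0, 0.0) + rng.normal(0, 2.0, n),
                "pure_noise": rng.normal(size=n),
            }
        )
        return make_table(frame, ["oracle_like", "noisy", "pure_noise"])

    def test_perfectly_informative_feature_tops_all_methods(self):
        ranking = rank_variables(self._table())
        for method in ("info_gain", "gini", "chi2"):
            assert ranking.order[method][0] == "oracle_like"

    def test_noise_scores_near_zero_relative_to_signal(self):
        ranking = rank_variables(self._table())
        for method in ("info_gain", "gini", "chi2"):
            assert (
                ranking.scores.loc["pure_noise", method]
                < 0.2 * ranking.scores.loc["oracle_like", method]
            )

    def test_orders_match_independent_recomputation(self):
        table = self._table(seed=5)
        ranking = rank_variables(table)
        y = table.data["condition"].to_numpy()
        for method, scorer in [
            ("info_gain", information_gain),
            ("gini", gini_gain),
            ("chi2", chi2_score),
        ]:
            recomputed = {
                f: scorer(discretize_equal_frequency(table.data[f].to_numpy(), 4), y)
                for f in table.feature_names
            }
            expected = sorted(recomputed, key=lambda f: (-recomputed[f], f))
            assert ranking.order[method] == expected

    def test_single_class_target_rejected(self):
        table = self._table()
        table.data["condition"] = "FT"
        with pytest.raises(ValueError):
            rank_variables(table)


class TestTSNE:
    def _blobs(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 0.3, size=(n // 2, 3))
        b = rng.normal(6, 0.3, size=(n // 2, 3))
        frame = pd.DataFrame(np.vstack([a, b]), columns=["f1", "f2", "f3"])
        frame["condition"] = ["A"] * (n // 2) + ["B"] * (n // 2)
        return make_table(frame, ["f1", "f2", "f3"])

    def test_reproducible_given_seed(self):
        table = self._blobs()
        e1 = tsne_embed(table, seed=7)
        e2 = tsne_embed(table, seed=7)
        np.testing.assert_array_equal(e1.coords, e2.coords)

    def test_output_shape_matches_complete_rows(self):
        table = self._blobs()
        emb = tsne_embed(table)
        assert emb.coords.shape == (len(table), 2)

    def test_separated_blobs_stay_separated(self):
        table = self._blobs()
        emb = tsne_embed(table, seed=0)
        y = emb.row_index["condition"].to_numpy()
        within, between = [], []
        for i, j in itertools.combinations(range(len(y)), 2):
            d = np.linalg.norm(emb.coords[i] - emb.coords[j])
            (within if y[i] == y[j] else between).append(d)
        assert np.mean(within) < np.mean(between)

    def test_too_few_rows_rejected(self):
        table = self._blobs(n=2)
        with pytest.raises(ValueError):
            tsne_embed(table)

    def test_oversized_perplexity_shrunk_with_warning(self):
        table = self._blobs(n=12)
        with pytest.warns(UserWarning, match="perplexity"):
            emb = tsne_embed(table, perplexity=30)
        assert emb.perplexity < 30


class TestKMeans:
    def test_two_distant_blobs_pure(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(0, 0.2, (20, 2)), rng.normal(10, 0.2, (20, 2))])
        ref = np.array([0] * 20 + [1] * 20)
        res = kmeans_cluster(pts, k=2, seed=0, reference=ref)
        assert res.purity == 1.0
        assert res.adjusted_rand == pytest.approx(1.0)

    def test_purity_invariant_to_label_permutation(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, 30)
        ref = rng.integers(0, 2, 30)
        assert cluster_purity(labels, ref) == cluster_purity(1 - labels, ref)

    def test_k_equal_one_purity_is_majority_share(self):
        pts = np.arange(10.0)[:, None]
        ref = np.array([0] * 7 + [1] * 3)
        res = kmeans_cluster(pts, k=1, seed=0, reference=ref)
        assert res.purity == pytest.approx(0.7)

    def test_fewer_rows_than_k_rejected(self):
        with pytest.raises(ValueError):
            kmeans_cluster(np.zeros((1, 2)), k=2)


class TestPCAProjection:
    def _table(self, x, names):
        frame = pd.DataFrame(x, columns=names)
        frame["condition"] = ["A", "B"] * (len(frame) // 2)
        return make_table(frame, names)

    def test_component_axes_orthonormal(self):
        rng = np.random.default_rng(2)
        table = self._table(rng.normal(size=(30, 4)), list("abcd"))
        proj = pca_projection(table)
        v = proj.loadings.to_numpy()
        np.testing.assert_allclose(v.T @ v, np.eye(2), atol=1e-9)

    def test_collinear_features_load_on_single_component(self):
        t = np.linspace(-1, 1, 20)
        table = self._table(np.column_stack([t, 2 * t]), ["a", "b"])
        proj = pca_projection(table)
        assert proj.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_loadings_match_eigendecomposition_oracle(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(60, 3))
        x = base @ np.array([[1.0, 0.5, 0.0], [0.0, 1.0, 0.3], [0.0, 0.0, 1.0]])
        table = self._table(x, ["a", "b", "c"])
        proj = pca_projection(table)
        xz = (x - x.mean(0)) / x.std(0)
        eigvals, eigvecs = np.linalg.eigh(np.cov(xz.T, bias=True))
        order = np.argsort(eigvals)[::-1]
        for i in range(2):
            oracle = eigvecs[:, order[i]]
            found = proj.loadings.to_numpy()[:, i]
            assert abs(abs(oracle @ found) - 1.0) < 1e-9  # equal up to sign
        # variance fractions non-increasing and in [0, 1]
        evr = proj.explained_variance_ratio
        assert 0 <= evr[1] <= evr[0] <= 1

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(4)
        table = self._table(rng.normal(size=(24, 3)), ["a", "b", "c"])
        proj = pca_projection(table)
        for col in ("PC1", "PC2"):
            loadings = proj.loadings[col].to_numpy()
            assert loadings[np.argmax(np.abs(loadings))] > 0

    def test_fewer_than_two_rows_rejected(self):
        table = self._table(np.zeros((2, 2)), ["a", "b"]).complete()
        table.data.drop(index=1, inplace=True)
        with pytest.raises(ValueError):
            pca_projection(table)
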