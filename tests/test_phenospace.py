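"""KS network distance, retrieval, PCA, LDA cross-validation, Welch's t."""

import numpy as np
import pandas as pd
import pytest

from veintop.metrics import GEOMETRY_COLUMNS, METRIC_COLUMNS
from veintop.phenospace import (
    ks_distance,
    lda_cv,
    nearest_neighbors,
    pairwise_lda,
    pca_fingerprints,
    welch_t,
)


class TestKSDistance:
    def test_identity(self):
        s = [0.1, 0.5, 0.9]
        assert ks_distance(s, s) == 0.0

    def test_disjoint_supports(self):
        assert ks_distance([0.1, 0.2], [0.3, 0.4]) == 1.0

    def test_interleaved_hand_case(self):
        assert ks_distance([0.1, 0.3], [0.2, 0.4]) == pytest.approx(0.5)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a, b = rng.random(rng.integers(1, 30)), rng.random(rng.integers(1, 30))
            d = ks_distance(a, b)
            assert 0.0 <= d <= 1.0
            assert d == ks_distance(b, a)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_distance([], [0.5])


class TestNearestNeighbors:
    def test_duplicate_ranks_first_with_zero_distance(self):
        samples = {"x": [0.2, 0.8], "dup": [0.2, 0.8], "far": [0.01, 0.02]}
        ranked = nearest_neighbors("x", samples, k=2)
        assert ranked[0] == ("dup", 0.0)

    def test_ranking_matches_brute_force(self):
        samples = {"a": [0.1, 0.2, 0.9], "b": [0.15, 0.25, 0.85], "c": [0.5, 0.6, 0.7], "d": [0.9, 0.95, 1.0]}
        ranked = nearest_neighbors("a", samples, k=3)
        expect = sorted((ks_distance(samples["a"], samples[i]), i) for i in "bcd")
        assert [i for i, _ in ranked] == [i for _, i in expect]

    def test_k_too_large(self):
        with pytest.raises(ValueError):
            nearest_neighbors("a", {"a": [0.1], "b": [0.2]}, k=2)


def _table(X: np.ndarray, labels=None) -> pd.DataFrame:
    df = pd.DataFrame(X, columns=METRIC_COLUMNS[: X.shape[1]])
    df["specimen_id"] = labels if labels is not None else [f"s{i}" for i in range(len(df))]
    df["species"] = df["specimen_id"]
    return df


class TestPCA:
    def test_rank_one_case(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal(50)
        X = np.column_stack([base, 2 * base + 1.0])
        fr, loadings = pca_fingerprints(_table(X), columns=METRIC_COLUMNS[:2])
        assert fr[0] == pytest.approx(1.0)
        assert loadings.shape == (2, 2)

    def test_isotropic_fractions_near_uniform(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((10_000, 8))
        fr, loadings = pca_fingerprints(_table(X))
        assert fr.sum() == pytest.approx(1.0)
        assert np.all(np.abs(fr - 1 / 8) < 0.02)
        # loadings rows are orthonormal
        assert np.allclose(loadings.to_numpy() @ loadings.to_numpy().T, np.eye(8), atol=1e-8)

    def test_constant_column_error_names_column(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((30, 8))
        X[:, 3] = 5.0
        with pytest.raises(ValueError, match=METRIC_COLUMNS[3]):
            pca_fingerprints(_table(X))


class TestLDA:
    def _blobs(self, n_per=100, sep=10.0, n_feat=8, seed=0, classes=("A", "B")):
        rng = np.random.default_rng(seed)
        frames = []
        for i, c in enumerate(classes):
            X = rng.standard_normal((n_per, n_feat)) + i * sep
            df = _table(X, labels=[c] * n_per)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def test_separable_classes_perfect_accuracy(self):
        accs = lda_cv(self._blobs(sep=10.0), label="specimen", feature_set="geometry+topology")
        assert np.all(accs == 1.0)

    def test_chance_level_on_pure_noise(self):
        accs = lda_cv(self._blobs(sep=0.0, n_per=100, seed=8), folds=10, seed=1)
        se = np.sqrt(0.25 / 200)
        assert abs(accs.mean() - 0.5) < 3 * se

    def test_reproducible_given_seed(self):
        t = self._blobs(sep=1.0, seed=5)
        a1 = lda_cv(t, seed=3)
        a2 = lda_cv(t, seed=3)
        assert np.array_equal(a1, a2)
        assert not np.array_equal(a1, lda_cv(t, seed=4))

    def test_small_classes_dropped_single_class_error(self):
        t = self._blobs(n_per=50)
        t = pd.concat([t, _table(np.zeros((3, 8)), labels=["tiny"] * 3)], ignore_index=True)
        accs = lda_cv(t)  # 'tiny' silently dropped
        assert len(accs) == 10
        only = _table(np.random.default_rng(0).standard_normal((30, 8)), labels=["one"] * 30)
        with pytest.raises(ValueError):
            lda_cv(only)

    def test_noise_columns_do_not_create_signal(self):
        # leakage guard: standardization is fit on train folds only, so extra
        # pure-noise features keep a noise problem at chance level
        t = self._blobs(sep=0.0, n_per=100, seed=12)
        accs = lda_cv(t, feature_set="geometry+topology", seed=2)
        accs_geo = lda_cv(t, feature_set="geometry", seed=2)
        se = np.sqrt(0.25 / 200)
        assert abs(accs.mean() - 0.5) < 3 * se
        assert abs(accs_geo.mean() - 0.5) < 3 * se

    def test_pairwise_chance_level_for_identical_classes(self):
        t = self._blobs(sep=0.0, n_per=60, seed=21, classes=("A", "B", "C"))
        mean = pairwise_lda(t, label="specimen", feature_set="geometry")
        assert abs(mean - 0.5) < 0.12

    def test_pairwise_reflects_separability(self):
        rng = np.random.default_rng(9)
        a = _table(rng.standard_normal((60, 8)), labels=["A"] * 60)
        b = _table(rng.standard_normal((60, 8)) + 8.0, labels=["B"] * 60)
        c = _table(rng.standard_normal((60, 8)) + 0.3, labels=["C"] * 60)
        t = pd.concat([a, b, c], ignore_index=True)
        mean, mat = pairwise_lda(t, return_matrix=True)
        assert mat.loc["A", "B"] == 1.0
        assert mat.loc["A", "C"] < mat.loc["A", "B"]
        with pytest.raises(ValueError):
            pairwise_lda(a)


class TestWelchT:
    def test_identical_samples(self):
        t, df, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_hand_computed_case(self):
        t, df, p = welch_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.0 / np.sqrt(2 / 3))
        assert df == pytest.approx(4.0)
        assert 0 < p < 0.05

    def test_zero_variance_equal_means(self):
        t, _, p = welch_t([2.0, 2.0], [2.0, 2.0])
        assert t == 0.0 and p == 1.0
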