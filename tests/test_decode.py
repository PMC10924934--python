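"""Decoder correctness (vs scikit-learn), AUC properties, CI, LOFO,
temporal generalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from riskdecode import decode as dc
from riskdecode import feature_prep as fp


def make_folds(rng, n=60, c=5, t=8, n_folds=5, signal=0.0, n_subjects=2):
    """Toy pooled folds; optional linear signal at every timepoint."""
    data = {}
    for s in range(n_subjects):
        y = rng.integers(0, 2, n).astype(float)
        X = rng.normal(size=(n, c, t))
        if signal:
            X += signal * (2 * y - 1)[:, None, None] * rng.normal(size=(1, c, 1))
        data[f"s{s}"] = (X, y)
    folds = fp.assemble_pseudo_population(
        data, n_folds=n_folds, seed=int(rng.integers(1 << 30)), times=np.arange(t) * 0.002
    )
    return [fp.normalize_fold(f) for f in folds]


class TestSolver:
    def test_matches_sklearn_coefficients(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, 8))
        y = (X[:, 0] + rng.normal(size=100) > 0).astype(float)
        w = dc.fit_l2_logistic(X, y, C=1.0, tol=1e-10)
        ref = LogisticRegression(C=1.0, tol=1e-12, max_iter=20000).fit(X, y)
        assert np.abs(w[:-1] - ref.coef_[0]).max() < 1e-5
        assert abs(w[-1] - ref.intercept_[0]) < 1e-5

    def test_batched_fit_equals_individual_fits(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 6))
        Y = rng.integers(0, 2, (7, 50)).astype(float)
        W = dc.fit_l2_logistic(X, Y, tol=1e-10)
        for k in range(7):
            wk = dc.fit_l2_logistic(X, Y[k], tol=1e-10)
            assert np.abs(W[k] - wk).max() < 1e-8

    def test_separable_data_stays_finite(self):
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = np.array([0.0, 0.0, 1.0, 1.0])
        w = dc.fit_l2_logistic(X, y)
        assert np.isfinite(w).all()


class TestAuc:
    def test_matches_sklearn_including_ties(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            s = rng.integers(0, 5, 50).astype(float)  # many ties
            y = rng.integers(0, 2, 50) * 2 - 1
            assert dc.roc_auc(s, y) == pytest.approx(roc_auc_score(y, s))

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(seed=hst.integers(0, 10_000))
    def test_invariant_to_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        s = rng.normal(size=40)
        y = np.concatenate([np.ones(20), -np.ones(20)])
        base = dc.roc_auc(s, y)
        assert dc.roc_auc(np.exp(s), y) == pytest.approx(base, abs=1e-12)
        assert dc.roc_auc(s**3 + 5 * s, y) == pytest.approx(base, abs=1e-12)

    def test_single_class_is_nan(self):
        assert np.isnan(dc.roc_auc(np.arange(4.0), np.ones(4)))


class TestDecodeTimecourse:
    def test_separable_blobs_decode_perfectly(self):
        rng = np.random.default_rng(3)
        folds = make_folds(rng, signal=50.0)
        curve = dc.decode_timecourse(folds)
        assert np.all(curve.mean_auc > 0.999)

    def test_shuffled_labels_are_chance(self):
        rng = np.random.default_rng(4)
        folds = make_folds(rng, signal=2.0)
        y = np.empty(120)
        y[folds[0].train_rows] = folds[0].train_y
        y[folds[0].test_rows] = folds[0].test_y
        perms = [rng.permutation(y) for _ in range(100)]
        curves = dc.decode_timecourse_batch(folds, perms)
        mean = curves.mean()
        se = curves.mean(axis=1).std() / np.sqrt(len(perms))
        assert abs(mean - 0.5) < 3 * se

    def test_degenerate_train_fold_rejected(self):
        rng = np.random.default_rng(5)
        folds = make_folds(rng)
        folds[0].train_y[:] = 1.0
        with pytest.raises(ValueError):
            dc.decode_timecourse(folds)


class TestBootstrap:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        folds = make_folds(rng, signal=1.0)
        a = dc.bootstrap_test_auc(folds, n_boot=50, seed=3)
        b = dc.bootstrap_test_auc(folds, n_boot=50, seed=3)
        assert np.array_equal(a, b)

    def test_point_estimate_inside_interval(self):
        rng = np.random.default_rng(7)
        folds = make_folds(rng, n=100, signal=1.0)
        curve = dc.decode_timecourse(folds)
        lo, hi = dc.bootstrap_test_auc(folds, n_boot=200, seed=1)
        inside = (curve.mean_auc >= lo) & (curve.mean_auc <= hi)
        assert inside.mean() >= 0.95

    def test_interval_narrows_with_larger_test_sets(self):
        """Duplicating every test row k times shrinks the CI roughly √k-fold."""
        rng = np.random.default_rng(8)
        folds = make_folds(rng, n=60, signal=1.0)
        k = 4
        import dataclasses

        big = [
            dataclasses.replace(
                f,
                test_X=np.repeat(f.test_X, k, axis=0),
                test_y=np.repeat(f.test_y, k),
                test_subject=np.repeat(f.test_subject, k),
                test_rows=np.repeat(f.test_rows, k),
            )
            for f in folds
        ]
        lo1, hi1 = dc.bootstrap_test_auc(folds, n_boot=300, seed=2)
        lo2, hi2 = dc.bootstrap_test_auc(big, n_boot=300, seed=2)
        ratio = np.median(hi1 - lo1) / np.median(hi2 - lo2)
        assert 1.3 < ratio < 3.2

    def test_too_few_replicates_rejected(self):
        rng = np.random.default_rng(9)
        with pytest.raises(ValueError):
            dc.bootstrap_test_auc(make_folds(rng), n_boot=1)


class TestLofo:
    def _informative_folds(self, rng, duplicate=False):
        n, t = 120, 4
        data = {}
        y = rng.integers(0, 2, n).astype(float)
        sig = (2 * y - 1)[:, None]
        cols = [sig * 2.0 + rng.normal(size=(n, 1)) * 0.3]
        if duplicate:
            cols.append(cols[0].copy())
        cols += [rng.normal(size=(n, 1)) for _ in range(3)]
        X = np.stack(cols, axis=1) * np.ones((1, 1, t))
        data["s0"] = (X, y)
        folds = fp.assemble_pseudo_population(data, n_folds=5, seed=0,
                                              times=np.arange(t) * 0.002)
        return [fp.normalize_fold(f) for f in folds]

    def test_sole_informative_feature_carries_the_auc(self):
        rng = np.random.default_rng(10)
        folds = self._informative_folds(rng)
        full = dc.decode_timecourse(folds)
        w = dc.lofo_weights(folds)
        assert np.all(w.delta_auc[0] > 0.25)
        assert np.allclose(w.delta_auc[0], full.mean_auc - 0.5, atol=0.2)

    def test_duplicated_feature_is_redundant(self):
        rng = np.random.default_rng(11)
        folds = self._informative_folds(rng, duplicate=True)
        w = dc.lofo_weights(folds)
        assert np.abs(w.delta_auc[0]).max() < 0.1
        assert np.abs(w.delta_auc[1]).max() < 0.1

    def test_noise_features_near_zero(self):
        rng = np.random.default_rng(12)
        folds = self._informative_folds(rng)
        w = dc.lofo_weights(folds)
        assert np.abs(w.delta_auc[2:]).max() < 0.1

    def test_single_feature_rejected(self):
        rng = np.random.default_rng(13)
        folds = make_folds(rng, c=1, n_subjects=1)
        with pytest.raises(ValueError):
            dc.lofo_weights(folds)


class TestWeightCorrelation:
    def _weights(self, seed=14):
        rng = np.random.default_rng(seed)
        return dc.FeatureWeights(rng.normal(size=(8, 10)), np.arange(10) * 0.05)

    def test_self_correlation_is_one(self):
        w = self._weights()
        r, _ = dc.weight_correlation(w, w, (0.0, 0.45), n_perm=50, seed=0)
        assert r == pytest.approx(1.0)

    def test_negated_map_gives_minus_one(self):
        w = self._weights()
        neg = dc.FeatureWeights(-w.delta_auc, w.times)
        r, _ = dc.weight_correlation(w, neg, (0.0, 0.45), n_perm=50, seed=0)
        assert r == pytest.approx(-1.0)

    def test_too_few_contacts_rejected(self):
        w = dc.FeatureWeights(np.zeros((2, 4)), np.arange(4) * 0.002)
        with pytest.raises(ValueError):
            dc.weight_correlation(w, w, (0.0, 0.01))


class TestGeneralization:
    def test_diagonal_equals_ordinary_decoding(self):
        rng = np.random.default_rng(15)
        folds = make_folds(rng, t=10, signal=1.0)
        window = (0.0, 0.018)
        gm = dc.generalization_matrix(folds, folds, window=window)
        t_idx = np.flatnonzero(
            (folds[0].times >= window[0]) & (folds[0].times <= window[1] + 1e-12)
        )
        curve = dc.decode_timecourse(folds, time_indices=t_idx)
        assert np.allclose(np.diag(gm.auc), curve.mean_auc, atol=1e-10)

    def test_mismatched_rows_rejected(self):
        rng = np.random.default_rng(16)
        a = make_folds(rng, t=6)
        b = make_folds(rng, t=6)
        with pytest.raises(ValueError):
            dc.generalization_matrix(a, b, window=(0.0, 0.01))
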