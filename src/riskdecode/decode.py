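"""Time-resolved decoding, bootstrap CIs, generalization, feature importance.

At every timepoint independently, an L2-regularized logistic regression is
fit on the pooled pseudo-population train rows and scored on the held-out
rows with ROC AUC; the curve is the across-fold mean. Permutation inference
(see :mod:`riskdecode.stats`) needs the same model refit under thousands of
label shuffles, so the solver here is a damped-Newton minimizer of the
penalized logistic loss vectorized over an arbitrary batch of label vectors
sharing one feature matrix — mathematically identical to a standard logistic
fit (it matches scikit-learn's coefficients to ~1e-7 at tight tolerance, a
correspondence asserted in the test suite) but amortizing the per-fit cost
across a whole permutation batch. The intercept is unpenalized, matching the
usual convention.

ROC AUC is computed from the rank statistic (Mann-Whitney form) with
midranks for ties, vectorized over batches of (scores, labels) pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .feature_prep import PseudoPopulationFold


def fit_l2_logistic(
    X: np.ndarray,
    Y: np.ndarray,
    C: float = 1.0,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> np.ndarray:
    """Fit L2-penalized logistic regression for a batch of label vectors.

    X: (n, d); Y: (..., n) with entries in {0, 1} (or {+1, -1}, converted).
    Returns weights of shape (..., d + 1); the last coefficient is the
    unpenalized intercept. Loss: sum of logistic losses + (1/2C)‖w‖².
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    squeeze = Y.ndim == 1
    if squeeze:
        Y = Y[None, :]
    Y = np.where(Y > 0, 1.0, 0.0)
    n, d = X.shape
    Xa = np.concatenate([X, np.ones((n, 1))], axis=1)
    P = Y.shape[0]
    W = np.zeros((P, d + 1))
    reg = (1.0 / C) * np.eye(d + 1)
    reg[d, d] = 0.0
    for _ in range(max_iter):
        S = np.clip(W @ Xa.T, -500, 500)
        Pr = 1.0 / (1.0 + np.exp(-S))
        G = (Pr - Y) @ Xa + W @ reg
        if np.max(np.abs(G)) < tol:
            break
        R = np.clip(Pr * (1.0 - Pr), 1e-10, None)
        H = np.matmul(Xa.T[None, :, :], R[:, :, None] * Xa[None, :, :]) + reg
        W -= np.linalg.solve(H, G[..., None])[..., 0]
    return W[0] if squeeze else W


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Batched ROC AUC via midranks; broadcasting over leading axes.

    ``labels`` in {+1, -1} (or {1, 0}); returns NaN where a batch member has
    a single class. Invariant to strictly increasing score transforms.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    scores, labels = np.broadcast_arrays(scores, labels)
    pos = labels > 0
    n1 = pos.sum(axis=-1)
    n0 = (~pos).sum(axis=-1)
    ranks = rankdata(scores, axis=-1)
    rank_sum = np.where(pos, ranks, 0.0).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        auc = (rank_sum - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    return np.where((n1 > 0) & (n0 > 0), auc, np.nan)


@dataclass
class DecodingCurve:
    times: np.ndarray
    fold_aucs: np.ndarray  # folds x timepoints
    mean_auc: np.ndarray
    decode_target: str = ""
    roi_label: str = ""


def _check_classes(folds: list[PseudoPopulationFold]) -> None:
    for i, f in enumerate(folds):
        if np.unique(f.train_y).size < 2:
            raise ValueError(f"fold {i} train split has a single class")


def decode_timecourse(
    folds: list[PseudoPopulationFold],
    C: float = 1.0,
    decode_target: str = "",
    roi_label: str = "",
    time_indices: np.ndarray | None = None,
) -> DecodingCurve:
    """Mean cross-validated ROC AUC at every timepoint."""
    _check_classes(folds)
    n_t_full = folds[0].train_X.shape[2]
    t_idx = np.arange(n_t_full) if time_indices is None else np.asarray(time_indices)
    fold_aucs = np.full((len(folds), t_idx.size), np.nan)
    for fi, fold in enumerate(folds):
        if np.unique(fold.test_y).size < 2:
            warnings.warn(f"fold {fi} test split degenerate; skipped")
            continue
        for ti, t in enumerate(t_idx):
            w = fit_l2_logistic(fold.train_X[:, :, t], fold.train_y, C=C)
            s = fold.test_X[:, :, t] @ w[:-1] + w[-1]
            fold_aucs[fi, ti] = roc_auc(s, fold.test_y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(fold_aucs, axis=0)
    times = folds[0].times[t_idx] if folds[0].times is not None else t_idx.astype(float)
    return DecodingCurve(times, fold_aucs, mean, decode_target, roi_label)


def decode_timecourse_batch(
    folds: list[PseudoPopulationFold],
    label_sets: list[np.ndarray],
    C: float = 1.0,
    time_indices: np.ndarray | None = None,
    tol: float = 1e-6,
) -> np.ndarray:
    """Mean-CV-AUC curves for many label assignments of the same rows.

    ``label_sets[k]`` has one label per pooled row (ordering given by the
    folds' ``train_rows``/``test_rows``); the model is refit for every label
    set at every (fold, timepoint). Returns (len(label_sets), timepoints).
    Used by permutation nulls, where only labels change between refits.
    """
    n_t_full = folds[0].train_X.shape[2]
    t_idx = np.arange(n_t_full) if time_indices is None else np.asarray(time_indices)
    L = np.stack(label_sets)  # (P, n_rows)
    P = L.shape[0]
    aucs = np.full((P, len(folds), t_idx.size), np.nan)
    for fi, fold in enumerate(folds):
        Ytr = L[:, fold.train_rows]
        Yte = L[:, fold.test_rows]
        for ti, t in enumerate(t_idx):
            W = fit_l2_logistic(fold.train_X[:, :, t], Ytr, C=C, tol=tol)
            S = W[:, :-1] @ fold.test_X[:, :, t].T + W[:, -1:]
            aucs[:, fi, ti] = roc_auc(S, Yte)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(aucs, axis=1)


def bootstrap_test_auc(
    folds: list[PseudoPopulationFold],
    n_boot: int = 500,
    seed: int = 0,
    C: float = 1.0,
    time_indices: np.ndarray | None = None,
) -> np.ndarray:
    """95% percentile CI of the mean CV AUC by resampling test rows.

    Models are fit once per (fold, timepoint) on the unresampled training
    rows; each bootstrap replicate resamples every fold's test rows with
    replacement, recomputes the AUC and averages across folds. Returns an
    array (2, timepoints) of the 2.5th/97.5th percentiles.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    _check_classes(folds)
    rng = np.random.default_rng(seed)
    n_t_full = folds[0].train_X.shape[2]
    t_idx = np.arange(n_t_full) if time_indices is None else np.asarray(time_indices)
    boot = np.full((n_boot, len(folds), t_idx.size), np.nan)
    for fi, fold in enumerate(folds):
        n_test = fold.test_y.size
        idx = rng.integers(0, n_test, size=(n_boot, n_test))
        yb = fold.test_y[idx]  # (B, n_test)
        for ti, t in enumerate(t_idx):
            w = fit_l2_logistic(fold.train_X[:, :, t], fold.train_y, C=C)
            s = fold.test_X[:, :, t] @ w[:-1] + w[-1]
            boot[:, fi, ti] = roc_auc(s[idx], yb)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(boot, axis=1)  # (B, T)
    return np.nanpercentile(means, [2.5, 97.5], axis=0)


@dataclass
class FeatureWeights:
    """Leave-one-feature-out importance: ΔAUC per contact and timepoint."""

    delta_auc: np.ndarray  # contacts x timepoints
    times: np.ndarray
    decode_target: str = ""
    roi_label: str = ""


def lofo_weights(
    folds: list[PseudoPopulationFold],
    C: float = 1.0,
    time_indices: np.ndarray | None = None,
    decode_target: str = "",
    roi_label: str = "",
) -> FeatureWeights:
    """Full-model mean CV AUC minus the mean CV AUC with one contact dropped."""
    n_c = folds[0].train_X.shape[1]
    if n_c < 2:
        raise ValueError("leave-one-feature-out needs at least 2 features")
    full = decode_timecourse(folds, C=C, time_indices=time_indices)
    deltas = np.zeros((n_c, full.mean_auc.size))
    for c in range(n_c):
        keep = np.arange(n_c) != c
        reduced_folds = [
            PseudoPopulationFold(
                train_X=f.train_X[:, keep, :],
                train_y=f.train_y,
                test_X=f.test_X[:, keep, :],
                test_y=f.test_y,
                train_subject=f.train_subject,
                test_subject=f.test_subject,
                column_subject=f.column_subject[keep],
                times=f.times,
                normalized=f.normalized,
                train_rows=f.train_rows,
                test_rows=f.test_rows,
            )
            for f in folds
        ]
        reduced = decode_timecourse(reduced_folds, C=C, time_indices=time_indices)
        deltas[c] = full.mean_auc - reduced.mean_auc
    return FeatureWeights(deltas, full.times, decode_target, roi_label)


def weight_correlation(
    weights_a: FeatureWeights,
    weights_b: FeatureWeights,
    window: tuple[float, float],
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Pearson r between window-averaged z-scored weight maps across contacts.

    The two maps must share the contact set. p is two-sided, from permuting
    the contact assignment of one map ``n_perm`` times.
    """
    if weights_a.delta_auc.shape[0] != weights_b.delta_auc.shape[0]:
        raise ValueError("weight maps must share the contact set")
    if weights_a.delta_auc.shape[0] < 3:
        raise ValueError("need at least 3 contacts")

    def window_avg(w: FeatureWeights) -> np.ndarray:
        z = (w.delta_auc - w.delta_auc.mean()) / (w.delta_auc.std() + 1e-30)
        m = (w.times >= window[0] - 1e-12) & (w.times <= window[1] + 1e-12)
        if not m.any():
            raise ValueError("window outside the weight map's time axis")
        return z[:, m].mean(axis=1)

    a, b = window_avg(weights_a), window_avg(weights_b)
    r = float(np.corrcoef(a, b)[0, 1])
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        null[k] = np.corrcoef(a, rng.permutation(b))[0, 1]
    p = float((np.sum(np.abs(null) >= abs(r)) + 1) / (n_perm + 1))
    return r, p


@dataclass
class GeneralizationMatrix:
    auc: np.ndarray  # train time x test time, mean over folds
    train_times: np.ndarray
    test_times: np.ndarray
    train_variable: str = ""
    test_variable: str = ""


def generalization_matrix(
    folds_train: list[PseudoPopulationFold],
    folds_test: list[PseudoPopulationFold],
    window: tuple[float, float] = (0.200, 0.500),
    C: float = 1.0,
    time_stride: int = 1,
) -> GeneralizationMatrix:
    """Train on one variable's labels at time t, test on another's at t'.

    The two fold lists must describe the same rows of the same feature space
    (only the labels differ). Models are fit once per (fold, train time) and
    applied to every test time without refitting or re-tuning.
    """
    label_pairs = []
    for ftr, fte in zip(folds_train, folds_test):
        if ftr.train_rows is None or fte.train_rows is None or not np.array_equal(
            ftr.train_rows, fte.train_rows
        ) or not np.array_equal(ftr.test_rows, fte.test_rows):
            raise ValueError("train/test fold lists must share the same row sets")
        label_pairs.append((ftr, fte))
    times = folds_train[0].times
    if times is None:
        raise ValueError("folds must carry a time axis")
    m = (times >= window[0] - 1e-12) & (times <= window[1] + 1e-12)
    t_idx = np.flatnonzero(m)[::time_stride]
    n_w = t_idx.size
    acc = np.zeros((len(folds_train), n_w, n_w))
    counts = np.zeros(len(folds_train))
    for fi, (ftr, fte) in enumerate(label_pairs):
        if np.unique(fte.test_y).size < 2:
            warnings.warn(f"fold {fi} degenerate test labels; skipped")
            continue
        counts[fi] = 1
        for i, t in enumerate(t_idx):
            w = fit_l2_logistic(ftr.train_X[:, :, t], ftr.train_y, C=C)
            # scores at every test time: (n_test, n_w)
            S = np.einsum("ncw,c->nw", fte.test_X[:, :, t_idx], w[:-1]) + w[-1]
            acc[fi, i, :] = roc_auc(S.T, fte.test_y[None, :])
    good = counts > 0
    mat = acc[good].mean(axis=0) if good.any() else np.full((n_w, n_w), np.nan)
    return GeneralizationMatrix(
        auc=mat,
        train_times=times[t_idx],
        test_times=times[t_idx],
    )


def generalization_matrix_batch(
    folds_train: list[PseudoPopulationFold],
    folds_test: list[PseudoPopulationFold],
    train_label_sets: list[np.ndarray],
    test_label_sets: list[np.ndarray],
    window: tuple[float, float] = (0.200, 0.500),
    C: float = 1.0,
    time_stride: int = 1,
) -> np.ndarray:
    """Generalization matrices for a batch of (train, test) label sets.

    Returns (batch, n_window_times, n_window_times); used for 2D permutation
    nulls where the same permutation is applied to both label vectors.
    """
    times = folds_train[0].times
    m = (times >= window[0] - 1e-12) & (times <= window[1] + 1e-12)
    t_idx = np.flatnonzero(m)[::time_stride]
    n_w = t_idx.size
    Ltr = np.stack(train_label_sets)
    Lte = np.stack(test_label_sets)
    P = Ltr.shape[0]
    acc = np.full((P, len(folds_train), n_w, n_w), np.nan)
    for fi, (ftr, fte) in enumerate(zip(folds_train, folds_test)):
        Ytr = Ltr[:, ftr.train_rows]
        Yte = Lte[:, fte.test_rows]
        Xte = fte.test_X[:, :, t_idx]  # (n_test, C, n_w)
        for i, t in enumerate(t_idx):
            W = fit_l2_logistic(ftr.train_X[:, :, t], Ytr, C=C)
            S = np.einsum("pc,ncw->pwn", W[:, :-1], Xte) + W[:, -1:, None]
            acc[:, fi, i, :] = roc_auc(S, Yte[:, None, :])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(acc, axis=1)
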