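"""Cluster-permutation inference, FDR across ROIs, cluster-timing tests.

Family-wise error over timepoints is controlled with the maximum cluster
statistic: target labels are permuted (within subject, since trials cannot
move across subjects), the whole per-timepoint decoding analysis is re-run
per permutation, permuted curves are thresholded at the per-timepoint 95th
percentile θ_t, and each permutation contributes the mass of its largest
suprathreshold cluster (0 if none) to the null. An observed cluster —
a maximal contiguous run with AUC_t > θ_t, with mass Σ(AUC_t − θ_t) —
is significant at FWE < 0.05 iff its mass exceeds the 95th percentile of
that max-cluster null (C_thresh); its p-value is one minus its percentile
rank in the null over 100. The 2D variant applies the same scheme to
train x test generalization matrices with 4-connected cells.

Cluster mass uses summed suprathreshold *excess* rather than a single peak
AUC; the alternative (summed raw AUC) is available behind ``mass="sum_auc"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import mannwhitneyu, percentileofscore

from .decode import decode_timecourse_batch, generalization_matrix_batch
from .feature_prep import PseudoPopulationFold


@dataclass
class NullDistribution:
    null_curves: np.ndarray  # permutations x timepoints (mean CV AUC)
    theta: np.ndarray  # per-timepoint cluster-forming threshold
    percentile: float = 95.0


@dataclass
class ClusterResult:
    span: tuple[float, float]
    timepoints: np.ndarray  # indices into the curve
    times: np.ndarray
    mass: float  # C_AUC
    c_thresh: float
    p: float
    significant: bool
    peak_time: float
    peak_auc: float
    q: float | None = None
    peak_ci: tuple[float, float] | None = None


def _pooled_labels_and_subjects(
    folds: list[PseudoPopulationFold],
) -> tuple[np.ndarray, np.ndarray]:
    f = folds[0]
    n_rows = f.train_rows.size + f.test_rows.size
    y = np.empty(n_rows)
    subj = np.empty(n_rows, dtype=int)
    y[f.train_rows] = f.train_y
    y[f.test_rows] = f.test_y
    subj[f.train_rows] = f.train_subject
    subj[f.test_rows] = f.test_subject
    return y, subj


def permute_within_subject(
    y: np.ndarray, subjects: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    out = y.copy()
    for s in np.unique(subjects):
        idx = np.flatnonzero(subjects == s)
        out[idx] = y[idx[rng.permutation(idx.size)]]
    return out


def permutation_null(
    folds: list[PseudoPopulationFold],
    n_perm: int = 1000,
    seed: int = 0,
    C: float = 1.0,
    time_indices: np.ndarray | None = None,
    percentile: float = 95.0,
) -> NullDistribution:
    """Label-permutation null of the mean-CV-AUC curve.

    Each permutation shuffles the pooled target labels within subject
    (preserving the fold structure) and re-runs the per-timepoint decoding.
    θ_t is the per-timepoint ``percentile`` of the permuted curves.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20 for a meaningful 95th percentile")
    rng = np.random.default_rng(seed)
    y, subj = _pooled_labels_and_subjects(folds)
    label_sets = [permute_within_subject(y, subj, rng) for _ in range(n_perm)]
    curves = decode_timecourse_batch(folds, label_sets, C=C, time_indices=time_indices)
    theta = np.nanpercentile(curves, percentile, axis=0)
    return NullDistribution(curves, theta, percentile)


def find_clusters(
    curve: np.ndarray, theta: np.ndarray, mass: str = "excess"
) -> list[tuple[np.ndarray, float]]:
    """Maximal contiguous runs with curve > theta and their cluster mass."""
    curve = np.asarray(curve, dtype=float)
    theta = np.broadcast_to(np.asarray(theta, dtype=float), curve.shape)
    above = curve > theta
    labels, n = ndimage.label(above)
    out = []
    for k in range(1, n + 1):
        idx = np.flatnonzero(labels == k)
        m = float(
            np.sum(curve[idx] - theta[idx]) if mass == "excess" else np.sum(curve[idx])
        )
        out.append((idx, m))
    return out


def max_cluster_null(
    null: NullDistribution, mass: str = "excess"
) -> np.ndarray:
    """Largest suprathreshold cluster mass of each permuted curve (0 if none)."""
    stats = np.zeros(null.null_curves.shape[0])
    for i, curve in enumerate(null.null_curves):
        clusters = find_clusters(curve, null.theta, mass=mass)
        if clusters:
            stats[i] = max(m for _, m in clusters)
    return stats


def cluster_significance(
    curve: np.ndarray,
    times: np.ndarray,
    null: NullDistribution,
    mass: str = "excess",
) -> list[ClusterResult]:
    """Observed clusters against the max-cluster null, FWE < 0.05."""
    null_stats = max_cluster_null(null, mass=mass)
    c_thresh = float(np.percentile(null_stats, 95))
    results = []
    for idx, m in find_clusters(curve, null.theta, mass=mass):
        p = 1.0 - percentileofscore(null_stats, m, kind="strict") / 100.0
        peak_local = idx[np.argmax(curve[idx])]
        results.append(
            ClusterResult(
                span=(float(times[idx[0]]), float(times[idx[-1]])),
                timepoints=idx,
                times=times[idx],
                mass=m,
                c_thresh=c_thresh,
                p=float(p),
                significant=bool(m > c_thresh),
                peak_time=float(times[peak_local]),
                peak_auc=float(curve[peak_local]),
            )
        )
    return results


def fdr_across_rois(p_values: dict[str, float], n_rois: int = 11) -> dict[str, float]:
    """Benjamini-Hochberg step-up with the family size fixed at ``n_rois``.

    ROIs tested but absent from ``p_values`` count toward the family size
    (the exploratory set), matching correction against the full ROI set.
    """
    items = list(p_values.items())
    p = np.array([v for _, v in items], dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = max(n_rois, p.size)
    order = np.argsort(p)
    q_sorted = p[order] * m / (np.arange(p.size) + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return {roi: float(qv) for (roi, _), qv in zip(items, q)}


def compare_cluster_timing(
    cluster_a: np.ndarray, cluster_b: np.ndarray
) -> tuple[float, float]:
    """Mann-Whitney U comparing the timepoint sets of two clusters.

    U counts pairs where the *later* cluster's timepoint exceeds the
    earlier's (later = greater mean latency), plus half of tied pairs, so
    complete separation gives U = n1·n2. p is from the two-sided normal
    approximation with continuity and tie correction.
    """
    a = np.asarray(cluster_a, dtype=float)
    b = np.asarray(cluster_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("clusters must be non-empty")
    if a.size == 1 and b.size == 1 and a[0] == b[0]:
        raise ValueError("identical singleton clusters: p undefined")
    later, earlier = (b, a) if b.mean() >= a.mean() else (a, b)
    res = mannwhitneyu(later, earlier, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


@dataclass
class Cluster2D:
    cells: np.ndarray  # boolean mask over (train time, test time)
    mass: float
    c_thresh: float
    p: float
    significant: bool
    train_extent: tuple[float, float]
    test_extent: tuple[float, float]


def _clusters_2d(mat: np.ndarray, theta: np.ndarray) -> list[tuple[np.ndarray, float]]:
    above = mat > theta
    labels, n = ndimage.label(above, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    out = []
    for k in range(1, n + 1):
        mask = labels == k
        out.append((mask, float(np.sum(mat[mask] - theta[mask]))))
    return out


def cluster_2d(
    matrix: np.ndarray,
    null_matrices: np.ndarray,
    train_times: np.ndarray,
    test_times: np.ndarray,
    percentiles: tuple[float, ...] = (95.0, 99.0),
) -> dict[float, list[Cluster2D]]:
    """2D max-cluster inference on a generalization matrix.

    ``null_matrices``: (permutations, n, n) from the same permutation scheme.
    Suprathreshold cells (matrix > per-cell percentile of the null) are
    grouped by 4-connectivity; inference mirrors the 1D case at each
    cluster-forming percentile, keeping FWE < 0.05.
    """
    out: dict[float, list[Cluster2D]] = {}
    for pct in percentiles:
        theta = np.nanpercentile(null_matrices, pct, axis=0)
        null_stats = np.zeros(null_matrices.shape[0])
        for i, nm in enumerate(null_matrices):
            cl = _clusters_2d(nm, theta)
            if cl:
                null_stats[i] = max(m for _, m in cl)
        c_thresh = float(np.percentile(null_stats, 95))
        results = []
        for mask, m in _clusters_2d(matrix, theta):
            p = 1.0 - percentileofscore(null_stats, m, kind="strict") / 100.0
            tr_idx, te_idx = np.nonzero(mask)
            results.append(
                Cluster2D(
                    cells=mask,
                    mass=m,
                    c_thresh=c_thresh,
                    p=float(p),
                    significant=bool(m > c_thresh),
                    train_extent=(float(train_times[tr_idx.min()]), float(train_times[tr_idx.max()])),
                    test_extent=(float(test_times[te_idx.min()]), float(test_times[te_idx.max()])),
                )
            )
        out[pct] = results
    return out


def permutation_null_2d(
    folds_train: list[PseudoPopulationFold],
    folds_test: list[PseudoPopulationFold],
    n_perm: int = 200,
    seed: int = 0,
    C: float = 1.0,
    window: tuple[float, float] = (0.200, 0.500),
    time_stride: int = 1,
) -> np.ndarray:
    """Null generalization matrices: permute both label vectors jointly.

    Each permutation draws one within-subject reordering of the rows and
    applies it to the train-variable and test-variable labels alike,
    preserving their mutual dependence under the null of no neural code.
    """
    rng = np.random.default_rng(seed)
    y_tr, subj = _pooled_labels_and_subjects(folds_train)
    y_te, _ = _pooled_labels_and_subjects(folds_test)
    tr_sets, te_sets = [], []
    for _ in range(n_perm):
        perm = np.arange(y_tr.size)
        for s in np.unique(subj):
            idx = np.flatnonzero(subj == s)
            perm[idx] = idx[rng.permutation(idx.size)]
        tr_sets.append(y_tr[perm])
        te_sets.append(y_te[perm])
    return generalization_matrix_batch(
        folds_train, folds_test, tr_sets, te_sets, window=window, C=C,
        time_stride=time_stride,
    )
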