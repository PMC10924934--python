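"""Decoding-ready inputs: confounds, residualization, folds, pseudo-population.

Each contact's epoch series is first residualized, within subject, against a
confound design holding every model variable *except* the one to be decoded
(plus event indicators and per-trial report accuracy). Two orthogonalization
steps are applied before the design is assembled: RePE is orthogonalized to
the outcome (they are strongly collinear), and RiPE_card2 to the observed
risk O.Risk. The card-1 risk prediction error is perfectly collinear with
O.Risk at card 1 and vanishes under this orthogonalization, so it never
enters the analysis.

The pooled "pseudo-population" treats contacts recorded in different
subjects as one simultaneous population: each subject's trials are split
into cross-validation folds first, then fold-wise train/test blocks are
concatenated across subjects. The pooled feature matrix is block-structured
— a row (trial epoch from subject s) is nonzero only in subject s's
contact columns; off-block entries are exactly 0, i.e. "at the mean" after
per-block normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import EpochTensor

DECODABLE = ("EV", "OUT", "RePE", "ERisk_card2", "RiPE_card2")

# event alignment of each parametric regressor
REGRESSOR_EVENT = {
    "EV": "CARD1_ON",
    "ERisk_card2": "CARD1_OFF",
    "OUT": "CARD2_ON",
    "RePE": "CARD2_ON",
    "RiPE_card2": "CARD2_ON",
    "ORisk": "CARD2_ON",
    "report_accuracy": "REPORT",
}

# a priori decoding event per variable
EVENT_OF_VARIABLE = {
    "EV": "CARD1_ON",
    "ERisk_card2": "CARD1_OFF",
    "OUT": "CARD2_ON",
    "RePE": "CARD2_ON",
    "RiPE_card2": "CARD2_ON",
}

_FRAME_COLUMN = {
    "EV": "ev",
    "OUT": "outcome",
    "RePE": "repe",
    "ERisk_card2": "erisk_card2",
    "RiPE_card2": "ripe_card2",
    "ORisk": "orisk",
}


def orthogonalize(target: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Residual of OLS regression of ``target`` on [1, reference]."""
    target = np.asarray(target, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if target.shape != reference.shape or target.size < 2:
        raise ValueError("target and reference must be equal-length vectors (n >= 2)")
    if np.ptp(reference) == 0:
        return target - target.mean()
    design = np.column_stack([np.ones_like(reference), reference])
    beta, *_ = np.linalg.lstsq(design, target, rcond=None)
    return target - design @ beta


@dataclass
class ConfoundDesign:
    """Epochs x covariates matrix aligned to an epoch ordering."""

    matrix: np.ndarray
    columns: list[str]
    epoch_events: np.ndarray
    epoch_trials: np.ndarray


def trial_variable(trials_frame: pd.DataFrame, name: str) -> np.ndarray:
    """Per-trial values of a decodable variable, orthogonalized where defined.

    RePE is returned orthogonalized to OUT and RiPE_card2 to ORisk (the two
    collinearity-breaking steps); other variables are returned raw.
    """
    if name == "RePE":
        return orthogonalize(
            trials_frame["repe"].to_numpy(float), trials_frame["outcome"].to_numpy(float)
        )
    if name == "RiPE_card2":
        return orthogonalize(
            trials_frame["ripe_card2"].to_numpy(float), trials_frame["orisk"].to_numpy(float)
        )
    return trials_frame[_FRAME_COLUMN[name]].to_numpy(float)


def build_confound_design(
    trials_frame: pd.DataFrame,
    epoch_events: np.ndarray,
    epoch_trials: np.ndarray,
    decode_target: str | tuple[str, ...],
) -> ConfoundDesign:
    """Everything except the decoded variable, aligned to its trial event.

    ``trials_frame`` is the per-trial table (one row per trial) from
    :func:`riskdecode.task_model.trials_to_frame`; rows of the design follow
    the epoch ordering given by (epoch_events, epoch_trials).
    ``decode_target`` may name several variables (e.g. for cross-variable
    generalization, where neither the train nor the test variable may be
    regressed out of the features).
    """
    targets = (decode_target,) if isinstance(decode_target, str) else tuple(decode_target)
    for t in targets:
        if t not in DECODABLE:
            raise ValueError(f"unknown decode target {t!r}")
    n = len(epoch_events)
    trials_idx = np.asarray(epoch_trials, dtype=int)
    cols: dict[str, np.ndarray] = {"intercept": np.ones(n)}
    for ev in ("CARD1_ON", "CARD1_OFF", "CARD2_ON"):
        cols[f"ind_{ev}"] = (epoch_events == ev).astype(float)

    per_trial: dict[str, np.ndarray] = {
        name: trial_variable(trials_frame, name) for name in DECODABLE
    }
    per_trial["ORisk"] = trials_frame["orisk"].to_numpy(float)
    per_trial["report_accuracy"] = trials_frame["report_correct"].to_numpy(float)

    for name, values in per_trial.items():
        if name in targets:
            continue
        ev = REGRESSOR_EVENT[name]
        mask = epoch_events == ev
        col = np.zeros(n)
        v = values[trials_idx[mask]]
        col[mask] = v - v.mean() if mask.any() else 0.0
        cols[name] = col

    matrix = np.column_stack(list(cols.values()))
    return ConfoundDesign(matrix, list(cols.keys()), np.asarray(epoch_events), trials_idx)


def residualize_features(epochs: EpochTensor, design: ConfoundDesign) -> EpochTensor:
    """Replace each (contact, timepoint) epoch-series by its OLS residual.

    Applied per subject, before any cross-subject pooling. The intercept in
    the design removes subject-mean activity. A shared, time-invariant design
    is used at every timepoint.
    """
    if design.matrix.shape[0] != epochs.data.shape[0]:
        raise ValueError("design rows must align with epochs")
    d = design.matrix
    rank = np.linalg.matrix_rank(d)
    if rank < d.shape[1]:
        warnings.warn("rank-deficient confound design; dependent columns dropped (pinv)")
    n_e, n_c, n_t = epochs.data.shape
    flat = epochs.data.reshape(n_e, n_c * n_t)
    resid = flat - d @ (np.linalg.pinv(d) @ flat)
    return EpochTensor(
        data=resid.reshape(n_e, n_c, n_t),
        times=epochs.times,
        event_types=epochs.event_types,
        trial_index=epochs.trial_index,
        channels=epochs.channels,
    )


def binarize_target(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split around the mean into {+1, −1}; exact zeros are masked out."""
    values = np.asarray(values, dtype=float)
    centered = values - values.mean()
    keep = np.abs(centered) > 1e-12
    labels = np.where(centered > 0, 1.0, -1.0)
    labels[~keep] = 0.0
    if np.unique(labels[keep]).size < 2:
        raise ValueError("fewer than 2 classes after binarization")
    return labels, keep


@dataclass
class PseudoPopulationFold:
    """One CV fold of the pooled (epochs x contacts x timepoints) design."""

    train_X: np.ndarray
    train_y: np.ndarray  # +1/-1
    test_X: np.ndarray
    test_y: np.ndarray
    train_subject: np.ndarray  # per-row subject index
    test_subject: np.ndarray
    column_subject: np.ndarray  # owning subject index per pooled column
    times: np.ndarray | None = None
    normalized: bool = False
    # bookkeeping for permutation tests: position of each row in the pooled order
    train_rows: np.ndarray | None = None
    test_rows: np.ndarray | None = None


def assemble_pseudo_population(
    subject_data: dict[str, tuple[np.ndarray, np.ndarray]],
    n_folds: int = 10,
    seed: int = 0,
    times: np.ndarray | None = None,
) -> list[PseudoPopulationFold]:
    """Split within subject, then concatenate across subjects per fold.

    ``subject_data`` maps subject id to ``(X, y)`` with X of shape
    (epochs, contacts, timepoints) and y the raw target values for those
    epochs. Binarization (with exact-zero masking) happens here, per subject
    over the pooled target; folds are stratified so each subject contributes
    an equal share of each class to every fold. Subjects with fewer usable
    epochs than folds are excluded with a warning.
    """
    rng = np.random.default_rng(seed)
    order = list(subject_data.keys())
    kept: list[str] = []
    per_subject: dict[str, dict] = {}
    all_y = np.concatenate([np.asarray(subject_data[s][1], float) for s in order])
    grand_mean = all_y.mean()
    for s in order:
        X, y = subject_data[s]
        y = np.asarray(y, dtype=float)
        centered = y - grand_mean
        keep = np.abs(centered) > 1e-12
        if keep.sum() < n_folds:
            warnings.warn(f"subject {s} has too few usable epochs; excluded")
            continue
        labels = np.where(centered > 0, 1.0, -1.0)
        per_subject[s] = {"X": np.asarray(X, float)[keep], "y": labels[keep]}
        kept.append(s)
    if not kept:
        raise ValueError("no subject has enough usable epochs")

    n_contacts = {s: per_subject[s]["X"].shape[1] for s in kept}
    total_c = sum(n_contacts.values())
    col_subject = np.concatenate(
        [np.full(n_contacts[s], si) for si, s in enumerate(kept)]
    )
    col_start = dict(zip(kept, np.cumsum([0] + [n_contacts[s] for s in kept[:-1]])))

    # stratified within-subject fold assignment
    fold_of: dict[str, np.ndarray] = {}
    for s in kept:
        y = per_subject[s]["y"]
        assign = np.empty(y.size, dtype=int)
        for cls in (1.0, -1.0):
            idx = np.flatnonzero(y == cls)
            rng.shuffle(idx)
            assign[idx] = np.arange(idx.size) % n_folds
        fold_of[s] = assign

    n_t = next(iter(per_subject.values()))["X"].shape[2]
    folds: list[PseudoPopulationFold] = []
    for f in range(n_folds):
        tr_X, tr_y, tr_s, te_X, te_y, te_s = [], [], [], [], [], []
        tr_rows, te_rows = [], []
        row0 = 0
        for si, s in enumerate(kept):
            X, y = per_subject[s]["X"], per_subject[s]["y"]
            c0 = col_start[s]
            block = np.zeros((X.shape[0], total_c, n_t))
            block[:, c0 : c0 + n_contacts[s], :] = X
            test_m = fold_of[s] == f
            tr_X.append(block[~test_m])
            te_X.append(block[test_m])
            tr_y.append(y[~test_m])
            te_y.append(y[test_m])
            tr_s.append(np.full((~test_m).sum(), si))
            te_s.append(np.full(test_m.sum(), si))
            rows = row0 + np.arange(X.shape[0])
            tr_rows.append(rows[~test_m])
            te_rows.append(rows[test_m])
            row0 += X.shape[0]
        folds.append(
            PseudoPopulationFold(
                train_X=np.concatenate(tr_X),
                train_y=np.concatenate(tr_y),
                test_X=np.concatenate(te_X),
                test_y=np.concatenate(te_y),
                train_subject=np.concatenate(tr_s),
                test_subject=np.concatenate(te_s),
                column_subject=col_subject,
                times=times,
                train_rows=np.concatenate(tr_rows),
                test_rows=np.concatenate(te_rows),
            )
        )
    return folds


def normalize_fold(fold: PseudoPopulationFold) -> PseudoPopulationFold:
    """Center/scale each (column, timepoint) using that subject-block's
    *training* rows only; apply to both train and test. Off-block zeros stay
    zero. Zero-variance features are scaled to 0 with a warning."""
    train_X = fold.train_X.copy()
    test_X = fold.test_X.copy()
    warned = False
    for si in np.unique(fold.column_subject):
        cols = fold.column_subject == si
        tr_rows = fold.train_subject == si
        te_rows = fold.test_subject == si
        block = train_X[np.ix_(tr_rows, cols)]
        mu = block.mean(axis=0)
        sd = block.std(axis=0)
        zero = sd == 0
        if zero.any() and not warned:
            warnings.warn("zero-variance feature(s) scaled to 0")
            warned = True
        sd_safe = np.where(zero, 1.0, sd)
        train_X[np.ix_(tr_rows, cols)] = np.where(zero, 0.0, (block - mu) / sd_safe)
        if te_rows.any():
            tb = test_X[np.ix_(te_rows, cols)]
            test_X[np.ix_(te_rows, cols)] = np.where(zero, 0.0, (tb - mu) / sd_safe)
    return PseudoPopulationFold(
        train_X=train_X,
        train_y=fold.train_y,
        test_X=test_X,
        test_y=fold.test_y,
        train_subject=fold.train_subject,
        test_subject=fold.test_subject,
        column_subject=fold.column_subject,
        times=fold.times,
        normalized=True,
        train_rows=fold.train_rows,
        test_rows=fold.test_rows,
    )
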