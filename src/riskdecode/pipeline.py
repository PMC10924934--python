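"""End-to-end experiment runner: simulate → preprocess → decode → infer.

A run is a pure function of its :class:`RunConfig`: the synthetic cohort,
every fold split, every permutation and every bootstrap derive from the
config seed, so two runs of the same config produce identical reports.

The ``test`` profile scales the permutation/bootstrap counts (200/100
instead of the full 1000/500) and optionally strides the decoding time grid;
it exists for desk-scale reruns of the whole pipeline and changes nothing
about the procedure itself.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import feature_prep, preprocess, stats, synthetic_data, task_model
from .decode import DecodingCurve, decode_timecourse, generalization_matrix
from .feature_prep import EVENT_OF_VARIABLE, PseudoPopulationFold
from .preprocess import EpochTensor
from .synthetic_data import CohortConfig, GroundTruth, SessionRecording


@dataclass
class DecodeSpec:
    variable: str
    roi: str


@dataclass
class RunConfig:
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    analyses: list[DecodeSpec] = field(default_factory=list)
    kl_global: float = preprocess.DEFAULT_KL_GLOBAL
    kl_electrode: float = preprocess.DEFAULT_KL_PER_ELECTRODE
    n_folds: int = 10
    n_perm: int = 1000
    n_boot: int = 500
    C: float = 1.0
    time_stride: int = 1
    profile: str = "full"  # "full" | "test"
    output_dir: str | None = None

    def effective_counts(self) -> tuple[int, int]:
        if self.profile == "test":
            return min(self.n_perm, 200), min(self.n_boot, 100)
        return self.n_perm, self.n_boot


@dataclass
class SubjectBundle:
    """One session's epochs plus its trial table, ready to residualize."""

    epochs: EpochTensor
    trials_frame: pd.DataFrame


def preprocess_cohort(
    sessions: list[SessionRecording],
    kl_global: float = preprocess.DEFAULT_KL_GLOBAL,
    kl_electrode: float = preprocess.DEFAULT_KL_PER_ELECTRODE,
    seed: int = 0,
    run_ica: bool = True,
) -> dict[str, list[SubjectBundle]]:
    """Run the signal chain on every session, grouped by subject."""
    out: dict[str, list[SubjectBundle]] = {}
    for rec in sessions:
        ep = preprocess.preprocess_session(
            rec, kl_global=kl_global, kl_electrode=kl_electrode, seed=seed, run_ica=run_ica
        )
        out.setdefault(rec.subject_id, []).append(
            SubjectBundle(ep, task_model.trials_to_frame(rec.trials))
        )
    return out


def build_subject_data(
    bundles: dict[str, list[SubjectBundle]],
    variable: str,
    roi: str,
    exclude: tuple[str, ...] | None = None,
    time_stride: int = 1,
) -> tuple[dict[str, tuple[np.ndarray, np.ndarray]], np.ndarray]:
    """Residualized, event-restricted ROI features per subject.

    Residualization runs per session (each session gets its own confound
    design); sessions are then concatenated within subject. Returns
    ``{subject: (trials x roi-channels x timepoints, target values)}`` and
    the decoding time axis (0..0.5 s, optionally strided).
    """
    exclude_set = (variable,) if exclude is None else tuple(exclude)
    event = EVENT_OF_VARIABLE[variable]
    subject_data: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    times_out: np.ndarray | None = None
    for subject, sess_list in bundles.items():
        xs, ys = [], []
        for bundle in sess_list:
            ep, frame = bundle.epochs, bundle.trials_frame
            design = feature_prep.build_confound_design(
                frame, ep.event_types, ep.trial_index, exclude_set
            )
            resid = feature_prep.residualize_features(ep, design)
            sel = resid.select_event(event)
            order = np.argsort(sel.trial_index)
            roi_mask = (sel.channels["roi_label"] == roi).to_numpy()
            if not roi_mask.any():
                xs = []
                break
            tmask = np.flatnonzero(sel.decoding_mask)[::time_stride]
            xs.append(sel.data[order][:, roi_mask][:, :, tmask])
            ys.append(feature_prep.trial_variable(frame, variable)[sel.trial_index[order]])
            if times_out is None:
                times_out = sel.times[tmask]
        if xs:
            subject_data[subject] = (np.concatenate(xs), np.concatenate(ys))
    if not subject_data:
        raise ValueError(f"no subject has contacts in ROI {roi!r}")
    return subject_data, times_out


def make_folds(
    subject_data: dict[str, tuple[np.ndarray, np.ndarray]],
    times: np.ndarray,
    n_folds: int,
    seed: int,
) -> list[PseudoPopulationFold]:
    folds = feature_prep.assemble_pseudo_population(
        subject_data, n_folds=n_folds, seed=seed, times=times
    )
    return [feature_prep.normalize_fold(f) for f in folds]


def relabel_folds(
    folds: list[PseudoPopulationFold], pooled_values: np.ndarray
) -> list[PseudoPopulationFold]:
    """Same rows, features and splits; labels binarized from another variable.

    Used for cross-variable generalization, where the train- and
    test-variable fold lists must partition identical rows. Exact zeros after
    mean-centering are not supported here (they would change the row set).
    """
    n_rows = folds[0].train_rows.size + folds[0].test_rows.size
    if pooled_values.size != n_rows:
        raise ValueError(
            "pooled value count does not match the folds' row set "
            "(rows were dropped during binarization of the original target)"
        )
    centered = pooled_values - pooled_values.mean()
    if not np.all(np.abs(centered) > 1e-12):
        raise ValueError("relabeling with exact-zero values would change the row set")
    labels = np.where(centered > 0, 1.0, -1.0)
    return [
        dataclasses.replace(
            f, train_y=labels[f.train_rows], test_y=labels[f.test_rows]
        )
        for f in folds
    ]


@dataclass
class GeneralizationResult:
    train_variable: str
    test_variable: str
    roi: str
    matrix: "np.ndarray"
    train_times: np.ndarray
    test_times: np.ndarray
    clusters: dict  # percentile -> list of stats.Cluster2D


def run_generalization_analysis(
    bundles: dict[str, list[SubjectBundle]],
    train_variable: str,
    test_variable: str,
    roi: str,
    window: tuple[float, float] = (0.200, 0.500),
    n_folds: int = 10,
    n_perm: int = 200,
    seed: int = 0,
    C: float = 1.0,
    time_stride: int = 1,
) -> GeneralizationResult:
    """Train on one variable, test on another, over a time x time grid.

    Features are residualized against a design excluding *both* variables
    (neither may be regressed out), then one fold split is built from the
    train variable's labels and relabeled with the test variable's.
    """
    exclude = (train_variable, test_variable)
    sd_train, times = build_subject_data(bundles, train_variable, roi, exclude=exclude)
    sd_test, _ = build_subject_data(bundles, test_variable, roi, exclude=exclude)
    folds_train = make_folds(sd_train, times, n_folds, seed)
    pooled_test = np.concatenate([sd_test[s][1] for s in sd_train.keys()])
    folds_test = relabel_folds(folds_train, pooled_test)
    mat = generalization_matrix(
        folds_train, folds_test, window=window, C=C, time_stride=time_stride
    )
    null = stats.permutation_null_2d(
        folds_train, folds_test, n_perm=n_perm, seed=seed + 1, C=C,
        window=window, time_stride=time_stride,
    )
    clusters = stats.cluster_2d(mat.auc, null, mat.train_times, mat.test_times)
    return GeneralizationResult(
        train_variable, test_variable, roi, mat.auc, mat.train_times, mat.test_times, clusters
    )


@dataclass
class AnalysisResult:
    variable: str
    roi: str
    curve: DecodingCurve
    clusters: list[stats.ClusterResult]
    theta: np.ndarray

    def significant(self) -> list[stats.ClusterResult]:
        return [c for c in self.clusters if c.significant]


def run_decode_analysis(
    bundles: dict[str, list[SubjectBundle]],
    variable: str,
    roi: str,
    n_folds: int = 10,
    n_perm: int = 200,
    seed: int = 0,
    C: float = 1.0,
    time_stride: int = 1,
) -> AnalysisResult:
    """Decoding curve + cluster-permutation inference for one (ROI, variable)."""
    subject_data, times = build_subject_data(
        bundles, variable, roi, time_stride=time_stride
    )
    folds = make_folds(subject_data, times, n_folds, seed)
    curve = decode_timecourse(folds, C=C, decode_target=variable, roi_label=roi)
    null = stats.permutation_null(folds, n_perm=n_perm, seed=seed + 1, C=C)
    clusters = stats.cluster_significance(curve.mean_auc, curve.times, null)
    return AnalysisResult(variable, roi, curve, clusters, null.theta)


def run_experiment(config: RunConfig) -> dict:
    """Execute every configured (ROI, variable) analysis; return the report."""
    t0 = time.time()
    n_perm, n_boot = config.effective_counts()
    sessions, ground_truth = synthetic_data.generate_cohort(config.cohort, config.seed)
    bundles = preprocess_cohort(
        sessions, config.kl_global, config.kl_electrode, seed=config.seed
    )
    results: list[AnalysisResult] = []
    for spec in config.analyses:
        results.append(
            run_decode_analysis(
                bundles,
                spec.variable,
                spec.roi,
                n_folds=config.n_folds,
                n_perm=n_perm,
                seed=config.seed,
                C=config.C,
                time_stride=config.time_stride,
            )
        )
    report = {
        "seed": config.seed,
        "profile": config.profile,
        "n_perm": n_perm,
        "n_boot": n_boot,
        "elapsed_s": round(time.time() - t0, 2),
        "analyses": [
            {
                "variable": r.variable,
                "roi": r.roi,
                "peak_auc": float(np.nanmax(r.curve.mean_auc)),
                "clusters": [
                    {
                        "span": list(c.span),
                        "mass": c.mass,
                        "c_thresh": c.c_thresh,
                        "p": c.p,
                        "significant": c.significant,
                        "peak_time": c.peak_time,
                        "peak_auc": c.peak_auc,
                    }
                    for c in r.clusters
                ],
            }
            for r in results
        ],
    }
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "summary.json").write_text(json.dumps(report, indent=1))
        rows = []
        for r in results:
            for ti, t in enumerate(r.curve.times):
                rows.append(
                    {
                        "roi": r.roi,
                        "variable": r.variable,
                        "time": t,
                        "mean_auc": r.curve.mean_auc[ti],
                        **{
                            f"fold{fi}": r.curve.fold_aucs[fi, ti]
                            for fi in range(r.curve.fold_aucs.shape[0])
                        },
                    }
                )
        pd.DataFrame(rows).to_csv(out / "curves.csv", index=False)
    report["_results"] = results
    report["_ground_truth"] = ground_truth
    report["_bundles"] = bundles
    return report


_UNIQUE_ALIAS = {"RePE_unique": "RePE", "RiPE_unique": "RiPE_card2"}


def make_recovery_suite(report: dict, ground_truth: GroundTruth | None = None) -> dict:
    """Compare significant clusters against the planted encodings.

    A planted (variable, ROI, latency) counts as recovered when some
    significant cluster for that analysis overlaps the encoding kernel's
    support. Returns per-encoding verdicts and an overall flag.
    """
    gt = ground_truth if ground_truth is not None else report.get("_ground_truth")
    if gt is None:
        raise ValueError("ground truth required for recovery checking")
    results: list[AnalysisResult] = report["_results"]
    verdicts = {}
    for enc in gt.encodings:
        var = _UNIQUE_ALIAS.get(enc.variable, enc.variable)
        if var not in EVENT_OF_VARIABLE:
            continue
        lo = enc.latency_center - enc.kernel_width / 2
        hi = enc.latency_center + enc.kernel_width / 2
        matching = [r for r in results if r.variable == var and r.roi == enc.roi_label]
        hit = any(
            c.span[1] >= lo and c.span[0] <= hi
            for r in matching
            for c in r.significant()
        )
        verdicts[f"{var}@{enc.roi_label}:{enc.latency_center:.3f}s"] = {
            "recovered": bool(hit) if matching else None,
            "analyzed": bool(matching),
        }
    analyzed = {k: v for k, v in verdicts.items() if v["analyzed"]}
    return {
        "encodings": verdicts,
        "all_recovered": all(v["recovered"] for v in analyzed.values()) if analyzed else False,
    }
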