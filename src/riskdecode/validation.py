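"""Calibration and parameter-recovery studies for the pipeline.

Two standing questions a decoding pipeline must answer before its output can
be trusted:

* **Error control** — on data that carry no information about the labels,
  how often does the cluster-permutation procedure declare at least one
  significant cluster? :func:`fwer_study` measures this family-wise error
  rate empirically on signal-free synthetic datasets; it should not exceed
  the nominal 5% beyond binomial noise.
* **Sensitivity** — when a known code is planted at a known (ROI, latency),
  does the full chain (raw synthesis → filtering → ICA → bipolar →
  residualization → pseudo-population decoding → cluster inference) recover
  it, and only it? :func:`run_recovery_study` plants each decodable
  variable at a chosen site, an outcome cascade across four regions at
  staggered latencies, one shared-pattern (coupled) reward→risk error code
  and one pair of independent codes on disjoint contacts, then runs every
  corresponding analysis.

Problem sizes here are desk-scale (4 subjects, 60 trials, 200 permutations,
a 10 ms decoding grid) — chosen so the whole battery runs on one CPU in
minutes while leaving every stage of the procedure identical to a
full-scale run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import feature_prep, pipeline, stats, synthetic_data
from .decode import decode_timecourse, lofo_weights, weight_correlation
from .synthetic_data import CohortConfig, EncodingSpec
from .task_model import simulate_trials


# ---------------------------------------------------------------------------
# Error control
# ---------------------------------------------------------------------------

def decode_and_cluster_null_dataset(
    n_subjects: int,
    n_contacts: int,
    n_trials: int,
    n_timepoints: int,
    n_folds: int,
    n_perm: int,
    data_seed: int,
    perm_seed: int,
) -> list[stats.ClusterResult]:
    """Full decoding + cluster inference on one signal-free dataset."""
    data = synthetic_data.generate_null_dataset(
        n_subjects, n_contacts, n_trials, n_timepoints, seed=data_seed
    )
    times = np.arange(n_timepoints) * 0.02
    folds = feature_prep.assemble_pseudo_population(
        data, n_folds=n_folds, seed=data_seed, times=times
    )
    folds = [feature_prep.normalize_fold(f) for f in folds]
    curve = decode_timecourse(folds)
    null = stats.permutation_null(folds, n_perm=n_perm, seed=perm_seed)
    return stats.cluster_significance(curve.mean_auc, curve.times, null)


def fwer_study(
    n_datasets: int = 200,
    n_subjects: int = 4,
    n_contacts: int = 20,
    n_trials: int = 60,
    n_perm: int = 200,
    n_timepoints: int = 26,
    n_folds: int = 5,
    seed: int = 0,
) -> dict:
    """Fraction of signal-free datasets with any FWE-significant cluster."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=(n_datasets, 2))
    hits = 0
    for d in range(n_datasets):
        clusters = decode_and_cluster_null_dataset(
            n_subjects, n_contacts, n_trials, n_timepoints, n_folds, n_perm,
            data_seed=int(seeds[d, 0]), perm_seed=int(seeds[d, 1]),
        )
        hits += any(c.significant for c in clusters)
    return {
        "fraction": hits / n_datasets,
        "hits": hits,
        "n_datasets": n_datasets,
        "nominal": 0.05,
        "binomial_se": float(np.sqrt(0.05 * 0.95 / n_datasets)),
    }


def random_reporter_accuracy(n_trials: int = 10000, seed: int = 0) -> dict:
    """Report accuracy of an agent reporting win/loss uniformly at random."""
    rng = np.random.default_rng(seed)
    trials = simulate_trials(n_trials, rng)
    reported_win = rng.random(n_trials) < 0.5
    correct = reported_win == np.array([t.outcome == 1 for t, _ in trials])
    return {
        "accuracy": float(correct.mean()),
        "n_trials": n_trials,
        "binomial_se": float(np.sqrt(0.25 / n_trials)),
    }


# ---------------------------------------------------------------------------
# Parameter recovery
# ---------------------------------------------------------------------------

# The recovery battery runs on two separate cohorts. The ICA denoising
# stage removes estimated global components whose sources carry small
# projections of *every* strong event-locked code in the cohort, spreading
# each code faintly across contacts; a cohort dense with strong codes
# therefore couples sites that were planted independently. The code-sharing
# simulations, whose whole point is (in)dependence between two codes, get
# their own cohort away from the multi-site cascade.

CASCADE_ROIS = {
    "vmPFC": 5,
    "AngularGyrus": 5,
    "Hippocampus": 5,
    "Amygdala": 5,
    "FrontalPole": 5,
}

# each decodable variable planted once at a known site/latency; the outcome
# cascade sweeps posterior -> anterior
CASCADE_ENCODINGS = [
    EncodingSpec("EV", "vmPFC", "CARD1_ON", 0.07),
    EncodingSpec("ERisk_card2", "FrontalPole", "CARD1_OFF", 0.20),
    EncodingSpec("OUT", "AngularGyrus", "CARD2_ON", 0.03),
    EncodingSpec("OUT", "Hippocampus", "CARD2_ON", 0.11),
    EncodingSpec("OUT", "Amygdala", "CARD2_ON", 0.21),
    EncodingSpec("OUT", "vmPFC", "CARD2_ON", 0.25),
]

CASCADE_ANALYSES = [
    ("EV", "vmPFC"),
    ("ERisk_card2", "FrontalPole"),
    ("OUT", "AngularGyrus"),
    ("OUT", "Hippocampus"),
    ("OUT", "Amygdala"),
    ("OUT", "vmPFC"),
]

SHARING_ROIS = {"AnteriorInsula": 5, "OFC": 8}

# the anterior-insula pair shares one spatial pattern (coupled code, late
# copy weaker); the OFC pair occupies disjoint contact blocks separated by
# a gap (independent codes, the second being the outcome-orthogonal part)
SHARING_ENCODINGS = [
    EncodingSpec("RePE", "AnteriorInsula", "CARD2_ON", 0.25, pattern_group="ai"),
    EncodingSpec(
        "RiPE_card2", "AnteriorInsula", "CARD2_ON", 0.45, amplitude=1.0, pattern_group="ai"
    ),
    EncodingSpec("OUT", "OFC", "CARD2_ON", 0.25, contact_fraction=0.4, disjoint_group="ofc"),
    EncodingSpec(
        "RePE_unique", "OFC", "CARD2_ON", 0.40, contact_fraction=0.4, disjoint_group="ofc"
    ),
]

SHARING_ANALYSES = [
    ("RePE", "AnteriorInsula"),
    ("RiPE_card2", "AnteriorInsula"),
    ("OUT", "OFC"),
    ("RePE", "OFC"),
]

# kept for overlap checks in the same order the studies reference them
RECOVERY_ENCODINGS = CASCADE_ENCODINGS + SHARING_ENCODINGS
RECOVERY_ANALYSES = CASCADE_ANALYSES + SHARING_ANALYSES

CASCADE = [("OUT", "AngularGyrus"), ("OUT", "Hippocampus"), ("OUT", "Amygdala"), ("OUT", "vmPFC")]


def _cohort(rois: dict, encodings: list[EncodingSpec]) -> CohortConfig:
    return CohortConfig(
        n_subjects=4,
        sessions_per_subject=(1, 1, 1, 1),
        trials_per_session=60,
        roi_contacts=dict(rois),
        contact_count_jitter=1,
        encodings=list(encodings),
    )


def recovery_cohort_config() -> CohortConfig:
    """The cascade cohort (single-site codes and the outcome sweep)."""
    return _cohort(CASCADE_ROIS, CASCADE_ENCODINGS)


def sharing_cohort_config() -> CohortConfig:
    """The code-sharing cohort (coupled and independent code pairs)."""
    return _cohort(SHARING_ROIS, SHARING_ENCODINGS)


@dataclass
class RecoveryStudy:
    analyses: dict = field(default_factory=dict)  # (variable, roi) -> AnalysisResult
    coupled: pipeline.GeneralizationResult | None = None
    independent: pipeline.GeneralizationResult | None = None
    weight_r: float = np.nan
    weight_p: float = np.nan
    coupled_weight_r: float = np.nan
    coupled_weight_p: float = np.nan
    ground_truth: synthetic_data.GroundTruth | None = None
    sharing_truth: synthetic_data.GroundTruth | None = None
    suite: dict = field(default_factory=dict)


def run_recovery_study(
    seed: int = 21,
    n_perm: int = 200,
    n_folds: int = 10,
    time_stride: int = 5,
) -> RecoveryStudy:
    """Plant all recovery encodings and run every corresponding analysis."""
    sessions, gt = synthetic_data.generate_cohort(recovery_cohort_config(), seed=seed)
    bundles_cascade = pipeline.preprocess_cohort(sessions, seed=seed)
    sessions_sh, gt_sh = synthetic_data.generate_cohort(sharing_cohort_config(), seed=seed)
    bundles = pipeline.preprocess_cohort(sessions_sh, seed=seed)
    study = RecoveryStudy(ground_truth=gt, sharing_truth=gt_sh)
    for var, roi in CASCADE_ANALYSES:
        study.analyses[(var, roi)] = pipeline.run_decode_analysis(
            bundles_cascade, var, roi, n_folds=n_folds, n_perm=n_perm, seed=seed,
            time_stride=time_stride,
        )
    for var, roi in SHARING_ANALYSES:
        study.analyses[(var, roi)] = pipeline.run_decode_analysis(
            bundles, var, roi, n_folds=n_folds, n_perm=n_perm, seed=seed,
            time_stride=time_stride,
        )
    study.coupled = pipeline.run_generalization_analysis(
        bundles, "RePE", "RiPE_card2", "AnteriorInsula",
        n_perm=n_perm, seed=seed + 1, time_stride=time_stride,
    )
    study.independent = pipeline.run_generalization_analysis(
        bundles, "OUT", "RePE", "OFC",
        n_perm=n_perm, seed=seed + 1, time_stride=time_stride,
    )

    # leave-one-feature-out importance maps for the two OFC codes
    sd_out, times = pipeline.build_subject_data(bundles, "OUT", "OFC")
    folds_out = pipeline.make_folds(sd_out, times, n_folds, seed)
    sd_repe, _ = pipeline.build_subject_data(bundles, "RePE", "OFC")
    folds_repe = pipeline.make_folds(sd_repe, times, n_folds, seed)
    t_idx = np.flatnonzero((times >= 0.2) & (times <= 0.5))[::time_stride]
    w_out = lofo_weights(folds_out, time_indices=t_idx, decode_target="OUT", roi_label="OFC")
    w_repe = lofo_weights(folds_repe, time_indices=t_idx, decode_target="RePE", roi_label="OFC")
    study.weight_r, study.weight_p = weight_correlation(
        w_out, w_repe, (0.2, 0.5), n_perm=1000, seed=seed
    )

    # positive control: the coupled anterior-insula pair shares one pattern,
    # so its importance maps should correlate strongly
    sd_a, times_a = pipeline.build_subject_data(bundles, "RePE", "AnteriorInsula")
    folds_a = pipeline.make_folds(sd_a, times_a, n_folds, seed)
    sd_b, _ = pipeline.build_subject_data(bundles, "RiPE_card2", "AnteriorInsula")
    folds_b = pipeline.make_folds(sd_b, times_a, n_folds, seed)
    t_idx_a = np.flatnonzero((times_a >= 0.2) & (times_a <= 0.5))[::time_stride]
    w_a = lofo_weights(folds_a, time_indices=t_idx_a, decode_target="RePE",
                       roi_label="AnteriorInsula")
    w_b = lofo_weights(folds_b, time_indices=t_idx_a, decode_target="RiPE_card2",
                       roi_label="AnteriorInsula")
    study.coupled_weight_r, study.coupled_weight_p = weight_correlation(
        w_a, w_b, (0.2, 0.5), n_perm=1000, seed=seed
    )

    results = list(study.analyses.values())
    suite_a = pipeline.make_recovery_suite({"_results": results}, gt)
    suite_b = pipeline.make_recovery_suite({"_results": results}, gt_sh)
    study.suite = {
        "encodings": {**suite_a["encodings"], **suite_b["encodings"]},
        "all_recovered": suite_a["all_recovered"] and suite_b["all_recovered"],
    }
    return study


def kernel_support(enc: EncodingSpec, half_max: bool = False) -> tuple[float, float]:
    """Time window covered by an encoding's kernel (optionally above half max)."""
    half = enc.kernel_width / (4.0 if half_max else 2.0)
    return enc.latency_center - half, enc.latency_center + half


def overlapping_cluster(
    result: pipeline.GeneralizationResult,
    train_window: tuple[float, float],
    test_window: tuple[float, float],
    percentile: float = 95.0,
):
    """Significant 2D clusters touching the given train x test block."""
    out = []
    for c in result.clusters[percentile]:
        if not c.significant:
            continue
        if (
            c.train_extent[1] >= train_window[0]
            and c.train_extent[0] <= train_window[1]
            and c.test_extent[1] >= test_window[0]
            and c.test_extent[0] <= test_window[1]
        ):
            out.append(c)
    return out
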