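"""Confound design, residualization, binarization and pseudo-population."""

import numpy as np
import pandas as pd
import pytest

from riskdecode import feature_prep as fp
from riskdecode import task_model as tm
from riskdecode.preprocess import EpochTensor


@pytest.fixture()
def trials_frame():
    rng = np.random.default_rng(0)
    return tm.trials_to_frame(tm.simulate_trials(60, rng, report_accuracy=0.9))


def epoch_layout(n_trials):
    events = np.array(
        ["GUESS", "CARD1_ON", "CARD1_OFF", "CARD2_ON", "REPORT"] * n_trials,
        dtype=object,
    )
    trials = np.repeat(np.arange(n_trials), 5)
    # chronological within trial: reshape to trial-major ordering
    events = np.concatenate(
        [np.array(["GUESS", "CARD1_ON", "CARD1_OFF", "CARD2_ON", "REPORT"], dtype=object)]
        * n_trials
    )
    return events, trials


class TestOrthogonalize:
    def test_residual_uncorrelated_with_reference(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(2, 500))
        r = fp.orthogonalize(a + 0.7 * b, b)
        assert abs(np.corrcoef(r, b)[0, 1]) < 1e-10

    def test_card1_risk_error_vanishes_against_its_observed_risk(self, trials_frame):
        """RiPE at card 1 is an affine function of its own observed risk."""
        ripe1 = trials_frame["ripe_card1"].to_numpy()
        orisk1 = (trials_frame["ev"] - trials_frame["p0"]).to_numpy() ** 2
        resid = fp.orthogonalize(ripe1, orisk1)
        assert np.abs(resid).max() < 1e-12

    def test_uncorrelated_target_only_loses_mean(self):
        rng = np.random.default_rng(2)
        b = rng.normal(size=400)
        a = rng.normal(size=400)
        a -= np.polyval(np.polyfit(b, a, 1), b)  # exactly decorrelate
        out = fp.orthogonalize(a + 5.0, b)
        assert np.allclose(out, a - a.mean(), atol=1e-10)

    def test_zero_variance_reference(self):
        a = np.arange(10.0)
        out = fp.orthogonalize(a, np.ones(10))
        assert np.allclose(out, a - a.mean())


class TestConfoundDesign:
    @pytest.mark.parametrize("target", fp.DECODABLE)
    def test_target_excluded_others_present(self, trials_frame, target):
        events, trials = epoch_layout(len(trials_frame))
        design = fp.build_confound_design(trials_frame, events, trials, target)
        assert target not in design.columns
        expected = {v for v in fp.DECODABLE if v != target}
        assert expected <= set(design.columns)
        assert {"intercept", "ORisk", "report_accuracy"} <= set(design.columns)

    def test_parametric_columns_centered_on_their_event(self, trials_frame):
        events, trials = epoch_layout(len(trials_frame))
        design = fp.build_confound_design(trials_frame, events, trials, "EV")
        for name in ("OUT", "RePE", "RiPE_card2", "ORisk", "report_accuracy"):
            col = design.matrix[:, design.columns.index(name)]
            ev = fp.REGRESSOR_EVENT[name]
            on_event = events == ev
            assert col[~on_event].max() == col[~on_event].min() == 0.0
            assert abs(col[on_event].mean()) < 1e-12

    def test_orisk_retained_when_decoding_ripe(self, trials_frame):
        events, trials = epoch_layout(len(trials_frame))
        design = fp.build_confound_design(trials_frame, events, trials, "RiPE_card2")
        assert "ORisk" in design.columns
        assert "RiPE_card2" not in design.columns

    def test_multiple_targets_excluded(self, trials_frame):
        events, trials = epoch_layout(len(trials_frame))
        design = fp.build_confound_design(trials_frame, events, trials, ("OUT", "RePE"))
        assert "OUT" not in design.columns and "RePE" not in design.columns

    def test_unknown_target_rejected(self, trials_frame):
        events, trials = epoch_layout(len(trials_frame))
        with pytest.raises(ValueError):
            fp.build_confound_design(trials_frame, events, trials, "P0")


def _epochs_from(data, events, trials):
    n_e, n_c, n_t = data.shape
    return EpochTensor(
        data=data,
        times=np.arange(n_t) * 0.002,
        event_types=events,
        trial_index=trials,
        channels=pd.DataFrame({"name": [f"c{i}" for i in range(n_c)]}),
    )


class TestResidualize:
    def test_residuals_orthogonal_to_all_columns(self, trials_frame):
        rng = np.random.default_rng(3)
        events, trials = epoch_layout(len(trials_frame))
        design = fp.build_confound_design(trials_frame, events, trials, "EV")
        data = rng.normal(size=(len(events), 3, 7))
        out = fp.residualize_features(_epochs_from(data, events, trials), design)
        for c in range(3):
            for t in range(7):
                v = out.data[:, c, t]
                for j in range(1, design.matrix.shape[1]):
                    col = design.matrix[:, j]
                    if col.std() == 0:
                        continue
                    r = np.corrcoef(v, col)[0, 1]
                    assert abs(r) < 1e-8

    def test_intercept_only_design_centers(self):
        rng = np.random.default_rng(4)
        data = rng.normal(size=(20, 2, 3)) + 5.0
        events = np.array(["CARD1_ON"] * 20, dtype=object)
        trials = np.arange(20)
        design = fp.ConfoundDesign(np.ones((20, 1)), ["intercept"], events, trials)
        out = fp.residualize_features(_epochs_from(data, events, trials), design)
        assert np.allclose(out.data, data - data.mean(axis=0), atol=1e-10)

    def test_confound_signal_removed_target_signal_kept(self, trials_frame):
        """Planted outcome activity is scrubbed; the unique reward-error
        component survives when reward error is the decode target."""
        rng = np.random.default_rng(5)
        events, trials = epoch_layout(len(trials_frame))
        out_v = trials_frame["outcome"].to_numpy(float)
        repe_u = fp.trial_variable(trials_frame, "RePE")
        data = rng.normal(size=(len(events), 1, 4)) * 0.1
        card2 = events == "CARD2_ON"
        data[card2, 0, :] += (2.0 * out_v + 1.5 * repe_u)[trials[card2], None]
        design = fp.build_confound_design(trials_frame, events, trials, "RePE")
        res = fp.residualize_features(_epochs_from(data, events, trials), design)
        v = res.data[card2, 0, 0]
        assert abs(np.corrcoef(v, out_v)[0, 1]) < 1e-8
        # the other card-2 covariates absorb a little of the unique component
        assert np.corrcoef(v, repe_u)[0, 1] > 0.8

    def test_misaligned_design_rejected(self, trials_frame):
        events, trials = epoch_layout(len(trials_frame))
        design = fp.build_confound_design(trials_frame, events, trials, "EV")
        with pytest.raises(ValueError):
            fp.residualize_features(
                _epochs_from(np.zeros((10, 1, 2)), events[:10], trials[:10]), design
            )


class TestBinarize:
    def test_outcomes_split_into_wins_and_losses(self):
        rng = np.random.default_rng(6)
        out = rng.integers(0, 2, 200).astype(float)
        labels, keep = fp.binarize_target(out)
        assert keep.all()
        assert np.array_equal(labels == 1.0, out == 1)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fp.binarize_target(np.full(10, 3.0))

    def test_exact_mean_values_masked(self):
        labels, keep = fp.binarize_target(np.array([0.0, 1.0, 2.0]))
        assert not keep[1] and keep[0] and keep[2]

    def test_outcome_classes_balanced(self):
        rng = np.random.default_rng(7)
        out = np.array([t.outcome for t, _ in tm.simulate_trials(10_000, rng)], float)
        labels, keep = fp.binarize_target(out)
        frac = (labels[keep] == 1).mean()
        assert abs(frac - 0.5) < 3 * 0.5 / np.sqrt(keep.sum())


def toy_subject_data(rng, spec):
    """spec: {subject: (n_trials, n_contacts)} with random features/labels."""
    out = {}
    for s, (n, c) in spec.items():
        out[s] = (rng.normal(size=(n, c, 6)), rng.integers(0, 2, n).astype(float))
    return out


class TestPseudoPopulation:
    def test_block_structure_and_width(self):
        rng = np.random.default_rng(8)
        data = toy_subject_data(rng, {"s1": (30, 10), "s2": (30, 20)})
        folds = fp.assemble_pseudo_population(data, n_folds=5, seed=0)
        f = folds[0]
        assert f.train_X.shape[1] == 30
        s1_rows = f.train_subject == 0
        assert np.all(f.train_X[np.ix_(s1_rows, f.column_subject == 1)] == 0)
        assert np.all(f.train_X[np.ix_(~s1_rows, f.column_subject == 0)] == 0)

    def test_test_rows_partition_all_rows(self):
        rng = np.random.default_rng(9)
        data = toy_subject_data(rng, {"s1": (40, 4), "s2": (40, 6)})
        folds = fp.assemble_pseudo_population(data, n_folds=10, seed=1)
        all_test = np.concatenate([f.test_rows for f in folds])
        assert sorted(all_test) == list(range(80))

    def test_per_subject_share_balanced(self):
        rng = np.random.default_rng(10)
        data = toy_subject_data(rng, {"s1": (50, 4), "s2": (50, 4)})
        folds = fp.assemble_pseudo_population(data, n_folds=10, seed=2)
        for f in folds:
            for si in (0, 1):
                n_test = (f.test_subject == si).sum()
                assert abs(n_test - 5) <= 1

    def test_small_subject_excluded_with_warning(self):
        rng = np.random.default_rng(11)
        data = toy_subject_data(rng, {"s1": (40, 4)})
        data["tiny"] = (rng.normal(size=(3, 4, 6)), np.array([0.0, 1.0, 1.0]))
        with pytest.warns(UserWarning, match="excluded"):
            folds = fp.assemble_pseudo_population(data, n_folds=10, seed=3)
        assert folds[0].column_subject.size == 4


class TestNormalizeFold:
    def _folds(self, seed=12):
        rng = np.random.default_rng(seed)
        data = toy_subject_data(rng, {"s1": (40, 3), "s2": (40, 5)})
        return fp.assemble_pseudo_population(data, n_folds=4, seed=0)

    def test_train_block_standardized(self):
        f = fp.normalize_fold(self._folds()[0])
        for si in (0, 1):
            rows = f.train_subject == si
            cols = f.column_subject == si
            block = f.train_X[np.ix_(rows, cols)]
            assert np.abs(block.mean(axis=0)).max() < 1e-8
            assert np.abs(block.std(axis=0) - 1).max() < 1e-8

    def test_off_block_zeros_preserved(self):
        f = fp.normalize_fold(self._folds()[0])
        rows = f.train_subject == 0
        assert np.all(f.train_X[np.ix_(rows, f.column_subject == 1)] == 0)
        rows_te = f.test_subject == 0
        assert np.all(f.test_X[np.ix_(rows_te, f.column_subject == 1)] == 0)

    def test_statistics_never_use_test_rows(self):
        """Mutating test data must not change the fitted normalization."""
        fold = self._folds()[0]
        a = fp.normalize_fold(fold)
        mutated = fp.PseudoPopulationFold(
            train_X=fold.train_X,
            train_y=fold.train_y,
            test_X=fold.test_X + 100.0,
            test_y=-fold.test_y,
            train_subject=fold.train_subject,
            test_subject=fold.test_subject,
            column_subject=fold.column_subject,
            train_rows=fold.train_rows,
            test_rows=fold.test_rows,
        )
        b = fp.normalize_fold(mutated)
        assert np.array_equal(a.train_X, b.train_X)
        # shifting test rows by a constant shifts the output by a scaled constant
        assert np.allclose(b.test_X - a.test_X, (b.test_X - a.test_X).round(12))

    def test_shuffled_train_rows_give_identical_statistics(self):
        fold = self._folds()[0]
        rng = np.random.default_rng(13)
        perm = rng.permutation(fold.train_y.size)
        shuffled = fp.PseudoPopulationFold(
            train_X=fold.train_X[perm],
            train_y=fold.train_y[perm],
            test_X=fold.test_X,
            test_y=fold.test_y,
            train_subject=fold.train_subject[perm],
            test_subject=fold.test_subject,
            column_subject=fold.column_subject,
            train_rows=fold.train_rows[perm],
            test_rows=fold.test_rows,
        )
        a = fp.normalize_fold(fold)
        b = fp.normalize_fold(shuffled)
        assert np.allclose(a.test_X, b.test_X)
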