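import numpy as np
import pytest

from eeg2bold.training import (
    FoldSpec,
    LossConfig,
    TrainConfig,
    compute_loss,
    early_stop_check,
    make_folds,
)


class TestComputeLoss:
    def test_identity_prediction_gives_minus_corr_weight(self):
        y = [0.0, 1.0, 0.0, -1.0]
        assert compute_loss(y, y) == pytest.approx(-0.1, abs=1e-9)

    def test_reversed_sequence_hand_value(self):
        """MSE 5, r -1 under the default 0.9 / 0.1 weights."""
        assert compute_loss([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(4.6, abs=1e-9)

    def test_default_weights(self):
        cfg = LossConfig()
        assert (cfg.weight_mse, cfg.weight_corr) == (0.9, 0.1)

    def test_zero_variance_correlation_defined_as_zero(self):
        assert compute_loss([1, 1, 1, 1], [0, 0, 0, 0]) == pytest.approx(0.9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_loss([1, 2], [1, 2, 3])


class TestMakeFolds:
    def test_many_runs_distinct_test_runs(self):
        runs = [f"run{i}" for i in range(80)]
        folds = make_folds(runs, 20, seed=0)
        assert len(folds) == 20
        assert len({f.test_run for f in folds}) == 20

    def test_partition_arithmetic(self):
        runs = [f"run{i}" for i in range(10)]
        for fold in make_folds(runs, 5, seed=1):
            assert len(fold.train_runs) + 2 == len(runs)
            members = {fold.test_run, fold.validation_run, *fold.train_runs}
            assert members == set(runs)

    def test_seeded_determinism(self):
        runs = [f"run{i}" for i in range(12)]
        assert make_folds(runs, 6, seed=3) == make_folds(runs, 6, seed=3)
        assert make_folds(runs, 6, seed=3) != make_folds(runs, 6, seed=4)

    def test_too_few_runs_rejected(self):
        with pytest.raises(ValueError):
            make_folds(["a", "b"], 1, seed=0)
        with pytest.raises(ValueError):
            make_folds(["a", "b", "c"], 4, seed=0)

    def test_overlapping_fold_spec_rejected(self):
        with pytest.raises(ValueError):
            FoldSpec(0, "run1", "run1", ("run2",))


class TestEarlyStop:
    def test_monotone_decrease_never_stops(self):
        val = list(np.linspace(1.0, 0.1, 40))
        train = list(np.linspace(1.0, 0.1, 40))
        assert not early_stop_check(train, val, patience=15)

    def test_fires_after_exact_patience_rise(self):
        train = list(np.linspace(1.0, 0.2, 21))
        val = [1.0, 0.5] + [0.5 + 0.01 * i for i in range(1, 20)]
        # validation rises for 15 consecutive epochs while training falls
        assert early_stop_check(train[:17], val[:17], patience=15)

    def test_counter_resets_on_improvement(self):
        train = list(np.linspace(1.0, 0.2, 17))
        val = [0.5] + [0.5 + 0.01 * i for i in range(1, 15)] + [0.4, 0.41]
        assert not early_stop_check(train, val, patience=15)

    def test_rising_train_loss_blocks_stop(self):
        val = [0.5] + [0.6] * 15
        train = [1.0] + [1.1] * 15  # training loss not decreasing
        assert not early_stop_check(train, val, patience=15)

    def test_empty_history_rejected(self):
        with pytest.raises(ValueError):
            early_stop_check([], [], patience=5)


class TestTrainConfig:
    def test_full_scale_defaults(self):
        cfg = TrainConfig()
        assert cfg.learning_rate == pytest.approx(3e-5)
        assert cfg.weight_decay == pytest.approx(3e-4)
        assert cfg.batch_size == 32
        assert cfg.scheduler_t_max_epochs == 50
        assert cfg.early_stop_patience_epochs == 15

    def test_patience_below_max_epochs_enforced(self):
        with pytest.raises(ValueError):
            TrainConfig(max_epochs=10, early_stop_patience_epochs=10)


class TestTrainFoldContract:
    """Cheap contract checks on a miniature problem (2-3 epochs)."""

    @pytest.fixture(scope="class")
    def mini_trained(self, desk_session):
        from dataclasses import replace
        from eeg2bold.training import train_fold
        from eeg2bold.workbench import desk_scale_config

        cfg = desk_scale_config(3)
        tcfg = replace(cfg.train, max_epochs=5, scheduler_t_max_epochs=5,
                       windows_per_epoch=32, window_s=20.0,
                       early_stop_patience_epochs=3)
        folds = make_folds([r.run_id for r in desk_session.runs], 1, 0)
        return train_fold(desk_session.pairs, folds[0], cfg.model, tcfg, cfg.loss)

    def test_history_and_stop_reason(self, mini_trained):
        assert len(mini_trained.train_losses) <= 5
        assert mini_trained.stop_reason in ("early_stop", "max_epochs")
        assert len(mini_trained.train_losses) == len(mini_trained.val_losses)

    def test_prediction_covers_test_run(self, mini_trained, desk_session):
        pair = desk_session.pairs[mini_trained.fold.test_run]
        assert mini_trained.y_pred.size == pair.n_samples
        assert np.all(np.isfinite(mini_trained.y_pred))

    def test_training_loss_decreases_initially(self, mini_trained):
        assert min(mini_trained.train_losses) < mini_trained.train_losses[0]

    def test_missing_run_rejected(self, desk_session):
        from eeg2bold.training import train_fold
        from eeg2bold.workbench import desk_scale_config

        cfg = desk_scale_config(3)
        bad = FoldSpec(0, "run99", "run1", ("run2", "run3"))
        with pytest.raises(ValueError):
            train_fold(desk_session.pairs, bad, cfg.model, cfg.train, cfg.loss)
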