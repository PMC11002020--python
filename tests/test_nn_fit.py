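"""Synthetic-signal sampling, noise augmentation, and neural regressors.

The expensive scaled-down trainings live in session fixtures (shared with
the end-to-end tests); the tests here that train from scratch use tiny
budgets and only check qualitative behavior (loss decreases, no divergence).
"""

import numpy as np
import pytest
from scipy.special import hyp1f1

import myot2.nn_fit as nn
from myot2.epg_core import TissueParams, mese_two_component
from myot2.nn_fit import (
    NoiseSpec,
    augment_and_normalize,
    build_model,
    predict_fat,
    predict_muscle,
    sample_training_params,
    simulate_training_signals,
    train,
)


class TestSampling:
    def test_ranges_and_reproducibility(self):
        a = sample_training_params("muscle", 100_000, seed=3)
        b = sample_training_params("muscle", 100_000, seed=3)
        assert a.equals(b)
        for nm, (lo, hi) in nn.TRAINING_RANGES["muscle"].items():
            col = a[nm]
            assert col.min() >= lo and col.max() <= hi
            # empirical extrema close to the range endpoints under uniformity
            span = hi - lo
            assert col.min() - lo < 0.01 * span
            assert hi - col.max() < 0.01 * span

    def test_fat_ff_fixed(self):
        t = sample_training_params("fat", 100, seed=0)
        assert (t["ff"] == 0.9).all()

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            sample_training_params("bone", 10, seed=0)


class TestSimulation:
    def test_rows_match_single_voxel_simulation(self, seq_profile):
        params = sample_training_params("muscle", 10, seed=4)
        signals = simulate_training_signals(params, seq_profile)
        for i in range(10):
            row = params.iloc[i]
            expected = mese_two_component(
                TissueParams(
                    t2f_ms=row["t2f"], t2w_ms=row["t2w"], ff=row["ff"], b1=row["b1"]
                ),
                seq_profile,
            )
            np.testing.assert_allclose(signals[i], expected, rtol=1e-12)

    def test_ff_zero_row_is_water_only(self, seq_ideal):
        import pandas as pd

        params = pd.DataFrame({"t2f": [150.0], "t2w": [40.0], "ff": [0.0], "b1": [1.0]})
        sig = simulate_training_signals(params, seq_ideal)[0]
        np.testing.assert_allclose(sig, np.exp(-np.arange(1, 18) * 7.5 / 40.0), rtol=1e-6)


class TestAugmentation:
    def test_no_noise_is_pure_normalization(self, seq_ideal):
        sig = np.exp(-np.arange(1, 18) * 7.5 / 40.0)
        out = augment_and_normalize(sig, None, np.random.default_rng(0))
        np.testing.assert_allclose(out[0], sig / np.linalg.norm(sig))

    def test_outputs_unit_norm(self):
        rng = np.random.default_rng(1)
        sig = np.abs(rng.standard_normal((200, 17))) + 0.1
        out = augment_and_normalize(sig, NoiseSpec("variance_range", 1e-7, 5e-5), rng)
        np.testing.assert_allclose(np.linalg.norm(out, axis=1), 1.0, atol=1e-9)

    def test_noise_floor_matches_rician_expectation(self, seq_ideal):
        """Per-echo mean at the highest training noise follows the Rician mean."""
        sig = np.exp(-np.arange(1, 18) * 7.5 / 20.0)  # fast decay: late echoes ~ 0
        n = 100_000
        rng = np.random.default_rng(5)
        spec = NoiseSpec("variance_range", 5e-5, 5e-5)
        out = augment_and_normalize(np.tile(sig, (n, 1)), spec, rng)
        sigma = np.sqrt(5e-5) * sig[0]
        # Rician mean: sigma * sqrt(pi/2) * 1F1(-1/2; 1; -s^2/(2 sigma^2))
        rice_mean = (
            sigma * np.sqrt(np.pi / 2) * hyp1f1(-0.5, 1.0, -(sig**2) / (2 * sigma**2))
        )
        expected = rice_mean / np.linalg.norm(sig)  # norm change is O(sigma^2)
        emp = out.mean(axis=0)
        np.testing.assert_allclose(emp, expected, rtol=0.05)

    def test_invalid_noise_spec(self):
        with pytest.raises(ValueError):
            NoiseSpec("variance_range", 0.0, 1e-5)
        with pytest.raises(ValueError):
            NoiseSpec("chisq", 1e-7, 1e-5)


class TestModel:
    def test_default_architecture_has_six_weighted_layers(self):
        b = build_model("muscle", etl=17)
        assert len(b.net.weights) == 6  # 5 hidden + linear output
        assert b.net.layer_sizes == [18, 256, 128, 64, 32, 16, 3]

    def test_fat_input_width_is_etl(self):
        b = build_model("fat", etl=17)
        assert b.net.layer_sizes[0] == 17

    def test_parameter_count_closed_form(self):
        b = build_model("fat", etl=17, layer_sizes=(8, 4))
        sizes = [17, 8, 4, 3]
        expected = sum(a * c + c for a, c in zip(sizes[:-1], sizes[1:]))
        assert b.net.n_params == expected

    def test_forward_on_zero_input_finite(self):
        b = build_model("muscle", etl=17)
        out = b.net.forward(np.zeros((2, 18)))
        assert np.all(np.isfinite(out))

    def test_increasing_widths_rejected(self):
        with pytest.raises(ValueError):
            build_model("fat", layer_sizes=(64, 128))


class TestTraining:
    def test_loss_decreases_substantially(self, muscle_bundle, seq_profile):
        """Final training MAE beats the untrained model's MAE by >= 5x."""
        params = sample_training_params("muscle", 2000, seed=55)
        signals = simulate_training_signals(params, seq_profile)
        x = augment_and_normalize(signals, None, np.random.default_rng(0))
        x = np.concatenate([x, nn._scale_t2f(params["t2f"].to_numpy())[:, None]], axis=1)
        untrained = build_model("muscle", etl=17, seed=0)
        targets = nn._scale_targets(params, "muscle")
        init_mae = float(
            np.mean(np.abs(untrained.net.forward(nn._standardize(muscle_bundle, x)) - targets))
        )
        assert muscle_bundle.loss_history[-1] < init_mae / 5.0

    def test_loss_below_first_epoch_from_epoch_five(self, muscle_bundle):
        hist = np.array(muscle_bundle.loss_history)
        assert np.all(hist[4:] < hist[0])

    def test_muscle_recovery_noiseless(self, seq_profile, muscle_bundle):
        """Scaled-down Muscle-Net: T2w MAE <= 2 ms for FF <= 0.8 voxels."""
        params = sample_training_params("muscle", 2000, seed=99)
        signals = simulate_training_signals(params, seq_profile)
        mask = params["ff"].to_numpy() <= 0.8
        maes = []
        # feed each voxel its own true T2f via small same-T2f groups
        x = augment_and_normalize(signals, None, np.random.default_rng(0))
        x = np.concatenate([x, nn._scale_t2f(params["t2f"].to_numpy())[:, None]], axis=1)
        out = nn._unscale(muscle_bundle.net.forward(nn._standardize(muscle_bundle, x)), "muscle")
        mae = np.mean(np.abs(out["t2w"][mask] - params["t2w"].to_numpy()[mask]))
        assert mae <= 2.0

    def test_fat_recovery_noiseless(self, seq_profile, fat_bundle):
        params = sample_training_params("fat", 2000, seed=98)
        signals = simulate_training_signals(params, seq_profile)
        out = predict_fat(fat_bundle, signals)
        mae = np.mean(np.abs(out["t2f"] - params["t2f"].to_numpy()))
        assert mae <= 5.0

    def test_divergence_detection(self, seq_ideal):
        b = build_model("fat", etl=17, layer_sizes=(16, 8))
        with pytest.raises(RuntimeError, match="diverged"):
            train(
                b, seq_ideal, n_train=256, epochs=1, steps_per_epoch=30, batch=64,
                seed=0, lr=1e300, lr_final=1e300,
            )


class TestPrediction:
    def test_scale_invariance(self, muscle_bundle, seq_profile):
        params = sample_training_params("muscle", 5, seed=1)
        signals = simulate_training_signals(params, seq_profile)
        a = predict_muscle(muscle_bundle, signals, 150.0)
        b = predict_muscle(muscle_bundle, 7.3 * signals, 150.0)
        # unit-norm normalization makes this exact up to float rounding
        np.testing.assert_allclose(a["t2w"], b["t2w"], rtol=1e-9)
        np.testing.assert_allclose(a["ff"], b["ff"], rtol=1e-9, atol=1e-9)

    def test_t2f_outside_training_range_rejected(self, muscle_bundle):
        with pytest.raises(ValueError):
            predict_muscle(muscle_bundle, np.ones(17), 300.0)

    def test_wrong_signal_length_rejected(self, fat_bundle):
        with pytest.raises(ValueError):
            predict_fat(fat_bundle, np.ones(11))

    def test_kind_mismatch_rejected(self, muscle_bundle):
        with pytest.raises(ValueError):
            predict_fat(muscle_bundle, np.ones(17))


def test_bundle_save_load_round_trip(tmp_path, fat_bundle, seq_profile):
    from myot2.nn_fit import load_bundle, save_bundle

    params = sample_training_params("fat", 10, seed=3)
    signals = simulate_training_signals(params, seq_profile)
    save_bundle(fat_bundle, tmp_path / "fatnet")
    back = load_bundle(tmp_path / "fatnet")
    a = predict_fat(fat_bundle, signals)
    b = predict_fat(back, signals)
    np.testing.assert_array_equal(a["t2f"], b["t2f"])
    assert back.seq_hash == seq_profile.seq_hash
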