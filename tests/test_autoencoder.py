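import numpy as np
import pandas as pd
import pytest

from ftirdae import autoencoder as ae
from ftirdae.autoencoder import (
    ArchitectureError,
    ArchitectureSpec,
    LayerSpec,
    LossConfig,
    NotTrainedError,
    TrainConfig,
    build_autoencoder,
    custom_loss,
    default_architecture,
    encode,
    make_fixed_spectrum,
    pair_preservation,
    reconstruct,
    silent_pc1_scores,
    spectral_comparison,
    train_autoencoder,
)
from ftirdae.spectra_io import RegionMask, SpectraSet, WavenumberGrid, l2_normalize

# Published layer table for the bundled architecture:
# (kind, filters, output length, parameter count)
LAYER_TABLE = [
    ("conv", 128, 493, 6912),
    ("conv", 64, 221, 434240),
    ("conv", 32, 85, 108576),
    ("conv", 16, 17, 27152),
    ("transposed_conv", 32, 85, 27168),
    ("transposed_conv", 64, 221, 108608),
    ("transposed_conv", 128, 493, 434304),
    ("transposed_conv", 1, 1037, 6785),
]


def tiny_arch(input_length=21, filters=(6, 4), dec_filters=(6, 1)):
    layers = [
        LayerSpec("conv", filters[0], kernel_length=5, stride=2),
        LayerSpec("conv", filters[1], kernel_length=3, stride=2),
        LayerSpec("transposed_conv", dec_filters[0], kernel_length=3, stride=2),
        LayerSpec("transposed_conv", dec_filters[1], kernel_length=5, stride=2,
                  activation="linear"),
    ]
    return ArchitectureSpec(layers=tuple(layers), input_length=input_length)


def tiny_spectra_set(n=12, p=21, seed=0, silent=(8, 12), drift_sd=0.0):
    """Unit-norm spectra on p points with optional per-sample silent drift."""
    rng = np.random.default_rng(seed)
    grid = WavenumberGrid(np.linspace(1000.0, 3000.0, p))
    base = np.exp(-0.5 * ((np.arange(p) - 4.0) / 2.0) ** 2)
    x = base[None, :] * rng.lognormal(0.0, 0.3, (n, 1))
    x = x + 0.05 * rng.normal(size=(n, p)) * 0.1
    if drift_sd:
        lo, hi = silent
        x[:, lo:hi] += rng.normal(0.0, drift_sd, (n, 1))
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    mask_flags = np.zeros(p, bool)
    mask_flags[silent[0] : silent[1]] = True
    mask = RegionMask(mask_flags, grid.values[silent[0]], grid.values[silent[1] - 1])
    return SpectraSet(grid, x, [f"t{i}" for i in range(n)]), mask


class TestArchitecture:
    def test_default_layer_shapes_and_param_counts(self):
        spec = default_architecture()
        shapes = spec.layer_shapes()
        params = spec.layer_param_counts()
        assert spec.input_length == 1037
        for (kind, filters, length, count), layer, (out_len, out_ch), n in zip(
            LAYER_TABLE, spec.layers, shapes, params
        ):
            assert layer.kind == kind and layer.filters == filters
            assert layer.kernel_length == 53 and layer.stride == 2
            assert out_len == length and out_ch == filters
            assert n == count
        assert sum(params) == sum(row[3] for row in LAYER_TABLE)
        assert spec.latent_dim == 272

    def test_final_layer_is_linear_others_elu(self):
        spec = default_architecture()
        assert all(l.activation == "elu" for l in spec.layers[:-1])
        assert spec.layers[-1].activation == "linear"

    def test_built_model_realizes_param_counts(self):
        model = build_autoencoder(default_architecture(), seed=0)
        per_layer = [layer.n_params for layer in model.network.layers]
        assert per_layer == [row[3] for row in LAYER_TABLE]
        assert model.total_params() == sum(row[3] for row in LAYER_TABLE)

    def test_length_underflow_is_architecture_error(self):
        with pytest.raises(ArchitectureError):
            ArchitectureSpec(layers=default_architecture().layers, input_length=100)

    def test_decoder_must_follow_encoder(self):
        layers = (
            LayerSpec("transposed_conv", 4, kernel_length=3, stride=2),
            LayerSpec("conv", 4, kernel_length=3, stride=2),
        )
        with pytest.raises(ArchitectureError):
            ArchitectureSpec(layers=layers, input_length=21)

    def test_seeded_initialization_is_deterministic(self):
        a = build_autoencoder(tiny_arch(), seed=3)
        b = build_autoencoder(tiny_arch(), seed=3)
        for wa, wb in zip(a.network.get_weights(), b.network.get_weights()):
            np.testing.assert_array_equal(wa, wb)


class TestCustomLoss:
    def mask(self):
        return RegionMask(np.array([False, True, True, False]), 1900.0, 2100.0)

    def test_hand_computed_example(self):
        cfg = LossConfig(silent=self.mask(), fixed_spectrum=[0.0, 0.0], lambda_weight=2.0)
        loss = custom_loss([[0.5, 0.2, 0.1, 0.4]], [[0.4, 9.0, 9.0, 0.6]], cfg)
        assert loss == pytest.approx(0.15)

    def test_zero_iff_exact_fit(self):
        target = np.array([[0.4, 0.7, 0.3, 0.6]])
        cfg = LossConfig(silent=self.mask(), fixed_spectrum=target[0, 1:3])
        predicted = target.copy()
        assert custom_loss(predicted, target, cfg) == 0.0
        bumped = predicted.copy()
        bumped[0, 0] += 0.01
        assert custom_loss(bumped, target, cfg) > 0.0

    def test_default_lambda_is_1000(self):
        cfg = LossConfig(silent=self.mask(), fixed_spectrum=[0.0, 0.0])
        assert cfg.lambda_weight == 1000.0

    def test_nonnegative_on_random_batches(self):
        rng = np.random.default_rng(0)
        cfg = LossConfig(silent=self.mask(), fixed_spectrum=rng.normal(size=2))
        for _ in range(25):
            pred = rng.normal(size=(3, 4))
            tgt = rng.normal(size=(3, 4))
            assert custom_loss(pred, tgt, cfg) >= 0.0

    def test_mask_length_mismatch_errors(self):
        cfg = LossConfig(silent=self.mask(), fixed_spectrum=[0.0, 0.0])
        with pytest.raises(ValueError, match="mask length"):
            custom_loss(np.ones((1, 7)), np.ones((1, 7)), cfg)

    def test_fixed_spectrum_length_validated(self):
        with pytest.raises(ValueError, match="fixed_spectrum"):
            LossConfig(silent=self.mask(), fixed_spectrum=[0.0, 0.0, 0.0])


class TestMakeFixedSpectrum:
    def test_mean_of_one_and_two(self, tiny_spectra):
        mask = RegionMask(np.array([False, True, True, False, False]), 1500.0, 2000.0)
        one = tiny_spectra.subset([0])
        np.testing.assert_allclose(
            make_fixed_spectrum(one, mask), one.absorbance[0, 1:3]
        )
        two = tiny_spectra.subset([0, 1])
        np.testing.assert_allclose(
            make_fixed_spectrum(two, mask), two.absorbance[:, 1:3].mean(axis=0)
        )

    def test_external_reference_modes(self, tiny_spectra):
        mask = RegionMask(np.array([False, True, True, False, False]), 1500.0, 2000.0)
        with pytest.raises(ValueError, match="reference"):
            make_fixed_spectrum(tiny_spectra, mask, mode="external_reference")
        ref = np.arange(5.0)
        np.testing.assert_allclose(
            make_fixed_spectrum(tiny_spectra, mask, "external_reference", ref),
            [1.0, 2.0],
        )


class TestTraining:
    def test_one_epoch_records_one_history_entry(self):
        spectra, mask = tiny_spectra_set(n=10)
        cfg = LossConfig(silent=mask, fixed_spectrum=make_fixed_spectrum(spectra, mask))
        model = build_autoencoder(tiny_arch(), seed=0)
        train_autoencoder(model, spectra, cfg, TrainConfig(max_epochs=1, seed=0))
        assert len(model.training_history) == 1
        assert model.trained

    def test_non_normalized_input_rejected(self):
        spectra, mask = tiny_spectra_set(n=6)
        cfg = LossConfig(silent=mask, fixed_spectrum=make_fixed_spectrum(spectra, mask))
        model = build_autoencoder(tiny_arch(), seed=0)
        bad = spectra.copy_with(spectra.absorbance * 2.0)
        with pytest.raises(ValueError, match="normalized"):
            train_autoencoder(model, bad, cfg, TrainConfig(max_epochs=1))

    def test_loss_decreases_over_training(self):
        spectra, mask = tiny_spectra_set(n=64, seed=1)
        cfg = LossConfig(silent=mask, fixed_spectrum=make_fixed_spectrum(spectra, mask))
        model = build_autoencoder(tiny_arch(), seed=1)
        train_autoencoder(
            model, spectra, cfg, TrainConfig(max_epochs=25, batch_size=16, seed=1)
        )
        hist = [h["train_loss"] for h in model.training_history]
        assert hist[-1] <= hist[0]

    def test_lambda_role_in_silent_region(self):
        # with lambda on, the silent region is pushed to the fixed spectrum;
        # with the lambda=0 ablation it keeps tracking the per-sample drift
        spectra, mask = tiny_spectra_set(n=96, seed=2, drift_sd=0.15)
        fixed = make_fixed_spectrum(spectra, mask)
        out = {}
        for lam in (1000.0, 0.0):
            cfg = LossConfig(silent=mask, fixed_spectrum=fixed, lambda_weight=lam)
            model = build_autoencoder(tiny_arch(), seed=2)
            train_autoencoder(
                model, spectra, cfg,
                TrainConfig(max_epochs=60, batch_size=16, seed=2, patience=60),
            )
            recon = reconstruct(model, spectra)
            out[lam] = recon.absorbance[:, mask.member_flags].var(axis=0).mean()
        raw_var = spectra.absorbance[:, mask.member_flags].var(axis=0).mean()
        assert out[1000.0] < 0.25 * raw_var  # flattened toward fixed spectrum
        assert out[0.0] > 4 * out[1000.0]  # ablation keeps the drift


class TestApply:
    def trained_tiny(self, n=24, seed=0):
        spectra, mask = tiny_spectra_set(n=n, seed=seed)
        cfg = LossConfig(silent=mask, fixed_spectrum=make_fixed_spectrum(spectra, mask))
        model = build_autoencoder(tiny_arch(), seed=seed)
        train_autoencoder(model, spectra, cfg, TrainConfig(max_epochs=5, seed=seed))
        return model, spectra, mask

    def test_reconstruct_preserves_shape_and_ids(self):
        model, spectra, _ = self.trained_tiny()
        recon = reconstruct(model, spectra)
        assert recon.absorbance.shape == spectra.absorbance.shape
        assert recon.sample_ids == spectra.sample_ids
        assert np.all(np.isfinite(recon.absorbance))

    def test_reconstruct_length_mismatch_errors(self):
        model, spectra, _ = self.trained_tiny()
        grid = WavenumberGrid(np.linspace(1000, 3000, 11))
        other = SpectraSet(grid, np.ones((2, 11)), ["a", "b"])
        with pytest.raises(ValueError):
            reconstruct(model, other)

    def test_encode_shape_and_untrained_error(self):
        model, spectra, _ = self.trained_tiny()
        latent = encode(model, spectra.subset([0]))
        assert latent.values.shape == (1, model.spec.latent_dim)
        fresh = build_autoencoder(tiny_arch(), seed=0)
        with pytest.raises(NotTrainedError):
            encode(fresh, spectra)

    def test_default_architecture_encodes_272(self):
        model = build_autoencoder(default_architecture(), seed=0)
        model.trained = True
        grid = WavenumberGrid(np.linspace(1000, 3000, 1037))
        x = np.random.default_rng(0).normal(size=(2, 1037))
        spectra = SpectraSet(grid, x, ["a", "b"])
        latent = encode(model, spectra)
        assert latent.values.shape == (2, 272)

    def test_encode_flattening_is_position_major(self):
        model, spectra, _ = self.trained_tiny()
        latent = encode(model, spectra)
        bottleneck = model.network.forward(
            spectra.absorbance.astype(np.float32)[:, :, None],
            upto=model.spec.n_encoder_layers,
        )
        # position-major: row-by-row unravel of (length, channels)
        np.testing.assert_allclose(
            latent.values[0], bottleneck[0].ravel(order="C"), rtol=1e-6
        )

    def test_save_load_round_trip(self, tmp_path):
        model, spectra, _ = self.trained_tiny()
        path = tmp_path / "model.npz"
        ae.save_model(model, path)
        back = ae.load_model(path)
        np.testing.assert_allclose(
            reconstruct(back, spectra).absorbance,
            reconstruct(model, spectra).absorbance,
            atol=1e-6,
        )
        np.testing.assert_allclose(
            encode(back, spectra).values, encode(model, spectra).values, atol=1e-6
        )


class TestDiagnostics:
    def test_silent_pc1_recovers_offset_ordering(self):
        rng = np.random.default_rng(3)
        spectra, mask = tiny_spectra_set(n=8, seed=3)
        offsets = rng.normal(0, 0.2, 8)
        x = spectra.absorbance.copy()
        x[:, mask.member_flags] = 0.1 + offsets[:, None]
        shifted = spectra.copy_with(x)
        scores = silent_pc1_scores(shifted, mask)
        assert list(np.argsort(scores)) == list(np.argsort(offsets))

    def test_identical_samples_score_zero(self):
        spectra, mask = tiny_spectra_set(n=4, seed=4)
        same = spectra.copy_with(np.tile(spectra.absorbance[0], (4, 1)))
        np.testing.assert_allclose(silent_pc1_scores(same, mask), 0.0, atol=1e-12)

    def test_score_variance_equals_leading_eigenvalue(self):
        spectra, mask = tiny_spectra_set(n=30, seed=5)
        scores = silent_pc1_scores(spectra, mask)
        x = spectra.absorbance[:, mask.member_flags]
        eigs = np.linalg.eigvalsh(np.cov(x.T, ddof=1))
        assert scores.var(ddof=1) == pytest.approx(eigs[-1], rel=1e-9)

    def test_pair_preservation_identity_and_permutation(self):
        rng = np.random.default_rng(6)
        grid = WavenumberGrid(np.linspace(1000, 3000, 10))
        x = rng.normal(size=(6, 10)) + 10 * np.arange(6)[:, None]  # well separated
        orig = SpectraSet(grid, x, [f"s{i}" for i in range(6)])
        same = orig.copy_with(x.copy())
        assert pair_preservation(orig, same) == 1.0
        perm = orig.copy_with(np.roll(x, 1, axis=0))
        assert pair_preservation(orig, perm) == 0.0

    def test_pair_preservation_single_swap_two_thirds(self):
        grid = WavenumberGrid(np.linspace(1000, 3000, 4))
        x = np.array(
            [[0.0, 0, 0, 0], [10.0, 10, 0, 0], [0.0, 0, 10, 10]]
        )
        orig = SpectraSet(grid, x, ["a", "b", "c"])
        # replace c's reconstruction with b's spectrum: a and b stay paired
        swapped = orig.copy_with(x[[0, 1, 1]])
        assert pair_preservation(orig, swapped) == pytest.approx(2 / 3)

    def test_pair_preservation_id_mismatch_errors(self):
        spectra, _ = tiny_spectra_set(n=3)
        other = SpectraSet(
            spectra.grid, spectra.absorbance, ["x0", "x1", "x2"]
        )
        with pytest.raises(ValueError):
            pair_preservation(spectra, other)

    def test_spectral_comparison_identity_and_shift(self):
        spectra, _ = tiny_spectra_set(n=5, seed=7)
        same = spectra.copy_with(spectra.absorbance.copy())
        table = spectral_comparison(spectra, same)
        np.testing.assert_allclose(table["effect_size"], 0.0)
        np.testing.assert_allclose(table["mean_abs_residual"], 0.0)
        shifted = spectra.absorbance.copy()
        shifted[:, 3] += 0.25
        table2 = spectral_comparison(spectra, spectra.copy_with(shifted))
        assert table2.loc[3, "mean_abs_residual"] == pytest.approx(0.25)

    def test_spectral_comparison_hand_t_statistic(self):
        grid = WavenumberGrid(np.linspace(1000, 3000, 2))
        orig = SpectraSet(grid, np.array([[1.0, 1], [2, 2], [3, 4]]), ["a", "b", "c"])
        recon = SpectraSet(grid, np.array([[1.0, 1], [2, 2], [4, 4]]), ["a", "b", "c"])
        table = spectral_comparison(orig, recon)
        # differences at column 0: (0, 0, -1); |t| = (1/3)/(sd/sqrt(3)) = 1
        assert table.loc[0, "t_statistic"] == pytest.approx(-1.0)
        assert table.loc[1, "t_statistic"] == 0.0 and table.loc[1, "p_value"] == 1.0
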