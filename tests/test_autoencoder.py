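import numpy as np
import pandas as pd
import pytest

from cfdeconv import autoencoder as ae
from cfdeconv import fixtures as fx
from cfdeconv import simulate as sim
from cfdeconv.errors import ModelFormatError, ValidationError
from conftest import heldout_frame


class TestArchitecture:
    def test_encoder_widths_match_contract(self):
        cfg = ae.ModelConfig(n_features=500)
        assert cfg.encoder_widths == (500, 512, 256, 128, 64, 2)
        assert cfg.decoder_widths == (2, 64, 128, 256, 512, 500)
        model = ae.build_model(cfg)
        shapes = [w.shape for w in model.enc_w]
        assert shapes == [(512, 500), (256, 512), (128, 256), (64, 128), (2, 64)]
        dec_shapes = [w.shape for w in model.dec_w]
        assert dec_shapes == [(64, 2), (128, 64), (256, 128), (512, 256), (500, 512)]
        assert model.effective_weight().shape == (500, 2)

    def test_decoder_layers_have_no_bias(self):
        model = ae.build_model(ae.ModelConfig(n_features=100))
        assert not hasattr(model, "dec_b")

    def test_same_seed_identical_initialization(self):
        a = ae.build_model(ae.ModelConfig(n_features=120, seed=5))
        b = ae.build_model(ae.ModelConfig(n_features=120, seed=5))
        for wa, wb in zip(a.enc_w + a.dec_w, b.enc_w + b.dec_w):
            np.testing.assert_array_equal(wa, wb)

    def test_tiny_feature_count_warns_and_caps(self):
        with pytest.warns(UserWarning):
            cfg = ae.ModelConfig(n_features=10)
        assert cfg.encoder_widths == (10, 10, 10, 10, 10, 2)

    def test_latent_dim_fixed_at_two(self):
        with pytest.raises(ValidationError):
            ae.ModelConfig(n_features=100, latent_dim=3)


class TestEncode:
    def test_inference_latent_nonnegative(self):
        model = ae.build_model(ae.ModelConfig(n_features=50, seed=0))
        rng = np.random.default_rng(0)
        latent = model.encode(rng.uniform(size=(40, 50)), inference=True)
        assert (latent >= 0).all()

    def test_inference_deterministic(self):
        model = ae.build_model(ae.ModelConfig(n_features=50, seed=0))
        x = np.random.default_rng(1).uniform(size=(8, 50))
        np.testing.assert_array_equal(model.encode(x), model.encode(x))

    def test_training_latent_unclamped(self):
        # raw latent must be able to go negative (no ReLU before the Comp loss)
        model = ae.build_model(ae.ModelConfig(n_features=50, seed=0))
        rng = np.random.default_rng(2)
        found_negative = False
        for seed in range(20):
            x = np.random.default_rng(seed).uniform(size=(30, 50))
            if (model.encode(x, inference=False) < 0).any():
                found_negative = True
                break
        assert found_negative

    def test_feature_mismatch_rejected(self):
        model = ae.build_model(ae.ModelConfig(n_features=50))
        with pytest.raises(ValidationError):
            model.encode(np.zeros((3, 49)))


class TestAtlasAndReconstruction:
    def test_zero_decoder_gives_half_atlas(self):
        model = ae.build_model(ae.ModelConfig(n_features=30))
        model.dec_w = [np.zeros_like(w) for w in model.dec_w]
        atlas = model.effective_atlas()
        np.testing.assert_allclose(atlas.to_numpy(), 0.5)

    def test_atlas_entries_strictly_inside_unit_interval(self):
        model = ae.build_model(ae.ModelConfig(n_features=80, seed=3))
        atlas = model.effective_atlas().to_numpy()
        assert (atlas > 0).all() and (atlas < 1).all()

    def test_unit_fraction_reconstructs_atlas_column(self):
        model = ae.build_model(ae.ModelConfig(n_features=40, seed=1))
        atlas = model.effective_atlas().to_numpy()
        np.testing.assert_allclose(
            model.reconstruct(np.array([[1.0, 0.0]]))[0], atlas[:, 0], atol=1e-12
        )
        np.testing.assert_allclose(
            model.reconstruct(np.array([[0.0, 0.0]]))[0], 0.0, atol=1e-12
        )
        np.testing.assert_allclose(
            model.reconstruct(np.array([[0.5, 0.5]]))[0],
            atlas.mean(axis=1),
            atol=1e-12,
        )


class TestLossComponents:
    def make_inputs(self, n=70, batch=6, seed=0):
        rng = np.random.default_rng(seed)
        model = ae.build_model(ae.ModelConfig(n_features=n, seed=seed))
        x = rng.uniform(size=(batch, n))
        y = rng.dirichlet((1.0, 1.0), size=batch)
        ref = rng.uniform(0.1, 0.9, size=(n, 2))
        return model, x, y, ref

    def test_perfect_latent_zeroes_comp(self):
        model, x, y, ref = self.make_inputs()
        losses = model.loss_components(x, y, ref, latent=y)
        assert losses["comp"] == 0.0

    def test_methy_minimum_at_reference_means(self):
        # cross-entropy is minimized (at the Bernoulli entropy) when the
        # atlas column equals the reference mean
        model, x, y, ref = self.make_inputs()
        w_eff = np.log(ref / (1 - ref))  # logit: sigmoid(w) == ref
        # overwrite the decoder so its effective matrix equals logit(ref):
        # the latent passes through the first two coordinates of each layer
        k = len(model.dec_w)
        model.dec_w = [np.zeros_like(w) for w in model.dec_w]
        model.dec_w[0][:2, :2] = np.eye(2)
        for i in range(1, k - 1):
            model.dec_w[i][:2, :2] = np.eye(2)
        model.dec_w[-1][:, :2] = w_eff
        np.testing.assert_allclose(model.effective_weight(), w_eff, atol=1e-12)
        losses = model.loss_components(x, y, ref)
        entropy = -np.mean(ref * np.log(ref) + (1 - ref) * np.log(1 - ref), axis=0)
        assert losses["methy_h"] == pytest.approx(entropy[0], abs=1e-10)
        assert losses["methy_t"] == pytest.approx(entropy[1], abs=1e-10)
        # perturbing the atlas away from ref can only increase the term
        model.dec_w[-1][:, :2] = w_eff + 0.3
        perturbed = model.loss_components(x, y, ref)
        assert perturbed["methy_h"] > losses["methy_h"]

    def test_all_terms_nonnegative(self):
        model, x, y, ref = self.make_inputs(seed=4)
        losses = model.loss_components(x, y, ref)
        assert all(v >= 0 for v in losses.values())


class TestGradients:
    def test_backward_matches_finite_differences(self):
        """Analytic gradients of the four-term loss vs central differences."""
        cfg = ae.ModelConfig(
            n_features=12, encoder_hidden=(8, 6, 5, 4), dropout_rate=0.0, seed=2
        )
        model = ae.build_model(cfg)
        rng = np.random.default_rng(3)
        x = rng.uniform(size=(5, 12))
        y = rng.dirichlet((1.0, 1.0), size=5)
        ref = rng.uniform(0.2, 0.8, size=(12, 2))

        _, grads = model._backward(x, y, ref, rng=None)
        params = model._parameters()
        eps = 1e-6
        rng_check = np.random.default_rng(0)
        for p, g in zip(params, grads):
            flat = p.ravel()
            for idx in rng_check.choice(flat.size, size=min(5, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = model.loss_components(x, y, ref)["total"]
                flat[idx] = orig - eps
                down = model.loss_components(x, y, ref)["total"]
                flat[idx] = orig
                numeric = (up - down) / (2 * eps)
                assert g.ravel()[idx] == pytest.approx(numeric, abs=1e-5), (
                    f"gradient mismatch at parameter shape {p.shape}"
                )


class TestTraining:
    def test_loss_trace_length_and_decrease(self, trained_bundle):
        history = trained_bundle["history"]
        assert len(history) == 256
        assert history["total"].iloc[-1] <= history["total"].iloc[0]

    def test_seeded_training_is_deterministic(self):
        ref, _, _ = fx.make_reference(
            fx.FixtureSpec(n_probes=40, n_dmp=40, n_tissue_dmp=0,
                           n_tumor=10, n_plasma=10, seed=8)
        )
        data = sim.generate_simulated_data(ref, samplenum=120, random_state=1)
        m1, h1 = ae.train(data.x, data.y, ref, epochs=5, seed=7)
        m2, h2 = ae.train(data.x, data.y, ref, epochs=5, seed=7)
        for a, b in zip(m1._parameters(), m2._parameters()):
            np.testing.assert_array_equal(a, b)
        pd.testing.assert_frame_equal(h1, h2)

    def test_heldout_tumor_fraction_rmse(self, trained_bundle):
        model, ref, heldout = (
            trained_bundle["model"],
            trained_bundle["ref"],
            trained_bundle["heldout"],
        )
        pred = ae.predict_fractions(model, heldout_frame(ref, heldout))
        rmse = float(
            np.sqrt(np.mean((pred["tumor_fraction"].to_numpy() - heldout.y[:, 1]) ** 2))
        )
        assert rmse <= 0.08

    def test_mean_prediction_monotone_in_true_fraction(self, trained_bundle):
        model = trained_bundle["model"]
        true_means = trained_bundle["true_means"]
        ref = trained_bundle["ref"]
        rng = np.random.default_rng(17)
        mu = true_means.to_numpy()
        means = []
        for f in np.arange(0.0, 0.51, 0.1):
            profile = (1 - f) * mu[:, 0] + f * mu[:, 1]
            reps = np.clip(
                profile[None, :] + rng.normal(0, 0.02, size=(20, mu.shape[0])), 0, 1
            )
            frame = pd.DataFrame(
                reps.T, index=ref.index, columns=[f"r{i}" for i in range(20)]
            )
            pred = ae.predict_fractions(model, frame)
            means.append(pred["tumor_fraction"].mean())
        assert np.all(np.diff(means) > 0)

    def test_atlas_recovers_true_tumor_profile(self, trained_bundle):
        atlas = trained_bundle["model"].effective_atlas()
        true_means = trained_bundle["true_means"]
        corr = np.corrcoef(atlas["tumor"], true_means["tumor"])[0, 1]
        assert corr >= 0.9
        corr_h = np.corrcoef(atlas["healthy"], true_means["healthy"])[0, 1]
        assert corr_h >= 0.9

    def test_identical_populations_yield_no_spurious_tumor_signal(self):
        # both populations drawn from the same means: atlas columns must agree
        # to within the fixture's noise scale
        spec = fx.FixtureSpec(
            n_probes=60, n_dmp=0, n_tissue_dmp=0, n_tumor=15, n_plasma=15,
            kappa=50.0, seed=21,
        )
        ref, _, _ = fx.make_reference(spec)
        data = sim.generate_simulated_data(ref, samplenum=300, random_state=2)
        model, _ = ae.train(data.x, data.y, ref, epochs=60, seed=2)
        atlas = model.effective_atlas().to_numpy()
        noise_scale = np.sqrt(0.25 / (spec.kappa + 1))
        assert np.mean(np.abs(atlas[:, 0] - atlas[:, 1])) <= noise_scale

    def test_pure_healthy_sample_gets_low_tumor_fraction(self, trained_bundle):
        model, ref = trained_bundle["model"], trained_bundle["ref"]
        atlas = model.effective_atlas()
        frame = pd.DataFrame(
            atlas["healthy"].to_numpy()[:, None], index=ref.index, columns=["pure_h"]
        )
        pred = ae.predict_fractions(model, frame)
        assert pred["tumor_fraction"].iloc[0] <= 0.05


class TestPredictFractions:
    def test_normalized_fractions_sum_to_one(self, trained_bundle):
        model, ref, heldout = (
            trained_bundle["model"],
            trained_bundle["ref"],
            trained_bundle["heldout"],
        )
        pred = ae.predict_fractions(model, heldout_frame(ref, heldout))
        totals = pred["healthy_fraction"] + pred["tumor_fraction"]
        np.testing.assert_allclose(totals, 1.0, atol=1e-9)
        assert (pred[["healthy_fraction", "tumor_fraction"]] >= 0).all().all()

    def test_missing_probe_rejected_with_names(self, trained_bundle):
        model, ref = trained_bundle["model"], trained_bundle["ref"]
        frame = pd.DataFrame(
            np.random.default_rng(0).uniform(size=(len(ref) - 1, 2)),
            index=ref.index[:-1],
            columns=["a", "b"],
        )
        with pytest.raises(ValidationError, match=str(ref.index[-1])):
            ae.predict_fractions(model, frame)


class TestSerialization:
    def test_round_trip_preserves_predictions(self, tmp_path, trained_bundle):
        model, ref, heldout = (
            trained_bundle["model"],
            trained_bundle["ref"],
            trained_bundle["heldout"],
        )
        path = tmp_path / "model.npz"
        ae.save_model(model, path)
        loaded = ae.load_model(path)
        assert loaded.probe_ids == model.probe_ids
        frame = heldout_frame(ref, heldout)
        pd.testing.assert_frame_equal(
            ae.predict_fractions(model, frame), ae.predict_fractions(loaded, frame)
        )
        for a, b in zip(model._parameters(), loaded._parameters()):
            np.testing.assert_array_equal(a, b)

    def test_truncated_file_is_a_format_error(self, tmp_path, trained_bundle):
        path = tmp_path / "model.npz"
        ae.save_model(trained_bundle["model"], path)
        data = path.read_bytes()
        path.write_bytes(data[: len(data) // 2])
        with pytest.raises(ModelFormatError):
            ae.load_model(path)

    def test_non_model_file_rejected(self, tmp_path):
        path = tmp_path / "other.npz"
        np.savez(path, a=np.zeros(3))
        with pytest.raises(ModelFormatError):
            ae.load_model(path)
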