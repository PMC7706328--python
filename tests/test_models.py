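"""Variant dispatch, conditional structure, rollout and prediction."""

import numpy as np
import pytest

from sdssm import autodiff as ad
from sdssm.datamodel import bundle_table, split_by_pattern, standardize
from sdssm.experiments import as_bundles, linear_variant_spec
from sdssm.models import SDSSM, NotTrainedError, VariantSpec
from sdssm.synthetic import simulate_linear_gaussian
from sdssm.training import TrainConfig, train


def tiny_spec(variant="cont", **kw):
    base = dict(variant=variant, z_dim=2, K=3, hidden_units=8, n_hidden=1,
                encoder_hidden=8)
    base.update(kw)
    return VariantSpec(**base)


class TestVariantDispatch:
    def test_cont_has_no_categorical_networks(self):
        model = SDSSM(tiny_spec("cont"), seed=0)
        assert "prior_d" not in model.networks
        assert "recognize_d" not in model.networks
        assert "prior_z" in model.networks

    def test_disc_has_no_continuous_prior(self):
        model = SDSSM(tiny_spec("disc"), seed=0)
        assert "prior_z" not in model.networks
        assert "prior_d" in model.networks
        assert model.latent_dim == 3

    def test_2l_instantiates_both_chains(self):
        model = SDSSM(tiny_spec("2l"), seed=0)
        assert "prior_z" in model.networks and "prior_d" in model.networks

    def test_2l_prior_chains_are_mutually_independent(self):
        model = SDSSM(tiny_spec("2l"), seed=0)
        B = 4
        state = model.init_chain_state(B)
        U = np.random.default_rng(0).standard_normal((B, model.du))
        z_prev = model.initial_z(B)
        pz1, _ = model.prior_z_params(z_prev, U, state["prior_z"])
        # a different growth-stage state cannot influence the z prior
        state2 = model.init_chain_state(B)
        state2["d_prev"] = np.roll(model.initial_d(B), 1, axis=1)
        pz2, _ = model.prior_z_params(z_prev, U, state2["prior_z"])
        assert np.array_equal(ad.value_of(pz1.mean), ad.value_of(pz2.mean))

    def test_default_routing_follows_variant(self):
        assert VariantSpec(variant="cont").routing().u_cols == (
            "temperature", "solar_radiation", "vpd", "elapsed_days",
            "accum_temp")
        assert VariantSpec(variant="disc").routing().u_cols == (
            "elapsed_days", "accum_temp")
        r2 = VariantSpec(variant="2l").routing()
        assert r2.u_cols == ("temperature", "solar_radiation", "vpd")
        assert r2.v_cols == ("elapsed_days", "accum_temp")
        for v in ("cont", "disc", "2l"):
            assert VariantSpec(variant=v).routing().r_cols == ()

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            VariantSpec(variant="deep")
        with pytest.raises(ValueError):
            VariantSpec(variant="cont", emit_from_stage=True)
        with pytest.raises(ValueError):
            VariantSpec(variant="cont", x_imputer_mode="bidirectional")


class TestLinearConfiguration:
    def test_prior_mean_reproduces_linear_dynamics_exactly(self):
        model = SDSSM(linear_variant_spec(z_dim=2, u_dim=1), seed=0)
        A = np.array([[0.9, 0.1], [0.0, 0.7]])
        Bc = np.array([[0.5], [0.2]])
        W = np.vstack([A.T, Bc.T])  # input order (z_prev, u)
        model.networks["prior_z"].mu_head.W.value = W
        model.networks["prior_z"].mu_head.b.value = np.zeros(2)
        rng = np.random.default_rng(1)
        z_prev = rng.standard_normal((5, 2))
        u = rng.standard_normal((5, 1))
        params, _ = model.prior_z_params(z_prev, u, None)
        assert np.allclose(ad.value_of(params.mean), z_prev @ A.T + u @ Bc.T)

    def test_emission_mean_reproduces_linear_map_exactly(self):
        model = SDSSM(linear_variant_spec(z_dim=2, u_dim=1), seed=0)
        C = np.array([[1.5], [-0.4]])
        model.networks["emit_x"].mu_head.W.value = C
        model.networks["emit_x"].mu_head.b.value = np.zeros(1)
        z = np.random.default_rng(2).standard_normal((6, 2))
        params = model.emit_x_params(z, np.zeros((6, 0)))
        assert np.allclose(ad.value_of(params.mean), z @ C)

    def test_zero_weights_give_standard_normal_prior(self):
        model = SDSSM(linear_variant_spec(), seed=0)
        model.set_param_values({k: np.zeros_like(v)
                                for k, v in model.param_values().items()})
        params, _ = model.prior_z_params(np.ones((3, 1)), np.ones((3, 1)),
                                         None)
        assert np.allclose(ad.value_of(params.mean), 0.0)
        assert np.allclose(ad.value_of(params.log_std), 0.0)


class TestConditionalStructure:
    def test_emission_ignores_unrelated_observation(self):
        model = SDSSM(tiny_spec("cont"), seed=1)
        z = np.random.default_rng(3).standard_normal((4, 2))
        S = np.random.default_rng(4).standard_normal((4, model.ds))
        p1 = model.emit_x_params(z, S)
        p2 = model.emit_x_params(z, S)  # y never enters the x emission
        assert np.array_equal(ad.value_of(p1.mean), ad.value_of(p2.mean))

    def test_emit_y_without_action_variables_depends_on_latent_only(self):
        model = SDSSM(tiny_spec("cont"), seed=1)
        assert model.dr == 0
        z = np.random.default_rng(5).standard_normal((4, 2))
        p = model.emit_y_params(z, np.zeros((4, 0)))
        assert ad.value_of(p.mean).shape == (4, 1)

    def test_markov_transition_table_propagates_by_matrix_power(self):
        # affine disc configuration with logits hand-set to a log transition
        # table: stepping on one-hot states reproduces the Markov chain
        P = np.array([[0.7, 0.2, 0.1],
                      [0.1, 0.8, 0.1],
                      [0.05, 0.3, 0.65]])
        spec = VariantSpec(variant="disc", K=3, n_hidden=0,
                           encoder_mode="identity",
                           x_imputer_mode="instantaneous",
                           u_cols=("u",), v_cols=(), s_cols=(), r_cols=())
        model = SDSSM(spec, seed=2)
        net = model.networks["prior_d"]
        W = np.zeros((4, 3))           # inputs: (d_prev one-hot [3], u [1])
        W[:3, :] = np.log(P)
        net.logit_head.W.value = W
        net.logit_head.b.value = np.zeros(3)
        u = np.zeros((3, 1))
        eye = np.eye(3)
        params, _ = model.prior_d_params(eye, u, None)
        assert np.allclose(ad.value_of(params.probs), P, atol=1e-12)
        # marginal propagation through the conditioner rows = matrix powers
        marg = np.array([1.0, 0.0, 0.0])
        for n in range(1, 6):
            marg = marg @ ad.value_of(params.probs)
            assert np.allclose(marg, np.linalg.matrix_power(P, n)[0],
                               atol=1e-10)


class TestRolloutAndPrediction:
    def make_trained_linear(self):
        from sdssm.experiments import default_lgssm_params
        params = default_lgssm_params()
        seqs = simulate_linear_gaussian(params, T=12, n_sequences=6, seed=3)
        model = SDSSM(linear_variant_spec(), seed=4)
        model.trained = True
        return model, seqs, params

    def test_rollout_reproducible_under_seed(self):
        model, seqs, _ = self.make_trained_linear()
        cov = {"U": seqs[0]["U"]}
        a = model.rollout(cov, n_samples=5, seed=11)
        b = model.rollout(cov, n_samples=5, seed=11)
        c = model.rollout(cov, n_samples=5, seed=12)
        assert np.array_equal(a["x"], b["x"])
        assert not np.array_equal(a["x"], c["x"])

    def test_first_step_prior_starts_from_zero_state(self):
        model, seqs, _ = self.make_trained_linear()
        U = seqs[0]["U"]
        p0, _ = model.prior_z_params(np.zeros((1, 1)), U[:1], None)
        draws = model.rollout({"U": U}, n_samples=20_000, seed=5)
        z1 = draws["z"][:, 0, 0]
        mu = float(ad.value_of(p0.mean)[0, 0])
        sd = float(np.exp(ad.value_of(p0.log_std))[0, 0])
        assert abs(z1.mean() - mu) < 4 * sd / np.sqrt(20_000)
        assert abs(z1.std() - sd) < 0.05 * sd + 1e-3

    def test_untrained_model_refuses_prediction(self):
        from sdssm.experiments import default_lgssm_params
        model = SDSSM(linear_variant_spec(), seed=0)
        seqs = simulate_linear_gaussian(default_lgssm_params(), T=5,
                                       n_sequences=1, seed=0)
        with pytest.raises(NotTrainedError):
            model.predict_sugar(as_bundles(seqs))

    def test_prediction_std_positive_and_mean_stable(self):
        model, seqs, _ = self.make_trained_linear()
        bundles = as_bundles(seqs)
        preds = model.predict_sugar(bundles, n_samples=16, seed=1)
        assert len(preds) == len(bundles)
        for p in preds:
            assert np.all(p.std > 0)
            assert np.all(np.isfinite(p.mean))
        # more samples converge to the same posterior-predictive mean
        p64 = model.predict_sugar(bundles, n_samples=64, seed=2)
        p256 = model.predict_sugar(bundles, n_samples=256, seed=3)
        gap = max(np.abs(a.mean - b.mean).max()
                  for a, b in zip(p64, p256))
        assert gap < 0.5  # same scale as one posterior std

    def test_checkpoint_roundtrip_is_exact(self, tmp_path, small_sim):
        table, _ = small_sim
        from sdssm.datamodel import split_by_beds
        split = split_by_beds(table, [1, 2], [3], [4])
        split, scaler = standardize(split)
        spec = tiny_spec("cont")
        model = SDSSM(spec, seed=9)
        cfg = TrainConfig(epochs=3, lr=1e-3, val_n_samples=4, seed=1)
        train(model, split, cfg, scaler=scaler)
        bundles = bundle_table(split.val, spec.routing())
        before = model.predict_sugar(bundles, n_samples=4, seed=7,
                                     scaler=scaler)
        model.save(tmp_path / "ckpt", scaler=scaler)
        loaded, scaler2 = SDSSM.load(tmp_path / "ckpt")
        after = loaded.predict_sugar(bundles, n_samples=4, seed=7,
                                     scaler=scaler2)
        for a, b in zip(before, after):
            assert np.allclose(a.mean, b.mean, atol=1e-10)
            assert np.allclose(a.std, b.std, atol=1e-10)
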