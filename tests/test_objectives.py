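"""Semisupervised bounds: structure, oracle agreement and gradients."""

import numpy as np
import pytest

from sdssm import autodiff as ad
from sdssm.experiments import (ScalarLGSSMOracle, default_lgssm_params,
                               linear_variant_spec)
from sdssm.models import SDSSM, VariantSpec
from sdssm.objectives import (labeled_elbo, labeled_elbo_2l, objective_loss,
                              unlabeled_elbo, unlabeled_elbo_2l)
from sdssm.synthetic import kalman_loglik, simulate_linear_gaussian
from conftest import central_diff


@pytest.fixture(scope="module")
def linear_data():
    params = default_lgssm_params()
    dense = simulate_linear_gaussian(params, T=6, n_sequences=3, seed=2)
    sparse = simulate_linear_gaussian(params, T=6, n_sequences=3, seed=3,
                                      label_period=3)
    return params, dense, sparse


def tiny_model(seed=0):
    return SDSSM(linear_variant_spec(), seed=seed)


class TestObjectiveStructure:
    def test_breakdown_identity(self, linear_data):
        _, dense, sparse = linear_data
        model = tiny_model()
        for data in (dense, sparse):
            _, bd = objective_loss(model, data, alpha=0.3, beta=0.7, seed=1)
            expected = (-(bd.recon_x + bd.recon_y) - bd.entropy_x
                        + bd.beta * (bd.kl_z + bd.kl_d)
                        + bd.alpha * bd.regression)
            assert np.isclose(bd.total, expected, atol=1e-9)
            assert bd.kl_z >= 0.0
            assert bd.kl_d == 0.0

    def test_beta_zero_leaves_reconstruction_only(self, linear_data):
        _, dense, _ = linear_data
        model = tiny_model()
        _, bd = objective_loss(model, dense, alpha=0.0, beta=0.0, seed=4)
        assert np.isclose(bd.elbo, bd.recon_x + bd.recon_y + bd.entropy_x)

    def test_alpha_zero_reduces_to_negative_elbo(self, linear_data):
        _, dense, _ = linear_data
        model = tiny_model()
        _, bd = objective_loss(model, dense, alpha=0.0, beta=0.5, seed=5)
        assert np.isclose(bd.total, -bd.elbo, atol=1e-9)

    def test_entropy_counts_only_masked_steps(self, linear_data):
        _, dense, _ = linear_data
        model = tiny_model()
        _, bd = objective_loss(model, dense, alpha=0.1, beta=0.5, seed=6)
        assert bd.entropy_x == 0.0  # fully labeled

    def test_invalid_arguments_rejected(self, linear_data):
        _, dense, _ = linear_data
        model = tiny_model()
        with pytest.raises(ValueError):
            objective_loss(model, dense, alpha=-0.1, beta=0.5)
        with pytest.raises(ValueError):
            objective_loss(model, dense, alpha=0.1, beta=1.5)
        with pytest.raises(ValueError):
            objective_loss(model, [], alpha=0.1, beta=0.5)

    def test_mask_purity_checked_by_pure_bounds(self, linear_data):
        _, dense, sparse = linear_data
        model = tiny_model()
        with pytest.raises(ValueError):
            labeled_elbo(model, sparse, beta=1.0)
        with pytest.raises(ValueError):
            unlabeled_elbo(model, dense, beta=1.0)

    def test_2l_bounds_require_2l_variant(self, linear_data):
        _, dense, _ = linear_data
        model = tiny_model()
        with pytest.raises(ValueError):
            labeled_elbo_2l(model, dense, beta=1.0)
        with pytest.raises(ValueError):
            unlabeled_elbo_2l(model, dense, beta=1.0)


class TestOracleAgreement:
    def test_exact_posterior_recognition_is_tight(self, linear_data):
        params, dense, _ = linear_data
        oracle = ScalarLGSSMOracle(params, recognition="exact",
                                   sequences=dense)
        mean, samples = labeled_elbo(oracle, dense, beta=1.0,
                                     mc_samples=400, seed=7)
        ll = np.array(kalman_loglik(params, dense))
        se = samples.std(axis=0, ddof=1) / np.sqrt(samples.shape[0])
        assert np.all(np.abs(mean - ll) < 3 * se + 1e-9)

    def test_arbitrary_recognition_stays_below_loglik(self, linear_data):
        params, dense, _ = linear_data
        ll_total = float(np.sum(kalman_loglik(params, dense)))
        rng = np.random.default_rng(8)
        for _ in range(20):
            coefs = {"g": rng.normal(0, 0.5), "wx": rng.normal(0, 0.5),
                     "wy": rng.normal(0, 0.5), "wu": rng.normal(0, 0.5),
                     "b": rng.normal(0, 0.5),
                     "log_std": rng.uniform(np.log(0.1), np.log(1.0))}
            oracle = ScalarLGSSMOracle(params, affine_coefs=coefs)
            mean, samples = labeled_elbo(oracle, dense, beta=1.0,
                                         mc_samples=64,
                                         seed=int(rng.integers(1 << 30)))
            total = float(mean.sum())
            se = float(samples.sum(axis=1).std(ddof=1) / 8.0)
            assert total <= ll_total + 3 * se

    def test_sharp_imputation_reduces_unlabeled_to_labeled_plus_entropy(
            self, linear_data):
        """With q(x|y) collapsed near x*, the unlabeled bound equals the
        labeled bound evaluated at x* plus the (constant) entropy."""
        params, _, _ = linear_data
        x_star = 0.4
        seqs = simulate_linear_gaussian(params, T=4, n_sequences=2, seed=9,
                                        label_period=None)
        unlabeled = []
        at_star = []
        for s in seqs:
            u = dict(s)
            u["m"] = np.zeros(4)
            u["x"] = np.zeros(4)
            unlabeled.append(u)
            a = dict(s)
            a["m"] = np.ones(4)
            a["x"] = np.full(4, x_star)
            at_star.append(a)

        # replace the imputation distribution with a near-delta at x*
        oracle_u = ScalarLGSSMOracle(params, affine_coefs={
            "g": 0.3, "wx": 0.2, "wy": 0.4, "wu": 0.1, "b": 0.0,
            "log_std": np.log(0.4)})
        sharp_log_std = -7.0

        def sharp_qx(y_t, U_t, S_t, x_state, train=False):
            B = np.asarray(y_t).shape[0]
            from sdssm.distributions import DiagGaussianParams
            return DiagGaussianParams(
                mean=np.full((B, 1), x_star),
                log_std=np.full((B, 1), sharp_log_std)), x_state

        oracle_u.recognize_x_step = sharp_qx
        mean_u, samp_u = unlabeled_elbo(oracle_u, unlabeled, beta=1.0,
                                        mc_samples=300, seed=10)
        oracle_l = ScalarLGSSMOracle(params, affine_coefs=oracle_u.affine)
        mean_l, samp_l = labeled_elbo(oracle_l, at_star, beta=1.0,
                                      mc_samples=300, seed=11)
        entropy = 4 * (0.5 * np.log(2 * np.pi * np.e) + sharp_log_std)
        se = np.sqrt(samp_u.std(0, ddof=1) ** 2
                     + samp_l.std(0, ddof=1) ** 2) / np.sqrt(300)
        assert np.all(np.abs(mean_u - (mean_l + entropy)) < 3 * se + 1e-6)


class TestGradients:
    def test_finite_difference_check_on_tiny_smooth_model(self):
        params = default_lgssm_params()
        seqs = simulate_linear_gaussian(params, T=2, n_sequences=2, seed=12,
                                        label_period=2)
        spec = VariantSpec(variant="cont", z_dim=1, n_hidden=1,
                           hidden_units=4, activation="tanh",
                           encoder_mode="lstm", encoder_hidden=4,
                           x_imputer_mode="instantaneous",
                           u_cols=("u",), v_cols=(), s_cols=(), r_cols=())
        model = SDSSM(spec, seed=13)

        def loss_fn():
            loss, _ = objective_loss(model, seqs, alpha=0.1, beta=0.5,
                                     seed=14)
            return ad.value_of(loss)

        loss, _ = objective_loss(model, seqs, alpha=0.1, beta=0.5, seed=14)
        ps = model.params()
        for p in ps.values():
            p.grad = None
        loss.backward()
        worst = central_diff(loss_fn, ps, eps=1e-5, per_param=3)
        assert worst < 1e-4

    def test_gradients_flow_into_every_network(self, linear_data):
        _, _, sparse = linear_data
        model = tiny_model(seed=1)
        loss, _ = objective_loss(model, sparse, alpha=0.5, beta=0.5, seed=15)
        loss.backward()
        touched = {name: any(p.grad is not None and np.any(p.grad != 0)
                             for k, p in model.params().items()
                             if k.startswith(name))
                   for name in ("prior_z", "recognize_z", "emit_x", "emit_y",
                                "recognize_x")}
        assert all(touched.values()), touched
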