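"""Greenhouse generator structure and the exact linear-Gaussian oracle."""

import numpy as np
import pytest
from scipy import stats

from sdssm.datamodel import split_by_pattern
from sdssm.synthetic import (GreenhouseSimConfig, LGSSMParams, kalman_filter,
                             kalman_loglik, prior_marginals,
                             simulate_greenhouse, simulate_linear_gaussian)


class TestGreenhouseSimulator:
    def test_default_structure(self, greenhouse_default):
        table, truth = greenhouse_default
        assert len(table) == 16 * 3 * 83
        assert len(list(table.sequences())) == 48
        for _, _, grp in table.sequences():
            observed = grp.sugar_brix.notna().to_numpy()
            assert np.array_equal(np.flatnonzero(observed),
                                  np.arange(0, 83, 3))

    def test_accumulated_temperature_is_running_sum(self, greenhouse_default):
        table, _ = greenhouse_default
        for _, _, grp in list(table.sequences())[:3]:
            assert np.allclose(grp.accum_temp.to_numpy(),
                               np.cumsum(grp.temperature.to_numpy()))
            assert np.all(np.diff(grp.accum_temp.to_numpy()) > 0)

    def test_seed_reproducibility(self):
        cfg = GreenhouseSimConfig(n_beds=2, n_steps=1, n_days=20)
        t1, _ = simulate_greenhouse(cfg, seed=5)
        t2, _ = simulate_greenhouse(cfg, seed=5)
        t3, _ = simulate_greenhouse(cfg, seed=6)
        assert t1 == t2
        assert not (t1 == t3)

    def test_brix_within_configured_range(self, greenhouse_default):
        table, _ = greenhouse_default
        sugar = table.frame.sugar_brix.dropna()
        assert sugar.min() >= 4.67 - 1e-12
        assert sugar.max() <= 10.73 + 1e-12

    def test_stage_path_monotone(self, greenhouse_default):
        _, truth = greenhouse_default
        for path in truth.stage.values():
            assert np.all(np.diff(path) >= 0)

    def test_water_path_follows_linear_gaussian_recursion(self):
        # residuals of the stated AR(1) recursion must be the configured
        # white noise (this is the generator's linear-Gaussian state core)
        cfg = GreenhouseSimConfig(n_beds=8, n_steps=3, n_days=83)
        table, truth = simulate_greenhouse(cfg, seed=11)
        resid = []
        for (bed, step), w in truth.water.items():
            grp = table.frame[(table.frame.bed_id == bed)
                              & (table.frame.step_id == step)]
            vpd = grp.vpd.to_numpy()
            vpd_anom = vpd - vpd.mean()
            phase = (bed + 2 * step) % cfg.irrigation_period
            for t in range(1, len(w)):
                pulse = (cfg.irrigation_amp
                         if (t % cfg.irrigation_period) == phase else 0.0)
                pred = (cfg.w_rho * w[t - 1]
                        - cfg.w_vpd_gain * vpd_anom[t] + pulse)
                resid.append(w[t] - pred)
        resid = np.asarray(resid)
        n = resid.size
        assert abs(resid.mean()) < 3 * cfg.w_sigma / np.sqrt(n)
        assert abs(resid.std() - cfg.w_sigma) < 0.05 * cfg.w_sigma

    def test_oracle_prediction_hits_noise_floor(self):
        # predicting from the true latents leaves only the emission noise:
        # MAE ~= sigma_x * sqrt(2/pi); any model is bounded below by this
        cfg = GreenhouseSimConfig()
        table, truth = simulate_greenhouse(cfg, seed=13)
        base = np.asarray(cfg.brix_stage_base)
        errs = []
        for (bed, step), c in truth.stress.items():
            grp = table.frame[(table.frame.bed_id == bed)
                              & (table.frame.step_id == step)]
            stage = truth.stage[(bed, step)]
            pred = (base[np.minimum(stage, len(base) - 1)]
                    + cfg.brix_stress_gain * c + truth.bed_effect[bed])
            obs = grp.sugar_brix.notna().to_numpy()
            errs.append(np.abs(grp.sugar_brix.to_numpy()[obs]
                               - pred[obs]))
        mae = float(np.concatenate(errs).mean())
        floor = cfg.brix_noise * np.sqrt(2 / np.pi)
        # clipping truncates a few extreme residuals, so allow a band
        assert 0.85 * floor <= mae <= 1.1 * floor

    def test_label_dropout_thins_schedule(self):
        cfg = GreenhouseSimConfig(label_dropout=0.5)
        table, _ = simulate_greenhouse(cfg, seed=21)
        split = split_by_pattern(table, "A")
        scheduled = 9 * 3 * int(np.ceil(83 / 3))
        labeled = split.labeled_counts["train"]
        assert 0.4 * scheduled < labeled < 0.6 * scheduled

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            GreenhouseSimConfig(label_period=0)
        with pytest.raises(ValueError):
            GreenhouseSimConfig(brix_noise=-1.0)


def scalar_params(**kw):
    defaults = dict(A=[[0.8]], B=[[0.3]], C_x=[[1.0]], C_y=[[0.7]],
                    Q=[[0.25]], R_x=[[0.2]], R_y=[[0.3]])
    defaults.update(kw)
    return LGSSMParams(**defaults)


class TestLinearGaussianSimulator:
    def test_near_zero_noise_matches_deterministic_recursion(self):
        params = scalar_params(Q=[[1e-16]], R_x=[[1e-16]], R_y=[[1e-16]])
        seqs = simulate_linear_gaussian(params, T=10, n_sequences=1, seed=0)
        s = seqs[0]
        z = 0.0
        for t in range(10):
            z = 0.8 * z + 0.3 * s["U"][t, 0]
            assert abs(s["z"][t, 0] - z) < 1e-6
            assert abs(s["x"][t] - z) < 1e-6
            assert abs(s["y"][t] - 0.7 * z) < 1e-6

    def test_state_moments_match_propagated_marginals(self):
        params = scalar_params()
        U = np.random.default_rng(1).standard_normal((1, 8, 1))
        n = 4000
        draws = simulate_linear_gaussian(
            params, T=8, n_sequences=n, seed=2,
            covariates=np.repeat(U, n, axis=0))
        Z = np.stack([d["z"][:, 0] for d in draws])
        means, covs = prior_marginals(params, U[0])
        sd = np.sqrt(covs[:, 0, 0])
        assert np.all(np.abs(Z.mean(0) - means[:, 0]) < 3 * sd / np.sqrt(n))
        var_se = np.sqrt(2.0 / n) * covs[:, 0, 0]
        assert np.all(np.abs(Z.var(0) - covs[:, 0, 0]) < 3 * var_se)

    def test_seed_reproducibility(self):
        params = scalar_params()
        a = simulate_linear_gaussian(params, T=5, n_sequences=2, seed=9)
        b = simulate_linear_gaussian(params, T=5, n_sequences=2, seed=9)
        for s1, s2 in zip(a, b):
            assert np.array_equal(s1["x"], s2["x"])
            assert np.array_equal(s1["z"], s2["z"])

    def test_label_period_masks_every_third_step(self):
        params = scalar_params()
        s = simulate_linear_gaussian(params, T=9, n_sequences=1, seed=0,
                                     label_period=3)[0]
        assert list(s["m"]) == [1, 0, 0, 1, 0, 0, 1, 0, 0]

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            LGSSMParams(A=[[0.5, 0.1]], B=[[0.3]], C_x=[[1.0]],
                        C_y=[[1.0]], Q=[[0.1]], R_x=[[0.1]], R_y=[[0.1]])
        with pytest.raises(ValueError):
            scalar_params(Q=[[-1.0]])


class TestKalmanOracle:
    def test_single_step_closed_form(self):
        # z ~ N(0,1), x = z + N(0,1): log p(x=0) = log N(0; 0, 2),
        # plus an independent y ~ N(0,1) channel that we subtract off
        params = LGSSMParams(A=[[0.0]], B=[[0.0]], C_x=[[1.0]],
                             C_y=[[0.0]], Q=[[1.0]], R_x=[[1.0]],
                             R_y=[[1.0]])
        seq = {"x": np.zeros(1), "m": np.ones(1), "y": np.zeros(1),
               "U": np.zeros((1, 1))}
        ll = kalman_loglik(params, [seq])[0]
        y_part = stats.norm(0, 1).logpdf(0.0)
        assert np.isclose(ll - y_part, stats.norm(0, np.sqrt(2)).logpdf(0.0))
        assert np.isclose(ll - y_part, -1.26551, atol=1e-5)

    def test_matches_dense_joint_gaussian(self):
        params = scalar_params()
        seq = simulate_linear_gaussian(params, T=3, n_sequences=1, seed=1)[0]
        ll = kalman_loglik(params, [seq])[0]

        A, B, Cx, Cy = 0.8, 0.3, 1.0, 0.7
        Q, Rx, Ry = 0.25, 0.2, 0.3
        T = 3
        mu_z = np.zeros(T)
        L = np.zeros((T, T))
        for t in range(T):
            mu_z[t] = A * (mu_z[t - 1] if t else 0.0) + B * seq["U"][t, 0]
            for k in range(t + 1):
                L[t, k] = A ** (t - k)
        Sz = L @ (Q * np.eye(T)) @ L.T
        H = np.zeros((2 * T, T))
        for t in range(T):
            H[t, t] = Cx
            H[T + t, t] = Cy
        mu_o = H @ mu_z
        S_o = H @ Sz @ H.T + np.diag([Rx] * T + [Ry] * T)
        obs = np.concatenate([seq["x"], seq["y"]])
        brute = stats.multivariate_normal(mu_o, S_o).logpdf(obs)
        assert abs(ll - brute) < 1e-9

    def test_missing_x_drops_that_emission_block(self):
        params = scalar_params()
        seq = simulate_linear_gaussian(params, T=4, n_sequences=1, seed=3,
                                       label_period=2)[0]
        ll = kalman_loglik(params, [seq])[0]
        assert np.isfinite(ll)
        # fully-observed likelihood of the same draws must differ
        dense = dict(seq)
        dense["m"] = np.ones(4)
        assert not np.isclose(kalman_loglik(params, [dense])[0], ll)

    def test_loglik_peaks_at_predictive_mean(self):
        params = scalar_params()
        base = simulate_linear_gaussian(params, T=1, n_sequences=1, seed=4)[0]
        # place the observation at the predictive mean, then shift it
        mean_pred = 0.3 * base["U"][0, 0]
        at_mean = dict(base, x=np.array([mean_pred]),
                       y=np.array([0.7 * mean_pred]))
        ll_mean = kalman_loglik(params, [at_mean])[0]
        for shift in (-1.0, 0.5, 2.0):
            shifted = dict(base, x=np.array([mean_pred + shift]),
                           y=np.array([0.7 * mean_pred]))
            assert kalman_loglik(params, [shifted])[0] <= ll_mean

    def test_smoother_consistent_with_filter_at_final_step(self):
        params = scalar_params()
        seq = simulate_linear_gaussian(params, T=6, n_sequences=1, seed=5)[0]
        _, fm, fP, sm, sP = kalman_filter(params, seq)
        assert np.allclose(fm[-1], sm[-1])
        assert np.allclose(fP[-1], sP[-1])
        # smoothing can only reduce marginal variance
        assert np.all(sP[:, 0, 0] <= fP[:, 0, 0] + 1e-12)
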