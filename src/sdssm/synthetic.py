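"""Synthetic greenhouse data with known ground truth, plus a linear-Gaussian
state-space special case with an exact Kalman filter/smoother/likelihood.

The greenhouse generator emulates the structure of a tomato water-stress
cultivation trial: 16 beds x 3 cultivation steps x 83 daily records, climate
covariates (seasonal temperature with AR(1) weather, correlated solar
radiation, VPD, CO2), growth covariates (elapsed days, accumulated
temperature), a dense stem-diameter channel and a sparse sugar-content
channel measured every third day.  Two ground-truth plant states drive the
emissions: a continuous water-content state w_t (AR(1), pushed down by VPD
and up by scheduled irrigation pulses) and a monotone growth-stage chain g_t
switched by accumulated-temperature thresholds.  Stem diameter reflects the
*instantaneous* water content on top of a growth trend whose rate is
depressed by *sustained* water deficit (growth integrates stress); sugar
content responds to the same sustained deficit — a slow exponential average
of -w_t — plus the growth stage, the agronomic signature of deficit
irrigation.  Because the stress integral is a function of the water-content
history, estimating sugar on unmeasured days requires tracking the latent
dynamics through the dense stem-diameter channel; a model trained on the
sparse measurement days alone cannot recover it from the instantaneous
observation.

The linear-Gaussian simulator and Kalman routines serve as the exact oracle
for the sequential ELBO machinery: the deep model with affine conditioners
contains this model class, so its bounds and posteriors can be compared to
closed-form answers.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .datamodel import SequenceTable

__all__ = [
    "GreenhouseSimConfig", "SimTruth", "simulate_greenhouse",
    "LGSSMParams", "simulate_linear_gaussian",
    "kalman_filter", "kalman_loglik", "prior_marginals",
]


@dataclass
class GreenhouseSimConfig:
    """Study-design and effect-size knobs of the greenhouse generator."""

    n_beds: int = 16
    n_steps: int = 3
    n_days: int = 83
    label_period: int = 3          # sugar measured every third day
    #: fraction of scheduled measurement days randomly skipped; the field
    #: campaign this emulates recorded roughly half of the nominal
    #: every-third-day schedule (about 380 labeled records per 9-bed
    #: training split rather than 756)
    label_dropout: float = 0.0
    brix_range: tuple = (4.67, 10.73)
    n_stages: int = 3
    start_date: str = "2017-08-28"
    # climate
    temp_start: float = 27.0       # degC, late-August mean
    temp_end: float = 14.0         # degC, mid-November mean
    temp_ar_rho: float = 0.7
    temp_ar_sigma: float = 1.2
    solar_sigma: float = 1.5       # MJ/m^2/day
    vpd_sigma: float = 0.08        # kPa
    co2_mean: float = 400.0        # ppm
    co2_sigma: float = 15.0
    # latent water content (AR(1) anomaly, unitless); the idiosyncratic
    # noise dominates the VPD coupling so the water path is not readable
    # from climate covariates alone
    w_rho: float = 0.85
    w_vpd_gain: float = 0.6        # VPD anomaly drawdown per kPa
    w_sigma: float = 0.35
    irrigation_period: int = 7     # days between irrigation pulses
    irrigation_amp: float = 0.45
    # emissions
    stem_base: float = 7.0         # mm at planting
    stem_growth: float = 3.0       # mm gained over the season
    stem_w_gain: float = 0.6       # mm per unit water content
    stem_stress_gain: float = 0.0  # mm lost per unit sustained deficit
    stem_noise: float = 0.5        # mm (daily-average effective noise)
    brix_stage_base: tuple = (5.4, 6.4, 7.3)
    stress_memory: float = 0.9     # EMA coefficient of sustained deficit
    brix_stress_gain: float = 2.0  # brix per unit sustained water deficit
    brix_bed_sigma: float = 0.15   # persistent bed-level brix offset
    brix_noise: float = 0.25

    def __post_init__(self):
        if not (self.n_days >= self.label_period >= 1):
            raise ValueError("need n_days >= label_period >= 1")
        if not 0.0 <= self.label_dropout < 1.0:
            raise ValueError("label_dropout must lie in [0, 1)")
        for name in ("temp_ar_sigma", "solar_sigma", "vpd_sigma", "co2_sigma",
                     "w_sigma", "stem_noise", "brix_noise"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_stages < 1:
            raise ValueError("n_stages must be at least 1")


@dataclass
class SimTruth:
    """Ground-truth latents and generator parameters of a simulated table."""

    water: dict = field(default_factory=dict)   # (bed, step) -> [T]
    stage: dict = field(default_factory=dict)   # (bed, step) -> [T] ints
    stress: dict = field(default_factory=dict)  # (bed, step) -> [T] EMA deficit
    bed_effect: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def save_json(self, path) -> None:
        payload = {
            "config": self.config,
            "bed_effect": {str(k): v for k, v in self.bed_effect.items()},
            "sequences": {
                f"{bed}:{step}": {
                    "water": np.asarray(self.water[(bed, step)]).tolist(),
                    "stage": np.asarray(self.stage[(bed, step)]).tolist(),
                    "stress": np.asarray(self.stress[(bed, step)]).tolist(),
                }
                for (bed, step) in self.water
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def simulate_greenhouse(config: GreenhouseSimConfig,
                        seed: int) -> tuple[SequenceTable, SimTruth]:
    """Generate one growing season; see the module docstring for the model."""
    cfg = config
    rng = np.random.default_rng(seed)
    T = cfg.n_days
    days = np.arange(T)
    season = days / max(T - 1, 1)
    dates = pd.date_range(cfg.start_date, periods=T).strftime("%Y-%m-%d")

    # stage thresholds split the expected season into n_stages equal parts
    expected_total = 0.5 * (cfg.temp_start + cfg.temp_end) * T
    thresholds = expected_total * (np.arange(1, cfg.n_stages) / cfg.n_stages)

    rows = []
    truth = SimTruth(config=asdict(cfg))
    bed_effects = rng.normal(0.0, cfg.brix_bed_sigma, size=cfg.n_beds)
    for bed in range(1, cfg.n_beds + 1):
        truth.bed_effect[bed] = float(bed_effects[bed - 1])
        for step in range(1, cfg.n_steps + 1):
            # climate: seasonal trend + AR(1) weather anomaly
            trend = cfg.temp_start + (cfg.temp_end - cfg.temp_start) * season
            anom = np.zeros(T)
            for t in range(1, T):
                anom[t] = (cfg.temp_ar_rho * anom[t - 1]
                           + rng.normal(0.0, cfg.temp_ar_sigma))
            temp = trend + anom
            solar = np.clip(18.0 - 11.0 * season + 0.6 * anom
                            + rng.normal(0.0, cfg.solar_sigma, T), 0.5, None)
            vpd = np.clip(0.25 + 0.035 * (temp - 10.0)
                          + rng.normal(0.0, cfg.vpd_sigma, T), 0.05, None)
            co2 = cfg.co2_mean + rng.normal(0.0, cfg.co2_sigma, T)
            accum = np.cumsum(temp)

            # latent water content: AR(1) driven by -VPD and irrigation
            pulse_phase = (bed + 2 * step) % cfg.irrigation_period
            w = np.zeros(T)
            vpd_anom = vpd - vpd.mean()
            for t in range(1, T):
                pulse = (cfg.irrigation_amp
                         if (t % cfg.irrigation_period) == pulse_phase else 0.0)
                w[t] = (cfg.w_rho * w[t - 1]
                        - cfg.w_vpd_gain * vpd_anom[t] + pulse
                        + rng.normal(0.0, cfg.w_sigma))

            # monotone growth stage from accumulated temperature
            stage = np.searchsorted(thresholds, accum)

            # sustained water deficit: slow EMA of -w (sugar integrates
            # stress over the fruit-development window)
            c = np.zeros(T)
            for t in range(1, T):
                c[t] = (cfg.stress_memory * c[t - 1]
                        + (1.0 - cfg.stress_memory) * (-w[t]))

            stem = (cfg.stem_base + cfg.stem_growth * accum / expected_total
                    + cfg.stem_w_gain * w - cfg.stem_stress_gain * c
                    + rng.normal(0.0, cfg.stem_noise, T))
            base = np.asarray(cfg.brix_stage_base, float)[
                np.minimum(stage, len(cfg.brix_stage_base) - 1)]
            brix = (base + cfg.brix_stress_gain * c
                    + bed_effects[bed - 1]
                    + rng.normal(0.0, cfg.brix_noise, T))
            brix = np.clip(brix, cfg.brix_range[0], cfg.brix_range[1])
            observed = (days % cfg.label_period) == 0
            if cfg.label_dropout > 0.0:
                observed = observed & (rng.random(T) >= cfg.label_dropout)
            sugar = np.where(observed, brix, np.nan)

            truth.water[(bed, step)] = w
            truth.stage[(bed, step)] = stage
            truth.stress[(bed, step)] = c
            rows.append(pd.DataFrame({
                "bed_id": bed, "step_id": step, "date": dates,
                "day_index": days,
                "temperature": temp, "solar_radiation": solar,
                "vpd": vpd, "co2": co2,
                "elapsed_days": days.astype(float), "accum_temp": accum,
                "stem_diameter": stem, "sugar_brix": sugar,
            }))
    return SequenceTable(pd.concat(rows, ignore_index=True)), truth


# ---------------------------------------------------------------------------
# linear-Gaussian state-space verification harness
# ---------------------------------------------------------------------------

@dataclass
class LGSSMParams:
    """z_t = A z_{t-1} + B u_t + N(0, Q);  x_t = C_x z_t + D_x s_t + N(0, R_x);
    y_t = C_y z_t + N(0, R_y);  z_0 = 0."""

    A: np.ndarray
    B: np.ndarray
    C_x: np.ndarray
    C_y: np.ndarray
    Q: np.ndarray          # process noise covariance [z, z]
    R_x: np.ndarray        # x observation noise covariance
    R_y: np.ndarray
    D_x: np.ndarray | None = None

    def __post_init__(self):
        self.A = np.atleast_2d(np.asarray(self.A, float))
        self.B = np.atleast_2d(np.asarray(self.B, float))
        self.C_x = np.atleast_2d(np.asarray(self.C_x, float))
        self.C_y = np.atleast_2d(np.asarray(self.C_y, float))
        self.Q = np.atleast_2d(np.asarray(self.Q, float))
        self.R_x = np.atleast_2d(np.asarray(self.R_x, float))
        self.R_y = np.atleast_2d(np.asarray(self.R_y, float))
        if self.D_x is not None:
            self.D_x = np.atleast_2d(np.asarray(self.D_x, float))
        z = self.A.shape[0]
        if self.A.shape != (z, z) or self.Q.shape != (z, z):
            raise ValueError("A and Q must be square with matching size")
        if self.B.shape[0] != z or self.C_x.shape[1] != z \
                or self.C_y.shape[1] != z:
            raise ValueError("B/C_x/C_y shapes inconsistent with state dim")
        for M in (self.Q, self.R_x, self.R_y):
            if np.any(np.diag(M) <= 0):
                raise ValueError("noise variances must be positive")

    @property
    def z_dim(self) -> int:
        return self.A.shape[0]

    @property
    def u_dim(self) -> int:
        return self.B.shape[1]


def simulate_linear_gaussian(params: LGSSMParams, T: int, n_sequences: int,
                             seed: int, covariates: np.ndarray | None = None,
                             label_period: int | None = None):
    """Ancestral draws from the LGSSM.

    Returns a list of dicts with keys ``x, m, y, U, S, z`` (z is the ground
    truth state path).  ``covariates``: optional [n_sequences, T, u_dim]
    control inputs; standard-normal draws when omitted.  ``label_period``
    masks x to every p-th day (None = fully observed).
    """
    rng = np.random.default_rng(seed)
    z_dim, u_dim = params.z_dim, params.u_dim
    dx, dy = params.C_x.shape[0], params.C_y.shape[0]
    if covariates is None:
        covariates = rng.standard_normal((n_sequences, T, u_dim))
    covariates = np.asarray(covariates, float)
    if covariates.shape != (n_sequences, T, u_dim):
        raise ValueError("covariates must have shape [n_sequences, T, u_dim]")
    Lq = np.linalg.cholesky(params.Q)
    Lx = np.linalg.cholesky(params.R_x)
    Ly = np.linalg.cholesky(params.R_y)
    sequences = []
    for i in range(n_sequences):
        z = np.zeros((T, z_dim))
        x = np.zeros((T, dx))
        y = np.zeros((T, dy))
        z_prev = np.zeros(z_dim)
        for t in range(T):
            z_t = (params.A @ z_prev + params.B @ covariates[i, t]
                   + Lq @ rng.standard_normal(z_dim))
            x[t] = params.C_x @ z_t + Lx @ rng.standard_normal(dx)
            y[t] = params.C_y @ z_t + Ly @ rng.standard_normal(dy)
            z[t] = z_t
            z_prev = z_t
        if label_period is None:
            m = np.ones(T)
        else:
            m = ((np.arange(T) % label_period) == 0).astype(float)
        sequences.append({
            "x": x[:, 0] * m if dx == 1 else x,
            "m": m,
            "y": y[:, 0] if dy == 1 else y,
            "U": covariates[i],
            "S": np.zeros((T, 0)),
            "R": np.zeros((T, 0)),
            "V": np.zeros((T, 0)),
            "z": z,
        })
    return sequences


def prior_marginals(params: LGSSMParams, U: np.ndarray):
    """Means and covariances of the unconditional state marginals p(z_t)."""
    T = U.shape[0]
    z = params.z_dim
    means = np.zeros((T, z))
    covs = np.zeros((T, z, z))
    m = np.zeros(z)
    P = np.zeros((z, z))
    for t in range(T):
        m = params.A @ m + params.B @ U[t]
        P = params.A @ P @ params.A.T + params.Q
        means[t], covs[t] = m, P
    return means, covs


def _observation_blocks(params: LGSSMParams, x_t, y_t, m_t, s_t=None):
    """Stack the observation channels available at one timestep."""
    rows, obs, noise = [], [], []
    offsets = []
    if m_t > 0:
        rows.append(params.C_x)
        off = np.zeros(params.C_x.shape[0])
        if params.D_x is not None and s_t is not None:
            off = params.D_x @ s_t
        offsets.append(off)
        obs.append(np.atleast_1d(np.asarray(x_t, float)))
        noise.append(params.R_x)
    rows.append(params.C_y)
    offsets.append(np.zeros(params.C_y.shape[0]))
    obs.append(np.atleast_1d(np.asarray(y_t, float)))
    noise.append(params.R_y)
    H = np.vstack(rows)
    c = np.concatenate(offsets)
    o = np.concatenate(obs)
    Rn = np.zeros((H.shape[0], H.shape[0]))
    i = 0
    for blk in noise:
        k = blk.shape[0]
        Rn[i:i + k, i:i + k] = blk
        i += k
    return H, c, o, Rn


def kalman_filter(params: LGSSMParams, seq: dict):
    """Exact filtering pass with prediction-error log-likelihood.

    ``seq`` needs keys x [T], m [T], y [T], U [T, u_dim] (and optionally
    S when D_x is set).  Missing x at a step simply drops that emission
    block.  Returns (loglik, filtered_means [T,z], filtered_covs [T,z,z],
    smoothed_means, smoothed_covs) where the smoother is Rauch-Tung-Striebel.
    """
    T = len(seq["y"])
    z = params.z_dim
    x = np.atleast_2d(np.asarray(seq["x"], float).reshape(T, -1))
    y = np.atleast_2d(np.asarray(seq["y"], float).reshape(T, -1))
    m_mask = np.asarray(seq["m"], float)
    U = np.asarray(seq["U"], float)
    S = np.asarray(seq.get("S", np.zeros((T, 0))), float)

    fm = np.zeros((T, z))
    fP = np.zeros((T, z, z))
    pm = np.zeros((T, z))
    pP = np.zeros((T, z, z))
    loglik = 0.0
    mean = np.zeros(z)
    P = np.zeros((z, z))
    for t in range(T):
        mean = params.A @ mean + params.B @ U[t]
        P = params.A @ P @ params.A.T + params.Q
        pm[t], pP[t] = mean, P
        H, c, o, Rn = _observation_blocks(params, x[t], y[t], m_mask[t],
                                          S[t] if S.shape[1] else None)
        innov_cov = H @ P @ H.T + Rn
        try:
            L = np.linalg.cholesky(innov_cov)
        except np.linalg.LinAlgError as err:
            raise FloatingPointError(
                "innovation covariance not positive definite") from err
        resid = o - (H @ mean + c)
        alpha = np.linalg.solve(L, resid)
        k = innov_cov.shape[0]
        loglik += float(-0.5 * (alpha @ alpha) - np.log(np.diag(L)).sum()
                        - 0.5 * k * np.log(2.0 * np.pi))
        K = P @ H.T @ np.linalg.inv(innov_cov)
        mean = mean + K @ resid
        P = (np.eye(z) - K @ H) @ P
        P = 0.5 * (P + P.T)
        fm[t], fP[t] = mean, P

    # Rauch-Tung-Striebel smoother
    sm = fm.copy()
    sP = fP.copy()
    for t in range(T - 2, -1, -1):
        G = fP[t] @ params.A.T @ np.linalg.inv(pP[t + 1])
        sm[t] = fm[t] + G @ (sm[t + 1] - pm[t + 1])
        sP[t] = fP[t] + G @ (sP[t + 1] - pP[t + 1]) @ G.T
    return loglik, fm, fP, sm, sP


def kalman_loglik(params: LGSSMParams, dataset) -> list[float]:
    """Exact marginal log-likelihood of each sequence in ``dataset``."""
    return [kalman_filter(params, seq)[0] for seq in dataset]
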