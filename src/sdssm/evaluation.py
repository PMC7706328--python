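"""Error metrics, uncertainty diagnostics, latent analysis and baselines.

Metrics follow the standard definitions: MAE, RMSE, and the relative errors
RAE = sum|e| / sum|y - ybar| and RSE = sum e^2 / sum (y - ybar)^2, whose
value is exactly 1 for the naive predictor that outputs the mean of the true
values.  Scoring is always restricted to timesteps with an observed sugar
measurement.

The difference-in-stem-diameter water-stress index is
DSD_i = max(SD_0..SD_i) - SD_i: subtracting from the running maximum removes
the monotone growth component and leaves only stress-induced shrinkage.

Baselines are a dropout-regularized multilayer perceptron on per-timestep
features and a stacked LSTM on sequences, both trained on labeled points
only, mirroring the conventional supervised alternatives to the
state-space models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from . import autodiff as ad
from .datamodel import (CovariateRouting, Scaler, SplitDataset, bundle_table,
                        standardize, split_by_pattern, stack_bundles)
from .models import SDSSM, VariantSpec
from .nn import Adam, Dense, Dropout, LSTMCell, clip_gradients
from .synthetic import GreenhouseSimConfig, simulate_greenhouse
from .training import TrainConfig, train
from .utils import seed_stream

__all__ = [
    "MetricsReport", "UncertaintyReport", "LatentAnalysis",
    "error_metrics", "dsd", "uncertainty_error_correlation",
    "latent_pca_correlations",
    "BaselineConfig", "BaselineResult", "fit_baseline",
    "prediction_mae", "semisupervised_benefit_experiment",
    "BASELINE_FEATURES",
]

#: per-timestep features fed to the MLP / sLSTM baselines
BASELINE_FEATURES = ("temperature", "solar_radiation", "vpd", "co2",
                     "elapsed_days", "accum_temp", "step_onehot",
                     "stem_diameter")


@dataclass
class MetricsReport:
    mae: float
    rmse: float
    rae: float
    rse: float
    n: int

    def to_dict(self) -> dict:
        return {"mae": self.mae, "rmse": self.rmse, "rae": self.rae,
                "rse": self.rse, "n": self.n}


@dataclass
class UncertaintyReport:
    pearson_r: float
    n: int


@dataclass
class LatentAnalysis:
    components: np.ndarray          # [n_pc, z_dim], orthonormal rows
    scores: np.ndarray              # [N, n_pc]
    explained_variance_ratio: np.ndarray
    corr_stem: np.ndarray           # correlation of each PC score with stem
    corr_dsd: np.ndarray


def error_metrics(y_true, y_pred) -> MetricsReport:
    """MAE / RMSE / RAE / RSE of predictions at observed sugar points."""
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same shape")
    n = y_true.size
    if n < 2:
        raise ValueError("error metrics need at least two points")
    err = y_pred - y_true
    mae = float(np.abs(err).mean())
    rmse = float(np.sqrt((err ** 2).mean()))
    dev = y_true - y_true.mean()
    abs_dev = np.abs(dev).sum()
    sq_dev = (dev ** 2).sum()
    if abs_dev == 0.0:
        warnings.warn("constant y_true: RAE/RSE undefined (NaN)",
                      RuntimeWarning, stacklevel=2)
        rae = rse = float("nan")
    else:
        rae = float(np.abs(err).sum() / abs_dev)
        rse = float((err ** 2).sum() / sq_dev)
    return MetricsReport(mae=mae, rmse=rmse, rae=rae, rse=rse, n=n)


def dsd(stem_diameter) -> np.ndarray:
    """Water-stress index: running max of stem diameter minus current value."""
    sd = np.asarray(stem_diameter, float)
    if sd.size == 0:
        raise ValueError("dsd needs at least one stem-diameter value")
    return np.maximum.accumulate(sd) - sd


def uncertainty_error_correlation(abs_errors, stds) -> UncertaintyReport:
    """Pearson correlation between predicted stds and absolute errors."""
    abs_errors = np.asarray(abs_errors, float)
    stds = np.asarray(stds, float)
    if abs_errors.shape != stds.shape:
        raise ValueError("inputs must share a shape")
    n = abs_errors.size
    if n < 3:
        raise ValueError("correlation needs at least three points")
    if np.std(abs_errors) == 0.0 or np.std(stds) == 0.0:
        warnings.warn("zero variance input: correlation undefined (NaN)",
                      RuntimeWarning, stacklevel=2)
        return UncertaintyReport(pearson_r=float("nan"), n=n)
    r = float(np.corrcoef(abs_errors, stds)[0, 1])
    return UncertaintyReport(pearson_r=r, n=n)


def latent_pca_correlations(latent_means, stem, dsd_vals,
                            n_components: int = 2) -> LatentAnalysis:
    """PCA of inferred latent means, correlated with stem diameter and DSD."""
    Z = np.asarray(latent_means, float)
    stem = np.asarray(stem, float)
    dsd_vals = np.asarray(dsd_vals, float)
    N, z_dim = Z.shape
    if N <= z_dim:
        raise ValueError("need more samples than latent dimensions")
    rank = np.linalg.matrix_rank(Z - Z.mean(axis=0))
    k = min(n_components, z_dim, rank)
    if k < n_components:
        warnings.warn(f"rank-deficient latents: returning {k} component(s)",
                      RuntimeWarning, stacklevel=2)
    pca = PCA(n_components=k)
    scores = pca.fit_transform(Z)

    def corr(a, b):
        if np.std(a) == 0 or np.std(b) == 0:
            return float("nan")
        return float(np.corrcoef(a, b)[0, 1])

    return LatentAnalysis(
        components=pca.components_,
        scores=scores,
        explained_variance_ratio=pca.explained_variance_ratio_,
        corr_stem=np.array([corr(scores[:, i], stem) for i in range(k)]),
        corr_dsd=np.array([corr(scores[:, i], dsd_vals) for i in range(k)]),
    )


# ---------------------------------------------------------------------------
# supervised baselines
# ---------------------------------------------------------------------------

@dataclass
class BaselineConfig:
    hidden: int = 64
    n_layers: int = 2
    dropout: float = 0.1
    epochs: int = 300
    lr: float = 1e-3
    seed: int = 0
    grad_clip: float = 10.0


@dataclass
class BaselineResult:
    kind: str
    test_predictions: list = field(default_factory=list)  # [T] per bundle
    test_bundles: list = field(default_factory=list)
    val_mae: float = float("nan")
    train_losses: list = field(default_factory=list)


def _baseline_routing() -> CovariateRouting:
    return CovariateRouting(u_cols=BASELINE_FEATURES)


class _MLPNet:
    def __init__(self, in_dim, cfg: BaselineConfig, rng):
        self.layers = []
        dim = in_dim
        for _ in range(cfg.n_layers):
            self.layers.append(Dense(dim, cfg.hidden, rng, activation="relu"))
            dim = cfg.hidden
        self.out = Dense(dim, 1, rng)
        self.drop = Dropout(cfg.dropout)

    def __call__(self, X, train, rng=None):
        h = X
        for layer in self.layers:
            h = self.drop(layer(h), train, rng)
        return self.out(h)

    def params(self):
        p = {}
        for i, layer in enumerate(self.layers):
            p.update(layer.params(f"mlp{i}."))
        p.update(self.out.params("out."))
        return p


class _SLSTMNet:
    def __init__(self, in_dim, cfg: BaselineConfig, rng):
        self.cells = []
        dim = in_dim
        for _ in range(cfg.n_layers):
            self.cells.append(LSTMCell(dim, cfg.hidden, rng))
            dim = cfg.hidden
        self.out = Dense(dim, 1, rng)
        self.drop = Dropout(cfg.dropout)

    def forward_sequence(self, X, train, rng=None):
        """X: [B, T, f] -> per-step predictions [B, T] (Tensor list)."""
        B, T, _ = X.shape
        states = [c.init_state(B) for c in self.cells]
        outs = []
        for t in range(T):
            h = X[:, t]
            for i, cell in enumerate(self.cells):
                h, states[i] = cell(h, states[i])
                h = self.drop(h, train, rng)
            outs.append(self.out(h))
        return outs

    def params(self):
        p = {}
        for i, cell in enumerate(self.cells):
            p.update(cell.params(f"lstm{i}."))
        p.update(self.out.params("out."))
        return p


def fit_baseline(kind: str, split: SplitDataset, config: BaselineConfig,
                 scaler: Scaler | None = None) -> BaselineResult:
    """Train a supervised baseline on labeled points of the training split.

    ``kind`` is "mlp" (per-timestep feedforward regressor) or "slstm"
    (stacked recurrent regressor).  Dropout is active during training only.
    Predictions are returned for every timestep of each test sequence, on
    the brix scale when ``scaler`` is given.
    """
    if kind not in ("mlp", "slstm"):
        raise ValueError("kind must be 'mlp' or 'slstm'")
    routing = _baseline_routing()
    train_bundles = bundle_table(split.train, routing)
    test_bundles = bundle_table(split.test, routing)
    val_bundles = bundle_table(split.val, routing)
    if not any(b.m.sum() for b in train_bundles):
        raise ValueError("no labeled points in the training split")
    rng = np.random.default_rng(seed_stream(config.seed, f"baseline-{kind}"))
    drop_rng = np.random.default_rng(seed_stream(config.seed, "dropout"))
    in_dim = train_bundles[0].U.shape[1]
    result = BaselineResult(kind=kind, test_bundles=test_bundles)

    if kind == "mlp":
        X = np.concatenate([b.U[b.m > 0] for b in train_bundles])
        t_ = np.concatenate([b.x[b.m > 0] for b in train_bundles])[:, None]
        net = _MLPNet(in_dim, config, rng)
        params = net.params()
        opt = Adam(params, lr=config.lr)
        for _ in range(config.epochs):
            pred = net(X, train=True, rng=drop_rng)
            loss = ad.mean_(ad.square(ad.sub(pred, t_)))
            opt.zero_grad()
            loss.backward()
            clip_gradients(params, config.grad_clip)
            opt.step()
            result.train_losses.append(float(ad.value_of(loss)))

        def predict(bundles):
            return [ad.value_of(net(b.U, train=False))[:, 0] for b in bundles]
    else:
        batches = stack_bundles(train_bundles)
        net = _SLSTMNet(in_dim, config, rng)
        params = net.params()
        opt = Adam(params, lr=config.lr)
        for _ in range(config.epochs):
            total, count = 0.0, 0.0
            for batch in batches:
                outs = net.forward_sequence(batch["U"], train=True,
                                            rng=drop_rng)
                for t, out in enumerate(outs):
                    m_t = batch["m"][:, t:t + 1]
                    resid = ad.sub(out, batch["x"][:, t:t + 1])
                    total = ad.add(total,
                                   ad.sum_(ad.mul(m_t, ad.square(resid))))
                    count += float(m_t.sum())
            loss = ad.div(total, max(count, 1.0))
            opt.zero_grad()
            loss.backward()
            clip_gradients(params, config.grad_clip)
            opt.step()
            result.train_losses.append(float(ad.value_of(loss)))

        def predict(bundles):
            preds = []
            for batch in stack_bundles(bundles):
                outs = net.forward_sequence(batch["U"], train=False)
                arr = np.stack([ad.value_of(o)[:, 0] for o in outs], axis=1)
                preds.extend(arr)
            return preds

    def to_brix(values):
        return (scaler.inverse_values("sugar_brix", values)
                if scaler is not None else np.asarray(values))

    result.test_predictions = [to_brix(p) for p in predict(test_bundles)]
    val_preds = predict(val_bundles)
    errs = []
    for b, p in zip(val_bundles, val_preds):
        obs = b.m > 0
        if obs.any():
            truth = to_brix(b.x[obs])
            errs.append(np.abs(truth - to_brix(p)[obs]))
    if errs:
        result.val_mae = float(np.concatenate(errs).mean())
    return result


# ---------------------------------------------------------------------------
# model scoring and the semisupervised-benefit experiment
# ---------------------------------------------------------------------------

def prediction_mae(model: SDSSM, bundles, scaler: Scaler | None = None,
                   n_samples: int = 16, seed: int = 0) -> float:
    """MAE of posterior-predictive sugar means at observed points only."""
    preds = model.predict_sugar(bundles, n_samples=n_samples, seed=seed,
                                scaler=scaler)
    errs = []
    for b, p in zip(bundles, preds):
        obs = b.m > 0
        if not obs.any():
            continue
        truth = b.x[obs]
        if scaler is not None:
            truth = scaler.inverse_values("sugar_brix", truth)
        errs.append(np.abs(truth - p.mean[obs]))
    if not errs:
        raise ValueError("no observed sugar points to score")
    return float(np.concatenate(errs).mean())


def semisupervised_benefit_experiment(
        n_replicates: int = 10, base_seed: int = 0,
        sim_config: GreenhouseSimConfig | None = None,
        variant_spec: VariantSpec | None = None,
        train_config: TrainConfig | None = None,
        pattern: str = "A") -> list[dict]:
    """Train semisupervised and supervised-only twins on fresh seasons.

    For each replicate a new sparse-label greenhouse season is simulated,
    split by beds, and the same architecture is trained twice from the same
    initialization — once with the full semisupervised objective over all
    daily records, once on the labeled-timestep subsequences only.  Both
    twins are selected by validation MAE and scored on the test beds at
    observed sugar points.  Returns one record per replicate with both test
    MAEs.
    """
    sim_config = sim_config or GreenhouseSimConfig()
    variant_spec = variant_spec or VariantSpec(
        variant="cont", z_dim=8, hidden_units=64, n_hidden=1)
    train_config = train_config or TrainConfig(
        epochs=200, lr=2e-3, beta_rate=1.0 / 200, alpha=1.0,
        seq_len=None, val_n_samples=6, val_every=5,
        impute_recognition_x=True)
    results = []
    for rep in range(n_replicates):
        rep_seed = seed_stream(base_seed, "replicate", rep)
        table, _ = simulate_greenhouse(sim_config, seed=rep_seed)
        split = split_by_pattern(table, pattern)
        split, scaler = standardize(split)
        routing = variant_spec.routing()
        test_bundles = bundle_table(split.test, routing)
        maes = {}
        for mode in ("semisupervised", "supervised"):
            model = SDSSM(variant_spec, seed=seed_stream(rep_seed, "init"))
            cfg = TrainConfig(**{**asdict_shallow(train_config),
                                 "mode": mode,
                                 "seed": seed_stream(rep_seed, mode)})
            train(model, split, cfg, scaler=scaler)
            maes[mode] = prediction_mae(
                model, test_bundles, scaler=scaler,
                n_samples=train_config.val_n_samples,
                seed=seed_stream(rep_seed, f"test-{mode}"))
        results.append({"replicate": rep,
                        "mae_semisupervised": maes["semisupervised"],
                        "mae_supervised": maes["supervised"],
                        "semisupervised_wins":
                            maes["semisupervised"] < maes["supervised"]})
    return results


def asdict_shallow(cfg) -> dict:
    return {k: getattr(cfg, k) for k in cfg.__dataclass_fields__}
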