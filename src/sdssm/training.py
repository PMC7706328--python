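"""Optimization loop: KL annealing, seeding, model selection, checkpoints.

Training maximizes the semisupervised objective by Adam with reparameterized
single-sample gradients.  The KL weight beta is annealed linearly, rising by
a fixed increment after each epoch from 0 and clamping at 1, which keeps the
early epochs reconstruction-dominated and avoids posterior collapse.  After
every epoch the model is scored by mean absolute error of its sugar
predictions on the validation split (original brix scale), and the epoch
with the lowest validation MAE is the checkpoint that training returns.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .datamodel import (Scaler, SplitDataset, bundle_table,
                        make_training_sequences)
from .models import SDSSM
from .nn import Adam, clip_gradients
from .objectives import LossBreakdown, objective_loss
from .utils import seed_stream

__all__ = ["TrainConfig", "TrainHistory", "TrainingDivergedError",
           "beta_schedule", "train"]


class TrainingDivergedError(RuntimeError):
    """Raised when the loss becomes non-finite; carries the LossBreakdown."""

    def __init__(self, epoch: int, breakdown: LossBreakdown):
        self.epoch = epoch
        self.breakdown = breakdown
        super().__init__(
            f"non-finite loss at epoch {epoch}: {asdict(breakdown)}")


def beta_schedule(epoch: int, rate: float = 1e-4) -> float:
    """KL weight beta = min(1, rate * epoch); epoch 0 gives beta = 0."""
    if epoch < 0:
        raise ValueError("epoch must be nonnegative")
    if rate <= 0:
        raise ValueError("annealing rate must be positive")
    return min(1.0, rate * epoch)


@dataclass
class TrainConfig:
    """Hyperparameters of one training run."""

    epochs: int = 100
    batch_size: int | None = None      # None = full batch per length group
    lr: float = 1e-3
    optimizer: str = "adam"
    beta_rate: float = 1e-4            # beta increment per epoch
    alpha: float = 0.1                 # regression-term weight
    mc_samples: int = 1
    seed: int = 0
    mode: str = "semisupervised"       # or "supervised" (SV baselines)
    seq_len: int | None = None         # window length (None = full sequences)
    stride: int | None = None
    grad_clip: float = 10.0
    patience: int | None = None        # early stop on validation MAE
    val_n_samples: int = 8
    val_every: int = 1                 # validate every k-th epoch
    use_observed_x_at_eval: bool = False
    impute_recognition_x: bool = False # condition recognition on q(x|y)
                                       # draws even where x is observed

    def __post_init__(self):
        if self.beta_rate <= 0:
            raise ValueError("beta_rate must be positive")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is provided")


@dataclass
class TrainHistory:
    """Per-epoch loss components and validation metrics."""

    epochs: list = field(default_factory=list)  # list of dict records
    best_epoch: int = -1
    best_val_mae: float = float("inf")

    def append(self, record: dict) -> None:
        self.epochs.append(record)

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for rec in self.epochs:
                fh.write(json.dumps(rec) + "\n")


def _validation_mae(model: SDSSM, val_bundles, scaler: Scaler | None,
                    config: TrainConfig, epoch: int) -> float:
    was_trained = model.trained
    model.trained = True  # allow prediction mid-training
    try:
        preds = model.predict_sugar(
            val_bundles, n_samples=config.val_n_samples,
            seed=seed_stream(config.seed, "val", epoch), scaler=scaler,
            use_observed_x=config.use_observed_x_at_eval)
    finally:
        model.trained = was_trained
    errs = []
    for bundle, pred in zip(val_bundles, preds):
        obs = bundle.m > 0
        if not obs.any():
            continue
        truth = bundle.x[obs]
        if scaler is not None:
            truth = scaler.inverse_values("sugar_brix", truth)
        errs.append(np.abs(truth - pred.mean[obs]))
    if not errs:
        return float("nan")
    return float(np.concatenate(errs).mean())


def train(model: SDSSM, split: SplitDataset, config: TrainConfig,
          scaler: Scaler | None = None) -> TrainHistory:
    """Jointly optimize generative and recognition parameters.

    The split should already be standardized (with ``scaler`` carrying the
    training statistics so validation MAE is reported in brix).  The model
    is left holding the parameters of the epoch with the lowest validation
    MAE and marked trained.
    """
    if config.mode not in ("semisupervised", "supervised"):
        raise ValueError("mode must be 'semisupervised' or 'supervised'")
    routing = model.spec.routing()
    train_bundles = bundle_table(split.train, routing)
    if not train_bundles:
        raise ValueError("training split is empty")
    if config.mode == "supervised":
        # SV baselines: the chain is trained on labeled timesteps only
        train_bundles = [b.labeled_subsequence() for b in train_bundles]
        train_bundles = [b for b in train_bundles if b.T >= 2]
        if not train_bundles:
            raise ValueError("supervised mode needs labeled training points")
    val_bundles = bundle_table(split.val, routing)
    if config.seq_len is not None:
        windows = make_training_sequences(train_bundles, config.seq_len,
                                          config.stride)
    else:
        windows = train_bundles

    params = model.params()
    optimizer = Adam(params, lr=config.lr)
    shuffle_rng = np.random.default_rng(seed_stream(config.seed, "shuffle"))
    history = TrainHistory()
    best_values = model.param_values()
    since_best = 0

    for epoch in range(config.epochs):
        beta = beta_schedule(epoch, config.beta_rate)
        order = shuffle_rng.permutation(len(windows))
        shuffled = [windows[i] for i in order]
        if config.batch_size is None:
            chunks = [shuffled]
        else:
            chunks = [shuffled[i:i + config.batch_size]
                      for i in range(0, len(shuffled), config.batch_size)]
        epoch_bd = None
        for i, chunk in enumerate(chunks):
            loss, bd = objective_loss(
                model, chunk, alpha=config.alpha, beta=beta,
                seed=seed_stream(config.seed, "noise",
                                 epoch * 10000 + i),
                mc_samples=config.mc_samples, train=True,
                impute_recognition_x=config.impute_recognition_x)
            if not bd.is_finite():
                raise TrainingDivergedError(epoch, bd)
            optimizer.zero_grad()
            loss.backward()
            clip_gradients(params, config.grad_clip)
            optimizer.step()
            epoch_bd = bd
        if epoch % config.val_every == 0 or epoch == config.epochs - 1:
            val_mae = _validation_mae(model, val_bundles, scaler, config,
                                      epoch)
        else:
            val_mae = float("nan")
        record = {"epoch": epoch, "beta": beta, "alpha": config.alpha,
                  "val_mae": val_mae}
        record.update({k: getattr(epoch_bd, k) for k in
                       ("recon_x", "recon_y", "kl_z", "kl_d", "entropy_x",
                        "regression", "elbo", "total")})
        history.append(record)
        if np.isfinite(val_mae) and val_mae < history.best_val_mae:
            history.best_val_mae = val_mae
            history.best_epoch = epoch
            best_values = model.param_values()
            since_best = 0
        else:
            since_best += 1
        if config.patience is not None and since_best > config.patience:
            break

    model.set_param_values(best_values)
    model.trained = True
    return history
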