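"""The optimization loop: stochastic patch training with per-epoch
whole-volume validation and best-checkpoint selection.

Defaults mirror the published recipe (Adam, lr 1e-4, weight decay 1e-5,
cosine annealing stepped per epoch, Dice loss, 100k iterations); the desk
presets used in tests shrink the iteration count, patch size and network
width, not the procedure. An "epoch" here is an iteration budget
(``epoch_length``) because stochastic patch sampling has no natural pass
over the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .errors import ConfigurationError, TrainingDivergedError
from .grid import MultiparametricStudy
from .infer_eval import InferenceConfig, sliding_window_predict
from .losses import LOSSES, tversky_loss
from .models import MultiHeadResUNet
from .nn import Adam, Tensor, cosine_annealing_lr
from .preprocess import AugmentConfig, PatchSpec, augment, sample_patch


class TrainConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    iterations: int = 100_000
    batch_size: int = 2
    loss: Literal["dice", "dice_ce", "tversky"] = "dice"
    tversky_alpha: float = 0.3
    tversky_beta: float = 0.7
    lr0: float = 1e-4
    weight_decay: float = 1e-5
    epoch_length: int = 250
    seed: int = 0
    patch_size: tuple[int, int, int] = (256, 256, 16)
    augment_probability: float = 1.0
    run_validation: bool = True

    @model_validator(mode="after")
    def _check(self):
        if self.lr0 <= 0:
            raise ValueError("lr0 must be > 0")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.tversky_alpha + self.tversky_beta <= 0:
            raise ValueError("tversky_alpha + tversky_beta must be > 0")
        if self.batch_size < 1 or self.epoch_length < 1:
            raise ValueError("batch_size and epoch_length must be >= 1")
        return self


@dataclass
class TrainHistory:
    loss: list[float] = field(default_factory=list)           # per iteration
    lr: list[float] = field(default_factory=list)             # per epoch
    val_dsc: list[float] = field(default_factory=list)        # per epoch
    best_epoch: int = -1
    best_val_dsc: float = -np.inf


@dataclass
class TrainResult:
    model: MultiHeadResUNet
    best_state: dict[str, np.ndarray]
    history: TrainHistory
    config: TrainConfig


def _make_loss(cfg: TrainConfig):
    if cfg.loss == "tversky":
        return lambda p, g: tversky_loss(p, g, alpha=cfg.tversky_alpha,
                                         beta=cfg.tversky_beta)
    return LOSSES[cfg.loss]


def _whole_volume_dsc(model, study: MultiparametricStudy,
                      infer_cfg: InferenceConfig, channels: Sequence[str]) -> float:
    probs = sliding_window_predict(model, study, infer_cfg, channel_names=channels)
    pred = probs >= infer_cfg.threshold
    ref = np.asarray(study.mask.data, dtype=bool)
    denom = pred.sum() + ref.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float(np.logical_and(pred, ref).sum()) / float(denom)


def train(model: MultiHeadResUNet,
          train_studies: list[MultiparametricStudy],
          val_studies: list[MultiparametricStudy],
          config: TrainConfig,
          infer_cfg: InferenceConfig | None = None) -> TrainResult:
    """Run the seeded patch-sampling / augment / forward / loss / step loop.

    After each epoch the model is validated by sliding-window inference on
    whole volumes (mean DSC) and the best-performing weights are kept.
    Two runs with identical inputs and seeds produce identical histories.
    """
    if not train_studies:
        raise ConfigurationError("empty training split")
    if config.run_validation and not val_studies:
        raise ConfigurationError("empty validation split (set run_validation=False to skip)")
    channels = list(model.config.input_channels)
    rng = np.random.default_rng(config.seed)
    patch_spec = PatchSpec(size_voxels=config.patch_size)
    aug_cfg = AugmentConfig(probability=config.augment_probability)
    loss_fn = _make_loss(config)
    if infer_cfg is None:
        infer_cfg = InferenceConfig(patch_size=config.patch_size)

    optimizer = Adam(model.parameters(), lr=config.lr0,
                     weight_decay=config.weight_decay)
    total_epochs = int(np.ceil(config.iterations / config.epoch_length))
    history = TrainHistory()
    best_state = model.state_dict()

    iteration = 0
    for epoch in range(total_epochs):
        lr = cosine_annealing_lr(config.lr0, epoch, total_epochs)
        optimizer.lr = lr
        history.lr.append(lr)
        epoch_iters = min(config.epoch_length, config.iterations - iteration)
        for _ in range(epoch_iters):
            xs, gs = [], []
            for _ in range(config.batch_size):
                study = train_studies[int(rng.integers(0, len(train_studies)))]
                patch = sample_patch(study, patch_spec, rng, channel_names=channels)
                patch = augment(patch, rng, aug_cfg)
                xs.append(patch.channels)
                gs.append(patch.mask)
            x = Tensor(np.stack(xs).astype(np.float32))
            g = np.stack(gs)[:, None].astype(np.float32)
            optimizer.zero_grad()
            logits = model(x)
            loss = loss_fn(logits.sigmoid(), g)
            value = loss.item()
            if not np.isfinite(value):
                raise TrainingDivergedError(
                    f"non-finite loss {value} at iteration {iteration} "
                    f"(epoch {epoch}, lr {lr:.3e})")
            loss.backward()
            optimizer.step()
            history.loss.append(value)
            iteration += 1
        if config.run_validation:
            scores = [_whole_volume_dsc(model, s, infer_cfg, channels)
                      for s in val_studies]
            val_dsc = float(np.mean(scores))
            history.val_dsc.append(val_dsc)
            if val_dsc > history.best_val_dsc:
                history.best_val_dsc = val_dsc
                history.best_epoch = epoch
                best_state = model.state_dict()
    if not config.run_validation:
        best_state = model.state_dict()
    return TrainResult(model=model, best_state=best_state, history=history,
                       config=config)


def select_best_epoch(val_dsc: Sequence[float]) -> int:
    """Index of the checkpoint the loop keeps: first strict maximum."""
    best, best_i = -np.inf, -1
    for i, v in enumerate(val_dsc):
        if v > best:
            best, best_i = v, i
    return best_i
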