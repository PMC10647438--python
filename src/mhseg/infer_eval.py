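"""Whole-volume sliding-window inference and segmentation metrics.

Inference tiles the (reflect-padded) volume with overlapping patches
(default 75% overlap), averages the per-window probabilities uniformly at
every voxel, and crops back to the input shape.

Metrics per (prediction, reference) pair: Dice similarity coefficient
(DSC), 95th-percentile Hausdorff distance (HD95, mm), mean surface
distance (MSD, mm), and signed relative volume difference (RVD, %;
negative = the prediction underestimates the reference volume). Surfaces
are 6-connectivity border voxels; distances are voxel-center distances in
mm; HD95/MSD are taken over the pooled bidirectional surface-distance
multiset (a symmetric convention — stated here because several exist).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator
from scipy.ndimage import binary_erosion, generate_binary_structure
from scipy.spatial import cKDTree

from .errors import ValidationError
from .grid import MultiparametricStudy

Predictor = Callable[[np.ndarray], np.ndarray]  # (C,X,Y,Z) -> (1,X,Y,Z) logits


class InferenceConfig(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    patch_size: tuple[int, int, int] = (256, 256, 16)
    overlap_fraction: float = 0.75
    aggregation: str = "mean"
    threshold: float = 0.5

    @model_validator(mode="after")
    def _check(self):
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        if self.aggregation != "mean":
            raise ValueError("only uniform mean aggregation is implemented")
        return self


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _window_starts(padded: int, patch: int, stride: int) -> list[int]:
    starts = list(range(0, padded - patch + 1, stride))
    if starts[-1] != padded - patch:  # flush final window
        starts.append(padded - patch)
    return starts


def sliding_window_predict(model, channels: np.ndarray | MultiparametricStudy,
                           cfg: InferenceConfig,
                           channel_names: Sequence[str] | None = None) -> np.ndarray:
    """Per-voxel foreground probability over a whole volume.

    ``model`` is anything exposing ``predict_logits((C,X,Y,Z)) ->
    (1,X,Y,Z)`` (or a bare callable with that signature). Every voxel's
    probability is the uniform mean over all windows covering it.
    """
    if isinstance(channels, MultiparametricStudy):
        if channel_names is None and hasattr(model, "config"):
            channel_names = model.config.input_channels
        channels = channels.channel_stack(channel_names)
    x = np.asarray(channels, dtype=np.float64)
    if x.ndim != 4:
        raise ValidationError(f"expected (C, X, Y, Z), got {x.shape}", field="channels")
    predict = model.predict_logits if hasattr(model, "predict_logits") else model
    if hasattr(model, "config") and x.shape[0] != len(model.config.input_channels):
        raise ValidationError(
            f"model expects channels {model.config.input_channels}, got {x.shape[0]}",
            field="channels")

    patch = cfg.patch_size
    stride = tuple(max(1, int(round(p * (1.0 - cfg.overlap_fraction)))) for p in patch)
    spatial = x.shape[1:]
    # reflect-pad so every axis fits at least one window and tiles flush
    padded = tuple(max(p, s) for p, s in zip(patch, spatial))
    pads = [(0, 0)] + [(0, pd - s) for pd, s in zip(padded, spatial)]
    xp = np.pad(x, pads, mode="reflect") if any(p != (0, 0) for p in pads) else x

    prob_sum = np.zeros(padded, dtype=np.float64)
    count = np.zeros(padded, dtype=np.float64)
    for sx in _window_starts(padded[0], patch[0], stride[0]):
        for sy in _window_starts(padded[1], patch[1], stride[1]):
            for sz in _window_starts(padded[2], patch[2], stride[2]):
                sl = (slice(sx, sx + patch[0]), slice(sy, sy + patch[1]),
                      slice(sz, sz + patch[2]))
                logits = np.asarray(predict(xp[(slice(None),) + sl]))
                prob_sum[sl] += _sigmoid(logits[0])
                count[sl] += 1.0
    assert count.min() >= 1.0
    probs = prob_sum / count
    return probs[tuple(slice(0, s) for s in spatial)]


# ---------------------------------------------------------------------------
# metrics


@dataclass
class SegmentationMetrics:
    dsc: float
    hd95_mm: float
    msd_mm: float
    rvd_percent: float
    degenerate: str | None = None  # None | both_empty | reference_empty | prediction_empty

    def as_dict(self) -> dict:
        return {"dsc": self.dsc, "hd95_mm": self.hd95_mm, "msd_mm": self.msd_mm,
                "rvd_percent": self.rvd_percent, "degenerate": self.degenerate}


_STRUCT6 = generate_binary_structure(3, 1)


def _surface_points(mask: np.ndarray, spacing: Sequence[float]) -> np.ndarray:
    border = mask & ~binary_erosion(mask, structure=_STRUCT6, border_value=0)
    idx = np.argwhere(border)
    return idx * np.asarray(spacing, dtype=np.float64)


def compute_metrics(pred_mask: np.ndarray, ref_mask: np.ndarray,
                    spacing_mm: Sequence[float]) -> SegmentationMetrics:
    """All four metrics for one binary (prediction, reference) pair."""
    p = np.asarray(pred_mask).astype(bool)
    r = np.asarray(ref_mask).astype(bool)
    if p.shape != r.shape:
        raise ValidationError(f"mask shapes differ: {p.shape} vs {r.shape}", field="masks")
    np_, nr = int(p.sum()), int(r.sum())
    if np_ == 0 and nr == 0:
        return SegmentationMetrics(1.0, 0.0, 0.0, 0.0, degenerate="both_empty")
    if nr == 0:
        return SegmentationMetrics(0.0, float("nan"), float("nan"), float("nan"),
                                   degenerate="reference_empty")
    dsc = 2.0 * float(np.logical_and(p, r).sum()) / (np_ + nr)
    rvd = 100.0 * (np_ - nr) / nr
    if np_ == 0:
        return SegmentationMetrics(0.0, float("nan"), float("nan"), rvd,
                                   degenerate="prediction_empty")
    sp = _surface_points(p, spacing_mm)
    sr = _surface_points(r, spacing_mm)
    d_pr = cKDTree(sr).query(sp)[0]
    d_rp = cKDTree(sp).query(sr)[0]
    pooled = np.concatenate([d_pr, d_rp])
    return SegmentationMetrics(dsc, float(np.percentile(pooled, 95)),
                               float(pooled.mean()), rvd)


def _bootstrap_ci(values: np.ndarray, rng: np.random.Generator,
                  n_boot: int = 1000, level: float = 0.95) -> tuple[float, float]:
    values = values[np.isfinite(values)]
    if len(values) == 0:
        return (float("nan"), float("nan"))
    if len(values) == 1:
        return (float(values[0]), float(values[0]))
    medians = np.median(values[rng.integers(0, len(values), size=(n_boot, len(values)))],
                        axis=1)
    lo, hi = np.percentile(medians, [(1 - level) / 2 * 100, (1 + level) / 2 * 100])
    return float(lo), float(hi)


METRIC_COLUMNS = ["dsc", "hd95_mm", "msd_mm", "rvd_percent"]


def evaluate_masks(pairs: dict[str, tuple[np.ndarray, np.ndarray]],
                   spacing_mm: Sequence[float], seed: int = 0,
                   n_boot: int = 1000) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-study metrics plus median and percentile-bootstrap CIs.

    ``pairs`` maps study_id -> (prediction, reference). Returns
    (per-study table, summary table).
    """
    rows = []
    for sid, (pred, ref) in pairs.items():
        m = compute_metrics(pred, ref, spacing_mm)
        rows.append({"study_id": sid, **m.as_dict()})
    per_study = pd.DataFrame(rows, columns=["study_id", *METRIC_COLUMNS, "degenerate"])
    rng = np.random.default_rng(seed)
    summary_rows = []
    for col in METRIC_COLUMNS:
        vals = per_study[col].to_numpy(dtype=np.float64)
        lo, hi = _bootstrap_ci(vals, rng, n_boot=n_boot)
        summary_rows.append({"metric": col, "median": float(np.nanmedian(vals)),
                             "ci_lo": lo, "ci_hi": hi,
                             "n": int(np.isfinite(vals).sum())})
    return per_study, pd.DataFrame(summary_rows, columns=["metric", "median",
                                                          "ci_lo", "ci_hi", "n"])


def evaluate_cohort(model, studies: list[MultiparametricStudy],
                    cfg: InferenceConfig,
                    channel_names: Sequence[str] | None = None,
                    seed: int = 0, n_boot: int = 1000
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sliding-window inference + metrics over a list of studies."""
    if not studies:
        raise ValidationError("no studies to evaluate", field="studies")
    pairs = {}
    spacing = studies[0].grid.spacing
    for study in studies:
        probs = sliding_window_predict(model, study, cfg, channel_names=channel_names)
        pred = probs >= cfg.threshold
        pairs[study.study_id] = (pred, np.asarray(study.mask.data, dtype=bool))
    return evaluate_masks(pairs, spacing, seed=seed, n_boot=n_boot)
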