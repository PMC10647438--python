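"""Channel-sensitivity analysis: sequential channel dropout and 3D
Grad-CAM saliency.

Channel dropout zeroes one (normalized) input channel at a time at test
time and re-measures the four segmentation metrics; since channels are
z-scored, zero corresponds to the channel mean in original units.

Grad-CAM for segmentation: the target scalar is the sum of foreground
logits over the voxels the model predicts positive; gradients of that
scalar w.r.t. a chosen convolutional layer's feature maps are averaged
spatially into per-map weights, the rectified weighted sum of the maps is
trilinearly upsampled to the input grid and min-max normalized to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import zoom

from .errors import ValidationError
from .grid import MultiparametricStudy, VolumeGrid
from .infer_eval import (METRIC_COLUMNS, InferenceConfig, compute_metrics,
                         sliding_window_predict)
from .models import MultiHeadResUNet
from .nn import Tensor


def channel_dropout_eval(model: MultiHeadResUNet,
                         studies: list[MultiparametricStudy],
                         cfg: InferenceConfig) -> pd.DataFrame:
    """Median metrics per dropout condition (baseline row ``none`` first).

    Deterministic: inference has no randomness, so re-running reproduces
    the table bit-for-bit.
    """
    if not studies:
        raise ValidationError("no studies given", field="studies")
    channels = list(model.config.input_channels)
    spacing = studies[0].grid.spacing
    stacks = {s.study_id: (s.channel_stack(channels),
                           np.asarray(s.mask.data, dtype=bool)) for s in studies}
    rows = []
    for condition in ["none"] + channels:
        if condition != "none" and condition not in channels:
            raise ValidationError(f"channel {condition!r} not in model inputs",
                                  field="channel")
        per_metric = {c: [] for c in METRIC_COLUMNS}
        for stack, ref in stacks.values():
            x = stack.copy()
            if condition != "none":
                x[channels.index(condition)] = 0.0
            probs = sliding_window_predict(model, x, cfg)
            m = compute_metrics(probs >= cfg.threshold, ref, spacing)
            for c in METRIC_COLUMNS:
                per_metric[c].append(getattr(m, c if c != "dsc" else "dsc"))
        rows.append({"dropout": condition,
                     **{c: float(np.nanmedian(per_metric[c])) for c in METRIC_COLUMNS},
                     "n": len(stacks)})
    return pd.DataFrame(rows, columns=["dropout", *METRIC_COLUMNS, "n"])


@dataclass
class SaliencyMap:
    """Per-voxel relevance in [0, 1] on the input grid."""

    values: VolumeGrid
    source_layer: str
    dropout_condition: str = "none"
    degenerate: bool = False


def gradcam3d(model: MultiHeadResUNet, study_input: np.ndarray,
              layer: str | None = None,
              spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
              dropout_condition: str = "none",
              target: str = "predicted") -> SaliencyMap:
    """3D Grad-CAM saliency from a named layer's feature maps.

    ``study_input`` is a (C, X, Y, Z) array matching the model's channel
    set (a center-cropped patch in typical use). ``layer`` defaults to the
    model's penultimate decoder block. ``target`` selects the scalar:
    ``predicted`` sums foreground logits over the predicted-positive
    voxels (standard segmentation adaptation); ``all`` sums every voxel.
    """
    layer = layer or model.penultimate_layer
    modules = dict(model.named_modules())
    if layer not in modules:
        raise ValidationError(f"no layer named {layer!r}; see named_modules()",
                              field="layer")
    arr = np.asarray(study_input, dtype=np.float32)
    # reflect-pad up to the network's tiling unit (2^depth) and crop back
    mult = 16
    spatial_in = arr.shape[1:]
    pads = [(0, 0)] + [(0, (-s) % mult) for s in spatial_in]
    if any(p != (0, 0) for p in pads):
        arr = np.pad(arr, pads, mode="reflect")
    x = Tensor(arr[None])
    model.zero_grad()
    logits = model(x)
    feat = modules[layer]._last_output
    if feat is None or feat.ndim != 5:
        raise ValidationError(f"layer {layer!r} did not emit spatial feature maps",
                              field="layer")
    if target == "predicted":
        sel = (logits.data > 0.0).astype(logits.data.dtype)  # sigmoid(z)>0.5 <=> z>0
    else:
        sel = np.ones_like(logits.data)
    spatial = arr.shape[1:]
    if not sel.any():
        return SaliencyMap(VolumeGrid(np.zeros(spatial_in), spacing), layer,
                           dropout_condition, degenerate=True)
    logits.backward(sel)
    grads = feat.grad[0]          # (C, x', y', z')
    acts = feat.data[0]
    weights = grads.mean(axis=(1, 2, 3))
    cam = np.maximum((weights[:, None, None, None] * acts).sum(axis=0), 0.0)
    if cam.shape != spatial:
        cam = zoom(cam, [t / c for t, c in zip(spatial, cam.shape)], order=1,
                   mode="nearest", grid_mode=True)
    cam = cam[tuple(slice(0, s) for s in spatial_in)]
    peak = cam.max()
    if peak <= 0:
        return SaliencyMap(VolumeGrid(np.zeros(spatial_in), spacing), layer,
                           dropout_condition, degenerate=True)
    return SaliencyMap(VolumeGrid(cam / peak, spacing), layer, dropout_condition)
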