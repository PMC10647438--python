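"""Resampling, intensity normalization, patch sampling, and augmentation.

Pipeline order is fixed: resample -> normalize -> (training only)
patch-sample -> augment. Patch sampling only selects a window; it never
alters voxel values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import center_of_mass, zoom

from .errors import SamplingError, ValidationError
from .grid import MultiparametricStudy, VolumeGrid

#: channels resampled with nearest-neighbor interpolation: quantitative
#: maps (ADC) keep their original discrete values, masks stay categorical
NEAREST_CHANNELS = ("adc",)


@dataclass
class PatchSpec:
    """Training sub-volume shape; anisotropic by design (in-plane focus)."""

    size_voxels: tuple[int, int, int] = (256, 256, 16)
    require_tumor: bool = True

    def __post_init__(self):
        if any(s < 1 for s in self.size_voxels):
            raise ValidationError("all patch dimensions must be >= 1", field="size_voxels")


def resample_volume(volume: VolumeGrid, target_spacing: Sequence[float],
                    order: int) -> VolumeGrid:
    target_spacing = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target_spacing):
        raise ValidationError("target spacing must be positive", field="target_spacing")
    factors = [a / b for a, b in zip(volume.spacing, target_spacing)]
    if np.allclose(factors, 1.0):
        return VolumeGrid(volume.data.copy(), target_spacing, volume.origin)
    data = zoom(np.asarray(volume.data, dtype=np.float64), factors, order=order,
                mode="grid-constant", grid_mode=True)
    return VolumeGrid(data, target_spacing, volume.origin)


def resample_study(study: MultiparametricStudy,
                   target_spacing: Sequence[float]) -> MultiparametricStudy:
    """Resample all channels and the mask to one grid at ``target_spacing``.

    t2w and DWI signal channels use linear interpolation (smooth intensity
    transitions); ADC and the mask use nearest neighbor (quantitative /
    categorical values preserved). The mask stays binary.
    """
    channels = {}
    for name, vol in study.channels.items():
        order = 0 if name in NEAREST_CHANNELS else 1
        channels[name] = resample_volume(vol, target_spacing, order=order)
    mask = resample_volume(study.mask, target_spacing, order=0)
    mask = mask.with_data(mask.data.astype(np.uint8))
    return MultiparametricStudy(study.study_id, channels, mask, dict(study.meta))


def normalize_channel(volume: VolumeGrid) -> VolumeGrid:
    """Zero-mean, unit-variance over the whole volume."""
    data = np.asarray(volume.data, dtype=np.float64)
    if data.size <= 1:
        raise ValidationError("volume must have more than one voxel", field="volume")
    std = data.std()
    if std == 0:
        raise ValidationError("constant volume cannot be normalized", field="volume")
    return volume.with_data((data - data.mean()) / std)


def normalize_study(study: MultiparametricStudy) -> MultiparametricStudy:
    """Each channel independently normalized; the mask is untouched."""
    channels = {name: normalize_channel(vol) for name, vol in study.channels.items()}
    return MultiparametricStudy(study.study_id, channels, study.mask, dict(study.meta))


def _pad_to(arr: np.ndarray, size: Sequence[int]) -> np.ndarray:
    # symmetric zero padding when the volume is smaller than the patch
    pads = []
    for dim, target in zip(arr.shape, size):
        short = max(0, target - dim)
        pads.append((short // 2, short - short // 2))
    if any(p != (0, 0) for p in pads):
        arr = np.pad(arr, pads)
    return arr


@dataclass
class Patch:
    """A training sample: stacked channels plus the matching mask window."""

    channels: np.ndarray  # (C, px, py, pz)
    mask: np.ndarray      # (px, py, pz), uint8
    corner: tuple[int, int, int]
    channel_names: tuple[str, ...]


MAX_PATCH_ATTEMPTS = 100


def sample_patch(study: MultiparametricStudy, spec: PatchSpec,
                 rng: np.random.Generator,
                 channel_names: Sequence[str] | None = None) -> Patch:
    """Draw one stochastic sub-volume of exactly ``spec.size_voxels``.

    When ``require_tumor`` is set, rejection-samples until at least one
    z-slice of the patch mask is non-empty (bounded attempts, then falls
    back to centering on the tumor centroid).
    """
    names = tuple(channel_names) if channel_names is not None else tuple(study.channel_names)
    stack = study.channel_stack(names)
    mask = np.asarray(study.mask.data, dtype=np.uint8)
    if spec.require_tumor and mask.sum() == 0:
        raise SamplingError(f"study {study.study_id}: empty mask with require_tumor")

    size = spec.size_voxels
    stack = np.stack([_pad_to(c, size) for c in stack])
    mask = _pad_to(mask, size)
    maxc = [mask.shape[i] - size[i] for i in range(3)]

    def cut(corner):
        sl = tuple(slice(c, c + s) for c, s in zip(corner, size))
        return stack[(slice(None),) + sl], mask[sl], corner

    for _ in range(MAX_PATCH_ATTEMPTS):
        corner = tuple(int(rng.integers(0, m + 1)) for m in maxc)
        ch, mk, corner = cut(corner)
        if not spec.require_tumor or mk.any():
            return Patch(ch, mk, corner, names)
    # fallback: center the patch on the tumor centroid
    centroid = center_of_mass(mask)
    corner = tuple(int(np.clip(round(c - s / 2), 0, m))
                   for c, s, m in zip(centroid, size, maxc))
    ch, mk, corner = cut(corner)
    if spec.require_tumor and not mk.any():
        raise SamplingError(f"study {study.study_id}: could not cover the tumor")
    return Patch(ch, mk, corner, names)


@dataclass
class AugmentConfig:
    """Magnitudes of the random training-time perturbations."""

    probability: float = 1.0
    shift_fraction: float = 0.1     # of each channel's std within the patch
    scale_range: tuple[float, float] = (0.9, 1.1)
    max_crop_jitter: int = 8        # in-plane voxels

    def __post_init__(self):
        if not 0 <= self.probability <= 1:
            raise ValidationError("probability must be in [0, 1]", field="probability")


def augment(patch: Patch, rng: np.random.Generator,
            config: AugmentConfig | None = None) -> Patch:
    """Seeded intensity shift + scale on image channels and a random
    in-plane crop-and-pad (integer translation with zero fill) applied to
    channels and mask alike. Output shape is unchanged; the mask receives
    only the spatial transform."""
    cfg = config if config is not None else AugmentConfig()
    if rng.random() >= cfg.probability:
        return patch
    channels = patch.channels.astype(np.float64, copy=True)
    mask = patch.mask.copy()

    scale = rng.uniform(*cfg.scale_range)
    for c in range(channels.shape[0]):
        shift = rng.normal(0.0, 1.0) * cfg.shift_fraction * channels[c].std()
        channels[c] = channels[c] * scale + shift

    j = cfg.max_crop_jitter
    if j > 0:
        dx, dy = int(rng.integers(-j, j + 1)), int(rng.integers(-j, j + 1))
        channels = _translate2d(channels, dx, dy)
        mask = _translate2d(mask[None], dx, dy)[0]
    return Patch(channels, mask.astype(np.uint8), patch.corner, patch.channel_names)


def _translate2d(stack: np.ndarray, dx: int, dy: int) -> np.ndarray:
    """Integer in-plane translation with zero fill (crop-and-pad)."""
    out = np.zeros_like(stack)
    _, X, Y, _ = stack.shape
    xs_src = slice(max(0, -dx), min(X, X - dx))
    xs_dst = slice(max(0, dx), min(X, X + dx))
    ys_src = slice(max(0, -dy), min(Y, Y - dy))
    ys_dst = slice(max(0, dy), min(Y, Y + dy))
    out[:, xs_dst, ys_dst, :] = stack[:, xs_src, ys_src, :]
    return out


def prepare_study(study: MultiparametricStudy,
                  target_spacing: Sequence[float] | None = None) -> MultiparametricStudy:
    """resample (optional) -> normalize; the fixed preprocessing chain."""
    if target_spacing is not None:
        study = resample_study(study, target_spacing)
    return normalize_study(study)
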