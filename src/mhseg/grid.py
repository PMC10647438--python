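"""In-memory containers for volumetric imaging data.

Axis convention used everywhere in this package: arrays are indexed
``(x, y, z)`` with 0-based voxel indices, ``y`` is the phase-encode
(anterior-posterior) axis and ``z`` the slice axis. Spacing is in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping

import numpy as np

from .errors import GridMismatchError, ValidationError


@dataclass
class VolumeGrid:
    """A 3D scalar field with voxel spacing and origin.

    The unit of all imaging I/O in this package.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError(f"expected a 3D array, got shape {self.data.shape}",
                                  field="data")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be three positive floats, got {self.spacing}",
                                  field="spacing")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_grid(self, other: "VolumeGrid", atol: float = 1e-6) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.spacing, other.spacing, atol=atol))

    def require_same_grid(self, other: "VolumeGrid", what: str = "volume") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"{what}: shape/spacing mismatch "
                f"({self.shape}@{self.spacing} vs {other.shape}@{other.spacing})")

    def with_data(self, data: np.ndarray) -> "VolumeGrid":
        return VolumeGrid(data, self.spacing, self.origin)


@dataclass
class MultiparametricStudy:
    """Named channels sharing one grid plus a binary tumor mask.

    The mask is defined on the t2w geometry; DWI-derived channels may be
    deliberately misaligned with it (that misalignment is the phenomenon
    the segmentation models are designed to tolerate).
    """

    study_id: str
    channels: dict[str, VolumeGrid]
    mask: VolumeGrid
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        if not self.channels:
            raise ValidationError("study must have at least one channel", field="channels")
        ref = next(iter(self.channels.values()))
        for name, vol in self.channels.items():
            ref.require_same_grid(vol, what=f"channel {name!r}")
        ref.require_same_grid(self.mask, what="mask")
        vals = np.unique(self.mask.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValidationError("mask must be binary", field="mask")

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    @property
    def grid(self) -> VolumeGrid:
        return next(iter(self.channels.values()))

    def channel_stack(self, names: Iterable[str] | None = None) -> np.ndarray:
        """Stack channels into a (C, X, Y, Z) float array in the given order."""
        names = list(names) if names is not None else self.channel_names
        missing = [n for n in names if n not in self.channels]
        if missing:
            raise ValidationError(f"missing channels {missing}", field="channels")
        return np.stack([np.asarray(self.channels[n].data, dtype=np.float64)
                         for n in names], axis=0)

    def with_channels(self, channels: Mapping[str, VolumeGrid],
                      mask: VolumeGrid | None = None) -> "MultiparametricStudy":
        return MultiparametricStudy(self.study_id, dict(channels),
                                    mask if mask is not None else self.mask,
                                    dict(self.meta))
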