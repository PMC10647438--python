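"""NIfTI volume I/O and dataset manifests.

Volumes are canonicalized to the closest-to-RAS axis order on read (so
phantom and patient paths behave identically) and written with an affine
built from spacing and origin. Array values round-trip bit-exactly and
spacing to 1e-6 mm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

from .errors import FormatError, ValidationError
from .grid import MultiparametricStudy, VolumeGrid
from .phantom import _largest_remainder


def read_volume(path: str | Path) -> VolumeGrid:
    path = Path(path)
    try:
        img = nib.load(path)
    except Exception as e:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read NIfTI file {path}: {e}") from e
    img = nib.as_closest_canonical(img)
    zooms = img.header.get_zooms()[:3]
    if len(zooms) < 3 or any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise FormatError(f"{path}: missing or invalid voxel spacing {zooms}")
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got shape {data.shape}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return VolumeGrid(data, tuple(float(z) for z in zooms), origin)


def write_volume(volume: VolumeGrid, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(volume.spacing) + [1.0])
    affine[:3, 3] = volume.origin
    data = np.asarray(volume.data)
    if data.dtype == np.bool_:
        data = data.astype(np.uint8)
    elif data.dtype == np.float64:
        data = data.astype(np.float32)
    nib.save(nib.Nifti1Image(data, affine), path)


@dataclass
class StudyRecord:
    study_id: str
    channels: dict[str, str]  # channel name -> path (relative to manifest dir)
    mask: str
    split: str = "train"


@dataclass
class DatasetManifest:
    """The dataset index: per-study channel/mask paths and split labels."""

    records: list[StudyRecord]
    spacing: tuple[float, float, float] | None = None
    root: Path = Path(".")
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [r.study_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate study_ids in manifest", field="records")
        for r in self.records:
            if not r.mask:
                raise ValidationError(f"study {r.study_id} has no mask", field="records")
            if r.split not in ("train", "val", "test"):
                raise ValidationError(f"study {r.study_id}: unknown split {r.split!r}",
                                      field="split")

    def split_ids(self, split: str) -> list[str]:
        return [r.study_id for r in self.records if r.split == split]

    def load_study(self, study_id: str) -> MultiparametricStudy:
        rec = next((r for r in self.records if r.study_id == study_id), None)
        if rec is None:
            raise ValidationError(f"unknown study {study_id!r}", field="study_id")
        channels = {name: read_volume(self.root / p) for name, p in rec.channels.items()}
        mask = read_volume(self.root / rec.mask)
        mask = mask.with_data((np.asarray(mask.data) > 0.5).astype(np.uint8))
        return MultiparametricStudy(study_id, channels, mask)

    def load_split(self, split: str) -> list[MultiparametricStudy]:
        return [self.load_study(sid) for sid in self.split_ids(split)]


def write_manifest(records: list[dict | StudyRecord], path: str | Path,
                   spacing: Sequence[float] | None = None,
                   extra: dict | None = None) -> None:
    path = Path(path)
    recs = [r if isinstance(r, dict) else vars(r) for r in records]
    payload = {"studies": recs,
               "spacing": list(spacing) if spacing is not None else None,
               **({"extra": extra} if extra else {})}
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2))


def read_manifest(path: str | Path, check_exists: bool = True) -> DatasetManifest:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
        records = [StudyRecord(**r) for r in payload["studies"]]
    except (json.JSONDecodeError, KeyError, TypeError) as e:
        raise FormatError(f"malformed manifest {path}: {e}") from e
    spacing = tuple(payload["spacing"]) if payload.get("spacing") else None
    manifest = DatasetManifest(records, spacing=spacing, root=path.parent,
                               extra=payload.get("extra", {}))
    if check_exists:
        for r in records:
            for p in list(r.channels.values()) + [r.mask]:
                if not (manifest.root / p).exists():
                    raise ValidationError(f"study {r.study_id}: missing file {p}",
                                          field="records")
    return manifest


def split_dataset(manifest: DatasetManifest, ratios: Sequence[float],
                  seed: int = 0) -> DatasetManifest:
    """(Re)assign splits by seeded permutation + largest-remainder counts."""
    n = len(manifest.records)
    counts = _largest_remainder(n, ratios)
    nonzero = sum(1 for c in np.asarray(ratios) if c > 0)
    if n < nonzero:
        raise ValidationError(f"{n} studies cannot fill {nonzero} non-empty splits",
                              field="ratios")
    labels = ["train"] * counts[0] + ["val"] * counts[1] + ["test"] * counts[2]
    perm = np.random.default_rng(seed).permutation(n)
    records = [StudyRecord(r.study_id, dict(r.channels), r.mask, r.split)
               for r in manifest.records]
    for slot, idx in enumerate(perm):
        records[idx].split = labels[slot]
    return DatasetManifest(records, spacing=manifest.spacing, root=manifest.root,
                           extra=dict(manifest.extra))
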