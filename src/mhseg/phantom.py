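"""Synthetic multiparametric studies with known ground truth.

The patient data this kind of model is trained on cannot be shared, so
every downstream stage is exercised on phantoms that emulate the relevant
physics at the level the pipeline cares about:

* a tumor that is hyperintense on t2w and shows impeded diffusion
  (low D) on DWI;
* mono-exponential DWI signal decay ``S_bi = S_b0 * exp(-b_i * D)`` with a
  known per-voxel diffusion coefficient D (mm^2/s);
* additive Gaussian noise on magnitude images, clipped at zero (a
  deliberate simplification of Rician noise);
* a smooth displacement field along the phase-encode axis (y), applied
  only to DWI-derived channels, emulating EPI distortion — the mask stays
  on the undistorted t2w geometry, so the inter-channel misalignment the
  multi-head models target is actually present.

Signal synthesis order matters: the diffusion map and the b=0 signal are
warped first, and the diffusion-weighted signals are computed *from the
warped quantities*, so the decay law holds exactly per voxel even on
distorted phantoms.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator
from scipy.ndimage import gaussian_filter, map_coordinates

from .errors import ValidationError
from .grid import MultiparametricStudy, VolumeGrid


class PhantomSpec(BaseModel):
    """Parameters of one synthetic study.

    Diffusion coefficients are in mm^2/s (typical soft tissue ~1.5e-3 to
    2e-3; cellular tumor ~0.7e-3 to 1.1e-3); b-values in s/mm^2; spacing
    in mm with the slice axis last.
    """

    model_config = ConfigDict(extra="forbid")

    grid_shape: tuple[int, int, int] = (64, 64, 16)
    spacing_mm: tuple[float, float, float] = (0.6, 0.6, 4.0)
    tumor_center_mm: tuple[float, float, float] | None = None  # None: grid center
    tumor_radii_mm: tuple[float, float, float] = (8.0, 8.0, 10.0)
    background_structures: int = 3
    d_tumor: float = 0.9e-3
    d_background: float = 1.8e-3
    b_values: tuple[float, ...] = (0.0, 1000.0)
    noise_sigma: float = 0.0
    distortion_magnitude_mm: float = 0.0
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if any(n < 1 for n in self.grid_shape):
            raise ValidationError("all dimensions must be >= 1", field="grid_shape")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValidationError("spacing must be positive", field="spacing_mm")
        if any(r <= 0 for r in self.tumor_radii_mm):
            raise ValidationError("all radii must be > 0", field="tumor_radii_mm")
        if list(self.b_values) != sorted(self.b_values) or len(set(self.b_values)) != len(self.b_values):
            raise ValidationError("b_values must be sorted ascending and unique", field="b_values")
        if any(b < 0 for b in self.b_values):
            raise ValidationError("b_values must be non-negative", field="b_values")
        if len(self.b_values) < 2:
            raise ValidationError("at least two b-values are needed to fit ADC", field="b_values")
        if not self.d_tumor < self.d_background:
            raise ValidationError("tumor must show impeded diffusion (d_tumor < d_background)",
                                  field="d_tumor")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0", field="noise_sigma")
        if self.distortion_magnitude_mm < 0:
            raise ValidationError("must be >= 0", field="distortion_magnitude_mm")
        center = self.center_mm()
        extent = [n * s for n, s in zip(self.grid_shape, self.spacing_mm)]
        for c, r, e in zip(center, self.tumor_radii_mm, extent):
            if c - r < 0 or c + r > e:
                raise ValidationError(
                    f"tumor ellipsoid (center {center} mm, radii {self.tumor_radii_mm} mm) "
                    f"exceeds the grid extent {extent} mm", field="tumor_radii_mm")
        return self

    def center_mm(self) -> tuple[float, float, float]:
        if self.tumor_center_mm is not None:
            return self.tumor_center_mm
        return tuple((n - 1) * s / 2.0 for n, s in zip(self.grid_shape, self.spacing_mm))


def _ellipsoid_support(shape, spacing, center_mm, radii_mm) -> np.ndarray:
    coords = np.meshgrid(*(np.arange(n) * s for n, s in zip(shape, spacing)),
                         indexing="ij")
    q = sum(((c - cc) / r) ** 2 for c, cc, r in zip(coords, center_mm, radii_mm))
    return q <= 1.0


def make_displacement_field(shape: Sequence[int], spacing: Sequence[float],
                            magnitude_mm: float,
                            rng: np.random.Generator) -> np.ndarray:
    """Smooth scalar displacement (mm) along the phase-encode axis (y).

    Sum of 2-4 seeded Gaussian bumps with random centers, widths, and
    signs, rescaled so the peak absolute displacement equals
    ``magnitude_mm``. Smooth (C^inf) by construction, emulating the
    slowly varying field-inhomogeneity patterns behind EPI distortion.
    """
    n_bumps = int(rng.integers(2, 5))
    field = np.zeros(tuple(shape), dtype=np.float64)
    coords = np.meshgrid(*(np.arange(n, dtype=np.float64) for n in shape), indexing="ij")
    for _ in range(n_bumps):
        center = [rng.uniform(0, n - 1) for n in shape]
        width = [rng.uniform(max(2.0, n / 8), max(3.0, n / 3)) for n in shape]
        amp = rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.0)
        field += amp * np.exp(-sum(((c - cc) / w) ** 2
                                   for c, cc, w in zip(coords, center, width)))
    peak = np.abs(field).max()
    if peak > 0:
        field *= magnitude_mm / peak
    return field


def warp_along_y(data: np.ndarray, displacement_mm: np.ndarray,
                 spacing_y: float, order: int = 1) -> np.ndarray:
    """Resample through the displacement field acting only along y."""
    x, y, z = np.meshgrid(*(np.arange(n, dtype=np.float64) for n in data.shape),
                          indexing="ij")
    coords = np.stack([x, y + displacement_mm / spacing_y, z])
    return map_coordinates(data.astype(np.float64), coords, order=order, mode="nearest")


def apply_epi_distortion(volume: VolumeGrid, magnitude_mm: float,
                         seed: int) -> VolumeGrid:
    """Warp a volume through a seeded smooth y-displacement field.

    Magnitude 0 returns the input unchanged; the field's peak equals
    ``magnitude_mm`` exactly (the resampling is linear interpolation, so
    feature shifts match it within interpolation tolerance).
    """
    if magnitude_mm < 0:
        raise ValidationError("must be >= 0", field="magnitude_mm")
    if magnitude_mm == 0:
        return volume.with_data(volume.data.copy())
    rng = np.random.default_rng(seed)
    field = make_displacement_field(volume.shape, volume.spacing, magnitude_mm, rng)
    return volume.with_data(warp_along_y(np.asarray(volume.data, dtype=np.float64),
                                         field, volume.spacing[1]))


def _b_name(b: float) -> str:
    return f"b{int(round(b))}"


def generate_study(spec: PhantomSpec, study_id: str = "phantom") -> MultiparametricStudy:
    """Generate one synthetic study.

    Returns a study with channels ``t2w``, one ``b{value}`` per b-value,
    and ``adc`` (two-point fit of the final, possibly noisy and distorted,
    lowest/highest-b pair — emulating a scanner-derived map sharing the DWI
    geometry). ``meta`` carries the warped true diffusion map (``d_true``)
    and the undistorted tumor support. Identical spec+seed reproduces
    bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    shape, spacing = spec.grid_shape, spec.spacing_mm
    center = spec.center_mm()

    tumor = _ellipsoid_support(shape, spacing, center, spec.tumor_radii_mm)

    # background structures: non-tumor ellipsoids adding anatomical clutter
    structures = np.zeros(shape, dtype=bool)
    extent = [n * s for n, s in zip(shape, spacing)]
    for _ in range(spec.background_structures):
        c = [rng.uniform(0.15 * e, 0.85 * e) for e in extent]
        r = [rng.uniform(0.05 * e, 0.15 * e) for e in extent]
        structures |= _ellipsoid_support(shape, spacing, c, r)
    structures &= ~tumor

    # t2w: low-frequency texture + structure contrast + tumor hyperintensity
    texture = gaussian_filter(rng.normal(0.0, 1.0, shape), sigma=(3, 3, 1))
    tstd = texture.std()
    if tstd > 0:
        texture /= tstd
    t2w = 0.4 + 0.05 * texture + 0.15 * structures + 0.4 * tumor

    # diffusion tissue model on the undistorted geometry
    d_map = np.full(shape, spec.d_background, dtype=np.float64)
    d_map[tumor] = spec.d_tumor
    s_b0 = 0.5 + 0.3 * tumor.astype(np.float64) + 0.1 * structures

    # EPI-like warp applied to the DWI-derived quantities only
    if spec.distortion_magnitude_mm > 0:
        field = make_displacement_field(shape, spacing, spec.distortion_magnitude_mm, rng)
        d_map = warp_along_y(d_map, field, spacing[1])
        s_b0 = warp_along_y(s_b0, field, spacing[1])

    sigma = spec.noise_sigma * float(s_b0.mean())
    channels: dict[str, VolumeGrid] = {}
    noisy: dict[float, np.ndarray] = {}
    t2w_noisy = t2w + (rng.normal(0.0, spec.noise_sigma * float(np.abs(t2w).mean()), shape)
                       if spec.noise_sigma > 0 else 0.0)
    channels["t2w"] = VolumeGrid(np.clip(t2w_noisy, 0.0, None), spacing)
    for b in spec.b_values:
        signal = s_b0 * np.exp(-b * d_map)
        if spec.noise_sigma > 0:
            signal = np.clip(signal + rng.normal(0.0, sigma, shape), 0.0, None)
        noisy[b] = signal
        channels[_b_name(b)] = VolumeGrid(signal, spacing)

    # scanner-style ADC from the lowest/highest-b pair of the final signals
    from .dwi_adc import fit_adc_two_point
    b_lo, b_hi = spec.b_values[0], spec.b_values[-1]
    adc = fit_adc_two_point(channels[_b_name(b_lo)], channels[_b_name(b_hi)],
                            b_hi - b_lo)
    channels["adc"] = adc.values

    mask = VolumeGrid(tumor.astype(np.uint8), spacing)
    return MultiparametricStudy(
        study_id=study_id, channels=channels, mask=mask,
        meta={"spec": spec.model_dump(), "d_true": d_map, "s_b0": s_b0,
              "tumor_support": tumor})


def _largest_remainder(n: int, ratios: Sequence[float]) -> list[int]:
    ratios = np.asarray(ratios, dtype=np.float64)
    if np.any(ratios < 0) or ratios.sum() <= 0:
        raise ValidationError("ratios must be non-negative and sum > 0", field="ratios")
    quota = n * ratios / ratios.sum()
    counts = np.floor(quota).astype(int)
    # distribute the leftover seats by descending fractional part,
    # ties broken by position (train before val before test)
    order = sorted(range(len(ratios)), key=lambda i: (-(quota[i] - counts[i]), i))
    for i in order[: n - counts.sum()]:
        counts[i] += 1
    return counts.tolist()


DEFAULT_SPLIT_RATIOS = (157.0, 25.0, 25.0)  # train : val : test


def generate_cohort(n: int, out_dir: str | Path, seed: int = 0,
                    spec_ranges: dict | None = None,
                    split_ratios: Sequence[float] = DEFAULT_SPLIT_RATIOS,
                    base_spec: PhantomSpec | None = None) -> Path:
    """Write ``n`` studies as NIfTI files plus a JSON manifest.

    ``spec_ranges`` maps PhantomSpec field names to (low, high) ranges
    sampled uniformly per study; remaining fields come from ``base_spec``.
    Split assignment uses seeded shuffling with largest-remainder
    allocation over ``split_ratios``.
    """
    if n < 1:
        raise ValidationError("n must be >= 1", field="n")
    from .io import write_manifest, write_volume

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    base = base_spec if base_spec is not None else PhantomSpec()
    spec_ranges = spec_ranges or {}

    counts = _largest_remainder(n, split_ratios)
    splits = ["train"] * counts[0] + ["val"] * counts[1] + ["test"] * counts[2]
    perm = rng.permutation(n)
    assignment = [None] * n
    for slot, study_idx in enumerate(perm):
        assignment[study_idx] = splits[slot]

    records = []
    for i in range(n):
        overrides = {}
        for key, (lo, hi) in spec_ranges.items():
            if isinstance(lo, (tuple, list)):
                overrides[key] = tuple(rng.uniform(l, h) for l, h in zip(lo, hi))
            else:
                overrides[key] = float(rng.uniform(lo, hi))
        spec = base.model_copy(update={**overrides,
                                       "seed": int(rng.integers(0, 2**31 - 1))})
        study_id = f"phantom_{i:03d}"
        study = generate_study(spec, study_id=study_id)
        sdir = out_dir / study_id
        sdir.mkdir(exist_ok=True)
        chan_paths = {}
        for name, vol in study.channels.items():
            p = sdir / f"{name}.nii.gz"
            write_volume(vol, p)
            chan_paths[name] = str(p.relative_to(out_dir))
        mask_path = sdir / "mask.nii.gz"
        write_volume(study.mask, mask_path)
        records.append({"study_id": study_id, "channels": chan_paths,
                        "mask": str(mask_path.relative_to(out_dir)),
                        "split": assignment[i]})

    manifest_path = out_dir / "manifest.json"
    write_manifest(records, manifest_path,
                   spacing=base.spacing_mm, extra={"seed": seed, "n": n})
    return manifest_path
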