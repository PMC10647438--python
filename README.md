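# mhseg

Multi-head dilated-encoder 3D segmentation for multiparametric MRI.

Tumor contours for pelvic cancers are drawn on anatomical T2-weighted
(T2W) MRI, but much of the tumor signal lives in diffusion-weighted
imaging (DWI) — the high-b image (b1000) and the apparent diffusion
coefficient (ADC) map derived from it. DWI is acquired with echo-planar
imaging and is geometrically distorted along the phase-encode axis, so
the channels a segmentation network consumes are *misaligned* with the
image its ground truth lives on. `mhseg` implements a family of 3D
residual U-Nets designed for exactly this situation, for researchers in
medical image analysis who want to study multi-channel fusion under
inter-channel misalignment with a fully controlled, reproducible setup.

## What's inside

- **Models** (`mhseg.models`): a baseline multi-channel residual U-Net
  (two residual blocks per level, instance norm + PReLU, filters
  32/64/128/256, bottleneck 512) and three multi-head variants whose
  first encoder level is replaced by parallel heads: a non-dilated head
  reading T2W only, plus dilation-2 and dilation-4 heads reading the
  DWI-derived channels — with shared dilated kernels and summation
  fusion (`multihead_1`, `multihead_2`) or independent heads with
  concat–project–sum fusion (`multihead_3`).
- **ADC fitting** (`mhseg.dwi_adc`): the mono-exponential model
  S_b = S_b0 · e^(−bD); two-point fit D = −(1/b)·ln(S_b/S_b0) and the
  closed-form log-linear least-squares fit over multiple b-values.
- **Phantoms** (`mhseg.phantom`): synthetic multiparametric studies with
  a known per-voxel diffusion map and a smooth, seeded displacement
  field along the phase-encode axis applied only to DWI-derived channels
  — so the inter-channel misalignment is present and quantifiable.
- **Pipeline** (`mhseg.preprocess`, `mhseg.training`, `mhseg.infer_eval`):
  resampling (linear for T2W/b1000, nearest-neighbor for ADC/masks),
  per-channel z-scoring, tumor-constrained patch sampling, augmentation,
  Adam + cosine annealing with Dice/Dice+CE/Tversky losses, per-epoch
  whole-volume validation with best-checkpoint selection, 75%-overlap
  sliding-window inference, and DSC / HD95 / MSD / relative-volume-
  difference metrics with bootstrap confidence intervals.
- **Interpretation** (`mhseg.interpret`): sequential channel dropout and
  3D Grad-CAM saliency maps.
- **NN engine** (`mhseg.nn`): the reverse-mode autodiff and 3D conv /
  transposed-conv / instance-norm / PReLU primitives the models run on,
  in pure NumPy, verified against finite differences.

The networks, training loop, and saliency all run on a single CPU at the
package's desk-scale presets (see `docs/methods.md`).

## Worked example

```python
import numpy as np
from mhseg.phantom import PhantomSpec, generate_study
from mhseg.dwi_adc import fit_adc_two_point
from mhseg.infer_eval import compute_metrics

spec = PhantomSpec(grid_shape=(24, 24, 16), spacing_mm=(1.5, 1.5, 3.0),
                   tumor_radii_mm=(8.0, 8.0, 10.0),
                   b_values=(0.0, 1000.0), noise_sigma=0.05,
                   distortion_magnitude_mm=3.0, seed=42)
study = generate_study(spec)

adc = fit_adc_two_point(study.channels["b0"], study.channels["b1000"], b=1000.0)
tumor = study.mask.data.astype(bool)
print(f"median ADC  tumor: {np.median(adc.values.data[tumor]):.2e} mm^2/s")
print(f"median ADC  other: {np.median(adc.values.data[~tumor]):.2e} mm^2/s")

dwi_support = study.channels["b1000"].data > 0.2
m = compute_metrics(dwi_support, tumor, spec.spacing_mm)
print(f"DWI-vs-mask misalignment: DSC {m.dsc:.3f}, RVD {m.rvd_percent:+.1f}%")
```

prints

```
median ADC  tumor: 9.14e-04 mm^2/s
median ADC  other: 1.80e-03 mm^2/s
DWI-vs-mask misalignment: DSC 0.992, RVD -1.5%
```

The fitted ADC separates tumor (impeded diffusion, ~0.9×10⁻³ mm²/s) from
background (~1.8×10⁻³ mm²/s) — the phantom's specified coefficients —
and the 3 mm phase-encode distortion leaves the DWI tumor support
measurably misaligned (DSC < 1) with the mask drawn on the undistorted
T2W geometry, which is the condition the multi-head models target.

Training and comparing models end to end:

```python
from mhseg.experiments import run_misalignment_comparison
result = run_misalignment_comparison(n_phantoms=20, distortion_mm=3.0, seed=1)
print(result.table)   # per-model medians + bootstrap CIs for all four metrics
```

The same pipeline is scriptable from the shell:

```bash
mhseg make-phantoms --n 20 --seed 1 --distortion-mm 3 --noise 0.05 --out cohort/
mhseg compute-adc --inputs cohort/phantom_000/b0.nii.gz \
      --inputs cohort/phantom_000/b1000.nii.gz \
      --b-values 0 --b-values 1000 --protocol two_point --out adc.nii.gz
mhseg train --config run.yaml --manifest cohort/manifest.json --out ckpt.npz
mhseg predict --checkpoint ckpt.npz --manifest cohort/manifest.json --out preds/
mhseg evaluate --pred preds/ --manifest cohort/manifest.json --out metrics.csv
mhseg sensitivity --checkpoint ckpt.npz --manifest cohort/manifest.json --out sens.csv
mhseg gradcam --checkpoint ckpt.npz --manifest cohort/manifest.json \
      --study phantom_000 --out cam.nii.gz
```

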