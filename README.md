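# usdot

Simulation, reconstruction and classification for **ultrasound-aided
time-domain diffuse optical tomography (TD-DOT) of breast lesions**.

Diffuse optical tomography estimates tissue absorption and reduced
scattering (μa, μs′, mm⁻¹) from pulsed near-infrared light, which in the
breast translates into chromophore contrasts (hemoglobin, water, lipid,
collagen) that separate malignant from benign lesions.  The inverse problem
is severely ill-posed; concurrent B-mode ultrasound supplies the lesion
morphology, reducing the reconstruction to a **two-region model**: the
domain Ω is split by a binary prior mask χ into inclusion and bulk, each
homogeneous, and per wavelength the parameters

```
h = [μa_in, μa_bulk, μs′_in, μs′_bulk, tshift]
```

are estimated by bounded least squares on preprocessed time-resolved
curves,

```
L(h) = ½ Σ_i Σ_j Σ_k ( P_k[y_ij] − P_k[A_ij[χh](t + tshift)] )² / σ²_ijk ,
```

where `A` is a time-domain diffusion forward model (implicit Euler,
Robin boundary, IRF convolution), `P_k` extracts the k-th of 80
self-normalized temporal bins over an automatically selected region of
interest, and `σ²_ijk = P_k[y_ij] / N_ij` are Poisson weights.  Only
source–detector separations above 27 mm enter the objective; boxes are
0 < μa < 0.06 mm⁻¹, 0 < μs′ < 2.2 mm⁻¹, |tshift| ≤ 25 ps.

The package is an end-to-end synthetic laboratory for this measurement:

| module | role |
| --- | --- |
| `usdot.phantom` | voxelized breast phantoms, lesion shapes, compression, coarse relabeling |
| `usdot.acoustics` | dual-scale stochastic speed-of-sound media + export for a wave solver |
| `usdot.optics` | chromophore spectral model → per-wavelength μa/μs′ maps (8 wavelengths, 635–1060 nm) |
| `usdot.forward` | TD diffusion solver, probe geometry, IRF, photon-budget Poisson noise |
| `usdot.preprocess` | ROI selection, binning, self-normalization, Poisson weights |
| `usdot.recon` | homogeneous (analytic) and two-region (numerical) fits |
| `usdot.priors` | Dice/volume/displacement metrics, 2D→3D extrapolation, prior degradation emulator |
| `usdot.classify` | 16-feature tables, PCA, logistic regression / kernel SVM / dense network |
| `usdot.pipeline` | study orchestration, seeding, manifests, resumability |

## Worked example

Simulate one malignant phantom at desk scale, reconstruct the inclusion at
785 nm with the ground-truth prior:

```python
import numpy as np
from usdot.phantom import (PhantomConfig, LesionSpec, generate_phantom,
                           generate_lesion_shape, insert_lesion, compress,
                           downsample_labels, extract_cuboid, TISSUE_INDEX)
from usdot.optics import assign_optical_properties
from usdot.forward import TimeGrid, default_probe, gaussian_irf, run_forward, apply_noise
from usdot.priors import PriorMask
from usdot.recon import TwoRegionParams, fit_homogeneous, fit_two_region

cfg = PhantomConfig(fat_fraction=0.66, fine_spacing=1.0, coarse_spacing=5.0)
vol = compress(generate_phantom(cfg, rng_seed=9), 45.0)
shape = generate_lesion_shape(LesionSpec(10.5, 0.3, "malignant", rng_seed=9), 1.0)
vol = insert_lesion(vol, shape, rng_seed=9, z_range=(2.0, 29.0))
coarse = extract_cuboid(downsample_labels(vol, 5), (60.0, 55.0, 30.0))

maps = assign_optical_properties(coarse, lesion_class="malignant", rng_seed=9)
ms = apply_noise(run_forward(maps, default_probe(), TimeGrid(dt=50.0, n_steps=80),
                             irf=gaussian_irf(400.0)), nexpect=1e6, rng_seed=9)

prior = PriorMask(coarse.labels == TISSUE_INDEX["lesion"], coarse.spacing, coarse.origin)
k = 3                                   # 785 nm
hom = fit_homogeneous(ms, k)
fit = fit_two_region(ms, prior, k,
                     init=TwoRegionParams(hom.params.mua_bulk, hom.params.mua_bulk,
                                          hom.params.musp_bulk, hom.params.musp_bulk))
mua_t, musp_t = maps.lesion_spectra()
print(f"truth  mua_in={mua_t[k]:.4f}  musp_in={musp_t[k]:.3f}")
print(f"fit    mua_in={fit.params.mua_in:.4f}  musp_in={fit.params.musp_in:.3f}")
```

prints

```
truth  mua_in=0.0090  musp_in=1.009
fit    mua_in=0.0114  musp_in=1.105
```

i.e. the inclusion absorption at 785 nm is recovered to within ~25% and the
scattering to within ~10% for this lesion — typical of the two-region model
with an exact prior at this noise level; errors grow (especially a
compensating overestimation of μa_in) when the prior underestimates the
lesion volume, as extracted ultrasound priors do by about 50%.

An end-to-end study (phantoms → data → fits with ground-truth and
ultrasound-quality priors → classification) runs via

```bash
usdot study --n-phantoms 28 --seed 0 --scale scaled --out-dir runs/demo
```

and prints per-prior-mode classification reports plus reconstruction error
summaries.  `usdot --help` lists the per-stage commands (`phantom`,
`acoustics`, `optics`, `forward`, `degrade-prior`, `fit`, `classify`).

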