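# Methods

This note documents the models implemented in `usdot`, the choices made
where the design was open, and what the synthetic data can and cannot show.

## Overview

The package simulates and analyzes a combined ultrasound + time-domain
diffuse optical tomography (TD-DOT) examination of a breast lesion under a
handheld reflectance probe:

1. a voxelized breast phantom with tissue labels and an embedded lesion;
2. a dual-scale stochastic acoustic medium (exported for an external wave
   solver; no wave propagation is performed here);
3. per-wavelength absorption/scattering maps from a chromophore model;
4. time-resolved photon-count curves from a diffusion-equation solver,
   convolved with an instrument response function (IRF) and subjected to
   photon-budget Poisson noise;
5. a two-region nonlinear reconstruction that uses a morphological prior
   (ground truth, or degraded to emulated ultrasound quality);
6. benign/malignant classification of the per-wavelength inclusion
   coefficients.

## Phantom model

The phantom is a slab held between two flat paddles, with an elliptical
lateral footprint (air margin around it), skin layers of 1.5 mm on the two
paddle surfaces and on the lateral rim, and an adipose/glandular parenchyma
obtained by thresholding a Gaussian random field (correlation length
5–6 mm) at the quantile matching the requested fat fraction.  Thin tubular
ducts/arteries/veins make up ~1% of the interior.  Compression to the
45 mm probe gap is an anisotropic affine rescale: z is compressed, x/y
dilated by the inverse square root, which conserves tissue volume to within
a few percent; chest-wall mechanics are not modeled.

Lesions are star-convex solids: a sphere of the requested equivalent radius
whose radial field is perturbed by random spherical harmonics of degree
2–4, scaled by a single `irregularity` knob (0 = digitized sphere; 0.5
gives ~25% radial standard deviation).  The radius field is rescaled so the
continuous volume matches the equivalent sphere.  Lesions are placed with
center of mass within 0.3·l of the ultrasound imaging plane y=0 (l = lesion
extent along y), fully inside soft tissue, and within a configurable depth
band (default 2–29 mm) so that the lesion lies in the optically and
acoustically probed region under the probe.

The optical grid is a coarse relabeling of the fine phantom: majority vote
per block, with residual air assigned to adipose or glandular tissue,
whichever dominates the breast.

## Acoustic medium

Per tissue i the speed of sound is `vbar_i + sigma_micro_i * w(r)` with
`vbar_i ~ N(mu_i, sigma_macro_i)` drawn once per phantom and `w` a white
standard Gaussian field (a correlated option exists but is off by default:
only the mean and texture level matter downstream, speckle statistics are
out of scope).  Defaults: adipose 1470 m/s, glandular-like tissues
1515 m/s, lesions 1550 m/s, sigma_macro 12 m/s; texture levels are drawn
uniformly in [1%, 5%] of the tissue mean, and the lesion's level is set to
half the minimum of the other tissues so lesions appear hypoechoic.  The
medium (plus a 7 MHz, 256-element, 0.2 mm-pitch transducer description,
beamforming reference 1465 m/s) is exported for an external k-space wave
simulator; B-mode image formation is a non-goal.

## Optical model

Absorption is linear in the five chromophores (Hb, HbO2, lipid, water,
collagen): `mu_a(lambda) = sum_i eps_i(lambda) C_i`.  The bundled
`data/chromophores.yaml` is an approximate literature-style compilation at
the eight probing wavelengths (635, 670, 685, 785, 905, 930, 975,
1060 nm); `eps * C` yields mm^-1 (Hb/HbO2 per uM, the others per unit
volume fraction).  Reduced scattering follows `mu_s' = a (lambda/600)^-b`
with a per-wavelength Gaussian perturbation of 10% of the value added as
model noise and a positivity floor of 0.05 mm^-1.

Tissue compositions are drawn once per phantom per tissue (no intra-tissue
spatial variation).  The class-conditional lesion distributions are
modeling choices chosen so that malignant lesions carry more total
hemoglobin, water and collagen and less lipid than benign ones, with bulk
tissues in between; the scattering amplitudes are fixed study conditions:
benign `a ~ N(1.5, 0.25) mm^-1`, malignant `a ~ N(1.4, 0.25) mm^-1`, and
25% of benign lesions are cysts with `a ~ N(0.3, 0.01) mm^-1` (cysts count
as benign for classification).  With these defaults the two classes are
linearly separable in the 16-dimensional log-feature space, which is what
makes the no-reconstruction classification reach 100%.

## Forward solver

The time-domain diffusion equation `(1/c) dPhi/dt = div(kappa grad Phi) -
mu_a Phi`, `kappa = 1/(3 mu_s')`, is discretized with cell-centered finite
differences (harmonic mean of kappa at faces) and implicit Euler in time.
The Robin condition `Phi + 2 A kappa dPhi/dn = 0` enters as a per-face
boundary conductance; `A = (1+r_d)/(1-r_d)` with the diffuse Fresnel
polynomial for `r_d` (A ≈ 3.25 at the default n = 1.4).  The pulsed source
is an initial condition: a unit-integral Gaussian of width 0.5 mm buried
one transport mean free path below the source; detectors read the boundary
exitance `Phi/(2A)` through a 1 mm Gaussian surface profile.  The probe has
8 sources (two rows of four at y = ±17.5 mm, 12 mm pitch) and 8 detectors
(rows at y = ±10.8 mm) on z = 0.

Default discretization mirrors the reference acquisition: 2 mm voxels on a
64x58x30 mm cuboid and 400 time steps of 25 ps.  Implicit Euler is
first-order: halving the step changes detector curves by ~2–3%; the fits
absorb most of the residual offset through the fictitious time-shift
parameter.  Model curves are convolved with the IRF (bundled synthetic
Gaussian, FWHM 400 ps, unit area; measured IRFs load from two-column
ASCII).  Poisson noise is anchored by `Nexpect` (default 1e6), the expected
total counts at the largest source–detector separation; all pairs share one
scale factor per wavelength so integral ratios are preserved.

## Preprocessing and reconstruction

Every curve is reduced to NTW = 80 equal-width bins spanning the ROI from
the first sample at 10% of the peak to the last at 1% of the peak
(sample-level thresholds, no sub-sample interpolation: reproducible, and
negligible on a 25 ps grid).  Bin integrals use the trapezoidal rule with
exact fractional edges; bins are normalized to unit total, making the
operator invariant to amplitude rescaling.  Poisson weights are
`sigma2_k = p_k / N` with N the ROI counts; empty bins get a `1/N^2` floor.

The homogeneous fit matches the extrapolated-boundary dipole solution of
the semi-infinite medium (convolved with the IRF, with a free time shift
bounded at ±25 ps) to all pairs with separation > 27 mm; it provides
effective bulk coefficients and initializes the two-region fit.

The two-region fit estimates (mu_a_in, mu_a_bulk, mu_s'_in, mu_s'_bulk,
tshift) by bounded trust-region least squares on the weighted binned
residuals, with boxes 0 < mu_a < 0.06 mm^-1, 0 < mu_s' < 2.2 mm^-1,
|tshift| ≤ 25 ps, and the same > 27 mm pair filter (long paths favor
absorption convergence and reduce sensitivity to local perturbations such
as vessels).  Each Jacobian column is a forward-difference solve; the
model curve is evaluated at t + tshift by linear interpolation before
binning.  Defaults: xtol 1e-4, ftol 1e-6, ≤ 60 residual evaluations;
initialization at the homogeneous bulk values with the inclusion equal to
the bulk and tshift = 0.  In the study pipeline, fits at neighboring
wavelengths warm-start each other (re-anchored to the current homogeneous
bulk), and looser tolerances (xtol 1e-3, ≤ 25 evaluations) are used, since
the residual errors there are dominated by model mismatch, not optimizer
precision.

## Priors

The Sørensen–Dice index, relative area (on the y=0 slice) and volume
mismatches, and per-axis center-of-mass displacement quantify prior
quality.  A 2D imaging-plane mask is extrapolated to 3D as the union of
balls carried by every interior pixel with radius equal to its boundary
distance (hemispherical fall-off: a disk maps to a ball).  The interactive
B-mode segmentation itself is not reproduced; instead a degradation
emulator maps the ground-truth mask to a prior of prescribed quality by
selecting level sets of the signed distance field (exact to one voxel) and
shifting by whole voxels.  Population defaults draw dV from N(-0.5, 0.17)
and the per-axis shifts from (0.04±0.13, 0.08±0.05, 0.14±0.08) mm — the
measured quality of distance-transform extrapolated ultrasound priors,
whose dominant feature is ~50% volume underestimation caused by the
beamforming speed mismatch.

## Classification

Features are the 16 log-coefficients (mu_a_in, mu_s'_in at 8 wavelengths),
z-scored with training-split statistics.  Logistic regression and the SVM
use stratified 60:40 splits; the SVM is model-selected over kernels
{RBF, polynomial(3), sigmoid} and C in {0.5, 1, 2, 3, 4, 5} by
cross-validated training accuracy.  The dense network (widths 16/32/16/1,
ReLU hidden, sigmoid output mapped to [-1, 1], hinge loss, minibatch SGD
with momentum, batch 32, ≤ 500 epochs, early stopping with patience 25 on
a 60:20:20 validation split) is implemented directly in numpy.  Metrics
are accuracy, precision, recall and F1 from the malignant/benign confusion
counts; the standard F1 = 2PR/(P+R) is used, and undefined metrics are
reported as undefined rather than zero.  Lesions with a non-converged fit
or a non-positive coefficient are excluded from the table (logged in
`attrs["excluded"]`).

## Study scales

`full_study_config()` reproduces the reference acquisition geometry
(0.5 mm phantom, 2 mm optics, 400 x 25 ps); at roughly a minute per
wavelength fit it is an overnight-scale computation for hundreds of
phantoms.  `scaled_study_config()` is the desk-scale variant used by the
test suite and examples: 1 mm phantom grid, 5 mm optical voxels on
60x55x30 mm, 80 x 50 ps time steps, lesion radii 7–11.5 mm, ≤ 25 residual
evaluations per fit, Nexpect = 1e6.  It preserves the full physics chain
and the statistical structure (class-conditional spectra, prior quality,
noise anchoring), at the cost of coarser partial-volume effects and larger
reconstruction errors than the full-resolution setting.  Consequences to
keep in mind when reading desk-scale results (the suite runs 28 phantoms):
the two-region fits show a heavier tail of large errors than a
full-resolution run would, reconstructed-feature classification is
estimated on a few dozen lesions (accuracies are averaged over several
stratified splits and still carry sampling noise of several points), and
classification accuracy from reconstructed features sits meaningfully
below the no-reconstruction ceiling.  The ideal-prior fits consistently
dominate the degraded-prior fits in median |relative error| of mu_a_in;
per-split accuracies, by contrast, can invert between prior modes at this
sample size.

What the synthetic data do not show: real B-mode speckle and segmentation
behavior (the prior quality is emulated, not measured), chest-wall and
nonlinear compression mechanics, intra-tissue optical heterogeneity,
detector afterpulsing/dark counts, and any mismatch between the bundled
extinction table and a particular instrument's calibration.

## Numerical notes

* Linear systems are solved by sparse LU, factored once per wavelength and
  reused across time steps (conjugate gradients are available for large
  verification grids).
* Reciprocity holds to machine precision when optodes sit on voxel
  centers; off-center optodes incur profile-sampling differences of a few
  percent at coarse grids.
* The absorption scaling identity exp(-dmu_a c t) is satisfied to O(dt)
  by implicit Euler; verification uses 5 ps steps.
* Degenerate inputs raise typed errors (empty priors, all-skin phantoms,
  curves without a positive peak, two empty masks in the Dice index).
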