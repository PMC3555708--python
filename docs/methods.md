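# Methods

## Model of the measurement problem

A thin fluorescent object (a primary cilium, or a microfiber standing in
for one) is embedded in a transparent gel and imaged as a z-stack with
voxel spacing (dz, dy, dx), typically 500/108/108 nm for the wide-field
water-immersion configuration this package defaults to. The optical
system is modelled as a separable anisotropic Gaussian PSF with lateral
and axial FWHM (defaults 540 and 2000 nm, the experimentally measured
resolutions for that configuration). The Gaussian approximation of the
axial response is the load-bearing assumption of the whole approach: it
is what makes "add lateral blur until the PSF is spherical" a valid
correction, since Gaussian widths compose in quadrature.

The pipeline estimates the object's centerline length in physical units
from (1) a resolution calibration on bead stacks, (2) Richardson–Lucy
(RL) deconvolution, (3) an isotropizing per-slice blur, (4) binarization
plus topology-preserving thinning along the Euclidean distance map, and
(5) the longest geodesic of the resulting polyline graph.

## Calibration (bead FWHM)

The estimator follows the per-plane-maximum procedure: the maximum pixel
intensity of every z-plane, plotted against the plane's z position, is
fitted with a 4-parameter Gaussian (amplitude, centre, σ, baseline);
FWHM = 2√(2 ln 2)·σ. For a Gaussian blob the per-plane maximum is exactly
Gaussian in the plane position, so the estimator is unbiased under the
PSF model; fits with R² < 0.9 or multi-peaked profiles raise errors
carrying diagnostics. The lateral FWHM uses the identical procedure
after reslicing the stack so y becomes the profiling axis. No finite-bead
correction is applied: estimates describe the bead ⊗ PSF product, the
same convention used when experimental resolutions are reported. A
sub-voxel bead position widens the apparent axial FWHM by up to ~4 %
(the impulse splits across two 500 nm planes), which is why the measured
raw ratio sits at 0.26–0.27 rather than exactly 540/2000 = 0.27.

## Deconvolution

RL with the measured (Gaussian) PSF, implemented with separable Gaussian
filtering for both H and Hᵀ (the kernel is symmetric), reflective
boundaries, non-negativity, and intensity conservation to ~1 %. The SNR
control maps to a stopping tolerance on the relative update norm,
tol = c/SNR with c = 1.0, calibrated once so the wide-field regime
(SNR 90) stops after ~50 updates on a bead phantom and the confocal
regime (SNR 10) after a handful — noisier data gets less sharpening.
This mapping is a convention of this implementation, not a claim of
equivalence with any commercial package's SNR semantics. A lightweight
"blind" variant alternates RL with a two-parameter Gaussian-width refit
and is provided as an approximation only.

## Isotropizing blur

From the post-deconvolution bead resolutions, the analytic plan blurs
each z-plane with a 2D Gaussian of FWHM √(fwhm_xz² − fwhm_xy²)
(quadrature); a search mode re-enacts the trial-of-kernels procedure by
scanning a σ ladder against re-measured bead stacks. Only in-plane
blurring is ever applied — per-plane totals are conserved and no
coupling across z is introduced. Blurring *undeconvolved* data is
rejected by design: it collapses the contrast a threshold needs (shown
as a behaviour test); the blur is only valid after deconvolution.

## Binarization

`half_max` thresholds at background + 0.5·(robust max − background),
with background = median and robust max = the 90th percentile of voxels
clearly above background (≥ 25 % of the span). The quantile definition
matters: RL produces a localized overshoot at bright object centres,
and a "brightest few voxels" maximum would chase it, dragging the
threshold up and shrinking every measured extent. Otsu and manual
thresholds are also available; the manual path exists because visual
thresholding is the one subjective step of the original workflow, and a
sensitivity test shows ±10 % threshold changes move fiber lengths < 2 %.

## Skeletonization and length

The binary object is eroded to a centerline by sequentially deleting
*simple points* — voxels whose removal preserves topology, decided by
the standard (26, 6) topological numbers — in increasing order of the
Euclidean distance transform computed with the physical anisotropic
spacing (distances in nm, never voxels). Voxels with exactly one
foreground neighbour are protected so curve endpoints survive. The
one-voxel-wide result becomes a multigraph of polylines between
endpoints and junctions; terminal branches shorter than 2× the object
diameter are pruned (sub-diameter spurs are thinning artifacts, not
structure); the reported length is the longest geodesic between
endpoints, in µm. A resample-to-isotropic + standard-thinning fallback
exists purely as a cross-check.

Two systematic errors and their handling:

* **End erosion.** Thinning retracts each tip by up to one radius, so a
  tube loses at most ~one diameter of length in total — negligible for
  high-aspect objects (50:1 here); no end-extension correction is
  applied by default.
* **Staircase inflation.** A 26-connected digital path zig-zags around
  the true centerline by up to half a voxel per axis. At 4.6:1
  anisotropy this is *not* a small effect: a single spurious z
  oscillation costs a full 500 nm step, and raw polyline lengths of
  oblique fibers run 15–25 % long. The corrected length therefore fits a
  cubic smoothing spline through the polyline whose residual budget is
  the voxel quantization variance, Σᵢ dᵢ²/12 per vertex — fixed entirely
  by the grid geometry, with no free parameter — and integrates its arc
  length. The uncorrected sum-of-steps total is still reported, because
  it is the quantity an uncorrected spatial-graph measurement yields and
  it is where residual optical distortion shows up as inflation.

## Synthetic phantoms

The generator emulates the calibration objects: sub-voxel beads (unit
impulses deposited with trilinear weights), microspheres, and fibers —
flat-capped tubes of default diameter 1 µm around a spline centerline.
Fiber populations draw true lengths from the stated normals (49.3 ± 2.3
and 17.9 ± 2.3 µm), orient uniformly on the sphere, and bend as circular
arcs with total turn uniform in [0°, 25°] ("mildly curved"). Objects are
rasterized by per-voxel volume fraction (3³ supersampling at the
surface), imaged by Gaussian-PSF convolution, optional flare (a 3× wider
Gaussian mixed at weight 0.15, fiber imaging only, emulating the
out-of-focus haze of raw wide-field stacks), Poisson noise scaled to an
expected peak photon count (8100 ≈ SNR 90; ~100 for the SNR 10 confocal
regime), additive read noise (σ = 3 counts), and optional 8-bit
quantization under the one-saturated-pixel exposure rule.

What the phantoms do *not* emulate: depth-dependent spherical
aberration, refractive-index mismatch, structured defocus lobes,
autofluorescent background, and physical distortion of the objects
themselves. Consequences worth stating plainly: (a) the smooth Gaussian
flare never crosses a half-max threshold, so the dramatic branching of
raw-data skeletons seen with real wide-field images appears here only as
extra staircase/thickness inflation of the *uncorrected* skeleton total,
not as gross branch artifacts; raw phantom stacks measured with the full
corrected estimator come out nearly unbiased, which real raw data would
not; (b) a deconvolved-only sphere measures slightly *wide* laterally
relative to z here (ratio ~1.1), whereas manual-threshold workflows on
real data report the opposite direction — that number is
threshold-convention-dependent and is not treated as a target.

## Experiment defaults (study conditions)

| parameter | default | note |
|---|---|---|
| preset | wf_water (dz 500, dxy 108 nm) | also wf_oil 250/68, clsm_water 400/66.4, clsm_oil 250/58.1 |
| PSF FWHM | 540 / 2000 nm | lateral / axial |
| photon_scale | 8100 | peak photons; √ gives SNR ≈ 90 |
| read_sigma | 3 counts | CCD-scale read noise |
| n_beads / n_spheres | 3 / 8 | spheres average the 500 nm z-phase quantization |
| fiber sets | 25 × N(49.3, 2.3²), 25 × N(17.9, 2.3²) µm | desk-scale samples of the two populations |
| fiber diameter | 1000 nm | configurable; not stated for the original fibers |
| curvature | ≤ 25° total bend | circular-arc model |
| binarization | half_max | manual/otsu available |
| prune cutoff | 2 × diameter | spurs are sub-diameter |
| polyline smoothing | on (quantization-variance spline) | fixed across every comparison |

Sample sizes are the package's own choice of desk scale; estimates
tighten as n grows but the conclusions (anisotropy ratio ~0.27 raw and
~1 restored, sphere ratio ~1 restored, fiber means within one population
SD) are stable across seeds at these sizes.

## Degenerate inputs and numerical choices

Constant images fail the FWHM fit with a diagnostic error; empty
thresholds raise with the threshold value; all-zero stacks refuse to
deconvolve; RL declares divergence only on three consecutive >1 % rises
of the update norm (plateau jitter is tolerated). Thinning tie-breaks
are deterministic (stable sort on the distance map, array order), so
skeletons are bit-reproducible. Reslicing is pure axis permutation —
never interpolation — and all reported lengths are computed in nm
internally and converted to µm at the interface.

## Known limitations

* Lengths below ~2 µm (a handful of voxels at this sampling) are at the
  resolution floor; the 2D projection baseline is then equally accurate.
* The z-extent of any single measured object is quantized at dz; ratios
  built from single objects inherit ±1-plane jumps (hence sphere
  averaging).
* The uncorrected-total inflation ordering (raw > deconvolved >
  restored) is reproduced in the mean; the deconvolved-vs-restored gap
  is small in this forward model because both are measured with the same
  automated threshold rather than by eye.
* Touching objects are rejected, not untangled: masks that merge in 3D
  (or projections that merge in 2D) flag every member object of the
  merged component as unmeasurable for that representation.
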