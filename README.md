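# cilia3d

Unbiased 3D length measurement of primary cilia, microfibers and other
thin curvilinear objects from fluorescence microscopy z-stacks.

## The problem

Primary cilia — solitary sensory organelles of 1–30 µm — are routinely
measured from 2D maximum-intensity projections of 3D stacks. A straight
object at polar angle θ to the focal plane projects to sin θ of its
length; averaged over uniformly random orientations, E[sin θ] = π/4, so
2D projection measurements systematically underestimate a randomly
oriented population by ~21 %, and more for bent objects. Measuring in 3D
instead runs into optical anisotropy: the axial point spread function
(PSF) is 3–4× wider than the lateral one (here 2000 nm vs 540 nm FWHM
for a wide-field water-immersion configuration at 108 nm pixels / 500 nm
z-steps), so objects smear along z and any 3D measurement is
direction-biased.

## The method

1. **Calibrate** — image a sub-resolution bead, plot the per-plane
   maximum intensity against z, fit a Gaussian; FWHM = 2√(2 ln 2)·σ gives
   the axial resolution. Reslice so y becomes the profiling axis and
   repeat for the lateral resolution. The xy:xz ratio (~0.27 raw)
   quantifies the anisotropy.
2. **Deconvolve** — Richardson–Lucy with the measured PSF
   (u ← u · Hᵀ(d / Hu)), stopping when the relative update norm falls
   below c/SNR.
3. **Isotropize** — blur every z-plane with a 2D Gaussian whose FWHM is
   √(fwhm_xz² − fwhm_xy²) (widths add in quadrature), making the
   effective PSF spherical so 3D measurements are direction-unbiased.
4. **Skeletonize** — binarize (half-max, Otsu, or manual threshold),
   erode to the centerline by deleting topology-preserving simple points
   in order of the anisotropic Euclidean distance map, prune sub-diameter
   spurs, and measure the longest geodesic path of the centerline
   polyline in physical units (with a digitization-variance smoothing
   spline to remove staircase inflation).

A synthetic-phantom module renders beads, 4 µm microspheres and curved
fibers of known length through the anisotropic-Gaussian-PSF forward
model with Poisson/read noise, so the whole chain is testable without a
microscope.

## Worked example

```python
import numpy as np
from cilia3d import (ExperimentConfig, NoiseSpec, apply_optics,
                     DeconSettings, deconvolve, estimate_resolution,
                     isotropize, plan_isotropizing_blur, binarize,
                     skeletonize3d, prune, measure)
from cilia3d.phantom import make_fiber_population, embed, render_object
from cilia3d.pipeline import calibrate_restoration, _fiber_margin

cfg = ExperimentConfig(seed=1)          # WF water: 108 nm xy, 500 nm z
cal = calibrate_restoration(cfg)        # bead calibration + blur plan
print(f"raw ratio {cal.summary()['raw']['ratio']:.3f} -> "
      f"restored {cal.summary()['decon_gb']['ratio']:.3f}")

spec = make_fiber_population(1, 49.3, 2.3, seed=7)[0]   # one ~50 um fiber
placed, shape = embed(spec, cfg.spacing, _fiber_margin(cfg))
raw = apply_optics(render_object(placed, shape, cfg.spacing), cfg.psf,
                   NoiseSpec(cfg.photon_scale, cfg.read_sigma, seed=11))
restored = isotropize(deconvolve(raw, cal.settings), cal.plan)
graph = prune(skeletonize3d(binarize(restored, largest_component=True)),
              2 * cfg.fiber_diameter)
length = measure(graph, smooth=True)["longest_path_um"]
print(f"true {spec.true_length/1000:.2f} um, measured {length:.2f} um")
```

Output:

```
raw ratio 0.271 -> restored 0.996
true 49.30 um, measured 48.05 um
```

The raw bead stack shows the 0.27 lateral-to-axial resolution ratio of
the anisotropic optics; after deconvolution and the isotropizing blur
the ratio is ~1, and the 3D skeleton recovers the fiber's true length to
within ~1.3 µm (the residual is tip erosion of roughly one fiber
diameter), where a 2D projection of the same tilted fiber would have
lost several micrometres.

The same steps are available from the shell:

```
cilia3d simulate --kind fiber --seed 7 --out fiber.tif
cilia3d calibrate --stack beads.tif --dz 500 --dxy 108 --out resolution.json
cilia3d restore --stack fiber.tif --dz 500 --dxy 108 \
    --psf-fwhm-xy 540 --psf-fwhm-z 2000 --snr 90 --sigma auto --out restored.tif
cilia3d skeletonize --stack restored.tif --dz 500 --dxy 108
cilia3d benchmark --seed 1 --outdir results/
```

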