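"""Experimental resolution (FWHM) measurement from bead stacks.

The procedure mirrors the classic bead-calibration workflow: for a stack
containing one isolated sub-resolution bead, record the maximum pixel
intensity of every z-plane, plot it against the plane's physical z
position, and fit a Gaussian; the fitted full-width half maximum is the
axial resolution.  Reslicing the stack so that y becomes the plane axis
and repeating the same per-plane-maximum fit yields the lateral
resolution.  The ratio of lateral to axial FWHM quantifies the optical
anisotropy that the restoration stage must remove (about 0.27 for the
wide-field water-immersion configuration modelled here).

Because the bead has finite size, the estimate is of the bead (x) PSF
product; no finite-bead correction is applied, matching how experimental
resolutions are usually reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

from .errors import EstimationError, ValidationError
from .imagestack import VoxelGrid, reslice
from .phantom import FWHM_TO_SIGMA


@dataclass
class Profile:
    """Per-plane maximum intensity versus physical position."""

    positions: np.ndarray  # nm
    values: np.ndarray
    saturated: bool = False  # flat top over more than 3 planes


@dataclass
class FWHMFit:
    fwhm: float  # nm
    sigma: float
    center: float
    amplitude: float
    baseline: float
    r_squared: float
    fwhm_se: float  # standard error of the FWHM from the fit covariance


@dataclass
class ResolutionEstimate:
    """Measured lateral and axial FWHM and their ratio.

    ``ratio`` is recomputed from the stored FWHM values; for raw optical
    data it is below 1 (axial resolution is worse), and can exceed 1 after
    deliberate lateral over-blurring.
    """

    fwhm_xy: float  # nm
    fwhm_xz: float  # nm
    fit_quality: dict = field(default_factory=dict)  # axis -> R^2
    fwhm_se: dict = field(default_factory=dict)  # axis -> fit SE (nm)

    @property
    def ratio(self) -> float:
        return self.fwhm_xy / self.fwhm_xz


def axial_profile(grid: VoxelGrid) -> Profile:
    """Maximum intensity of each z-plane against its physical z position."""
    values = grid.data.reshape(grid.shape[0], -1).max(axis=1).astype(float)
    positions = grid.positions("z")
    peak = values.max()
    saturated = bool(np.count_nonzero(values == peak) > 3)
    return Profile(positions, values, saturated)


def _gaussian(x, amplitude, center, sigma, baseline):
    return baseline + amplitude * np.exp(-0.5 * ((x - center) / sigma) ** 2)


def fwhm_from_profile(profile: Profile, p0: tuple | None = None, min_r2: float = 0.9) -> FWHMFit:
    """Least-squares Gaussian fit of a single-peaked intensity profile.

    The model has amplitude, centre, sigma and baseline; FWHM is
    ``2 sqrt(2 ln 2) * sigma``.  The default initializer uses the max for
    the amplitude, the argmax for the centre, the half-max crossing width
    for sigma and the min for the baseline, and can be overridden via
    ``p0``.  Raises :class:`EstimationError` (with diagnostics) for
    multi-peaked profiles, non-convergent fits and fits with R^2 below
    ``min_r2``.
    """
    x = np.asarray(profile.positions, float)
    y = np.asarray(profile.values, float)
    if len(x) < 5:
        raise ValidationError("profile needs at least 5 points")
    span = float(y.max() - y.min())
    if span <= 0:
        raise EstimationError("profile is constant; no peak to fit")
    peaks, _ = signal.find_peaks(y, prominence=0.2 * span)
    if len(peaks) > 1:
        raise EstimationError(
            f"profile has {len(peaks)} peaks; expected a single bead",
            diagnostics={"peaks": peaks.tolist()},
        )
    if p0 is None:
        amp0 = span
        c0 = float(x[np.argmax(y)])
        base0 = float(y.min())
        half = base0 + 0.5 * amp0
        above = x[y > half]
        width = float(above.max() - above.min()) if len(above) > 1 else float(np.ptp(x)) / 4
        p0 = (amp0, c0, max(width / 2.0, np.diff(x).min() / 4), base0)
    try:
        popt, pcov = optimize.curve_fit(_gaussian, x, y, p0=p0, maxfev=10000)
    except RuntimeError as exc:
        raise EstimationError(f"Gaussian fit did not converge: {exc}") from exc
    amplitude, center, sigma, baseline = popt
    sigma = abs(sigma)
    resid = y - _gaussian(x, *popt)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    if r2 < min_r2:
        raise EstimationError(
            f"Gaussian fit R^2 = {r2:.3f} below {min_r2}",
            diagnostics={"popt": popt.tolist(), "r_squared": r2},
        )
    k = 1.0 / FWHM_TO_SIGMA  # 2 sqrt(2 ln 2)
    sigma_se = float(np.sqrt(np.abs(pcov[2, 2]))) if np.all(np.isfinite(pcov)) else np.nan
    return FWHMFit(
        fwhm=k * sigma,
        sigma=sigma,
        center=float(center),
        amplitude=float(amplitude),
        baseline=float(baseline),
        r_squared=r2,
        fwhm_se=k * sigma_se,
    )


def estimate_resolution(bead_stack: VoxelGrid) -> ResolutionEstimate:
    """Lateral and axial FWHM of a single-bead stack.

    Axial: per-plane-maximum profile along z of the stack as acquired.
    Lateral: the same procedure after reslicing to the xz view, so that y
    becomes the profiling axis.
    """
    fit_z = fwhm_from_profile(axial_profile(bead_stack))
    fit_y = fwhm_from_profile(axial_profile(reslice(bead_stack, "xz")))
    return ResolutionEstimate(
        fwhm_xy=fit_y.fwhm,
        fwhm_xz=fit_z.fwhm,
        fit_quality={"xy": fit_y.r_squared, "xz": fit_z.r_squared},
        fwhm_se={"xy": fit_y.fwhm_se, "xz": fit_z.fwhm_se},
    )
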