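"""Synthetic calibration phantoms and the optical forward model.

This module stands in for the physical calibration objects of the wet
experiment: sub-resolution beads (point sources), 4 um microspheres and
electrospun microfibers of known length embedded in an agarose block.  Each
object is rasterized into an anisotropically sampled voxel grid by partial
volume (supersampled volume fraction per voxel), then pushed through an
optical forward model: convolution with a separable anisotropic Gaussian
point spread function, Poisson photon noise, and additive Gaussian read
noise.  The Gaussian PSF is an explicit modelling choice: the wide-field
axial response is well approximated by a Gaussian, and the whole
isotropization strategy downstream relies on that approximation.

Coordinates follow the package-wide ``(z, y, x)`` order in nanometres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import interpolate, ndimage
from scipy.spatial import cKDTree

from .errors import ValidationError
from .imagestack import VoxelGrid

#: sigma = FWHM_TO_SIGMA * FWHM for a Gaussian
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass
class PSFModel:
    """Separable anisotropic Gaussian point spread function.

    ``fwhm_lateral`` applies to both in-plane axes (x and y),
    ``fwhm_axial`` to z; both in nm.  The axial width normally exceeds the
    lateral one by a factor 3-4 for wide-field optics.
    """

    fwhm_lateral: float
    fwhm_axial: float

    def __post_init__(self):
        if self.fwhm_lateral <= 0 or self.fwhm_axial <= 0:
            raise ValidationError("PSF FWHM values must be positive")

    @property
    def sigmas(self) -> tuple[float, float, float]:
        """(sigma_z, sigma_y, sigma_x) in nm."""
        s_lat = self.fwhm_lateral * FWHM_TO_SIGMA
        return (self.fwhm_axial * FWHM_TO_SIGMA, s_lat, s_lat)


@dataclass
class NoiseSpec:
    """Detection-noise model.

    photon_scale is the expected photon count at the brightest voxel
    (so SNR ~= sqrt(photon_scale) in the shot-noise limit); 0 disables
    Poisson noise.  read_sigma is the additive Gaussian read noise SD in
    the same count units.  The same seed and spec give bit-identical
    output.
    """

    photon_scale: float = 0.0
    read_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.photon_scale < 0 or self.read_sigma < 0:
            raise ValidationError("noise parameters must be non-negative")


@dataclass
class PhantomSpec:
    """Ground-truth description of one synthetic object.

    For fibers ``centerline`` holds the ordered spline control points (nm);
    the smooth curve through them (see :func:`fiber_curve`) is the true
    centerline and ``true_length`` its converged arc length.  Beads and
    spheres are located by ``center``; a bead is a sub-voxel impulse of
    unit integrated intensity regardless of its nominal diameter.
    """

    kind: str  # bead | sphere | fiber
    diameter: float  # nm
    center: np.ndarray | None = None  # (z, y, x) nm
    centerline: np.ndarray | None = None  # (n, 3) control points, nm
    object_intensity: float = 1.0
    background_intensity: float = 0.0
    true_length: float | None = None  # nm, fibers only
    name: str = ""

    def __post_init__(self):
        if self.kind not in ("bead", "sphere", "fiber"):
            raise ValidationError(f"unknown phantom kind {self.kind!r}")
        if self.diameter <= 0:
            raise ValidationError("diameter must be positive")
        if self.kind == "fiber":
            self.centerline = np.atleast_2d(np.asarray(self.centerline, float))
            if self.centerline.shape[0] < 2 or self.centerline.shape[1] != 3:
                raise ValidationError("fiber centerline needs >= 2 control points")
            if self.true_length is None:
                self.true_length = arc_length(self.centerline)
        else:
            if self.center is None:
                raise ValidationError(f"{self.kind} phantom needs a center")
            self.center = np.asarray(self.center, float)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned physical bounding box (lo, hi) in nm, incl. radius."""
        r = self.diameter / 2.0
        if self.kind == "fiber":
            pts = fiber_curve(self.centerline, 256)
            return pts.min(axis=0) - r, pts.max(axis=0) + r
        if self.kind == "bead":
            return self.center.copy(), self.center.copy()
        return self.center - r, self.center + r

    def shifted(self, offset) -> "PhantomSpec":
        offset = np.asarray(offset, float)
        if self.kind == "fiber":
            return replace(self, centerline=self.centerline + offset)
        return replace(self, center=self.center + offset)


# ---------------------------------------------------------------------------
# centerline geometry


def fiber_curve(control_points: np.ndarray, n: int) -> np.ndarray:
    """Evaluate the smooth interpolating spline through the control points.

    Degree is min(3, n_ctrl - 1); with two control points this is the
    straight chord.  Returns ``n`` points including both endpoints.
    """
    ctrl = np.atleast_2d(np.asarray(control_points, float))
    k = min(3, len(ctrl) - 1)
    if k < 1:
        raise ValidationError("need at least 2 control points")
    if k == 1:
        t = np.linspace(0.0, 1.0, n)[:, None]
        seg = np.linspace(0, 1, len(ctrl))
        return np.stack(
            [np.interp(t[:, 0], seg, ctrl[:, j]) for j in range(3)], axis=1
        )
    tck, _ = interpolate.splprep(ctrl.T, k=k, s=0)
    u = np.linspace(0.0, 1.0, n)
    return np.stack(interpolate.splev(u, tck), axis=1)


def _polyline_length(pts: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def arc_length(control_points: np.ndarray, rtol: float = 1e-4) -> float:
    """Arc length (nm) of the spline through the control points.

    The polyline is refined (doubling the sample count) until successive
    estimates agree to ``rtol`` (0.01 %).
    """
    ctrl = np.atleast_2d(np.asarray(control_points, float))
    if len(ctrl) == 2:
        return float(np.linalg.norm(ctrl[1] - ctrl[0]))
    n = 64
    prev = _polyline_length(fiber_curve(ctrl, n))
    for _ in range(12):
        n *= 2
        cur = _polyline_length(fiber_curve(ctrl, n))
        if prev > 0 and abs(cur - prev) / prev < rtol:
            return cur
        prev = cur
    return prev


def projected_arc_length(control_points: np.ndarray, axis: str = "z") -> float:
    """Arc length of the centerline's orthogonal projection (nm).

    Projecting along z keeps (y, x).  By the triangle inequality this is
    never longer than the 3D arc length, with equality only for curves
    lying in a single plane perpendicular to the projection axis - the
    geometric mechanism by which maximum-projection measurements
    underestimate tilted objects.
    """
    ax = {"z": 0, "y": 1, "x": 2}[axis]
    pts = fiber_curve(np.atleast_2d(np.asarray(control_points, float)), 4096)
    keep = [i for i in range(3) if i != ax]
    return _polyline_length(pts[:, keep])


# ---------------------------------------------------------------------------
# population generator


def make_fiber_population(
    n: int,
    length_mean: float,
    length_sd: float,
    diameter: float = 1000.0,
    curvature: float = 25.0,
    seed: int = 0,
) -> list[PhantomSpec]:
    """Draw a population of randomly posed, mildly curved fiber phantoms.

    Parameters
    ----------
    n : int
        Population size.
    length_mean, length_sd : float
        Mean and SD of the true-length distribution in micrometres
        (normal, truncated to positive lengths longer than the diameter).
    diameter : float
        Fiber diameter in nm (circular cross-section).
    curvature : float
        Maximum total bend angle in degrees; each fiber is a circular arc
        with a turn drawn uniformly from [0, curvature], represented by
        three spline control points (two when the draw is ~straight).
    seed : int
        Seeds the whole population; identical seeds reproduce the
        population bit-exactly.

    The fibers are centred at the origin with uniform-on-sphere
    orientation; the realized spline arc length is rescaled to match the
    drawn length and recorded as ``true_length``.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if length_sd < 0:
        raise ValidationError("length_sd must be >= 0")
    if length_mean * 1000.0 <= diameter:
        raise ValidationError("mean length must exceed the fiber diameter")
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n):
        L = 0.0
        while L * 1000.0 <= diameter:
            L = rng.normal(length_mean, length_sd)
        L_nm = L * 1000.0
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        bend = math.radians(rng.uniform(0.0, curvature))
        ctrl = _arc_control_points(L_nm, u, bend, rng)
        # rescale so the realized spline length equals the drawn length
        for _ in range(3):
            realized = arc_length(ctrl)
            ctrl = ctrl * (L_nm / realized)
        specs.append(
            PhantomSpec(
                kind="fiber",
                diameter=diameter,
                centerline=ctrl,
                true_length=arc_length(ctrl),
                name=f"fiber_{i:03d}",
            )
        )
    return specs


def _arc_control_points(L: float, u: np.ndarray, bend: float, rng) -> np.ndarray:
    """Control points of a circular arc of length L, tangent direction u.

    ``bend`` is the total turn angle along the arc; 0 gives a straight
    segment (two points).  The bend plane is chosen uniformly around u.
    """
    if bend < 1e-3:
        return np.stack([-0.5 * L * u, 0.5 * L * u])
    # orthonormal frame (u, v)
    a = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    v1 = np.cross(u, a)
    v1 /= np.linalg.norm(v1)
    v2 = np.cross(u, v1)
    phi = rng.uniform(0, 2 * math.pi)
    v = math.cos(phi) * v1 + math.sin(phi) * v2
    R = L / bend
    # arc in the (u, v) plane, parameterized by angle from -bend/2..bend/2
    ang = np.array([-bend / 2, 0.0, bend / 2])
    pts = R * np.outer(np.sin(ang), u) + R * np.outer(1.0 - np.cos(ang), v)
    return pts - pts.mean(axis=0)


# ---------------------------------------------------------------------------
# rasterization


def embed(
    spec: PhantomSpec,
    spacing,
    margin,
    rng: np.random.Generator | None = None,
):
    """Translate a phantom into a grid that contains it with ``margin``.

    ``margin`` is a scalar or (z, y, x) triple in nm; it should be at
    least the PSF support so the forward model does not clip the object.
    Returns ``(shifted_spec, shape)``.  If ``rng`` is given the object is
    additionally jittered by a random sub-voxel offset so phantoms do not
    all sit at the same grid phase.
    """
    spacing = np.asarray(spacing, float)
    margin = np.broadcast_to(np.asarray(margin, float), (3,))
    lo, hi = spec.bounds()
    jitter = rng.uniform(0, spacing) if rng is not None else np.zeros(3)
    offset = margin - lo + jitter
    extent = (hi - lo) + 2 * margin + jitter
    shape = tuple(int(np.ceil(e / s)) + 1 for e, s in zip(extent, spacing))
    return spec.shifted(offset), shape


def render_object(
    spec: PhantomSpec,
    shape,
    spacing,
    supersample: int = 3,
    dtype=np.float32,
) -> VoxelGrid:
    """Rasterize a phantom into a grid by per-voxel volume fraction.

    Each voxel's value is ``object_intensity`` times the fraction of the
    voxel inside the object (estimated on a ``supersample**3`` sub-grid for
    voxels straddling the surface) plus ``background_intensity``.  A bead
    is a sub-voxel impulse: its integrated intensity, ``object_intensity``,
    is split over the 8 nearest voxels with trilinear weights.
    """
    shape = tuple(int(s) for s in shape)
    spacing = np.asarray(spacing, float)
    lo, hi = spec.bounds()
    grid_hi = (np.array(shape) - 1) * spacing
    if np.any(lo < -1e-6) or np.any(hi > grid_hi + 1e-6):
        raise ValidationError(
            f"object bounds {lo}..{hi} exceed grid extent 0..{grid_hi}"
        )
    out = np.full(shape, float(spec.background_intensity), dtype=dtype)
    if spec.kind == "bead":
        _deposit_impulse(out, spec.center / spacing, spec.object_intensity)
        return VoxelGrid(out, tuple(spacing), name=spec.name)
    if spec.kind == "sphere":
        frac = _sphere_fraction(shape, spacing, spec.center, spec.diameter / 2, supersample)
    else:
        frac = _fiber_fraction(shape, spacing, spec, supersample)
    out += spec.object_intensity * frac.astype(dtype)
    return VoxelGrid(out, tuple(spacing), name=spec.name)


def _deposit_impulse(out, idx, total):
    base = np.floor(idx).astype(int)
    frac = idx - base
    for dz in (0, 1):
        for dy in (0, 1):
            for dx in (0, 1):
                w = (
                    (frac[0] if dz else 1 - frac[0])
                    * (frac[1] if dy else 1 - frac[1])
                    * (frac[2] if dx else 1 - frac[2])
                )
                z, y, x = base + (dz, dy, dx)
                if 0 <= z < out.shape[0] and 0 <= y < out.shape[1] and 0 <= x < out.shape[2]:
                    out[z, y, x] += total * w


def _subvoxel_offsets(spacing, supersample):
    """Sub-voxel sample offsets (nm) of an s^3 stratified grid, per axis."""
    s = supersample
    off1 = (np.arange(s) + 0.5) / s - 0.5
    oz, oy, ox = np.meshgrid(off1 * spacing[0], off1 * spacing[1], off1 * spacing[2], indexing="ij")
    return np.stack([oz.ravel(), oy.ravel(), ox.ravel()], axis=1)


def _sphere_fraction(shape, spacing, center, radius, supersample):
    coords = [np.arange(n) * s - c for n, s, c in zip(shape, spacing, center)]
    dz2 = coords[0][:, None, None] ** 2
    dy2 = coords[1][None, :, None] ** 2
    dx2 = coords[2][None, None, :] ** 2
    dist = np.sqrt(dz2 + dy2 + dx2)
    h = 0.5 * float(np.linalg.norm(spacing))
    frac = (dist <= radius - h).astype(np.float64)
    shell = np.abs(dist - radius) < h
    if np.any(shell):
        idx = np.argwhere(shell)
        centers = idx * spacing
        offs = _subvoxel_offsets(spacing, supersample)
        sub = centers[:, None, :] + offs[None, :, :]  # (m, s^3, 3)
        d = np.linalg.norm(sub - np.asarray(center, float), axis=2)
        frac[shell] = (d <= radius).mean(axis=1)
    return frac


def _fiber_fraction(shape, spacing, spec: PhantomSpec, supersample):
    """Volume fraction of a flat-capped tube around the centerline curve.

    The tube is the set of points within ``radius`` of the curve, clipped
    by the planes normal to the end tangents (cut fibers have flat ends,
    not the hemispherical caps a pure distance criterion would give).
    """
    radius = spec.diameter / 2.0
    step = min(40.0, radius / 4.0)
    n = max(2, int(np.ceil(spec.true_length / step)) + 1)
    samples = fiber_curve(spec.centerline, n)
    h = 0.5 * float(np.linalg.norm(spacing))
    # exact distance-to-sampled-centerline field in a band of radius
    # r + h around the curve; everything further out is background
    dist = _paint_distance(shape, spacing, samples, radius + h)
    t0 = samples[1] - samples[0]
    t0 /= np.linalg.norm(t0)
    t1 = samples[-1] - samples[-2]
    t1 /= np.linalg.norm(t1)

    def _overhang(points):
        # positive when the point lies beyond a flat end cap
        o0 = -np.einsum("...i,i->...", points - samples[0], t0)
        o1 = np.einsum("...i,i->...", points - samples[-1], t1)
        return np.maximum(o0, o1)

    coords = np.stack(
        np.meshgrid(*[np.arange(s) * d for s, d in zip(shape, spacing)], indexing="ij"),
        axis=-1,
    ).astype(np.float32)
    near = dist <= radius + h
    over = np.full(shape, np.inf, np.float32)
    over[near] = _overhang(coords[near])
    frac = ((dist <= radius - h) & (over <= -h)).astype(np.float64)
    shell = near & ~((dist <= radius - h) & (over <= -h)) & (over < h)
    if np.any(shell):
        idx = np.argwhere(shell)
        centers = idx * spacing
        offs = _subvoxel_offsets(spacing, supersample)
        tree = cKDTree(samples)
        m = len(idx)
        sub = (centers[:, None, :] + offs[None, :, :]).reshape(m * len(offs), 3)
        d, _ = tree.query(sub)
        inside = (d <= radius) & (_overhang(sub) <= 0)
        frac[shell] = inside.reshape(m, len(offs)).mean(axis=1)
    return frac


def _paint_distance(shape, spacing, samples, reach):
    """Min distance (nm) from each voxel centre to the sample points,
    computed only within ``reach`` of the polyline (inf elsewhere)."""
    dist = np.full(shape, np.inf, dtype=np.float32)
    half = np.ceil(reach / spacing).astype(int)
    coords = [np.arange(n) * s for n, s in zip(shape, spacing)]
    for p in samples:
        c = np.round(p / spacing).astype(int)
        lo = np.maximum(c - half, 0)
        hi = np.minimum(c + half + 1, shape)
        if np.any(lo >= hi):
            continue
        sl = tuple(slice(a, b) for a, b in zip(lo, hi))
        dz = coords[0][sl[0]] - p[0]
        dy = coords[1][sl[1]] - p[1]
        dx = coords[2][sl[2]] - p[2]
        d = np.sqrt(
            dz[:, None, None] ** 2 + dy[None, :, None] ** 2 + dx[None, None, :] ** 2
        ).astype(np.float32)
        np.minimum(dist[sl], d, out=dist[sl])
    return dist


# ---------------------------------------------------------------------------
# optics


def render_psf_kernel(psf: PSFModel, spacing, n_sigma: float = 4.0) -> VoxelGrid:
    """Sample the separable Gaussian PSF on a voxel grid, normalized to sum 1.

    The support extends ``n_sigma`` standard deviations per axis (>= 3
    required so that the truncated mass stays below 0.1 %).
    """
    if n_sigma < 3.0:
        raise ValidationError("kernel support must be at least 3 sigma per axis")
    spacing = np.asarray(spacing, float)
    sigmas = np.asarray(psf.sigmas)
    half = np.maximum(np.ceil(n_sigma * sigmas / spacing).astype(int), 1)
    axes = []
    for h, s, d in zip(half, sigmas, spacing):
        x = np.arange(-h, h + 1) * d
        axes.append(np.exp(-0.5 * (x / s) ** 2))
    kernel = axes[0][:, None, None] * axes[1][None, :, None] * axes[2][None, None, :]
    kernel /= kernel.sum()
    return VoxelGrid(kernel, tuple(spacing), name="psf_kernel")


def gaussian_convolve(data: np.ndarray, psf: PSFModel, spacing) -> np.ndarray:
    """Convolve with the Gaussian PSF via separable filtering (reflect edges).

    Mathematically identical to convolution with the rendered kernel but
    O(N) per axis; used by both the forward model and deconvolution.
    """
    sigmas_px = [s / d for s, d in zip(psf.sigmas, spacing)]
    return ndimage.gaussian_filter(data, sigmas_px, mode="reflect")


def apply_optics(
    grid: VoxelGrid,
    psf: PSFModel,
    noise: NoiseSpec | None = None,
    flare_weight: float = 0.0,
    flare_scale: float = 3.0,
    quantize_8bit: bool = False,
) -> VoxelGrid:
    """Image a phantom grid through the optical forward model.

    Convolution with the PSF (plus an optional 'flare' component: the same
    object blurred by a ``flare_scale`` x wider Gaussian, mixed in with
    weight ``flare_weight`` to emulate the out-of-focus haze around bright
    objects in raw wide-field stacks), then Poisson photon noise scaled so
    the brightest voxel expects ``photon_scale`` counts, then additive read
    noise, then optional 8-bit quantization with the exposure convention
    that only the single brightest voxel reaches 255.
    """
    data = np.asarray(grid.data, np.float32)
    blurred = gaussian_convolve(data, psf, grid.spacing)
    if flare_weight > 0:
        wide = PSFModel(psf.fwhm_lateral * flare_scale, psf.fwhm_axial * flare_scale)
        blurred = (1.0 - flare_weight) * blurred + flare_weight * gaussian_convolve(
            data, wide, grid.spacing
        )
    out = blurred
    if noise is not None and (noise.photon_scale > 0 or noise.read_sigma > 0):
        rng = np.random.default_rng(noise.seed)
        peak = float(out.max())
        if noise.photon_scale > 0 and peak > 0:
            scale = noise.photon_scale / peak
            counts = rng.poisson(np.asarray(out, np.float64) * scale).astype(np.float64)
            if noise.read_sigma > 0:
                counts += rng.normal(0.0, noise.read_sigma, size=out.shape)
            out = np.clip(counts / scale, 0, None).astype(np.float32)
        elif noise.read_sigma > 0:
            out = np.clip(
                out + rng.normal(0.0, noise.read_sigma, size=out.shape), 0, None
            ).astype(np.float32)
    result = VoxelGrid(out, grid.spacing, bit_depth=grid.bit_depth, name=grid.name)
    if quantize_8bit:
        from .imagestack import to_8bit

        result = to_8bit(result)
    return result
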