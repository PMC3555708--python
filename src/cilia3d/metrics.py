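"""2D baseline measurements, sphere-diameter ratios and population statistics.

The 2D baseline re-creates the common practice of measuring object length
on a maximum-intensity projection: project along z, binarize, thin to a
2D centerline, and take the longest geodesic.  Projection geometry makes
this a biased estimator for randomly oriented objects — a straight
segment at polar angle theta projects to sin(theta) of its length, and
averaging over the uniform sphere gives pi/4 (~0.785) of the true mean.

The accuracy bookkeeping follows a calibration mindset: a method's mean
is deemed accurate when it falls within one standard deviation of the
generating population mean (inclusive at the boundary), and methods are
compared to the population with a one-sample Z test using the population
SD, z = (x̄ - mu) / (sd / sqrt(n)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .errors import ThresholdError, ValidationError
from .imagestack import VoxelGrid, max_projection
from .skeleton import BinaryMask, measure, skeletonize3d, threshold_value


@dataclass
class PopulationSummary:
    mean: float  # um
    sd: float  # um
    n: int

    def __post_init__(self):
        if self.sd < 0 or self.n < 1:
            raise ValidationError("population needs sd >= 0 and n >= 1")


@dataclass
class LengthMeasurement:
    object_id: str
    method: str  # mp2d | skel3d_raw | skel3d_decon | skel3d_decon_gb
    length: float  # um (0 when rejected)
    rejected: bool = False
    reason: str = ""


def mp_length(
    grid: VoxelGrid,
    method: str = "half_max",
    manual_threshold: float | None = None,
    smooth: bool = False,
) -> float:
    """Length (um) of a fiber-like object from its z maximum projection.

    Deterministic stand-in for a manual line-tool trace: binarize the
    projection, keep the largest component, thin to a 2D centerline and
    measure the longest geodesic with the in-plane pixel spacing.
    Raises :class:`ThresholdError` when binarization comes up empty.
    """
    img, (dy, dx) = max_projection(grid, "z")
    t = threshold_value(img, method, manual_threshold)
    mask2d = img >= t
    if not mask2d.any():
        raise ThresholdError(f"empty 2D binarization at threshold {t:g}", threshold=t)
    labels, n = ndimage.label(mask2d, structure=np.ones((3, 3), int))
    if n > 1:
        sizes = ndimage.sum_labels(mask2d, labels, index=np.arange(1, n + 1))
        mask2d = labels == (1 + int(np.argmax(sizes)))
    # lift to a one-plane volume; thinning in a single plane reduces to 2D
    mask = BinaryMask(
        mask2d[None], (max(dy, dx), dy, dx), threshold_used=t, method=method
    )
    graph = skeletonize3d(mask)
    return measure(graph, smooth=smooth)["longest_path_um"]


@dataclass
class SphereDiameters:
    d_xy: float  # um
    d_xz: float  # um

    @property
    def ratio(self) -> float:
        return self.d_xy / self.d_xz


def sphere_diameters(grid: VoxelGrid, method: str = "half_max") -> SphereDiameters:
    """xy and xz diameters (um) of a single sphere from binary projections.

    The z-projection is binarized and the mean of the Feret (axis-aligned)
    extents along x and y gives d_xy; the y-projection (xz view) gives the
    extent along z as d_xz.  Axial smearing in raw data shows up as
    ratio d_xy/d_xz < 1.
    """
    img_z, (dy, dx) = max_projection(grid, "z")
    img_y, (dz, _) = max_projection(grid, "y")
    out = []
    for img, sp_row, sp_col in ((img_z, dy, dx), (img_y, dz, dx)):
        t = threshold_value(img, method)
        m = img >= t
        if not m.any():
            raise ThresholdError(f"empty sphere projection at threshold {t:g}", threshold=t)
        rows = np.flatnonzero(m.any(axis=1))
        cols = np.flatnonzero(m.any(axis=0))
        out.append(
            (
                (rows[-1] - rows[0] + 1) * sp_row,
                (cols[-1] - cols[0] + 1) * sp_col,
            )
        )
    (ext_y, ext_x), (ext_z, _) = out
    return SphereDiameters(d_xy=(ext_x + ext_y) / 2.0 / 1000.0, d_xz=ext_z / 1000.0)


def z_test(sample, population: PopulationSummary) -> tuple[float, float]:
    """One-sample Z test of a sample mean against a known population.

    ``z = (mean(sample) - mu) / (sd / sqrt(n_sample))`` with the two-sided
    p-value from the standard normal.
    """
    sample = np.asarray(sample, float)
    if sample.size < 2:
        raise ValidationError("z test needs a sample of n >= 2")
    if population.sd <= 0:
        raise ValidationError("population sd must be positive for a Z test")
    z = (sample.mean() - population.mean) / (population.sd / math.sqrt(sample.size))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def within_one_sd(sample_mean: float, population: PopulationSummary) -> bool:
    """Accuracy criterion: |mean - mu| <= sd, inclusive at the boundary."""
    return abs(sample_mean - population.mean) <= population.sd


def rejection_rate(n_rejected: int, n_total: int) -> float:
    """Percentage of objects excluded from analysis."""
    if n_total < 1:
        raise ValidationError("n_total must be >= 1")
    if not 0 <= n_rejected <= n_total:
        raise ValidationError("need 0 <= n_rejected <= n_total")
    return 100.0 * n_rejected / n_total


def rejected_by_contact(object_masks) -> list[bool]:
    """Flag objects whose binary masks merge into a shared component.

    Mirrors the touching-objects exclusion rule: if the union of the
    per-object masks contains a connected component holding more than one
    object, every object in that component is rejected for the method the
    masks came from.  Works for 3D masks and for 2D projection masks
    (pass 2D arrays), where objects separated only along z merge and both
    get thrown out.
    """
    masks = [np.asarray(m, bool) for m in object_masks]
    if not masks:
        return []
    union = np.logical_or.reduce(masks)
    structure = np.ones((3,) * union.ndim, int)
    labels, _ = ndimage.label(union, structure=structure)
    owners: dict[int, set[int]] = {}
    for i, m in enumerate(masks):
        for lab in np.unique(labels[m]):
            if lab:
                owners.setdefault(int(lab), set()).add(i)
    rejected = [False] * len(masks)
    for members in owners.values():
        if len(members) > 1:
            for i in members:
                rejected[i] = True
    return rejected


def summarize_method(
    measurements: list[LengthMeasurement], population: PopulationSummary
) -> dict:
    """Per-method summary: mean, sd, n, Z statistic, accuracy flag."""
    lengths = np.array([m.length for m in measurements if not m.rejected], float)
    n_rej = sum(m.rejected for m in measurements)
    out = {
        "n": int(lengths.size),
        "n_rejected": int(n_rej),
        "rejection_pct": rejection_rate(n_rej, len(measurements)) if measurements else 0.0,
    }
    if lengths.size:
        out["mean_um"] = float(lengths.mean())
        out["sd_um"] = float(lengths.std(ddof=1)) if lengths.size > 1 else 0.0
        out["within_one_sd"] = within_one_sd(out["mean_um"], population)
    if lengths.size >= 2:
        z, p = z_test(lengths, population)
        out["z"] = z
        out["p"] = p
    return out
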