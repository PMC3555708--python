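import numpy as np
import networkx as nx
import pytest

from cilia3d.errors import ThresholdError, ValidationError
from cilia3d.imagestack import VoxelGrid
from cilia3d.phantom import PhantomSpec, embed, render_object
from cilia3d.skeleton import (
    BinaryMask,
    binarize,
    graph_from_skeleton,
    measure,
    prune,
    skeleton_length,
    skeletonize3d,
)

WF = (500.0, 108.0, 108.0)
ISO = (1.0, 1.0, 1.0)


def _tube_mask(shape, axis_len, radius, spacing=ISO):
    """Axis-aligned solid tube along x, centred in z/y."""
    nz, ny, nx = shape
    zz, yy = np.mgrid[0:nz, 0:ny]
    disk = ((zz - nz // 2) * spacing[0]) ** 2 + ((yy - ny // 2) * spacing[1]) ** 2 <= radius**2
    mask = np.zeros(shape, bool)
    x0 = (nx - axis_len) // 2
    mask[:, :, x0 : x0 + axis_len] = disk[:, :, None]
    return BinaryMask(mask, spacing, 0.5, "manual")


class TestBinarize:
    def test_manual_threshold_above_max_is_empty(self, wf_spacing):
        g = VoxelGrid(np.ones((4, 6, 6)), wf_spacing)
        with pytest.raises(ThresholdError):
            binarize(g, "manual", manual_threshold=2.0)

    def test_manual_threshold_below_min_is_full(self, wf_spacing):
        g = VoxelGrid(np.ones((4, 6, 6)), wf_spacing)
        assert binarize(g, "manual", manual_threshold=0.5).mask.all()

    def test_halfmax_on_rendered_sphere_recovers_diameter(self):
        # noise-free partial-volume sphere: half-max edge within 1 voxel
        d = 4000.0
        spec = PhantomSpec(kind="sphere", diameter=d, center=np.array([3000.0, 3000.0, 3000.0]))
        grid = render_object(spec, (13, 56, 56), WF)
        mask = binarize(grid, "half_max").mask
        for ax, pitch in ((0, 500.0), (1, 108.0), (2, 108.0)):
            other = tuple(i for i in range(3) if i != ax)
            extent = np.flatnonzero(mask.any(axis=other))
            width = (extent[-1] - extent[0] + 1) * pitch
            assert abs(width - d) <= pitch + 1e-6

    def test_threshold_sensitivity_on_fiber(self):
        # observers disagreeing by +/-10 % around half-max change the
        # skeleton length by < 2 % for a high-contrast fiber
        ctrl = np.array([[1500.0, 1500.0, 1200.0], [1500.0, 2200.0, 26200.0]])
        spec = PhantomSpec(kind="fiber", diameter=1000.0, centerline=ctrl)
        grid = render_object(spec, (7, 35, 256), WF)
        from cilia3d.skeleton import threshold_value

        t = threshold_value(grid.data, "half_max")
        lengths = []
        for factor in (0.9, 1.1):
            mask = binarize(grid, "manual", manual_threshold=t * factor)
            lengths.append(measure(skeletonize3d(mask), smooth=True)["longest_path_um"])
        assert abs(lengths[0] - lengths[1]) / lengths[1] < 0.02

    def test_largest_component_isolation(self, wf_spacing):
        data = np.zeros((5, 10, 10))
        data[2, 2:8, 2:8] = 1.0  # big blob
        data[0, 0, 0] = 1.0  # speck
        m = binarize(VoxelGrid(data, wf_spacing), "manual", 0.5, largest_component=True)
        assert m.mask.sum() == 36


class TestThinning:
    def test_straight_tube_thins_to_axis(self):
        g = skeletonize3d(_tube_mask((11, 13, 105), 101, 4.5))
        m = measure(g)
        assert m["n_branches"] == 1
        sk = np.argwhere(g.skeleton)
        # stays on/near the axis, spans most of the tube minus end erosion
        assert np.ptp(sk[:, 1]) <= 1 and np.ptp(sk[:, 0]) <= 1
        assert m["longest_path_um"] * 1000 >= (101 - 1) - 2 * 9.0  # erosion <= 1 diameter

    def test_solid_sphere_degenerates_to_point(self):
        zz, yy, xx = np.mgrid[0:21, 0:21, 0:21]
        mask = (zz - 10) ** 2 + (yy - 10) ** 2 + (xx - 10) ** 2 <= 64
        g = skeletonize3d(BinaryMask(mask, ISO, 0.5, "manual"))
        assert measure(g)["longest_path_um"] * 1000 <= 10  # << 16-voxel diameter

    def test_torus_preserves_cycle(self):
        zz, yy, xx = np.mgrid[0:9, 0:41, 0:41]
        rho = np.sqrt((yy - 20.0) ** 2 + (xx - 20.0) ** 2)
        torus = (rho - 14.0) ** 2 + (zz - 4.0) ** 2 <= 9.0
        g = prune(skeletonize3d(BinaryMask(torus, ISO, 0.5, "manual")), min_branch=8.0)
        m = measure(g, smooth=True)
        assert m["cyclic"]
        # Euler characteristic of a single cycle: V - E = 0
        assert g.graph.number_of_nodes() - g.graph.number_of_edges() == 0
        assert m["longest_path_um"] * 1000 == pytest.approx(2 * np.pi * 14.0, rel=0.1)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValidationError):
            skeletonize3d(BinaryMask(np.zeros((3, 3, 3), bool), ISO, 0.5, "manual"))

    def test_resample_fallback_agrees_with_edt(self):
        bm = _tube_mask((9, 11, 60), 50, 2.2, spacing=(500.0, 108.0, 108.0) if False else (2.0, 1.0, 1.0))
        a = measure(skeletonize3d(bm, method="edt"), smooth=True)["longest_path_um"]
        b = measure(skeletonize3d(bm, method="resample"), smooth=True)["longest_path_um"]
        assert a == pytest.approx(b, rel=0.10)


class TestGraphAndLength:
    def test_axis_aligned_path_length_exact(self):
        skel = np.zeros((3, 3, 101), bool)
        skel[1, 1, :] = True
        g = graph_from_skeleton(skel, WF)
        assert skeleton_length(g) == pytest.approx(100 * 108.0 / 1000.0)  # 10.80 um

    def test_diagonal_staircase_length(self):
        n = 40
        skel = np.zeros((3, n + 1, n + 1), bool)
        for i in range(n + 1):
            skel[1, i, i] = True
        g = graph_from_skeleton(skel, WF)
        expected = n * np.hypot(108.0, 108.0) / 1000.0
        assert skeleton_length(g) == pytest.approx(expected, rel=1e-9)

    def test_rotation_invariance_90deg(self):
        bm = _tube_mask((11, 13, 64), 56, 4.0, spacing=(500.0, 108.0, 108.0))
        a = measure(skeletonize3d(bm), smooth=True)["longest_path_um"]
        rot = BinaryMask(np.transpose(bm.mask, (2, 1, 0)), (108.0, 108.0, 500.0), 0.5, "manual")
        b = measure(skeletonize3d(rot), smooth=True)["longest_path_um"]
        assert a == pytest.approx(b, rel=0.01)

    @pytest.mark.parametrize("theta_deg,phi_deg", [(15.0, 30.0), (45.0, 45.0), (75.0, 10.0), (90.0, 0.0)])
    def test_digitization_bias_bounded_for_oblique_tubes(self, theta_deg, phi_deg):
        # straight tubes at arbitrary orientation: measured length within
        # truth minus at most one diameter (end erosion), plus one voxel
        # diagonal + 2 % digitization slack
        L, d = 15_000.0, 900.0
        th, ph = np.radians(theta_deg), np.radians(phi_deg)
        u = np.array([np.cos(th), np.sin(th) * np.sin(ph), np.sin(th) * np.cos(ph)])
        ctrl = np.stack([-0.5 * L * u, 0.5 * L * u])
        spec = PhantomSpec(kind="fiber", diameter=d, centerline=ctrl)
        placed, shape = embed(spec, WF, 1200.0)
        grid = render_object(placed, shape, WF)
        mask = binarize(grid, "half_max")
        length = measure(skeletonize3d(mask), smooth=True)["longest_path_um"] * 1000
        diag = np.linalg.norm(WF)
        assert length <= L + diag + 0.02 * L
        assert length >= L - d - diag - 0.02 * L

    def test_end_erosion_proportional_to_diameter(self):
        # thicker tubes lose more length at the tips, bounded by ~1 diameter
        for radius, axis_len in ((2.0, 80), (5.0, 80)):
            bm = _tube_mask((15, 15, 100), axis_len, radius)
            length = measure(skeletonize3d(bm))["longest_path_um"] * 1000
            shortfall = (axis_len - 1) - length
            assert 0 <= shortfall <= 2 * 2 * radius


class TestPrune:
    def _path_with_spur(self):
        # in 26-connectivity the attachment voxels form a small junction
        # cluster, so assertions use endpoints/lengths, not edge counts
        skel = np.zeros((3, 12, 40), bool)
        skel[1, 4, :] = True  # main path
        for k in range(1, 7):
            skel[1, 4 + k, 20] = True  # 6-voxel spur
        return graph_from_skeleton(skel, ISO)

    def test_unbranched_path_untouched(self):
        skel = np.zeros((3, 3, 30), bool)
        skel[1, 1, :] = True
        g = graph_from_skeleton(skel, ISO)
        p = prune(g, min_branch=100.0)
        assert p.graph.number_of_edges() == g.graph.number_of_edges()
        assert p.total_length_nm() == g.total_length_nm()

    def test_spur_removed_and_idempotent(self):
        g = self._path_with_spur()
        assert len(g.endpoints) == 3
        p1 = prune(g, min_branch=8.0)
        assert len(p1.endpoints) == 2
        assert measure(p1)["longest_path_um"] == pytest.approx(39.0 / 1000.0)
        assert p1.total_length_nm() < g.total_length_nm()
        p2 = prune(p1, min_branch=8.0)
        assert p2.total_length_nm() == p1.total_length_nm()

    def test_long_branch_survives(self):
        g = self._path_with_spur()
        p = prune(g, min_branch=1.5)  # cutoff below spur length
        assert len(p.endpoints) == 3
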