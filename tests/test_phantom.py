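import numpy as np
import pytest

from cilia3d.calibrate import estimate_resolution
from cilia3d.errors import ValidationError
from cilia3d.phantom import (
    FWHM_TO_SIGMA,
    NoiseSpec,
    PhantomSpec,
    PSFModel,
    apply_optics,
    arc_length,
    embed,
    fiber_curve,
    make_fiber_population,
    projected_arc_length,
    render_object,
    render_psf_kernel,
)

WF = (500.0, 108.0, 108.0)


class TestRasterization:
    def test_sphere_integrated_intensity_matches_volume(self):
        d = 4000.0
        spec = PhantomSpec(kind="sphere", diameter=d, center=np.array([3000.0, 3000.0, 3000.0]))
        grid = render_object(spec, (13, 56, 56), WF)
        expected = (4.0 / 3.0) * np.pi * (d / 2) ** 3 / grid.voxel_volume
        assert grid.data.sum() == pytest.approx(expected, rel=0.01)

    def test_supersampling_converged(self):
        spec = PhantomSpec(kind="sphere", diameter=4000.0, center=np.array([3000.0, 3000.0, 3000.0]))
        s3 = render_object(spec, (13, 56, 56), WF, supersample=3).data.sum()
        s6 = render_object(spec, (13, 56, 56), WF, supersample=6).data.sum()
        assert abs(s6 - s3) / s3 < 0.005

    def test_bead_is_unit_impulse(self):
        spec = PhantomSpec(kind="bead", diameter=170.0, center=np.array([1234.0, 777.0, 913.0]))
        grid = render_object(spec, (7, 21, 21), WF)
        assert grid.data.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.count_nonzero(grid.data) <= 8

    def test_straight_fiber_halfmax_support_span(self):
        # 50 um fiber along x, 1 um diameter: half-max support spans the
        # true length to within one voxel
        L, d = 50_000.0, 1000.0
        ctrl = np.array([[1000.0, 1500.0, 1000.0], [1000.0, 1500.0, 1000.0 + L]])
        spec = PhantomSpec(kind="fiber", diameter=d, centerline=ctrl)
        nx = int((L + 2000.0) / WF[2]) + 1
        grid = render_object(spec, (5, 29, nx), WF)
        profile = grid.data.max(axis=(0, 1))
        above = np.flatnonzero(profile >= 0.5 * profile.max())
        span = (above[-1] - above[0]) * WF[2]
        assert abs(span - L) <= WF[2]

    def test_object_outside_grid_rejected(self):
        spec = PhantomSpec(kind="sphere", diameter=4000.0, center=np.array([0.0, 0.0, 0.0]))
        with pytest.raises(ValidationError):
            render_object(spec, (8, 20, 20), WF)


class TestPopulation:
    @pytest.mark.parametrize("mean,n", [(49.3, 119), (17.9, 318)])
    def test_sample_mean_matches_population(self, mean, n):
        specs = make_fiber_population(n, mean, 2.3, seed=11)
        lengths = np.array([s.true_length for s in specs]) / 1000.0
        se = 2.3 / np.sqrt(n)
        assert abs(lengths.mean() - mean) < 3 * se

    def test_zero_curvature_gives_straight_chords(self):
        specs = make_fiber_population(5, 20.0, 0.5, curvature=0.0, seed=3)
        for s in specs:
            chord = np.linalg.norm(s.centerline[-1] - s.centerline[0])
            assert chord == pytest.approx(s.true_length, rel=1e-9)

    def test_seeded_generation_reproducible(self):
        a = make_fiber_population(4, 18.0, 2.0, seed=42)
        b = make_fiber_population(4, 18.0, 2.0, seed=42)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.centerline, y.centerline)

    def test_impossible_geometry_rejected(self):
        with pytest.raises(ValidationError):
            make_fiber_population(3, 0.5, 0.0, diameter=1000.0, seed=0)


class TestPSF:
    def test_sigma_from_fwhm(self):
        psf = PSFModel(540.0, 2000.0)
        assert psf.sigmas[1] == pytest.approx(229.3, abs=0.05)  # 540 / 2.3548

    def test_kernel_normalized(self):
        k = render_psf_kernel(PSFModel(540.0, 2000.0), WF)
        assert k.data.sum() == pytest.approx(1.0, abs=1e-6)

    def test_kernel_measured_fwhm_matches_spec(self):
        from cilia3d.calibrate import axial_profile, fwhm_from_profile
        from cilia3d.imagestack import reslice

        k = render_psf_kernel(PSFModel(540.0, 2000.0), WF, n_sigma=5)
        ax = fwhm_from_profile(axial_profile(k)).fwhm
        lat = fwhm_from_profile(axial_profile(reslice(k, "xz"))).fwhm
        assert ax == pytest.approx(2000.0, rel=0.03)
        assert lat == pytest.approx(540.0, rel=0.03)

    def test_too_narrow_support_rejected(self):
        with pytest.raises(ValidationError):
            render_psf_kernel(PSFModel(540.0, 2000.0), WF, n_sigma=2)


class TestOptics:
    def test_identity_limit(self):
        rng = np.random.default_rng(0)
        from cilia3d.imagestack import VoxelGrid

        g = VoxelGrid(rng.random((6, 10, 10)).astype(np.float32), WF)
        out = apply_optics(g, PSFModel(1e-3, 1e-3), None)
        np.testing.assert_allclose(out.data, g.data, rtol=1e-5)

    def test_convolution_conserves_intensity(self):
        spec = PhantomSpec(kind="sphere", diameter=2000.0, center=np.array([4000.0, 4000.0, 4000.0]))
        g = render_object(spec, (17, 75, 75), WF)
        out = apply_optics(g, PSFModel(540.0, 2000.0), None)
        assert out.data.sum() == pytest.approx(g.data.sum(), rel=1e-3)

    def test_linear_in_object_intensity(self):
        spec = PhantomSpec(kind="sphere", diameter=2000.0, center=np.array([4000.0, 4000.0, 4000.0]))
        g1 = render_object(spec, (17, 75, 75), WF)
        g2 = g1.with_data(g1.data * 3.0)
        psf = PSFModel(540.0, 2000.0)
        np.testing.assert_allclose(
            apply_optics(g2, psf, None).data,
            3.0 * apply_optics(g1, psf, None).data,
            rtol=1e-5,
        )

    def test_noise_seeded_bit_reproducible(self):
        spec = PhantomSpec(kind="sphere", diameter=2000.0, center=np.array([4000.0, 4000.0, 4000.0]))
        g = render_object(spec, (17, 75, 75), WF)
        psf = PSFModel(540.0, 2000.0)
        noise = NoiseSpec(photon_scale=8100.0, read_sigma=3.0, seed=7)
        a = apply_optics(g, psf, noise)
        b = apply_optics(g, psf, noise)
        np.testing.assert_array_equal(a.data, b.data)

    def test_bead_parameter_recovery_through_optics(self):
        spec = PhantomSpec(kind="bead", diameter=170.0, center=np.zeros(3))
        placed, shape = embed(spec, WF, (4400.0, 1600.0, 1600.0))
        truth = render_object(placed, shape, WF)
        img = apply_optics(truth, PSFModel(540.0, 2000.0), NoiseSpec(8100.0, 3.0, seed=1))
        res = estimate_resolution(img)
        assert res.fwhm_xy == pytest.approx(540.0, rel=0.05)
        assert res.fwhm_xz == pytest.approx(2000.0, rel=0.05)

    def test_8bit_exposure_rule(self):
        spec = PhantomSpec(kind="sphere", diameter=2000.0, center=np.array([4000.0, 4000.0, 4000.0]))
        g = render_object(spec, (17, 75, 75), WF)
        out = apply_optics(g, PSFModel(540.0, 2000.0), None, quantize_8bit=True)
        assert out.data.dtype == np.uint8
        assert np.count_nonzero(out.data == 255) == 1


class TestCenterlineGeometry:
    def test_two_point_arc_length(self):
        ctrl = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 50_000.0]])
        assert arc_length(ctrl) == pytest.approx(50_000.0)

    def test_semicircle_closed_form(self):
        r = 8000.0
        theta = np.linspace(0.0, np.pi, 13)
        ctrl = np.stack([np.zeros_like(theta), r * np.sin(theta), r * np.cos(theta)], axis=1)
        assert arc_length(ctrl) == pytest.approx(np.pi * r, rel=1e-4)

    def test_refinement_converged(self):
        specs = make_fiber_population(1, 30.0, 0.0, curvature=40.0, seed=5)
        coarse = arc_length(specs[0].centerline, rtol=1e-4)
        fine = arc_length(specs[0].centerline, rtol=1e-6)
        assert coarse == pytest.approx(fine, rel=1e-4)

    def test_projection_never_longer_than_arc(self):
        specs = make_fiber_population(20, 25.0, 3.0, seed=9)
        for s in specs:
            assert projected_arc_length(s.centerline, "z") <= s.true_length * (1 + 1e-9)

    def test_projection_equality_for_planar_fiber(self):
        # a fiber lying in one z-plane projects at full length
        ctrl = np.array([[500.0, 1000.0, 1000.0], [500.0, 9000.0, 21000.0]])
        assert projected_arc_length(ctrl, "z") == pytest.approx(arc_length(ctrl), rel=1e-9)

    def test_curve_passes_through_control_points(self):
        ctrl = np.array([[0.0, 0.0, 0.0], [1000.0, 2000.0, 4000.0], [0.0, 4000.0, 8000.0]])
        pts = fiber_curve(ctrl, 501)
        np.testing.assert_allclose(pts[0], ctrl[0], atol=1e-6)
        np.testing.assert_allclose(pts[-1], ctrl[-1], atol=1e-6)
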