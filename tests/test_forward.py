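"""Forward model: transmission, phase, refraction and the mixed image."""

import numpy as np
import pytest

import eiphase as ei


@pytest.fixture(scope="module")
def smooth_phantom(pet):
    """Band-limited lumpy object — the slowly-varying regime where the
    Taylor/TIE description is quantitatively valid."""
    return ei.textured_phantom(
        (128, 64), 20.0, 46.0, seed=5, n_blobs=5, blob_scale_um=250.0,
        blob_thickness_um=200.0, background_um=0.0, smooth_um=60.0, material=pet,
    )


class TestPointwiseMaps:
    def test_transmission_of_pet_slab(self, pet):
        t = ei.slab(500.0, (8, 8), 20.0, 46.0, material=pet)
        assert ei.transmission(t)[0, 0] == pytest.approx(0.98934, rel=1e-4)
        assert np.all(ei.transmission(ei.slab(0.0, (4, 4), 1, 1, material=pet)) == 1.0)

    def test_transmission_monotone_in_thickness(self, pet):
        t = ei.wedge(0.0, 2000.0, (64, 2), 10.0, 10.0, material=pet)
        trans = ei.transmission(t)[:, 0]
        assert np.all(np.diff(trans) < 0)

    def test_phase_shift_of_pet_slab(self, pet):
        t = ei.slab(500.0, (4, 4), 20.0, 46.0, material=pet)
        phi = ei.phase_shift(t)
        assert phi.values[0, 0] == pytest.approx(-27.98, rel=1e-3)

    def test_phase_linearity(self, pet):
        t1 = ei.slab(100.0, (4, 4), 1, 1, material=pet)
        t2 = ei.slab(200.0, (4, 4), 1, 1, material=pet)
        assert ei.phase_shift(t2).values[0, 0] == pytest.approx(
            2 * ei.phase_shift(t1).values[0, 0], rel=1e-14
        )


class TestRefractionAngle:
    def test_constant_phase_refracts_nothing(self, pet):
        phi = ei.PhaseMap(np.full((32, 8), -3.0), 20.0, 46.0)
        assert np.all(ei.refraction_angle_y(phi, 27.0).values == 0.0)

    def test_linear_ramp_exact_for_central_differences(self, pet):
        y = np.arange(64)[:, None] * 20e-6
        a = 5.0e4  # rad/m
        phi = ei.PhaseMap(np.broadcast_to(a * y, (64, 8)).copy(), 20.0, 46.0)
        k = ei.wavenumber(27.0)
        np.testing.assert_allclose(
            ei.refraction_angle_y(phi, 27.0).values, a / k, rtol=1e-12
        )

    def test_wire_matches_analytic_chord_derivative(self, pet):
        d = 500.0
        t = ei.cylinder_wire(d, (256, 4), 5.0, 46.0, material=pet)
        refr = ei.refraction_angle_y(ei.phase_shift(t), 27.0)
        y_um = (np.arange(256) - 127.5) * 5.0
        inside = np.abs(y_um) < 0.85 * d / 2  # away from the edge singularity
        # chord t = 2·sqrt(r² − y²) ⇒ Δθ_y = −δ·∂y t = 2δy/sqrt(r² − y²)
        r_um = d / 2
        with np.errstate(invalid="ignore"):
            expected = 2 * pet.delta * y_um / np.sqrt(r_um**2 - y_um**2)
        got = refr.values[:, 2]
        rel = np.abs(got[inside] - expected[inside]) / np.abs(expected[inside]).max()
        assert rel.max() <= 0.01
        # antisymmetric about the wire axis
        np.testing.assert_allclose(got, -got[::-1], atol=1e-12)


class TestSimulateMixedImage:
    def test_uniform_slab_gives_pure_attenuation(self, pet, wire_geometry, slit_curve, wp50):
        t = ei.slab(500.0, (64, 32), 20.0, 46.0, material=pet)
        s = ei.simulate_mixed_image(t, wire_geometry, slit_curve, wp50)
        np.testing.assert_allclose(s.values, np.exp(-21.427 * 500e-6), rtol=1e-4)

    def test_empty_field_gives_unity(self, pet, wire_geometry, slit_curve, wp50):
        t = ei.slab(0.0, (32, 32), 20.0, 46.0, material=pet)
        s = ei.simulate_mixed_image(t, wire_geometry, slit_curve, wp50)
        np.testing.assert_allclose(s.values, 1.0, atol=1e-14)

    def test_matches_spectral_compact_form_when_smooth(
        self, smooth_phantom, wire_geometry, wp50, slit_curve
    ):
        # the regrouped single-material form evaluated spectrally with the
        # same stencils is an independent oracle for the spatial simulator
        a = ei.simulate_mixed_image(smooth_phantom, wire_geometry, slit_curve, wp50)
        b = ei.simulate_mixed_image_spectral(smooth_phantom, wire_geometry, wp50, stencil="difference")
        assert np.sqrt(np.mean((a.values - b.values) ** 2)) <= 1e-6

    def test_compact_form_on_wire_limited_by_edge_steepness(
        self, pet, wire_geometry, slit_curve, wp50
    ):
        # at the wire's edge the thickness jumps ~140 µm per step and the
        # discrete chain rule T·Δt ≈ −ΔT/μ leaves an O(µΔt) residual
        t = ei.cylinder_wire(500.0, (128, 64), 20.0, 46.0, material=pet)
        a = ei.simulate_mixed_image(t, wire_geometry, slit_curve, wp50)
        b = ei.simulate_mixed_image_spectral(t, wire_geometry, wp50, stencil="difference")
        assert np.sqrt(np.mean((a.values - b.values) ** 2)) <= 5e-4

    def test_exact_curve_converges_quadratically_to_linearized(self, pet, wire_geometry):
        # discrepancy is driven by the curve's curvature term (z·Δθ)²·C″/2,
        # so halving δ must shrink it at least four-fold
        curve = ei.AnalyticCurve(20.0, 250.0, 5.0)
        wp = ei.working_point(curve, 0.35, "lower")

        def discrepancy(scale):
            m = ei.Material("scaled", pet.delta * scale, pet.beta, pet.energy_keV)
            t = ei.sphere(300.0, (128, 128), 20.0, 20.0, material=m)
            a = ei.simulate_mixed_image(t, wire_geometry, curve, wp, mode="linearized")
            b = ei.simulate_mixed_image(t, wire_geometry, curve, wp, mode="exact-curve")
            return np.sqrt(np.mean((a.values - b.values) ** 2))

        assert discrepancy(1.0) / discrepancy(0.5) >= 3.5

    def test_lsf_preserves_mean_of_edge_flat_image(self, pet, slit_curve, wp50):
        geom = ei.BeamGeometry(27.0, 3.85, 20.0, 46.0, lsf_fwhm_x_um=100.0)
        t = ei.sphere(400.0, (64, 64), 20.0, 46.0, material=pet)
        s0 = ei.simulate_mixed_image(t, ei.BeamGeometry(27.0, 3.85, 20.0, 46.0), slit_curve, wp50)
        s1 = ei.simulate_mixed_image(t, geom, slit_curve, wp50)
        assert s1.values.mean() == pytest.approx(s0.values.mean(), abs=1e-7)
        assert not np.allclose(s1.values, s0.values)  # blur did act

    def test_zero_slope_working_point_rejected(self, pet, wire_geometry, slit_curve):
        wp = ei.WorkingPoint(y_e_um=0.0, c0=1.0, c1_per_um=0.0, branch="lower")
        t = ei.slab(10.0, (16, 16), 20.0, 46.0, material=pet)
        with pytest.raises(ValueError, match="slope"):
            ei.simulate_mixed_image(t, wire_geometry, slit_curve, wp)

    def test_exact_mode_rejects_shift_outside_tabulated_support(self, pet, wire_geometry):
        analytic = ei.AnalyticCurve(20.0, 250.0, 0.0)
        grid = np.linspace(-8.0, 8.0, 64)  # deliberately narrow support
        tab = ei.TabulatedCurve(grid, analytic(grid) / analytic(grid).max())
        wp = ei.working_point(tab, 0.5, "lower")
        t = ei.cylinder_wire(500.0, (64, 16), 20.0, 46.0, material=pet)
        with pytest.raises(ValueError, match="support"):
            ei.simulate_mixed_image(t, wire_geometry, tab, wp, mode="exact-curve")


class TestTaylorValidity:
    def test_zero_object_has_zero_ratio(self, pet, wire_geometry, slit_curve, wp50):
        t = ei.slab(0.0, (32, 16), 20.0, 46.0, material=pet)
        report = ei.taylor_validity_check(t, wire_geometry, slit_curve, wp50)
        assert report["ratio"] == 0.0
        assert report["within_linear_regime"]

    def test_ratio_scales_linearly_with_distance(self, pet, slit_curve, wp50):
        t = ei.cylinder_wire(500.0, (64, 8), 20.0, 46.0, material=pet)
        r1 = ei.taylor_validity_check(t, ei.BeamGeometry(27.0, 1.0, 20.0, 46.0), slit_curve, wp50)
        r2 = ei.taylor_validity_check(t, ei.BeamGeometry(27.0, 2.0, 20.0, 46.0), slit_curve, wp50)
        assert r2["ratio"] == pytest.approx(2 * r1["ratio"], rel=1e-12)

    def test_wire_at_synchrotron_geometry_reports_shift(self, pet, wire_geometry, slit_curve, wp50):
        t = ei.cylinder_wire(500.0, (64, 8), 20.0, 46.0, material=pet)
        report = ei.taylor_validity_check(t, wire_geometry, slit_curve, wp50)
        assert report["max_shift_um"] > 0
        assert report["curve_fwhm_um"] == pytest.approx(250.0, rel=1e-3)
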