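"""Level-set machinery validated against analytic circle solutions:
constant normal flow moves a disc front linearly, curvature flow follows
r(t) = sqrt(r0^2 - 2 w t), and signed-distance maintenance keeps |grad phi|
near one without moving the front."""

import numpy as np
import pytest

from conftest import analytic_disc_field, zero_set_mean_radius
from echoseg import (
    BinaryMask,
    ContourCollapseError,
    DegenerateInputError,
    LevelSetField,
    ParameterError,
    SpeedParams,
    curvature,
    evolve,
    evolve_step,
    extract_zero_level,
    reinitialize,
    signed_distance_from_mask,
)


class TestSignedDistance:
    def test_disc_center_depth(self, disc_mask):
        phi = signed_distance_from_mask(disc_mask).phi
        assert phi[64, 64] == pytest.approx(-20, abs=0.5)

    def test_sign_change_exactly_across_boundary(self, disc_mask):
        phi = signed_distance_from_mask(disc_mask).phi
        assert (phi[disc_mask.pixels] < 0).all()
        assert (phi[~disc_mask.pixels] > 0).all()

    def test_unit_gradient_away_from_boundary_and_medial_axis(self):
        f = analytic_disc_field(20.0)
        gr, gc = np.gradient(f.phi)
        g = np.hypot(gr, gc)
        rr, cc = np.mgrid[0:128, 0:128].astype(float)
        r = np.hypot(rr - 64, cc - 64)
        sel = (np.abs(r - 20) > 2) & (r > 2)
        assert g[sel].min() > 0.95 and g[sel].max() < 1.05

    @pytest.mark.parametrize("value", [True, False])
    def test_uniform_mask_is_degenerate(self, value):
        with pytest.raises(DegenerateInputError):
            signed_distance_from_mask(BinaryMask(np.full((16, 16), value)))


class TestCurvature:
    def test_disc_contour_curvature_is_inverse_radius(self):
        f = analytic_disc_field(20.0)
        k = curvature(f)
        on_contour = np.abs(f.phi) < 0.5
        assert 0.04 < k[on_contour].mean() < 0.06

    def test_straight_edge_has_zero_curvature(self):
        rr, _ = np.mgrid[0:64, 0:64].astype(float)
        f = LevelSetField(rr - 32.0)
        k = curvature(f)
        assert np.abs(k[np.abs(f.phi) < 0.5]).max() < 1e-6

    def test_convex_interior_gives_positive_curvature(self):
        f = analytic_disc_field(15.0)
        k = curvature(f)
        assert (k[np.abs(f.phi) < 0.5] > 0).all()


class TestEvolveStep:
    def test_zero_speed_leaves_field_unchanged(self):
        f = analytic_disc_field(30.0)
        p = SpeedParams(curvature_weight=0.0, constant_speed=0.0)
        out = evolve_step(f, p, dt=0.4)
        assert np.array_equal(out.phi, f.phi)

    def test_outward_constant_flow_grows_radius_by_dt(self):
        f = analytic_disc_field(30.0)
        p = SpeedParams(curvature_weight=0.0, constant_speed=1.0)
        out = evolve_step(f, p, dt=0.4)
        r = zero_set_mean_radius(out)
        assert r == pytest.approx(30.4, abs=0.05)

    def test_dt_above_stability_bound_rejected(self):
        p = SpeedParams(curvature_weight=1.0, constant_speed=1.0)
        with pytest.raises(ParameterError):
            evolve_step(analytic_disc_field(30.0), p, dt=0.2)

    def test_band_exterior_is_bit_exact_frozen(self):
        f = analytic_disc_field(30.0)
        p = SpeedParams(curvature_weight=0.5, constant_speed=0.3, band_width=6.0)
        out = evolve_step(f, p, dt=p.stable_dt())
        outside = np.abs(f.phi) > 6.0
        assert np.array_equal(out.phi[outside], f.phi[outside])


class TestReinitialize:
    def test_exact_signed_distance_is_fixed_point(self):
        f = analytic_disc_field(20.0)
        out = reinitialize(f)
        band = np.abs(f.phi) <= 6.0
        assert np.abs(out.phi - f.phi)[band].max() < 0.1

    def test_scaled_field_restored_to_unit_gradient(self):
        f = analytic_disc_field(20.0)
        out = reinitialize(LevelSetField(3.0 * f.phi))
        assert zero_set_mean_radius(out) == pytest.approx(20.0, abs=0.5)
        gr, gc = np.gradient(out.phi)
        g = np.hypot(gr, gc)
        band = np.abs(out.phi) <= 6.0
        assert ((g[band] >= 0.9) & (g[band] <= 1.1)).mean() >= 0.95

    def test_no_sign_change_signals_collapse(self):
        with pytest.raises(ContourCollapseError):
            reinitialize(LevelSetField(np.ones((32, 32))))


class TestEvolve:
    def test_single_iteration_loop_contract(self):
        f = analytic_disc_field(20.0)
        p = SpeedParams(curvature_weight=1.0, constant_speed=0.0, max_iters=1, tol=1e9)
        _, iterations, converged = evolve(f, p)
        assert iterations == 1 and converged

    def test_stationary_field_converges_immediately(self):
        f = analytic_disc_field(20.0)
        p = SpeedParams(curvature_weight=0.0, constant_speed=0.0, max_iters=50)
        _, iterations, converged = evolve(f, p)
        assert converged and iterations == 1

    def test_constant_flow_radius_linear_in_time(self):
        beta = 1.0
        p = SpeedParams(curvature_weight=0.0, constant_speed=beta, max_iters=50, tol=1e-12)
        f, iters, _ = evolve(analytic_disc_field(30.0), p)
        t = iters * p.stable_dt()
        expected = 30.0 + beta * t
        assert zero_set_mean_radius(f) == pytest.approx(expected, rel=0.02)

    def test_curvature_flow_matches_shrinking_circle(self):
        # run to t = 50: r = sqrt(900 - 100)
        p = SpeedParams(curvature_weight=1.0, constant_speed=0.0, max_iters=445, tol=1e-12)
        f, iters, _ = evolve(analytic_disc_field(30.0), p)
        t = iters * p.stable_dt()
        expected = np.sqrt(900.0 - 2.0 * t)
        assert zero_set_mean_radius(f) == pytest.approx(expected, rel=0.02)

    def test_curvature_flow_collapses_small_disc(self):
        p = SpeedParams(curvature_weight=1.0, constant_speed=0.0, max_iters=10**5, tol=1e-12)
        with pytest.raises(ContourCollapseError) as err:
            evolve(analytic_disc_field(8.0), p)
        assert err.value.last_field is not None

    def test_convex_contour_stays_simple_under_curvature_flow(self):
        from shapely.geometry import LinearRing

        p = SpeedParams(curvature_weight=1.0, constant_speed=0.0, max_iters=10, tol=1e-12)
        f = analytic_disc_field(25.0)
        for _ in range(5):  # 50 steps total, checked every 10
            f, _, _ = evolve(f, p)
            contour = max(
                (c for c in extract_zero_level(f) if c.closed),
                key=lambda c: len(c.vertices),
            )
            assert LinearRing(contour.vertices).is_simple


class TestExtractZeroLevel:
    def test_disc_contour_radius(self):
        contours = extract_zero_level(analytic_disc_field(20.0))
        assert len(contours) == 1 and contours[0].closed
        v = contours[0].vertices
        radii = np.hypot(v[:, 0] - 64, v[:, 1] - 64)
        assert (np.abs(radii - 20) < 0.5).all()

    def test_two_disjoint_discs_give_two_contours(self):
        rr, cc = np.mgrid[0:128, 0:128].astype(float)
        phi = np.minimum(
            np.hypot(rr - 32, cc - 32) - 12, np.hypot(rr - 90, cc - 90) - 12
        )
        contours = extract_zero_level(LevelSetField(phi))
        assert len(contours) == 2 and all(c.closed for c in contours)

    def test_all_positive_field_yields_empty_list(self):
        assert extract_zero_level(LevelSetField(np.ones((16, 16)))) == []

    def test_interior_on_left_orientation(self):
        from scipy import ndimage

        contour = extract_zero_level(analytic_disc_field(20.0))[0]
        v = contour.vertices
        mids = 0.5 * (v[:-1] + v[1:])
        d = v[1:] - v[:-1]
        left = np.column_stack([-d[:, 1], d[:, 0]])
        left /= np.hypot(left[:, 0], left[:, 1])[:, None]
        sample = mids + 0.75 * left
        phi = analytic_disc_field(20.0).phi
        vals = ndimage.map_coordinates(phi, [sample[:, 0], sample[:, 1]], order=1)
        assert vals.mean() < 0
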