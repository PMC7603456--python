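"""Idealized geometry, parameter blending, fiber orientations, membrane equilibrium."""

import numpy as np
import pytest
from scipy.optimize import fsolve

from fsgsim.config import FiberConfig, GeometryConfig, MaterialConfig
from fsgsim.geometry import (
    EquilibriumError,
    assign_fiber_orientations,
    blend_region_params,
    build_geometry,
    build_material_field,
    solve_equilibrium,
)


@pytest.fixture()
def geometry():
    return build_geometry(GeometryConfig())


@pytest.fixture()
def material(geometry):
    return build_material_field(geometry, MaterialConfig())


@pytest.fixture()
def fibers(geometry):
    return assign_fiber_orientations(geometry, FiberConfig())


class TestBuildGeometry:
    def test_zero_sac_is_plain_cylinder(self):
        geo = build_geometry(GeometryConfig(sac_height=0.0))
        assert set(geo.region) == {"parent"}
        np.testing.assert_allclose(geo.profile_radius, geo.parent_radius)
        np.testing.assert_allclose(geo.depth, 0.0)

    def test_monotone_radius_profile(self, geometry):
        assert np.all(np.diff(geometry.profile_radius) >= 0)
        assert geometry.profile_radius[0] == pytest.approx(geometry.parent_radius)
        assert geometry.profile_radius[-1] == pytest.approx(
            geometry.parent_radius + geometry.sac_height)

    def test_region_band_layout(self, geometry):
        regions = list(geometry.region)
        # parent then neck then dome, each a contiguous band
        assert regions == sorted(regions, key=["parent", "neck", "dome"].index)
        assert {"parent", "neck", "dome"} == set(regions)

    def test_zero_neck_warns(self):
        with pytest.warns(UserWarning, match="neck"):
            build_geometry(GeometryConfig(neck_fraction=0.0))

    def test_overlapping_regions_rejected(self):
        with pytest.raises(ValueError):
            GeometryConfig(parent_fraction=0.7, neck_fraction=0.4)


class TestBlending:
    def test_endpoints_exact(self):
        m = MaterialConfig()
        at0 = blend_region_params(m.parent.adventitia, m.dome.adventitia, 0.0)
        at1 = blend_region_params(m.parent.adventitia, m.dome.adventitia, 1.0)
        assert at0.attachment == m.parent.adventitia.attachment
        assert at1.recruitment_init == m.dome.adventitia.recruitment_init

    def test_midpoint_attachment_max(self):
        # parent adventitia attachment max 1.0, dome 1.1 -> 1.05 at midpoint
        m = MaterialConfig()
        mid = blend_region_params(m.parent.adventitia, m.dome.adventitia, 0.5)
        assert mid.attachment[2] == pytest.approx(1.05)

    def test_position_out_of_range(self):
        m = MaterialConfig()
        with pytest.raises(ValueError):
            blend_region_params(m.parent.media, m.dome.media, 1.2)

    def test_field_matches_pointwise_blend(self, geometry, material):
        m = MaterialConfig()
        i = int(np.argmax(geometry.region == "neck"))
        pos = geometry.blend_pos[i]
        expect = blend_region_params(m.parent.media, m.dome.media, pos)
        assert material.m_e[i, 0] == pytest.approx(expect.m_e)
        np.testing.assert_allclose(material.attachment[i, 0, 0], expect.attachment)


class TestFiberOrientations:
    def test_parent_splay_angles(self, geometry, fibers):
        par = geometry.region == "parent"
        np.testing.assert_allclose(np.rad2deg(fibers.angles[par, 0, 0]), 30.0)
        np.testing.assert_allclose(np.rad2deg(fibers.angles[par, 1, 0]), 60.0)
        np.testing.assert_allclose(np.rad2deg(fibers.angles[par, 0, 1]), -30.0)

    def test_dome_principal_curvature_directions(self, geometry, fibers):
        # on an axisymmetric surface the principal directions are the
        # circumferential (0) and meridional (90 deg) tangents
        dome = geometry.region == "dome"
        np.testing.assert_allclose(fibers.angles[dome, :, 0], 0.0, atol=1e-12)
        np.testing.assert_allclose(np.abs(np.rad2deg(fibers.angles[dome, :, 1])),
                                   90.0, atol=1e-9)

    def test_umbilic_fallback_at_apex(self, geometry, fibers):
        assert fibers.umbilic[geometry.apex_index]
        assert not fibers.umbilic[0]

    def test_unit_direction_vectors(self, fibers):
        vecs = fibers.direction_vectors()
        np.testing.assert_allclose(np.linalg.norm(vecs, axis=-1), 1.0)


class TestEquilibrium:
    def test_zero_pressure_identity(self, geometry, material, fibers):
        eq = solve_equilibrium(geometry, material, fibers, 0.0)
        np.testing.assert_allclose(eq.lam_circ, 1.0, atol=1e-9)
        np.testing.assert_allclose(eq.lam_merid, 1.0, atol=1e-9)
        np.testing.assert_allclose(eq.jacobian, 1.0, atol=1e-9)

    def test_thin_cylinder_against_laplace_oracle(self):
        # single-point cylinder, matrix-only wall, membrane variant; compare
        # with an independently solved closed-form Laplace system
        geo = build_geometry(GeometryConfig(sac_height=0.0, n_points=4))
        mat_cfg = MaterialConfig()
        for region in (mat_cfg.parent, mat_cfg.dome):
            region.media.m_c = 0.0
            region.adventitia.m_c = 0.0
        mat = build_material_field(geo, mat_cfg)
        fib = assign_fiber_orientations(geo)
        P = 2000.0
        eq = solve_equilibrium(geo, mat, fib, P, variant="membrane")

        c = mat.iso_stiffness[0].sum() * 0  # per-layer handled below
        H = geo.thickness
        cs = mat.iso_stiffness[0]  # (2,) both layers identical here

        def oracle(x):
            lt, lm = x
            lr = 1.0 / (lt * lm)
            # incompressible neo-Hookean Cauchy diagonal: 2c(b_i - mean-free)
            # with reaction pressure from sigma_rr = 0 (thin membrane)
            def sig(axis_sq):
                return 2.0 * (axis_sq - lr ** 2)
            s_t = sig(lt ** 2)
            s_m = sig(lm ** 2)
            N_t = sum(cs[L] * s_t * lr * H[L] for L in range(2))
            N_m = sum(cs[L] * s_m * lr * H[L] for L in range(2))
            r = lt * geo.parent_radius
            return [N_t / r - P / 1e6, 2 * N_m / r - P / 1e6]

        sol = fsolve(oracle, [1.1, 1.02], full_output=False)
        assert eq.lam_circ[0] == pytest.approx(sol[0], rel=1e-6)
        assert eq.lam_merid[0] == pytest.approx(sol[1], rel=1e-6)

    def test_spherical_apex_equal_stresses(self, geometry, material, fibers):
        # sphere-like apex with 0/90 fiber pair: both in-plane stretches equal
        eq = solve_equilibrium(geometry, material, fibers, 9000.0)
        i = geometry.apex_index
        assert eq.lam_circ[i] == pytest.approx(eq.lam_merid[i], rel=1e-6)

    def test_monotone_with_pressure(self, geometry, material, fibers):
        prev = None
        eq = None
        for P in (2000.0, 6000.0, 10000.0, 13000.0):
            eq = solve_equilibrium(geometry, material, fibers, P, x0=eq)
            if prev is not None:
                assert np.all(eq.lam_circ >= prev - 1e-10)
            prev = eq.lam_circ

    def test_incompressibility_bounds(self, geometry, material, fibers):
        thick = solve_equilibrium(geometry, material, fibers, 12000.0)
        assert np.max(np.abs(thick.jacobian - 1.0)) <= 0.02
        memb = solve_equilibrium(geometry, material, fibers, 12000.0,
                                 variant="membrane")
        np.testing.assert_allclose(memb.jacobian, 1.0, atol=1e-12)

    def test_protective_vs_load_bearing_adventitia(self, geometry, material,
                                                   fibers):
        # parent adventitia: fibers recruited only supraphysiologically ->
        # fiber stretch below the recruitment minimum at physiological load;
        # dome adventitia: collagen recruited (bears load) at diastole
        eq = solve_equilibrium(geometry, material, fibers, 8000.0)
        par = geometry.region == "parent"
        dome = geometry.region == "dome"
        assert np.all(eq.lam4[par, 1, :] < material.recruitment[par, 1, :, 0])
        assert np.any(eq.lam4[dome, 1, :] > material.recruitment[dome, 1, :, 0])

    def test_limit_point_raises_diagnostic(self, geometry, material, fibers):
        with pytest.raises(EquilibriumError, match="not converged"):
            solve_equilibrium(geometry, material, fibers, 5.0e6, max_newton=25)

    def test_fiber_stats_cross_pairing(self, geometry, material, fibers):
        eq = solve_equilibrium(geometry, material, fibers, 9000.0)
        stats = eq.fiber_stats(material.recruitment)
        # largest fiber stretch pairs with the smallest recruitment stretch
        i = geometry.apex_index
        assert stats[i, 1, 0, 2] == pytest.approx(
            eq.lam4[i, 1, 0] / material.recruitment[i, 1, 0, 0])
        clamped = eq.fiber_stats(material.recruitment, clamp=True)
        assert np.all(clamped >= 1.0)
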