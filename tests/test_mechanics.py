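"""Material-point mechanics: invariants, triangular recruitment, ensemble stress."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from fsgsim.mechanics import (
    AttachmentDistribution,
    FiberFamily,
    InvalidDeformationError,
    LayerComposition,
    RecruitmentDistribution,
    branch_coefficients,
    collagen_dpsi_dI4,
    collagen_dpsi_dI4_arrays,
    collagen_fiber_stretch,
    compute_invariants,
    second_pk_stress,
    triangular_pdf,
    volumetric_dpsi_dI3,
    volumetric_energy,
)

E1 = np.array([1.0, 0.0, 0.0])
ATT = AttachmentDistribution(1.0, 1.05, 1.1)


def fam(direction=E1, rec=(1.18, 1.24, 1.30)):
    return FiberFamily(direction=np.asarray(direction, dtype=float),
                       recruitment=RecruitmentDistribution(*rec), attachment=ATT)


def dpsi_quadrature(lam: float, dist: RecruitmentDistribution, K: float) -> float:
    """Independent oracle: adaptive quadrature of the ensemble energy derivative.

    d/dI4 of int psi_fiber(lam/x) rho(x) dx, with dI4 = 2 lam dlam.
    """
    if lam <= dist.min:
        return 0.0
    val, _ = quad(lambda x: (lam / x - 1.0) / x * triangular_pdf(x, dist),
                  dist.min, min(lam, dist.max), limit=400, epsabs=1e-14)
    return K * val / (2.0 * lam)


class TestInvariants:
    def test_identity(self):
        state = compute_invariants(np.eye(3), [fam()])
        assert state.jacobian == pytest.approx(1.0)
        assert state.I1_bar == pytest.approx(3.0)
        assert state.fiber_stretches[0] == pytest.approx(1.0)

    def test_isochoric_uniaxial(self):
        lam = 1.3
        F = np.diag([lam, lam ** -0.5, lam ** -0.5])
        state = compute_invariants(F, [fam()])
        assert state.jacobian == pytest.approx(1.0)
        assert state.fiber_stretches[0] == pytest.approx(lam)

    def test_dilatational_fiber_stretch_oracle(self):
        # random F scaled to det 1.2; compare against direct tensor algebra
        rng = np.random.default_rng(7)
        A = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        F = A * (1.2 / np.linalg.det(A)) ** (1.0 / 3.0)
        state = compute_invariants(F, [fam()])
        C = F.T @ F
        expected = 1.2 ** (-1.0 / 3.0) * math.sqrt(C[0, 0])
        assert state.fiber_stretches[0] == pytest.approx(expected, rel=1e-12)
        assert state.I3 == pytest.approx(1.44, rel=1e-12)

    def test_negative_jacobian_rejected(self):
        with pytest.raises(InvalidDeformationError):
            compute_invariants(-np.eye(3))

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_modified_tensor_is_unimodular(self, seed):
        rng = np.random.default_rng(seed)
        F = rng.normal(size=(3, 3)) + 2.5 * np.eye(3)
        if np.linalg.det(F) <= 0.05:
            return
        state = compute_invariants(F)
        Fbar = state.jacobian ** (-1.0 / 3.0) * state.deformation_gradient
        assert np.linalg.det(Fbar.T @ Fbar) == pytest.approx(1.0, abs=1e-10)


class TestTriangularPdf:
    DIST = RecruitmentDistribution(1.18, 1.24, 1.30)

    def test_zero_at_endpoints(self):
        assert triangular_pdf(self.DIST.min, self.DIST) == 0.0
        assert triangular_pdf(self.DIST.max, self.DIST) == 0.0

    def test_mode_height(self):
        expected = 2.0 / (self.DIST.max - self.DIST.min)
        assert triangular_pdf(self.DIST.mode, self.DIST) == pytest.approx(expected)

    @pytest.mark.parametrize("triple", [(1.18, 1.24, 1.30), (1.0, 1.0, 1.2),
                                        (1.1, 1.3, 1.3)])
    def test_normalization(self, triple):
        dist = RecruitmentDistribution(*triple)
        total, _ = quad(lambda x: triangular_pdf(x, dist), dist.min, dist.max,
                        limit=200)
        assert total == pytest.approx(1.0, rel=1e-9)

    def test_degenerate_point_mass_flag(self):
        dist = RecruitmentDistribution(1.2, 1.2, 1.2)
        assert dist.degenerate
        assert np.isinf(triangular_pdf(1.2, dist))
        assert triangular_pdf(1.19, dist) == 0.0

    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            RecruitmentDistribution(1.3, 1.2, 1.4)


class TestCollagenEnsembleStress:
    """The analytic piecewise stress against the quadrature oracle (Eq-level)."""

    DISTS = [RecruitmentDistribution(1.18, 1.24, 1.30),
             RecruitmentDistribution(1.01, 1.05, 1.10),
             RecruitmentDistribution(1.0, 1.0, 1.2),      # left-degenerate
             RecruitmentDistribution(1.1, 1.3, 1.3)]      # right-degenerate

    def test_zero_below_recruitment_minimum(self):
        dist = self.DISTS[0]
        assert collagen_dpsi_dI4(1.0, dist, 1.0) == 0.0
        assert collagen_dpsi_dI4(dist.min, dist, 1.0) == 0.0

    @pytest.mark.parametrize("dist", DISTS)
    def test_matches_quadrature_to_1e8(self, dist):
        lams = np.concatenate([
            np.linspace(dist.min + 1e-4, dist.max + 0.4, 40),
            [dist.mode, dist.max, dist.min + 1e-9]])
        for lam in lams:
            analytic = collagen_dpsi_dI4(float(lam), dist, K_c=1.0, m_c=0.8)
            oracle = 0.8 * dpsi_quadrature(float(lam), dist, 1.0)
            assert analytic == pytest.approx(oracle, rel=1e-8, abs=1e-14)

    def test_branch_coefficients_reproduce_piecewise(self):
        dist = self.DISTS[0]
        c = branch_coefficients(dist, K_c=1.0)
        for lam, keys in [(1.21, ("c1", "c2", "c3", "c4")),
                          (1.27, ("c5", "c6", "c7", "c8"))]:
            k1, k2, k3, k4 = (c[k] for k in keys)
            h = (k1 * lam * math.log(lam) + k2 * math.log(lam)
                 + k3 * lam + k4) / lam
            assert h == pytest.approx(collagen_dpsi_dI4(lam, dist, 1.0), rel=1e-12)
        lam = 1.5
        h3 = (c["c9"] * lam + c["c10"]) / lam
        assert h3 == pytest.approx(collagen_dpsi_dI4(lam, dist, 1.0), rel=1e-12)

    def test_degenerate_heaviside_branch(self):
        dist = RecruitmentDistribution(1.2, 1.2, 1.2)
        lam = 1.35
        expected = (lam - 1.2) / (2.0 * lam * 1.2 ** 2)   # K=1, single fiber
        assert collagen_dpsi_dI4(lam, dist, 1.0) == pytest.approx(expected)
        assert collagen_dpsi_dI4(1.1, dist, 1.0) == 0.0

    def test_vectorized_matches_scalar(self):
        dist = self.DISTS[0]
        lams = np.linspace(0.9, 1.6, 57)
        triples = np.broadcast_to(np.array(dist.as_tuple()), (57, 3))
        vec = collagen_dpsi_dI4_arrays(lams, triples, 1.0, 0.7)
        scal = [collagen_dpsi_dI4(float(x), dist, 1.0, 0.7) for x in lams]
        np.testing.assert_allclose(vec, scal, rtol=1e-13)

    def test_c1_continuity_at_branch_boundaries(self):
        dist = self.DISTS[0]
        eps = 1e-9
        for b in dist.as_tuple():
            lo = collagen_dpsi_dI4(b - eps, dist, 1.0)
            hi = collagen_dpsi_dI4(b + eps, dist, 1.0)
            assert hi == pytest.approx(lo, abs=1e-7)

    def test_first_pk_stress_affine_beyond_full_recruitment(self):
        # PK1 fiber stress T = 2 lam * dPsi/dI4; linear once all recruited
        dist = self.DISTS[0]
        lams = np.array([1.35, 1.55, 1.75])
        T = np.array([2 * l * collagen_dpsi_dI4(float(l), dist, 1.0) for l in lams])
        slope1 = (T[1] - T[0]) / (lams[1] - lams[0])
        slope2 = (T[2] - T[1]) / (lams[2] - lams[1])
        assert slope1 == pytest.approx(slope2, rel=1e-10)

    def test_monotone_nondecreasing_in_stretch(self):
        dist = self.DISTS[1]
        lams = np.linspace(0.95, 1.8, 300)
        T = np.array([2 * l * collagen_dpsi_dI4(float(l), dist, 1.0) for l in lams])
        assert np.all(np.diff(T) >= -1e-14)


class TestFiberStretch:
    def test_mode_ratio_identity(self):
        dist = RecruitmentDistribution(1.18, 1.24, 1.30)
        stats = collagen_fiber_stretch(1.24, dist)
        assert stats.mode == pytest.approx(1.0)

    def test_clamped_below_recruitment(self):
        dist = RecruitmentDistribution(1.18, 1.24, 1.30)
        stats = collagen_fiber_stretch(1.1, dist)
        assert stats.as_tuple() == (1.0, 1.0, 1.0)
        raw = collagen_fiber_stretch(1.1, dist, clamp=False)
        assert raw.max == pytest.approx(1.1 / 1.18)

    def test_hand_division(self):
        dist = RecruitmentDistribution(1.18, 1.24, 1.30)
        stats = collagen_fiber_stretch(1.3, dist)
        assert stats.max == pytest.approx(1.3 / 1.18, abs=1e-4)
        assert stats.mode == pytest.approx(1.0484, abs=1e-4)
        assert stats.min == pytest.approx(1.0)


class TestVolumetric:
    def test_stress_free_at_unit_jacobian(self):
        assert volumetric_energy(1.0, 100.0) == 0.0
        assert volumetric_dpsi_dI3(1.0, 100.0) == 0.0

    def test_hand_value(self):
        expected = 25.0 * (0.1 - math.log(1.1))
        assert volumetric_energy(1.1, 100.0) == pytest.approx(expected, rel=1e-12)

    def test_convex_in_jacobian_near_unity(self):
        # positive second derivative of Psi_vol(J^2) in J around 1
        h = 1e-4
        f = lambda J: volumetric_energy(J * J, 100.0)
        second = (f(1 + h) - 2 * f(1.0) + f(1 - h)) / h ** 2
        assert second > 0


class TestSecondPk:
    LAYER = LayerComposition(layer_tag="media")

    def test_stress_free_reference(self):
        fibers = [fam(rec=(1.01, 1.05, 1.1))]
        S = second_pk_stress(np.eye(3), self.LAYER, fibers)
        np.testing.assert_allclose(S, 0.0, atol=1e-14)

    def test_symmetry_for_random_deformation(self):
        rng = np.random.default_rng(11)
        F = rng.normal(size=(3, 3)) * 0.1 + np.diag([1.2, 1.05, 0.9])
        fibers = [fam(), fam(direction=np.array([0.0, 1.0, 0.0]))]
        S = second_pk_stress(F, self.LAYER, fibers)
        np.testing.assert_allclose(S, S.T, atol=1e-12)

    def test_neo_hookean_pushforward_oracle(self):
        # pure matrix layer (no collagen mass), isochoric uniaxial stretch:
        # deviatoric Cauchy stress must equal the closed-form 2c*dev(B)
        layer = LayerComposition(m_c=0.0, layer_tag="media")
        lam = 1.4
        F = np.diag([lam, lam ** -0.5, lam ** -0.5])
        S = second_pk_stress(F, layer, [fam()])
        sigma = F @ S @ F.T / np.linalg.det(F)
        B = F @ F.T
        c = layer.iso_stiffness
        expected = 2.0 * c * (B - np.trace(B) / 3.0 * np.eye(3))
        np.testing.assert_allclose(sigma, expected, atol=1e-12)

    def test_kappa_default_is_100_Kc(self):
        assert LayerComposition(K_c=2.0).kappa == pytest.approx(200.0)

    def test_invalid_composition_rejected(self):
        with pytest.raises(ValueError):
            LayerComposition(m_c=-0.1)
        with pytest.raises(ValueError):
            LayerComposition(layer_tag="intima")
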