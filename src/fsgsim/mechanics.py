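"""Material-point mechanics of the layered arterial wall.

The wall is a nearly incompressible fiber-reinforced composite.  Each layer
carries an isotropic neo-Hookean matrix (elastin + passive smooth muscle) and
families of collagen fibers whose waviness is represented by a *triangular
distribution of recruitment stretches*: a fiber straightens and begins to bear
load only once the tissue stretch along its direction exceeds its recruitment
stretch.  Individual straightened fibers are linear in the first
Piola-Kirchhoff sense, so integrating over the triangular distribution yields
closed-form piecewise expressions for the ensemble stress (a toe region while
fibers are being recruited, affine once all are recruited).

Kinematics uses the isochoric/volumetric multiplicative split
``F = J^(1/3) * Fbar`` with modified invariants ``I1bar``, ``I2bar`` and the
fiber pseudo-invariant ``I4bar = m . Cbar m``.  Stress is assembled as
``S = 2 dPsi/dC`` with the standard deviatoric projector
``Dev(A) = J^(-2/3) (A - (A:C)/3 C^-1)`` applied to the isochoric terms.

Units: stiffness-like constants and the bulk modulus are in MPa; all stretches
and masses are dimensionless (normalized masses equal 1 in the healthy
reference tissue).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "RecruitmentDistribution",
    "AttachmentDistribution",
    "FiberFamily",
    "FiberStretchStats",
    "LayerComposition",
    "DeformationState",
    "InvalidDeformationError",
    "compute_invariants",
    "triangular_pdf",
    "branch_coefficients",
    "collagen_dpsi_dI4",
    "collagen_dpsi_dI4_arrays",
    "collagen_fiber_stretch",
    "volumetric_energy",
    "volumetric_dpsi_dI3",
    "second_pk_stress",
]


class InvalidDeformationError(ValueError):
    """Raised for a deformation gradient with non-positive determinant."""


@dataclass(frozen=True)
class RecruitmentDistribution:
    """Triangular distribution (min, mode, max) of fiber recruitment stretches."""

    min: float
    mode: float
    max: float

    def __post_init__(self) -> None:
        if not (self.min <= self.mode <= self.max):
            raise ValueError(
                f"recruitment triple must be ordered, got "
                f"({self.min}, {self.mode}, {self.max})"
            )
        if self.min < 1.0 - 1e-12:
            raise ValueError(f"recruitment stretches must be >= 1, got min={self.min}")

    @property
    def degenerate(self) -> bool:
        """True when min == max, i.e. a single-recruitment (Heaviside) family."""
        return self.max - self.min <= 1e-12

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.min, self.mode, self.max)


@dataclass(frozen=True)
class AttachmentDistribution:
    """Homeostatic target (min, mode, max) of the collagen fiber-stretch distribution.

    The mode is what the physiological parameter tables call the *mean*
    attachment stretch; for the triangular recruitment model the two coincide.
    """

    min: float
    mode: float
    max: float

    def __post_init__(self) -> None:
        if not (self.min <= self.mode <= self.max):
            raise ValueError(
                f"attachment triple must be ordered, got "
                f"({self.min}, {self.mode}, {self.max})"
            )

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.min, self.mode, self.max)


@dataclass(frozen=True)
class FiberStretchStats:
    """(min, mode, max) collagen fiber stretches implied by a tissue stretch."""

    min: float
    mode: float
    max: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.min, self.mode, self.max)


@dataclass(frozen=True)
class FiberFamily:
    """A collagen fiber family: reference direction plus its stretch distributions."""

    direction: np.ndarray
    recruitment: RecruitmentDistribution
    attachment: AttachmentDistribution

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if not math.isclose(n, 1.0, rel_tol=0, abs_tol=1e-8):
            raise ValueError(f"fiber direction must be a unit vector, |m| = {n}")
        object.__setattr__(self, "direction", d)


@dataclass
class LayerComposition:
    """Normalized constituent masses and stiffness constants of one wall layer.

    ``m_e``, ``m_c``, ``m_sm`` are dimensionless normalized mass densities
    (1 in healthy reference tissue); ``K_e``, ``K_sm``, ``K_c`` are
    stiffness-like constants in MPa and ``kappa`` is the bulk modulus in MPa.
    """

    m_e: float = 1.0
    m_c: float = 1.0
    m_sm: float = 1.0
    K_e: float = 0.1
    K_sm: float = 0.1
    K_c: float = 1.0
    kappa: float | None = None  # default: 100 x K_c
    layer_tag: str = "media"

    def __post_init__(self) -> None:
        if min(self.m_e, self.m_c, self.m_sm) < 0:
            raise ValueError("normalized masses must be non-negative")
        if min(self.K_e, self.K_sm, self.K_c) <= 0:
            raise ValueError("stiffness constants must be positive")
        if self.kappa is None:
            self.kappa = 100.0 * self.K_c
        if self.layer_tag not in ("media", "adventitia"):
            raise ValueError(f"unknown layer tag {self.layer_tag!r}")

    @property
    def iso_stiffness(self) -> float:
        """Effective neo-Hookean coefficient m_e*K_e + m_sm*K_sm (MPa)."""
        return self.m_e * self.K_e + self.m_sm * self.K_sm


@dataclass
class DeformationState:
    """Invariants of a deformation gradient at a material point."""

    deformation_gradient: np.ndarray
    jacobian: float
    I1_bar: float
    I2_bar: float
    I3: float
    fiber_stretches: list[float] = field(default_factory=list)


def compute_invariants(F: np.ndarray, fibers: Sequence[FiberFamily] = ()) -> DeformationState:
    """Modified invariants and fiber stretches of a deformation gradient.

    Raises :class:`InvalidDeformationError` when ``det F <= 0``.
    """
    F = np.asarray(F, dtype=float)
    J = float(np.linalg.det(F))
    if J <= 0:
        raise InvalidDeformationError(f"det(F) = {J} <= 0")
    C = F.T @ F
    Cbar = J ** (-2.0 / 3.0) * C
    I1b = float(np.trace(Cbar))
    I2b = 0.5 * float(np.trace(Cbar) ** 2 - np.trace(Cbar @ Cbar))
    stretches = [
        float(np.sqrt(f.direction @ Cbar @ f.direction)) for f in fibers
    ]
    return DeformationState(
        deformation_gradient=F,
        jacobian=J,
        I1_bar=I1b,
        I2_bar=I2b,
        I3=J * J,
        fiber_stretches=stretches,
    )


def triangular_pdf(lambda_r, dist: RecruitmentDistribution):
    """Triangular recruitment-stretch density; vectorized over ``lambda_r``.

    For a degenerate distribution (min == max) the density is a point mass; the
    function returns ``inf`` at the atom and 0 elsewhere so the caller can
    detect the flag.
    """
    x = np.asarray(lambda_r, dtype=float)
    a, m, b = dist.min, dist.mode, dist.max
    if dist.degenerate:
        out = np.where(np.isclose(x, a), np.inf, 0.0)
        return out if out.ndim else float(out)
    out = np.zeros_like(x)
    if m > a:
        rising = (x > a) & (x <= m)
        out = np.where(rising, 2.0 * (x - a) / ((b - a) * (m - a)), out)
    if b > m:
        falling = (x > m) & (x <= b)
        out = np.where(falling, 2.0 * (b - x) / ((b - a) * (b - m)), out)
    return out if out.ndim else float(out)


def branch_coefficients(dist: RecruitmentDistribution, K_c: float) -> dict[str, float]:
    """Closed-form constants c1..c10 of the piecewise ensemble stress.

    The derivative of the collagen strain energy with respect to the fiber
    pseudo-invariant has four branches in the tissue fiber stretch
    ``lam = lambda4bar``: zero below ``dist.min``, then

    ``h1 = (c1*lam*ln(lam) + c2*ln(lam) + c3*lam + c4) / lam``     (toe, rising)
    ``h2 = (c5*lam*ln(lam) + c6*ln(lam) + c7*lam + c8) / lam``     (toe, falling)
    ``h3 = (c9*lam + c10) / lam``                                  (all recruited)

    obtained by exact integration of the per-fiber quadratic energy against
    the triangular recruitment density.  Requires a non-degenerate
    distribution with ``min < mode < max``.
    """
    a, m, b = dist.min, dist.mode, dist.max
    if dist.degenerate or m <= a or b <= m:
        raise ValueError("branch coefficients need a strict min < mode < max")
    K = K_c
    N1 = (b - a) * (m - a)
    N2 = (b - a) * (b - m)
    la, lm, lb = math.log(a), math.log(m), math.log(b)
    # Cumulative g1 integrals over [a, m]
    A = (2.0 / N1) * (lm - la + a / m - 1.0)          # int g1 / x^2
    B = (2.0 / N1) * (m - a - a * (lm - la))          # int g1 / x
    return {
        "c1": K / N1,
        "c2": K * a / N1,
        "c3": -K * (2.0 + la) / N1,
        "c4": K * a * (2.0 - la) / N1,
        "c5": -K / N2,
        "c6": -K * b / N2,
        "c7": 0.5 * K * A + (K / N2) * (b / m + lm + 1.0),
        "c8": -0.5 * K * B + (K / N2) * (b * lm - b - m),
        "c9": 0.5 * K * (A + (2.0 / N2) * (b / m - 1.0 + lm - lb)),
        "c10": -0.5 * K * (B + (2.0 / N2) * (b * (lb - lm) - b + m)),
    }


def _rise_P(v, a):
    """log(v/a) + a/v - 1, stable near v = a (cancels to second order)."""
    u = (v - a) / v
    series = u * u * (0.5 + u * (1.0 / 3.0 + u * (0.25 + 0.2 * u)))
    direct = np.where(u > 1e-300, np.log(np.maximum(v / a, 1e-300)) + a / v - 1.0, 0.0)
    return np.where(u < 1e-4, series, direct)


def _rise_Q(v, a):
    """v - a - a*log(v/a), stable near v = a (cancels to second order)."""
    w = (v - a) / a
    series = a * w * w * (0.5 - w * (1.0 / 3.0 - w * (0.25 - 0.2 * w)))
    direct = np.where(w > 1e-300, v - a - a * np.log(np.maximum(v / a, 1e-300)), 0.0)
    return np.where(w < 1e-4, series, direct)


def _cumulative_moments(u: float, dist: RecruitmentDistribution) -> tuple[float, float]:
    """(int_a^u rho/x^2 dx, int_a^u rho/x dx) for the triangular density."""
    a, m, b = dist.min, dist.mode, dist.max
    u = min(u, b)
    P = Q = 0.0
    if m > a:
        N1 = (b - a) * (m - a)
        v = min(u, m)
        if v > a:
            P += (2.0 / N1) * float(_rise_P(v, a))
            Q += (2.0 / N1) * float(_rise_Q(v, a))
    if u > m and b > m:
        N2 = (b - a) * (b - m)
        P += (2.0 / N2) * (b / m - b / u + math.log(m / u))
        Q += (2.0 / N2) * (b * math.log(u / m) - u + m)
    return P, Q


def collagen_dpsi_dI4(lambda4: float, dist: RecruitmentDistribution,
                      K_c: float, m_c: float = 1.0) -> float:
    """Collagen ensemble energy derivative ``m_c * dPsi/dI4bar`` (MPa).

    Evaluates the closed-form piecewise expression (zero / toe / toe / affine
    first Piola-Kirchhoff stress).  A degenerate distribution is treated as a
    single-recruitment (Heaviside) family.
    """
    lam = float(lambda4)
    if lam < 0:
        raise ValueError("fiber stretch must be non-negative")
    if lam <= dist.min:
        return 0.0
    if dist.degenerate:
        a = dist.min
        return m_c * K_c * (lam - a) / (2.0 * lam * a * a)
    P, Q = _cumulative_moments(lam, dist)
    return m_c * K_c * (lam * P - Q) / (2.0 * lam)


def collagen_dpsi_dI4_arrays(lambda4: np.ndarray, triples: np.ndarray,
                             K_c: np.ndarray, m_c: np.ndarray) -> np.ndarray:
    """Vectorized collagen ensemble energy derivative over stretch fields.

    ``lambda4`` and the leading dimensions of ``triples`` (..., 3) broadcast;
    degenerate triples (min == max) take the Heaviside single-recruitment
    branch.  Identical piecewise closed forms as :func:`collagen_dpsi_dI4`.
    """
    lam = np.asarray(lambda4, dtype=float)
    a = np.asarray(triples[..., 0], dtype=float)
    m = np.asarray(triples[..., 1], dtype=float)
    b = np.asarray(triples[..., 2], dtype=float)
    eps = 1e-12
    u = np.minimum(lam, b)
    v = np.minimum(u, m)
    with np.errstate(divide="ignore", invalid="ignore"):
        N1 = (b - a) * (m - a)
        N2 = (b - a) * (b - m)
        rising = (v > a) & (N1 > eps)
        P1 = np.where(rising, 2.0 / np.where(rising, N1, 1.0) * _rise_P(v, a), 0.0)
        Q1 = np.where(rising, 2.0 / np.where(rising, N1, 1.0) * _rise_Q(v, a), 0.0)
        falling = (u > m) & (N2 > eps)
        P2 = np.where(falling, 2.0 / np.where(falling, N2, 1.0)
                      * (b / m - b / u + np.log(np.maximum(m / u, eps))), 0.0)
        Q2 = np.where(falling, 2.0 / np.where(falling, N2, 1.0)
                      * (b * np.log(np.maximum(u / m, eps)) - u + m), 0.0)
        out = K_c * m_c * (lam * (P1 + P2) - (Q1 + Q2)) / (2.0 * lam)
        heaviside = K_c * m_c * (lam - a) / (2.0 * lam * a * a)
        out = np.where(b - a <= eps, heaviside, out)
    return np.where(lam <= a, 0.0, out)


def collagen_fiber_stretch(lambda4: float, dist: RecruitmentDistribution,
                           clamp: bool = True) -> FiberStretchStats:
    """Fiber-stretch statistics implied by a tissue stretch.

    Fibers recruited first (smallest recruitment stretch) are stretched most:
    ``max = lambda4/dist.min``, ``mode = lambda4/dist.mode``,
    ``min = lambda4/dist.max``.  With ``clamp=True`` each value is floored at
    1 (an unrecruited fiber bears no load); the unclamped ratios are what the
    remodelling laws track.
    """
    hi = lambda4 / dist.min
    md = lambda4 / dist.mode
    lo = lambda4 / dist.max
    if clamp:
        hi, md, lo = max(hi, 1.0), max(md, 1.0), max(lo, 1.0)
    return FiberStretchStats(min=lo, mode=md, max=hi)


def volumetric_energy(I3: float, kappa: float) -> float:
    """Dilatational strain energy ``kappa/4 * (I3 - 1 - 2 ln sqrt(I3))`` (MPa)."""
    if I3 <= 0:
        raise ValueError("I3 must be positive")
    return 0.25 * kappa * (I3 - 1.0 - math.log(I3))


def volumetric_dpsi_dI3(I3: float, kappa: float) -> float:
    """Derivative of the dilatational energy; vanishes at I3 = 1."""
    if I3 <= 0:
        raise ValueError("I3 must be positive")
    return 0.25 * kappa * (1.0 - 1.0 / I3)


def second_pk_stress(F: np.ndarray,
                     layers: LayerComposition | Sequence[LayerComposition],
                     fibers: Sequence[FiberFamily]) -> np.ndarray:
    """Second Piola-Kirchhoff stress ``S = 2 dPsi/dC`` of one or more layers (MPa).

    Assembles isotropic (neo-Hookean in I1bar), anisotropic (collagen ensemble
    per fiber family) and volumetric contributions using the isochoric-split
    chain rule.  When several layers are passed their stresses are summed
    (coincident-layer idealization); per-layer resultants should call this
    once per layer.
    """
    if isinstance(layers, LayerComposition):
        layers = [layers]
    F = np.asarray(F, dtype=float)
    J = float(np.linalg.det(F))
    if J <= 0:
        raise InvalidDeformationError(f"det(F) = {J} <= 0")
    C = F.T @ F
    Cinv = np.linalg.inv(C)
    I = np.eye(3)
    I1 = float(np.trace(C))
    Jm23 = J ** (-2.0 / 3.0)
    S = np.zeros((3, 3))
    for layer in layers:
        # isotropic: Psi = iso_stiffness * (I1bar - 3)
        S += 2.0 * layer.iso_stiffness * Jm23 * (I - (I1 / 3.0) * Cinv)
        # anisotropic: per fiber family
        for fam in fibers:
            mvec = fam.direction
            I4 = float(mvec @ C @ mvec)
            lam4 = math.sqrt(Jm23 * I4)
            dpsi = collagen_dpsi_dI4(lam4, fam.recruitment, layer.K_c, layer.m_c)
            if dpsi != 0.0:
                S += 2.0 * dpsi * Jm23 * (np.outer(mvec, mvec) - (I4 / 3.0) * Cinv)
        # volumetric: S_vol = kappa/2 (I3 - 1) C^-1
        I3 = J * J
        S += 0.5 * layer.kappa * (I3 - 1.0) * Cinv
    return S
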