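"""Idealized axisymmetric vessel + sac and its quasi-static equilibrium.

A two-layer (media/adventitia) axisymmetric membrane stands in for the full
3-D structural solve: the slow growth-and-remodelling laws only consume
stretch fields, which a stress-resultant membrane supplies at desk scale.
The reference surface is parameterized by a meridian coordinate s in [0, 1]
split into *parent artery*, *neck* and *dome* subregions; material
parameters are linearly blended through the neck, and fiber directions
rotate from the splayed parent-artery architecture to the principal
curvature directions of the dome.

Equilibrium at each material point solves a blended Laplace law for the
in-plane stretch pair plus, in the default "thick" variant, a
through-thickness radial-stress condition that lets the bulk-modulus
penalty control the Jacobian (|J - 1| stays within a couple of percent).
The "membrane" variant enforces J = 1 exactly instead.  Points are solved
simultaneously by a damped, vectorized Newton iteration with
finite-difference Jacobians.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import FiberConfig, GeometryConfig, MaterialConfig, LayerMaterial
from .mechanics import collagen_dpsi_dI4_arrays

__all__ = [
    "IdealGeometry",
    "MaterialField",
    "FiberField",
    "EquilibriumField",
    "EquilibriumError",
    "build_geometry",
    "blend_region_params",
    "build_material_field",
    "assign_fiber_orientations",
    "solve_equilibrium",
]

MPA = 1.0e6  # Pa per MPa

_LAYERS = ("media", "adventitia")
_BLEND_KEYS = ("K_e", "K_sm", "K_c", "m_e", "m_c", "m_sm")


class EquilibriumError(RuntimeError):
    """No equilibrium found (e.g. pressure beyond a limit point)."""


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


@dataclass
class IdealGeometry:
    """Discretized axisymmetric reference surface with region labels.

    ``profile_radius`` is the local reference radius (m), monotone from the
    parent radius to the sac apex; ``sphericity`` blends the local Laplace
    operator from cylindrical (0) to spherical (1); ``depth`` is the
    normalized sac depth (0 in the parent, 1 at the apex); ``blend_pos``
    drives material interpolation through the neck.
    """

    s: np.ndarray
    region: np.ndarray           # 'parent' | 'neck' | 'dome' per point
    blend_pos: np.ndarray        # 0 (parent params) .. 1 (dome params)
    sphericity: np.ndarray
    profile_radius: np.ndarray   # m
    depth: np.ndarray
    parent_radius: float
    sac_height: float
    thickness: np.ndarray        # (2,) [media, adventitia], m

    @property
    def n_points(self) -> int:
        return self.s.size

    @property
    def apex_index(self) -> int:
        return int(np.argmax(self.depth))


def build_geometry(cfg: GeometryConfig) -> IdealGeometry:
    """Construct the idealized parent + neck + dome meridian discretization."""
    s = np.linspace(0.0, 1.0, cfg.n_points)
    s_p, s_n = cfg.parent_fraction, cfg.neck_fraction
    if cfg.sac_height == 0.0:
        # degenerate sac: plain cylinder, everything is parent artery
        n = cfg.n_points
        return IdealGeometry(
            s=s, region=np.array(["parent"] * n), blend_pos=np.zeros(n),
            sphericity=np.zeros(n), profile_radius=np.full(n, cfg.parent_radius),
            depth=np.zeros(n), parent_radius=cfg.parent_radius, sac_height=0.0,
            thickness=np.array([cfg.thickness_media, cfg.thickness_adventitia]))
    if s_n == 0.0:
        warnings.warn("neck fraction is 0: material parameters jump discontinuously")

    region = np.where(s < s_p, "parent", np.where(s < s_p + s_n, "neck", "dome"))
    with np.errstate(divide="ignore", invalid="ignore"):
        pos = np.clip((s - s_p) / s_n, 0.0, 1.0) if s_n > 0 else (s >= s_p).astype(float)
    # normalized apex coordinate: 0 through the parent, ramping through the
    # neck (30%) and dome (70%) to 1 at the apex
    dome_len = 1.0 - s_p - s_n
    d = np.clip((s - s_p - s_n) / dome_len, 0.0, 1.0) if dome_len > 0 else np.zeros_like(s)
    depth = np.where(s < s_p, 0.0, np.where(s < s_p + s_n, 0.3 * pos, 0.3 + 0.7 * d))
    profile_radius = cfg.parent_radius + cfg.sac_height * _smoothstep(depth)
    return IdealGeometry(
        s=s, region=region, blend_pos=pos, sphericity=_smoothstep(pos),
        profile_radius=profile_radius, depth=depth,
        parent_radius=cfg.parent_radius, sac_height=cfg.sac_height,
        thickness=np.array([cfg.thickness_media, cfg.thickness_adventitia]))


def blend_region_params(parent: LayerMaterial, dome: LayerMaterial,
                        position: float) -> LayerMaterial:
    """Componentwise linear interpolation of one layer's parameters.

    ``position`` 0 returns the parent-artery values exactly, 1 the dome
    values; the neck uses intermediate positions.
    """
    if not 0.0 <= position <= 1.0:
        raise ValueError("blend position must lie in [0, 1]")
    t = position
    kwargs = {k: (1 - t) * getattr(parent, k) + t * getattr(dome, k)
              for k in _BLEND_KEYS}
    for trip in ("attachment", "recruitment_init"):
        p = np.array(getattr(parent, trip))
        q = np.array(getattr(dome, trip))
        kwargs[trip] = tuple((1 - t) * p + t * q)
    return LayerMaterial(**kwargs)


@dataclass
class MaterialField:
    """Per-point, per-layer material arrays blended through the neck.

    Stiffnesses in MPa; masses dimensionless; triples ordered (min, mode,
    max) with shape (n_points, n_layers, n_families, 3).
    """

    K_e: np.ndarray      # (n, 2)
    K_sm: np.ndarray
    K_c: np.ndarray
    kappa: np.ndarray
    m_e: np.ndarray
    m_c: np.ndarray
    m_sm: np.ndarray
    recruitment: np.ndarray   # (n, 2, 2, 3)
    attachment: np.ndarray    # (n, 2, 2, 3)

    def copy(self) -> "MaterialField":
        return MaterialField(**{k: getattr(self, k).copy()
                                for k in self.__dataclass_fields__})

    @property
    def iso_stiffness(self) -> np.ndarray:
        """Effective neo-Hookean coefficient per point/layer (MPa)."""
        return self.m_e * self.K_e + self.m_sm * self.K_sm


def build_material_field(geometry: IdealGeometry, material: MaterialConfig) -> MaterialField:
    """Blend the parent and dome parameter tables over the geometry."""
    n = geometry.n_points
    t = geometry.blend_pos[:, None]                      # (n, 1) over layers
    arrays: dict[str, np.ndarray] = {}
    for key in _BLEND_KEYS:
        par = np.array([getattr(material.parent.media, key),
                        getattr(material.parent.adventitia, key)])
        dom = np.array([getattr(material.dome.media, key),
                        getattr(material.dome.adventitia, key)])
        arrays[key] = (1 - t) * par + t * dom
    triples = {}
    for trip in ("attachment", "recruitment_init"):
        par = np.array([getattr(material.parent.media, trip),
                        getattr(material.parent.adventitia, trip)])  # (2, 3)
        dom = np.array([getattr(material.dome.media, trip),
                        getattr(material.dome.adventitia, trip)])
        blended = (1 - t[:, :, None]) * par + t[:, :, None] * dom    # (n, 2, 3)
        # both fiber families of a layer share the layer's distribution
        triples[trip] = np.repeat(blended[:, :, None, :], 2, axis=2)  # (n, 2, 2, 3)
    return MaterialField(
        K_e=arrays["K_e"], K_sm=arrays["K_sm"], K_c=arrays["K_c"],
        kappa=material.kappa_factor * arrays["K_c"],
        m_e=arrays["m_e"], m_c=arrays["m_c"], m_sm=arrays["m_sm"],
        recruitment=triples["recruitment_init"], attachment=triples["attachment"])


@dataclass
class FiberField:
    """In-plane fiber angles from the circumferential direction (radians).

    Shape (n_points, n_layers, n_families).  In the parent artery the two
    families sit at +/- the layer angle; on the dome they align with the
    principal curvature directions (circumferential and meridional); the
    neck interpolates.  ``umbilic`` flags near-apex points where the two
    principal curvatures coincide and the circumferential/meridional
    fallback is used.
    """

    angles: np.ndarray
    umbilic: np.ndarray = field(default=None)  # (n,) bool

    def direction_vectors(self) -> np.ndarray:
        """Unit fiber vectors in the local (radial, circ, merid) frame, (n,2,2,3)."""
        a = self.angles
        out = np.zeros(a.shape + (3,))
        out[..., 1] = np.cos(a)
        out[..., 2] = np.sin(a)
        return out


def assign_fiber_orientations(geometry: IdealGeometry,
                              fibers: FiberConfig = FiberConfig()) -> FiberField:
    """Fiber angles per point/layer/family with neck interpolation.

    Parent: families at +/-30 deg (media) and +/-60 deg (adventitia) about
    the circumferential direction.  Dome: the principal curvature directions
    of the axisymmetric surface, i.e. circumferential (0) and meridional
    (90 deg); near the apex the surface is locally spherical (umbilic) and
    the same pair is used as the documented fallback, with a flag.  Family
    angles interpolate along the shortest rotation through the neck
    (family 1 -> circumferential-side direction, family 2 -> meridional).
    """
    t = geometry.blend_pos
    parent_angles = np.deg2rad([fibers.media_angle_deg, fibers.adventitia_angle_deg])
    angles = np.zeros((geometry.n_points, 2, 2))
    for L, alpha in enumerate(parent_angles):
        # family 1: +alpha -> 0 (circumferential);  family 2: -alpha -> -pi/2 (meridional)
        angles[:, L, 0] = (1 - t) * alpha
        angles[:, L, 1] = (1 - t) * (-alpha) + t * (-0.5 * np.pi)
    umbilic = (geometry.sphericity >= 1.0) & (geometry.depth >= 0.99)
    return FiberField(angles=angles, umbilic=umbilic)


@dataclass
class EquilibriumField:
    """Per-point equilibrium solution at one pressure."""

    pressure: float               # Pa
    lam_circ: np.ndarray          # (n,)
    lam_merid: np.ndarray
    lam_rad: np.ndarray
    jacobian: np.ndarray
    current_radius: np.ndarray    # m
    lam4: np.ndarray              # (n, 2, 2) fiber stretches per layer/family
    residual: np.ndarray
    newton_iterations: int = 0

    def fiber_stats(self, recruitment: np.ndarray, clamp: bool = False) -> np.ndarray:
        """(min, mode, max) fiber-stretch triples, shape (n, 2, 2, 3).

        Cross-pairing with the recruitment triple: the largest fiber stretch
        corresponds to the smallest recruitment stretch.  ``clamp`` floors
        the values at 1 (load-bearing statistics); the raw ratios drive the
        remodelling laws.
        """
        stats = self.lam4[..., None] / recruitment[..., ::-1]
        return np.maximum(stats, 1.0) if clamp else stats


def _stress_eval(lam_r: np.ndarray, lam_t: np.ndarray, lam_m: np.ndarray,
                 geometry: IdealGeometry, mat: MaterialField,
                 fiber_dirs: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cauchy stress diagonal per layer in the principal (r, circ, merid) frame.

    Returns (sigma (n, 2, 3) in MPa, J (n,), lam4 (n, 2, 2)).
    """
    J = lam_r * lam_t * lam_m
    Jm23 = J ** (-2.0 / 3.0)
    C_diag = np.stack([lam_r ** 2, lam_t ** 2, lam_m ** 2], axis=-1)  # (n, 3)
    I1 = C_diag.sum(axis=-1)

    cos2 = np.cos(fiber_dirs) ** 2         # (n, 2, 2) angles -> cos^2
    sin2 = 1.0 - cos2
    I4 = cos2 * lam_t[:, None, None] ** 2 + sin2 * lam_m[:, None, None] ** 2
    lam4 = np.sqrt(Jm23[:, None, None] * I4)
    dpsi = collagen_dpsi_dI4_arrays(lam4, mat.recruitment,
                                    mat.K_c[:, :, None], mat.m_c[:, :, None])

    # per-layer second Piola-Kirchhoff diagonal (radial, circ, merid), (n, 2, 3)
    c_iso = mat.iso_stiffness                                    # (n, 2)
    Cinv = 1.0 / C_diag                                          # (n, 3)
    S = 2.0 * c_iso[:, :, None] * Jm23[:, None, None] \
        * (1.0 - (I1[:, None, None] / 3.0) * Cinv[:, None, :])
    # fiber structure tensor diagonal: (0, cos^2, sin^2) minus deviatoric part
    struct = np.stack([np.zeros_like(cos2), cos2, sin2], axis=-1)  # (n, 2, 2, 3)
    S_fib = 2.0 * dpsi[..., None] * Jm23[:, None, None, None] \
        * (struct - (I4[..., None] / 3.0) * Cinv[:, None, None, :])
    S = S + S_fib.sum(axis=2)
    I3 = J * J
    S = S + 0.5 * mat.kappa[:, :, None] * (I3[:, None, None] - 1.0) * Cinv[:, None, :]
    sigma = C_diag[:, None, :] * S / J[:, None, None]            # (n, 2, 3)
    return sigma, J, lam4


def _solve_lam_rad(lam_t: np.ndarray, lam_m: np.ndarray,
                   geometry: IdealGeometry, mat: MaterialField,
                   fiber_dirs: np.ndarray, pressure_mpa: float,
                   lam_r0: np.ndarray | None = None) -> np.ndarray:
    """Radial stretch from the through-thickness condition sigma_rr = -P/2.

    The thickness-averaged radial Cauchy stress is strictly increasing in
    the radial stretch (the bulk penalty dominates), so a safeguarded
    Newton/bisection hybrid converges unconditionally.  This eliminates the
    stiff penalty direction from the outer membrane iteration.
    """
    target = -0.5 * pressure_mpa
    wts = geometry.thickness / geometry.thickness.sum()

    def rr(lam_r: np.ndarray) -> np.ndarray:
        sigma, _, _ = _stress_eval(lam_r, lam_t, lam_m, geometry, mat, fiber_dirs)
        return (sigma[:, :, 0] * wts[None, :]).sum(axis=1) - target

    lo = np.full_like(lam_t, 0.02)
    hi = np.full_like(lam_t, 4.0)
    x = lam_r0.copy() if lam_r0 is not None else 1.0 / (lam_t * lam_m)
    x = np.clip(x, lo, hi)
    f = rr(x)
    scale = float(np.mean(mat.kappa))
    for _ in range(80):
        if np.all(np.abs(f) <= 1e-12 * scale):
            break
        # maintain the bracket (f is increasing in lam_r)
        hi = np.where(f > 0, np.minimum(hi, x), hi)
        lo = np.where(f < 0, np.maximum(lo, x), lo)
        eps = 1e-8
        df = (rr(x + eps) - f) / eps
        with np.errstate(divide="ignore", invalid="ignore"):
            x_new = x - f / df
        bad = ~np.isfinite(x_new) | (x_new <= lo) | (x_new >= hi)
        x = np.where(bad, 0.5 * (lo + hi), x_new)
        f = rr(x)
    return x


def _field_residual(x: np.ndarray, geometry: IdealGeometry, mat: MaterialField,
                    fiber_dirs: np.ndarray, pressure_mpa: float,
                    variant: str, lam_r0: np.ndarray | None = None
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """In-plane membrane residuals (n, 2) for the stretch pair field.

    ``x`` is (n, 2) = (lam_circ, lam_merid).  The radial stretch comes from
    the inner through-thickness solve ("thick") or exact incompressibility
    ("membrane").  Returns (residuals, lam_r, J, lam4).
    """
    lam_t = x[:, 0]
    lam_m = x[:, 1]
    if variant == "thick":
        lam_r = _solve_lam_rad(lam_t, lam_m, geometry, mat, fiber_dirs,
                               pressure_mpa, lam_r0)
    else:
        lam_r = 1.0 / (lam_t * lam_m)
    sigma, J, lam4 = _stress_eval(lam_r, lam_t, lam_m, geometry, mat, fiber_dirs)
    if variant == "membrane":
        # plane stress: the incompressibility reaction removes the radial
        # stress per layer, leaving only in-plane stress differences
        sigma = sigma - sigma[:, :, 0:1]
    h = lam_r[:, None] * geometry.thickness[None, :]             # current thickness, m
    N_t = (sigma[:, :, 1] * h).sum(axis=1)                       # MPa*m
    N_m = (sigma[:, :, 2] * h).sum(axis=1)
    r_cur = lam_t * geometry.profile_radius
    w = geometry.sphericity
    R1 = (N_t + w * N_m) / r_cur - pressure_mpa
    R2 = 2.0 * N_m / r_cur - pressure_mpa
    return np.stack([R1, R2], axis=-1), lam_r, J, lam4


def solve_equilibrium(geometry: IdealGeometry, mat: MaterialField,
                      fibers: FiberField, pressure: float,
                      variant: str = "thick", tol: float = 1e-8,
                      max_newton: int = 60,
                      x0: EquilibriumField | None = None) -> EquilibriumField:
    """Solve the blended membrane equilibrium at one pressure (Pa).

    All points are advanced together by a damped Newton iteration with
    forward-difference Jacobians; a previous :class:`EquilibriumField` can
    warm-start the solve.  Raises :class:`EquilibriumError` when any point
    fails to converge (diagnostic includes the worst residual).
    """
    n = geometry.n_points
    p_mpa = pressure / MPA
    if x0 is not None:
        x = np.stack([x0.lam_circ, x0.lam_merid], axis=-1).copy()
        lam_r = x0.lam_rad.copy()
    else:
        x = np.ones((n, 2))
        lam_r = np.ones(n)
    angles = fibers.angles
    scale = max(abs(p_mpa), 1e-9)

    def res_of(xx: np.ndarray, lr0: np.ndarray):
        return _field_residual(xx, geometry, mat, angles, p_mpa, variant, lr0)

    res, lam_r, J, lam4 = res_of(x, lam_r)
    it = 0
    for it in range(1, max_newton + 1):
        if np.abs(res).max() <= tol * scale:
            break
        # forward-difference Jacobian, assembled column by column on the field
        jac = np.empty((n, 2, 2))
        eps = 1e-7
        for k in range(2):
            xp = x.copy()
            xp[:, k] += eps
            rp, _, _, _ = res_of(xp, lam_r)
            jac[:, :, k] = (rp - res) / eps
        try:
            step = np.linalg.solve(jac, res[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError as exc:
            raise EquilibriumError(f"singular Jacobian at Newton step {it}") from exc
        # relative trust region on the in-plane stretch increments
        cap = 0.1 * np.abs(x)
        step = np.clip(step, -cap, cap)
        x = np.clip(x - step, 0.1, 15.0)
        res, lam_r, J, lam4 = res_of(x, lam_r)
    worst = float(np.abs(res).max())
    if worst > tol * scale:
        raise EquilibriumError(
            f"equilibrium not converged after {max_newton} Newton iterations "
            f"(worst residual {worst:.3e}, pressure {pressure:.1f} Pa)")

    lam_t, lam_m = x[:, 0], x[:, 1]
    return EquilibriumField(
        pressure=pressure, lam_circ=lam_t, lam_merid=lam_m, lam_rad=lam_r,
        jacobian=lam_r * lam_t * lam_m,
        current_radius=lam_t * geometry.profile_radius,
        lam4=lam4, residual=np.abs(res).max(axis=1), newton_iterations=it)
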