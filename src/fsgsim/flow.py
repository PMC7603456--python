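"""Wall-shear-stress extraction and pulsatile flow metrics.

The wall shear stress (WSS) vector is the tangential component of the fluid
traction on the lumen surface.  Over a cardiac cycle its tip traces a *shear
stress rosette* at each wall point; the wall shear stress aspect ratio
(WSSAR) condenses the rosette into a scalar in [0, 1] measuring flow
bidirectionality: 0 for purely uni-directional flow, 1 for fully
bi-directional (e.g. rotating) flow.  Two quadratic stimulus functions map
either the WSS magnitude (low-WSS hypothesis) or the WSSAR (dysfunctional-
endothelium hypothesis) to a degradation signal in [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "WssTimeSeries",
    "RosetteSummary",
    "DegradationThresholds",
    "wss_vector",
    "principal_directions",
    "compute_rosette",
    "wssar",
    "f_wss",
    "f_ar",
]


@dataclass(frozen=True)
class WssTimeSeries:
    """Time-sampled WSS vectors (Pa) at one wall point with outward normal."""

    times: np.ndarray     # (n,), s, strictly increasing
    vectors: np.ndarray   # (n, 3), Pa
    normal: np.ndarray    # (3,), unit outward normal

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.vectors, dtype=float)
        n = np.asarray(self.normal, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("need at least 2 time samples")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if v.shape != (t.size, 3):
            raise ValueError(f"vectors must be ({t.size}, 3), got {v.shape}")
        nn = np.linalg.norm(n)
        if not math.isclose(nn, 1.0, rel_tol=0, abs_tol=1e-8):
            raise ValueError(f"normal must be a unit vector, |n| = {nn}")
        scale = float(np.max(np.linalg.norm(v, axis=1), initial=0.0))
        if scale > 0 and float(np.max(np.abs(v @ n))) > 1e-6 * scale:
            raise ValueError("WSS vectors must lie in the tangent plane")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "vectors", v)
        object.__setattr__(self, "normal", n)

    @property
    def magnitudes(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=1)

    def mean_magnitude(self) -> float:
        """Time-averaged WSS magnitude (trapezoid rule)."""
        t = self.times
        return float(np.trapezoid(self.magnitudes, t) / (t[-1] - t[0]))


@dataclass(frozen=True)
class RosetteSummary:
    """Principal tangent directions and the WSSAR of a rosette."""

    eta1: np.ndarray
    eta2: np.ndarray
    tau_ranges: tuple[float, float]   # (range along eta1, range along eta2), Pa
    wssar: float
    degenerate: bool = False          # no flow at all
    isotropic: bool = False           # principal direction not unique


@dataclass(frozen=True)
class DegradationThresholds:
    """Thresholds of the two degradation stimulus functions.

    ``tau_L``/``tau_C`` (Pa) bound the low-WSS law: full degradation below
    ``tau_L``, none above ``tau_C``.  ``tau_C_AR``/``tau_H_AR``
    (dimensionless, WSSAR is a ratio) bound the bidirectionality law: none
    below ``tau_C_AR``, full above ``tau_H_AR``.  ``D_max`` is the maximum
    degradation rate (1/year).
    """

    tau_L: float = 0.5
    tau_C: float = 1.0
    tau_C_AR: float = 0.7
    tau_H_AR: float = 0.8
    D_max: float = 1.5

    def __post_init__(self) -> None:
        if not self.tau_L < self.tau_C:
            raise ValueError("require tau_L < tau_C")
        if not self.tau_C_AR < self.tau_H_AR:
            raise ValueError("require tau_C_AR < tau_H_AR")
        if self.D_max < 0:
            raise ValueError("D_max must be non-negative")


def wss_vector(sigma: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """Shearing component of the fluid traction: tau = s*n - ((s*n).n) n."""
    n = np.asarray(normal, dtype=float)
    if not math.isclose(float(np.linalg.norm(n)), 1.0, rel_tol=0, abs_tol=1e-8):
        raise ValueError("normal must be a unit vector")
    traction = np.asarray(sigma, dtype=float) @ n
    return traction - (traction @ n) * n


def _tangent_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal basis of the tangent plane."""
    n = np.asarray(normal, dtype=float)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(n @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = ref - (ref @ n) * n
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v


def principal_directions(series: WssTimeSeries,
                         method: str = "auto",
                         resolution_deg: float = 0.5) -> RosetteSummary:
    """Principal tangent directions of a WSS rosette by in-plane angle sweep.

    ``eta1`` maximizes the time integral of the projected WSS over a
    discretized sweep of the in-plane angle (default resolution 0.5 deg);
    ``eta2 = normal x eta1``.  ``method="signed"`` uses the signed integral,
    ``"absolute"`` the integral of the absolute projection, and ``"auto"``
    (default) falls back from signed to range maximization (the peak-to-peak
    projection, which the aspect ratio itself is built from, and which is
    exact for sample-aligned axes) when the signed integral is degenerate —
    a centred rosette's symmetric oscillation averages to zero.  A rosette
    whose objective is flat in the angle is flagged ``isotropic``; an
    all-zero series is flagged ``degenerate``.

    Returns a :class:`RosetteSummary`; the WSSAR entry is filled in from the
    projection ranges along the two principal directions.
    """
    if method not in ("auto", "signed", "absolute"):
        raise ValueError(f"unknown method {method!r}")
    u, v = _tangent_basis(series.normal)
    t = series.times
    p_u = series.vectors @ u
    p_v = series.vectors @ v
    total = float(np.trapezoid(np.hypot(p_u, p_v), t))
    if total <= 0.0:
        return RosetteSummary(eta1=u, eta2=v, tau_ranges=(0.0, 0.0),
                              wssar=0.0, degenerate=True, isotropic=True)

    thetas = np.deg2rad(np.arange(0.0, 180.0, resolution_deg))
    proj = np.outer(np.cos(thetas), p_u) + np.outer(np.sin(thetas), p_v)

    isotropic = False
    fallback = None
    if method in ("auto", "signed"):
        signed = np.trapezoid(proj, t, axis=1)
        # a centred (or noise-dominated) rosette has a signed integral far
        # below the magnitude integral; its argmax direction is meaningless
        if np.max(np.abs(signed)) < 0.05 * total and method == "auto":
            fallback = "range"
        else:
            best = int(np.argmax(np.abs(signed)))
            theta = thetas[best]
            if signed[best] < 0:
                theta += math.pi
    if method == "absolute" or fallback == "range":
        if method == "absolute":
            obj = np.trapezoid(np.abs(proj), t, axis=1)
        else:
            obj = np.ptp(proj, axis=1)
        best = int(np.argmax(obj))
        theta = thetas[best]
        # flat objective (to sampling accuracy) -> any direction admissible
        if float(np.ptp(obj)) < 1e-3 * float(np.mean(obj)):
            isotropic = True
            theta = 0.0

    eta1 = math.cos(theta) * u + math.sin(theta) * v
    eta2 = np.cross(series.normal, eta1)
    r1 = float(np.ptp(series.vectors @ eta1))
    r2 = float(np.ptp(series.vectors @ eta2))
    tau_max, tau_min = max(r1, r2), min(r1, r2)
    ar = tau_min / tau_max if tau_max > 0 else 0.0
    return RosetteSummary(eta1=eta1, eta2=eta2, tau_ranges=(r1, r2),
                          wssar=ar, degenerate=tau_max == 0.0,
                          isotropic=isotropic)


def compute_rosette(series: WssTimeSeries, **kwargs) -> RosetteSummary:
    """Alias for :func:`principal_directions` returning the full summary."""
    return principal_directions(series, **kwargs)


def wssar(series: WssTimeSeries, **kwargs) -> float:
    """Wall shear stress aspect ratio in [0, 1] (0 if there is no flow)."""
    return compute_rosette(series, **kwargs).wssar


def f_wss(tau_mag, thresholds: DegradationThresholds = DegradationThresholds()):
    """Low-WSS degradation stimulus: 1 below tau_L, quadratic decay, 0 above tau_C."""
    tau = np.asarray(tau_mag, dtype=float)
    if np.any(tau < 0):
        raise ValueError("WSS magnitude must be non-negative")
    tL, tC = thresholds.tau_L, thresholds.tau_C
    mid = ((tC - tau) / (tC - tL)) ** 2
    out = np.where(tau <= tL, 1.0, np.where(tau >= tC, 0.0, mid))
    return out if out.ndim else float(out)


def f_ar(tau_ar, thresholds: DegradationThresholds = DegradationThresholds()):
    """Bidirectionality stimulus: 0 below tau_C_AR, quadratic rise, 1 above tau_H_AR."""
    ar = np.asarray(tau_ar, dtype=float)
    if np.any((ar < 0) | (ar > 1)):
        raise ValueError("WSSAR must lie in [0, 1]")
    tC, tH = thresholds.tau_C_AR, thresholds.tau_H_AR
    mid = ((ar - tC) / (tH - tC)) ** 2
    out = np.where(ar < tC, 0.0, np.where(ar >= tH, 1.0, mid))
    return out if out.ndim else float(out)
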