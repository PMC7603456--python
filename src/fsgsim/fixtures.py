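"""Deterministic generators of synthetic test inputs.

Everything the test suite and examples consume — WSS rosette time series
with prescribed bidirectionality, cardiac waveforms, uniaxial stretch
protocols — is generated here as a pure function of a spec and a seed, so
no external data is ever needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .flow import WssTimeSeries, _tangent_basis

__all__ = ["RosetteSpec", "make_rosette", "make_uniaxial_protocol"]


@dataclass(frozen=True)
class RosetteSpec:
    """Specification of a synthetic WSS rosette at one wall point.

    ``ratio`` is the cross-direction amplitude ratio in [0, 1]; for a
    noise-free rosette the series' WSSAR equals it exactly.  ``mode``:
    ``"fixed"`` keeps the direction constant while the magnitude pulses
    (uni-directional), ``"alternating"``/``"rotating"`` trace an ellipse
    with semi-axis ratio ``ratio`` (a circle for ratio 1, a line for 0).
    The time grid covers one closed period with ``n_samples`` intervals, so
    periodic trapezoid integrals vanish exactly for centred rosettes.
    """

    base_angle_deg: float = 0.0
    magnitude: float = 1.0            # Pa, major semi-axis / mean magnitude
    pulsatility: float = 0.5          # magnitude envelope amplitude (fixed mode)
    ratio: float = 0.0
    mode: str = "fixed"
    noise: float = 0.0                # relative Gaussian noise on components
    seed: int = 0
    period: float = 0.8               # s
    n_samples: int = 200
    normal: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.ratio <= 1.0:
            raise ValueError("ratio must lie in [0, 1]")
        if self.mode not in ("fixed", "alternating", "rotating"):
            raise ValueError(f"unknown rosette mode {self.mode!r}")


def make_rosette(spec: RosetteSpec) -> WssTimeSeries:
    """Synthesize the WSS time series described by ``spec``."""
    n = np.asarray(spec.normal, dtype=float)
    n = n / np.linalg.norm(n)
    u, v = _tangent_basis(n)
    ang = math.radians(spec.base_angle_deg)
    e_base = math.cos(ang) * u + math.sin(ang) * v
    e_cross = math.cos(ang) * v - math.sin(ang) * u
    t = np.linspace(0.0, spec.period, spec.n_samples + 1)
    phi = 2.0 * math.pi * t / spec.period
    A = spec.magnitude
    if spec.mode == "fixed":
        mag = A * (1.0 + spec.pulsatility * np.sin(phi))
        vecs = np.outer(mag, e_base)
    elif spec.mode == "rotating":
        vecs = A * (np.outer(np.cos(phi), e_base) +
                    spec.ratio * np.outer(np.sin(phi), e_cross))
    else:  # alternating: sign-flipping principal component, elliptic path
        vecs = A * (np.outer(np.sin(phi), e_base) +
                    spec.ratio * np.outer(np.cos(phi), e_cross))
    if spec.noise > 0:
        rng = np.random.default_rng(spec.seed)
        vecs = vecs + rng.normal(0.0, spec.noise * A, size=vecs.shape)
        vecs = vecs - np.outer(vecs @ n, n)   # re-project to the tangent plane
    return WssTimeSeries(times=t, vectors=vecs, normal=n)


def make_uniaxial_protocol(stretch_range: tuple[float, float] = (1.0, 1.5),
                           steps: int = 50) -> np.ndarray:
    """Isochoric uniaxial deformation-gradient sequence, shape (steps, 3, 3).

    ``F = diag(lam, 1/sqrt(lam), 1/sqrt(lam))`` for lam swept linearly over
    the range; a degenerate range yields the single matching gradient.
    """
    lo, hi = stretch_range
    if lo <= 0 or hi < lo:
        raise ValueError("invalid stretch range")
    lams = np.linspace(lo, hi, 1 if hi == lo else steps)
    out = np.zeros((lams.size, 3, 3))
    out[:, 0, 0] = lams
    out[:, 1, 1] = out[:, 2, 2] = 1.0 / np.sqrt(lams)
    return out
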