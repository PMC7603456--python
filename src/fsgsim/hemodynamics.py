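"""Reduced-order wall-shear-stress sources.

The growth-and-remodelling laws only consume WSS fields, so a full
Navier-Stokes solve is replaced by (a) a Poiseuille estimate in the parent
vessel and (b) a configurable attenuation of that estimate into the sac,
with an optional oscillatory cross-direction component to exercise the
bidirectionality (WSSAR) pathway.  The attenuation depends on the *current*
(deformed) sac geometry, encoding the observed feedback loop: as the sac
enlarges, the low-WSS region deepens and widens.

Blood constants default to density 1066 kg/m^3 and dynamic viscosity
3.5e-3 Pa s; the cardiac cycle is 0.8 s sampled 200 times (the sample grid
includes both endpoints of the period so periodic trapezoid integrals are
exact).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import FluidConfig, SurrogateConfig
from .flow import WssTimeSeries
from .geometry import EquilibriumField, IdealGeometry

__all__ = ["Waveform", "poiseuille_wss", "synthesize_waveform", "sac_wss_model",
           "SacWssField"]


@dataclass(frozen=True)
class Waveform:
    """One cardiac cycle of inlet flow rate and outlet pressure."""

    period: float          # s
    times: np.ndarray      # (n,), s, closed over [0, period]
    flow: np.ndarray       # m^3/s
    pressure: np.ndarray   # Pa

    @property
    def mean_flow(self) -> float:
        return float(np.trapezoid(self.flow, self.times) / self.period)

    @property
    def mean_pressure(self) -> float:
        return float(np.trapezoid(self.pressure, self.times) / self.period)

    @property
    def diastolic_pressure(self) -> float:
        return float(self.pressure.min())

    @property
    def systolic_pressure(self) -> float:
        return float(self.pressure.max())


def poiseuille_wss(Q: float, radius: float, mu: float = 3.5e-3) -> float:
    """Fully developed Poiseuille wall shear stress 4*mu*Q/(pi r^3) (Pa)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    return 4.0 * mu * Q / (math.pi * radius ** 3)


def _pulse_shape(t_hat: np.ndarray, peak_fraction: float) -> np.ndarray:
    """Smooth zero-mean periodic pulse, unit maximum, systolic peak at t_hat = peak."""
    phase = 2.0 * math.pi * (t_hat - peak_fraction + 0.25)
    raw = np.sin(phase) + 0.3 * np.sin(2.0 * phase - 0.5 * math.pi + 0.6)
    # subtract the analytic mean (zero for pure harmonics) and normalize peak
    return raw / np.max(np.abs(raw))


def synthesize_waveform(cfg: FluidConfig = FluidConfig()) -> Waveform:
    """Parametric cardiac waveform with exact configured means.

    Flow and pressure share a smooth two-harmonic pulse shape scaled by
    their amplitude ratios; amplitude 0 gives the steady limit.  The time
    grid has ``samples_per_cycle`` intervals over one period (endpoint
    included), so the trapezoid-rule mean equals the configured mean to
    machine precision.
    """
    n = cfg.samples_per_cycle
    t = np.linspace(0.0, cfg.period, n + 1)
    shape = _pulse_shape(t / cfg.period, cfg.peak_time_fraction)
    # remove the (tiny) discrete mean so sampled averages are exact
    shape = shape - np.trapezoid(shape, t) / cfg.period
    flow = cfg.mean_flow * (1.0 + cfg.flow_amplitude_ratio * shape)
    pressure = cfg.mean_pressure * (1.0 + cfg.pressure_amplitude_ratio * shape)
    return Waveform(period=cfg.period, times=t, flow=flow, pressure=pressure)


@dataclass
class SacWssField:
    """Surrogate WSS over the idealized surface at one G&R instant."""

    magnitude: np.ndarray             # (n,) cycle-mean |tau|, Pa
    oscillation_ratio: np.ndarray     # (n,) cross-direction amplitude ratio
    parent_wss: float                 # Pa
    series_normal: np.ndarray

    def point_series(self, i: int, waveform: Waveform,
                     seed: int = 0, noise: float = 0.0) -> WssTimeSeries:
        """Rosette time series at point ``i`` (meridional base direction).

        The magnitude envelope follows the flow waveform's pulsatility; the
        cross-direction component (circumferential) has the point's
        oscillation ratio, so the series' WSSAR equals that ratio for a
        noise-free field.
        """
        from .fixtures import RosetteSpec, make_rosette

        spec = RosetteSpec(
            magnitude=float(self.magnitude[i]),
            ratio=float(self.oscillation_ratio[i]),
            mode="rotating" if self.oscillation_ratio[i] > 0 else "fixed",
            pulsatility=0.0 if self.oscillation_ratio[i] > 0 else 0.5,
            noise=noise, seed=seed + i, period=waveform.period,
            n_samples=waveform.times.size - 1, normal=tuple(self.series_normal))
        return make_rosette(spec)


def sac_wss_model(geometry: IdealGeometry, equilibrium: EquilibriumField,
                  fluid: FluidConfig = FluidConfig(),
                  surrogate: SurrogateConfig = SurrogateConfig()) -> SacWssField:
    """Surrogate WSS field over the current deformed configuration.

    The parent-artery level is Poiseuille WSS at the current parent radius;
    into the sac the magnitude is attenuated exponentially with the
    *effective depth* ``depth * r_current / r_parent_current``, which both
    deepens and widens as the sac enlarges (the low-WSS feedback loop).  The
    oscillatory cross-direction ratio grows with the same effective depth,
    capped at 1.  Deterministic; any stochastic noise is added only when
    individual point series are drawn with a seed.
    """
    parent_mask = geometry.region == "parent"
    if parent_mask.any():
        lam_parent = float(np.mean(equilibrium.lam_circ[parent_mask]))
    else:
        lam_parent = float(equilibrium.lam_circ[0])
    r_parent = geometry.parent_radius * lam_parent
    tau_parent = poiseuille_wss(fluid.mean_flow, r_parent, fluid.mu)
    eff_depth = geometry.depth * equilibrium.current_radius / r_parent
    magnitude = tau_parent * np.exp(-surrogate.attenuation * eff_depth)
    # oscillatory bidirectionality grows with depth but saturates below the
    # perfect-rotation limit (deep-sac recirculation stays directional)
    ratio = np.clip(surrogate.oscillation_gain * eff_depth, 0.0,
                    surrogate.oscillation_cap)
    return SacWssField(magnitude=magnitude, oscillation_ratio=ratio,
                       parent_wss=tau_parent,
                       series_normal=np.array([0.0, 0.0, 1.0]))
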