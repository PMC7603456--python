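"""Run configuration: every model symbol bound to a named, validated setting.

Conventions: lengths in metres, pressures in Pa, stiffness-like constants and
the bulk modulus in MPa (converted where mechanics and loading meet), rates
in 1/year, the G&R time step in years, cardiac times in seconds.  Defaults
reproduce the reference physiological parameterization of the healthy parent
artery and the aneurysm dome (stiffnesses, attachment and initial recruitment
stretch triples, remodelling rates, degradation thresholds, cardiac waveform
constants).  Unknown keys are rejected.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = ["RunConfig", "load_config", "save_config", "schema_markdown"]


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class GeometryConfig(_Block):
    """Idealized axisymmetric parent vessel + sac."""

    parent_radius: float = Field(2.0e-3, gt=0, description="parent artery lumen radius [m]")
    sac_height: float = Field(2.0e-3, ge=0, description="sac bulge height above the parent radius [m]")
    thickness_media: float = Field(1.5e-4, gt=0, description="medial layer thickness [m] (uniform)")
    thickness_adventitia: float = Field(1.0e-4, gt=0, description="adventitial layer thickness [m] (uniform)")
    n_points: int = Field(64, ge=4, description="number of material points along the meridian")
    parent_fraction: float = Field(0.3, ge=0, lt=1, description="meridian fraction labelled parent artery")
    neck_fraction: float = Field(0.15, ge=0, lt=1, description="meridian fraction labelled neck (blend band)")

    @model_validator(mode="after")
    def _check_partition(self) -> "GeometryConfig":
        if self.parent_fraction + self.neck_fraction >= 1.0:
            raise ValueError("parent_fraction + neck_fraction must be < 1 (regions overlap)")
        return self


class LayerMaterial(_Block):
    """Material constants and stretch triples of one layer in one region."""

    K_e: float = Field(0.1, gt=0, description="elastin stiffness-like constant [MPa]")
    K_sm: float = Field(0.1, gt=0, description="passive smooth-muscle stiffness-like constant [MPa]")
    K_c: float = Field(1.0, gt=0, description="collagen fiber stiffness-like constant [MPa]")
    m_e: float = Field(1.0, ge=0, description="normalized elastin mass density [-]")
    m_c: float = Field(1.0, ge=0, description="normalized collagen mass density [-]")
    m_sm: float = Field(1.0, ge=0, description="normalized smooth-muscle mass density [-]")
    attachment: tuple[float, float, float] = Field(
        (0.95, 1.0, 1.05), description="(min, mode/mean, max) attachment stretches [-]")
    recruitment_init: tuple[float, float, float] = Field(
        (1.01, 1.05, 1.1), description="initial (min, mode, max) recruitment stretches [-]")

    @model_validator(mode="after")
    def _check_ordered(self) -> "LayerMaterial":
        for name in ("attachment", "recruitment_init"):
            lo, md, hi = getattr(self, name)
            if not lo <= md <= hi:
                raise ValueError(f"{name} triple must be ordered (min <= mode <= max)")
        return self


class RegionMaterial(_Block):
    media: LayerMaterial = LayerMaterial()
    adventitia: LayerMaterial = LayerMaterial()


def _parent_defaults() -> RegionMaterial:
    return RegionMaterial(
        media=LayerMaterial(attachment=(0.95, 1.0, 1.05),
                            recruitment_init=(1.01, 1.05, 1.1)),
        adventitia=LayerMaterial(attachment=(0.8, 0.9, 1.0),
                                 recruitment_init=(1.2, 1.25, 1.3)),
    )


def _dome_defaults() -> RegionMaterial:
    # medial atrophy of the diseased sac: elastin/SMC masses reduced
    return RegionMaterial(
        media=LayerMaterial(attachment=(0.8, 0.9, 1.0),
                            recruitment_init=(1.2, 1.25, 1.3),
                            m_e=0.2, m_sm=0.2),
        adventitia=LayerMaterial(attachment=(1.0, 1.05, 1.1),
                                 recruitment_init=(1.01, 1.05, 1.1)),
    )


class MaterialConfig(_Block):
    parent: RegionMaterial = Field(default_factory=_parent_defaults)
    dome: RegionMaterial = Field(default_factory=_dome_defaults)
    kappa_factor: float = Field(100.0, gt=0,
                                description="bulk modulus as multiple of K_c [-]")


class FiberConfig(_Block):
    media_angle_deg: float = Field(30.0, description="parent medial fiber angle from circumferential [deg]")
    adventitia_angle_deg: float = Field(60.0, description="parent adventitial fiber angle from circumferential [deg]")


class ThresholdConfig(_Block):
    tau_L: float = Field(0.5, gt=0, description="full-degradation WSS threshold [Pa]")
    tau_C: float = Field(1.0, gt=0, description="no-degradation WSS threshold [Pa]")
    tau_C_AR: float = Field(0.7, ge=0, description="no-degradation WSSAR threshold [-]")
    tau_H_AR: float = Field(0.8, le=1, description="full-degradation WSSAR threshold [-]")
    D_max: float = Field(1.5, ge=0, description="maximum degradation rate [1/year]")

    @model_validator(mode="after")
    def _check_order(self) -> "ThresholdConfig":
        if not self.tau_L < self.tau_C:
            raise ValueError("tau_L must be < tau_C")
        if not self.tau_C_AR < self.tau_H_AR:
            raise ValueError("tau_C_AR must be < tau_H_AR")
        return self


class RateConfig(_Block):
    alpha0: float = Field(10.0, ge=0, description="recruitment remodelling rate [1/year]")
    epsilon: float = Field(0.0, ge=0, description="collagen mass growth rate [1/year]")
    alpha_att: float = Field(0.5, ge=0, le=1, description="attachment adaptation gain per step [-]")


class ScheduleConfig(_Block):
    dt: float = Field(0.02, gt=0, description="G&R time step [years]")
    degradation_steps: int = Field(100, ge=0, description="degradation window length [steps]")
    stabilization_steps: int = Field(50, ge=0, description="stabilization window length [steps]")
    wss_refresh_cadence: int = Field(20, ge=1, description="flow-metric refresh interval [steps]")

    @property
    def n_steps(self) -> int:
        return self.degradation_steps + self.stabilization_steps

    @property
    def total_years(self) -> float:
        return self.n_steps * self.dt


class FluidConfig(_Block):
    rho: float = Field(1066.0, gt=0, description="blood density [kg/m^3]")
    mu: float = Field(3.5e-3, gt=0, description="blood dynamic viscosity [Pa s]")
    period: float = Field(0.8, gt=0, description="cardiac period [s]")
    samples_per_cycle: int = Field(200, ge=8, description="CFD samples per cardiac cycle")
    mean_flow: float = Field(2.54e-6, ge=0, description="mean inlet flow rate [m^3/s]")
    mean_pressure: float = Field(9752.285, gt=0,
                                 description="mean outlet pressure [Pa] (mean of the two printed outlets)")
    flow_amplitude_ratio: float = Field(0.6, ge=0, description="flow pulsatility (amplitude / mean) [-]")
    pressure_amplitude_ratio: float = Field(0.2, ge=0,
                                            description="pressure pulsatility (amplitude / mean) [-]")
    peak_time_fraction: float = Field(0.25, ge=0, lt=1, description="systolic peak timing (fraction of cycle)")


class SurrogateConfig(_Block):
    attenuation: float = Field(0.15, ge=0, description="sac WSS attenuation rate per unit effective depth [-]")
    oscillation_gain: float = Field(0.35, ge=0,
                                    description="cross-direction amplitude ratio per unit effective depth [-]")
    oscillation_cap: float = Field(0.75, ge=0, le=1,
                                   description="saturation ceiling of the oscillation ratio [-]")
    noise: float = Field(0.0, ge=0, description="relative Gaussian noise on WSS vectors [-]")


class SolverConfig(_Block):
    tol: float = Field(1e-8, gt=0, description="relative equilibrium residual tolerance [-]")
    max_newton: int = Field(60, ge=1, description="maximum Newton iterations per solve")
    variant: str = Field("thick", description="'thick' (3 unknowns, penalty) or 'membrane' (J = 1 exactly)")

    @model_validator(mode="after")
    def _check_variant(self) -> "SolverConfig":
        if self.variant not in ("thick", "membrane"):
            raise ValueError("variant must be 'thick' or 'membrane'")
        return self


class RunConfig(_Block):
    """Top-level configuration of a fluid-solid-growth run."""

    geometry: GeometryConfig = GeometryConfig()
    material: MaterialConfig = MaterialConfig()
    fibers: FiberConfig = FiberConfig()
    thresholds: ThresholdConfig = ThresholdConfig()
    rates: RateConfig = RateConfig()
    schedule: ScheduleConfig = ScheduleConfig()
    fluid: FluidConfig = FluidConfig()
    surrogate: SurrogateConfig = SurrogateConfig()
    solver: SolverConfig = SolverConfig()
    seed: int = Field(0, ge=0, description="seed for any stochastic fixture noise")

    def config_hash(self) -> str:
        """Stable hash of the resolved configuration, for provenance logging."""
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML config; an empty/missing body means defaults."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        return RunConfig()
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return RunConfig(**data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the fully resolved configuration as YAML (lossless round trip)."""
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))


def schema_markdown() -> str:
    """Markdown documentation of every configuration key (auto-generated)."""
    lines = ["# Configuration schema", ""]
    for block_name, field in RunConfig.model_fields.items():
        ann = field.annotation
        if isinstance(ann, type) and issubclass(ann, BaseModel):
            lines.append(f"## `{block_name}`")
            for key, sub in ann.model_fields.items():
                desc = sub.description or ""
                default = sub.get_default(call_default_factory=True)
                if isinstance(default, BaseModel):
                    default = "(nested block)"
                lines.append(f"- `{block_name}.{key}` = `{default}` — {desc}")
            lines.append("")
        else:
            lines.append(f"- `{block_name}` = `{field.get_default()}` — {field.description or ''}")
    return "\n".join(lines)
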