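"""Orchestration of the three fluid-solid-growth phases.

1. **Initial homeostasis** — starting from the prescribed recruitment
   distributions, a fixed-point iteration alternates quasi-static
   equilibrium (diastole/systole) with recruitment remodelling until the
   collagen fiber-stretch distribution matches the attachment distribution
   everywhere (mechanobiological equilibrium of the detected aneurysm).
2. **Degradation** — flow metrics from the hemodynamic surrogate drive
   first-order decay of the constituent masses (low-WSS or high-WSSAR
   stimulus); the sac enlarges and the low-WSS region grows with it.
3. **Stabilization** — the attachment-stretch distribution adapts toward
   the current (elevated) fiber stretches, restoring a new, spatially
   heterogeneous homeostasis for the enlarged sac.

The default schedule is 3 simulated years at dt = 0.02 yr (150 steps:
100 degradation + 50 stabilization), with flow metrics refreshed every
20 steps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import RunConfig
from .flow import DegradationThresholds, f_ar, f_wss, wssar
from .geometry import (EquilibriumField, FiberField, IdealGeometry, MaterialField,
                       assign_fiber_orientations, build_geometry,
                       build_material_field, solve_equilibrium)
from .hemodynamics import SacWssField, Waveform, sac_wss_model, synthesize_waveform
from .remodelling import (GnRParams, adapt_attachment_arrays, degrade_mass,
                          grow_collagen_mass, remodel_recruitment_arrays)

__all__ = ["EvolutionState", "Trajectory", "HomeostasisResult",
           "initialize_state", "run_homeostasis", "run_evolution",
           "summarize_trajectory"]

log = logging.getLogger(__name__)


@dataclass
class EvolutionState:
    """Full spatial state of the evolving wall at one G&R instant."""

    step: int
    time: float                       # years
    geometry: IdealGeometry
    material: MaterialField           # masses + recruitment + attachment evolve
    fibers: FiberField
    eq_dias: EquilibriumField | None = None
    eq_sys: EquilibriumField | None = None
    wss_magnitude: np.ndarray | None = None   # (n,), Pa
    wssar_field: np.ndarray | None = None     # (n,)
    stimulus: np.ndarray | None = None        # (n,)

    def max_fiber_stats(self) -> np.ndarray:
        """Unclamped fiber-stretch triples at the max(dias, sys) configuration.

        The remodelling laws act where the fibers are most stretched during
        the cardiac cycle, taken pointwise as the larger of the diastolic
        and systolic fiber stretches.
        """
        lam4 = np.maximum(self.eq_dias.lam4, self.eq_sys.lam4)
        return lam4[..., None] / self.material.recruitment[..., ::-1]


@dataclass
class HomeostasisResult:
    state: EvolutionState
    iterations: int
    converged: bool
    residual_history: list[float] = field(default_factory=list)


@dataclass
class Trajectory:
    """Per-step scalar records plus the final state of an evolution run."""

    records: list[dict] = field(default_factory=list)
    final_state: EvolutionState | None = None
    aborted: bool = False
    abort_reason: str = ""

    @property
    def n_steps(self) -> int:
        return len(self.records)


def initialize_state(cfg: RunConfig) -> tuple[EvolutionState, Waveform]:
    """Build geometry, blended material field, fibers and the waveform."""
    geometry = build_geometry(cfg.geometry)
    material = build_material_field(geometry, cfg.material)
    fibers = assign_fiber_orientations(geometry, cfg.fibers)
    waveform = synthesize_waveform(cfg.fluid)
    state = EvolutionState(step=0, time=0.0, geometry=geometry,
                           material=material, fibers=fibers)
    log.info("initialized state: %d points, config hash %s",
             geometry.n_points, cfg.config_hash())
    return state, waveform


def _solve_both(state: EvolutionState, waveform: Waveform, cfg: RunConfig) -> None:
    sol = cfg.solver
    state.eq_dias = solve_equilibrium(
        state.geometry, state.material, state.fibers,
        waveform.diastolic_pressure, variant=sol.variant, tol=sol.tol,
        max_newton=sol.max_newton, x0=state.eq_dias)
    state.eq_sys = solve_equilibrium(
        state.geometry, state.material, state.fibers,
        waveform.systolic_pressure, variant=sol.variant, tol=sol.tol,
        max_newton=sol.max_newton, x0=state.eq_sys)


def run_homeostasis(state: EvolutionState, waveform: Waveform, cfg: RunConfig,
                    max_iters: int = 100, tol: float = 1e-3) -> HomeostasisResult:
    """Fixed-point search for the initial homeostatic recruitment field.

    Alternates diastolic/systolic equilibrium with one recruitment-
    remodelling Euler step until the maximum relative deviation of the
    fiber-stretch statistics from the attachment triple drops below ``tol``
    (default 1e-3).  Raises no error on non-convergence; the result carries
    the residual history for diagnosis.
    """
    params = GnRParams(alpha0=cfg.rates.alpha0, epsilon=cfg.rates.epsilon,
                       alpha_att=cfg.rates.alpha_att,
                       D_max=cfg.thresholds.D_max, dt=cfg.schedule.dt)
    history: list[float] = []
    converged = False
    updates = 0
    for _ in range(max_iters + 1):
        _solve_both(state, waveform, cfg)
        stats = state.max_fiber_stats()
        proposed = remodel_recruitment_arrays(
            state.material.recruitment, stats, state.material.attachment, params)
        # effective relative remodelling rate: the clamp at recruitment
        # stretch 1 (and the ordering projection) can legitimately block an
        # update where the attachment target is kinematically unreachable —
        # the constrained fixed point is then stationary and counts as
        # mechanobiological equilibrium
        residual = float(np.max(np.abs(proposed - state.material.recruitment))
                         / (params.alpha0 * params.dt))
        history.append(residual)
        log.info("homeostasis iter %d: residual %.3e", updates, residual)
        if residual < tol:
            converged = True
            break
        if updates >= max_iters:
            break
        state.material.recruitment = proposed
        updates += 1
    return HomeostasisResult(state=state, iterations=updates, converged=converged,
                             residual_history=history)


def _refresh_flow(state: EvolutionState, waveform: Waveform, cfg: RunConfig,
                  scenario: str) -> SacWssField:
    fld = sac_wss_model(state.geometry, state.eq_sys, cfg.fluid, cfg.surrogate)
    state.wss_magnitude = fld.magnitude
    if scenario == "wssar":
        vals = np.empty(state.geometry.n_points)
        for i in range(vals.size):
            series = fld.point_series(i, waveform, seed=cfg.seed,
                                      noise=cfg.surrogate.noise)
            vals[i] = wssar(series)
        state.wssar_field = vals
    else:
        state.wssar_field = fld.oscillation_ratio * 0.0
    return fld


def _record(state: EvolutionState, thresholds: DegradationThresholds,
            params: GnRParams) -> dict:
    geo = state.geometry
    apex = geo.apex_index
    stats = state.max_fiber_stats()
    rates = params.alpha0 * np.abs(stats - state.material.attachment) \
        / state.material.attachment
    return {
        "step": state.step,
        "time": state.time,
        "apex_radius": float(state.eq_sys.current_radius[apex]),
        "max_displacement": float(np.max(state.eq_sys.current_radius
                                         - geo.profile_radius)),
        "max_jacobian_dev": float(np.max(np.abs(state.eq_sys.jacobian - 1.0))),
        "min_wss": float(np.min(state.wss_magnitude)),
        "mean_wss": float(np.mean(state.wss_magnitude)),
        "max_wssar": float(np.max(state.wssar_field)),
        "max_stimulus": float(np.max(state.stimulus)),
        "min_m_c": float(np.min(state.material.m_c)),
        "min_m_e": float(np.min(state.material.m_e)),
        "att_mode_max": float(np.max(state.material.attachment[..., 1])),
        "att_mode_min": float(np.min(state.material.attachment[..., 1])),
        "max_remodelling_rate": float(np.max(rates)),
    }


def run_evolution(state: EvolutionState, waveform: Waveform, cfg: RunConfig,
                  scenario: str = "low_wss") -> Trajectory:
    """Run the degradation + stabilization schedule from a homeostatic state.

    Per step: refresh the surrogate flow metrics on cadence (during the
    degradation window), evaluate the scenario's stimulus, degrade masses,
    re-solve equilibrium at both pressures, remodel the recruitment
    distribution at the max(dias, sys) configuration, and — inside the
    stabilization window — adapt the attachment distribution.  Equilibrium
    failure aborts the run, returning the trajectory accumulated so far.
    """
    if scenario not in ("low_wss", "wssar"):
        raise ValueError(f"unknown scenario {scenario!r}")
    sched = cfg.schedule
    th = DegradationThresholds(tau_L=cfg.thresholds.tau_L, tau_C=cfg.thresholds.tau_C,
                               tau_C_AR=cfg.thresholds.tau_C_AR,
                               tau_H_AR=cfg.thresholds.tau_H_AR,
                               D_max=cfg.thresholds.D_max)
    params = GnRParams(alpha0=cfg.rates.alpha0, epsilon=cfg.rates.epsilon,
                       alpha_att=cfg.rates.alpha_att, D_max=th.D_max, dt=sched.dt)
    traj = Trajectory()
    if state.eq_sys is None:
        _solve_both(state, waveform, cfg)
    for step in range(state.step + 1, sched.n_steps + 1):
        in_degradation = step <= sched.degradation_steps
        if state.wss_magnitude is None or (
                in_degradation and (step - 1) % sched.wss_refresh_cadence == 0):
            _refresh_flow(state, waveform, cfg, scenario)
        if in_degradation:
            if scenario == "low_wss":
                state.stimulus = np.asarray(f_wss(state.wss_magnitude, th))
            else:
                state.stimulus = np.asarray(f_ar(state.wssar_field, th))
        else:
            state.stimulus = np.zeros(state.geometry.n_points)

        stim = state.stimulus[:, None]           # broadcast over layers
        mat = state.material
        mat.m_e = degrade_mass(mat.m_e, stim, params)
        mat.m_c = degrade_mass(mat.m_c, stim, params)
        mat.m_sm = degrade_mass(mat.m_sm, stim, params)

        try:
            _solve_both(state, waveform, cfg)
        except Exception as exc:  # equilibrium failure: return partial trajectory
            traj.aborted = True
            traj.abort_reason = str(exc)
            traj.final_state = state
            log.error("evolution aborted at step %d: %s", step, exc)
            return traj

        stats = state.max_fiber_stats()
        if params.epsilon > 0:
            # fibroblast stretch = maximal fiber stretch at systole
            lam_f = (state.eq_sys.lam4[..., None]
                     / mat.recruitment[..., ::-1])[..., 2].mean(axis=2)
            mat.m_c = grow_collagen_mass(mat.m_c, lam_f,
                                         mat.attachment[..., 2].mean(axis=2), params)
        mat.recruitment = remodel_recruitment_arrays(
            mat.recruitment, stats, mat.attachment, params)
        if not in_degradation:
            mat.attachment = adapt_attachment_arrays(
                mat.attachment, stats, params.alpha_att)

        state.step = step
        state.time = round(step * sched.dt, 10)
        traj.records.append(_record(state, th, params))
        log.info("step %3d (t=%.2f yr): apex radius %.3f mm, min WSS %.3f Pa",
                 step, state.time, 1e3 * traj.records[-1]["apex_radius"],
                 traj.records[-1]["min_wss"])
    traj.final_state = state
    return traj


def summarize_trajectory(traj: Trajectory) -> pd.DataFrame:
    """Machine-readable per-step summary of an evolution trajectory."""
    if not traj.records:
        raise ValueError("empty trajectory")
    return pd.DataFrame.from_records(traj.records)
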