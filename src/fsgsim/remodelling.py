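"""Growth and remodelling evolution laws.

Four slow-timescale laws evolve the wall composition and the collagen
natural configuration, all driven by the current mechanical state:

* **mass degradation** — first-order decay of elastin, collagen and smooth
  muscle normalized masses at a rate ``F_X * D_max`` set by a flow-derived
  stimulus ``F_X`` in [0, 1];
* **recruitment remodelling** — the (min, mode, max) recruitment stretches
  drift so that the collagen fiber-stretch distribution in the loaded
  configuration tracks the attachment-stretch distribution (note the
  cross-pairing: the *smallest* recruitment stretch governs the *largest*
  fiber stretch);
* **collagen mass growth** — fibroblast-mediated growth proportional to the
  deviation of the (maximal) fiber stretch from its attachment value;
* **attachment adaptation** — a discrete per-step shift of the attachment
  stretches toward the current fiber stretches, the stabilization mechanism
  that lets an enlarged sac find a new homeostasis.

Time integration is explicit Euler at ``dt`` (default 0.02 year).  All
update functions are elementwise and accept numpy arrays for their stretch
and mass arguments so whole fields can be stepped at once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .mechanics import AttachmentDistribution, FiberStretchStats, RecruitmentDistribution

__all__ = [
    "GnRParams",
    "degrade_mass",
    "remodel_recruitment",
    "remodel_recruitment_arrays",
    "grow_collagen_mass",
    "adapt_attachment",
    "adapt_attachment_arrays",
]


@dataclass(frozen=True)
class GnRParams:
    """Rates of the growth-and-remodelling laws.

    ``alpha0``: recruitment remodelling rate (1/year); ``epsilon``: collagen
    growth rate (1/year, 0 in the reference parameterization); ``alpha_att``:
    attachment adaptation gain per step (dimensionless, in [0, 1]);
    ``D_max``: maximum degradation rate (1/year); ``dt``: step (years).
    """

    alpha0: float = 10.0
    epsilon: float = 0.0
    alpha_att: float = 0.5
    D_max: float = 1.5
    dt: float = 0.02

    def __post_init__(self) -> None:
        if min(self.alpha0, self.epsilon, self.D_max) < 0:
            raise ValueError("rates must be non-negative")
        if not 0.0 <= self.alpha_att <= 1.0:
            raise ValueError("alpha_att must lie in [0, 1]")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.D_max * self.dt >= 1.0:
            raise ValueError("explicit Euler requires D_max * dt < 1")


def degrade_mass(m, stimulus, params: GnRParams):
    """One Euler step of dm/dt = -F_X * D_max * m.  Elementwise."""
    m = np.asarray(m, dtype=float)
    s = np.asarray(stimulus, dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise ValueError("stimulus must lie in [0, 1]")
    out = m * (1.0 - s * params.D_max * params.dt)
    return out if out.ndim else float(out)


def remodel_recruitment(dist: RecruitmentDistribution,
                        stats: FiberStretchStats,
                        att: AttachmentDistribution,
                        params: GnRParams) -> RecruitmentDistribution:
    """One Euler step of the recruitment-distribution remodelling law.

    ``stats`` are the *unclamped* fiber-stretch statistics evaluated at the
    configuration (diastolic or systolic) where the modal fiber stretch is
    largest.  Cross-pairing: ``dist.min`` is driven by the max pair,
    ``dist.max`` by the min pair.  Updates that would drive a recruitment
    stretch below 1 are clamped with a warning, and ordering is re-enforced.
    """
    new = _recruitment_step(
        np.array(dist.as_tuple()), np.array(stats.as_tuple()),
        np.array(att.as_tuple()), params)
    return RecruitmentDistribution(*new)


def _recruitment_step(dist_t: np.ndarray, stats_t: np.ndarray,
                      att_t: np.ndarray, params: GnRParams) -> np.ndarray:
    """Euler update of (..., 3) recruitment triples; shared scalar/array core."""
    rate = params.alpha0 * (stats_t[..., ::-1] - att_t[..., ::-1]) / att_t[..., ::-1]
    new = dist_t + params.dt * rate
    if np.any(new < 1.0):
        warnings.warn("recruitment stretch clamped at 1", stacklevel=3)
        new = np.maximum(new, 1.0)
    # re-enforce min <= mode <= max
    new[..., 1] = np.maximum(new[..., 1], new[..., 0])
    new[..., 2] = np.maximum(new[..., 2], new[..., 1])
    return new


def remodel_recruitment_arrays(dist_triples: np.ndarray,
                               stats_triples: np.ndarray,
                               att_triples: np.ndarray,
                               params: GnRParams) -> np.ndarray:
    """Vectorized recruitment remodelling on (..., 3) triple arrays.

    Triples are ordered (min, mode, max); ``stats_triples`` likewise, so the
    cross-pairing is realized by reversing the last axis.
    """
    return _recruitment_step(np.asarray(dist_triples, dtype=float),
                             np.asarray(stats_triples, dtype=float),
                             np.asarray(att_triples, dtype=float), params)


def grow_collagen_mass(m_c, lambda4f, att_f, params: GnRParams):
    """One Euler step of fibroblast-driven collagen growth.

    ``lambda4f`` is the fibroblast stretch, identified with the maximal
    collagen fiber stretch, evaluated at systole; ``att_f`` its homeostatic
    (attachment) value.  Elementwise.
    """
    m = np.asarray(m_c, dtype=float)
    lam = np.asarray(lambda4f, dtype=float)
    att = np.asarray(att_f, dtype=float)
    out = m * (1.0 + params.epsilon * params.dt * (lam - att) / att)
    return out if out.ndim else float(out)


def adapt_attachment(att: AttachmentDistribution,
                     stats: FiberStretchStats,
                     alpha_att: float) -> AttachmentDistribution:
    """Discrete attachment-stretch adaptation (stabilization mechanism).

    Per quantile q in {min, mode, max}:
    ``att_q <- att_q + alpha_att * (stretch_q - att_q)``.  ``alpha_att = 1``
    jumps to the current stretches exactly; 0 leaves the target unchanged.
    """
    new = adapt_attachment_arrays(np.array(att.as_tuple()),
                                  np.array(stats.as_tuple()), alpha_att)
    return AttachmentDistribution(*new)


def adapt_attachment_arrays(att_triples: np.ndarray,
                            stats_triples: np.ndarray,
                            alpha_att: float) -> np.ndarray:
    """Vectorized attachment adaptation on (..., 3) triple arrays."""
    att = np.asarray(att_triples, dtype=float)
    stats = np.asarray(stats_triples, dtype=float)
    new = att + alpha_att * (stats - att)
    # keep min <= mode <= max
    new[..., 1] = np.maximum(new[..., 1], new[..., 0])
    new[..., 2] = np.maximum(new[..., 2], new[..., 1])
    return new
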