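"""Partition of mechanical work into elastic, viscous and adhesive parts.

For a Kelvin–Voigt element driven through a linear displacement ramp of
amplitude D over duration T the partition is closed-form:

    W_el   = ½·k·D²          (recoverable spring energy, rate-independent)
    W_visc = η·D²/T          (irreversible dashpot dissipation, ∝ 1/T)

so halving the ramp time doubles the dissipated energy while leaving the
stored energy untouched — the central rate effect this package quantifies.
The numerical route integrates a sampled trace by trapezoidal quadrature and
must agree with the closed forms; both are exposed so each can check the
other.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .constitutive import (
    NO_ADHESION,
    AdhesionModel,
    HillParams,
    ViscoelasticParams,
    adhesion_force,
    hill_force,
)
from .loading import Trace

__all__ = [
    "EnergyBudget",
    "elastic_work",
    "viscous_work_ramp",
    "partition_trace",
    "total_work_per_contraction",
    "crossover_time",
]

#: relative tolerance for the conservation identity w_total = w_el + w_visc + w_adh
RTOL_ANALYTIC = 1e-9
RTOL_NUMERICAL = 1e-6


@dataclass(frozen=True)
class EnergyBudget:
    """Energy bookkeeping for one loading event (all in J).

    ``w_total`` must equal ``w_el + w_visc + w_adh`` to within the stated
    tolerance (1e-9 relative for analytic budgets, 1e-6 for numerical ones);
    the constructor enforces this conservation identity.
    """

    w_el: float
    w_visc: float
    w_adh: float
    w_total: float
    method: Literal["analytic", "numerical"]

    def __post_init__(self) -> None:
        if self.w_el < 0 or self.w_visc < 0:
            raise ValueError("elastic and viscous works must be >= 0")
        if self.method not in ("analytic", "numerical"):
            raise ValueError(f"unknown method: {self.method!r}")
        rtol = RTOL_ANALYTIC if self.method == "analytic" else RTOL_NUMERICAL
        parts = self.w_el + self.w_visc + self.w_adh
        scale = max(abs(self.w_total), abs(parts), 1e-300)
        if abs(self.w_total - parts) > rtol * scale:
            raise ValueError(
                f"energy budget violates conservation: total={self.w_total!r} "
                f"vs parts sum={parts!r} (method={self.method})"
            )

    def to_dict(self) -> dict:
        return {
            "w_el": self.w_el, "w_el_units": "J",
            "w_visc": self.w_visc, "w_visc_units": "J",
            "w_adh": self.w_adh, "w_adh_units": "J",
            "w_total": self.w_total, "w_total_units": "J",
            "method": self.method,
        }


def elastic_work(k: float, D: float) -> float:
    """Recoverable elastic energy ``½·k·D²`` (J); independent of ramp time."""
    if k < 0 or D < 0:
        raise ValueError("k and D must be >= 0")
    return 0.5 * k * D * D


def viscous_work_ramp(eta: float, D: float, T: float) -> float:
    """Viscous dissipation ``η·D²/T`` (J) of a linear ramp.

    Exact for constant-velocity loading: the dashpot power is η·(D/T)²,
    constant over the ramp, so the dissipated energy is η·(D/T)²·T = η·D²/T.
    """
    if eta < 0 or D < 0:
        raise ValueError("eta and D must be >= 0")
    if T <= 0:
        raise ValueError(f"ramp duration T must be > 0, got {T}")
    return eta * D * D / T


def crossover_time(p: ViscoelasticParams) -> float:
    """Ramp duration T* = 2η/k at which dissipation equals storage (s).

    Setting η·D²/T = ½·k·D² gives T* independent of amplitude D: ramps
    faster than T* are viscous-dominated, slower ones elastic-dominated.
    """
    if p.k <= 0:
        raise ValueError("crossover time requires k > 0")
    return 2.0 * p.eta / p.k


def total_work_per_contraction(p: HillParams, D: float, v: float) -> float:
    """Hill-muscle mechanical work F(v)·D (J) for constant-velocity shortening.

    The force is constant along the contraction, so work is force times
    shortening distance; it decreases strictly with v and vanishes at vmax.
    """
    if D < 0:
        raise ValueError(f"shortening distance D must be >= 0, got {D}")
    return float(hill_force(p, v)) * D


def partition_trace(
    trace: Trace,
    p: ViscoelasticParams,
    adh: AdhesionModel = NO_ADHESION,
) -> EnergyBudget:
    """Numerically partition the work stored in a sampled loading trace.

    Fills the trace's cumulative work columns in place and returns the final
    budget.  Components by trapezoidal quadrature on the trace grid:

    * ``w_el    = ∫ k·x dx``       (spring, integrated over displacement)
    * ``w_visc  = ∫ η·v² dt``      (dashpot, integrated over time)
    * ``w_adh   = ∫ F_adh(x) dx``
    * ``w_total = ∫ F dx``         (the independent total, not the sum)

    Only monotone loading is modelled; a trace whose displacement decreases
    anywhere is rejected.
    """
    x, v, t, F = trace.x, trace.v, trace.t, trace.F
    if np.any(np.diff(x) < 0):
        raise ValueError("displacement must be non-decreasing (unloading not modeled)")

    trace.w_el = cumulative_trapezoid(p.k * x, x, initial=0.0)
    trace.w_visc = cumulative_trapezoid(p.eta * v * v, t, initial=0.0)
    trace.w_adh = cumulative_trapezoid(np.asarray(adhesion_force(adh, x)), x,
                                       initial=0.0)
    trace.w_total = cumulative_trapezoid(F, x, initial=0.0)
    return EnergyBudget(
        w_el=float(trace.w_el[-1]),
        w_visc=float(trace.w_visc[-1]),
        w_adh=float(trace.w_adh[-1]),
        w_total=float(trace.w_total[-1]),
        method="numerical",
    )


def analytic_budget(
    p: ViscoelasticParams, D: float, T: float, w_adh: float = 0.0
) -> EnergyBudget:
    """Closed-form energy budget of a KV element under a linear ramp."""
    w_el = elastic_work(p.k, D)
    w_visc = viscous_work_ramp(p.eta, D, T)
    return EnergyBudget(w_el=w_el, w_visc=w_visc, w_adh=w_adh,
                        w_total=w_el + w_visc + w_adh, method="analytic")
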