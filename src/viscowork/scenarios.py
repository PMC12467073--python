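"""Builders for the reference scenarios: tissue/muscle rows, the
nanoparticle size-speed grid, and the single-particle worked example.

Two conventions deserve emphasis because they are easy to trip over:

* **Indentation depth equals particle diameter.**  The scenario grid labels
  D the nanoparticle diameter but uses the same value as the indentation
  depth in both energy formulas (full engulfment of the particle requires
  the membrane to deflect by one diameter).  A 50 nm particle is therefore
  indented to 50 nm, a 200 nm particle to 200 nm.

* **Membrane parameters scale linearly with diameter.**  Stiffness and
  damping of the effective membrane element grow in proportion to particle
  size from the 50 nm reference (k = 0.01 N/m, η = 5.00e-7 N·s/m); a 200 nm
  particle sees 4x both.  More elaborate contact laws (Hertz, JKR) can be
  substituted but are not built in.

The standalone worked example (100 nm particle, k = 0.010 N/m, η = 1.0e-6
N·s/m) is kept verbatim as its own fixture: its stiffness does *not* follow
the linear scaling rule, and the two parameter sets are deliberately not
reconciled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .constitutive import ViscoelasticParams
from .energetics import (
    EnergyBudget,
    analytic_budget,
    partition_trace,
    total_work_per_contraction,
)
from .constitutive import HillParams
from .loading import DEFAULT_N, make_linear_ramp, sample_trace

__all__ = [
    "NPScenario",
    "ScenarioRow",
    "REFERENCE_NP",
    "scale_np_params",
    "np_grid",
    "table2_rows",
    "worked_example_np",
    "TISSUE_KV",
    "TISSUE_HILL",
]

# tendon-like specimen used throughout the tissue-scale rows
TISSUE_KV = ViscoelasticParams(k=1000.0, eta=50.0)
TISSUE_D = 0.10  # m
TISSUE_HILL = HillParams(fmax=100.0, a=10.0, b=0.5)
HILL_D = 0.05  # m shortening distance per contraction


@dataclass(frozen=True)
class NPScenario:
    """One nanoparticle indentation scenario.

    ``diameter_nm`` doubles as the indentation depth (see module docstring);
    ``depth`` exposes it in metres.
    """

    label: str
    diameter_nm: float
    k: float
    eta: float
    T: float

    def __post_init__(self) -> None:
        if self.diameter_nm <= 0:
            raise ValueError(f"diameter must be > 0, got {self.diameter_nm}")
        if self.T <= 0:
            raise ValueError(f"loading duration T must be > 0, got {self.T}")

    @property
    def depth(self) -> float:
        """Indentation depth in metres (equal to the particle diameter)."""
        return self.diameter_nm * 1e-9

    @property
    def params(self) -> ViscoelasticParams:
        return ViscoelasticParams(k=self.k, eta=self.eta)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "diameter": self.diameter_nm, "diameter_units": "nm",
            "k": self.k, "k_units": "N/m",
            "eta": self.eta, "eta_units": "N·s/m",
            "T": self.T, "T_units": "s",
        }


#: 50 nm reference particle from which the size grid is scaled
REFERENCE_NP = NPScenario(label="Small NP reference", diameter_nm=50.0,
                          k=0.01, eta=5.00e-7, T=0.1)


@dataclass(frozen=True)
class ScenarioRow:
    """A computed scenario: parameters plus its energy budget(s).

    ``w_el``/``w_visc`` are ``None`` for Hill rows, which have no internal
    elastic/viscous partition — only the total mechanical work is defined.
    When a numerical cross-check was run its budget is kept in ``numerical``.
    """

    label: str
    parameters: dict = field(compare=False)
    w_el: float | None
    w_visc: float | None
    w_total: float
    numerical: EnergyBudget | None = None

    def to_dict(self) -> dict:
        d = {"label": self.label, "parameters": dict(self.parameters),
             "w_el": self.w_el, "w_visc": self.w_visc,
             "w_total": self.w_total, "energy_units": "J"}
        if self.numerical is not None:
            d["numerical"] = self.numerical.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioRow":
        num = d.get("numerical")
        budget = None
        if num is not None:
            budget = EnergyBudget(w_el=num["w_el"], w_visc=num["w_visc"],
                                  w_adh=num["w_adh"], w_total=num["w_total"],
                                  method=num["method"])
        return cls(label=d["label"], parameters=dict(d["parameters"]),
                   w_el=d["w_el"], w_visc=d["w_visc"], w_total=d["w_total"],
                   numerical=budget)


def scale_np_params(
    diameter_nm: float, reference: NPScenario = REFERENCE_NP
) -> ViscoelasticParams:
    """Membrane parameters for a particle of the given diameter.

    Linear-in-diameter scaling of both stiffness and damping from the 50 nm
    reference element.
    """
    if diameter_nm <= 0:
        raise ValueError(f"diameter must be > 0, got {diameter_nm}")
    ratio = diameter_nm / reference.diameter_nm
    return ViscoelasticParams(k=reference.k * ratio, eta=reference.eta * ratio)


def _evaluate_np(scenario: NPScenario, n: int = DEFAULT_N) -> ScenarioRow:
    """Analytic budget plus numerical cross-check for one NP scenario."""
    analytic = analytic_budget(scenario.params, scenario.depth, scenario.T)
    trace = sample_trace(make_linear_ramp(scenario.depth, scenario.T, n),
                         scenario.params)
    numerical = partition_trace(trace, scenario.params)
    return ScenarioRow(
        label=scenario.label,
        parameters=scenario.to_dict(),
        w_el=analytic.w_el, w_visc=analytic.w_visc, w_total=analytic.w_total,
        numerical=numerical,
    )


def np_grid(
    diameters_nm: list[float],
    times: list[float],
    n: int = DEFAULT_N,
    reference: NPScenario = REFERENCE_NP,
) -> list[ScenarioRow]:
    """Cartesian size x speed grid of nanoparticle indentation scenarios.

    Each cell is evaluated both analytically (closed forms) and numerically
    (trapezoidal trace integration); both results are recorded in the row.
    Rows are ordered size-major, matching the reference table.
    """
    if not diameters_nm or not times:
        raise ValueError("np_grid requires non-empty diameter and time lists")
    rows = []
    times_sorted = sorted(times, reverse=True)  # slow before fast
    for d in diameters_nm:
        p = scale_np_params(d, reference)
        for T in times_sorted:
            speed = "Slow" if T == max(times_sorted) else "Fast"
            size = "Small" if d <= reference.diameter_nm else "Large"
            label = f"{size} NP—{speed}" if len(times) > 1 else f"{d:g} nm NP"
            sc = NPScenario(label=label, diameter_nm=d, k=p.k, eta=p.eta, T=T)
            rows.append(_evaluate_np(sc, n))
    return rows


def table2_rows(n: int = DEFAULT_N) -> list[ScenarioRow]:
    """The five tissue/muscle reference rows, energies computed on the fly.

    Hookean ideal spring, Kelvin–Voigt slow/fast stretch (tendon-like
    specimen, k = 1000 N/m, η = 50 N·s/m, D = 0.10 m) and Hill muscle
    slow/fast contraction (fmax = 100 N, a = 10 N, b = 0.5 m/s, D = 0.05 m).
    """
    rows: list[ScenarioRow] = []

    hook = ViscoelasticParams(k=TISSUE_KV.k, eta=0.0)
    b = analytic_budget(hook, TISSUE_D, 1.0)
    rows.append(ScenarioRow(
        label="Hookean spring (ideal)",
        parameters={"k": hook.k, "D": TISSUE_D, "T": "any"},
        w_el=b.w_el, w_visc=b.w_visc, w_total=b.w_total))

    for speed, T in (("slow", 1.0), ("fast", 0.01)):
        b = analytic_budget(TISSUE_KV, TISSUE_D, T)
        trace = sample_trace(make_linear_ramp(TISSUE_D, T, n), TISSUE_KV)
        num = partition_trace(trace, TISSUE_KV)
        rows.append(ScenarioRow(
            label=f"Kelvin–Voigt ({speed})",
            parameters={"k": TISSUE_KV.k, "eta": TISSUE_KV.eta,
                        "D": TISSUE_D, "T": T},
            w_el=b.w_el, w_visc=b.w_visc, w_total=b.w_total, numerical=num))

    for speed, v in (("slow", 0.10), ("fast", 0.50)):
        w = total_work_per_contraction(TISSUE_HILL, HILL_D, v)
        rows.append(ScenarioRow(
            label=f"Hill muscle ({speed})",
            parameters={"fmax": TISSUE_HILL.fmax, "a": TISSUE_HILL.a,
                        "b": TISSUE_HILL.b, "D": HILL_D, "v": v},
            w_el=None, w_visc=None, w_total=w))
    return rows


def worked_example_np(n: int = DEFAULT_N) -> tuple[ScenarioRow, ScenarioRow]:
    """Single-particle worked example: 100 nm particle, slow vs fast entry.

    Uses the standalone parameter set (k = 0.010 N/m, η = 1.0e-6 N·s/m,
    D = 100 nm) verbatim — *not* the linear scaling rule — with entry times
    T = 0.1 s (slow) and T = 1e-4 s (fast).
    """
    slow = NPScenario(label="Worked example—Slow", diameter_nm=100.0,
                      k=0.010, eta=1.0e-6, T=0.1)
    fast = NPScenario(label="Worked example—Fast", diameter_nm=100.0,
                      k=0.010, eta=1.0e-6, T=1.0e-4)
    return _evaluate_np(slow, n), _evaluate_np(fast, n)
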