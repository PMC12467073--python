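"""Displacement protocols and sampled force/power/work traces.

The only first-class protocol is the constant-velocity linear ramp
``x(t) = D·(t/T)``, the loading history behind every closed-form energy
result in this package.  Other temporal profiles (holds, spikes,
oscillations) can be added by constructing a :class:`Trace` directly from
pre-sampled kinematics.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constitutive import NO_ADHESION, AdhesionModel, ViscoelasticParams, kv_force

__all__ = ["RampProtocol", "Trace", "make_linear_ramp", "sample_trace"]

#: default number of samples on the uniform grid; trapezoidal work integrals
#: on linear ramps are then accurate to ~1e-8 relative.
DEFAULT_N = 10_001

TRACE_COLUMNS = (
    "t_s", "x_m", "v_m_per_s", "F_N", "P_W",
    "W_el_J", "W_visc_J", "W_adh_J", "W_total_J",
)


@dataclass(frozen=True)
class RampProtocol:
    """Linear displacement ramp: amplitude ``D`` (m) over duration ``T`` (s).

    Velocity is the constant ``D/T`` everywhere, taken as the right-limit at
    t = 0 (the force therefore jumps to ``η·D/T`` at the first sample; this
    is the behaviour of the ideal ramp, not a numerical artefact).
    """

    D: float
    T: float
    n: int = DEFAULT_N

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError(f"ramp amplitude D must be >= 0, got {self.D}")
        if self.T <= 0:
            raise ValueError(f"ramp duration T must be > 0, got {self.T}")
        if self.n < 2:
            raise ValueError(f"need at least 2 samples, got {self.n}")

    @property
    def velocity(self) -> float:
        """Constant ramp velocity D/T (m/s)."""
        return self.D / self.T

    def sample(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Sampled kinematics ``(t, x, v)`` on the uniform grid."""
        t = np.linspace(0.0, self.T, self.n)
        x = self.D * (t / self.T)
        v = np.full_like(t, self.velocity)
        return t, x, v


def make_linear_ramp(D: float, T: float, n: int = DEFAULT_N) -> RampProtocol:
    """Build a linear ramp protocol x(t) = D·(t/T) with ``n`` samples."""
    return RampProtocol(D=D, T=T, n=n)


@dataclass
class Trace:
    """Sampled loading history with force, power and cumulative works.

    All arrays share one uniform time grid.  The cumulative work columns
    (``w_el``, ``w_visc``, ``w_adh``, ``w_total``, all J) start at zero and
    are filled by :func:`viscowork.energetics.partition_trace`.
    """

    t: np.ndarray
    x: np.ndarray
    v: np.ndarray
    F: np.ndarray
    P: np.ndarray
    w_el: np.ndarray = field(default=None)  # type: ignore[assignment]
    w_visc: np.ndarray = field(default=None)  # type: ignore[assignment]
    w_adh: np.ndarray = field(default=None)  # type: ignore[assignment]
    w_total: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        zeros = np.zeros_like(self.t)
        for name in ("w_el", "w_visc", "w_adh", "w_total"):
            if getattr(self, name) is None:
                setattr(self, name, zeros.copy())
        n = len(self.t)
        for name in ("x", "v", "F", "P", "w_el", "w_visc", "w_adh", "w_total"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"trace column {name} has wrong length")
        if n < 2 or np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing with >= 2 samples")
        if self.t[0] != 0.0:
            raise ValueError("time grid must start at t = 0")
        if self.x[0] != 0.0:
            raise ValueError("displacement must start at x = 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t_s": self.t, "x_m": self.x, "v_m_per_s": self.v,
            "F_N": self.F, "P_W": self.P,
            "W_el_J": self.w_el, "W_visc_J": self.w_visc,
            "W_adh_J": self.w_adh, "W_total_J": self.w_total,
        })

    def to_csv(self, path_or_buf) -> None:
        """Write the trace as RFC-4180 CSV with >= 6 significant digits."""
        self.to_frame().to_csv(path_or_buf, index=False, float_format="%.8e",
                               lineterminator="\n")

    @classmethod
    def from_csv(cls, path_or_buf) -> "Trace":
        df = pd.read_csv(path_or_buf)
        missing = set(TRACE_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"trace CSV missing columns: {sorted(missing)}")
        return cls(
            t=df["t_s"].to_numpy(), x=df["x_m"].to_numpy(),
            v=df["v_m_per_s"].to_numpy(), F=df["F_N"].to_numpy(),
            P=df["P_W"].to_numpy(),
            w_el=df["W_el_J"].to_numpy(), w_visc=df["W_visc_J"].to_numpy(),
            w_adh=df["W_adh_J"].to_numpy(), w_total=df["W_total_J"].to_numpy(),
        )

    def to_csv_string(self) -> str:
        buf = io.StringIO()
        self.to_csv(buf)
        return buf.getvalue()


def sample_trace(
    protocol: RampProtocol,
    model: ViscoelasticParams,
    adh: AdhesionModel = NO_ADHESION,
) -> Trace:
    """Evaluate the Kelvin–Voigt response along a ramp and fill the trace.

    Force at each sample is the KV law at the sampled (x, v); power is F·v;
    cumulative work columns are filled by trapezoidal quadrature via
    :func:`viscowork.energetics.partition_trace`.
    """
    t, x, v = protocol.sample()
    F = kv_force(model, x, v, adh)
    trace = Trace(t=t, x=x, v=v, F=np.asarray(F), P=np.asarray(F) * v)
    from .energetics import partition_trace  # deferred: energetics uses Trace

    partition_trace(trace, model, adh)
    return trace
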