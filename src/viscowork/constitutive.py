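"""Force laws for the material models: Kelvin–Voigt, adhesion, Hill muscle.

The Kelvin–Voigt (KV) element is a spring and dashpot in parallel,
``F = k·x + η·ẋ``: resistance grows with deformation rate, which is what
makes mechanical work rate-dependent in the first place.  An optional
adhesion term ``F_adh(x)`` models particle–membrane attraction during
nanoparticle indentation.  The Hill relation is the classical hyperbolic
muscle force–velocity law ``(F + a)(v + b) = (F_max + a)·b``, used here for
concentric shortening only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Union

import numpy as np

from .units import field_from_dict

ArrayLike = Union[float, np.ndarray]

__all__ = [
    "ViscoelasticParams",
    "AdhesionModel",
    "HillParams",
    "kv_force",
    "adhesion_force",
    "hill_force",
    "hill_vmax",
]


@dataclass(frozen=True)
class ViscoelasticParams:
    """Kelvin–Voigt element: stiffness ``k`` (N/m) and damping ``eta`` (N·s/m)."""

    k: float
    eta: float

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError(f"stiffness k must be >= 0, got {self.k}")
        if self.eta < 0:
            raise ValueError(f"damping eta must be >= 0, got {self.eta}")

    def to_dict(self) -> dict:
        return {"k": self.k, "k_units": "N/m", "eta": self.eta, "eta_units": "N·s/m"}

    @classmethod
    def from_dict(cls, d: dict) -> "ViscoelasticParams":
        return cls(
            k=field_from_dict(d, "k", "N/m"),
            eta=field_from_dict(d, "eta", "N·s/m"),
        )


@dataclass(frozen=True)
class AdhesionModel:
    """Adhesion force contribution F_adh(x).

    ``none`` is the default (identically zero force).  ``constant`` applies a
    fixed pull ``f0`` for any positive indentation; ``exponential`` decays as
    ``f0·exp(-x/lam)`` with decay length ``lam`` (m), a generic short-range
    surface-interaction profile.
    """

    kind: Literal["none", "constant", "exponential"] = "none"
    f0: float = 0.0
    lam: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("none", "constant", "exponential"):
            raise ValueError(f"unknown adhesion kind: {self.kind!r}")
        if self.f0 < 0:
            raise ValueError(f"adhesion amplitude f0 must be >= 0, got {self.f0}")
        if self.kind == "exponential":
            if self.lam is None or self.lam <= 0:
                raise ValueError("exponential adhesion requires decay length lam > 0")

    def to_dict(self) -> dict:
        d: dict = {"kind": self.kind, "f0": self.f0, "f0_units": "N"}
        if self.kind == "exponential":
            d.update(lam=self.lam, lam_units="m")
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AdhesionModel":
        kind = d.get("kind", "none")
        if kind == "none":
            return cls()
        f0 = field_from_dict(d, "f0", "N")
        if kind == "exponential":
            return cls(kind=kind, f0=f0, lam=field_from_dict(d, "lam", "m"))
        return cls(kind=kind, f0=f0)


NO_ADHESION = AdhesionModel()


@dataclass(frozen=True)
class HillParams:
    """Hill force–velocity constants: ``fmax`` (N), ``a`` (N), ``b`` (m/s)."""

    fmax: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if self.fmax < 0:
            raise ValueError(f"fmax must be >= 0, got {self.fmax}")
        if self.a <= 0:
            raise ValueError(f"Hill constant a must be > 0, got {self.a}")
        if self.b <= 0:
            raise ValueError(f"Hill constant b must be > 0, got {self.b}")

    def to_dict(self) -> dict:
        return {
            "fmax": self.fmax, "fmax_units": "N",
            "a": self.a, "a_units": "N",
            "b": self.b, "b_units": "m/s",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HillParams":
        return cls(
            fmax=field_from_dict(d, "fmax", "N"),
            a=field_from_dict(d, "a", "N"),
            b=field_from_dict(d, "b", "m/s"),
        )


def adhesion_force(adh: AdhesionModel, x: ArrayLike) -> ArrayLike:
    """Adhesion force at indentation ``x`` (m).

    The constant form is zero exactly at x = 0 (no contact, no pull) and f0
    for any positive indentation; the exponential form is f0·exp(-x/lam).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("indentation x must be >= 0")
    if adh.kind == "none":
        out = np.zeros_like(x)
    elif adh.kind == "constant":
        out = np.where(x > 0, adh.f0, 0.0)
    elif adh.kind == "exponential":
        out = adh.f0 * np.exp(-x / adh.lam)
    else:  # pragma: no cover - caught at construction
        raise ValueError(f"unknown adhesion kind: {adh.kind!r}")
    return out if out.ndim else float(out)


def kv_force(
    p: ViscoelasticParams,
    x: ArrayLike,
    v: ArrayLike,
    adh: AdhesionModel = NO_ADHESION,
) -> ArrayLike:
    """Kelvin–Voigt force ``k·x + η·v + F_adh(x)`` at state (x, v).

    The indentation coordinate is one-sided: ``x`` must be non-negative.
    Accepts scalars or equally-shaped arrays for ``x`` and ``v``.
    """
    x = np.asarray(x, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any(x < 0):
        raise ValueError("indentation x must be >= 0")
    out = p.k * x + p.eta * v + adhesion_force(adh, x)
    out = np.asarray(out)
    return out if out.ndim else float(out)


def hill_vmax(p: HillParams) -> float:
    """Maximum (zero-force) shortening velocity, ``b·fmax/a`` (m/s)."""
    return p.b * p.fmax / p.a


def hill_force(p: HillParams, v: ArrayLike) -> ArrayLike:
    """Hill muscle force at shortening velocity ``v`` (m/s), concentric only.

    Rearranged from ``(F + a)(v + b) = (fmax + a)·b``:

        F(v) = (fmax + a)·b / (v + b) − a

    so F(0) = fmax and F(vmax) = 0 with vmax = b·fmax/a.  Eccentric
    (v < 0) and super-maximal (v > vmax) velocities are outside the
    concentric Hill regime and rejected.
    """
    v = np.asarray(v, dtype=float)
    vmax = hill_vmax(p)
    if np.any(v < 0) or np.any(v > vmax * (1 + 1e-12) + 1e-300):
        raise ValueError(
            f"shortening velocity outside the concentric Hill regime [0, {vmax}]"
        )
    out = (p.fmax + p.a) * p.b / (v + p.b) - p.a
    # clamp the float residue at v = vmax so F(vmax) is exactly 0
    out = np.maximum(np.asarray(out), 0.0)
    return out if out.ndim else float(out)
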