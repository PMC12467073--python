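"""Unit handling for parameter ingest and serialization.

All internal quantities are SI (m, s, N, J, N/m, N·s/m).  Config files and
constructors may carry values in the convenience units common in the
nano-indentation literature (nm, ms, nN); they are converted on ingest and
every serialized value is written back with an explicit unit string.
"""

from __future__ import annotations

# multiplicative factor that converts a value in the given unit to SI
_TO_SI: dict[str, float] = {
    # length
    "m": 1.0,
    "mm": 1e-3,
    "um": 1e-6,
    "µm": 1e-6,
    "nm": 1e-9,
    # time
    "s": 1.0,
    "ms": 1e-3,
    "us": 1e-6,
    "µs": 1e-6,
    # force
    "N": 1.0,
    "mN": 1e-3,
    "uN": 1e-6,
    "nN": 1e-9,
    "pN": 1e-12,
    # velocity
    "m/s": 1.0,
    "mm/s": 1e-3,
    "um/s": 1e-6,
    "nm/s": 1e-9,
    # stiffness
    "N/m": 1.0,
    "mN/m": 1e-3,
    # damping
    "N·s/m": 1.0,
    "N*s/m": 1.0,
    "N.s/m": 1.0,
    "Ns/m": 1.0,
    # energy
    "J": 1.0,
    "aJ": 1e-18,
    "fJ": 1e-15,
    "pJ": 1e-12,
}


def to_si(value: float, units: str) -> float:
    """Convert ``value`` expressed in ``units`` to its SI equivalent.

    Raises
    ------
    ValueError
        If the unit string is not recognised.
    """
    try:
        return float(value) * _TO_SI[units]
    except KeyError:
        raise ValueError(f"unknown unit string: {units!r}") from None


def field_from_dict(d: dict, key: str, default_units: str) -> float:
    """Read ``d[key]`` and convert using ``d[f"{key}_units"]`` if present."""
    units = d.get(f"{key}_units", default_units)
    return to_si(d[key], units)
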