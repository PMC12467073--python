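"""Writers and golden-table verification for the reference scenarios.

``reproduce_tables`` regenerates the tissue/muscle reference table and the
nanoparticle size-speed table from the model, writes them as CSV, and diffs
every numeric cell against the published reference values embedded below.
The embedded numbers are comparison targets only; every value in the
emitted tables is computed at run time by the energetics module.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .scenarios import ScenarioRow, np_grid, table2_rows

__all__ = [
    "CellDiff",
    "reproduce_tables",
    "rows_to_frame",
    "write_rows_csv",
    "write_rows_json",
    "read_rows_json",
    "write_fixtures",
]

# published reference energies (J): (w_el, w_visc, w_total), None where the
# model defines no partition.  Matching tolerance follows printed precision.
TABLE2_PRINTED: dict[str, tuple[float | None, float | None, float]] = {
    "Hookean spring (ideal)": (5.0, 0.0, 5.0),
    "Kelvin–Voigt (slow)": (5.0, 0.50, 5.50),
    "Kelvin–Voigt (fast)": (5.0, 50.0, 55.0),
    "Hill muscle (slow)": (None, None, 4.0833),
    "Hill muscle (fast)": (None, None, 2.25),
}

TABLE3_PRINTED: dict[str, tuple[float, float]] = {
    "Small NP—Slow": (1.25e-17, 1.25e-20),
    "Small NP—Fast": (1.25e-17, 1.25e-17),
    "Large NP—Slow": (8.00e-16, 8.00e-19),
    "Large NP—Fast": (8.00e-16, 8.00e-16),
}

NP_DIAMETERS_NM = [50.0, 200.0]
NP_TIMES_S = [0.1, 1.0e-4]

# printed precision: values are quoted to 3-5 significant figures
PRINT_RTOL = 5e-4


@dataclass(frozen=True)
class CellDiff:
    """One mismatched table cell: computed vs published reference."""

    table: str
    row: str
    column: str
    computed: float
    reference: float

    def __str__(self) -> str:
        return (f"{self.table} [{self.row}] {self.column}: "
                f"computed {self.computed:.6g} != reference {self.reference:.6g}")


def _close(a: float, b: float) -> bool:
    return math.isclose(a, b, rel_tol=PRINT_RTOL, abs_tol=1e-30)


def rows_to_frame(rows: list[ScenarioRow]) -> pd.DataFrame:
    """Tabulate scenario rows; Hill rows carry empty elastic/viscous cells."""
    return pd.DataFrame({
        "label": [r.label for r in rows],
        "W_el_J": [r.w_el for r in rows],
        "W_visc_J": [r.w_visc for r in rows],
        "W_total_J": [r.w_total for r in rows],
    })


def write_rows_csv(rows: list[ScenarioRow], path: Path) -> None:
    rows_to_frame(rows).to_csv(path, index=False, float_format="%.8e",
                               lineterminator="\n")


def write_rows_json(rows: list[ScenarioRow], path: Path) -> None:
    path.write_text(json.dumps([r.to_dict() for r in rows], indent=2,
                               ensure_ascii=False) + "\n", encoding="utf-8")


def read_rows_json(path: Path) -> list[ScenarioRow]:
    return [ScenarioRow.from_dict(d)
            for d in json.loads(path.read_text(encoding="utf-8"))]


def _diff_rows(table: str, rows: list[ScenarioRow],
               printed: dict) -> list[CellDiff]:
    diffs: list[CellDiff] = []
    for row in rows:
        if row.label not in printed:
            continue
        ref = printed[row.label]
        if table == "table2":
            pairs = zip(("W_el_J", "W_visc_J", "W_total_J"),
                        (row.w_el, row.w_visc, row.w_total), ref)
        else:
            pairs = zip(("W_el_J", "W_visc_J"), (row.w_el, row.w_visc), ref)
        for col, computed, reference in pairs:
            if reference is None:
                continue
            if computed is None or not _close(computed, reference):
                diffs.append(CellDiff(table, row.label, col,
                                      float("nan") if computed is None
                                      else computed, reference))
    return diffs


def reproduce_tables(outdir: Path, n: int = 10_001,
                     fmt: str = "csv") -> list[CellDiff]:
    """Regenerate both reference tables, write them, and diff every cell.

    Returns the list of mismatched cells (empty on full agreement).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t2 = table2_rows(n)
    t3 = np_grid(NP_DIAMETERS_NM, NP_TIMES_S, n)
    for name, rows in (("table2", t2), ("table3", t3)):
        if fmt in ("csv", "both"):
            write_rows_csv(rows, outdir / f"{name}.csv")
        if fmt in ("json", "both"):
            write_rows_json(rows, outdir / f"{name}.json")
    return (_diff_rows("table2", t2, TABLE2_PRINTED)
            + _diff_rows("table3", t3, TABLE3_PRINTED))


def write_fixtures(outdir: Path) -> list[Path]:
    """Emit every built-in scenario as a JSON config file with unit fields."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, payload) -> None:
        p = outdir / f"{name}.json"
        p.write_text(json.dumps(payload, indent=2, ensure_ascii=False) + "\n",
                     encoding="utf-8")
        written.append(p)

    emit("tissue_kv", {
        "k": 1000.0, "k_units": "N/m", "eta": 50.0, "eta_units": "N·s/m",
        "D": 0.10, "D_units": "m", "T_slow": 1.0, "T_fast": 0.01,
        "T_units": "s",
    })
    emit("tissue_kv_ramp_figs", {
        "k": 1000.0, "k_units": "N/m", "eta": 50.0, "eta_units": "N·s/m",
        "D": 0.02, "D_units": "m", "T_slow": 2.0, "T_fast": 0.5,
        "T_units": "s",
    })
    emit("hill_muscle", {
        "fmax": 100.0, "fmax_units": "N", "a": 10.0, "a_units": "N",
        "b": 0.5, "b_units": "m/s", "D": 0.05, "D_units": "m",
        "v_slow": 0.10, "v_fast": 0.50, "v_units": "m/s",
    })
    emit("np_worked_example", {
        "diameter": 100.0, "diameter_units": "nm",
        "k": 0.010, "k_units": "N/m", "eta": 1.0e-6, "eta_units": "N·s/m",
        "T_slow": 0.1, "T_fast": 1.0e-4, "T_units": "s",
    })
    emit("np_grid", {
        "diameters": NP_DIAMETERS_NM, "diameter_units": "nm",
        "times": NP_TIMES_S, "T_units": "s",
        "reference": {"diameter": 50.0, "diameter_units": "nm",
                      "k": 0.01, "k_units": "N/m",
                      "eta": 5.00e-7, "eta_units": "N·s/m"},
    })
    return written
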