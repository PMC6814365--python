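"""Lifetime-voltage calibration and conversion.

A voltage-sensitive dye's weighted mean lifetime responds linearly to
membrane potential:  tau = m * V_mem + b,  with the sensitivity ``m`` in
ps/mV and the 0 mV lifetime ``b`` in ps.  Per-cell calibrations come from
paired voltage-clamp / lifetime measurements; the population calibration
(mean m and b across cells of a line) converts lifetimes measured without
an electrode into absolute membrane potential:

    V_mem  = (tau - b) / m            (absolute potential)
    dV_mem = d tau / m                (potential change)

with first-order error propagation

    dV  = |V| * sqrt[ (dtau^2 + db^2) / (tau - b)^2 + (dm / m)^2 ]
    dDV = |DV| * sqrt[ (dDtau / Dtau)^2 + (dm / m)^2 ]

Note the propagated absolute error vanishes at V_mem = 0 by construction;
an optional floor (dtau/|m|) is provided for users who prefer a
non-degenerate uncertainty there.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

__all__ = [
    "CellCalibration",
    "PopulationCalibration",
    "fit_cell_calibration",
    "aggregate_calibration",
    "lifetime_to_vmem",
    "dlifetime_to_dvmem",
    "propagate_vmem_error",
    "propagate_dvmem_error",
    "load_calibration",
    "save_calibration",
    "PRESETS",
]


@dataclass
class CellCalibration:
    """One cell's linear lifetime-voltage relationship (tau in ps, V in mV)."""

    m: float  # sensitivity, ps/mV
    b: float  # 0 mV lifetime, ps
    dm: float = float("nan")  # standard error of m
    db: float = float("nan")  # standard error of b
    residuals: list[float] = field(default_factory=list)
    n_steps: int = 0
    voltages: list[float] = field(default_factory=list)
    lifetimes: list[float] = field(default_factory=list)

    @property
    def saturated(self) -> bool:
        """True when the line is a perfect 2-point fit (SEs undefined)."""
        return self.n_steps <= 2


@dataclass
class PopulationCalibration:
    """Average calibration across all cells of one line."""

    m: float
    b: float
    m_sem: float = float("nan")
    b_sem: float = float("nan")
    n_cells: int = 0
    cell_line: str = ""
    cells: list[CellCalibration] = field(default_factory=list)


# Population calibrations for lines whose values are commonly cited
# (sensitivity ps/mV, 0 mV lifetime ps, SEMs).
PRESETS: dict[str, PopulationCalibration] = {
    "hek293t": PopulationCalibration(m=3.50, b=1770.0, m_sem=0.08, b_sem=20.0,
                                     cell_line="hek293t"),
    "a431": PopulationCalibration(m=3.55, b=1740.0, m_sem=0.08, b_sem=20.0,
                                  cell_line="a431"),
}


def fit_cell_calibration(
    pairs: list[tuple[float, float]] | np.ndarray,
) -> CellCalibration:
    """Ordinary least-squares line tau(V) from (V_mV, tau_ps) pairs.

    Voltage is the controlled variable (set by the clamp), so lifetime is
    regressed on voltage.  Standard errors come from the residual variance;
    a 2-point fit is exact and flagged ``saturated``.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 2:
        raise ValueError("need >= 2 (voltage, lifetime) pairs")
    v, tau = arr[:, 0], arr[:, 1]
    if np.ptp(v) == 0:
        raise ValueError("all voltages identical; slope undefined")
    res = stats.linregress(v, tau)
    fitted = res.intercept + res.slope * v
    return CellCalibration(
        m=float(res.slope),
        b=float(res.intercept),
        dm=float(res.stderr) if len(arr) > 2 else float("nan"),
        db=float(res.intercept_stderr) if len(arr) > 2 else float("nan"),
        residuals=(tau - fitted).tolist(),
        n_steps=len(arr),
        voltages=v.tolist(),
        lifetimes=tau.tolist(),
    )


def aggregate_calibration(
    cells: list[CellCalibration], cell_line: str = ""
) -> PopulationCalibration:
    """Arithmetic mean and SEM of slopes and intercepts across cells."""
    if not cells:
        raise ValueError("no cells to aggregate")
    ms = np.array([c.m for c in cells])
    bs = np.array([c.b for c in cells])
    n = len(cells)
    sem = lambda x: float(x.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return PopulationCalibration(
        m=float(ms.mean()), b=float(bs.mean()),
        m_sem=sem(ms), b_sem=sem(bs),
        n_cells=n, cell_line=cell_line, cells=list(cells),
    )


def lifetime_to_vmem(tau_ps, cal: PopulationCalibration | CellCalibration):
    """V_mem (mV) from lifetime (ps):  (tau - b) / m.  Accepts arrays."""
    if cal.m == 0:
        raise ValueError("calibration slope is zero; conversion undefined")
    return (np.asarray(tau_ps, dtype=float) - cal.b) / cal.m


def dlifetime_to_dvmem(dtau_ps, cal: PopulationCalibration | CellCalibration):
    """Voltage change (mV) from lifetime change (ps):  dtau / m."""
    if cal.m == 0:
        raise ValueError("calibration slope is zero; conversion undefined")
    return np.asarray(dtau_ps, dtype=float) / cal.m


def propagate_vmem_error(
    tau_ps: float,
    dtau_ps: float,
    cal: PopulationCalibration,
    floor: bool = False,
) -> float:
    """Propagated uncertainty of an absolute V_mem determination (mV).

    Combines lifetime error, intercept error and slope error; the result
    scales with |V_mem| and is therefore 0 at the 0 mV lifetime (flagged by
    raising unless all errors are zero).  With ``floor=True`` the result is
    bounded below by dtau/|m|.
    """
    dm = 0.0 if np.isnan(cal.m_sem) else cal.m_sem
    db = 0.0 if np.isnan(cal.b_sem) else cal.b_sem
    diff = tau_ps - cal.b
    if diff == 0:
        if dtau_ps == 0 and db == 0:
            return 0.0
        if floor:
            return abs(dtau_ps / cal.m)
        raise ZeroDivisionError(
            "tau equals the 0 mV lifetime: relative error term undefined "
            "(use floor=True for a bounded estimate)"
        )
    v = lifetime_to_vmem(tau_ps, cal)
    dv = abs(v) * np.sqrt((dtau_ps**2 + db**2) / diff**2 + (dm / cal.m) ** 2)
    if floor:
        dv = max(dv, abs(dtau_ps / cal.m))
    return float(dv)


def propagate_dvmem_error(
    dtau_ps: float, ddtau_ps: float, cal: PopulationCalibration
) -> float:
    """Propagated uncertainty of a V_mem change (mV).

    Only the slope error enters besides the lifetime-change error.  The
    degenerate dtau = 0 case reduces to ddtau / |m|.
    """
    dm = 0.0 if np.isnan(cal.m_sem) else cal.m_sem
    if dtau_ps == 0:
        return float(abs(ddtau_ps / cal.m))
    dv = dlifetime_to_dvmem(dtau_ps, cal)
    return float(abs(dv) * np.sqrt((ddtau_ps / dtau_ps) ** 2 + (dm / cal.m) ** 2))


_SCHEMA_VERSION = 1


def save_calibration(cal: PopulationCalibration, path: str | Path) -> None:
    """Write a population calibration as versioned JSON."""
    payload = {
        "schema_version": _SCHEMA_VERSION,
        "cell_line": cal.cell_line,
        "m_ps_per_mv": cal.m,
        "b_ps": cal.b,
        "m_sem": None if np.isnan(cal.m_sem) else cal.m_sem,
        "b_sem": None if np.isnan(cal.b_sem) else cal.b_sem,
        "n_cells": cal.n_cells,
        "cells": [
            {k: v for k, v in asdict(c).items() if k not in ("residuals",)}
            for c in cal.cells
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_calibration(path: str | Path) -> PopulationCalibration:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema_version") != _SCHEMA_VERSION:
        raise ValueError(f"unsupported calibration schema: {payload.get('schema_version')}")
    cells = [
        CellCalibration(
            m=c["m"], b=c["b"], dm=c.get("dm", float("nan")),
            db=c.get("db", float("nan")), n_steps=c.get("n_steps", 0),
            voltages=c.get("voltages", []), lifetimes=c.get("lifetimes", []),
        )
        for c in payload.get("cells", [])
    ]
    return PopulationCalibration(
        m=payload["m_ps_per_mv"],
        b=payload["b_ps"],
        m_sem=payload["m_sem"] if payload["m_sem"] is not None else float("nan"),
        b_sem=payload["b_sem"] if payload["b_sem"] is not None else float("nan"),
        n_cells=payload.get("n_cells", len(cells)),
        cell_line=payload.get("cell_line", ""),
        cells=cells,
    )
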