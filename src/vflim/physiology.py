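"""Downstream physiology computations.

Goldman-Hodgkin-Katz (GHK) membrane-potential estimation over parameter
grids, Freedman-Diaconis histograms of V_mem distributions, time-series
voltage-change extraction, and four-parameter-logistic dose-response fits.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.constants import R as GAS_CONSTANT
from scipy.constants import physical_constants

from .calibration import PopulationCalibration, dlifetime_to_dvmem

FARADAY = physical_constants["Faraday constant"][0]

__all__ = [
    "GHKParams",
    "BufferPreset",
    "BUFFERS",
    "STANDARD_GRID",
    "ghk_vmem",
    "ghk_range",
    "fd_histogram",
    "timeseries_delta_vmem",
    "fit_4pl",
    "four_param_logistic",
]


@dataclass(frozen=True)
class BufferPreset:
    """Total monovalent-ion concentrations of an extracellular buffer (mM).

    Totals are stoichiometric sums over the salt recipe, e.g. for HBSS
    K = KCl + KH2PO4, Na = NaCl + NaHCO3 + 2*Na2HPO4,
    Cl = NaCl + KCl + 2*CaCl2 + 2*MgCl2.
    """

    name: str
    k_out: float
    na_out: float
    cl_out: float


BUFFERS: dict[str, BufferPreset] = {
    # HBSS: 137.9 NaCl, 5.3 KCl, 4.2 NaHCO3, 1.3 CaCl2, 0.49 MgCl2,
    #       0.44 KH2PO4, 0.34 Na2HPO4 (mM)
    "hbss": BufferPreset(
        "hbss",
        k_out=5.3 + 0.44,
        na_out=137.9 + 4.2 + 2 * 0.34,
        cl_out=137.9 + 5.3 + 2 * 1.3 + 2 * 0.49,
    ),
    # high-K HBSS: 120 KCl, 23.3 NaCl, minor salts as above
    "highk": BufferPreset(
        "highk",
        k_out=120.0 + 0.44,
        na_out=23.3 + 4.2 + 2 * 0.34,
        cl_out=120.0 + 23.3 + 2 * 1.3 + 2 * 0.49,
    ),
}


@dataclass(frozen=True)
class GHKParams:
    """GHK voltage-equation inputs: relative permeabilities (P_K fixed 1)
    and ion concentrations in mM; temperature in K."""

    p_na: float
    p_cl: float
    k_in: float
    na_in: float
    cl_in: float
    k_out: float
    na_out: float
    cl_out: float
    p_k: float = 1.0
    temperature: float = 293.0

    def __post_init__(self) -> None:
        for name in ("k_in", "na_in", "cl_in", "k_out", "na_out", "cl_out"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.p_k < 0 or self.p_na < 0 or self.p_cl < 0:
            raise ValueError("permeabilities must be nonnegative")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


# "Standard" permeability/concentration values bracketed by one value
# below and one above each: 3^5 = 243 combinations.
STANDARD_GRID: dict[str, list[float]] = {
    "p_na": [0.01, 0.05, 0.2],
    "p_cl": [0.2, 0.45, 0.9],
    "k_in": [90.0, 150.0, 200.0],
    "na_in": [5.0, 15.0, 50.0],
    "cl_in": [2.0, 10.0, 35.0],
}


def ghk_vmem(params: GHKParams) -> float:
    """GHK membrane potential in mV.

    V = (RT/F) ln[(P_K[K]out + P_Na[Na]out + P_Cl[Cl]in) /
                  (P_K[K]in + P_Na[Na]in + P_Cl[Cl]out)]

    Chloride, being an anion, enters with in/out reversed relative to the
    cations.
    """
    num = params.p_k * params.k_out + params.p_na * params.na_out + params.p_cl * params.cl_in
    den = params.p_k * params.k_in + params.p_na * params.na_in + params.p_cl * params.cl_out
    if num <= 0 or den <= 0:
        raise ValueError("GHK logarithm argument must be positive")
    return float(1000.0 * GAS_CONSTANT * params.temperature / FARADAY * np.log(num / den))


def ghk_range(
    grid: dict[str, list[float]] | None = None,
    buffer: BufferPreset | str = "hbss",
    temperature: float = 293.0,
) -> dict:
    """Exhaustive GHK evaluation over the Cartesian product of a grid.

    Returns the extreme potentials and the parameter combinations that
    achieve them, plus all evaluated values.
    """
    grid = grid or STANDARD_GRID
    buf = BUFFERS[buffer] if isinstance(buffer, str) else buffer
    keys = ["p_na", "p_cl", "k_in", "na_in", "cl_in"]
    for k in keys:
        if not grid.get(k):
            raise ValueError(f"grid for {k} is empty")
    combos = []
    values = []
    for combo in itertools.product(*(grid[k] for k in keys)):
        params = GHKParams(
            **dict(zip(keys, combo)),
            k_out=buf.k_out, na_out=buf.na_out, cl_out=buf.cl_out,
            temperature=temperature,
        )
        combos.append(params)
        values.append(ghk_vmem(params))
    values = np.array(values)
    imin, imax = int(values.argmin()), int(values.argmax())
    return {
        "min_mv": float(values[imin]),
        "max_mv": float(values[imax]),
        "argmin": combos[imin],
        "argmax": combos[imax],
        "values_mv": values,
        "n_combinations": len(values),
    }


def fd_histogram(values) -> tuple[float, np.ndarray, np.ndarray]:
    """Histogram with the Freedman-Diaconis bin width 2*IQR*n^(-1/3).

    The IQR uses linear-interpolation quantiles.  Edges are anchored at the
    data minimum; the last edge is extended to include the maximum, so the
    counts always sum to n.  Degenerate IQR = 0 (e.g. all values identical)
    falls back to a single bin.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 values")
    iqr = float(np.quantile(x, 0.75) - np.quantile(x, 0.25))
    width = 2.0 * iqr * n ** (-1.0 / 3.0)
    span = x[-1] - x[0]
    if width <= 0 or span == 0:
        width = span if span > 0 else 1.0
        edges = np.array([x[0], x[0] + width])
    else:
        n_edges = int(np.ceil(span / width)) + 1
        edges = x[0] + width * np.arange(n_edges + 1)
    counts, edges = np.histogram(x, bins=edges)
    return width, edges, counts


def timeseries_delta_vmem(
    frames: list[pd.DataFrame],
    cal: PopulationCalibration,
    baseline_frame: int = 0,
    response_frame: int = -1,
) -> pd.DataFrame:
    """Per-ROI voltage change between two frames of a lifetime time series.

    ``frames`` are per-ROI lifetime tables (index label, column ``tau_m``
    in ps) as produced by ``segmentation.roi_mean_lifetime`` (times 1000 if
    the map was in ns).  ROIs missing or unfit in either frame propagate as
    NaN with a diagnostic column.
    """
    base = frames[baseline_frame]
    resp = frames[response_frame]
    labels = sorted(set(base.index) | set(resp.index))
    rows = []
    for g in labels:
        t0 = base["tau_m"].get(g, np.nan)
        t1 = resp["tau_m"].get(g, np.nan)
        if np.isnan(t0) or np.isnan(t1):
            rows.append((g, np.nan, "missing in baseline or response frame"))
        else:
            rows.append((g, float(dlifetime_to_dvmem(t1 - t0, cal)), ""))
    return pd.DataFrame(rows, columns=["label", "delta_vmem_mv", "note"]).set_index("label")


def four_param_logistic(x, bottom, top, ec50, hill):
    """y = bottom + (top - bottom) / (1 + (ec50 / x)^hill)."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ec50 / x) ** hill)


def fit_4pl(
    doses, responses
) -> dict:
    """Least-squares four-parameter-logistic dose-response fit.

    Returns bottom, top, ec50, hill plus a ``degenerate`` flag raised when
    the response span is indistinguishable from flat.  Decreasing responses
    are captured by a negative Hill coefficient.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if len(np.unique(x)) < 4:
        raise ValueError("need >= 4 distinct dose levels")
    if np.any(x <= 0):
        raise ValueError("doses must be positive")
    span = y.max() - y.min()
    scale = span if span > 0 else 1.0
    ec50_0 = float(np.exp(np.mean(np.log(x))))
    increasing = y[np.argmax(x)] >= y[np.argmin(x)]
    p0 = [float(y.min()), float(y.max()), ec50_0, 1.0 if increasing else -1.0]
    try:
        popt, _ = optimize.curve_fit(
            four_param_logistic, x, y, p0=p0, maxfev=20000,
            bounds=([-np.inf, -np.inf, 1e-12, -50], [np.inf, np.inf, np.inf, 50]),
        )
    except RuntimeError as err:
        raise RuntimeError(f"4PL fit did not converge: {err}") from err
    bottom, top, ec50, hill = (float(v) for v in popt)
    # the 4PL is invariant under (bottom, top, hill) -> (top, bottom, -hill);
    # canonical form: bottom <= top, hill sign encodes direction
    if bottom > top:
        bottom, top, hill = top, bottom, -hill
    degenerate = abs(top - bottom) < 0.05 * max(scale, 1e-12) or span == 0
    return {
        "bottom": bottom, "top": top, "ec50": ec50, "hill": hill,
        "degenerate": bool(degenerate),
    }
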