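"""Functional readouts: BTK-inhibitor sensitivity (IC50) and growth support
(doubling time).

Viability plates are normalized to the mean medium-control OD and fitted
with a four-parameter logistic on log10 concentration; the fitted midpoint
is the IC50.  A response whose dynamic range is below a small epsilon (the
highly inhibitor-resistant phenotype) yields an explicit indeterminate flag
instead of a number.

Growth is quantified from bead-calibrated counts: cell counts are rescaled
by expected/observed beads, log2-transformed and regressed on time; the
doubling time is the reciprocal slope, with a confidence interval from the
slope's standard error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .phospho import compare_phospho
from .simulate import GrowthSeries

__all__ = [
    "DoseResponse",
    "DoublingTimeFit",
    "normalize_viability",
    "normalize_plate",
    "fit_dose_response",
    "fit_doubling_time",
    "compare_doubling_times",
    "significance_stars",
]


def normalize_viability(od_wells, medium_control_wells) -> np.ndarray:
    """Each well OD divided by the mean medium-control OD."""
    controls = np.asarray(medium_control_wells, dtype=float)
    if len(controls) == 0:
        raise ValueError("need at least one medium-control well")
    mean_control = controls.mean()
    if mean_control <= 0:
        raise ValueError(f"mean control OD must be > 0, got {mean_control}")
    return np.asarray(od_wells, dtype=float) / mean_control


def normalize_plate(plate: pd.DataFrame) -> pd.DataFrame:
    """Split a plate table (concentration_um, od490, is_medium_control) into
    normalized per-well viabilities."""
    controls = plate.loc[plate["is_medium_control"], "od490"]
    wells = plate.loc[~plate["is_medium_control"]]
    viability = normalize_viability(wells["od490"], controls)
    return pd.DataFrame(
        {"concentration_um": wells["concentration_um"].to_numpy(), "viability": viability}
    )


@dataclass
class DoseResponse:
    top: float | None
    bottom: float | None
    ic50: float | None  # same units as the input concentrations
    hill: float | None
    residual_ss: float | None
    converged: bool
    indeterminate: bool  # flat response, no meaningful IC50
    extrapolated: bool  # fitted IC50 outside the tested range


def _four_pl(logc: np.ndarray, top: float, bottom: float, log_ic50: float, hill: float):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logc - log_ic50)))


def fit_dose_response(
    data: pd.DataFrame, flat_epsilon: float = 0.2
) -> DoseResponse:
    """Least-squares 4PL fit of normalized viability vs log10 concentration.

    ``data`` needs columns ``concentration_um`` and ``viability`` (one row
    per well; replicate wells enter the fit individually).  Requires >= 4
    distinct concentrations.  A dynamic range (max - min of per-concentration
    mean viability) below ``flat_epsilon`` is flagged indeterminate.
    """
    conc = data["concentration_um"].to_numpy(dtype=float)
    via = data["viability"].to_numpy(dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be strictly positive")
    distinct = np.unique(conc)
    if len(distinct) < 4:
        raise ValueError(f"need >= 4 distinct concentrations, got {len(distinct)}")
    means = np.array([via[conc == c].mean() for c in distinct])
    if means.max() - means.min() < flat_epsilon:
        return DoseResponse(
            top=None, bottom=None, ic50=None, hill=None, residual_ss=None,
            converged=False, indeterminate=True, extrapolated=False,
        )
    logc = np.log10(conc)
    p0 = (
        float(means.max()),
        float(means.min()),
        float(np.log10(np.median(distinct))),
        1.0,
    )
    try:
        popt, _ = optimize.curve_fit(_four_pl, logc, via, p0=p0, maxfev=20000)
    except RuntimeError:
        return DoseResponse(
            top=None, bottom=None, ic50=None, hill=None, residual_ss=None,
            converged=False, indeterminate=False, extrapolated=False,
        )
    top, bottom, log_ic50, hill = (float(v) for v in popt)
    ic50 = 10.0**log_ic50
    resid = via - _four_pl(logc, *popt)
    return DoseResponse(
        top=top,
        bottom=bottom,
        ic50=ic50,
        hill=hill,
        residual_ss=float(np.sum(resid**2)),
        converged=True,
        indeterminate=False,
        extrapolated=not (distinct.min() <= ic50 <= distinct.max()),
    )


@dataclass
class DoublingTimeFit:
    doubling_time_h: float | None
    ci_low_h: float | None
    ci_high_h: float | None
    slope_per_h: float
    slope_stderr: float
    non_growing: bool


def fit_doubling_time(series: GrowthSeries, ci_level: float = 0.95) -> DoublingTimeFit:
    """Doubling time from log2(bead-normalized counts) regressed on time.

    Exact on noise-free exponential data for any grid.  A non-positive slope
    is reported as non-growing (no doubling time).  The CI maps the slope's
    t-based interval through DT = 1/slope; if the interval includes zero the
    upper bound is unbounded (inf).
    """
    d = series.data
    if len(d) < 3:
        raise ValueError(f"need >= 3 timepoints to fit, got {len(d)}")
    counts = series.normalized_counts()
    t = d["time_h"].to_numpy(dtype=float)
    pos = counts > 0
    if pos.sum() < 2 or len(np.unique(counts[pos])) < 2:
        raise ValueError("need >= 2 distinct positive normalized counts")
    t, counts = t[pos], counts[pos]
    reg = stats.linregress(t, np.log2(counts))
    slope, stderr = float(reg.slope), float(reg.stderr)
    if slope <= 0:
        return DoublingTimeFit(
            doubling_time_h=None, ci_low_h=None, ci_high_h=None,
            slope_per_h=slope, slope_stderr=stderr, non_growing=True,
        )
    dt = 1.0 / slope
    tcrit = stats.t.ppf(0.5 + ci_level / 2, df=len(t) - 2)
    lo_slope, hi_slope = slope - tcrit * stderr, slope + tcrit * stderr
    ci_low = 1.0 / hi_slope if hi_slope > 0 else None
    ci_high = 1.0 / lo_slope if lo_slope > 0 else float("inf")
    return DoublingTimeFit(
        doubling_time_h=dt, ci_low_h=ci_low, ci_high_h=ci_high,
        slope_per_h=slope, slope_stderr=stderr, non_growing=False,
    )


def significance_stars(p: float) -> str:
    """Figure-legend star annotation: * P<0.05, ** P<0.01, *** P<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_doubling_times(
    group_a, group_b, sided: str = "two-sided"
) -> tuple[float, float, str]:
    """Unpaired t test on replicate doubling times with star annotation.

    Returns ``(t_statistic, p_value, stars)``.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError(
            f"need >= 2 replicates per group, got ({len(group_a)}, {len(group_b)})"
        )
    t, p = compare_phospho(group_a, group_b, sided=sided)
    return t, p, significance_stars(p)
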