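"""Post-processing metrics: decadal means, measure effectiveness, winter peaks.

These reproduce the diagnostics used to judge emission-control options:
decade-averaged dissolved surface concentrations, the percent reduction a
measure achieves relative to a paired control run sharing the same weather
realization, and the winter concentration peak that sea-ice blocking of
volatilization produces in seasonally ice-covered basins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import SimulationOutput
from .scenarios import DAYS_PER_YEAR

__all__ = [
    "decadal_mean_cw",
    "measure_effectiveness",
    "winter_peak_stats",
    "annual_ice_days",
    "ScenarioMetrics",
    "scenario_metrics",
]

#: months counted as the ice season for reporting purposes (Dec-Apr)
WINTER_MONTHS = (12, 1, 2, 3, 4)


def _monthly_cw(output: SimulationOutput, basin: str) -> pd.Series:
    return output.monthly_mean("c_w")[basin]


def decadal_mean_cw(
    output: SimulationOutput, basin: str, windows: list[tuple[int, int]]
) -> pd.Series:
    """Mean dissolved surface concentration over each (start, end) year span.

    Spans are inclusive; means are taken over monthly-mean values.  Raises if
    a window lies outside the simulated period or is empty.
    """
    monthly = _monthly_cw(output, basin)
    years = monthly.index.get_level_values("year")
    values = {}
    for (y0, y1) in windows:
        if y1 < y0:
            raise ValueError(f"empty window ({y0}, {y1})")
        if y0 < output.year[0] or y1 > output.year[-1]:
            raise ValueError(f"window ({y0}, {y1}) outside run span")
        sel = monthly[(years >= y0) & (years <= y1)]
        values[f"{y0}-{y1}"] = float(sel.mean())
    return pd.Series(values, name=basin)


def measure_effectiveness(
    control: SimulationOutput,
    treated: SimulationOutput,
    basin: str,
    horizon: tuple[int, int],
) -> float:
    """Percent reduction achieved by a measure over the horizon window.

    ``100 × (1 − mean C_W,treated / mean C_W,control)`` over the inclusive
    year span, using monthly means.  Control and treated runs are expected to
    share the weather realization (paired design); the result is invariant to
    the units of C_W.
    """
    c = decadal_mean_cw(control, basin, [horizon]).iloc[0]
    t = decadal_mean_cw(treated, basin, [horizon]).iloc[0]
    if c == 0:
        raise ZeroDivisionError("control mean concentration is zero")
    return 100.0 * (1.0 - t / c)


def winter_peak_stats(output: SimulationOutput, basin: str) -> pd.DataFrame:
    """Per-year month of maximum monthly C_W and max/min amplitude.

    Ties break toward the earliest month.  Years whose series is entirely
    zero get amplitude NaN (undefined) rather than raising.
    """
    monthly = _monthly_cw(output, basin)
    rows = []
    for year, grp in monthly.groupby(level="year", sort=True):
        vals = grp.droplevel("year")
        peak_month = int(vals.index[int(np.argmax(vals.to_numpy()))])
        vmax, vmin = float(vals.max()), float(vals.min())
        if vmax == 0.0:
            amplitude = np.nan
        elif vmin == 0.0:
            amplitude = np.inf
        else:
            amplitude = vmax / vmin
        rows.append({"year": int(year), "peak_month": peak_month, "amplitude": amplitude})
    return pd.DataFrame(rows).set_index("year")


def annual_ice_days(output: SimulationOutput, basin: str) -> pd.Series:
    """Days per calendar year with any ice cover."""
    counts = output.annual_ice_days(basin)
    years = output.year.reshape(-1, DAYS_PER_YEAR)[:, 0]
    return pd.Series(counts, index=years, name=f"ice_days:{basin}")


@dataclass
class ScenarioMetrics:
    """Bundle of per-basin diagnostics for a treated-vs-control pair."""

    basin: str
    decadal_means_control: pd.Series
    decadal_means_treated: pd.Series
    effectiveness_percent: float
    winter_peaks_control: pd.DataFrame
    ice_days_control: pd.Series


def scenario_metrics(
    control: SimulationOutput,
    treated: SimulationOutput,
    basin: str,
    horizon: tuple[int, int],
    decades: list[tuple[int, int]] | None = None,
) -> ScenarioMetrics:
    """Compute the standard diagnostic bundle for one basin."""
    if decades is None:
        y0 = int(control.year[0])
        y1 = int(control.year[-1])
        decades = [(y, min(y + 9, y1)) for y in range(y0, y1 + 1, 10)]
    return ScenarioMetrics(
        basin=basin,
        decadal_means_control=decadal_mean_cw(control, basin, decades),
        decadal_means_treated=decadal_mean_cw(treated, basin, decades),
        effectiveness_percent=measure_effectiveness(control, treated, basin, horizon),
        winter_peaks_control=winter_peak_stats(control, basin),
        ice_days_control=annual_ice_days(control, basin),
    )


def plot_cw(outputs, basin: str, labels=None, ax=None):
    """Simple line plot of monthly C_W for one basin across runs."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    labels = labels or [o.provenance.get("label", str(i)) for i, o in enumerate(outputs)]
    for out, lab in zip(outputs, labels):
        monthly = _monthly_cw(out, basin)
        t = monthly.index.get_level_values("year") + (
            monthly.index.get_level_values("month") - 0.5) / 12.0
        ax.plot(t, monthly.to_numpy(), label=lab, lw=0.8)
    ax.set_xlabel("year")
    ax.set_ylabel("C_W (ng/L)")
    ax.set_title(basin)
    ax.legend(fontsize=8)
    return ax
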