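"""Synthetic daily forcing and climate / nutrient / emission scenarios.

The simulator is driven entirely by internally generated forcing: daily air
temperature, wind speed, precipitation, shortwave radiation, river discharge,
river nutrient and contaminant loads, and atmospheric contaminant gas-phase
concentration, per basin.  The "random weather" (RW) generator produces a
stationary climate — a sinusoidal seasonal cycle plus seeded Gaussian annual
anomalies — emulating present-day Baltic conditions with interannual
variability but no trend.

Scenario transforms layered on top of an RW realization:

* **a1b** — a severe-warming climate: on average 7 % higher wind speed, 60 %
  higher air temperature (on the °C scale of the period mean) and 20 % more
  precipitation.  Wind and precipitation are scaled multiplicatively; the
  temperature change is applied as a uniform additive delta equal to
  ``(factor − 1) ×`` the realized period-mean of the base series, so the
  transformed/base period-mean ratio equals the factor exactly while winters
  warm by the same amount as summers (a multiplicative mode is available via
  ``temperature_mode="scale"``, but note that scaling signed °C values makes
  sub-zero winters *colder*).
* **CL / IL / BSAP** — nutrient-load scenarios: constant loads, a linear ramp
  up (increasing loads), or a linear ramp down to a Baltic Sea Action Plan
  target fraction reached at a target year, then constant.
* **current / red_river / red_air** — emission-control scenarios: unchanged,
  or a step reduction of the river contaminant load or of the atmospheric
  contaminant concentration by ``reduction_fraction`` from ``reduction_year``
  onward.

A 365-day no-leap calendar is used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DAYS_PER_YEAR",
    "FORCING_VARIABLES",
    "VariableClimate",
    "ClimatologyParams",
    "ScenarioSpec",
    "ForcingSeries",
    "ForcingDay",
    "generate_rw_forcing",
    "apply_a1b_transform",
    "build_nutrient_loads",
    "build_emission_scenario",
    "apply_scenario",
]

DAYS_PER_YEAR = 365

#: Forcing variables, in the fixed order used for random-number generation.
FORCING_VARIABLES = (
    "air_temp",      # °C
    "wind",          # m/s at 10 m
    "precip",        # m/day
    "radiation",     # W/m², shortwave
    "discharge",     # m³/day river inflow
    "din_load",      # kg N/day river dissolved inorganic nitrogen load
    "dip_load",      # kg P/day river dissolved inorganic phosphorus load
    "cont_load",     # kg/day river contaminant load
    "air_conc",      # ng/m³ atmospheric gas-phase contaminant concentration
)

#: Variables allowed to take negative values.
_SIGNED = frozenset({"air_temp"})

_DEFAULT_PEAK_DOY = {
    "air_temp": 210,
    "wind": 20,
    "precip": 210,
    "radiation": 172,
    "discharge": 130,
    "din_load": 130,
    "dip_load": 130,
    "cont_load": 130,
    "air_conc": 172,
}


@dataclass(frozen=True)
class VariableClimate:
    """Climatology of one forcing variable in one basin.

    Daily value = ``mean + amplitude·cos(2π(doy − peak_doy)/365) + a_y`` where
    ``a_y ~ N(0, sigma²)`` is one draw per year (AR(0) annual anomalies).
    Non-negative variables are clipped at zero after summation.
    """

    mean: float
    amplitude: float = 0.0
    sigma: float = 0.0
    peak_doy: int = 200

    def validate(self, name: str) -> None:
        if self.amplitude < 0:
            raise ValueError(f"{name}: amplitude must be >= 0, got {self.amplitude}")
        if self.sigma < 0:
            raise ValueError(f"{name}: sigma must be >= 0, got {self.sigma}")
        if name not in _SIGNED and self.mean < 0:
            raise ValueError(f"{name}: mean must be >= 0, got {self.mean}")


@dataclass
class ClimatologyParams:
    """Per-basin climatologies plus the random seed for anomaly draws.

    ``basins`` maps basin name -> {variable name -> :class:`VariableClimate`}.
    Every basin must define every variable in :data:`FORCING_VARIABLES`.
    The same seed always reproduces the identical forcing series.
    """

    basins: dict[str, dict[str, VariableClimate]]
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.basins:
            raise ValueError("climatology must define at least one basin")
        for bname, variables in self.basins.items():
            for var in FORCING_VARIABLES:
                if var not in variables:
                    raise ValueError(f"basin {bname!r} missing climatology for {var!r}")
                variables[var].validate(var)

    @property
    def basin_names(self) -> tuple[str, ...]:
        return tuple(self.basins)


_CLIMATES = ("RW", "a1b")
_NUTRIENTS = ("CL", "IL", "BSAP")
_EMISSIONS = ("current", "red_river", "red_air")


@dataclass
class ScenarioSpec:
    """A (climate, nutrients, emissions) scenario triple.

    Parameters
    ----------
    climate : {"RW", "a1b"}
    nutrients : {"CL", "IL", "BSAP"}
    emissions : {"current", "red_river", "red_air"}
    reduction_year : int
        Calendar year from whose 1 January the emission reduction applies.
    reduction_fraction : float
        Fraction removed (0.9 = a 90 % cut).
    a1b_wind_factor, a1b_temp_factor, a1b_precip_factor : float
        Period-mean multipliers of the a1b transform (defaults 1.07, 1.60,
        1.20).  The temperature factor acts on the °C-scale period mean.
    temperature_mode : {"delta", "scale"}
        How the temperature factor is realized (see module docstring).
    nutrient_target_factor : float or None
        Load multiplier reached at ``nutrient_ramp_end_year``.  Defaults:
        1.5 for IL, 0.6 for BSAP (ignored for CL).
    nutrient_ramp_end_year : int or None
        Year at which the ramp target is reached (defaults 2100 for IL,
        2021 for BSAP); the multiplier is constant afterwards.
    """

    climate: str = "RW"
    nutrients: str = "CL"
    emissions: str = "current"
    reduction_year: int = 2006
    reduction_fraction: float = 0.9
    a1b_wind_factor: float = 1.07
    a1b_temp_factor: float = 1.60
    a1b_precip_factor: float = 1.20
    temperature_mode: str = "delta"
    nutrient_target_factor: float | None = None
    nutrient_ramp_end_year: int | None = None

    def __post_init__(self) -> None:
        if self.climate not in _CLIMATES:
            raise ValueError(f"climate must be one of {_CLIMATES}, got {self.climate!r}")
        if self.nutrients not in _NUTRIENTS:
            raise ValueError(f"nutrients must be one of {_NUTRIENTS}, got {self.nutrients!r}")
        if self.emissions not in _EMISSIONS:
            raise ValueError(f"emissions must be one of {_EMISSIONS}, got {self.emissions!r}")
        if not 0.0 <= self.reduction_fraction <= 1.0:
            raise ValueError("reduction_fraction must be within [0, 1]")
        for name in ("a1b_wind_factor", "a1b_temp_factor", "a1b_precip_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.temperature_mode not in ("delta", "scale"):
            raise ValueError("temperature_mode must be 'delta' or 'scale'")
        if self.nutrient_target_factor is not None and self.nutrient_target_factor < 0:
            raise ValueError("nutrient_target_factor must be >= 0")

    def resolved_nutrient_ramp(self) -> tuple[float, int]:
        """Return (target factor, end year) with scenario defaults filled in."""
        if self.nutrients == "IL":
            return (
                self.nutrient_target_factor if self.nutrient_target_factor is not None else 1.5,
                self.nutrient_ramp_end_year if self.nutrient_ramp_end_year is not None else 2100,
            )
        if self.nutrients == "BSAP":
            return (
                self.nutrient_target_factor if self.nutrient_target_factor is not None else 0.6,
                self.nutrient_ramp_end_year if self.nutrient_ramp_end_year is not None else 2021,
            )
        return (1.0, 0)

    def label(self) -> str:
        return f"{self.climate}{self.nutrients}:{self.emissions}"


@dataclass(frozen=True)
class ForcingDay:
    """One day of forcing; each field is an array over basins."""

    air_temp: np.ndarray
    wind: np.ndarray
    precip: np.ndarray
    radiation: np.ndarray
    discharge: np.ndarray
    din_load: np.ndarray
    dip_load: np.ndarray
    cont_load: np.ndarray
    air_conc: np.ndarray


@dataclass
class ForcingSeries:
    """Uniformly daily-spaced forcing for all basins (365-day calendar).

    ``data`` maps each name in :data:`FORCING_VARIABLES` to an array of shape
    ``(n_days, n_basins)``.  Column order follows ``basins``.
    """

    basins: tuple[str, ...]
    start_year: int
    data: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        n_days = None
        for var in FORCING_VARIABLES:
            if var not in self.data:
                raise ValueError(f"forcing missing variable {var!r}")
            arr = np.asarray(self.data[var], dtype=float)
            if arr.ndim != 2 or arr.shape[1] != len(self.basins):
                raise ValueError(f"{var}: expected shape (n_days, {len(self.basins)})")
            if n_days is None:
                n_days = arr.shape[0]
            elif arr.shape[0] != n_days:
                raise ValueError("all forcing variables must share the same length")
            self.data[var] = arr
        if n_days is None or n_days == 0:
            raise ValueError("forcing series is empty")
        if n_days % DAYS_PER_YEAR:
            raise ValueError("forcing length must be a whole number of 365-day years")
        for var in FORCING_VARIABLES:
            if var in _SIGNED:
                continue
            if np.any(self.data[var] < 0):
                raise ValueError(f"{var}: negative values are not allowed")

    # -- time coordinates ------------------------------------------------
    @property
    def n_days(self) -> int:
        return self.data["air_temp"].shape[0]

    @property
    def n_years(self) -> int:
        return self.n_days // DAYS_PER_YEAR

    @property
    def end_year(self) -> int:
        """Last simulated calendar year (inclusive)."""
        return self.start_year + self.n_years - 1

    @property
    def year(self) -> np.ndarray:
        return self.start_year + np.arange(self.n_days) // DAYS_PER_YEAR

    @property
    def doy(self) -> np.ndarray:
        """Day of year, 1-based."""
        return np.arange(self.n_days) % DAYS_PER_YEAR + 1

    @property
    def frac_year(self) -> np.ndarray:
        return self.year + (self.doy - 0.5) / DAYS_PER_YEAR

    def __getattr__(self, name):
        data = self.__dict__.get("data")
        if data is not None and name in data:
            return data[name]
        raise AttributeError(name)

    def basin_index(self, name: str) -> int:
        try:
            return self.basins.index(name)
        except ValueError:
            raise KeyError(f"unknown basin {name!r}") from None

    def day(self, i: int) -> ForcingDay:
        return ForcingDay(**{var: self.data[var][i] for var in FORCING_VARIABLES})

    def copy(self) -> "ForcingSeries":
        return ForcingSeries(
            basins=self.basins,
            start_year=self.start_year,
            data={var: self.data[var].copy() for var in FORCING_VARIABLES},
        )

    def to_dataframe(self):
        """Tidy long-format DataFrame: date, basin, variable, value."""
        import pandas as pd

        year, doy = self.year, self.doy
        dates = np.array(
            [f"{y:04d}-{m:02d}-{d:02d}" for y, m, d in zip(year, *_month_day(doy))]
        )
        frames = []
        for var in FORCING_VARIABLES:
            for j, b in enumerate(self.basins):
                frames.append(
                    pd.DataFrame(
                        {"date": dates, "basin": b, "variable": var, "value": self.data[var][:, j]}
                    )
                )
        return pd.concat(frames, ignore_index=True)


_MONTH_LENGTHS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
_MONTH_EDGES = np.concatenate([[0], np.cumsum(_MONTH_LENGTHS)])
#: month (1..12) of each 1-based day-of-year in the 365-day calendar
MONTH_OF_DOY = np.searchsorted(_MONTH_EDGES, np.arange(1, DAYS_PER_YEAR + 1), side="left")


def _month_day(doy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    month = MONTH_OF_DOY[doy - 1]
    day = doy - _MONTH_EDGES[month - 1]
    return month, day


def generate_rw_forcing(
    params: ClimatologyParams, start_year: int, n_years: int
) -> ForcingSeries:
    """Generate a "random weather" forcing realization.

    Stationary by construction: each variable is its seasonal sinusoid plus
    one Gaussian annual anomaly per year; non-negative variables are clipped
    at zero.  Identical ``params`` (including seed) yield a bit-identical
    series.
    """
    if n_years < 1:
        raise ValueError(f"n_years must be >= 1, got {n_years}")
    rng = np.random.default_rng(params.seed)
    basins = params.basin_names
    n_days = n_years * DAYS_PER_YEAR
    doy = np.arange(n_days) % DAYS_PER_YEAR + 1
    year_idx = np.arange(n_days) // DAYS_PER_YEAR

    data: dict[str, np.ndarray] = {}
    # draw anomalies in a fixed (variable, basin) order for determinism
    for var in FORCING_VARIABLES:
        out = np.empty((n_days, len(basins)))
        for j, bname in enumerate(basins):
            vc = params.basins[bname][var]
            seasonal = vc.mean + vc.amplitude * np.cos(
                2.0 * np.pi * (doy - vc.peak_doy) / DAYS_PER_YEAR
            )
            anomalies = rng.normal(0.0, vc.sigma, n_years) if vc.sigma > 0 else np.zeros(n_years)
            out[:, j] = seasonal + anomalies[year_idx]
        if var not in _SIGNED:
            np.maximum(out, 0.0, out=out)
        data[var] = out
    return ForcingSeries(basins=basins, start_year=start_year, data=data)


def apply_a1b_transform(base: ForcingSeries, spec: ScenarioSpec) -> ForcingSeries:
    """Apply the a1b warming transform to an RW forcing series.

    Wind and precipitation are multiplied by their factors.  Air temperature
    is shifted additively by ``(temp_factor − 1) ×`` the per-basin realized
    period mean (default mode), or multiplied directly in ``"scale"`` mode.
    Nutrient and contaminant forcing are untouched.
    """
    out = base.copy()
    out.data["wind"] *= spec.a1b_wind_factor
    out.data["precip"] *= spec.a1b_precip_factor
    if spec.temperature_mode == "scale":
        out.data["air_temp"] *= spec.a1b_temp_factor
    else:
        delta = (spec.a1b_temp_factor - 1.0) * base.data["air_temp"].mean(axis=0)
        out.data["air_temp"] += delta
    return out


def _nutrient_multiplier(spec: ScenarioSpec, series: ForcingSeries) -> np.ndarray:
    """Daily load multiplier implied by the nutrient scenario."""
    if spec.nutrients == "CL":
        return np.ones(series.n_days)
    target, end_year = spec.resolved_nutrient_ramp()
    t = series.frac_year
    t0 = float(series.start_year)
    t1 = float(end_year)
    if t1 <= t0:
        # target already reached before the series starts
        return np.full(series.n_days, target)
    frac = np.clip((t - t0) / (t1 - t0), 0.0, 1.0)
    return 1.0 + frac * (target - 1.0)


def build_nutrient_loads(
    spec: ScenarioSpec, base_loads: ForcingSeries, horizon: int | None = None
) -> ForcingSeries:
    """Apply the nutrient-load scenario to the river DIN/DIP loads.

    CL holds loads at the base level; IL ramps them linearly up and BSAP
    linearly down, reaching the target factor at the ramp end year (or after
    ``horizon`` years from the series start, if given) and holding it
    thereafter.  All other forcing fields are untouched.
    """
    if horizon is not None:
        spec = replace(spec, nutrient_ramp_end_year=base_loads.start_year + horizon)
    mult = _nutrient_multiplier(spec, base_loads)[:, None]
    out = base_loads.copy()
    out.data["din_load"] *= mult
    out.data["dip_load"] *= mult
    return out


def build_emission_scenario(spec: ScenarioSpec, base: ForcingSeries) -> ForcingSeries:
    """Apply the emission-control scenario to the contaminant forcing.

    ``red_river`` multiplies the river contaminant load, and ``red_air`` the
    atmospheric concentration, by ``1 − reduction_fraction`` from 1 January of
    ``reduction_year`` onward; ``current`` returns an identical copy.
    """
    out = base.copy()
    if spec.emissions == "current":
        return out
    if not (base.start_year <= spec.reduction_year <= base.end_year):
        raise ValueError(
            f"reduction_year {spec.reduction_year} outside series "
            f"[{base.start_year}, {base.end_year}]"
        )
    after = base.year >= spec.reduction_year
    factor = 1.0 - spec.reduction_fraction
    var = "cont_load" if spec.emissions == "red_river" else "air_conc"
    out.data[var][after] *= factor
    return out


def apply_scenario(spec: ScenarioSpec, base: ForcingSeries) -> ForcingSeries:
    """Compose climate, nutrient, and emission transforms on an RW series."""
    out = base
    if spec.climate == "a1b":
        out = apply_a1b_transform(out, spec)
    out = build_nutrient_loads(spec, out)
    out = build_emission_scenario(spec, out)
    return out
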