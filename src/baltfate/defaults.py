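"""Default study configuration: Baltic-analogue basins, climatology, D5.

Three named basins drain in a chain toward the open boundary: the Bothnian
Bay (cold, oligotrophic, seasonally ice covered), the Gotland Sea (the large
central basin), and the Fehmarn Belt (the small transition basin next to the
boundary).  Numbers are round, literature-plausible magnitudes chosen to give
Baltic-like behaviour — northern seasonal ice, a eutrophic central basin, a
river-dominated contaminant input — not a calibration to any observed data
set.  Everything is configurable; these constructors are convenience
defaults.
"""

from __future__ import annotations

from .biogeo import BiogeoParams
from .contaminant import ChemicalProperties, ProcessParams, d5_properties
from .hydro import Basin, BasinGeometry, HeatIceParams
from .scenarios import ClimatologyParams, VariableClimate

__all__ = [
    "baltic_geometry",
    "baltic_climatology",
    "single_box_geometry",
    "constant_climatology",
    "d5_properties",
]

BOTHNIAN_BAY = "bothnian_bay"
GOTLAND_SEA = "gotland_sea"
FEHMARN_BELT = "fehmarn_belt"


def baltic_geometry() -> BasinGeometry:
    """Three-basin Baltic analogue draining through the Fehmarn Belt."""
    return BasinGeometry(
        basins=[
            Basin(
                name=BOTHNIAN_BAY, area=3.6e10, h_surf=20.0, h_deep=20.0,
                downstream=GOTLAND_SEA, deep_inflow=5e7,
                deep_inflow_salinity=4.0, latitude=65.0,
            ),
            Basin(
                name=GOTLAND_SEA, area=2.0e11, h_surf=20.0, h_deep=40.0,
                downstream=FEHMARN_BELT, deep_inflow=8e8,
                deep_inflow_salinity=10.0, latitude=57.0,
            ),
            Basin(
                name=FEHMARN_BELT, area=1.0e10, h_surf=15.0, h_deep=10.0,
                downstream="open", deep_inflow=5e8,
                deep_inflow_salinity=17.0, latitude=54.5,
            ),
        ],
    )


def baltic_climatology(seed: int = 0) -> ClimatologyParams:
    """Seasonal climatology of the three default basins.

    Air temperature in °C, wind m/s, precipitation m/day, shortwave W/m²,
    discharge m³/day, nutrient loads kg/day, river contaminant load kg/day,
    atmospheric contaminant concentration ng/m³.  The contaminant forcing is
    a hypothetical but realistic constant-emission scenario with river loads
    dominating atmospheric absorption.
    """
    v = VariableClimate

    def basin(t_mean, t_amp, wind_mean, rad_mean, rad_amp, q_mean, q_amp,
              din, dip, cont):
        return {
            "air_temp": v(mean=t_mean, amplitude=t_amp, sigma=0.8, peak_doy=210),
            "wind": v(mean=wind_mean, amplitude=1.5, sigma=0.35, peak_doy=20),
            "precip": v(mean=1.6e-3, amplitude=4e-4, sigma=1e-4, peak_doy=210),
            "radiation": v(mean=rad_mean, amplitude=rad_amp, sigma=4.0, peak_doy=172),
            "discharge": v(mean=q_mean, amplitude=q_amp, sigma=0.07 * q_mean, peak_doy=130),
            "din_load": v(mean=din, amplitude=0.3 * din, sigma=0.05 * din, peak_doy=130),
            "dip_load": v(mean=dip, amplitude=0.3 * dip, sigma=0.05 * dip, peak_doy=130),
            "cont_load": v(mean=cont),
            "air_conc": v(mean=1.0),
        }

    return ClimatologyParams(
        basins={
            BOTHNIAN_BAY: basin(3.0, 11.0, 7.0, 80.0, 80.0, 3.0e8, 1.0e8,
                                8.0e4, 1.5e3, 5.0),
            GOTLAND_SEA: basin(7.0, 7.0, 7.5, 115.0, 100.0, 5.5e8, 1.5e8,
                               8.0e5, 4.0e4, 30.0),
            FEHMARN_BELT: basin(9.0, 8.0, 8.0, 120.0, 100.0, 1.0e8, 3.0e7,
                                2.0e5, 8.0e3, 5.0),
        },
        seed=seed,
    )


def single_box_geometry(
    area: float = 1e10,
    h_surf: float = 20.0,
    h_deep: float = 20.0,
    deep_inflow: float = 0.0,
    deep_inflow_salinity: float = 0.0,
    **geometry_kwargs,
) -> BasinGeometry:
    """One basin draining straight to the boundary; handy for oracle tests."""
    return BasinGeometry(
        basins=[Basin(name="box", area=area, h_surf=h_surf, h_deep=h_deep,
                      downstream="open", deep_inflow=deep_inflow,
                      deep_inflow_salinity=deep_inflow_salinity)],
        **geometry_kwargs,
    )


def constant_climatology(
    basins: tuple[str, ...] = ("box",),
    seed: int = 0,
    air_temp: float = 10.0,
    wind: float = 7.0,
    precip: float = 0.0,
    radiation: float = 100.0,
    discharge: float = 1e8,
    din_load: float = 1e5,
    dip_load: float = 5e3,
    cont_load: float = 10.0,
    air_conc: float = 1.0,
) -> ClimatologyParams:
    """Season- and noise-free climatology (every day identical)."""
    v = VariableClimate
    per_basin = {
        "air_temp": v(mean=air_temp),
        "wind": v(mean=wind),
        "precip": v(mean=precip),
        "radiation": v(mean=radiation),
        "discharge": v(mean=discharge),
        "din_load": v(mean=din_load),
        "dip_load": v(mean=dip_load),
        "cont_load": v(mean=cont_load),
        "air_conc": v(mean=air_conc),
    }
    return ClimatologyParams(basins={b: dict(per_basin) for b in basins}, seed=seed)
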