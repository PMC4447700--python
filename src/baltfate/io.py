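"""YAML configuration and CSV/NetCDF output helpers."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml

from .biogeo import BiogeoParams
from .contaminant import ChemicalProperties, ProcessParams
from .engine import SimulationConfig, SimulationOutput
from .hydro import Basin, BasinGeometry, HeatIceParams
from .scenarios import FORCING_VARIABLES, ClimatologyParams, ScenarioSpec, VariableClimate

__all__ = [
    "geometry_to_dict", "geometry_from_dict",
    "climatology_to_dict", "climatology_from_dict",
    "config_to_yaml", "config_from_yaml", "load_config",
    "write_output",
]


def _plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def geometry_to_dict(geom: BasinGeometry) -> dict:
    return {
        "basins": [_plain(b) for b in geom.basins],
        "evap_fraction": geom.evap_fraction,
        "sw_absorption": geom.sw_absorption,
        "boundary_din": geom.boundary_din,
        "boundary_dip": geom.boundary_dip,
        "boundary_doc": geom.boundary_doc,
        "boundary_contaminant": geom.boundary_contaminant,
    }


def geometry_from_dict(d: dict) -> BasinGeometry:
    basins = [Basin(**b) for b in d["basins"]]
    kwargs = {k: v for k, v in d.items() if k != "basins"}
    return BasinGeometry(basins=basins, **kwargs)


def climatology_to_dict(clim: ClimatologyParams) -> dict:
    return {
        "seed": clim.seed,
        "basins": {
            b: {var: _plain(vc) for var, vc in variables.items()}
            for b, variables in clim.basins.items()
        },
    }


def climatology_from_dict(d: dict) -> ClimatologyParams:
    basins = {
        b: {var: VariableClimate(**vc) for var, vc in variables.items()}
        for b, variables in d["basins"].items()
    }
    return ClimatologyParams(basins=basins, seed=d.get("seed", 0))


def config_to_yaml(config: SimulationConfig) -> str:
    doc = {
        "geometry": geometry_to_dict(config.geometry),
        "climatology": climatology_to_dict(config.climatology),
        "chemical": _plain(config.chemical),
        "scenario": _plain(config.scenario),
        "bio_params": _plain(config.bio_params),
        "process_params": _plain(config.process_params),
        "heat_ice": _plain(config.heat_ice),
        "start_year": config.start_year,
        "end_year": config.end_year,
        "seed": config.seed,
        "output_cadence": config.output_cadence,
        "budget_tolerance": config.budget_tolerance,
        "label": config.label,
    }
    # keep insertion order: basin order is meaningful (climatology must
    # match geometry) and the dump doubles as the provenance-hash input
    return yaml.safe_dump(doc, sort_keys=False)


def config_from_yaml(text: str) -> SimulationConfig:
    doc = yaml.safe_load(text)
    kwargs = {}
    if "geometry" in doc:
        kwargs["geometry"] = geometry_from_dict(doc["geometry"])
    if "climatology" in doc:
        kwargs["climatology"] = climatology_from_dict(doc["climatology"])
    if "chemical" in doc:
        kwargs["chemical"] = ChemicalProperties(**doc["chemical"])
    if "scenario" in doc:
        kwargs["scenario"] = ScenarioSpec(**doc["scenario"])
    if "bio_params" in doc:
        kwargs["bio_params"] = BiogeoParams(**doc["bio_params"])
    if "process_params" in doc:
        kwargs["process_params"] = ProcessParams(**doc["process_params"])
    if "heat_ice" in doc:
        kwargs["heat_ice"] = HeatIceParams(**doc["heat_ice"])
    for key in ("start_year", "end_year", "seed", "output_cadence",
                "budget_tolerance", "label"):
        if key in doc and doc[key] is not None:
            kwargs[key] = doc[key]
    return SimulationConfig(**kwargs)


def load_config(path: str | Path) -> SimulationConfig:
    return config_from_yaml(Path(path).read_text())


def write_output(output: SimulationOutput, out_dir: str | Path,
                 cadence: str = "monthly", netcdf: bool = False) -> Path:
    """Write a run to a directory: tidy CSV, budget JSON, provenance JSON.

    With ``netcdf=True`` also writes a (time × basin × variable) NetCDF file
    via xarray's scipy backend if those packages are importable.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = output.to_dataframe(cadence=cadence)
    df.to_csv(out_dir / "timeseries.csv", index=False)
    (out_dir / "budget.json").write_text(
        json.dumps(output.budget_summary(), indent=2))
    (out_dir / "provenance.json").write_text(
        json.dumps(output.provenance, indent=2))
    if netcdf:
        try:
            import xarray as xr
        except ImportError as exc:  # pragma: no cover
            raise RuntimeError("NetCDF export requires xarray (+ scipy)") from exc
        ds = xr.Dataset(
            {var: (("time", "basin"), output.daily[var]) for var in output.daily},
            coords={
                "time": output.frac_year,
                "basin": list(output.basins),
                "year": ("time", output.year),
                "doy": ("time", output.doy),
            },
        )
        ds.to_netcdf(out_dir / "timeseries.nc", engine="scipy")
    return out_dir
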