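"""Daily time-stepping engine, budget accounting and scenario comparison.

The engine composes the forcing/scenario layer, basin physics, the NPD
biogeochemistry and the contaminant mass balance into one daily loop
(operator splitting, fixed order: water/salt → heat/ice → biogeochemistry →
contaminant advection → air–water exchange → transformation → settling/
sediment) and records per-basin time series plus cumulative budgets for
water, salt, nitrogen, phosphorus and the contaminant.  A closure check at
the end of every run aborts on conservation breaches.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np

from . import defaults
from .biogeo import BiogeoParams, BiogeoState, step_biogeo
from .contaminant import (
    NG_L_M3_TO_KG,
    ChemicalProperties,
    ContaminantState,
    MassBudget,
    ProcessParams,
    advect_contaminant,
    air_water_exchange_terms,
    phase_partition,
    settle_and_exchange_sediment,
    transformation_losses,
)
from .hydro import (
    BasinGeometry,
    HeatIceParams,
    PhysicalState,
    salt_boundary_fluxes,
    step_heat_ice,
    step_water_and_salt,
)
from .scenarios import (
    DAYS_PER_YEAR,
    MONTH_OF_DOY,
    ClimatologyParams,
    ForcingSeries,
    ScenarioSpec,
    apply_scenario,
    generate_rw_forcing,
)

__all__ = [
    "SimulationConfig",
    "SimulationOutput",
    "ElementBudget",
    "ConservationError",
    "run_simulation",
    "compare_scenarios",
    "ScenarioComparison",
]

__version__ = "0.1.0"

#: variables recorded daily per basin
OUTPUT_VARIABLES = (
    "c_w",          # dissolved surface concentration, ng/L bulk water
    "c_total_surf", # total surface concentration, ng/L
    "c_total_deep",
    "c_sed",        # sediment concentration, ng/g dw
    "aw_flux",      # net air->water flux density, ng/m²/day
    "ice_frac",
    "t_surf",
    "s_surf",
    "din_s", "dip_s", "phy_s", "det_s", "doc_s", "poc_s",
)


class ConservationError(RuntimeError):
    """A budget failed to close within tolerance; carries the budget dump."""

    def __init__(self, message: str, budgets: dict):
        super().__init__(message)
        self.budgets = budgets


@dataclass
class ElementBudget:
    """Simple conserved-quantity ledger: inventories and boundary terms."""

    name: str
    initial: float = 0.0
    inputs: float = 0.0
    losses: float = 0.0
    final: float = 0.0

    def closure_error(self) -> float:
        residual = self.initial + self.inputs - self.losses - self.final
        scale = max(abs(self.inputs), abs(self.initial), 1e-30)
        return abs(residual) / scale

    def to_dict(self) -> dict:
        return {
            "name": self.name, "initial": self.initial, "inputs": self.inputs,
            "losses": self.losses, "final": self.final,
            "closure_error": self.closure_error(),
        }


@dataclass
class SimulationConfig:
    """Everything needed to reproduce one run.

    ``start_year``/``end_year`` are inclusive calendar years.  ``seed``
    drives the weather realization (runs sharing a seed share weather, the
    paired design used for scenario contrasts).  ``budget_tolerance`` is the
    relative closure tolerance at which a run aborts.  ``leak_fraction`` is a
    test hook that removes contaminant mass without logging it, to exercise
    the conservation abort.
    """

    geometry: BasinGeometry = field(default_factory=defaults.baltic_geometry)
    climatology: ClimatologyParams | None = None
    chemical: ChemicalProperties = field(default_factory=defaults.d5_properties)
    scenario: ScenarioSpec = field(default_factory=ScenarioSpec)
    bio_params: BiogeoParams = field(default_factory=BiogeoParams)
    process_params: ProcessParams = field(default_factory=ProcessParams)
    heat_ice: HeatIceParams = field(default_factory=HeatIceParams)
    start_year: int = 1990
    end_year: int = 2030
    seed: int = 0
    output_cadence: str = "monthly"
    budget_tolerance: float = 1e-3
    check_budget: bool = True
    leak_fraction: float = 0.0
    spinup_bio: BiogeoState | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.end_year <= self.start_year:
            raise ValueError("end_year must be > start_year")
        if self.output_cadence not in ("monthly", "daily"):
            raise ValueError("output_cadence must be 'monthly' or 'daily'")
        if self.climatology is None:
            self.climatology = defaults.baltic_climatology(seed=self.seed)
        if tuple(self.climatology.basin_names) != self.geometry.names:
            raise ValueError(
                "climatology basins must match geometry basins in order: "
                f"{self.climatology.basin_names} vs {self.geometry.names}"
            )

    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year + 1

    def with_scenario(self, scenario: ScenarioSpec, label: str | None = None
                      ) -> "SimulationConfig":
        return replace(self, scenario=scenario, label=label or scenario.label())

    def provenance_hash(self) -> str:
        from .io import config_to_yaml

        return hashlib.sha256(config_to_yaml(self).encode()).hexdigest()[:16]


@dataclass
class SimulationOutput:
    """Recorded run: daily per-basin series, budgets, provenance."""

    basins: tuple[str, ...]
    start_year: int
    year: np.ndarray
    doy: np.ndarray
    daily: dict[str, np.ndarray]
    contaminant_budget: MassBudget
    element_budgets: dict[str, ElementBudget]
    provenance: dict

    @property
    def n_days(self) -> int:
        return len(self.year)

    @property
    def frac_year(self) -> np.ndarray:
        return self.year + (self.doy - 0.5) / DAYS_PER_YEAR

    def basin_index(self, basin: str) -> int:
        try:
            return self.basins.index(basin)
        except ValueError:
            raise KeyError(f"unknown basin {basin!r}") from None

    def series(self, var: str, basin: str) -> np.ndarray:
        return self.daily[var][:, self.basin_index(basin)]

    def monthly_mean(self, var: str):
        """Monthly means as a DataFrame indexed by (year, month)."""
        import pandas as pd

        month = MONTH_OF_DOY[self.doy - 1]
        idx = pd.MultiIndex.from_arrays([self.year, month], names=["year", "month"])
        df = pd.DataFrame(self.daily[var], index=idx, columns=list(self.basins))
        return df.groupby(level=["year", "month"], sort=False).mean()

    def to_dataframe(self, cadence: str | None = None, variables=None):
        """Tidy long table: year, month/doy, basin, variable, value."""
        import pandas as pd

        variables = variables or OUTPUT_VARIABLES
        frames = []
        if (cadence or "monthly") == "monthly":
            for var in variables:
                m = self.monthly_mean(var).reset_index().melt(
                    id_vars=["year", "month"], var_name="basin", value_name="value")
                m["variable"] = var
                frames.append(m)
        else:
            for var in variables:
                for j, b in enumerate(self.basins):
                    frames.append(pd.DataFrame({
                        "year": self.year, "doy": self.doy, "basin": b,
                        "variable": var, "value": self.daily[var][:, j]}))
        return pd.concat(frames, ignore_index=True)

    def annual_ice_days(self, basin: str) -> "np.ndarray":
        """Number of days per year with any ice cover."""
        ice = self.series("ice_frac", basin) > 0
        return ice.reshape(-1, DAYS_PER_YEAR).sum(axis=1)

    def budget_summary(self) -> dict:
        out = {"contaminant": self.contaminant_budget.to_dict()}
        out.update({k: b.to_dict() for k, b in self.element_budgets.items()})
        return out


def _initial_states(config: SimulationConfig):
    geom = config.geometry
    clim = config.climatology
    t0 = np.array([max(clim.basins[b]["air_temp"].mean, 0.0) for b in geom.names])
    phys = PhysicalState.initial(geom, t_surf=t0)
    bio = config.spinup_bio.copy() if config.spinup_bio is not None \
        else BiogeoState.initial(geom)
    cont = ContaminantState.zeros(geom)
    return phys, bio, cont


def build_forcing(config: SimulationConfig) -> ForcingSeries:
    """RW realization for the config's seed with the scenario applied."""
    base = generate_rw_forcing(
        replace_seed(config.climatology, config.seed), config.start_year, config.n_years
    )
    return apply_scenario(config.scenario, base)


def replace_seed(clim: ClimatologyParams, seed: int) -> ClimatologyParams:
    if clim.seed == seed:
        return clim
    return ClimatologyParams(basins=clim.basins, seed=seed)


def run_simulation(config: SimulationConfig) -> SimulationOutput:
    """Run the coupled model from start to end year.

    Deterministic for a given config (the only randomness is the seeded
    weather draw).  Raises :class:`ConservationError` if any budget closure
    exceeds ``config.budget_tolerance``.
    """
    geom = config.geometry
    chem = config.chemical
    bp = config.bio_params
    pp = config.process_params
    forcing = build_forcing(config)
    n_days = forcing.n_days
    nb = geom.n_basins
    dt = 1.0

    phys, bio, cont = _initial_states(config)

    budget = MassBudget(
        initial_water=cont.water_inventory(geom),
        initial_sediment=cont.sediment_inventory(geom),
    )
    water_budget = ElementBudget("water", initial=float(np.sum(geom.v_surf + geom.v_deep)))
    salt_budget = ElementBudget(
        "salt",
        initial=float(np.sum(phys.s_surf * geom.v_surf + phys.s_deep * geom.v_deep)),
    )
    n_budget = ElementBudget("nitrogen", initial=bio.nitrogen_inventory(geom, bp))
    p_budget = ElementBudget("phosphorus", initial=bio.phosphorus_inventory(geom, bp))

    daily = {var: np.empty((n_days, nb)) for var in OUTPUT_VARIABLES}
    fdata = forcing.data
    leak = config.leak_fraction

    for i in range(n_days):
        fday = forcing.day(i)

        # --- physics ---------------------------------------------------
        new_phys, flows = step_water_and_salt(phys, geom, fday, dt)
        # boundary fluxes are accounted at the start-of-step salinity that
        # the advection scheme itself used
        s_in, s_out = salt_boundary_fluxes(phys, geom, flows, dt)
        phys = new_phys
        salt_budget.inputs += s_in
        salt_budget.losses += s_out
        water_budget.inputs += float(np.sum(flows.q_fresh + flows.q_deep) * dt)
        water_budget.losses += float(flows.q_out[geom.boundary_idx] * dt)
        phys = step_heat_ice(phys, geom, fday, dt, config.heat_ice)

        # --- biogeochemistry -------------------------------------------
        bio, bfx = step_biogeo(bio, phys, geom, fday, bp, dt, flows)
        n_budget.inputs += bfx.n_river + bfx.n_boundary_in
        n_budget.losses += bfx.n_boundary_out + bfx.n_burial
        p_budget.inputs += bfx.p_river + bfx.p_boundary_in
        p_budget.losses += bfx.p_boundary_out + bfx.p_burial

        # --- contaminant ------------------------------------------------
        cont, afx = advect_contaminant(cont, geom, flows, fday, dt)
        budget.river_input += afx["river_input"]
        budget.boundary_in += afx["boundary_in"]
        budget.boundary_out += afx["boundary_out"]

        f_diss_s, _, _ = phase_partition(
            cont.c_surf, bio.doc_s * 1e-3, bio.poc_s * 1e-3, chem, phys.t_surf)
        absorption, volatilization = air_water_exchange_terms(
            f_diss_s * cont.c_surf, fday.air_conc, phys.t_surf, fday.wind,
            phys.ice_frac, chem, pp)
        net = (absorption - volatilization) * dt          # ng/m²
        cont.c_surf = cont.c_surf + net * geom.areas / (geom.v_surf * 1e3)
        budget.atmospheric_absorption += float(np.sum(absorption * dt * geom.areas) * 1e-12)
        budget.volatilization += float(np.sum(volatilization * dt * geom.areas) * 1e-12)

        cont, tfx = transformation_losses(cont, phys, bio, geom, chem, dt)
        budget.hydrolysis += tfx["hydrolysis"]
        budget.biodegradation_water += tfx["biodegradation_water"]
        budget.biodegradation_sediment += tfx["biodegradation_sediment"]

        cont, sfx = settle_and_exchange_sediment(cont, phys, bio, geom, chem, bp, pp, dt)
        budget.settling += sfx["settling"]
        budget.resuspension += sfx["resuspension"]
        budget.burial += sfx["burial"]

        if leak:
            # unlogged mass removal: must trip the conservation abort
            cont.c_surf = cont.c_surf * (1.0 - leak)

        # --- record -----------------------------------------------------
        daily["c_w"][i] = f_diss_s * cont.c_surf
        daily["c_total_surf"][i] = cont.c_surf
        daily["c_total_deep"][i] = cont.c_deep
        daily["c_sed"][i] = cont.sed_conc_ng_g(geom)
        daily["aw_flux"][i] = absorption - volatilization
        daily["ice_frac"][i] = phys.ice_frac
        daily["t_surf"][i] = phys.t_surf
        daily["s_surf"][i] = phys.s_surf
        daily["din_s"][i] = bio.din_s
        daily["dip_s"][i] = bio.dip_s
        daily["phy_s"][i] = bio.phy_s
        daily["det_s"][i] = bio.det_s
        daily["doc_s"][i] = bio.doc_s
        daily["poc_s"][i] = bio.poc_s

    budget.water_inventory = cont.water_inventory(geom)
    budget.sediment_inventory = cont.sediment_inventory(geom)
    water_budget.final = float(np.sum(geom.v_surf + geom.v_deep))
    salt_budget.final = float(np.sum(phys.s_surf * geom.v_surf + phys.s_deep * geom.v_deep))
    n_budget.final = bio.nitrogen_inventory(geom, bp)
    p_budget.final = bio.phosphorus_inventory(geom, bp)

    element_budgets = {b.name: b for b in (water_budget, salt_budget, n_budget, p_budget)}
    output = SimulationOutput(
        basins=geom.names,
        start_year=config.start_year,
        year=forcing.year,
        doy=forcing.doy,
        daily=daily,
        contaminant_budget=budget,
        element_budgets=element_budgets,
        provenance={
            "config_hash": config.provenance_hash(),
            "seed": config.seed,
            "version": __version__,
            "label": config.label or config.scenario.label(),
        },
    )

    if config.check_budget:
        errors = {name: b.closure_error() for name, b in element_budgets.items()}
        errors["contaminant"] = budget.closure_error()
        bad = {k: v for k, v in errors.items() if v > config.budget_tolerance}
        if bad:
            raise ConservationError(
                f"budget closure breached tolerance {config.budget_tolerance}: {bad}",
                budgets=output.budget_summary(),
            )
    return output


@dataclass
class ScenarioComparison:
    """Paired scenario runs sharing one weather realization."""

    configs: list[SimulationConfig]
    outputs: list[SimulationOutput]

    @property
    def labels(self) -> list[str]:
        return [o.provenance["label"] for o in self.outputs]

    def cw_ratio(self, basin: str, treated: int = 1, control: int = 0,
                 window: tuple[int, int] | None = None) -> float:
        """Period-mean C_W ratio treated/control over an inclusive year window."""
        o_c, o_t = self.outputs[control], self.outputs[treated]
        mask = np.ones(o_c.n_days, dtype=bool)
        if window is not None:
            mask = (o_c.year >= window[0]) & (o_c.year <= window[1])
        c = o_c.series("c_w", basin)[mask].mean()
        t = o_t.series("c_w", basin)[mask].mean()
        if c == 0:
            raise ZeroDivisionError("control mean concentration is zero")
        return float(t / c)

    def summary_table(self, window: tuple[int, int] | None = None):
        """Per-basin period-mean C_W and ratios to the first (control) run."""
        import pandas as pd

        rows = []
        for basin in self.outputs[0].basins:
            for k, out in enumerate(self.outputs):
                mask = np.ones(out.n_days, dtype=bool)
                if window is not None:
                    mask = (out.year >= window[0]) & (out.year <= window[1])
                mean_cw = float(out.series("c_w", basin)[mask].mean())
                rows.append({
                    "basin": basin,
                    "scenario": self.labels[k],
                    "mean_c_w": mean_cw,
                })
        df = pd.DataFrame(rows)
        control = df.groupby("basin")["mean_c_w"].transform("first")
        df["ratio_to_control"] = df["mean_c_w"] / control
        return df


def compare_scenarios(configs: list[SimulationConfig]) -> ScenarioComparison:
    """Run several scenarios on an identical weather realization.

    All configs must share geometry, chemical, years and seed so that
    differences between runs are purely scenario-driven.
    """
    if len(configs) < 2:
        raise ValueError("need at least two configs to compare")
    ref = configs[0]
    for c in configs[1:]:
        if c.geometry.names != ref.geometry.names:
            raise ValueError("configs must share basin geometry")
        if (c.start_year, c.end_year) != (ref.start_year, ref.end_year):
            raise ValueError("configs must share the simulated time range")
        if c.seed != ref.seed:
            raise ValueError("configs must share the weather seed (paired design)")
    outputs = [run_simulation(c) for c in configs]
    return ScenarioComparison(configs=list(configs), outputs=outputs)
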