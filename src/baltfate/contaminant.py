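"""Dynamic mass balance of a neutral hydrophobic organic chemical.

State: bulk-water total concentration per basin layer (ng/L) and a sediment
active-layer pool (ng/m²).  Within each water parcel the chemical is
instantaneously partitioned among truly dissolved, DOC-bound and POC-bound
phases by equilibrium three-phase partitioning; process kinetics act on the
relevant phases:

* air–water exchange — two-film model on the dissolved phase, blocked
  linearly by sea-ice cover;
* hydrolysis — dissolved phase only (a chemical sorbed to particles is
  protected), Arrhenius temperature correction;
* biodegradation — dissolved + DOC phases in water, whole pool in sediment;
* settling — POC-bound mass sinks with the detritus sinking velocity into the
  sediment, which also resuspends, buries, degrades and exchanges dissolved
  chemical diffusively with the bottom water;
* advection — the total concentration rides the water flows.

Default property values describe decamethylcyclopentasiloxane (D5), a cyclic
volatile methylsiloxane: highly volatile (log K_AW ≈ 3.1), highly hydrophobic
(log K_OW ≈ 8.1), hydrolyzable when dissolved (half-life ~65 d at 25 °C) and
persistent when particle-bound.

All process terms are linear in the contaminant concentration for fixed
physics and biogeochemistry, so scaling every contaminant input scales every
concentration by the same factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import exp, log

import numpy as np

from .hydro import BasinGeometry, Flows, PhysicalState, advect_two_layer
from .biogeo import BiogeoState, BiogeoParams

__all__ = [
    "ChemicalProperties",
    "ProcessParams",
    "ContaminantState",
    "MassBudget",
    "phase_partition",
    "air_water_flux",
    "air_water_exchange_terms",
    "transfer_velocities",
    "transformation_losses",
    "settle_and_exchange_sediment",
    "advect_contaminant",
    "d5_properties",
]

R_GAS = 8.314  # J/mol/K
T_REF = 298.15  # K
LN2 = log(2.0)

#: kg of chemical per (ng/L × m³) of water
NG_L_M3_TO_KG = 1e-9


def _vant_hoff(k_ref: float, du: float, t_celsius) -> np.ndarray:
    """van't Hoff / Arrhenius factor relative to 25 °C.

    ``du`` is the internal energy of the forward transfer into the numerator
    phase (J/mol); returns ``k_ref · exp(du/R · (1/T − 1/T_ref))``.
    """
    t_k = np.asarray(t_celsius, dtype=float) + 273.15
    return k_ref * np.exp(du / R_GAS * (1.0 / t_k - 1.0 / T_REF))


def _arrhenius(k_ref: float, ea: float, t_celsius) -> np.ndarray:
    """Rate constant at T relative to 25 °C: ``k_ref·exp(−Ea/R·(1/T − 1/T_ref))``.

    Positive activation energy gives the usual slower kinetics in cold water.
    """
    t_k = np.asarray(t_celsius, dtype=float) + 273.15
    return k_ref * np.exp(-ea / R_GAS * (1.0 / t_k - 1.0 / T_REF))


@dataclass
class ChemicalProperties:
    """Physical-chemical property card of one neutral organic chemical.

    Partition coefficients are log10 values at 25 °C.  ``du_aw`` is the
    internal energy of *dissolution* (air→water transfer, J/mol): negative
    values give the physically usual lower volatility (lower K_AW) in cold
    water.  ``du_ow`` is the energy of water→organic-phase transfer: negative
    values give stronger sorption in cold water.  Degradation rates are
    first-order (1/day) at 25 °C with Arrhenius activation energies (J/mol).
    If ``log_koc`` is omitted it is estimated from K_OW as
    ``log_koc = log10(0.35) + log_kow``; K_DOC is a fixed fraction of K_OC.
    """

    name: str = "chemical"
    log_kow: float = 6.0
    log_kaw: float = 0.0
    log_koc: float | None = None
    du_aw: float = -30e3
    du_ow: float = -20e3
    hydrolysis_rate_25: float = 0.0
    hydrolysis_ea: float = 90e3
    biodeg_water_25: float = 0.0
    biodeg_water_ea: float = 50e3
    biodeg_sed_25: float = 0.0
    biodeg_sed_ea: float = 50e3
    kdoc_fraction: float = 0.1

    def __post_init__(self) -> None:
        for name in ("hydrolysis_rate_25", "biodeg_water_25", "biodeg_sed_25"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.kdoc_fraction < 0:
            raise ValueError("kdoc_fraction must be >= 0")

    # -- temperature-dependent coefficients -----------------------------
    def kaw(self, t_celsius) -> np.ndarray:
        """Dimensionless air–water partition coefficient at T (°C)."""
        return _vant_hoff(10.0 ** self.log_kaw, self.du_aw, t_celsius)

    def koc(self, t_celsius) -> np.ndarray:
        """Organic-carbon–water partition coefficient, L/kg OC, at T (°C)."""
        log_koc = self.log_koc if self.log_koc is not None else self.log_kow + np.log10(0.35)
        return _vant_hoff(10.0 ** log_koc, -self.du_ow, t_celsius)

    def kdoc(self, t_celsius) -> np.ndarray:
        return self.kdoc_fraction * self.koc(t_celsius)

    def k_hydrolysis(self, t_celsius) -> np.ndarray:
        """Hydrolysis rate in the dissolved phase, 1/day at T (°C)."""
        return _arrhenius(self.hydrolysis_rate_25, self.hydrolysis_ea, t_celsius)

    def k_biodeg_water(self, t_celsius) -> np.ndarray:
        return _arrhenius(self.biodeg_water_25, self.biodeg_water_ea, t_celsius)

    def k_biodeg_sed(self, t_celsius) -> np.ndarray:
        return _arrhenius(self.biodeg_sed_25, self.biodeg_sed_ea, t_celsius)


def d5_properties() -> ChemicalProperties:
    """Default property card for decamethylcyclopentasiloxane (D5)."""
    return ChemicalProperties(
        name="D5",
        log_kow=8.1,
        log_kaw=3.1,
        log_koc=5.2,
        du_aw=-30e3,
        du_ow=-20e3,
        hydrolysis_rate_25=LN2 / 65.0,
        hydrolysis_ea=90e3,
        biodeg_water_25=0.0,
        biodeg_sed_25=LN2 / 1200.0,
    )


@dataclass
class ProcessParams:
    """Environmental process parameters of the contaminant model.

    Two-film transfer velocities (m/s): air-side
    ``k_a = 1e-3·(0.3 + 0.2·u10)`` and water-side ``k_w = 0.17e-6·u10²``
    floored at ``kw_floor``.  Sediment: first-order resuspension and burial
    (1/day) of the active-layer pool and a sediment–water diffusive transfer
    velocity (m/day) acting on the pore-water/dissolved gradient.
    """

    ka_base: float = 0.3e-3
    ka_wind: float = 0.2e-3
    kw_coeff: float = 0.17e-6
    kw_floor: float = 1e-7
    sed_resuspension: float = 1e-4
    sed_burial: float = 5e-5
    sed_diffusion: float = 1e-2

    def __post_init__(self) -> None:
        for name in ("ka_base", "ka_wind", "kw_coeff", "kw_floor",
                     "sed_resuspension", "sed_burial", "sed_diffusion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class ContaminantState:
    """Contaminant pools: bulk-water totals (ng/L) and sediment (ng/m²)."""

    c_surf: np.ndarray
    c_deep: np.ndarray
    sed: np.ndarray

    @classmethod
    def zeros(cls, geom: BasinGeometry) -> "ContaminantState":
        n = geom.n_basins
        return cls(np.zeros(n), np.zeros(n), np.zeros(n))

    def copy(self) -> "ContaminantState":
        return ContaminantState(self.c_surf.copy(), self.c_deep.copy(), self.sed.copy())

    def water_inventory(self, geom: BasinGeometry) -> float:
        """Water-column mass, kg."""
        return float(np.sum(self.c_surf * geom.v_surf + self.c_deep * geom.v_deep) * NG_L_M3_TO_KG)

    def sediment_inventory(self, geom: BasinGeometry) -> float:
        """Sediment mass, kg."""
        return float(np.sum(self.sed * geom.areas) * 1e-12)

    def sed_conc_ng_g(self, geom: BasinGeometry) -> np.ndarray:
        """Sediment concentration, ng/g dry weight."""
        return self.sed / geom.sed_mass_per_area


@dataclass
class MassBudget:
    """Cumulative process fluxes (kg) and inventories for closure checks."""

    initial_water: float = 0.0
    initial_sediment: float = 0.0
    river_input: float = 0.0
    atmospheric_absorption: float = 0.0
    volatilization: float = 0.0
    hydrolysis: float = 0.0
    biodegradation_water: float = 0.0
    biodegradation_sediment: float = 0.0
    settling: float = 0.0
    resuspension: float = 0.0
    burial: float = 0.0
    boundary_in: float = 0.0
    boundary_out: float = 0.0
    water_inventory: float = 0.0
    sediment_inventory: float = 0.0

    @property
    def total_inputs(self) -> float:
        return self.river_input + self.atmospheric_absorption + self.boundary_in

    @property
    def total_losses(self) -> float:
        return (self.volatilization + self.hydrolysis + self.biodegradation_water
                + self.biodegradation_sediment + self.burial + self.boundary_out)

    def closure_error(self) -> float:
        """|initial + inputs − losses − final| relative to cumulative inputs."""
        residual = (self.initial_water + self.initial_sediment + self.total_inputs
                    - self.total_losses
                    - self.water_inventory - self.sediment_inventory)
        scale = max(self.total_inputs, self.initial_water + self.initial_sediment, 1e-30)
        return abs(residual) / scale

    def to_dict(self) -> dict:
        from dataclasses import asdict

        d = asdict(self)
        d["closure_error"] = self.closure_error()
        return d


# ----------------------------------------------------------------------
# phase partitioning
# ----------------------------------------------------------------------

def phase_partition(c_total, doc_mg_l, poc_mg_l, chem: ChemicalProperties, t_celsius):
    """Equilibrium three-phase partitioning of the bulk-water concentration.

    ``doc_mg_l``/``poc_mg_l`` are sorbent concentrations in mg C/L; partition
    coefficients are temperature-corrected.  Returns ``(f_diss, f_doc,
    f_poc)``; the fractions sum to one exactly.
    """
    doc = np.asarray(doc_mg_l, dtype=float)
    poc = np.asarray(poc_mg_l, dtype=float)
    if np.any(doc < 0) or np.any(poc < 0):
        raise ValueError("sorbent concentrations must be >= 0")
    kdoc_term = chem.kdoc(t_celsius) * doc * 1e-6  # mg C/L -> kg C/L
    koc_term = chem.koc(t_celsius) * poc * 1e-6
    denom = 1.0 + kdoc_term + koc_term
    f_diss = 1.0 / denom
    return f_diss, kdoc_term * f_diss, koc_term * f_diss


# ----------------------------------------------------------------------
# air-water exchange
# ----------------------------------------------------------------------

def transfer_velocities(wind, params: ProcessParams | None = None):
    """(k_w, k_a) in m/s from 10-m wind speed."""
    p = params or ProcessParams()
    wind = np.asarray(wind, dtype=float)
    k_w = np.maximum(p.kw_coeff * wind**2, p.kw_floor)
    k_a = p.ka_base + p.ka_wind * wind
    return k_w, k_a


def air_water_exchange_terms(
    c_diss, c_air, t_celsius, wind, ice_fraction,
    chem: ChemicalProperties, params: ProcessParams | None = None,
):
    """Gross absorption and volatilization flux densities, ng/m²/day.

    Two-film model: ``k_OL = (1/k_w + 1/(k_a·K_AW))⁻¹``; both directions are
    scaled by open water ``(1 − ice_fraction)``.  ``c_diss`` in ng/L,
    ``c_air`` in ng/m³.
    """
    ice = np.asarray(ice_fraction, dtype=float)
    if np.any(ice < 0) or np.any(ice > 1):
        raise ValueError("ice_fraction must be within [0, 1]")
    kaw = chem.kaw(t_celsius)
    k_w, k_a = transfer_velocities(wind, params)
    k_ol = 1.0 / (1.0 / k_w + 1.0 / (k_a * kaw))  # m/s
    k_ol_day = k_ol * 86400.0
    open_water = 1.0 - ice
    absorption = k_ol_day * (np.asarray(c_air, float) / kaw) * open_water
    volatilization = k_ol_day * (np.asarray(c_diss, float) * 1e3) * open_water  # ng/L -> ng/m³
    return absorption, volatilization


def air_water_flux(c_diss, c_air, t_celsius, wind, ice_fraction,
                   chem: ChemicalProperties, params: ProcessParams | None = None):
    """Net air→water flux density, ng/m²/day (positive into the water)."""
    absorption, volatilization = air_water_exchange_terms(
        c_diss, c_air, t_celsius, wind, ice_fraction, chem, params)
    return absorption - volatilization


# ----------------------------------------------------------------------
# transformation
# ----------------------------------------------------------------------

def transformation_losses(
    state: ContaminantState,
    phys: PhysicalState,
    bio: BiogeoState,
    geom: BasinGeometry,
    chem: ChemicalProperties,
    dt: float = 1.0,
) -> tuple[ContaminantState, dict[str, float]]:
    """First-order hydrolysis and biodegradation.

    Hydrolysis acts on the dissolved phase only (POC- and DOC-bound mass is
    protected); water biodegradation acts on dissolved + DOC; sediment
    degradation acts on the whole pool.  Rates are Arrhenius-corrected to the
    local water temperature.  Returns the new state and the step's losses
    (kg) keyed ``hydrolysis``, ``biodegradation_water``,
    ``biodegradation_sediment``.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    new = state.copy()
    losses = {"hydrolysis": 0.0, "biodegradation_water": 0.0, "biodegradation_sediment": 0.0}
    for layer, t, vol in (("c_surf", phys.t_surf, geom.v_surf),
                          ("c_deep", phys.t_deep, geom.v_deep)):
        doc = (bio.doc_s if layer == "c_surf" else bio.doc_d) * 1e-3  # mg/m³ -> mg/L
        poc = (bio.poc_s if layer == "c_surf" else bio.poc_d) * 1e-3
        c = getattr(state, layer)
        f_diss, f_doc, _ = phase_partition(c, doc, poc, chem, t)
        hyd = chem.k_hydrolysis(t) * f_diss * c * dt
        bio_w = chem.k_biodeg_water(t) * (f_diss + f_doc) * c * dt
        setattr(new, layer, getattr(new, layer) - hyd - bio_w)
        losses["hydrolysis"] += float(np.sum(hyd * vol) * NG_L_M3_TO_KG)
        losses["biodegradation_water"] += float(np.sum(bio_w * vol) * NG_L_M3_TO_KG)
    sed_deg = chem.k_biodeg_sed(phys.t_deep) * state.sed * dt
    new.sed = new.sed - sed_deg
    losses["biodegradation_sediment"] = float(np.sum(sed_deg * geom.areas) * 1e-12)
    return new, losses


# ----------------------------------------------------------------------
# settling and sediment exchange
# ----------------------------------------------------------------------

def settle_and_exchange_sediment(
    state: ContaminantState,
    phys: PhysicalState,
    bio: BiogeoState,
    geom: BasinGeometry,
    chem: ChemicalProperties,
    bio_params: BiogeoParams,
    params: ProcessParams | None = None,
    dt: float = 1.0,
) -> tuple[ContaminantState, dict[str, float]]:
    """Particle settling, sediment resuspension/burial and diffusive exchange.

    POC-bound mass settles with the detritus sinking velocity surface→deep→
    sediment.  The sediment loses a first-order resuspension flux to the deep
    water and a first-order burial flux (permanent), and exchanges dissolved
    chemical with the bottom water through a diffusive transfer velocity
    acting on the pore-water vs dissolved concentration difference, with the
    pore-water concentration set by K_OC equilibrium with the sediment
    organic-carbon fraction.  Returns the new state and the step's kg fluxes
    keyed ``settling``, ``resuspension``, ``burial`` (``settling`` and
    ``resuspension`` include the diffusive exchange, signed by direction).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    p = params or ProcessParams()
    new = state.copy()

    _, _, f_poc_s = phase_partition(state.c_surf, bio.doc_s * 1e-3, bio.poc_s * 1e-3,
                                    chem, phys.t_surf)
    _, _, f_poc_d = phase_partition(state.c_deep, bio.doc_d * 1e-3, bio.poc_d * 1e-3,
                                    chem, phys.t_deep)
    f_diss_d = phase_partition(state.c_deep, bio.doc_d * 1e-3, bio.poc_d * 1e-3,
                               chem, phys.t_deep)[0]

    w = bio_params.w_s
    settle_s = np.minimum(w / geom.h_surf * dt, 0.9) * f_poc_s * state.c_surf  # ng/L
    settle_d = np.minimum(w / geom.h_deep * dt, 0.9) * f_poc_d * state.c_deep
    new.c_surf = new.c_surf - settle_s
    new.c_deep = new.c_deep + settle_s * geom.v_surf / geom.v_deep - settle_d
    dep = settle_d * geom.h_deep * 1e3  # ng/L × m -> ng/m²
    new.sed = new.sed + dep

    resus = p.sed_resuspension * state.sed * dt        # ng/m²
    bur = p.sed_burial * state.sed * dt
    new.sed = new.sed - resus - bur
    new.c_deep = new.c_deep + resus / (geom.h_deep * 1e3)

    # diffusive sediment-water exchange on the dissolved gradient
    f_oc = bio.sed_oc / geom.sed_mass_per_area  # g C / g dry
    koc = chem.koc(phys.t_deep)
    with np.errstate(divide="ignore", invalid="ignore"):
        c_pw = np.where(f_oc > 0,
                        (state.sed / geom.sed_mass_per_area) * 1e3 / (koc * f_oc),
                        0.0)  # ng/L pore water
    diff = p.sed_diffusion * (c_pw - f_diss_d * state.c_deep) * 1e3 * dt  # ng/m²
    # cap so the sediment pool cannot be overdrawn in one step
    diff = np.clip(diff, -0.5 * geom.h_deep * 1e3 * state.c_deep, 0.5 * state.sed)
    new.sed = new.sed - diff
    new.c_deep = new.c_deep + diff / (geom.h_deep * 1e3)

    to_kg_area = geom.areas * 1e-12
    fluxes = {
        "settling": float(np.sum(dep * to_kg_area)
                          + np.sum(np.where(diff < 0, -diff, 0.0) * to_kg_area)),
        "resuspension": float(np.sum(resus * to_kg_area)
                              + np.sum(np.where(diff > 0, diff, 0.0) * to_kg_area)),
        "burial": float(np.sum(bur * to_kg_area)),
    }
    return new, fluxes


# ----------------------------------------------------------------------
# advection
# ----------------------------------------------------------------------

def advect_contaminant(
    state: ContaminantState,
    geom: BasinGeometry,
    flows: Flows,
    forcing_day=None,
    dt: float = 1.0,
) -> tuple[ContaminantState, dict[str, float]]:
    """Carry the total concentration with the water flows and add river loads.

    River water carries ``forcing_day.cont_load`` (kg/day) into the surface
    layers; the deep boundary inflow carries ``geom.boundary_contaminant``
    (ng/L); the open-boundary surface outflow removes mass permanently.
    Returns the new state and kg fluxes keyed ``river_input``,
    ``boundary_in``, ``boundary_out``.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    new = state.copy()
    c_surf, c_deep, b_in, b_out = advect_two_layer(
        state.c_surf, state.c_deep, flows, geom, dt,
        boundary_conc=geom.boundary_contaminant)
    fluxes = {
        "river_input": 0.0,
        "boundary_in": b_in * NG_L_M3_TO_KG,
        "boundary_out": b_out * NG_L_M3_TO_KG,
    }
    if forcing_day is not None:
        load = np.asarray(forcing_day.cont_load, dtype=float)  # kg/day
        c_surf = c_surf + load * 1e9 * dt / geom.v_surf        # kg -> ng/L×m³
        fluxes["river_input"] = float(np.sum(load) * dt)
    new.c_surf, new.c_deep = c_surf, c_deep
    return new, fluxes
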