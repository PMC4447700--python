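"""Nutrient–phytoplankton–detritus (NPD) dynamics with organic-carbon pools.

A single phytoplankton group grows on dissolved inorganic nitrogen and
phosphorus (Monod kinetics, multiplied by a light term and a Q10 temperature
factor), dies into detritus with a dissolved-organic-carbon exudation side
branch, and detritus remineralizes and sinks through the deep layer into a
sediment organic-carbon pool that mineralizes (returning nutrients to the
bottom water) and buries.  Stoichiometry is fixed Redfield (C:N:P mass).

The purpose of the module is to supply the contaminant model with sorbent
concentrations (POC = phytoplankton C + detritus C, and DOC) that respond to
nutrient loads and temperature; it makes no claim of full Baltic ecology (no
zooplankton, oxygen, silica, or nitrogen fixation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hydro import BasinGeometry, Flows, PhysicalState, advect_two_layer

__all__ = ["BiogeoParams", "BiogeoState", "step_biogeo", "BiogeoFluxes"]


@dataclass
class BiogeoParams:
    """NPD parameters; rates are per day, concentrations mg/m³.

    mu_max/m/r_20 at the 20 °C reference; q10 scales growth and
    mineralization.  Redfield mass ratios default to C:N:P = 41:7.2:1.
    """

    mu_max: float = 1.2            # 1/day at 20 °C
    q10: float = 2.0
    k_n: float = 20.0              # mg N/m³ half-saturation
    k_p: float = 3.0               # mg P/m³ half-saturation
    k_i: float = 40.0              # W/m² light half-saturation
    light_attenuation: float = 0.25  # mean in-layer fraction of surface irradiance
    mortality: float = 0.05        # 1/day at 20 °C, Q10-scaled (overwintering stock)
    r_20: float = 0.03             # detritus mineralization, 1/day at 20 °C
    w_s: float = 1.5               # detritus sinking, m/day
    c_to_n: float = 41.0 / 7.2     # mass C per mass N
    c_to_p: float = 41.0           # mass C per mass P
    doc_exudation: float = 0.1     # fraction of mortality C routed to DOC
    doc_decay: float = 0.002       # 1/day, semi-labile DOC
    river_doc_conc: float = 5000.0 # mg C/m³ in river water
    sed_mineralization: float = 2e-3  # 1/day at 20 °C
    sed_burial: float = 5e-5       # 1/day, permanent loss

    def __post_init__(self) -> None:
        for name in (
            "mu_max", "k_n", "k_p", "k_i", "light_attenuation", "mortality",
            "r_20", "w_s", "doc_exudation", "doc_decay", "river_doc_conc",
            "sed_mineralization", "sed_burial",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.q10 < 1:
            raise ValueError("q10 must be >= 1")

    @property
    def n_to_c(self) -> float:
        return 1.0 / self.c_to_n

    @property
    def p_to_c(self) -> float:
        return 1.0 / self.c_to_p


@dataclass
class BiogeoState:
    """Pools per basin: *_s surface layer, *_d deep layer (mg/m³); sed_oc is
    the sediment organic carbon pool (g C/m²).  POC ≡ phy + det (derived)."""

    din_s: np.ndarray
    din_d: np.ndarray
    dip_s: np.ndarray
    dip_d: np.ndarray
    phy_s: np.ndarray
    phy_d: np.ndarray
    det_s: np.ndarray
    det_d: np.ndarray
    doc_s: np.ndarray
    doc_d: np.ndarray
    sed_oc: np.ndarray

    _FIELDS = ("din_s", "din_d", "dip_s", "dip_d", "phy_s", "phy_d",
               "det_s", "det_d", "doc_s", "doc_d", "sed_oc")

    @classmethod
    def initial(cls, geom: BasinGeometry,
                din: float = 50.0, dip: float = 10.0, phy: float = 20.0,
                det: float = 20.0, doc: float = 500.0, sed_oc: float = 20.0
                ) -> "BiogeoState":
        n = geom.n_basins
        mk = lambda v: np.full(n, float(v))
        return cls(mk(din), mk(din), mk(dip), mk(dip), mk(phy), mk(phy * 0.2),
                   mk(det), mk(det), mk(doc), mk(doc), mk(sed_oc))

    def copy(self) -> "BiogeoState":
        return BiogeoState(*[getattr(self, f).copy() for f in self._FIELDS])

    @property
    def poc_s(self) -> np.ndarray:
        return self.phy_s + self.det_s

    @property
    def poc_d(self) -> np.ndarray:
        return self.phy_d + self.det_d

    def nitrogen_inventory(self, geom: BasinGeometry, params: BiogeoParams) -> float:
        """Total N, kg (water column + sediment)."""
        nc = params.n_to_c
        water = (
            (self.din_s + (self.phy_s + self.det_s) * nc) * geom.v_surf
            + (self.din_d + (self.phy_d + self.det_d) * nc) * geom.v_deep
        ).sum() * 1e-6  # mg -> kg
        sed = (self.sed_oc * nc * geom.areas).sum() * 1e-3  # g -> kg
        return float(water + sed)

    def phosphorus_inventory(self, geom: BasinGeometry, params: BiogeoParams) -> float:
        pc = params.p_to_c
        water = (
            (self.dip_s + (self.phy_s + self.det_s) * pc) * geom.v_surf
            + (self.dip_d + (self.phy_d + self.det_d) * pc) * geom.v_deep
        ).sum() * 1e-6
        sed = (self.sed_oc * pc * geom.areas).sum() * 1e-3
        return float(water + sed)


@dataclass
class BiogeoFluxes:
    """Boundary/permanent fluxes of one step, kg of N and P, for budgets."""

    n_river: float = 0.0
    n_boundary_in: float = 0.0
    n_boundary_out: float = 0.0
    n_burial: float = 0.0
    p_river: float = 0.0
    p_boundary_in: float = 0.0
    p_boundary_out: float = 0.0
    p_burial: float = 0.0


def step_biogeo(
    state: BiogeoState,
    phys: PhysicalState,
    geom: BasinGeometry,
    forcing_day,
    params: BiogeoParams,
    dt: float = 1.0,
    flows: Flows | None = None,
) -> tuple[BiogeoState, BiogeoFluxes]:
    """Advance the biogeochemical pools one step.

    Process order within the step (all tendencies from start-of-step values):
    advection with the day's water flows (if given), river loads, growth,
    mortality/exudation, mineralization, DOC decay, sinking, sediment
    mineralization and burial.  Growth is capped by available nutrients so
    pools stay non-negative at dt = 1 day; N and P are conserved up to the
    returned boundary/burial fluxes.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    p = params
    new = state.copy()
    fx = BiogeoFluxes()
    nc, pc = p.n_to_c, p.p_to_c

    # --- advection of all water-column pools ---------------------------
    if flows is not None:
        for attr, bconc in (
            ("din", geom.boundary_din), ("dip", geom.boundary_dip),
            ("phy", 0.0), ("det", 0.0), ("doc", geom.boundary_doc),
        ):
            cs, cd, b_in, b_out = advect_two_layer(
                getattr(state, attr + "_s"), getattr(state, attr + "_d"),
                flows, geom, dt, boundary_conc=bconc)
            setattr(new, attr + "_s", cs)
            setattr(new, attr + "_d", cd)
            if attr == "din":
                fx.n_boundary_in += b_in * 1e-6
                fx.n_boundary_out += b_out * 1e-6
            elif attr == "dip":
                fx.p_boundary_in += b_in * 1e-6
                fx.p_boundary_out += b_out * 1e-6
            elif attr in ("phy", "det"):
                fx.n_boundary_out += b_out * nc * 1e-6
                fx.p_boundary_out += b_out * pc * 1e-6
            # DOC carries no N or P

    # --- river loads ----------------------------------------------------
    new.din_s = new.din_s + forcing_day.din_load * 1e6 * dt / geom.v_surf  # kg->mg
    new.dip_s = new.dip_s + forcing_day.dip_load * 1e6 * dt / geom.v_surf
    new.doc_s = new.doc_s + forcing_day.discharge * p.river_doc_conc * dt / geom.v_surf
    fx.n_river = float(np.sum(forcing_day.din_load) * dt)
    fx.p_river = float(np.sum(forcing_day.dip_load) * dt)

    # --- growth (surface layer only; light does not reach the deep layer)
    tfac_s = p.q10 ** ((phys.t_surf - 20.0) / 10.0)
    # ice (plus its snow cover) cuts the light reaching the water column
    irradiance = p.light_attenuation * forcing_day.radiation * (1.0 - phys.ice_frac)
    light_lim = np.where(irradiance + p.k_i > 0, irradiance / (irradiance + p.k_i), 0.0)
    nut_lim = np.minimum(
        np.where(state.din_s + p.k_n > 0, state.din_s / (state.din_s + p.k_n), 0.0),
        np.where(state.dip_s + p.k_p > 0, state.dip_s / (state.dip_s + p.k_p), 0.0),
    )
    growth = p.mu_max * tfac_s * light_lim * nut_lim * state.phy_s * dt
    # cap so nutrient pools cannot go negative within one step
    growth = np.minimum(growth, 0.9 * new.din_s / nc)
    growth = np.minimum(growth, 0.9 * new.dip_s / pc)
    growth = np.maximum(growth, 0.0)
    new.phy_s = new.phy_s + growth
    new.din_s = new.din_s - growth * nc
    new.dip_s = new.dip_s - growth * pc

    # --- mortality: detritus + DOC exudation (N, P of the exuded share
    # are returned directly to the inorganic pools so DOC carries C only)
    for layer, t_layer in (("s", phys.t_surf), ("d", phys.t_deep)):
        phy = getattr(state, f"phy_{layer}")
        mort = p.mortality * p.q10 ** ((t_layer - 20.0) / 10.0) * phy * dt
        setattr(new, f"phy_{layer}", getattr(new, f"phy_{layer}") - mort)
        setattr(new, f"det_{layer}", getattr(new, f"det_{layer}") + (1 - p.doc_exudation) * mort)
        setattr(new, f"doc_{layer}", getattr(new, f"doc_{layer}") + p.doc_exudation * mort)
        setattr(new, f"din_{layer}", getattr(new, f"din_{layer}") + p.doc_exudation * mort * nc)
        setattr(new, f"dip_{layer}", getattr(new, f"dip_{layer}") + p.doc_exudation * mort * pc)

    # --- detritus mineralization and DOC decay --------------------------
    for layer, t in (("s", phys.t_surf), ("d", phys.t_deep)):
        tfac = p.q10 ** ((t - 20.0) / 10.0)
        miner = np.minimum(p.r_20 * tfac * dt, 0.9) * getattr(state, f"det_{layer}")
        setattr(new, f"det_{layer}", getattr(new, f"det_{layer}") - miner)
        setattr(new, f"din_{layer}", getattr(new, f"din_{layer}") + miner * nc)
        setattr(new, f"dip_{layer}", getattr(new, f"dip_{layer}") + miner * pc)
        decay = np.minimum(p.doc_decay * dt, 0.9) * getattr(state, f"doc_{layer}")
        setattr(new, f"doc_{layer}", getattr(new, f"doc_{layer}") - decay)

    # --- sinking: surface det -> deep det -> sediment OC ----------------
    sink_s = np.minimum(p.w_s / geom.h_surf * dt, 0.9) * state.det_s   # mg/m³
    sink_d = np.minimum(p.w_s / geom.h_deep * dt, 0.9) * state.det_d
    new.det_s = new.det_s - sink_s
    new.det_d = new.det_d + sink_s * geom.v_surf / geom.v_deep - sink_d
    new.sed_oc = new.sed_oc + sink_d * geom.h_deep * 1e-3               # mg/m² -> g/m²

    # --- sediment mineralization (to bottom water) and burial -----------
    tfac_d = p.q10 ** ((phys.t_deep - 20.0) / 10.0)
    sed_min = np.minimum(p.sed_mineralization * tfac_d * dt, 0.9) * state.sed_oc  # g C/m²
    sed_bur = np.minimum(p.sed_burial * dt, 0.9) * state.sed_oc
    new.sed_oc = new.sed_oc - sed_min - sed_bur
    new.din_d = new.din_d + sed_min * nc * 1e3 / geom.h_deep            # g/m² -> mg/m³
    new.dip_d = new.dip_d + sed_min * pc * 1e3 / geom.h_deep
    fx.n_burial = float(np.sum(sed_bur * nc * geom.areas) * 1e-3)       # g -> kg
    fx.p_burial = float(np.sum(sed_bur * pc * geom.areas) * 1e-3)

    for f in BiogeoState._FIELDS:
        if np.any(getattr(new, f) < 0):
            raise RuntimeError(
                f"biogeo pool {f} went negative; reduce dt or rate parameters"
            )
    return new, fx
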