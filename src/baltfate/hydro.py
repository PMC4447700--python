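"""Simplified basin physics: water and salt balances, surface heat, sea ice.

Each basin is two fixed-volume layers (rigid lid).  Freshwater (rivers plus
net precipitation) and a parameterized deep salty inflow enter each basin; the
deep inflow is entrained upward into the surface layer and the total surplus
leaves as surface outflow along a chain of basins draining to a single open
boundary.  Surface temperature relaxes toward air temperature with a shortwave
heating term; ice is a freezing-degree-day (FDD) model: once the surface water
is at its salinity-dependent freezing point, air-temperature deficit days
accumulate FDD and the ice fraction is min(1, FDD/FDD_full); warming melts the
FDD reservoir before the water warms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Basin",
    "BasinGeometry",
    "PhysicalState",
    "Flows",
    "freezing_point",
    "step_water_and_salt",
    "step_heat_ice",
    "advect_two_layer",
    "NumericalStabilityError",
]

OPEN_BOUNDARY = "open"


class NumericalStabilityError(RuntimeError):
    """Raised when a step produces an unphysical state; reduce dt."""


def freezing_point(salinity):
    """Freezing point of seawater, °C (linearized): T_f = −0.054·S."""
    return -0.054 * np.asarray(salinity, dtype=float)


@dataclass
class Basin:
    """Static geometry of one basin.

    Areas in m², thicknesses in m, deep inflow in m³/day with its salinity in
    PSU.  ``downstream`` names the basin receiving this basin's surface
    outflow, or ``"open"`` for the boundary basin.  Sediment active layer:
    thickness (m) and dry bulk density (kg dry matter/m³).
    """

    name: str
    area: float
    h_surf: float
    h_deep: float
    downstream: str = OPEN_BOUNDARY
    deep_inflow: float = 0.0
    deep_inflow_salinity: float = 0.0
    latitude: float = 58.0
    sed_thickness: float = 0.02
    sed_density: float = 250.0

    def __post_init__(self) -> None:
        for attr in ("area", "h_surf", "h_deep", "sed_thickness", "sed_density"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"basin {self.name!r}: {attr} must be > 0")
        if self.deep_inflow < 0 or self.deep_inflow_salinity < 0:
            raise ValueError(f"basin {self.name!r}: deep inflow/salinity must be >= 0")

    @property
    def v_surf(self) -> float:
        return self.area * self.h_surf

    @property
    def v_deep(self) -> float:
        return self.area * self.h_deep


@dataclass
class BasinGeometry:
    """Connected set of basins draining to one open boundary.

    ``boundary_*`` are the concentrations carried by the deep inflow water
    (DIN/DIP/DOC in mg/m³, contaminant in ng/L).  ``evap_fraction`` gives
    evaporation as a fixed fraction of precipitation; ``sw_absorption`` is the
    fraction of shortwave radiation absorbed in the surface layer.
    """

    basins: list[Basin]
    evap_fraction: float = 0.8
    sw_absorption: float = 0.5
    boundary_din: float = 40.0
    boundary_dip: float = 20.0
    boundary_doc: float = 300.0
    boundary_contaminant: float = 0.0

    def __post_init__(self) -> None:
        names = [b.name for b in self.basins]
        if len(set(names)) != len(names):
            raise ValueError("duplicate basin names")
        open_basins = [b.name for b in self.basins if b.downstream == OPEN_BOUNDARY]
        if len(open_basins) != 1:
            raise ValueError("exactly one basin must drain to the open boundary")
        if not 0.0 <= self.evap_fraction <= 1.0:
            raise ValueError("evap_fraction must be within [0, 1]")
        index = {n: i for i, n in enumerate(names)}
        # downstream index, -1 for the open boundary; check connectivity/acyclicity
        self._downstream_idx = np.empty(len(names), dtype=int)
        for i, b in enumerate(self.basins):
            if b.downstream == OPEN_BOUNDARY:
                self._downstream_idx[i] = -1
            elif b.downstream in index:
                self._downstream_idx[i] = index[b.downstream]
            else:
                raise ValueError(f"basin {b.name!r} drains to unknown basin {b.downstream!r}")
        order = []
        for i in range(len(names)):
            seen, j = set(), i
            while j != -1:
                if j in seen:
                    raise ValueError("basin connection graph contains a cycle")
                seen.add(j)
                j = self._downstream_idx[j]
        # topological order: upstream basins before their downstream receivers
        depth = np.zeros(len(names), dtype=int)
        for i in range(len(names)):
            j, d = i, 0
            while self._downstream_idx[j] != -1:
                j = self._downstream_idx[j]
                d += 1
            depth[i] = d
        self._topo_order = np.argsort(-depth, kind="stable")
        self._index = index
        self.areas = np.array([b.area for b in self.basins])
        self.h_surf = np.array([b.h_surf for b in self.basins])
        self.h_deep = np.array([b.h_deep for b in self.basins])
        self.v_surf = self.areas * self.h_surf
        self.v_deep = self.areas * self.h_deep
        self.q_deep = np.array([b.deep_inflow for b in self.basins])
        self.s_deep_in = np.array([b.deep_inflow_salinity for b in self.basins])
        self.sed_mass_per_area = np.array(
            [b.sed_thickness * b.sed_density * 1e3 for b in self.basins]
        )  # g dry matter per m²

    @property
    def n_basins(self) -> int:
        return len(self.basins)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.basins)

    @property
    def downstream_idx(self) -> np.ndarray:
        return self._downstream_idx

    @property
    def topo_order(self) -> np.ndarray:
        return self._topo_order

    @property
    def boundary_idx(self) -> int:
        return int(np.where(self._downstream_idx == -1)[0][0])

    def index(self, name: str) -> int:
        return self._index[name]


@dataclass
class PhysicalState:
    """Physical state arrays over basins: temperatures (°C), salinities
    (PSU), ice fraction (0–1) and the freezing-degree-day reservoir (°C·day).
    """

    t_surf: np.ndarray
    t_deep: np.ndarray
    s_surf: np.ndarray
    s_deep: np.ndarray
    ice_frac: np.ndarray
    fdd: np.ndarray

    @classmethod
    def initial(
        cls,
        geom: BasinGeometry,
        t_surf: float | np.ndarray = 5.0,
        s_surf: float | np.ndarray | None = None,
    ) -> "PhysicalState":
        n = geom.n_basins
        if s_surf is None:
            s_surf = 0.5 * geom.s_deep_in
        return cls(
            t_surf=np.broadcast_to(np.asarray(t_surf, float), (n,)).copy(),
            t_deep=np.broadcast_to(np.asarray(t_surf, float), (n,)).copy(),
            s_surf=np.broadcast_to(np.asarray(s_surf, float), (n,)).copy(),
            s_deep=geom.s_deep_in.astype(float).copy(),
            ice_frac=np.zeros(n),
            fdd=np.zeros(n),
        )

    def copy(self) -> "PhysicalState":
        return PhysicalState(
            self.t_surf.copy(), self.t_deep.copy(), self.s_surf.copy(),
            self.s_deep.copy(), self.ice_frac.copy(), self.fdd.copy(),
        )


@dataclass(frozen=True)
class Flows:
    """Water flows of one daily step (m³/day).

    ``q_fresh``: river + net precipitation input per basin; ``q_deep``: deep
    boundary inflow (equal to the upward entrainment); ``q_out``: surface
    outflow toward the downstream basin (or the open sea for the boundary
    basin).  Rigid lid: q_out = q_fresh + q_deep + upstream inflows exactly.
    """

    q_fresh: np.ndarray
    q_deep: np.ndarray
    q_out: np.ndarray


def compute_flows(geom: BasinGeometry, forcing_day) -> Flows:
    net_precip = (1.0 - geom.evap_fraction) * forcing_day.precip * geom.areas
    q_fresh = forcing_day.discharge + net_precip
    q_out = np.zeros(geom.n_basins)
    local = q_fresh + geom.q_deep
    for i in geom.topo_order:
        q_out[i] += local[i]
        j = geom.downstream_idx[i]
        if j >= 0:
            q_out[j] += q_out[i]
    return Flows(q_fresh=q_fresh, q_deep=geom.q_deep.copy(), q_out=q_out)


def advect_two_layer(
    c_surf: np.ndarray,
    c_deep: np.ndarray,
    flows: Flows,
    geom: BasinGeometry,
    dt: float,
    boundary_conc: float = 0.0,
):
    """Advect a well-mixed tracer with the daily water flows (explicit, using
    start-of-step concentrations, hence exactly conservative).

    Deep inflow carries ``boundary_conc``; entrainment lifts deep water into
    the surface layer; surface outflow follows the basin chain and leaves the
    system at the open boundary.

    Returns ``(c_surf_new, c_deep_new, boundary_in, boundary_out)`` where the
    boundary terms are tracer masses (conc unit × m³) for budget accounting.
    """
    q_entrain = flows.q_deep
    # upstream surface inflows
    inflow = np.zeros_like(c_surf)
    np.add.at(inflow, geom.downstream_idx[geom.downstream_idx >= 0],
              (flows.q_out * c_surf)[geom.downstream_idx >= 0])
    d_surf = q_entrain * c_deep + inflow - flows.q_out * c_surf
    d_deep = flows.q_deep * boundary_conc - q_entrain * c_deep
    c_surf_new = c_surf + dt * d_surf / geom.v_surf
    c_deep_new = c_deep + dt * d_deep / geom.v_deep
    boundary_in = float(np.sum(flows.q_deep) * boundary_conc * dt)
    b = geom.boundary_idx
    boundary_out = float(flows.q_out[b] * c_surf[b] * dt)
    return c_surf_new, c_deep_new, boundary_in, boundary_out


def step_water_and_salt(
    state: PhysicalState, geom: BasinGeometry, forcing_day, dt: float = 1.0
) -> tuple[PhysicalState, Flows]:
    """Advance salinity one step and return the day's water flows.

    Volumes are conserved exactly (rigid lid: outflow balances all inputs);
    salt is conserved globally except for the declared boundary fluxes (deep
    salty inflow in, surface outflow at the open boundary out).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    flows = compute_flows(geom, forcing_day)
    new = state.copy()
    s_surf, _, _, _ = advect_two_layer(state.s_surf, state.s_deep, flows, geom, dt)
    # deep layer receives the configured inflow salinity, not a shared scalar
    d_deep = flows.q_deep * (geom.s_deep_in - state.s_deep)
    s_deep = state.s_deep + dt * d_deep / geom.v_deep
    if np.any(s_surf < 0) or np.any(s_deep < 0):
        raise NumericalStabilityError(
            "negative salinity produced; reduce dt or check flow magnitudes"
        )
    new.s_surf, new.s_deep = s_surf, s_deep
    return new, flows


def salt_boundary_fluxes(state: PhysicalState, geom: BasinGeometry, flows: Flows, dt: float):
    """(salt in, salt out) across the boundary for one step, PSU·m³."""
    salt_in = float(np.sum(flows.q_deep * geom.s_deep_in) * dt)
    b = geom.boundary_idx
    salt_out = float(flows.q_out[b] * state.s_surf[b] * dt)
    return salt_in, salt_out


@dataclass
class HeatIceParams:
    """Degree-day ice model and relaxation constants.

    tau_surf/tau_deep: relaxation times (days) of surface temperature toward
    air temperature and deep toward surface.  fdd_full: freezing-degree-day
    sum at which the ice fraction reaches 1 (°C·day); the reservoir saturates
    at fdd_cap (ice thickness does not grow indefinitely).  melt_factor
    scales the melting efficiency of positive degree days relative to the
    freezing efficiency of negative ones: spring melt is driven largely by
    shortwave absorption that the air-temperature surplus alone understates,
    so degree-day ice models conventionally use a larger melt coefficient.
    """

    tau_surf: float = 14.0
    tau_deep: float = 120.0
    fdd_full: float = 100.0
    fdd_cap: float = 150.0
    melt_factor: float = 4.0
    enable_ice: bool = True

    def __post_init__(self) -> None:
        if min(self.tau_surf, self.tau_deep, self.fdd_full, self.fdd_cap,
               self.melt_factor) <= 0:
            raise ValueError("heat/ice parameters must be > 0")


def step_heat_ice(
    state: PhysicalState,
    geom: BasinGeometry,
    forcing_day,
    dt: float = 1.0,
    params: HeatIceParams | None = None,
) -> PhysicalState:
    """Advance temperatures and ice one step.

    Surface water relaxes toward air temperature (plus absorbed shortwave
    heating) but cannot cool below the freezing point; while the water sits at
    the freezing point, air-temperature deficit accumulates the FDD reservoir
    (ice grows) and air-temperature surplus depletes it (ice melts before the
    water warms).  Ice fraction = min(1, FDD/FDD_full).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    p = params or HeatIceParams()
    new = state.copy()
    tf = freezing_point(state.s_surf)
    # heat capacity of the surface layer: °C/day per W/m²
    rho_cp = 4.186e6  # J/m³/K
    heating = geom.sw_absorption * forcing_day.radiation * 86400.0 / (rho_cp * geom.h_surf)
    t_pot = state.t_surf + dt * ((forcing_day.air_temp - state.t_surf) / p.tau_surf + heating)

    if p.enable_ice:
        at_freezing = (state.fdd > 0) | (t_pot <= tf)
        freezing_air = forcing_day.air_temp < tf
        grow = dt * np.where(at_freezing & freezing_air, tf - forcing_day.air_temp, 0.0)
        melt = dt * p.melt_factor * np.where(
            (state.fdd > 0) & ~freezing_air, forcing_day.air_temp - tf, 0.0)
        fdd = np.clip(state.fdd + grow - melt, 0.0, p.fdd_cap)
        new.fdd = fdd
        new.ice_frac = np.minimum(fdd / p.fdd_full, 1.0)
        new.t_surf = np.where(fdd > 0, tf, np.maximum(t_pot, tf))
    else:
        new.fdd = np.zeros_like(state.fdd)
        new.ice_frac = np.zeros_like(state.ice_frac)
        new.t_surf = np.maximum(t_pot, tf)

    new.t_deep = state.t_deep + dt * (new.t_surf - state.t_deep) / p.tau_deep
    return new
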