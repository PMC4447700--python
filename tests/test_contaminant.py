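"""Partitioning, air-water exchange, transformation, settling, advection."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from baltfate.biogeo import BiogeoParams, BiogeoState
from baltfate.contaminant import (
    ChemicalProperties,
    ContaminantState,
    ProcessParams,
    advect_contaminant,
    air_water_flux,
    d5_properties,
    phase_partition,
    settle_and_exchange_sediment,
    transfer_velocities,
    transformation_losses,
)
from baltfate.defaults import constant_climatology, single_box_geometry
from baltfate.hydro import PhysicalState, compute_flows
from baltfate.scenarios import generate_rw_forcing


def _chem_no_tcorr(**kw):
    """Chemical with temperature corrections switched off for arithmetic checks."""
    defaults = dict(du_aw=0.0, du_ow=0.0)
    defaults.update(kw)
    return ChemicalProperties(**defaults)


class TestPhasePartition:
    def test_no_sorbents_all_dissolved(self):
        f_diss, f_doc, f_poc = phase_partition(1.0, 0.0, 0.0, d5_properties(), 10.0)
        assert f_diss == 1.0 and f_doc == 0.0 and f_poc == 0.0

    def test_known_single_sorbent_fraction(self):
        # K_OC = 1e5 L/kg with 1 mg C/L POC gives K_OC·POC = 0.1
        chem = _chem_no_tcorr(log_koc=5.0, kdoc_fraction=0.0)
        f_diss, f_doc, f_poc = phase_partition(1.0, 0.0, 1.0, chem, 25.0)
        assert f_diss == pytest.approx(1.0 / 1.1, rel=1e-12)
        assert f_poc == pytest.approx(0.1 / 1.1, rel=1e-12)
        assert f_doc == 0.0

    def test_stronger_sorption_strictly_lowers_dissolved_fraction(self):
        weak = _chem_no_tcorr(log_koc=5.0)
        strong = _chem_no_tcorr(log_koc=5.0 + np.log10(2.0))
        f_weak = phase_partition(1.0, 0.0, 0.5, weak, 10.0)[0]
        f_strong = phase_partition(1.0, 0.0, 0.5, strong, 10.0)[0]
        assert f_strong < f_weak

    def test_cold_water_sorbs_more(self):
        # negative transfer energy: K_OC rises as temperature falls
        chem = d5_properties()
        assert phase_partition(1.0, 0.0, 1.0, chem, 0.0)[0] < \
            phase_partition(1.0, 0.0, 1.0, chem, 25.0)[0]

    def test_negative_sorbent_rejected(self):
        with pytest.raises(ValueError):
            phase_partition(1.0, -0.1, 0.0, d5_properties(), 10.0)

    @given(doc=st.floats(0.0, 50.0), poc=st.floats(0.0, 50.0),
           t=st.floats(-1.0, 30.0))
    def test_fractions_sum_to_one_and_stay_bounded(self, doc, poc, t):
        f = phase_partition(1.0, doc, poc, d5_properties(), t)
        assert sum(f) == pytest.approx(1.0, abs=1e-12)
        assert all(0.0 <= x <= 1.0 for x in f)


class TestAirWaterExchange:
    def test_full_ice_blocks_any_flux(self):
        flux = air_water_flux(5.0, 100.0, 2.0, 10.0, 1.0, d5_properties())
        assert flux == 0.0

    def test_equilibrium_means_zero_flux(self):
        chem = _chem_no_tcorr(log_kaw=np.log10(2.0))
        c_air = 500.0  # ng/m³ ; equilibrium C_diss = c_air/K_AW in ng/m³
        c_diss = c_air / 2.0 / 1e3  # ng/L
        flux = air_water_flux(c_diss, c_air, 25.0, 5.0, 0.0, chem)
        assert flux == pytest.approx(0.0, abs=1e-12)

    def test_two_film_series_resistance_arithmetic(self):
        # k_w = 1e-5, k_a = 1e-3 m/s, K_AW = 2 -> k_OL = 1/(1e5 + 500) m/s
        chem = _chem_no_tcorr(log_kaw=np.log10(2.0))
        params = ProcessParams(kw_coeff=0.0, kw_floor=1e-5, ka_base=1e-3, ka_wind=0.0)
        k_ol_expected = 1.0 / (1e5 + 500.0)
        assert k_ol_expected == pytest.approx(9.95e-6, rel=1e-3)
        # gradient of 1 ng/L dissolved against clean air
        flux = air_water_flux(1.0, 0.0, 25.0, 0.0, 0.0, chem, params)
        assert flux == pytest.approx(-k_ol_expected * 86400.0 * 1e3, rel=1e-12)

    def test_ice_scales_flux_linearly(self):
        args = (5.0, 10.0, 2.0, 8.0)
        chem = d5_properties()
        full = air_water_flux(*args, 0.0, chem)
        half = air_water_flux(*args, 0.5, chem)
        assert half == pytest.approx(0.5 * full, rel=1e-12)

    def test_invalid_ice_fraction_rejected(self):
        with pytest.raises(ValueError):
            air_water_flux(1.0, 1.0, 5.0, 5.0, 1.5, d5_properties())

    def test_wind_speeds_up_both_film_velocities(self):
        k_w_lo, k_a_lo = transfer_velocities(2.0)
        k_w_hi, k_a_hi = transfer_velocities(12.0)
        assert k_w_hi > k_w_lo and k_a_hi > k_a_lo

    def test_cold_water_holds_chemical_better(self):
        # lower K_AW in cold water -> weaker volatilization drive
        chem = d5_properties()
        assert chem.kaw(0.0) < chem.kaw(25.0)


def _bare_bio(geom, doc=0.0, phy=0.0, det=0.0, sed_oc=0.0):
    return BiogeoState.initial(geom, din=0.0, dip=0.0, phy=phy, det=det,
                               doc=doc, sed_oc=sed_oc)


class TestTransformation:
    def test_zero_rates_leave_state_unchanged(self):
        geom = single_box_geometry()
        chem = ChemicalProperties()  # all rates default to zero
        state = ContaminantState(np.array([3.0]), np.array([1.0]), np.array([50.0]))
        phys = PhysicalState.initial(geom, t_surf=10.0)
        new, losses = transformation_losses(state, phys, _bare_bio(geom), geom, chem)
        np.testing.assert_array_equal(new.c_surf, state.c_surf)
        np.testing.assert_array_equal(new.sed, state.sed)
        assert all(v == 0.0 for v in losses.values())

    def test_dissolved_chemical_decays_exponentially(self):
        geom = single_box_geometry()
        k = 0.002
        chem = _chem_no_tcorr(hydrolysis_rate_25=k, hydrolysis_ea=0.0)
        state = ContaminantState(np.array([10.0]), np.array([0.0]), np.array([0.0]))
        phys = PhysicalState.initial(geom, t_surf=25.0)
        bio = _bare_bio(geom)
        n = 300
        for _ in range(n):
            state, _ = transformation_losses(state, phys, bio, geom, chem)
        assert state.c_surf[0] == pytest.approx(10.0 * np.exp(-k * n), rel=2e-3)

    def test_particle_bound_mass_protected_from_hydrolysis(self):
        # with half the chemical on particles the hydrolysis loss halves
        geom = single_box_geometry()
        chem = _chem_no_tcorr(log_koc=5.0, kdoc_fraction=0.0,
                              hydrolysis_rate_25=0.01, hydrolysis_ea=0.0)
        phys = PhysicalState.initial(geom, t_surf=25.0)
        # K_OC·POC = 1  ->  f_poc = 0.5
        bio_sorbed = _bare_bio(geom, det=10.0 * 1e3)  # 10 mg C/L
        f_poc = phase_partition(1.0, 0.0, 10.0, chem, 25.0)[2]
        assert f_poc == pytest.approx(0.5, rel=1e-12)

        free = ContaminantState(np.array([1.0]), np.array([0.0]), np.array([0.0]))
        sorbed = free.copy()
        _, loss_free = transformation_losses(free, phys, _bare_bio(geom), geom, chem)
        _, loss_sorbed = transformation_losses(sorbed, phys, bio_sorbed, geom, chem)
        assert loss_sorbed["hydrolysis"] == pytest.approx(
            0.5 * loss_free["hydrolysis"], rel=1e-12)


class TestSedimentExchange:
    def test_no_particles_no_settling(self):
        geom = single_box_geometry()
        state = ContaminantState(np.array([5.0]), np.array([5.0]), np.array([0.0]))
        phys = PhysicalState.initial(geom, t_surf=10.0)
        params = ProcessParams(sed_resuspension=0.0, sed_diffusion=0.0)
        new, fluxes = settle_and_exchange_sediment(
            state, phys, _bare_bio(geom), geom, d5_properties(), BiogeoParams(), params)
        assert fluxes["settling"] == 0.0
        np.testing.assert_array_equal(new.sed, state.sed)

    def test_deposition_only_bookkeeping_identity(self):
        geom = single_box_geometry()
        phys = PhysicalState.initial(geom, t_surf=10.0)
        bio = _bare_bio(geom, det=200.0)
        params = ProcessParams(sed_resuspension=0.0, sed_burial=0.0, sed_diffusion=0.0)
        state = ContaminantState(np.array([5.0]), np.array([5.0]), np.array([0.0]))
        total = 0.0
        for _ in range(50):
            state, fluxes = settle_and_exchange_sediment(
                state, phys, bio, geom, d5_properties(), BiogeoParams(), params)
            total += fluxes["settling"]
        assert state.sediment_inventory(geom) == pytest.approx(total, rel=1e-12)

    def test_steady_sediment_inventory_is_deposition_over_losses(self):
        # constant deposition D against burial b and degradation k:
        # steady M = D/(b + k)
        geom = single_box_geometry()
        phys = PhysicalState.initial(geom, t_surf=25.0)
        bio = _bare_bio(geom, det=200.0)
        k_deg = 1e-3
        chem = _chem_no_tcorr(log_koc=5.2, biodeg_sed_25=k_deg, biodeg_sed_ea=0.0)
        b = 5e-4
        params = ProcessParams(sed_resuspension=0.0, sed_burial=b, sed_diffusion=0.0)
        bp = BiogeoParams()
        state = ContaminantState(np.array([5.0]), np.array([5.0]), np.array([0.0]))
        deposition = None
        for _ in range(8000):
            c_deep_before = state.c_deep.copy()
            state, fluxes = settle_and_exchange_sediment(
                state, phys, bio, geom, chem, bp, params)
            deposition = fluxes["settling"]
            state, _ = transformation_losses(state, phys, bio, geom, chem)
            state.c_surf[:] = 5.0  # hold the water column constant
            state.c_deep[:] = c_deep_before
        expected = deposition / (b + k_deg)
        assert state.sediment_inventory(geom) == pytest.approx(expected, rel=5e-3)


class TestAdvection:
    def test_no_flows_no_loads_unchanged(self):
        geom = single_box_geometry()
        clim = constant_climatology(discharge=0.0, precip=0.0, cont_load=0.0)
        fday = generate_rw_forcing(clim, 2000, 1).day(0)
        flows = compute_flows(geom, fday)
        state = ContaminantState(np.array([2.0]), np.array([3.0]), np.array([0.0]))
        new, fluxes = advect_contaminant(state, geom, flows, fday)
        np.testing.assert_array_equal(new.c_surf, state.c_surf)
        np.testing.assert_array_equal(new.c_deep, state.c_deep)
        assert fluxes["river_input"] == 0.0

    def test_equal_exchange_at_equal_concentration_is_neutral(self):
        # deep inflow carrying the ambient concentration changes nothing
        c0 = 4.0
        geom = single_box_geometry(deep_inflow=1e8, deep_inflow_salinity=10.0,
                                   boundary_contaminant=c0)
        clim = constant_climatology(discharge=0.0, precip=0.0, cont_load=0.0)
        fday = generate_rw_forcing(clim, 2000, 1).day(0)
        flows = compute_flows(geom, fday)
        state = ContaminantState(np.array([c0]), np.array([c0]), np.array([0.0]))
        new, _ = advect_contaminant(state, geom, flows, fday)
        np.testing.assert_allclose(new.c_surf, c0, rtol=1e-14)
        np.testing.assert_allclose(new.c_deep, c0, rtol=1e-14)

    def test_steady_concentration_is_load_over_outflow(self):
        # single box, river load L, outflow Q: C* = L/Q (unit-consistent)
        load, q = 10.0, 1e8  # kg/day, m³/day
        geom = single_box_geometry(area=1e8, h_surf=20.0, h_deep=10.0)
        clim = constant_climatology(basins=geom.names, discharge=q, precip=0.0,
                                    cont_load=load)
        fday = generate_rw_forcing(clim, 2000, 1).day(0)
        flows = compute_flows(geom, fday)
        state = ContaminantState.zeros(geom)
        for _ in range(2000):
            state, _ = advect_contaminant(state, geom, flows, fday)
        expected = load * 1e9 / q  # ng/L
        assert state.c_surf[0] == pytest.approx(expected, rel=1e-3)

    def test_mass_conserved_up_to_logged_fluxes(self):
        from baltfate.defaults import baltic_climatology, baltic_geometry

        geom = baltic_geometry()
        fday = generate_rw_forcing(baltic_climatology(seed=8), 2000, 1).day(50)
        flows = compute_flows(geom, fday)
        state = ContaminantState(np.array([1.0, 2.0, 3.0]),
                                 np.array([0.5, 1.0, 1.5]),
                                 np.zeros(3))
        m0 = state.water_inventory(geom)
        new, fx = advect_contaminant(state, geom, flows, fday)
        m1 = new.water_inventory(geom)
        net = fx["river_input"] + fx["boundary_in"] - fx["boundary_out"]
        assert m1 - m0 == pytest.approx(net, rel=1e-10)
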