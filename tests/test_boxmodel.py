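"""Box-ocean model: equilibrium, conservation, stability, forcing response."""

import numpy as np
import pytest

from reefcarb import boxmodel as bm
from reefcarb import scenarios as sc
from reefcarb import synthdata as sd
from reefcarb.constants import PGC_PER_MOLC

PCO2_1850 = 285.2


@pytest.fixture(scope="module")
def config():
    return bm.default_config()


@pytest.fixture(scope="module")
def init_state(config):
    return bm.init_preindustrial(config, PCO2_1850)


def constant_pathway(ppm=PCO2_1850, start=1850, end=2350):
    years = np.arange(start, end + 1)
    return sd.CO2Pathway(rcp_id="RCP4.5", years=years, co2_ppm=np.full(years.size, ppm))


class TestTransportOperator:
    def test_volume_weighted_conservation(self, config):
        a_mat = config.transport_matrix()
        vols = np.asarray(config.volumes)
        # residual must be roundoff relative to the volume flows themselves
        flow_scale = np.abs(vols[:, None] * a_mat).max()
        assert np.abs(vols @ a_mat).max() < 1e-12 * flow_scale

    def test_reef_box_area_fraction_bounded(self):
        with pytest.raises(ValueError, match="2%"):
            bm.default_config(areas=(1.0e14, 2.21e14, 1.38e14, 0.0))


class TestPreindustrialInit:
    def test_per_box_flux_negligible_at_start(self, config, init_state):
        ks = bm._box_constants(config, 1850.0, None)
        flux = bm._airsea_fluxes(init_state, config, ks, PCO2_1850, [None] * 3)
        assert np.all(np.abs(flux) * PGC_PER_MOLC < 1e-6)

    def test_control_drift_over_500_years(self, config, init_state):
        run = bm.integrate(
            config, constant_pathway(), years=(1850, 2350), init_state=init_state, control=True
        )
        assert np.abs(run.global_flux).max() < 1e-3

    def test_control_inventory_conservation(self, config, init_state):
        run = bm.integrate(
            config, constant_pathway(), years=(1850, 2350), init_state=init_state, control=True
        )
        d0, a0 = run.initial_inventory
        d1, a1 = run.final_inventory
        assert abs(d1 - d0) / d0 < 1e-4   # < 0.01%
        assert abs(a1 - a0) / a0 < 1e-12  # Alk untouched by gas exchange


class TestStep:
    def test_fixed_point_at_equilibrium(self, init_state):
        cfg = bm.default_config(overturning_sv=0.0, mixing_sv=())
        new = bm.step(init_state, cfg, PCO2_1850, None, dt=0.05)
        np.testing.assert_allclose(new.dic, init_state.dic, rtol=1e-12)
        np.testing.assert_allclose(new.alk, init_state.alk, rtol=1e-12)

    def test_reef_increment_exactly_two_to_one(self, init_state):
        cfg = bm.default_config(
            overturning_sv=0.0, mixing_sv=(), piston_velocity_m_per_day=0.0
        )
        eps = 1e-4
        new = bm.step(init_state, cfg, PCO2_1850, (2 * eps, eps), dt=0.05)
        d_alk = new.alk[0] - init_state.alk[0]
        d_dic = new.dic[0] - init_state.dic[0]
        # 2:1 by construction; differencing against unequal baselines leaves
        # only rounding residue
        assert d_alk == pytest.approx(2.0 * d_dic, rel=1e-9)

    def test_sealed_atmosphere_mass_balance(self, init_state):
        """With kw = 0, global DIC gain in one step equals the reef input."""
        cfg = bm.default_config(piston_velocity_m_per_day=0.0)
        dt, dic_f = 0.05, 0.01   # Pmol/y
        new = bm.step(init_state, cfg, PCO2_1850, (2 * dic_f, dic_f), dt=dt)
        vols = np.asarray(cfg.volumes)
        gain = (new.dic - init_state.dic) @ vols
        expected = dic_f * 1e15 * dt
        assert abs(gain - expected) / expected < 1e-12

    def test_negative_concentration_names_box(self, init_state):
        with pytest.raises(bm.UnstableTimestepError, match="reef"):
            bm.step(init_state, bm.default_config(), PCO2_1850, (-1e6, -1e6), dt=0.05)

    def test_oversized_timestep_rejected(self, init_state):
        with pytest.raises(ValueError):
            bm.step(init_state, bm.default_config(), PCO2_1850, None, dt=0.5)


class TestIntegrate:
    def test_deterministic_repetition(self, config, init_state):
        p = sd.rcp_co2_pathway("RCP2.6")
        r1 = bm.integrate(config, p, years=(1850, 2000), init_state=init_state)
        r2 = bm.integrate(config, p, years=(1850, 2000), init_state=init_state)
        assert np.array_equal(r1.global_flux, r2.global_flux)
        assert np.array_equal(r1.dic, r2.dic)

    def test_stronger_forcing_more_uptake(self, config, init_state):
        r85 = bm.integrate(
            config, sd.rcp_co2_pathway("RCP8.5"), years=(1850, 2100), init_state=init_state
        )
        r26 = bm.integrate(
            config, sd.rcp_co2_pathway("RCP2.6"), years=(1850, 2100), init_state=init_state
        )
        in_2090s = (r85.years >= 2090) & (r85.years <= 2099)
        assert r85.global_flux[in_2090s].mean() > r26.global_flux[in_2090s].mean()

    def test_zero_amplitude_series_reproduces_reference_bitwise(self, config, init_state):
        p = sd.rcp_co2_pathway("RCP4.5")
        spec = sc.ScenarioSpec("RCP4.5", 150.0, end_year=2050)
        zero = sc.zero_flux_series(spec)
        ref = bm.integrate(config, p, years=(1850, 2050), init_state=init_state)
        zrun = bm.integrate(config, p, flux_series=zero, years=(1850, 2050), init_state=init_state)
        assert np.array_equal(ref.global_flux, zrun.global_flux)
        assert np.array_equal(ref.dic, zrun.dic)
        assert np.array_equal(ref.alk, zrun.alk)

    def test_linearity_in_g0(self, config, init_state):
        """Enhancement scales ~2x from G0=150 to 300 (weak chemistry nonlinearity)."""
        p = sd.rcp_co2_pathway("RCP4.5")
        ref = bm.integrate(config, p, years=(1850, 2100), init_state=init_state)
        runs = {}
        for g0 in (150.0, 300.0):
            series = sc.build_scenario(sc.ScenarioSpec("RCP4.5", g0))
            runs[g0] = bm.integrate(
                config, p, flux_series=series, years=(1850, 2100), init_state=init_state
            )
        enh150 = (runs[150.0].global_flux - ref.global_flux).sum()
        enh300 = (runs[300.0].global_flux - ref.global_flux).sum()
        assert enh300 / enh150 == pytest.approx(2.0, rel=0.1)

    def test_timestep_convergence(self, init_state):
        """Cumulative uptake at dt=0.05 within 0.5% of dt=0.01."""
        p = sd.rcp_co2_pathway("RCP4.5")
        series = sc.build_scenario(sc.ScenarioSpec("RCP4.5", 150.0))
        cums = {}
        for dt in (0.05, 0.01):
            cfg = bm.default_config(dt=dt)
            init = bm.init_preindustrial(cfg, PCO2_1850)
            run = bm.integrate(cfg, p, flux_series=series, years=(1850, 2050), init_state=init)
            cums[dt] = run.global_flux.sum()
        assert cums[0.05] == pytest.approx(cums[0.01], rel=5e-3)

    def test_carbon_and_alkalinity_closure(self, config, init_state):
        p = sd.rcp_co2_pathway("RCP8.5")
        series = sc.build_scenario(sc.ScenarioSpec("RCP8.5", 300.0))
        run = bm.integrate(config, p, flux_series=series, years=(1850, 2100), init_state=init_state)
        assert run.carbon_closure_error() < 1e-9
        assert run.alkalinity_closure_error() < 1e-9

    def test_missing_pathway_years_rejected(self, config, init_state):
        p = sd.rcp_co2_pathway("RCP4.5", start_year=1900)
        with pytest.raises(KeyError):
            bm.integrate(config, p, years=(1850, 2000), init_state=init_state)
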