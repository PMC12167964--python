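"""Reduced-complexity transient ocean carbon cycle (four-box model).

A desk-scale stand-in for a 3-D ocean biogeochemical GCM: four well-mixed
boxes — a small reef-shelf surface box, an open tropical surface box, a
high-latitude surface box and a deep reservoir — exchange water through a
fixed overturning loop (high-lat -> deep -> tropical -> high-lat) and
bidirectional mixing.  Surface boxes exchange CO2 with a prescribed
atmosphere through a constant piston velocity,

    F = kw * K0 * (pCO2_atm - pCO2_box) * A        [mol y-1, positive into ocean],

and the reef-derived alkalinity/DIC scenario fluxes are injected wholly
into the reef-shelf box.  DIC and Alk are advected identically; air-sea
exchange alters DIC only.  Integration is explicit Euler with a default
step of 0.05 y; all forcings (atmospheric CO2, warming, reef fluxes) are
held constant within each calendar year.

The default configuration uses a single uniform preindustrial surface
temperature.  This idealization makes the per-box gas-exchange equilibrium
an exact stationary state of the transport operator (a preindustrial
control with zero drift), at the cost of omitting the temperature-driven
solubility pump; anthropogenic fluxes are defined relative to the control,
so the omission does not enter the scenario-minus-reference feedback
diagnostics.  Optional per-RCP linear SST warming ramps perturb the surface
boxes after 2005.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import carbchem
from .constants import PGC_PER_MOLC, RHO_SEAWATER, SV_TO_M3_PER_YEAR
from .scenarios import FluxSeries
from .synthdata import CO2Pathway

__all__ = [
    "BOX_NAMES",
    "BoxOceanConfig",
    "BoxOceanState",
    "RunOutput",
    "UnstableTimestepError",
    "StationarityError",
    "default_config",
    "init_preindustrial",
    "step",
    "integrate",
]

BOX_NAMES = ("reef", "trop", "hilat", "deep")
_REEF, _TROP, _HILAT, _DEEP = 0, 1, 2, 3
_SURFACE = (_REEF, _TROP, _HILAT)


class UnstableTimestepError(RuntimeError):
    pass


class StationarityError(RuntimeError):
    pass


@dataclass(frozen=True)
class BoxOceanConfig:
    """Geometry, transport, gas exchange and thermal forcing of the box ocean.

    Areas in m2, volumes in m3, transports in Sv, piston velocity in m d-1,
    warming ramps in degC per century applied to surface boxes (first entry
    2005-2100, second entry 2100-2300, both linear in time).
    """

    volumes: tuple[float, float, float, float]
    areas: tuple[float, float, float, float]
    temperatures: tuple[float, float, float, float]
    salinities: tuple[float, float, float, float]
    alk_preindustrial: float            # mol m-3, uniform
    overturning_sv: float
    mixing_sv: tuple[tuple[str, str, float], ...]
    piston_velocity_m_per_day: float
    warming_ramps: dict = field(
        default_factory=lambda: {
            "RCP2.6": (0.6, 0.0),
            "RCP4.5": (1.4, 0.1),
            "RCP8.5": (3.0, 1.5),
        }
    )
    historical_warming: float = 0.4     # degC, linear 1850-2005, all RCP runs
    dt: float = 0.05                    # years

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.volumes):
            raise ValueError("box volumes must be positive")
        if any(a < 0 for a in self.areas):
            raise ValueError("box areas must be non-negative")
        if self.dt > 0.1:
            raise ValueError("time step must be <= 0.1 y for stability")
        total_area = sum(self.areas)
        if self.areas[_REEF] > 0.02 * total_area:
            raise ValueError("reef-shelf box area must be <= 2% of total surface area")

    def transport_matrix(self) -> np.ndarray:
        """Linear operator A with dC/dt = A @ C (per-volume units, y-1).

        Built from directed volume flows; inflow equals outflow for every
        box, so volume-weighted tracer totals are conserved: V^T A = 0.
        """
        idx = {name: i for i, name in enumerate(BOX_NAMES)}
        flows: list[tuple[int, int, float]] = []
        psi = self.overturning_sv * SV_TO_M3_PER_YEAR
        if psi > 0:
            flows += [(_HILAT, _DEEP, psi), (_DEEP, _TROP, psi), (_TROP, _HILAT, psi)]
        for a, b, m_sv in self.mixing_sv:
            m = m_sv * SV_TO_M3_PER_YEAR
            flows += [(idx[a], idx[b], m), (idx[b], idx[a], m)]
        mat = np.zeros((4, 4))
        vols = np.asarray(self.volumes)
        for src, dst, q in flows:
            mat[dst, src] += q / vols[dst]
            mat[src, src] -= q / vols[src]
        return mat

    def surface_temperature(self, box: int, t: float, rcp_id: str | None) -> float:
        """Box temperature at model year ``t`` (degC)."""
        t0 = self.temperatures[box]
        if rcp_id is None or box == _DEEP:
            return t0
        warm = self.historical_warming * min(max((t - 1850.0) / 155.0, 0.0), 1.0)
        ramp = self.warming_ramps.get(rcp_id)
        if ramp is not None and t > 2005.0:
            r1, r2 = ramp
            warm += r1 * (min(t, 2100.0) - 2005.0) / 100.0
            if t > 2100.0:
                warm += r2 * (t - 2100.0) / 100.0
        return t0 + warm


def default_config(**overrides) -> BoxOceanConfig:
    """The package's standard box ocean.

    Realistic total volume (~1.34e18 m3) and surface area (3.6e14 m2); the
    reef-shelf box is a 50 m deep, 1e12 m2 (~0.3% of ocean area) coastal
    band flushed in ~0.2 y, giving reef water a residence time short
    relative to air-sea CO2 equilibration — the regime in which most of the
    uptake enhancement escapes the reef region.
    """
    base = dict(
        volumes=(5.0e13, 2.21e16, 3.45e16, 1.282e18),
        areas=(1.0e12, 2.21e14, 1.38e14, 0.0),
        temperatures=(18.0, 18.0, 18.0, 3.0),
        salinities=(35.0, 35.0, 35.0, 35.0),
        alk_preindustrial=2.35,
        overturning_sv=30.0,
        mixing_sv=(("reef", "trop", 8.0), ("trop", "hilat", 60.0), ("hilat", "deep", 70.0)),
        piston_velocity_m_per_day=4.0,
    )
    base.update(overrides)
    return BoxOceanConfig(**base)


@dataclass
class BoxOceanState:
    """Per-box DIC and Alk (mol m-3) at a model time (years)."""

    time: float
    dic: np.ndarray
    alk: np.ndarray

    def copy(self) -> "BoxOceanState":
        return BoxOceanState(self.time, self.dic.copy(), self.alk.copy())

    def inventory(self, volumes) -> tuple[float, float]:
        """Volume-integrated (DIC, Alk) in mol."""
        v = np.asarray(volumes)
        return float(self.dic @ v), float(self.alk @ v)


@dataclass
class RunOutput:
    """Annual diagnostics of one transient integration."""

    years: np.ndarray
    box_flux: np.ndarray          # (n_years, 4) PgC y-1, annual mean, positive into ocean
    global_flux: np.ndarray       # PgC y-1
    dic: np.ndarray               # (n_years, 4) mol m-3, end-of-year
    alk: np.ndarray
    reef_dic_input: np.ndarray    # cumulative mol since start
    reef_alk_input: np.ndarray
    cumulative_airsea_mol: np.ndarray
    initial_inventory: tuple[float, float]
    final_inventory: tuple[float, float]
    config: BoxOceanConfig
    rcp_id: str | None
    scenario_name: str | None
    is_control: bool

    def carbon_closure_error(self) -> float:
        """Relative error of: air-sea uptake + reef DIC input = DIC inventory change.

        The inventory difference can only be resolved down to the floating
        point granularity of the ~2.6e18 mol ocean inventory, so the error
        is scaled by at least 1e-6 of the initial inventory (still nine
        orders of magnitude above one ulp).
        """
        gained = self.final_inventory[0] - self.initial_inventory[0]
        supplied = self.cumulative_airsea_mol[-1] + self.reef_dic_input[-1]
        scale = max(abs(gained), abs(supplied), 1e-6 * self.initial_inventory[0])
        return abs(gained - supplied) / scale

    def alkalinity_closure_error(self) -> float:
        gained = self.final_inventory[1] - self.initial_inventory[1]
        supplied = self.reef_alk_input[-1]
        scale = max(abs(gained), abs(supplied), 1e-6 * self.initial_inventory[1])
        return abs(gained - supplied) / scale

    def to_frame(self) -> pd.DataFrame:
        data = {"year": self.years, "global_flux_pgc_yr": self.global_flux}
        for i, name in enumerate(BOX_NAMES):
            data[f"flux_{name}_pgc_yr"] = self.box_flux[:, i]
        for i, name in enumerate(BOX_NAMES):
            data[f"dic_{name}_mol_m3"] = self.dic[:, i]
            data[f"alk_{name}_mol_m3"] = self.alk[:, i]
        return pd.DataFrame(data)


def _box_constants(config: BoxOceanConfig, t: float, rcp_id: str | None):
    """Per-surface-box equilibrium constants at the year's temperatures."""
    out = []
    for b in _SURFACE:
        cond = carbchem.SeawaterConditions(
            temperature=config.surface_temperature(b, t, rcp_id),
            salinity=config.salinities[b],
        )
        out.append(carbchem.equilibrium_constants(cond))
    return out


def _airsea_fluxes(state, config, ks_surface, pco2_atm, h_cache) -> np.ndarray:
    """Per-box air-sea CO2 flux (mol y-1, positive into ocean)."""
    kw = config.piston_velocity_m_per_day * 365.25    # m y-1
    flux = np.zeros(4)
    for j, b in enumerate(_SURFACE):
        ks = ks_surface[j]
        dic_kg = state.dic[b] / RHO_SEAWATER
        alk_kg = state.alk[b] / RHO_SEAWATER
        pco2_box, h = carbchem.pco2_from_dic_alk(dic_kg, alk_kg, ks, h_cache[j])
        h_cache[j] = h
        k0_vol = ks.k0 * RHO_SEAWATER                 # mol m-3 atm-1
        flux[b] = kw * k0_vol * (pco2_atm - pco2_box) * 1e-6 * config.areas[b]
    return flux


def init_preindustrial(
    config: BoxOceanConfig,
    pco2_atm_1850: float,
    drift_tol_pgc: float = 1e-6,
    max_polish_years: float = 2000.0,
) -> BoxOceanState:
    """Preindustrial equilibrium state at the 1850 atmospheric pCO2.

    Surface boxes are set to gas-exchange equilibrium via the inverse
    chemistry solve at the prescribed uniform alkalinity; the deep box
    inherits the high-latitude DIC.  If the resulting state is not already
    stationary (non-uniform surface temperatures), the model is integrated
    at fixed atmospheric pCO2 until the global air-sea flux falls below
    ``drift_tol_pgc`` (PgC y-1), up to ``max_polish_years``.
    """
    alk = np.full(4, config.alk_preindustrial)
    dic = np.zeros(4)
    for b in _SURFACE:
        cond = carbchem.SeawaterConditions(
            temperature=config.temperatures[b], salinity=config.salinities[b]
        )
        dic[b] = carbchem.dic_from_pco2(pco2_atm_1850, alk[b], cond, units="mol/m3")
    dic[_DEEP] = dic[_HILAT]
    state = BoxOceanState(time=1850.0, dic=dic, alk=alk)

    chunk = 50.0
    elapsed = 0.0
    candidate = state
    while True:
        probe, drift = _spinup_chunk(candidate, config, pco2_atm_1850, chunk)
        if drift < drift_tol_pgc:
            return candidate
        candidate = probe
        elapsed += chunk
        if elapsed > max_polish_years:
            raise StationarityError(
                f"preindustrial state did not reach stationarity within "
                f"{max_polish_years} y (drift {drift:.3e} PgC y-1)"
            )


def _spinup_chunk(state, config, pco2_atm, years):
    """Integrate at fixed atmospheric pCO2; return (end state, max |global flux|)."""
    s = state.copy()
    a_mat = config.transport_matrix()
    ks_surface = _box_constants(config, s.time, None)
    h_cache = [None, None, None]
    dt = config.dt
    n = int(round(years / dt))
    max_flux = 0.0
    for _ in range(n):
        s.dic += dt * (a_mat @ s.dic)
        s.alk += dt * (a_mat @ s.alk)
        flux = _airsea_fluxes(s, config, ks_surface, pco2_atm, h_cache)
        s.dic += dt * flux / np.asarray(config.volumes)
        max_flux = max(max_flux, abs(flux.sum()) * PGC_PER_MOLC)
        s.time += dt
    return s, max_flux


def step(
    state: BoxOceanState,
    config: BoxOceanConfig,
    pco2_atm: float,
    reef_fluxes: tuple[float, float] | None,
    dt: float,
    rcp_id: str | None = None,
) -> BoxOceanState:
    """Advance the model one explicit-Euler step of ``dt`` years.

    ``reef_fluxes`` is the (alk, dic) injection in Pmol y-1, applied wholly
    to the reef-shelf box.  Raises :class:`UnstableTimestepError` naming the
    offending box if any concentration becomes negative.
    """
    if dt > 0.1:
        raise ValueError("time step must be <= 0.1 y")
    new = state.copy()
    a_mat = config.transport_matrix()
    vols = np.asarray(config.volumes)
    new.dic += dt * (a_mat @ state.dic)
    new.alk += dt * (a_mat @ state.alk)
    ks_surface = _box_constants(config, state.time, rcp_id)
    flux = _airsea_fluxes(new, config, ks_surface, pco2_atm, [None, None, None])
    new.dic += dt * flux / vols
    if reef_fluxes is not None:
        alk_f, dic_f = reef_fluxes
        new.alk[_REEF] += dt * alk_f * 1e15 / vols[_REEF]
        new.dic[_REEF] += dt * dic_f * 1e15 / vols[_REEF]
    new.time += dt
    for arr, tracer in ((new.dic, "DIC"), (new.alk, "Alk")):
        bad = np.nonzero(arr <= 0)[0]
        if bad.size:
            raise UnstableTimestepError(
                f"unstable timestep: negative {tracer} in box {BOX_NAMES[bad[0]]!r}"
            )
    return new


def integrate(
    config: BoxOceanConfig,
    co2_pathway: CO2Pathway,
    flux_series: FluxSeries | None = None,
    years: tuple[int, int] | None = None,
    init_state: BoxOceanState | None = None,
    control: bool = False,
    scenario_name: str | None = None,
) -> RunOutput:
    """Transient integration under a prescribed atmospheric CO2 pathway.

    ``flux_series=None`` gives a reference (no-reef-flux) run; ``control=True``
    holds atmospheric CO2 at its start-year value with no warming (the
    preindustrial control used for drift removal).  A scenario run and its
    reference share the historical segment bitwise because the zero reef
    flux enters the arithmetic identically.
    """
    y0, y1 = years if years is not None else (int(co2_pathway.years[0]), int(co2_pathway.years[-1]))
    run_years = np.arange(y0, y1 + 1)
    co2 = co2_pathway.at(run_years)
    if control:
        co2 = np.full_like(co2, co2[0])
    rcp_id = None if control else co2_pathway.rcp_id

    if flux_series is not None:
        fs_years = flux_series.years
        if fs_years[0] > y0 or fs_years[-1] < y1:
            raise ValueError("flux series does not cover the integration years")

    if init_state is None:
        init_state = init_preindustrial(config, float(co2[0]))
    state = init_state.copy()
    state.time = float(y0)

    a_mat = config.transport_matrix()
    vols = np.asarray(config.volumes)
    v_reef = vols[_REEF]
    dt = config.dt
    n_sub = int(round(1.0 / dt))
    if abs(n_sub * dt - 1.0) > 1e-12:
        raise ValueError("dt must divide one year evenly")

    n_years = run_years.size
    box_flux = np.zeros((n_years, 4))
    dic_out = np.zeros((n_years, 4))
    alk_out = np.zeros((n_years, 4))
    reef_dic_cum = np.zeros(n_years)
    reef_alk_cum = np.zeros(n_years)
    airsea_cum = np.zeros(n_years)

    inv0 = state.inventory(vols)
    h_cache = [None, None, None]
    total_airsea = 0.0
    total_reef_dic = 0.0
    total_reef_alk = 0.0

    # Kahan-compensated state accumulation: per-step increments can be ~10
    # ulp of the box concentrations (preindustrial control), and plain
    # addition would leak them, breaking carbon bookkeeping closure.
    comp_dic = np.zeros(4)
    comp_alk = np.zeros(4)

    def _kadd(target, comp, delta):
        y = delta - comp
        t = target + y
        comp[:] = (t - target) - y
        target[:] = t

    reef_delta = np.zeros(4)
    for i, year in enumerate(run_years):
        pco2_atm = co2[i]
        if flux_series is not None:
            j = int(year - fs_years[0])
            alk_f = flux_series.alk_flux[j] * 1e15   # mol y-1
            dic_f = flux_series.dic_flux[j] * 1e15
        else:
            alk_f = dic_f = 0.0
        ks_surface = _box_constants(config, float(year), rcp_id)
        year_flux = np.zeros(4)
        for _ in range(n_sub):
            _kadd(state.dic, comp_dic, dt * (a_mat @ state.dic))
            _kadd(state.alk, comp_alk, dt * (a_mat @ state.alk))
            flux = _airsea_fluxes(state, config, ks_surface, pco2_atm, h_cache)
            reef_delta[_REEF] = dt * dic_f / v_reef
            _kadd(state.dic, comp_dic, dt * flux / vols + reef_delta)
            reef_delta[_REEF] = dt * alk_f / v_reef
            _kadd(state.alk, comp_alk, reef_delta)
            year_flux += flux * dt
            total_airsea += flux.sum() * dt
        total_reef_dic += dic_f
        total_reef_alk += alk_f
        state.time = float(year + 1)
        if np.any(state.dic <= 0) or np.any(state.alk <= 0):
            bad = int(np.nonzero((state.dic <= 0) | (state.alk <= 0))[0][0])
            raise UnstableTimestepError(
                f"unstable timestep: negative tracer in box {BOX_NAMES[bad]!r}"
            )
        box_flux[i] = year_flux * PGC_PER_MOLC   # annual mean over 1 y
        dic_out[i] = state.dic
        alk_out[i] = state.alk
        reef_dic_cum[i] = total_reef_dic
        reef_alk_cum[i] = total_reef_alk
        airsea_cum[i] = total_airsea

    return RunOutput(
        years=run_years,
        box_flux=box_flux,
        global_flux=box_flux.sum(axis=1),
        dic=dic_out,
        alk=alk_out,
        reef_dic_input=reef_dic_cum,
        reef_alk_input=reef_alk_cum,
        cumulative_airsea_mol=airsea_cum,
        initial_inventory=inv0,
        final_inventory=state.inventory(vols),
        config=config,
        rcp_id=co2_pathway.rcp_id,
        scenario_name=scenario_name,
        is_control=control,
    )
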