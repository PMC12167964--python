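"""Ensemble orchestration and feedback diagnostics.

Runs the nine reef-flux scenarios (three RCPs x three historical production
rates) against same-RCP no-reef-flux references and a preindustrial
control, and derives the quantities that characterize the carbonate
feedback: annual and cumulative enhancement of anthropogenic carbon uptake,
the share occurring in the reef box, carbon-budget conversions to GtCO2,
and the time for reef-water alkalinity trends to emerge from natural
variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import boxmodel, scenarios, synthdata
from .constants import GTCO2_PER_PGC

__all__ = [
    "EnhancementDiagnostics",
    "EnsembleResult",
    "EmergenceResult",
    "compute_enhancement",
    "pgc_to_gtco2",
    "time_of_emergence",
    "run_ensemble",
]


@dataclass
class EnhancementDiagnostics:
    """Scenario-minus-reference uptake anomalies for one ensemble member."""

    scenario_name: str
    years: np.ndarray
    annual: np.ndarray            # PgC y-1
    cumulative: np.ndarray        # PgC
    percent_of_reference: np.ndarray   # % of cumulative reference uptake since start
    reef_share: np.ndarray        # fraction of annual enhancement in the reef box
    peak_value: float             # PgC y-1
    peak_year: int

    def cumulative_at(self, year: int) -> float:
        idx = np.nonzero(self.years == year)[0]
        if idx.size == 0:
            raise KeyError(f"year {year} outside diagnostics")
        return float(self.cumulative[int(idx[0])])

    def reef_share_at(self, year: int) -> float:
        idx = np.nonzero(self.years == year)[0]
        if idx.size == 0:
            raise KeyError(f"year {year} outside diagnostics")
        return float(self.reef_share[int(idx[0])])


def compute_enhancement(
    scenario_run: boxmodel.RunOutput, reference_run: boxmodel.RunOutput
) -> EnhancementDiagnostics:
    """Uptake enhancement of a scenario run over its no-reef-flux reference.

    The runs must share years, configuration and CO2 pathway (the reference
    differs only in carrying no reef fluxes); the preindustrial control
    cancels in the difference and is not needed here.
    """
    if not np.array_equal(scenario_run.years, reference_run.years):
        raise ValueError("runs do not share a year axis")
    if scenario_run.config is not reference_run.config and scenario_run.config != reference_run.config:
        raise ValueError("runs do not share a configuration")
    if scenario_run.rcp_id != reference_run.rcp_id:
        raise ValueError("runs do not share a CO2 pathway")

    years = scenario_run.years
    annual = scenario_run.global_flux - reference_run.global_flux
    cumulative = np.cumsum(annual)  # annual means x 1 y

    ref_cum = np.cumsum(reference_run.global_flux)
    percent = np.full_like(annual, np.nan)
    ok = ref_cum > 0
    percent[ok] = 100.0 * cumulative[ok] / ref_cum[ok]

    reef_delta = scenario_run.box_flux[:, 0] - reference_run.box_flux[:, 0]
    reef_share = np.full_like(annual, np.nan)
    sig = annual > 1e-6
    reef_share[sig] = reef_delta[sig] / annual[sig]

    window = (years >= 2005) & (years <= 2300)
    if np.any(window):
        sub = annual[window]
        i = int(np.argmax(sub))   # argmax returns the earliest maximum
        peak_value = float(sub[i])
        peak_year = int(years[window][i])
    else:
        peak_value, peak_year = float(annual.max()), int(years[int(np.argmax(annual))])

    return EnhancementDiagnostics(
        scenario_name=scenario_run.scenario_name or "unnamed",
        years=years,
        annual=annual,
        cumulative=cumulative,
        percent_of_reference=percent,
        reef_share=reef_share,
        peak_value=peak_value,
        peak_year=peak_year,
    )


def pgc_to_gtco2(x_pgc: float) -> float:
    """Carbon mass in PgC expressed as GtCO2 (molar-mass ratio 44.009/12.011)."""
    return x_pgc * GTCO2_PER_PGC


@dataclass
class EmergenceResult:
    """Monte-Carlo distribution of years until a trend emerges from AR(1) noise."""

    median: float | None
    q25: float | None
    q75: float | None
    fraction_emerged: float
    emergence_years: np.ndarray   # per-realization; +inf where never emerged


def time_of_emergence(
    trend: float,
    sigma: float,
    phi: float,
    window: int = 300,
    n_realizations: int = 500,
    seed: int = 0,
    min_years: int = 5,
) -> EmergenceResult:
    """Years of annual sampling needed for a linear alkalinity trend to emerge.

    ``trend`` is in concentration units per century, ``sigma``/``phi`` the
    stationary standard deviation and lag-1 autocorrelation of AR(1) natural
    variability in the same concentration units.  For each realization the
    ordinary-least-squares trend over a growing record is tested against
    twice its standard error, inflated for serial correlation through the
    effective sample size n_eff = n*(1-phi)/(1+phi); emergence is the first
    record length at which the trend is significant.  Returns the median and
    quartiles over realizations (None when trend == 0, the no-emergence
    sentinel).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if not (-1.0 < phi < 1.0):
        raise ValueError("phi must satisfy |phi| < 1")
    if trend == 0:
        return EmergenceResult(None, None, None, 0.0, np.full(n_realizations, np.inf))

    rng = np.random.default_rng(seed)
    slope_per_year = trend / 100.0
    t = np.arange(window, dtype=float)

    eps = rng.standard_normal((n_realizations, window)) * sigma * np.sqrt(1.0 - phi * phi)
    eps[:, 0] = rng.standard_normal(n_realizations) * sigma
    from scipy.signal import lfilter

    noise = lfilter([1.0], [1.0, -phi], eps, axis=1)
    y = slope_per_year * t[None, :] + noise

    infl = np.sqrt((1.0 + phi) / (1.0 - phi))
    emergence = np.full(n_realizations, np.inf)
    emerged = np.zeros(n_realizations, dtype=bool)
    for n in range(min_years, window + 1):
        tt = t[:n]
        yy = y[:, :n]
        t_mean = tt.mean()
        sxx = float(((tt - t_mean) ** 2).sum())
        slope = ((tt - t_mean) @ (yy - yy.mean(axis=1, keepdims=True)).T) / sxx
        resid = yy - yy.mean(axis=1, keepdims=True) - slope[:, None] * (tt - t_mean)[None, :]
        dof = max(n - 2, 1)
        se = np.sqrt(resid.var(axis=1, ddof=0) * n / dof / sxx) * infl
        newly = (~emerged) & (np.abs(slope) > 2.0 * se)
        emergence[newly] = n
        emerged |= newly
        if emerged.all():
            break

    finite = np.isfinite(emergence)
    if not finite.any():
        return EmergenceResult(None, None, None, 0.0, emergence)
    med, q25, q75 = (float(np.percentile(emergence[finite], p)) for p in (50, 25, 75))
    return EmergenceResult(med, q25, q75, float(finite.mean()), emergence)


@dataclass
class EnsembleResult:
    """All runs and diagnostics of the nine-member reef-flux ensemble."""

    summary: pd.DataFrame
    diagnostics: dict
    scenario_runs: dict
    reference_runs: dict
    control_run: boxmodel.RunOutput


def run_ensemble(
    config: boxmodel.BoxOceanConfig | None = None,
    g0_values=scenarios.HISTORICAL_PRODUCTION_TGC,
    rcp_ids=scenarios.RCP_IDS,
    years: tuple[int, int] = (1850, 2300),
) -> EnsembleResult:
    """Run references, scenarios and control; summarize the feedback.

    Produces one reference (no reef flux) run per RCP, one scenario run per
    (RCP, G0) member, and a preindustrial control, all from a shared
    preindustrial equilibrium state, plus a summary table of peak
    enhancement, cumulative enhancement at 2100/2300, percent of reference
    uptake, and reef-box shares.
    """
    if config is None:
        config = boxmodel.default_config()
    pathways = {r: synthdata.rcp_co2_pathway(r) for r in rcp_ids}
    first = pathways[rcp_ids[0]]
    init = boxmodel.init_preindustrial(config, float(first.at(years[0])))

    control = boxmodel.integrate(
        config, first, years=years, init_state=init, control=True, scenario_name="control"
    )

    reference_runs = {}
    for r in rcp_ids:
        reference_runs[r] = boxmodel.integrate(
            config, pathways[r], years=years, init_state=init, scenario_name=f"{r}_reference"
        )

    scenario_runs = {}
    diagnostics = {}
    rows = []
    for r in rcp_ids:
        for g0 in g0_values:
            spec = scenarios.ScenarioSpec(rcp_id=r, g0_tgc=g0, start_year=years[0], end_year=years[1])
            series = scenarios.build_scenario(spec)
            run = boxmodel.integrate(
                config, pathways[r], flux_series=series, years=years,
                init_state=init, scenario_name=spec.name,
            )
            scenario_runs[spec.name] = run
            diag = compute_enhancement(run, reference_runs[r])
            diagnostics[spec.name] = diag
            rows.append(
                {
                    "scenario": spec.name,
                    "rcp": r,
                    "g0_tgc_yr": g0,
                    "peak_enhancement_pgc_yr": diag.peak_value,
                    "peak_year": diag.peak_year,
                    "cumulative_2100_pgc": diag.cumulative_at(2100),
                    "cumulative_2300_pgc": diag.cumulative_at(2300),
                    "percent_of_reference_2300": float(
                        diag.percent_of_reference[diag.years == 2300][0]
                    ),
                    "reef_share_2040": diag.reef_share_at(2040),
                    "reef_share_2300": diag.reef_share_at(2300),
                }
            )

    return EnsembleResult(
        summary=pd.DataFrame(rows),
        diagnostics=diagnostics,
        scenario_runs=scenario_runs,
        reference_runs=reference_runs,
        control_run=control,
    )
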