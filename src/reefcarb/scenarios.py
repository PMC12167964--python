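"""Reef carbonate-production decline scenarios.

Builds time-evolving global fluxes of alkalinity and dissolved inorganic
carbon (DIC) released to the surface ocean by declining coral reef net
ecosystem calcification (NEC).  Areal NEC anchor values (kgCaCO3 m-2 y-1 at
2005, 2050 and 2100 for each RCP) are interpolated with a three-parameter
exponential decay, converted to a dimensionless relative production anomaly,
and scaled by an assumed historical global carbonate production rate G0
(TgC y-1).  Because a unit decline in calcification adds alkalinity and DIC
to seawater in a 2:1 molar ratio, the alkalinity flux is exactly twice the
DIC flux at every time.

The areal anchors enter only as ratios, so no global reef area is needed:
the relative anomaly rescales G0 directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .constants import M_C, M_CACO3

__all__ = [
    "RCP_IDS",
    "NEC_ANCHORS",
    "HISTORICAL_PRODUCTION_TGC",
    "NECAnchors",
    "DecayCurve",
    "ScenarioSpec",
    "FluxSeries",
    "UnfittableAnchorsError",
    "NoExponentialFitError",
    "fit_decay_curve",
    "relative_anomaly",
    "anomaly_to_global_fluxes",
    "tgc_to_pgcaco3",
    "build_scenario",
]

RCP_IDS = ("RCP2.6", "RCP4.5", "RCP8.5")

#: central estimate of present-day areal reef carbonate production and its
#: projected values at 2050 and 2100 under each RCP (kgCaCO3 m-2 y-1);
#: negative values denote net dissolution.
NEC_ANCHORS = {
    "RCP2.6": ((2005, 2.8), (2050, 0.95), (2100, 0.73)),
    "RCP4.5": ((2005, 2.8), (2050, -0.63), (2100, -1.39)),
    "RCP8.5": ((2005, 2.8), (2050, -1.45), (2100, -1.57)),
}

#: historical global reef carbonate production rates spanning observational
#: uncertainty (TgC y-1)
HISTORICAL_PRODUCTION_TGC = (30.0, 150.0, 300.0)

PERTURBATION_START_YEAR = 2005
DEFAULT_START_YEAR = 1850
DEFAULT_END_YEAR = 2300


class UnfittableAnchorsError(ValueError):
    """Anchor values are not strictly decreasing: no decay to fit."""


class NoExponentialFitError(RuntimeError):
    """No a + b*exp(-k*t) curve passes through the anchors (root not bracketed)."""


@dataclass(frozen=True)
class NECAnchors:
    """Three (year, areal NEC) anchor points for one RCP."""

    rcp_id: str
    points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.rcp_id not in RCP_IDS:
            raise ValueError(f"unknown RCP id {self.rcp_id!r}; expected one of {RCP_IDS}")
        if len(self.points) != 3:
            raise ValueError("exactly three anchor points are required")
        years = [p[0] for p in self.points]
        values = [p[1] for p in self.points]
        if not (years[0] < years[1] < years[2]):
            raise ValueError("anchor years must be strictly increasing")
        if values[0] <= 0:
            raise ValueError("present-day NEC anchor must be positive")
        if not (values[0] > values[1] > values[2]):
            raise UnfittableAnchorsError(
                f"unfittable anchors: NEC values {values} are not strictly decreasing"
            )

    @classmethod
    def for_rcp(cls, rcp_id: str) -> "NECAnchors":
        if rcp_id not in NEC_ANCHORS:
            raise ValueError(f"unknown RCP id {rcp_id!r}; expected one of {RCP_IDS}")
        return cls(rcp_id=rcp_id, points=NEC_ANCHORS[rcp_id])


@dataclass(frozen=True)
class DecayCurve:
    """Fitted areal NEC trajectory NEC(t) = a + b*exp(-k*(t - t0)).

    ``a`` is the long-term asymptote, ``b`` the decaying amplitude and ``k``
    the decay rate; all NEC values in kgCaCO3 m-2 y-1, ``k`` in y-1.
    """

    a: float
    b: float
    k: float
    t0: float = PERTURBATION_START_YEAR

    def nec(self, year):
        """Areal NEC at ``year`` (scalar or array)."""
        year = np.asarray(year, dtype=float)
        out = self.a + self.b * np.exp(-self.k * (year - self.t0))
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class ScenarioSpec:
    """One member of the nine-scenario ensemble: an RCP and a G0 value."""

    rcp_id: str
    g0_tgc: float
    start_year: int = DEFAULT_START_YEAR
    end_year: int = DEFAULT_END_YEAR
    perturbation_start: int = PERTURBATION_START_YEAR

    def __post_init__(self) -> None:
        if self.rcp_id not in RCP_IDS:
            raise ValueError(f"unknown RCP id {self.rcp_id!r}")
        if self.g0_tgc <= 0:
            raise ValueError("historical production G0 must be positive")
        if not self.start_year < self.perturbation_start < self.end_year:
            raise ValueError("years must satisfy start < perturbation start < end")

    @property
    def name(self) -> str:
        g0 = self.g0_tgc
        g0s = str(int(g0)) if float(g0).is_integer() else str(g0)
        return f"{self.rcp_id}_{g0s}"


@dataclass
class FluxSeries:
    """Annual global reef-derived alkalinity/DIC source fluxes (Pmol y-1)."""

    spec: ScenarioSpec
    years: np.ndarray
    nec_areal: np.ndarray        # kgCaCO3 m-2 y-1
    rel_anomaly: np.ndarray      # dimensionless
    caco3_anomaly: np.ndarray    # Pmol CaCO3-carbon y-1 (== dic_flux)
    alk_flux: np.ndarray         # Pmol y-1
    dic_flux: np.ndarray         # Pmol y-1

    def validate(self) -> None:
        if not np.array_equal(self.alk_flux, 2.0 * self.dic_flux):
            raise AssertionError("alkalinity flux must equal 2 x DIC flux exactly")
        pre = self.years < self.spec.perturbation_start
        if np.any(self.alk_flux[pre] != 0.0):
            raise AssertionError("fluxes must be zero before the perturbation start")
        if np.any(np.diff(self.alk_flux) < 0):
            raise AssertionError("fluxes must be non-decreasing in time")
        if self.years[-1] >= 2300:
            f2150 = self.flux_at(2150)[0]
            f2300 = self.flux_at(2300)[0]
            if f2300 > 0 and (f2300 - f2150) > 0.01 * f2300:
                raise AssertionError("fluxes must plateau after ~2150")

    def flux_at(self, year: float) -> tuple[float, float]:
        """(alk, dic) flux in Pmol y-1 at an exact year in the series."""
        idx = np.nonzero(self.years == year)[0]
        if idx.size == 0:
            raise KeyError(f"year {year} not in series")
        i = int(idx[0])
        return float(self.alk_flux[i]), float(self.dic_flux[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "nec_areal": self.nec_areal,
                "rel_anomaly": self.rel_anomaly,
                "caco3_pmol_yr": self.caco3_anomaly,
                "alk_pmol_yr": self.alk_flux,
                "dic_pmol_yr": self.dic_flux,
            }
        )


def fit_decay_curve(anchors: NECAnchors) -> DecayCurve:
    """Fit NEC(t) = a + b*exp(-k*(t - t0)) exactly through three anchors.

    Eliminating a and b leaves one equation in k,

        (exp(-k*d1) - exp(-k*d2)) / (1 - exp(-k*d1)) = (y1 - y2)/(y0 - y1),

    whose left side decreases monotonically from (d2-d1)/d1 (k -> 0) to 0
    (k -> inf); the root is bracketed and solved with Brent's method.

    Raises
    ------
    UnfittableAnchorsError
        if the anchor NEC values are not strictly decreasing.
    NoExponentialFitError
        if no positive decay rate reproduces the anchors.
    """
    (t0, y0), (t1, y1), (t2, y2) = anchors.points
    d1, d2 = t1 - t0, t2 - t0
    r = (y1 - y2) / (y0 - y1)

    if not (0.0 < r < (d2 - d1) / d1):
        raise NoExponentialFitError(
            f"no exponential fit: anchor ratio {r:.6g} outside (0, {(d2 - d1) / d1:.6g})"
        )

    def g(k: float) -> float:
        e1 = math.exp(-k * d1)
        e2 = math.exp(-k * d2)
        return (e1 - e2) / (1.0 - e1) - r

    lo, hi = 1e-9, 1.0
    n_expand = 0
    while g(hi) > 0.0:
        hi *= 10.0
        n_expand += 1
        if n_expand > 6:
            raise NoExponentialFitError("no exponential fit: root not bracketed (k too large)")
    while g(lo) < 0.0:
        lo /= 10.0
        n_expand += 1
        if n_expand > 12:
            raise NoExponentialFitError("no exponential fit: root not bracketed (k too small)")

    k = brentq(g, lo, hi, xtol=1e-15, rtol=8.9e-16)
    b = (y0 - y1) / (1.0 - math.exp(-k * d1))
    a = y0 - b
    curve = DecayCurve(a=a, b=b, k=k, t0=t0)

    for year, value in anchors.points:
        if abs(curve.nec(year) - value) > 1e-6:
            raise NoExponentialFitError("no exponential fit: anchor misfit exceeds 1e-6")
    return curve


def relative_anomaly(curve: DecayCurve, year):
    """Relative carbonate-production anomaly (NEC(t0) - NEC(t)) / NEC(t0).

    Zero for years at or before the reference year t0; exceeds one once the
    reef transitions to net dissolution (NEC < 0).  Accepts scalars or
    arrays; years before 1850 are rejected.
    """
    yr = np.asarray(year, dtype=float)
    if np.any(yr < 1850):
        raise ValueError("year must be >= 1850")
    nec0 = curve.nec(curve.t0)
    rel = (nec0 - curve.nec(yr)) / nec0
    rel = np.where(yr <= curve.t0, 0.0, rel)
    return rel if rel.ndim else float(rel)


def anomaly_to_global_fluxes(rel, g0_tgc: float) -> tuple:
    """Convert a relative anomaly into global (alk, dic) fluxes in Pmol y-1.

    The DIC flux is rel * G0 in moles of carbon; the alkalinity flux is twice
    that, reflecting the 2:1 molar signature of CaCO3 production decline.
    """
    rel_arr = np.asarray(rel, dtype=float)
    if np.any(rel_arr < 0):
        raise ValueError("relative anomaly must be non-negative")
    if g0_tgc <= 0:
        raise ValueError("historical production G0 must be positive")
    molc_per_year = g0_tgc * 1e12 / M_C        # mol C y-1
    dic = rel_arr * molc_per_year / 1e15        # Pmol y-1
    alk = 2.0 * dic
    if rel_arr.ndim == 0:
        return float(alk), float(dic)
    return alk, dic


def tgc_to_pgcaco3(g_tgc: float) -> float:
    """Carbonate production in TgC y-1 expressed as PgCaCO3 y-1."""
    if g_tgc < 0:
        raise ValueError("production must be non-negative")
    return g_tgc * (M_CACO3 / M_C) / 1000.0


def build_scenario(spec: ScenarioSpec, anchors: NECAnchors | None = None) -> FluxSeries:
    """Compose fit -> anomaly -> flux into an annual global flux series.

    Fluxes are identically zero before the perturbation start (2005),
    follow the fitted decay curve from 2005 to 2100, and are held at their
    2100 values thereafter (production declines saturate by then and the
    fluxes are maintained until the end of the scenario).
    """
    if anchors is None:
        anchors = NECAnchors.for_rcp(spec.rcp_id)
    curve = fit_decay_curve(anchors)
    years = np.arange(spec.start_year, spec.end_year + 1)
    rel = relative_anomaly(curve, np.minimum(years, 2100))
    alk, dic = anomaly_to_global_fluxes(rel, spec.g0_tgc)
    series = FluxSeries(
        spec=spec,
        years=years,
        nec_areal=curve.nec(np.minimum(years, 2100)),
        rel_anomaly=rel,
        caco3_anomaly=dic,
        alk_flux=alk,
        dic_flux=dic,
    )
    series.validate()
    return series


def zero_flux_series(spec: ScenarioSpec) -> FluxSeries:
    """A flux series of all zeros on the same year axis (reference probe)."""
    years = np.arange(spec.start_year, spec.end_year + 1)
    z = np.zeros_like(years, dtype=float)
    return FluxSeries(
        spec=spec,
        years=years,
        nec_areal=np.full_like(z, np.nan),
        rel_anomaly=z,
        caco3_anomaly=z.copy(),
        alk_flux=2.0 * z,
        dic_flux=z.copy(),
    )
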