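"""Synthetic inputs: RCP CO2 pathways, reef-location masks, alkalinity noise.

Everything the pipeline consumes that is not printed in the scenario
definition is generated here, deterministically, with no downloads:

* annual atmospheric CO2 mole-fraction pathways for RCP2.6/4.5/8.5
  (1850-2300), built as a documented parametric approximation — monotone
  piecewise-cubic (PCHIP) interpolation through round-number anchor values
  consistent with the published RCP/ECP concentration trajectories
  (preindustrial ~285 ppm; 2100 values ~421/538/936 ppm; extensions
  declining to ~361, stabilizing at ~543 and ~1962 ppm respectively);
* random tropical reef-cell masks on a regular lat-lon grid, standing in
  for a real warm-water reef atlas;
* AR(1) interannual alkalinity variability for trend-detectability tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr
from scipy.interpolate import PchipInterpolator
from scipy.signal import lfilter

from .constants import EARTH_RADIUS_M
from .scenarios import RCP_IDS, FluxSeries

__all__ = [
    "CO2Pathway",
    "GridSpec",
    "ReefMask",
    "rcp_co2_pathway",
    "make_reef_mask",
    "grid_fluxes",
    "alkalinity_noise",
]

# Anchor years/ppm for the parametric pathways.  Historical segment is
# shared; scenario segments diverge from 2010.
_HIST_ANCHORS = (
    (1850, 285.2), (1875, 289.0), (1900, 295.7), (1925, 305.0),
    (1950, 311.3), (1975, 331.0), (1990, 354.0), (2000, 369.5), (2005, 378.8),
)
_SCENARIO_ANCHORS = {
    "RCP2.6": (
        (2010, 389.0), (2020, 412.0), (2030, 431.0), (2040, 440.0), (2050, 443.0),
        (2060, 442.0), (2070, 437.0), (2080, 432.0), (2090, 426.0), (2100, 421.0),
        (2150, 399.0), (2200, 384.0), (2250, 371.0), (2300, 361.0),
    ),
    "RCP4.5": (
        (2010, 389.0), (2020, 411.0), (2030, 435.0), (2040, 461.0), (2050, 487.0),
        (2060, 508.0), (2070, 524.0), (2080, 531.0), (2090, 535.0), (2100, 538.0),
        (2150, 543.0), (2200, 543.0), (2250, 543.0), (2300, 543.0),
    ),
    "RCP8.5": (
        (2010, 389.0), (2020, 415.0), (2030, 449.0), (2040, 489.0), (2050, 541.0),
        (2060, 611.0), (2070, 677.0), (2080, 758.0), (2090, 845.0), (2100, 936.0),
        (2150, 1429.0), (2200, 1794.0), (2250, 1962.0), (2300, 1962.0),
    ),
}


@dataclass(frozen=True)
class CO2Pathway:
    """Annual atmospheric CO2 mole fraction (ppm), 1850-2300."""

    rcp_id: str
    years: np.ndarray
    co2_ppm: np.ndarray
    provenance: str = "parametric"

    def at(self, years):
        """CO2 (ppm) at the requested integer year(s)."""
        yr = np.asarray(years)
        idx = np.searchsorted(self.years, yr)
        if np.any(idx >= self.years.size) or np.any(self.years[idx] != yr):
            raise KeyError("requested year outside pathway coverage")
        out = self.co2_ppm[idx]
        return out if out.ndim else float(out)

    def validate(self) -> None:
        if self.years[0] <= 1850 and not (280.0 <= self.co2_ppm[0] <= 290.0):
            raise AssertionError("1850 CO2 must lie in [280, 290] ppm")
        if np.any(np.diff(self.years) != 1):
            raise AssertionError("pathway must cover every year with no gaps")


def rcp_co2_pathway(rcp_id: str, start_year: int = 1850, end_year: int = 2300) -> CO2Pathway:
    """Annual CO2 pathway for one RCP from the parametric anchor fit."""
    if rcp_id not in _SCENARIO_ANCHORS:
        raise ValueError(f"unknown RCP id {rcp_id!r}; expected one of {RCP_IDS}")
    anchors = _HIST_ANCHORS + _SCENARIO_ANCHORS[rcp_id]
    ay = np.array([a[0] for a in anchors], dtype=float)
    av = np.array([a[1] for a in anchors], dtype=float)
    years = np.arange(start_year, end_year + 1)
    co2 = PchipInterpolator(ay, av)(years)
    path = CO2Pathway(rcp_id=rcp_id, years=years, co2_ppm=co2)
    path.validate()
    return path


@dataclass(frozen=True)
class GridSpec:
    """Regular lat-lon grid: cell centers, degrees north/east, 0-based indices."""

    resolution_deg: float = 2.0

    @property
    def lats(self) -> np.ndarray:
        r = self.resolution_deg
        return np.arange(-90.0 + r / 2.0, 90.0, r)

    @property
    def lons(self) -> np.ndarray:
        r = self.resolution_deg
        return np.arange(-180.0 + r / 2.0, 180.0, r)

    def cell_areas(self) -> np.ndarray:
        """Spherical cell areas (m2), shape (nlat, nlon)."""
        r = np.deg2rad(self.resolution_deg)
        lat = np.deg2rad(self.lats)
        band = EARTH_RADIUS_M**2 * r * (np.sin(lat + r / 2.0) - np.sin(lat - r / 2.0))
        return np.repeat(band[:, None], self.lons.size, axis=1)


@dataclass(frozen=True)
class ReefMask:
    """Boolean reef flag and cell areas on a regular grid (synthetic atlas)."""

    grid: GridSpec
    reef: np.ndarray      # bool, (nlat, nlon)
    areas: np.ndarray     # m2, (nlat, nlon)
    seed: int

    @property
    def total_reef_area(self) -> float:
        return float(self.areas[self.reef].sum())

    @property
    def n_cells(self) -> int:
        return int(self.reef.sum())


def make_reef_mask(
    grid: GridSpec, n_cells: int, seed: int, max_abs_lat: float = 30.0
) -> ReefMask:
    """Seed ``n_cells`` reef cells at random within the tropical band.

    A synthetic stand-in for a warm-water reef atlas: cells are drawn
    uniformly from the band |lat| <= ``max_abs_lat`` (<= 35 degrees),
    deterministically under ``seed``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if max_abs_lat > 35.0:
        raise ValueError("reef cells must stay within |lat| <= 35 degrees")
    lats = grid.lats
    tropical_rows = np.nonzero(np.abs(lats) <= max_abs_lat)[0]
    n_lon = grid.lons.size
    candidates = [(i, j) for i in tropical_rows for j in range(n_lon)]
    if n_cells > len(candidates):
        raise ValueError(f"n_cells {n_cells} exceeds tropical cell count {len(candidates)}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=n_cells, replace=False)
    reef = np.zeros((lats.size, n_lon), dtype=bool)
    for c in chosen:
        reef[candidates[c]] = True
    return ReefMask(grid=grid, reef=reef, areas=grid.cell_areas(), seed=seed)


def grid_fluxes(flux_series: FluxSeries, mask: ReefMask, year: float) -> xr.Dataset:
    """Distribute one year's global fluxes uniformly over the reef cells.

    Returns per-cell flux densities (mol m-2 yr-1) whose area-weighted sum
    reproduces the global totals to machine precision; non-reef cells are
    zero.
    """
    if mask.n_cells == 0:
        raise ValueError("reef mask is empty")
    alk_global, dic_global = flux_series.flux_at(year)   # Pmol y-1
    a_tot = mask.total_reef_area
    alk_density = np.where(mask.reef, alk_global * 1e15 / a_tot, 0.0)
    dic_density = np.where(mask.reef, dic_global * 1e15 / a_tot, 0.0)
    return xr.Dataset(
        {
            "alk_flux": (("lat", "lon"), alk_density, {"units": "mol m-2 yr-1"}),
            "dic_flux": (("lat", "lon"), dic_density, {"units": "mol m-2 yr-1"}),
            "reef_mask": (("lat", "lon"), mask.reef.astype(np.int8)),
            "cell_area": (("lat", "lon"), mask.areas, {"units": "m2"}),
        },
        coords={"lat": mask.grid.lats, "lon": mask.grid.lons},
        attrs={"year": float(year), "scenario": flux_series.spec.name},
    )


def alkalinity_noise(sigma: float, phi: float, n_years: int, seed: int) -> np.ndarray:
    """Stationary AR(1) annual alkalinity anomalies.

    x_t = phi * x_{t-1} + eps_t with innovation variance sigma^2*(1-phi^2),
    so the stationary variance equals sigma^2; the first sample is drawn
    from the stationary distribution.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if not (-1.0 < phi < 1.0):
        raise ValueError("phi must satisfy |phi| < 1")
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal(n_years) * sigma * np.sqrt(1.0 - phi * phi)
    eps[0] = rng.standard_normal() * sigma
    return lfilter([1.0], [1.0, -phi], eps)
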