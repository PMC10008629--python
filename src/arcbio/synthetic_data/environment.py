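"""Multi-year summer environment simulator with warming and sea-ice decline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from arcbio._stats import EARTH_RADIUS_KM, haversine_km, subseed_rng
from arcbio.synthetic_data.grid import Grid

#: canonical covariate names; depth and dist_coast are static, dist_ice_edge is
#: derived from SSIC each year rather than simulated directly.
VARIABLES = ("SSST", "SSIC", "SCHL", "SZOOC", "salinity", "depth", "dist_coast", "dist_ice_edge")
STATIC_VARIABLES = ("depth", "dist_coast")
DERIVED_VARIABLES = ("dist_ice_edge",)

ICE_EDGE_THRESHOLD = 15.0  # % sea ice concentration contour defining the ice edge

_BOUNDS = {
    "SSIC": (0.0, 100.0),
    "SCHL": (0.0, None),
    "SZOOC": (0.0, None),
    "salinity": (0.0, None),
}


@dataclass(frozen=True)
class VariableSpec:
    """Generator recipe for one covariate: baseline field plus linear drift and noise.

    ``trend_per_decade`` is in native units per 10 years; ``noise_sd`` is i.i.d.
    per cell-year; ``interannual_sd`` is a shared per-year offset.
    """

    baseline: np.ndarray | float
    trend_per_decade: float = 0.0
    noise_sd: float = 0.0
    interannual_sd: float = 0.0


@dataclass
class EnvStack:
    """Per-year, per-variable covariate rasters on a shared grid."""

    grid: Grid
    years: list[int]
    data: dict[str, np.ndarray]  # variable -> (n_years, n_rows, n_cols)

    def __post_init__(self) -> None:
        n = (len(self.years),) + self.grid.shape
        for var, arr in self.data.items():
            if arr.shape != n:
                raise ValueError(f"{var}: expected shape {n}, got {arr.shape}")

    @property
    def variables(self) -> list[str]:
        return list(self.data)

    def year_index(self, year: int) -> int:
        try:
            return self.years.index(int(year))
        except ValueError:
            raise KeyError(f"year {year} not in stack ({self.years[0]}..{self.years[-1]})") from None

    def layer(self, variable: str, year: int) -> np.ndarray:
        if variable not in self.data:
            raise KeyError(f"unknown variable {variable!r}")
        return self.data[variable][self.year_index(year)]

    def layers(self, year: int, variables=None) -> dict[str, np.ndarray]:
        variables = self.variables if variables is None else list(variables)
        return {v: self.layer(v, year) for v in variables}

    def extract(self, lon, lat, year, variables) -> dict[str, np.ndarray]:
        """Covariate values at point coordinates for one year (cell-resolved)."""
        row, col = self.grid.cell_index(lon, lat)
        if np.any(row < 0):
            raise ValueError("coordinates outside grid bounds")
        return {v: self.layer(v, year)[row, col] for v in variables}


def default_trend_spec(grid: Grid, warming_per_decade: float = 0.6, ice_loss_per_decade: float = -8.0,
                       noise_sd: float = 0.15, interannual_sd: float = 0.1) -> dict[str, VariableSpec]:
    """Plausible Arctic-like baselines: SST falls with latitude, ice rises with it."""
    lat = grid.lat_grid.astype(float)
    lat_min, lat_max = float(lat.min()), float(lat.max())
    frac = (lat - lat_min) / (lat_max - lat_min)  # 0 at south edge, 1 at north
    return {
        "SSST": VariableSpec(10.0 - 12.0 * frac, warming_per_decade, noise_sd, interannual_sd),
        "SSIC": VariableSpec(np.clip(140.0 * frac - 40.0, 0.0, 100.0), ice_loss_per_decade,
                             noise_sd * 10, interannual_sd * 10),
        "SCHL": VariableSpec(2.5 - 2.0 * frac, 0.15, noise_sd, interannual_sd),
        "SZOOC": VariableSpec(2.0 - 1.5 * frac, 0.12, noise_sd, interannual_sd),
        "salinity": VariableSpec(33.0 + 2.0 * frac, 0.0, noise_sd, interannual_sd),
        "depth": VariableSpec(-3000.0 + 2500.0 * np.exp(-3.0 * frac)),
        "dist_coast": VariableSpec(np.nan),  # placeholder, computed from the land mask
    }


def _distance_to_cells(grid: Grid, target_mask: np.ndarray) -> np.ndarray:
    """Min haversine distance (km) from every cell center to cells in target_mask."""
    out = np.full(grid.shape, np.inf)
    ti, tj = np.nonzero(target_mask)
    if ti.size == 0:
        return out
    tlat = grid.lat_centers[ti]
    tlon = grid.lon_centers[tj]
    lat = grid.lat_grid.reshape(-1)
    lon = grid.lon_grid.reshape(-1)
    # chunk over grid cells to bound memory on fine grids
    chunk = max(1, int(2e7) // max(1, ti.size))
    flat = np.empty(lat.size)
    for s in range(0, lat.size, chunk):
        e = min(s + chunk, lat.size)
        d = haversine_km(lon[s:e, None], lat[s:e, None], tlon[None, :], tlat[None, :])
        flat[s:e] = d.min(axis=1)
    return flat.reshape(grid.shape)


def distance_to_coast(grid: Grid) -> np.ndarray:
    """Distance (km) from each ocean cell center to the nearest land cell center."""
    if not grid.land_mask.any():
        return np.zeros(grid.shape)
    return _distance_to_cells(grid, grid.land_mask)


def ice_edge_distance(grid: Grid, ssic: np.ndarray, threshold: float = ICE_EDGE_THRESHOLD) -> np.ndarray:
    """Shortest great-circle distance to the sea-ice contour at ``threshold`` %.

    Contour cells (distance exactly 0) are ocean cells at or above the threshold
    with a 4-neighbour ocean cell below it. Degenerate years: all cells at/above
    threshold -> 0 everywhere; no cell at/above threshold -> distance to the
    northern domain edge.
    """
    ocean = grid.ocean_mask
    icy = (ssic >= threshold) & ocean
    open_water = (ssic < threshold) & ocean
    if not open_water.any():
        return np.zeros(grid.shape)
    if not icy.any():
        # ice-free fallback: meridional distance to the northern domain edge
        dlat = grid.lat_north_bound - grid.lat_grid
        return np.radians(dlat) * EARTH_RADIUS_KM

    edge = np.zeros(grid.shape, dtype=bool)
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        neighbour = np.roll(open_water, shift, axis=axis)
        # rolled values across the lat boundary are not real neighbours
        if axis == 0:
            if shift == 1:
                neighbour[0, :] = False
            else:
                neighbour[-1, :] = False
        edge |= icy & neighbour
    if not edge.any():  # icy and open water in disjoint row bands without contact
        edge = icy
    dist = _distance_to_cells(grid, edge)
    dist[edge] = 0.0
    return dist


def simulate_environment(
    grid: Grid,
    years,
    trend_spec: dict[str, VariableSpec] | None = None,
    seed: int = 0,
) -> tuple[EnvStack, dict[str, np.ndarray]]:
    """Simulate the covariate stack; returns (stack, truth) where truth maps each
    simulated variable to its imposed per-pixel trend in units/year.

    SSIC is clipped to [0, 100] after the linear signal is applied; SCHL/SZOOC/
    salinity are floored at 0. ``dist_ice_edge`` is recomputed per year from the
    SSIC field; ``dist_coast`` always comes from the land mask.
    """
    years = [int(y) for y in years]
    if len(years) < 2:
        raise ValueError("need at least 2 years")
    spec = default_trend_spec(grid) if trend_spec is None else dict(trend_spec)
    unknown = set(spec) - (set(VARIABLES) - set(DERIVED_VARIABLES))
    if unknown:
        raise ValueError(f"trend spec names unknown variable(s): {sorted(unknown)}")

    rng = subseed_rng(seed, "simulate_environment")
    n_years = len(years)
    t = np.asarray(years, dtype=float) - years[0]
    data: dict[str, np.ndarray] = {}
    truth: dict[str, np.ndarray] = {}

    for var in VARIABLES:
        if var in DERIVED_VARIABLES:
            continue
        if var == "dist_coast":
            field2d = distance_to_coast(grid)
            data[var] = np.broadcast_to(field2d, (n_years,) + grid.shape).copy()
            truth[var] = np.zeros(grid.shape)
            continue
        if var not in spec:
            continue
        vs = spec[var]
        baseline = np.broadcast_to(np.asarray(vs.baseline, dtype=float), grid.shape)
        slope = vs.trend_per_decade / 10.0
        interannual = (
            rng.normal(0.0, vs.interannual_sd, size=n_years) if vs.interannual_sd > 0 else np.zeros(n_years)
        )
        arr = baseline[None] + slope * t[:, None, None] + interannual[:, None, None]
        if vs.noise_sd > 0:
            arr = arr + rng.normal(0.0, vs.noise_sd, size=arr.shape)
        lo, hi = _BOUNDS.get(var, (None, None))
        if lo is not None or hi is not None:
            arr = np.clip(arr, lo, hi)
        data[var] = arr
        truth[var] = np.full(grid.shape, slope)

    ssic = data["SSIC"]
    data["dist_ice_edge"] = np.stack([ice_edge_distance(grid, ssic[k]) for k in range(n_years)])

    land = grid.land_mask
    for var in data:
        data[var][:, land] = np.nan

    return EnvStack(grid=grid, years=years, data=data), truth
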