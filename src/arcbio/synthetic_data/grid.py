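"""Regular lon-lat grid with marine-area regions and a southern land fringe."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from arcbio._stats import subseed_rng


@dataclass(frozen=True)
class Grid:
    """Cell-center registered lon-lat grid.

    ``region_id`` partitions ocean cells into marine areas 1..R; 0 marks cells
    outside the domain (land). ``lat_centers`` is strictly ascending (south to
    north), one entry per row.
    """

    lat_centers: np.ndarray
    lon_centers: np.ndarray
    cell_size_deg: float
    region_id: np.ndarray
    land_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.region_id.shape != self.shape or self.land_mask.shape != self.shape:
            raise ValueError("raster shape mismatch")
        if not np.all(np.diff(self.lat_centers) > 0):
            raise ValueError("lat_centers must be strictly ascending")
        if np.any((self.region_id > 0) & self.land_mask):
            raise ValueError("land cells must have region id 0")
        if np.any((self.region_id == 0) & ~self.land_mask):
            raise ValueError("every ocean cell needs a region id")

    @property
    def n_rows(self) -> int:
        return int(self.lat_centers.size)

    @property
    def n_cols(self) -> int:
        return int(self.lon_centers.size)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def ocean_mask(self) -> np.ndarray:
        return ~self.land_mask

    @property
    def n_regions(self) -> int:
        return int(self.region_id.max())

    @property
    def region_ids(self) -> np.ndarray:
        return np.arange(1, self.n_regions + 1)

    @property
    def lat_grid(self) -> np.ndarray:
        return np.broadcast_to(self.lat_centers[:, None], self.shape)

    @property
    def lon_grid(self) -> np.ndarray:
        return np.broadcast_to(self.lon_centers[None, :], self.shape)

    @property
    def lat_north_bound(self) -> float:
        return float(self.lat_centers[-1] + self.cell_size_deg / 2.0)

    def bounds(self) -> tuple[float, float, float, float]:
        """(lon_min, lon_max, lat_min, lat_max) of the outer cell edges."""
        h = self.cell_size_deg / 2.0
        return (
            float(self.lon_centers[0] - h),
            float(self.lon_centers[-1] + h),
            float(self.lat_centers[0] - h),
            float(self.lat_centers[-1] + h),
        )

    def cell_index(self, lon, lat):
        """Row/col indices for coordinate arrays; -1 where outside the grid bounds."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        lon_min, lon_max, lat_min, lat_max = self.bounds()
        inside = (lon >= lon_min) & (lon <= lon_max) & (lat >= lat_min) & (lat <= lat_max)
        row = np.floor((lat - lat_min) / self.cell_size_deg).astype(int)
        col = np.floor((lon - lon_min) / self.cell_size_deg).astype(int)
        row = np.clip(row, 0, self.n_rows - 1)
        col = np.clip(col, 0, self.n_cols - 1)
        row = np.where(inside, row, -1)
        col = np.where(inside, col, -1)
        return row, col


def make_grid(
    extent: tuple[float, float, float, float],
    cell_size_deg: float,
    n_regions: int,
    seed: int,
) -> Grid:
    """Build a grid over ``extent`` = (lon_min, lon_max, lat_min, lat_max).

    Regions are contiguous equal-width longitude sectors numbered 1..n_regions
    west to east. A southern land fringe of seeded, smoothly varying depth
    emulates the continental margin; everything else is ocean.
    """
    lon_min, lon_max, lat_min, lat_max = map(float, extent)
    if cell_size_deg <= 0:
        raise ValueError("cell_size_deg must be positive")
    if lat_max - lat_min < 10.0:
        raise ValueError("extent must span at least 10 degrees of latitude")
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")

    n_rows = int(round((lat_max - lat_min) / cell_size_deg))
    n_cols = int(round((lon_max - lon_min) / cell_size_deg))
    lat_centers = lat_min + (np.arange(n_rows) + 0.5) * cell_size_deg
    lon_centers = lon_min + (np.arange(n_cols) + 0.5) * cell_size_deg

    rng = subseed_rng(seed, "make_grid")
    base = max(1, n_rows // 20)
    depth = base + rng.integers(0, base + 1, size=n_cols)
    # smooth the fringe so the coastline is not pixel noise
    kernel = np.ones(5) / 5.0
    depth = np.rint(np.convolve(np.concatenate([depth[-2:], depth, depth[:2]]), kernel, "valid")).astype(int)
    depth = np.clip(depth, 1, max(1, n_rows // 4))
    rows = np.arange(n_rows)[:, None]
    land_mask = rows < depth[None, :]

    sector_width = (lon_max - lon_min) / n_regions
    sector = np.floor((lon_centers - lon_min) / sector_width).astype(int)
    sector = np.clip(sector, 0, n_regions - 1) + 1
    region_id = np.broadcast_to(sector[None, :], (n_rows, n_cols)).copy()
    region_id[land_mask] = 0

    return Grid(
        lat_centers=lat_centers,
        lon_centers=lon_centers,
        cell_size_deg=float(cell_size_deg),
        region_id=region_id,
        land_mask=land_mask,
    )
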