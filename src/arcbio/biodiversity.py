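"""Richness maps/trends, species-accrual detection, Sorensen beta-diversity
partition (turnover vs nestedness), and regime range-size change."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from arcbio._stats import ols_trend, pearson_r, pixelwise_ols
from arcbio.synthetic_data.grid import Grid


@dataclass
class TrendMap:
    slope: np.ndarray  # species/year
    p_value: np.ndarray
    std_err: np.ndarray
    n_years: int


@dataclass
class RangeChange:
    species_id: str
    n_loss: int
    n_gain: int
    n_stable_present: int
    n_stable_absent: int

    @property
    def direction(self) -> str:
        d = self.n_gain - self.n_loss
        return "accrual" if d > 0 else ("reduction" if d < 0 else "unchanged")

    def percentages(self) -> dict[str, float]:
        """Loss/gain/stable as % of baseline-present cells (loss + stable_present)."""
        base = self.n_loss + self.n_stable_present
        if base == 0:
            return {"loss_pct": float("nan"), "gain_pct": float("nan"), "stable_pct": float("nan")}
        return {
            "loss_pct": 100.0 * self.n_loss / base,
            "gain_pct": 100.0 * self.n_gain / base,
            "stable_pct": 100.0 * self.n_stable_present / base,
        }


def richness_stack(binaries: dict[str, np.ndarray]) -> np.ndarray:
    """Pixel-wise species count (SR) from per-species binary presence maps."""
    maps = list(binaries.values())
    if not maps:
        raise ValueError("no binary maps supplied")
    shape = maps[0].shape
    if any(m.shape != shape for m in maps):
        raise ValueError("binary maps on mixed grids")
    return np.sum([m.astype(int) for m in maps], axis=0)


def regional_mean_richness(sr: np.ndarray, grid: Grid) -> dict[int, float]:
    """Mean SR over ocean cells of each region."""
    out = {}
    for r in grid.region_ids:
        cells = grid.region_id == r
        out[int(r)] = float(sr[cells].mean()) if cells.any() else float("nan")
    return out


def richness_series_table(
    sr_by_year: dict[int, dict[str, np.ndarray]], grid: Grid
) -> pd.DataFrame:
    """Long table region x guild x year of mean SR.

    ``sr_by_year[year][guild]`` are SR rasters; guild 'all' should be included by
    the caller (richness is additive across guilds).
    """
    rows = []
    for year in sorted(sr_by_year):
        for guild, sr in sr_by_year[year].items():
            for region, mean_sr in regional_mean_richness(sr, grid).items():
                rows.append({"region": region, "guild": guild, "year": int(year), "SR": mean_sr})
    return pd.DataFrame(rows)


def richness_trend(sr_by_year: dict[int, np.ndarray]) -> TrendMap:
    """Per-pixel OLS trend of SR on year (complete-case pixels only)."""
    years = sorted(sr_by_year)
    if len(years) < 3:
        raise ValueError("need >= 3 years for a trend")
    stack = np.stack([np.asarray(sr_by_year[y], dtype=float) for y in years])
    res = pixelwise_ols(stack, np.asarray(years, dtype=float))
    return TrendMap(res["slope"], res["p_value"], res["std_err"], len(years))


def regional_trend_table(series: pd.DataFrame) -> pd.DataFrame:
    """OLS trend per region-guild on the regional mean SR series.

    Output columns: region, guild, slope_per_decade, p, adj_R2.
    """
    rows = []
    for (region, guild), g in series.groupby(["region", "guild"]):
        g = g.sort_values("year")
        tr = ols_trend(g["year"], g["SR"])
        rows.append(
            {
                "region": region,
                "guild": guild,
                "slope_per_decade": tr.slope * 10.0,
                "p": tr.p_value,
                "adj_R2": tr.adj_r_squared,
            }
        )
    return pd.DataFrame(rows)


def accrual_mask(trend: TrendMap, min_per_decade: float = 1.0) -> np.ndarray:
    """Pixels gaining at least ``min_per_decade`` species per decade (>= rule)."""
    with np.errstate(invalid="ignore"):
        return np.nan_to_num(trend.slope, nan=-np.inf) * 10.0 >= min_per_decade


def accrual_frequencies(mask: np.ndarray, grid: Grid) -> pd.DataFrame:
    """Fraction of each region's ocean cells flagged as accrual areas."""
    rows = []
    for r in grid.region_ids:
        cells = grid.region_id == r
        n = int(cells.sum())
        rows.append(
            {
                "region": int(r),
                "n_cells": n,
                "n_accrual": int((mask & cells).sum()),
                "frequency": float((mask & cells).sum() / n) if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def accrual_series(
    mask: np.ndarray,
    sr_by_year: dict[int, np.ndarray],
    grid: Grid,
    sst_anomaly: pd.DataFrame | None = None,
    low_ice_years: dict[int, set] | None = None,
) -> pd.DataFrame:
    """Annual regional mean SR over accrual cells, with optional SST-anomaly and
    low-ice annotations (the data behind the Hovmoller panels).

    ``sst_anomaly`` needs columns region, year, anomaly.
    """
    rows = []
    years = sorted(sr_by_year)
    for r in grid.region_ids:
        cells = (grid.region_id == r) & mask
        for year in years:
            mean_sr = float(sr_by_year[year][cells].mean()) if cells.any() else float("nan")
            rows.append({"region": int(r), "year": int(year), "mean_SR_accrual": mean_sr})
    table = pd.DataFrame(rows)
    if sst_anomaly is not None:
        table = table.merge(
            sst_anomaly.rename(columns={"anomaly": "sst_anomaly"})[["region", "year", "sst_anomaly"]],
            on=["region", "year"],
            how="left",
        )
    if low_ice_years is not None:
        table["ice_regime_flag"] = [
            "low" if row.year in low_ice_years.get(row.region, set()) else "high"
            for row in table.itertuples()
        ]
    return table


def accrual_sst_correlation(series: pd.DataFrame) -> pd.DataFrame:
    """Pearson r between the accrual-area SR series and SST anomaly per region."""
    rows = []
    for region, g in series.groupby("region"):
        r, p = pearson_r(g["sst_anomaly"], g["mean_SR_accrual"])
        rows.append({"region": region, "pearson_r": r, "p": p})
    return pd.DataFrame(rows)


def beta_decompose(
    stack_a: np.ndarray, stack_b: np.ndarray, species: list[str] | None = None
) -> dict[str, np.ndarray]:
    """Pairwise Sorensen dissimilarity partition per pixel.

    With a = shared species, b = only-in-A, c = only-in-B:
    beta_sor = (b+c)/(2a+b+c); beta_sim = min(b,c)/(a+min(b,c));
    beta_sne = beta_sor - beta_sim. Pixels where both communities are empty are NaN.
    Stacks are (n_species, n_rows, n_cols) booleans over the same species list.
    """
    stack_a = np.asarray(stack_a, dtype=bool)
    stack_b = np.asarray(stack_b, dtype=bool)
    if stack_a.shape != stack_b.shape:
        raise ValueError("community stacks must share shape (same species list)")
    a = (stack_a & stack_b).sum(axis=0).astype(float)
    b = (stack_a & ~stack_b).sum(axis=0).astype(float)
    c = (~stack_a & stack_b).sum(axis=0).astype(float)
    denom_sor = 2 * a + b + c
    m = np.minimum(b, c)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta_sor = np.where(denom_sor > 0, (b + c) / denom_sor, np.nan)
        beta_sim = np.where(a + m > 0, m / (a + m), np.where(denom_sor > 0, 0.0, np.nan))
        # a=0 and exactly one side occupied: complete dissimilarity is turnover-free
        only_one_side = (a == 0) & (m == 0) & (denom_sor > 0)
        beta_sim = np.where(only_one_side, 0.0, beta_sim)
    beta_sne = beta_sor - beta_sim
    return {"beta_sor": beta_sor, "beta_sim": beta_sim, "beta_sne": beta_sne}


def regime_average_binary(annual_binaries: np.ndarray, years, years_subset) -> np.ndarray:
    """Mean of annual binary maps over the chosen years, re-binarized at >= 0.5."""
    years = [int(y) for y in years]
    subset = [int(y) for y in years_subset]
    if not subset:
        raise ValueError("years_subset must be non-empty")
    missing = set(subset) - set(years)
    if missing:
        raise ValueError(f"years not in stack: {sorted(missing)}")
    idx = [years.index(y) for y in subset]
    mean = np.asarray(annual_binaries, dtype=float)[idx].mean(axis=0)
    return mean >= 0.5


def range_size_change(
    binary_a: np.ndarray, binary_b: np.ndarray, in_region: np.ndarray, species_id: str = ""
) -> tuple[RangeChange, np.ndarray]:
    """Four-way pixel classification between regimes A (baseline) and B.

    Returns the count summary and a categorical raster with codes
    0 = stable absent, 1 = loss (A only), 2 = gain (B only), 3 = stable present,
    -1 = outside region.
    """
    if binary_a.shape != binary_b.shape or binary_a.shape != in_region.shape:
        raise ValueError("rasters must share a grid")
    a = np.asarray(binary_a, dtype=bool) & in_region
    b = np.asarray(binary_b, dtype=bool) & in_region
    cat = np.full(binary_a.shape, -1, dtype=int)
    cat[in_region] = 0
    cat[a & ~b] = 1
    cat[~a & b] = 2
    cat[a & b] = 3
    change = RangeChange(
        species_id=species_id,
        n_loss=int((cat == 1).sum()),
        n_gain=int((cat == 2).sum()),
        n_stable_present=int((cat == 3).sum()),
        n_stable_absent=int((cat == 0).sum()),
    )
    return change, cat


def range_change_by_region(
    binary_a: np.ndarray, binary_b: np.ndarray, grid: Grid, species_id: str = ""
) -> pd.DataFrame:
    """Per-region gain/loss counts and direction for one species."""
    rows = []
    for r in grid.region_ids:
        cells = grid.region_id == r
        change, _ = range_size_change(binary_a, binary_b, cells, species_id)
        rows.append(
            {
                "species_id": species_id,
                "region": int(r),
                "n_loss": change.n_loss,
                "n_gain": change.n_gain,
                "n_stable_present": change.n_stable_present,
                "direction": change.direction,
            }
        )
    return pd.DataFrame(rows)
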