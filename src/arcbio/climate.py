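"""Summer anomalies, high/low sea-ice regime classification, pixel-wise
Mann-Kendall trends with Sen slopes, and >=2-of-4 climate/productivity hotspots."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as _sps

from arcbio.synthetic_data.environment import EnvStack
from arcbio.synthetic_data.grid import Grid

log = logging.getLogger(__name__)

WARMING_FLAG_THRESHOLD_C = 0.5  # SST anomaly magnitude flagged as moderate/high warming

#: hotspot variables and required trend directions
HOTSPOT_SIGNS = {"SSST": +1, "SSIC": -1, "SCHL": +1, "SZOOC": +1}

#: default decadal-magnitude bounds (|Sen slope x 10| within [lo, hi]) per variable;
#: realized bounds are scenario-dependent, so these stay configuration.
DEFAULT_HOTSPOT_BOUNDS = {
    "SSST": (0.05, 10.0),
    "SSIC": (0.5, 100.0),
    "SCHL": (0.02, 5.0),
    "SZOOC": (0.02, 5.0),
}


class MKResult(NamedTuple):
    S: float
    var_S: float
    z: float
    p: float
    sen_slope: float


@dataclass
class IceRegimes:
    low_years: dict[int, set]  # region -> years with below-climatology summer ice
    high_years: dict[int, set]
    pooled_low: set
    pooled_high: set


@dataclass
class MKTrendMap:
    variable: str
    S: np.ndarray
    var_S: np.ndarray
    z: np.ndarray
    p: np.ndarray
    sen_slope: np.ndarray


@dataclass
class HotspotMap:
    indicators: dict[str, np.ndarray]  # variable -> large-change boolean raster
    n_large: np.ndarray
    hotspot: np.ndarray
    overlap: pd.DataFrame  # region x mask percent overlap with accrual cells


def regional_summer_mean(env: EnvStack, variable: str, grid: Grid) -> pd.DataFrame:
    """Regional mean of the (already summer-aggregated) layer per year."""
    if variable not in env.data:
        raise ValueError(f"unknown variable {variable!r}")
    rows = []
    for year in env.years:
        layer = env.layer(variable, year)
        for r in grid.region_ids:
            cells = grid.region_id == r
            rows.append({"region": int(r), "year": int(year), "mean": float(np.nanmean(layer[cells]))})
    return pd.DataFrame(rows)


def summer_anomaly(
    env: EnvStack,
    variable: str,
    grid: Grid,
    climatology: dict[int, float] | int | None = None,
) -> pd.DataFrame:
    """Per region-year anomaly = regional summer mean minus the regional
    climatology mean.

    ``climatology`` is either a precomputed {region: mean} (e.g. the truth
    baseline standing in for a 30-year reference), an integer k meaning the mean
    of the first k analysis years, or None for the full-record mean. SST rows are
    flagged where the anomaly reaches the moderate/high warming magnitude
    (>= 0.5 degC).
    """
    means = regional_summer_mean(env, variable, grid)
    if climatology is None:
        climatology = len(env.years)
    if isinstance(climatology, int):
        window = set(env.years[:climatology])
        ref = means[means["year"].isin(window)].groupby("region")["mean"].mean().to_dict()
    else:
        ref = {int(r): float(v) for r, v in climatology.items()}
    out = means.copy()
    out["variable"] = variable
    out["anomaly"] = out["mean"] - out["region"].map(ref)
    if variable == "SSST":
        out["warming_flag"] = out["anomaly"] >= WARMING_FLAG_THRESHOLD_C
    return out[["region", "year", "variable", "anomaly"] + (["warming_flag"] if variable == "SSST" else [])]


def classify_ice_regimes(ssic_anomalies: pd.DataFrame) -> IceRegimes:
    """Low ice where the regional SSIC anomaly is negative, high where >= 0;
    pooled sets are the years classified the same way in every region."""
    low: dict[int, set] = {}
    high: dict[int, set] = {}
    for region, g in ssic_anomalies.groupby("region"):
        if g["year"].nunique() < 2:
            raise ValueError("need >= 2 years to classify regimes")
        low[int(region)] = set(g.loc[g["anomaly"] < 0, "year"].astype(int))
        high[int(region)] = set(g.loc[g["anomaly"] >= 0, "year"].astype(int))
        if not low[int(region)] or not high[int(region)]:
            warnings.warn(f"region {region}: one ice regime is empty", stacklevel=2)
    pooled_low = set.intersection(*low.values()) if low else set()
    pooled_high = set.intersection(*high.values()) if high else set()
    if not pooled_low or not pooled_high:
        warnings.warn("pooled regime intersection is empty; fall back to per-region analyses", stacklevel=2)
    return IceRegimes(low, high, pooled_low, pooled_high)


def mann_kendall(series) -> MKResult:
    """Mann-Kendall monotonic trend test with tie-corrected variance and Sen slope.

    S = sum over i<j of sign(x_j - x_i);
    var_S = [n(n-1)(2n+5) - sum_t t(t-1)(2t+5)] / 18 over tie groups of size t;
    z uses the +/-1 continuity correction; p is two-sided normal;
    Sen slope = median of pairwise slopes.
    """
    x = np.asarray(series, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 4:
        raise ValueError(f"Mann-Kendall needs >= 4 values, got {n}")
    i, j = np.triu_indices(n, k=1)
    diff = x[j] - x[i]
    S = float(np.sign(diff).sum())
    _, tie_counts = np.unique(x, return_counts=True)
    ties = tie_counts[tie_counts > 1]
    var_S = (n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    if S > 0:
        z = (S - 1) / np.sqrt(var_S)
    elif S < 0:
        z = (S + 1) / np.sqrt(var_S)
    else:
        z = 0.0
    p = float(2.0 * _sps.norm.sf(abs(z)))
    dt = (j - i).astype(float)
    sen = float(np.median(diff / dt))
    return MKResult(S, float(var_S), float(z), p, sen)


def mann_kendall_map(stack: np.ndarray, variable: str = "") -> MKTrendMap:
    """Vectorized per-pixel Mann-Kendall over a (n_years, n_rows, n_cols) stack.

    Pixels with any missing year are NaN in every output (complete-case).
    """
    stack = np.asarray(stack, dtype=float)
    n = stack.shape[0]
    if n < 4:
        raise ValueError("need >= 4 years")
    shape = stack.shape[1:]
    complete = np.all(np.isfinite(stack), axis=0)
    i, j = np.triu_indices(n, k=1)
    diff = stack[j] - stack[i]  # (n_pairs, rows, cols)
    S = np.sign(diff).sum(axis=0)

    # tie correction: count, per pixel, multiplicities of equal values
    sorted_vals = np.sort(stack, axis=0)
    same = np.concatenate(
        [np.ones((1,) + shape, dtype=bool), np.diff(sorted_vals, axis=0) == 0], axis=0
    )
    # run lengths of equal values per pixel
    tie_term = np.zeros(shape)
    run = np.zeros(shape)
    for k in range(n):
        run = np.where(same[k], run + 1, 1) if k else np.ones(shape)
        # when a run ends (next differs or last), add t(t-1)(2t+5) for t = run
        ends = (k == n - 1) | ~same[k + 1] if k < n - 1 else np.ones(shape, dtype=bool)
        tie_term += np.where(ends, run * (run - 1) * (2 * run + 5), 0.0)
    var_S = (n * (n - 1) * (2 * n + 5) - tie_term) / 18.0

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(S > 0, (S - 1) / np.sqrt(var_S), np.where(S < 0, (S + 1) / np.sqrt(var_S), 0.0))
    p = 2.0 * _sps.norm.sf(np.abs(z))
    dt = (j - i).astype(float)[:, None, None]
    sen = np.median(diff / dt, axis=0)
    for arr in (S, var_S, z, p, sen):
        arr[~complete] = np.nan
    return MKTrendMap(variable, S, var_S, z, p, sen)


def hotspot_map(
    trend_maps: dict[str, MKTrendMap],
    accrual: np.ndarray,
    grid: Grid,
    bounds: dict[str, tuple[float, float]] | None = None,
    p_threshold: float = 0.05,
    min_large: int = 2,
) -> HotspotMap:
    """Large-change indicator per variable (significant MK trend of the required
    sign with decadal magnitude inside the configured bounds); hotspot where at
    least ``min_large`` indicators overlap; per-region accrual overlap stats."""
    missing = set(HOTSPOT_SIGNS) - set(trend_maps)
    if missing:
        raise ValueError(f"missing trend maps for: {sorted(missing)}")
    bounds = {**DEFAULT_HOTSPOT_BOUNDS, **(bounds or {})}
    indicators = {}
    for var, sign in HOTSPOT_SIGNS.items():
        tm = trend_maps[var]
        lo, hi = bounds[var]
        decadal = tm.sen_slope * 10.0
        with np.errstate(invalid="ignore"):
            ind = (
                (tm.p < p_threshold)
                & (np.sign(decadal) == sign)
                & (np.abs(decadal) >= lo)
                & (np.abs(decadal) <= hi)
            )
        indicators[var] = np.nan_to_num(ind.astype(float), nan=0.0).astype(bool)
    n_large = np.sum([ind.astype(int) for ind in indicators.values()], axis=0)
    hotspot = n_large >= min_large

    rows = []
    masks = {"hotspot": hotspot, **indicators}
    for r in grid.region_ids:
        cells = grid.region_id == r
        n_accrual = int((accrual & cells).sum())
        for name, mask in masks.items():
            if n_accrual:
                pct = 100.0 * float((accrual & cells & mask).sum()) / n_accrual
            else:
                pct = float("nan")
            rows.append({"region": int(r), "mask": name, "percent_accrual_overlap": pct})
    return HotspotMap(indicators, n_large, hotspot, pd.DataFrame(rows))
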