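"""Shared numeric utilities: great-circle distance, seeded RNG derivation, OLS trends."""

from __future__ import annotations

import zlib
from typing import NamedTuple

import numpy as np
from scipy import stats as _sps

EARTH_RADIUS_KM = 6371.0
KM_PER_DEG_LAT = float(np.pi * EARTH_RADIUS_KM / 180.0)  # ~111.19


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points in decimal degrees (broadcasting)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def pairwise_haversine_km(lon, lat):
    """Symmetric distance matrix (km) for vectors of coordinates in degrees."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    return haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])


def subseed_rng(master_seed: int, *names: str) -> np.random.Generator:
    """Derive a named child generator from a master seed.

    Every stochastic operation in the package draws from a child stream keyed by a
    stable string, so a single master seed reproduces the full pipeline bitwise.
    """
    keys = [zlib.crc32(str(n).encode("utf8")) for n in names]
    return np.random.default_rng(np.random.SeedSequence([int(master_seed) & 0xFFFFFFFF, *keys]))


class OLSTrend(NamedTuple):
    slope: float
    intercept: float
    p_value: float
    r_squared: float
    adj_r_squared: float
    std_err: float


def ols_trend(x, y) -> OLSTrend:
    """Simple linear regression with two-sided slope p-value and adjusted R^2.

    adj R^2 = 1 - (1 - R^2) (n - 1) / (n - 2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 finite observations, got {n}")
    res = _sps.linregress(x, y)
    r2 = res.rvalue**2
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return OLSTrend(res.slope, res.intercept, res.pvalue, r2, adj, res.stderr)


def pixelwise_ols(stack: np.ndarray, x) -> dict[str, np.ndarray]:
    """Per-pixel OLS of ``stack[t, i, j]`` on ``x[t]`` (complete-case only).

    Pixels with any missing (NaN) year are returned as NaN in every output.
    Returns slope, intercept, p_value, std_err rasters.
    """
    stack = np.asarray(stack, dtype=float)
    x = np.asarray(x, dtype=float)
    n = x.size
    if stack.shape[0] != n:
        raise ValueError("time axis length mismatch")
    if n < 3:
        raise ValueError("need >= 3 time steps")
    complete = np.all(np.isfinite(stack), axis=0)
    xm = x - x.mean()
    sxx = float(np.sum(xm**2))
    ymean = stack.mean(axis=0)
    slope = np.tensordot(xm, stack, axes=(0, 0)) / sxx
    intercept = ymean - slope * x.mean()
    resid = stack - (intercept[None] + slope[None] * x[:, None, None])
    sse = np.sum(resid**2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mse = sse / (n - 2)
        se = np.sqrt(mse / sxx)
        t = np.where(se > 0, slope / se, np.where(slope == 0, 0.0, np.inf))
    p = 2.0 * _sps.t.sf(np.abs(t), df=n - 2)
    for arr in (slope, intercept, p, se):
        arr[~complete] = np.nan
    return {"slope": slope, "intercept": intercept, "p_value": p, "std_err": se}


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation with two-sided p; (nan, nan) when either side is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r, p = _sps.pearsonr(x, y)
    return float(r), float(p)
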