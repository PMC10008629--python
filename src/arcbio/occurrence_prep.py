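"""Occurrence cleaning, distance-based spatial thinning, and two-round pseudo-absence
selection (buffered random sampling, then environmental profiling)."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from arcbio._stats import haversine_km, pairwise_haversine_km, subseed_rng
from arcbio.synthetic_data.environment import EnvStack
from arcbio.synthetic_data.grid import Grid

log = logging.getLogger(__name__)

TRAINING_BASE_COLUMNS = ["species_id", "year", "longitude", "latitude", "label"]
PRESENCE = "presence"
PSEUDO_ABSENCE = "pseudo_absence"


class NoEligibleCellsError(RuntimeError):
    """Raised when the pseudo-absence candidate pool is empty."""


@dataclass(frozen=True)
class EnvProfile:
    """Occupied [min, max] covariate ranges pooled over all presence rows."""

    ranges: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for var, (lo, hi) in self.ranges.items():
            if lo > hi:
                raise ValueError(f"{var}: min > max")

    @property
    def variables(self) -> list[str]:
        return list(self.ranges)

    def inside_all(self, values: dict[str, np.ndarray]) -> np.ndarray:
        """True where every profiled variable falls inside its occupied range."""
        inside = None
        for var, (lo, hi) in self.ranges.items():
            v = np.asarray(values[var], dtype=float)
            this = (v >= lo) & (v <= hi)
            inside = this if inside is None else inside & this
        return inside


def clean_occurrences(raw: pd.DataFrame, grid: Grid) -> pd.DataFrame:
    """Drop exact coordinate duplicates (per species-year), land records, and
    records outside the grid bounds. Empty input passes through."""
    if raw.empty:
        return raw.copy()
    n0 = len(raw)
    occ = raw.drop_duplicates(subset=["species_id", "longitude", "latitude", "year"], keep="first")
    row, col = grid.cell_index(occ["longitude"].to_numpy(), occ["latitude"].to_numpy())
    inside = row >= 0
    at_sea = np.zeros(len(occ), dtype=bool)
    at_sea[inside] = ~grid.land_mask[row[inside], col[inside]]
    occ = occ.loc[inside & at_sea].reset_index(drop=True)
    log.info("clean_occurrences: %d -> %d rows (%d dropped)", n0, len(occ), n0 - len(occ))
    return occ


def _thin_once(dist: np.ndarray, thin_km: float, rng: np.random.Generator) -> np.ndarray:
    """One randomized thinning run on a distance matrix; returns kept indices.

    Iteratively removes the point with the most neighbours closer than thin_km,
    breaking ties uniformly at random, until no violating pair remains.
    """
    n = dist.shape[0]
    close = (dist < thin_km)
    np.fill_diagonal(close, False)
    alive = np.ones(n, dtype=bool)
    counts = close.sum(axis=1)
    while True:
        counts_alive = np.where(alive, counts, -1)
        worst = counts_alive.max()
        if worst <= 0:
            break
        candidates = np.nonzero(counts_alive == worst)[0]
        drop = int(rng.choice(candidates))
        alive[drop] = False
        counts[close[drop]] -= 1
    return np.nonzero(alive)[0]


def thin_occurrences(
    occ: pd.DataFrame, thin_km: float, n_reps: int = 10, seed: int = 0
) -> pd.DataFrame:
    """Spatially thin records per species-year so that no two retained records are
    closer than ``thin_km`` great-circle km; keeps the largest of ``n_reps``
    randomized runs (first on ties). Deterministic for a fixed seed."""
    if thin_km <= 0:
        raise ValueError("thin_km must be positive")
    if occ.empty:
        return occ.copy()
    kept_parts = []
    for (sp, year), group in occ.groupby(["species_id", "year"], sort=True):
        if len(group) == 1:
            kept_parts.append(group)
            continue
        dist = pairwise_haversine_km(group["longitude"].to_numpy(), group["latitude"].to_numpy())
        best = None
        for rep in range(n_reps):
            rng = subseed_rng(seed, "thin", str(sp), str(year), str(rep))
            kept = _thin_once(dist, thin_km, rng)
            if best is None or kept.size > best.size:
                best = kept
        kept_parts.append(group.iloc[best])
    out = pd.concat(kept_parts).sort_index().reset_index(drop=True)
    log.info("thin_occurrences(%g km): %d -> %d rows", thin_km, len(occ), len(out))
    return out


def build_env_profile(presences: pd.DataFrame, variables) -> EnvProfile:
    """Per-variable [min, max] over pooled presence rows (all years together)."""
    variables = list(variables)
    if presences.empty:
        raise ValueError("cannot profile zero presence rows")
    missing = [v for v in variables if v not in presences.columns]
    if missing:
        raise ValueError(f"presence rows lack covariates: {missing}")
    vals = presences[variables].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("presence covariates contain missing values")
    return EnvProfile({v: (float(presences[v].min()), float(presences[v].max())) for v in variables})


def extract_covariates(df: pd.DataFrame, env: EnvStack, variables) -> pd.DataFrame:
    """Append covariate columns (cell-resolved, per row's year) to a point table."""
    out = df.copy()
    for var in variables:
        out[var] = np.nan
    for year, idx in df.groupby("year").groups.items():
        sub = df.loc[idx]
        vals = env.extract(sub["longitude"].to_numpy(), sub["latitude"].to_numpy(), int(year), variables)
        for var in variables:
            out.loc[idx, var] = vals[var]
    return out


def sample_pseudoabsences(
    grid: Grid,
    env: EnvStack,
    presences: pd.DataFrame,
    year: int,
    n_target: int,
    buffer_km: float = 100.0,
    mode: str = "random",
    profile: EnvProfile | None = None,
    seed: int = 0,
    variables=None,
    species_id: str | None = None,
    require_all_outside: bool = False,
) -> pd.DataFrame:
    """Draw pseudo-absence rows for one species-year at ocean cell centers.

    Candidate cells exclude everything within ``buffer_km`` of that year's
    presences. ``mode='profiled'`` additionally drops cells whose covariates lie
    inside the occupied range on ALL profiled variables (i.e. a cell stays
    eligible if at least one profiled variable is outside its range; set
    ``require_all_outside=True`` for the stricter reading). Sampling is without
    replacement; if the pool is smaller than ``n_target`` the whole pool is
    returned with a warning.
    """
    if mode not in ("random", "profiled"):
        raise ValueError("mode must be 'random' or 'profiled'")
    if mode == "profiled" and profile is None:
        raise ValueError("profiled mode requires an EnvProfile")
    variables = list(variables) if variables is not None else (profile.variables if profile else [])
    if species_id is None:
        species_id = str(presences["species_id"].iloc[0]) if len(presences) else "unknown"

    pres_year = presences[presences["year"] == year]
    candidate = grid.ocean_mask.copy()
    rows, cols = np.nonzero(candidate)
    lat = grid.lat_centers[rows]
    lon = grid.lon_centers[cols]

    if len(pres_year):
        d = haversine_km(
            lon[:, None], lat[:, None],
            pres_year["longitude"].to_numpy()[None, :], pres_year["latitude"].to_numpy()[None, :],
        )
        outside_buffer = d.min(axis=1) > buffer_km
    else:
        outside_buffer = np.ones(rows.size, dtype=bool)

    eligible = outside_buffer
    if mode == "profiled":
        values = {v: env.layer(v, year)[rows, cols] for v in profile.variables}
        inside_all = profile.inside_all(values)
        if require_all_outside:
            outside_any_var = None
            for var, (lo, hi) in profile.ranges.items():
                v = values[var]
                out_v = (v < lo) | (v > hi)
                outside_any_var = out_v if outside_any_var is None else outside_any_var & out_v
            eligible = eligible & outside_any_var
        else:
            eligible = eligible & ~inside_all
        finite = np.ones(rows.size, dtype=bool)
        for v in profile.variables:
            finite &= np.isfinite(values[v])
        eligible &= finite

    pool = np.nonzero(eligible)[0]
    if pool.size == 0:
        raise NoEligibleCellsError(
            f"{species_id} year {year}: no eligible cells for pseudo-absences (mode={mode})"
        )
    n = min(int(n_target), pool.size)
    if n < n_target:
        warnings.warn(
            f"{species_id} year {year}: eligible pool ({pool.size}) smaller than target ({n_target})",
            stacklevel=2,
        )
    rng = subseed_rng(seed, "pseudoabsence", species_id, str(year), mode)
    chosen = rng.choice(pool, size=n, replace=False)
    out = pd.DataFrame(
        {
            "species_id": species_id,
            "year": int(year),
            "longitude": lon[chosen],
            "latitude": lat[chosen],
            "label": PSEUDO_ABSENCE,
        }
    )
    if variables:
        out = extract_covariates(out, env, variables)
    return out


def build_training_set(
    species_id: str,
    presences: pd.DataFrame,
    grid: Grid,
    env: EnvStack,
    variables,
    n_target_per_year: int,
    buffer_km: float = 100.0,
    mode: str = "random",
    profile: EnvProfile | None = None,
    seed: int = 0,
    require_all_outside: bool = False,
) -> pd.DataFrame:
    """Presences plus per-year pseudo-absences, with covariates, as one table."""
    variables = list(variables)
    pres = presences[presences["species_id"] == species_id].copy()
    if pres.empty:
        raise ValueError(f"no presences for {species_id}")
    pres = extract_covariates(pres, env, variables)
    pres["label"] = PRESENCE
    parts = [pres[TRAINING_BASE_COLUMNS + variables]]
    for year in sorted(pres["year"].unique()):
        pa = sample_pseudoabsences(
            grid, env, pres, int(year), n_target_per_year, buffer_km=buffer_km,
            mode=mode, profile=profile, seed=seed, variables=variables,
            species_id=species_id, require_all_outside=require_all_outside,
        )
        parts.append(pa[TRAINING_BASE_COLUMNS + variables])
    out = pd.concat(parts, ignore_index=True)
    return out.dropna(subset=variables).reset_index(drop=True)


def thinning_report(before: pd.DataFrame, after: pd.DataFrame, thin_km: float, n_reps: int, seed: int) -> dict:
    return {
        "rows_before": int(len(before)),
        "rows_after": int(len(after)),
        "thin_km": float(thin_km),
        "n_reps": int(n_reps),
        "seed": int(seed),
    }
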