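"""Virtual species with Gaussian-product niches and biased presence-only sampling."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from arcbio._stats import KM_PER_DEG_LAT, subseed_rng
from arcbio.synthetic_data.environment import EnvStack
from arcbio.synthetic_data.grid import Grid

OCCURRENCE_COLUMNS = ["species_id", "guild", "longitude", "latitude", "year", "source"]

GUILDS = ("apex", "meso")

#: guild defaults: apex predators are wider-ranging — broader thermal breadth and
#: larger annual range-front displacement capacity than mesopredators.
GUILD_DEFAULTS = {
    "apex": {"breadth_scale": 1.6, "mobility_km_per_year": 250.0, "prevalence_target": 0.25},
    "meso": {"breadth_scale": 1.0, "mobility_km_per_year": 60.0, "prevalence_target": 0.2},
}


class NoSamplableCellsError(RuntimeError):
    """Raised when every candidate cell has zero sampling weight."""


@dataclass(frozen=True)
class NicheResponse:
    optimum: float
    breadth: float

    def __post_init__(self) -> None:
        if self.breadth <= 0:
            raise ValueError("breadth must be positive")

    def component(self, x):
        """Gaussian response in [0, 1]: exp(-((x - optimum) / breadth)^2 / 2)."""
        x = np.asarray(x, dtype=float)
        return np.exp(-0.5 * ((x - self.optimum) / self.breadth) ** 2)


@dataclass(frozen=True)
class VirtualSpecies:
    species_id: str
    guild: str
    response: dict[str, NicheResponse]
    prevalence_target: float
    allowed_regions: frozenset[int]
    mobility_km_per_year: float

    def __post_init__(self) -> None:
        if not self.response:
            raise ValueError("niche must use at least one variable")
        if not self.allowed_regions:
            raise ValueError("allowed_regions must be non-empty")
        if not 0 < self.prevalence_target < 1:
            raise ValueError("prevalence_target must be in (0, 1)")

    def suitability(self, layers: dict[str, np.ndarray]) -> np.ndarray:
        """Product-of-Gaussians suitability in [0, 1]; pure function of the inputs."""
        out = None
        for var, resp in self.response.items():
            comp = resp.component(layers[var])
            out = comp if out is None else out * comp
        return out


def define_virtual_species(
    guild: str,
    niche_spec: dict[str, tuple[float, float]],
    seed: int = 0,
    species_id: str | None = None,
    prevalence_target: float | None = None,
    allowed_regions=None,
    mobility_km_per_year: float | None = None,
) -> VirtualSpecies:
    """Build a species from per-variable (optimum, breadth) pairs.

    Guild defaults make apex species broader-niched and more mobile than meso
    species; explicit arguments override them. Breadths in ``niche_spec`` are
    scaled by the guild's breadth factor.
    """
    if guild not in GUILDS:
        raise ValueError(f"guild must be one of {GUILDS}")
    if not niche_spec:
        raise ValueError("niche_spec must not be empty")
    defaults = GUILD_DEFAULTS[guild]
    rng = subseed_rng(seed, "define_virtual_species", guild)
    if species_id is None:
        species_id = f"{guild}_{rng.integers(0, 10**6):06d}"
    response = {
        var: NicheResponse(float(opt), float(br) * defaults["breadth_scale"])
        for var, (opt, br) in niche_spec.items()
    }
    return VirtualSpecies(
        species_id=species_id,
        guild=guild,
        response=response,
        prevalence_target=float(defaults["prevalence_target"] if prevalence_target is None else prevalence_target),
        allowed_regions=frozenset(int(r) for r in (allowed_regions or [])) or frozenset({1}),
        mobility_km_per_year=float(defaults["mobility_km_per_year"] if mobility_km_per_year is None else mobility_km_per_year),
    )


def occupancy_map(
    species: VirtualSpecies,
    env: EnvStack,
    year: int,
    baseline_front_lat: float | None = None,
) -> np.ndarray:
    """Truth occupancy: suitability thresholded at the quantile hitting the
    prevalence target within the species' allowed regions.

    When ``baseline_front_lat`` is given, poleward expansion is capped at
    ``mobility_km_per_year`` per elapsed year beyond that latitude front.
    """
    grid = env.grid
    layers = env.layers(year, list(species.response))
    suit = species.suitability(layers)
    allowed = np.isin(grid.region_id, list(species.allowed_regions))
    candidate = allowed & grid.ocean_mask & np.isfinite(suit)
    occ = np.zeros(grid.shape, dtype=bool)
    if not candidate.any():
        return occ
    vals = suit[candidate]
    thr = np.quantile(vals, 1.0 - species.prevalence_target)
    occ[candidate] = suit[candidate] >= thr
    if baseline_front_lat is not None:
        elapsed = year - env.years[0]
        max_lat = baseline_front_lat + species.mobility_km_per_year * elapsed / KM_PER_DEG_LAT
        occ &= grid.lat_grid <= max_lat
    return occ


def range_front_latitude(occ: np.ndarray, grid: Grid) -> float:
    """Northernmost occupied cell-center latitude (the poleward range front)."""
    rows = np.nonzero(occ.any(axis=1))[0]
    return float(grid.lat_centers[rows[-1]]) if rows.size else float(grid.lat_centers[0])


def sample_occurrences(
    species: VirtualSpecies,
    env: EnvStack,
    year: int,
    n_samples: int,
    bias_field: np.ndarray | None = None,
    seed: int = 0,
    baseline_front_lat: float | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw presence-only records with sampling probability proportional to
    suitability x occupancy x bias; points are jittered uniformly within cells.

    Returns (occurrence table, truth occupancy raster).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    grid = env.grid
    if bias_field is None:
        bias_field = np.ones(grid.shape)
    bias_field = np.asarray(bias_field, dtype=float)
    if bias_field.shape != grid.shape or np.any(bias_field < 0):
        raise ValueError("bias_field must be a non-negative raster on the grid")

    occ = occupancy_map(species, env, year, baseline_front_lat=baseline_front_lat)
    suit = species.suitability(env.layers(year, list(species.response)))
    weights = np.where(occ, np.nan_to_num(suit) * bias_field, 0.0)
    total = weights.sum()
    if total <= 0:
        raise NoSamplableCellsError(
            f"{species.species_id} year {year}: no samplable cells (all weights zero)"
        )

    rng = subseed_rng(seed, "sample_occurrences", species.species_id, str(year))
    flat_p = (weights / total).reshape(-1)
    cells = rng.choice(flat_p.size, size=int(n_samples), p=flat_p)
    rows, cols = np.unravel_index(cells, grid.shape)
    h = grid.cell_size_deg / 2.0
    lon = grid.lon_centers[cols] + rng.uniform(-h, h, size=cells.size)
    lat = grid.lat_centers[rows] + rng.uniform(-h, h, size=cells.size)
    table = pd.DataFrame(
        {
            "species_id": species.species_id,
            "guild": species.guild,
            "longitude": lon,
            "latitude": lat,
            "year": int(year),
            "source": "synthetic",
        }
    )[OCCURRENCE_COLUMNS]
    return table, occ
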