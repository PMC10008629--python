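"""Turn-key synthetic scenario: grid + environment + guild-structured species + sampling."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from arcbio._stats import subseed_rng
from arcbio.synthetic_data.environment import EnvStack, simulate_environment
from arcbio.synthetic_data.grid import Grid, make_grid
from arcbio.synthetic_data.species import (
    OCCURRENCE_COLUMNS,
    VirtualSpecies,
    define_virtual_species,
    occupancy_map,
    range_front_latitude,
    sample_occurrences,
)

DEFAULT_EXTENT = (-180.0, 180.0, 50.0, 90.0)
DEFAULT_YEARS = tuple(range(2000, 2020))

#: covariates virtual niches are built on (all responsive to the warming signal)
NICHE_VARIABLES = ("SSST", "SSIC", "depth")


@dataclass
class Scenario:
    grid: Grid
    env: EnvStack
    truth_trends: dict[str, np.ndarray]
    species: list[VirtualSpecies]
    occurrences: pd.DataFrame
    truth_occupancy: dict[str, np.ndarray]  # species_id -> (n_years, n_rows, n_cols) bool
    bias_field: np.ndarray

    @property
    def guilds(self) -> dict[str, str]:
        return {sp.species_id: sp.guild for sp in self.species}


def _draw_species(rng: np.random.Generator, guild: str, index: int, n_regions: int, seed: int) -> VirtualSpecies:
    # thermal optimum spans cold Arctic to boreal-influx affinities
    sst_opt = float(rng.uniform(-1.0, 7.0))
    sst_breadth = float(rng.uniform(1.8, 2.8))
    ice_opt = float(rng.uniform(0.0, 50.0))
    ice_breadth = float(rng.uniform(30.0, 60.0))
    depth_opt = float(rng.uniform(-2500.0, -200.0))
    depth_breadth = float(rng.uniform(900.0, 1800.0))
    niche = {
        "SSST": (sst_opt, sst_breadth),
        "SSIC": (ice_opt, ice_breadth),
        "depth": (depth_opt, depth_breadth),
    }
    # most species range over the whole domain; a third get a contiguous sector subset
    if rng.uniform() < 0.33 and n_regions > 2:
        width = int(rng.integers(max(2, n_regions // 2), n_regions))
        start = int(rng.integers(1, n_regions - width + 2))
        allowed = range(start, start + width)
    else:
        allowed = range(1, n_regions + 1)
    return define_virtual_species(
        guild,
        niche,
        seed=seed + index,
        species_id=f"{guild}{index:02d}",
        allowed_regions=allowed,
    )


def build_scenario(
    seed: int = 0,
    extent: tuple[float, float, float, float] = DEFAULT_EXTENT,
    cell_size_deg: float = 1.0,
    years=DEFAULT_YEARS,
    n_regions: int = 8,
    n_apex: int = 4,
    n_meso: int = 8,
    n_samples_per_year: int = 80,
    trend_spec=None,
    coastal_bias_scale_km: float = 800.0,
) -> Scenario:
    """Generate the full synthetic input set from one master seed.

    Occurrence sampling effort decays exponentially with distance to coast,
    emulating ship-based survey bias. Poleward expansion of each species is
    capped by its guild mobility from the first-year range front.
    """
    grid = make_grid(extent, cell_size_deg, n_regions, seed)
    env, truth_trends = simulate_environment(grid, years, trend_spec=trend_spec, seed=seed)

    rng = subseed_rng(seed, "scenario_species")
    species = [_draw_species(rng, "apex", i + 1, n_regions, seed) for i in range(n_apex)]
    species += [_draw_species(rng, "meso", i + 1, n_regions, seed) for i in range(n_meso)]

    dist_coast = np.nan_to_num(env.data["dist_coast"][0], nan=0.0)
    bias = np.exp(-dist_coast / coastal_bias_scale_km)
    bias[grid.land_mask] = 0.0

    tables = []
    truth_occupancy: dict[str, np.ndarray] = {}
    for sp in species:
        occ0 = occupancy_map(sp, env, env.years[0])
        front = range_front_latitude(occ0, grid)
        occ_stack = np.zeros((len(env.years),) + grid.shape, dtype=bool)
        for k, year in enumerate(env.years):
            table, occ = sample_occurrences(
                sp, env, year, n_samples_per_year, bias_field=bias, seed=seed, baseline_front_lat=front
            )
            occ_stack[k] = occ
            tables.append(table)
        truth_occupancy[sp.species_id] = occ_stack

    occurrences = pd.concat(tables, ignore_index=True)[OCCURRENCE_COLUMNS]
    return Scenario(
        grid=grid,
        env=env,
        truth_trends=truth_trends,
        species=species,
        occurrences=occurrences,
        truth_occupancy=truth_occupancy,
        bias_field=bias,
    )
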