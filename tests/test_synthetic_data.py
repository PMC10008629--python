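import math

import numpy as np
import pandas as pd
import pytest

from arcbio._stats import EARTH_RADIUS_KM, pixelwise_ols, subseed_rng
from arcbio.synthetic_data.environment import (
    VariableSpec,
    ice_edge_distance,
    simulate_environment,
)
from arcbio.synthetic_data.grid import make_grid
from arcbio.synthetic_data.species import (
    GUILD_DEFAULTS,
    NicheResponse,
    NoSamplableCellsError,
    VirtualSpecies,
    define_virtual_species,
    occupancy_map,
    sample_occurrences,
)
from tests.conftest import noise_free_spec


class TestMakeGrid:
    def test_standard_domain(self):
        grid = make_grid((-180, 180, 50, 90), 1.0, 8, seed=0)
        assert grid.shape == (40, 360)
        assert grid.n_regions == 8
        # each region is a contiguous 45-degree longitude sector
        for r in range(1, 9):
            cols = np.nonzero((grid.region_id == r).any(axis=0))[0]
            assert cols.size == 45
            assert np.all(np.diff(cols) == 1)

    def test_single_region(self, small_grid):
        grid = make_grid((-180, 180, 50, 90), 5.0, 1, seed=0)
        assert set(np.unique(grid.region_id[grid.ocean_mask])) == {1}

    def test_determinism(self):
        a = make_grid((-180, 180, 50, 90), 2.0, 8, seed=11)
        b = make_grid((-180, 180, 50, 90), 2.0, 8, seed=11)
        assert np.array_equal(a.region_id, b.region_id)
        assert np.array_equal(a.land_mask, b.land_mask)

    def test_invalid_cell_size(self):
        with pytest.raises(ValueError):
            make_grid((-180, 180, 50, 90), 0.0, 8, seed=0)

    def test_region_partition_invariant(self, small_grid):
        # every ocean cell has exactly one region id 1..R; land is 0
        assert np.all(small_grid.region_id[small_grid.ocean_mask] >= 1)
        assert np.all(small_grid.region_id[small_grid.ocean_mask] <= small_grid.n_regions)
        assert np.all(small_grid.region_id[small_grid.land_mask] == 0)
        assert np.all(np.diff(small_grid.lat_centers) > 0)

    def test_cell_index_roundtrip(self, small_grid):
        row, col = small_grid.cell_index(small_grid.lon_centers[3], small_grid.lat_centers[2])
        assert (row, col) == (2, 3)
        row, _ = small_grid.cell_index(0.0, 49.0)
        assert row == -1


class TestSimulateEnvironment:
    def test_trend_recovery_noise_free(self, small_grid):
        env, truth = simulate_environment(
            small_grid, range(2000, 2020), trend_spec=noise_free_spec(small_grid), seed=1
        )
        res = pixelwise_ols(env.data["SSST"], np.asarray(env.years, dtype=float))
        ocean = small_grid.ocean_mask
        assert np.allclose(res["slope"][ocean], truth["SSST"][ocean], atol=1e-10)

    def test_ssic_decline_slope(self, small_grid):
        env, _ = simulate_environment(
            small_grid, range(2000, 2020), trend_spec=noise_free_spec(small_grid, ssic_trend=-10.0), seed=1
        )
        res = pixelwise_ols(env.data["SSIC"], np.asarray(env.years, dtype=float))
        # away from the clip boundaries the imposed -1 %/yr is recovered
        interior = (env.data["SSIC"][0] > 25) & (env.data["SSIC"][-1] > 5) & small_grid.ocean_mask
        assert interior.any()
        assert np.allclose(res["slope"][interior], -1.0, atol=1e-8)

    def test_bounds_and_static_variables(self, small_env, small_grid):
        ocean = small_grid.ocean_mask
        assert np.nanmin(small_env.data["SSIC"]) >= 0
        assert np.nanmax(small_env.data["SSIC"]) <= 100
        assert np.nanmin(small_env.data["SCHL"]) >= 0
        assert np.nanmin(small_env.data["SZOOC"]) >= 0
        for var in ("depth", "dist_coast"):
            stack = small_env.data[var]
            assert np.allclose(stack[0][ocean], stack[-1][ocean])

    def test_unknown_variable_rejected(self, small_grid):
        spec = noise_free_spec(small_grid)
        spec["XXX"] = VariableSpec(0.0)
        with pytest.raises(ValueError, match="unknown variable"):
            simulate_environment(small_grid, range(2000, 2005), trend_spec=spec, seed=0)

    def test_needs_two_years(self, small_grid):
        with pytest.raises(ValueError):
            simulate_environment(small_grid, [2000], seed=0)

    def test_ice_edge_all_ice(self, small_grid):
        dist = ice_edge_distance(small_grid, np.full(small_grid.shape, 100.0))
        assert np.all(dist == 0.0)

    def test_ice_edge_ice_free(self, small_grid):
        dist = ice_edge_distance(small_grid, np.zeros(small_grid.shape))
        expected = np.radians(small_grid.lat_north_bound - small_grid.lat_grid) * EARTH_RADIUS_KM
        assert np.allclose(dist, expected)

    def test_ice_edge_zero_on_contour(self, small_env, small_grid):
        ssic = small_env.data["SSIC"][0]
        dist = small_env.data["dist_ice_edge"][0]
        ocean = small_grid.ocean_mask
        icy = (ssic >= 15) & ocean
        below = (ssic < 15) & ocean
        if icy.any() and below.any():
            # contour cells (icy with an open-water 4-neighbour) sit at distance 0
            contour = dist == 0
            assert np.all(icy[contour & ocean])
            assert np.all(dist[ocean & np.isfinite(dist)] >= 0)


class TestVirtualSpecies:
    def test_gaussian_at_optimum(self):
        resp = NicheResponse(optimum=4.0, breadth=2.0)
        assert resp.component(4.0) == pytest.approx(1.0)

    def test_gaussian_at_one_breadth(self):
        resp = NicheResponse(optimum=4.0, breadth=2.0)
        assert resp.component(6.0) == pytest.approx(math.exp(-0.5), abs=1e-12)

    def test_two_variable_product(self):
        sp = define_virtual_species("meso", {"SSST": (4.0, 2.0), "depth": (-500.0, 300.0)}, seed=0)
        suit = sp.suitability({"SSST": np.array([4.0]), "depth": np.array([-500.0])})
        assert suit[0] == pytest.approx(1.0)

    def test_guild_defaults(self):
        apex = define_virtual_species("apex", {"SSST": (4.0, 2.0)}, seed=0)
        meso = define_virtual_species("meso", {"SSST": (4.0, 2.0)}, seed=0)
        assert apex.response["SSST"].breadth > meso.response["SSST"].breadth
        assert apex.mobility_km_per_year > meso.mobility_km_per_year

    def test_empty_niche_rejected(self):
        with pytest.raises(ValueError):
            define_virtual_species("apex", {}, seed=0)

    def test_breadth_positive(self):
        with pytest.raises(ValueError):
            NicheResponse(optimum=0.0, breadth=0.0)

    def test_suitability_pure(self, small_env):
        sp = define_virtual_species("meso", {"SSST": (2.0, 2.0)}, seed=3)
        layers = small_env.layers(2000, ["SSST"])
        a = sp.suitability(layers)
        b = sp.suitability(layers)
        assert np.array_equal(a, b, equal_nan=True)


def _one_cell_species(grid, env):
    """Species whose occupancy truth is a single cell (highest-SSST cell)."""
    opt = float(np.nanmax(env.layer("SSST", 2000)))
    return VirtualSpecies(
        species_id="sp1",
        guild="meso",
        response={"SSST": NicheResponse(opt, 1.0)},
        prevalence_target=1.0 / int(grid.ocean_mask.sum()),
        allowed_regions=frozenset(grid.region_ids.tolist()),
        mobility_km_per_year=1000.0,
    )


class TestSampleOccurrences:
    def test_degenerate_single_cell(self, small_grid):
        # noisy environment -> unique per-cell SST values -> single-cell occupancy
        env, _ = simulate_environment(small_grid, range(2000, 2004), seed=13)
        sp = _one_cell_species(small_grid, env)
        table, occ = sample_occurrences(sp, env, 2000, 50, seed=5)
        assert occ.sum() == 1
        r, c = np.nonzero(occ)
        row, col = small_grid.cell_index(table["longitude"].to_numpy(), table["latitude"].to_numpy())
        assert np.all(row == r[0]) and np.all(col == c[0])

    def test_zero_bias_region_excluded(self, small_env, small_grid):
        sp = define_virtual_species(
            "meso", {"SSST": (0.0, 6.0)}, seed=1, allowed_regions=small_grid.region_ids.tolist(),
            prevalence_target=0.5,
        )
        bias = np.ones(small_grid.shape)
        bias[small_grid.region_id == 3] = 0.0
        table, _ = sample_occurrences(sp, small_env, 2001, 300, bias_field=bias, seed=2)
        row, col = small_grid.cell_index(table["longitude"].to_numpy(), table["latitude"].to_numpy())
        assert not np.any(small_grid.region_id[row, col] == 3)

    def test_determinism(self, small_env, small_grid):
        sp = define_virtual_species(
            "apex", {"SSST": (0.0, 6.0)}, seed=1, allowed_regions=small_grid.region_ids.tolist()
        )
        a, _ = sample_occurrences(sp, small_env, 2002, 500, seed=9)
        b, _ = sample_occurrences(sp, small_env, 2002, 500, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_all_zero_weights_error(self, small_env, small_grid):
        sp = _one_cell_species(small_grid, small_env)
        bias = np.zeros(small_grid.shape)
        with pytest.raises(NoSamplableCellsError):
            sample_occurrences(sp, small_env, 2000, 10, bias_field=bias, seed=0)

    def test_records_inside_allowed_regions(self, small_env, small_grid):
        sp = define_virtual_species(
            "meso", {"SSST": (0.0, 5.0)}, seed=4, allowed_regions=[1, 2], prevalence_target=0.4
        )
        table, occ = sample_occurrences(sp, small_env, 2003, 400, seed=3)
        row, col = small_grid.cell_index(table["longitude"].to_numpy(), table["latitude"].to_numpy())
        assert np.all(np.isin(small_grid.region_id[row, col], [1, 2]))
        assert np.all(np.isin(small_grid.region_id[occ], [1, 2]))

    def test_sampling_frequency_converges_to_weights(self, small_env, small_grid):
        # empirical per-cell frequency at n=1e5 matches normalized weights to 3 SE
        sp = define_virtual_species(
            "meso", {"SSST": (0.0, 5.0)}, seed=4, allowed_regions=small_grid.region_ids.tolist(),
            prevalence_target=0.3,
        )
        n = 100_000
        table, occ = sample_occurrences(sp, small_env, 2004, n, seed=8)
        suit = sp.suitability(small_env.layers(2004, ["SSST"]))
        weights = np.where(occ, np.nan_to_num(suit), 0.0)
        p = weights / weights.sum()
        row, col = small_grid.cell_index(table["longitude"].to_numpy(), table["latitude"].to_numpy())
        counts = np.zeros(small_grid.shape)
        np.add.at(counts, (row, col), 1)
        se = np.sqrt(p * (1 - p) / n)
        inside = p > 0
        assert np.all(np.abs(counts[inside] / n - p[inside]) <= 3 * se[inside] + 1e-12)


class TestMobilityCap:
    def test_poleward_front_capped(self, small_grid):
        env, _ = simulate_environment(
            small_grid, range(2000, 2020),
            trend_spec=noise_free_spec(small_grid, ssst_trend=3.0), seed=2,
        )
        sp = define_virtual_species(
            "meso", {"SSST": (6.0, 1.5)}, seed=1, allowed_regions=small_grid.region_ids.tolist(),
            mobility_km_per_year=20.0, prevalence_target=0.2,
        )
        occ0 = occupancy_map(sp, env, 2000)
        from arcbio.synthetic_data.species import range_front_latitude

        front0 = range_front_latitude(occ0, small_grid)
        occ_end = occupancy_map(sp, env, 2019, baseline_front_lat=front0)
        front_end = range_front_latitude(occ_end, small_grid)
        max_allowed = front0 + 20.0 * 19 / 111.19 + small_grid.cell_size_deg
        assert front_end <= max_allowed
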