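import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from habrange import (
    BiomeMap,
    GridSpec,
    SpeciesRecord,
    bootstrap_percentiles,
    climate_only_change,
    critical_loss_fraction,
    marginal_loss_curve,
    percentile_curves,
    range_change,
    scenario_aggregate,
)
from habrange.stats import ChangeTable, local_mean_range_map, primary_mega_biome


def table_from_changes(changes, year=2016):
    rows = [
        {"species_id": f"s{i}", "year": year, "delta_pct": v,
         "climate_only_pct": 0.0, "excluded": not math.isfinite(v)}
        for i, v in enumerate(changes)
    ]
    return ChangeTable(frame=pd.DataFrame(rows), t0=1850)


class TestRangeChange:
    def test_unchanged_range_is_zero(self):
        assert range_change(1234.5, 1234.5) == 0.0

    def test_total_loss_is_minus_hundred(self):
        assert range_change(0.0, 50.0) == -100.0

    def test_expansion_is_linear(self):
        assert range_change(1.5 * 80.0, 80.0) == pytest.approx(50.0)

    def test_zero_baseline_excluded_as_nan(self):
        assert math.isnan(range_change(10.0, 0.0))

    def test_climate_only_static_biomes_zero(self):
        assert climate_only_change(200.0, 200.0) == 0.0
        assert climate_only_change(100.0, 200.0) == -50.0


class TestPercentiles:
    def test_identical_species_collapse_all_percentiles(self):
        out = percentile_curves(table_from_changes([-20.0] * 5))
        assert np.all(out["value"] == -20.0)

    def test_median_of_three(self):
        out = percentile_curves(table_from_changes([-90, -50, -10]), percentiles=(50,))
        assert out["value"].iloc[0] == -50.0

    def test_evenly_spaced_values_match_rank_oracle(self):
        vals = np.linspace(-100, 0, 101)
        out = percentile_curves(table_from_changes(list(vals)), percentiles=(10,))
        # brute force: sorted rank with linear interpolation, h = p/100*(n-1)
        srt = np.sort(vals)
        h = 0.10 * 100
        expected = srt[int(h)]  # integer rank, no interpolation needed
        assert out["value"].iloc[0] == pytest.approx(expected)

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(-100, 100, allow_nan=False), min_size=1, max_size=50),
           st.integers(1, 99))
    def test_matches_brute_force_sort_and_rank(self, values, p):
        out = percentile_curves(table_from_changes(values), percentiles=(p,))
        srt = np.sort(np.asarray(values, dtype=float))
        h = p / 100 * (len(srt) - 1)
        lo = int(np.floor(h))
        hi = min(lo + 1, len(srt) - 1)
        expected = srt[lo] + (h - lo) * (srt[hi] - srt[lo])
        assert out["value"].iloc[0] == pytest.approx(expected, abs=1e-9)

    def test_excluded_species_dropped(self):
        out = percentile_curves(table_from_changes([float("nan"), -30.0]),
                                percentiles=(50,))
        assert out["value"].iloc[0] == -30.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            percentile_curves(table_from_changes([float("nan")]))


class TestCriticalLoss:
    def test_no_species_below_threshold(self):
        out = critical_loss_fraction(table_from_changes([-10, -40, 0]), 2016)
        assert out.loc[out["group"] == "__all__", "share_within"].iloc[0] == 0.0

    def test_half_of_species_critical(self):
        out = critical_loss_fraction(table_from_changes([-60, -60, -10, 0]), 2016)
        assert out["share_within"].iloc[0] == 0.5

    def test_boundary_value_not_counted(self):
        out = critical_loss_fraction(table_from_changes([-50.0, -10.0]), 2016)
        assert out["share_within"].iloc[0] == 0.0

    def test_group_shares_recombine_to_overall(self):
        changes = [-80, -70, -20, -60, -10, 5]
        groups = {f"s{i}": ("tropical" if i < 3 else "temperate") for i in range(6)}
        out = critical_loss_fraction(table_from_changes(changes), 2016, groups=groups)
        overall = out.loc[out["group"] == "__all__", "share_of_all"].iloc[0]
        by_group = out.loc[out["group"] != "__all__", "share_of_all"].sum()
        assert by_group == pytest.approx(overall)

    def test_empty_group_flagged_nan(self):
        groups = {"s0": "a", "s1": "a"}
        out = critical_loss_fraction(table_from_changes([-60, -10]), 2016,
                                     groups={**groups, "ghost": "b"})
        row_b = out[out["group"] == "b"]
        assert math.isnan(row_b["share_within"].iloc[0])


class TestPrimaryMegaBiome:
    grid = GridSpec(1.0, 0.0, 1.0, 0.0, 2.0)

    def _species(self, eoo, biomes={1, 2}):
        return SpeciesRecord("sp", "bird", np.asarray(eoo, float),
                             frozenset(biomes), frozenset())

    def test_single_biome_range(self):
        bm = BiomeMap(1850, self.grid, np.array([[1, 1]]))
        out = primary_mega_biome(self._species([[1.0, 1.0]]), bm,
                                 {1: "tropical"}, np.ones((1, 2)))
        assert out == "tropical"

    def test_largest_area_share_wins(self):
        bm = BiomeMap(1850, self.grid, np.array([[1, 2]]))
        areas = np.array([[7.0, 3.0]])  # 70/30 split
        out = primary_mega_biome(self._species([[1.0, 1.0]]), bm,
                                 {1: "tropical", 2: "temperate"}, areas)
        assert out == "tropical"

    def test_exact_tie_breaks_to_lower_label(self):
        bm = BiomeMap(1850, self.grid, np.array([[1, 2]]))
        out = primary_mega_biome(self._species([[1.0, 1.0]]), bm,
                                 {1: "b_label", 2: "a_label"}, np.ones((1, 2)))
        assert out == "a_label"

    def test_zero_baseline_rejected(self):
        bm = BiomeMap(1850, self.grid, np.array([[3, 3]]))
        with pytest.raises(ValueError):
            primary_mega_biome(self._species([[1.0, 1.0]]), bm,
                               {3: "x"}, np.ones((1, 2)))


class TestMarginalLoss:
    def test_linear_loss_gives_constant_marginal(self):
        years = [1900, 1950, 2000]
        areas = [1e6, 2e6, 3e6]
        losses = [-1.0, -2.0, -3.0]
        out = marginal_loss_curve(years, losses, areas)
        m = out["marginal_loss_pct_per_km2"].to_numpy()
        assert np.isnan(m[0])
        np.testing.assert_allclose(m[1:], -1e-6)

    def test_zero_conversion_gives_no_marginal_values(self):
        out = marginal_loss_curve([1900, 2000], [-1.0, -1.0], [5e5, 5e5])
        assert out["marginal_loss_pct_per_km2"].isna().all()

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            marginal_loss_curve([1900], [-1.0, -2.0], [1e6, 2e6])


class TestLocalMeanRangeMap:
    def test_single_species_constant_map(self):
        fld = np.array([[0.5, 1.0]])
        out = local_mean_range_map([fld], [4200.0], np.ones((1, 2)))
        np.testing.assert_array_equal(out, [[4200.0, 4200.0]])

    def test_overlap_cell_averages_sizes(self):
        f1 = np.array([[1.0, 1.0]])
        f2 = np.array([[0.0, 0.7]])
        out = local_mean_range_map([f1, f2], [100.0, 300.0], np.ones((1, 2)))
        assert out[0, 0] == 100.0
        assert out[0, 1] == pytest.approx(200.0)

    def test_empty_cells_are_nan(self):
        f = np.array([[1.0, 0.0]])
        out = local_mean_range_map([f], [100.0], np.ones((1, 2)))
        assert math.isnan(out[0, 1])

    def test_small_ranged_cluster_lowers_regional_mean(self, hist_world, rng):
        # regions hosting small-ranged species show smaller local means
        from habrange.model import HabitatRangeModel

        res = HabitatRangeModel.from_world(hist_world).fit()
        m = res.local_mean_range_map()
        lat = hist_world.grid.lat_centers()
        tropics = np.abs(lat) < hist_world.config.tropic_lat
        trop_mean = np.nanmean(m[tropics, :])
        extra_mean = np.nanmean(m[~tropics, :])
        assert trop_mean < extra_mean


class TestBootstrap:
    def test_degenerate_input_has_zero_sd(self):
        out = bootstrap_percentiles(np.full(50, -20.0), n_boot=200, seed=1)
        assert np.all(out["sd"] == 0.0)
        assert np.all(out["mean"] == -20.0)

    def test_same_seed_reproduces_exactly(self):
        x = np.random.default_rng(3).normal(size=100)
        a = bootstrap_percentiles(x, n_boot=500, seed=11)
        b = bootstrap_percentiles(x, n_boot=500, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_percentiles(np.array([]), seed=1)

    def test_seed_required(self):
        with pytest.raises(ValueError):
            bootstrap_percentiles(np.ones(10), seed=None)


class TestScenarioAggregate:
    def test_identical_curves_have_zero_sd(self):
        years = np.array([2020, 2050])
        c = {m: (years, np.array([-5.0, -10.0])) for m in "abc"}
        out = scenario_aggregate(c)
        np.testing.assert_array_equal(out["sd"], 0.0)

    def test_hand_computed_mean_and_sample_sd(self):
        years = np.array([2100])
        c = {"a": (years, [-10.0]), "b": (years, [-20.0]), "c": (years, [-30.0])}
        out = scenario_aggregate(c)
        assert out["mean"].iloc[0] == pytest.approx(-20.0)
        assert out["sd"].iloc[0] == pytest.approx(10.0)  # sample (n-1) SD

    def test_single_model_sd_flagged(self):
        out = scenario_aggregate({"a": (np.array([2100]), [-10.0])})
        assert math.isnan(out["sd"].iloc[0])
        assert out["n_models"].iloc[0] == 1

    def test_mismatched_time_grids_rejected(self):
        with pytest.raises(ValueError):
            scenario_aggregate({"a": (np.array([2100]), [-10.0]),
                                "b": (np.array([2090]), [-10.0])})
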