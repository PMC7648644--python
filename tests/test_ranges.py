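import numpy as np
import pytest

from habrange import (
    BiomeMap,
    GridSpec,
    LandUseSeries,
    SpeciesRecord,
    actual_range_field,
    compute_range_series,
    no_migration_filter,
    potential_range_field,
    range_area,
)

GRID = GridSpec(1.0, 0.0, 1.0, 0.0, 2.0)  # 1 x 2 cells


def biome_map(codes, year=1850):
    return BiomeMap(year, GRID, np.asarray(codes), code_list=(1, 2))


def species(eoo, biomes, artificial=()):
    return SpeciesRecord("sp", "mammal", np.asarray(eoo, float),
                         frozenset(biomes), frozenset(artificial))


def lu(crop=0.0, past=0.0, urb=0.0):
    full = lambda v: np.broadcast_to(np.asarray(v, float), GRID.shape).copy()
    return {"cropland": full(crop), "pasture": full(past), "urban": full(urb)}


class TestPotentialField:
    def test_all_biomes_suitable_returns_eoo(self):
        sp = species([[0.3, 0.8]], {1, 2})
        np.testing.assert_array_equal(
            potential_range_field(sp, biome_map([[1, 2]])), [[0.3, 0.8]])

    def test_no_suitable_biomes_gives_zero(self):
        sp = species([[0.3, 0.8]], set())
        assert np.all(potential_range_field(sp, biome_map([[1, 2]])) == 0.0)

    def test_two_cell_indicator(self):
        sp = species([[1.0, 0.5]], {1})
        np.testing.assert_array_equal(
            potential_range_field(sp, biome_map([[1, 2]])), [[1.0, 0.0]])

    def test_grid_mismatch_rejected(self):
        sp = species([[1.0, 0.5]], {1})
        other = BiomeMap(1850, GridSpec(1.0, 0.0, 1.0, 0.0, 3.0), np.ones((1, 3), int))
        with pytest.raises(ValueError):
            potential_range_field(sp, other)


class TestActualField:
    def test_zero_land_use_equals_potential(self):
        sp = species([[1.0, 0.5]], {1})
        bm = biome_map([[1, 2]])
        np.testing.assert_array_equal(
            actual_range_field(sp, bm, lu()), potential_range_field(sp, bm))

    def test_fully_tolerant_species_keeps_whole_eoo(self):
        sp = species([[0.7, 0.7]], {1, 2}, artificial=("cropland", "pasture", "urban"))
        out = actual_range_field(sp, biome_map([[1, 2]]), lu(crop=0.4, past=0.3, urb=0.1))
        np.testing.assert_allclose(out, [[0.7, 0.7]])

    def test_mixed_tolerance_hand_value(self):
        # eoo=1, natural suitable, cropland 0.3 unsuitable, pasture 0.1
        # suitable, urban 0 -> 0.6 + 0.1 = 0.7
        sp = species([[1.0, 1.0]], {1}, artificial=("pasture",))
        out = actual_range_field(sp, biome_map([[1, 1]]), lu(crop=0.3, past=0.1))
        np.testing.assert_allclose(out, [[0.7, 0.7]])

    def test_extended_counts_artificial_outside_potential_range(self):
        sp = species([[1.0, 1.0]], {1}, artificial=("cropland",))
        bm = biome_map([[1, 2]])
        fields = lu(crop=[0.0, 0.6])
        ext = actual_range_field(sp, bm, fields, mode="extended")
        strict = actual_range_field(sp, bm, fields, mode="strict")
        # unsuitable-biome cell converted to tolerated cropland: counts only
        # in extended mode
        assert ext[0, 1] == pytest.approx(0.6)
        assert strict[0, 1] == 0.0

    def test_strict_actual_bounded_by_potential(self, rng):
        for _ in range(50):
            eoo = rng.random((1, 2))
            sp = species(eoo, {1}, artificial=("cropland",))
            bm = biome_map(rng.integers(1, 3, (1, 2)))
            f = rng.dirichlet([1, 1, 1, 2], size=2)[:, :3].T.reshape(3, 1, 2)
            fields = {"cropland": f[0], "pasture": f[1], "urban": f[2]}
            strict = actual_range_field(sp, bm, fields, mode="strict")
            assert np.all(strict <= potential_range_field(sp, bm) + 1e-12)

    def test_unknown_mode_rejected(self):
        sp = species([[1.0, 1.0]], {1})
        with pytest.raises(ValueError):
            actual_range_field(sp, biome_map([[1, 1]]), lu(), mode="loose")

    def test_oversum_land_use_rejected(self):
        sp = species([[1.0, 1.0]], {1})
        with pytest.raises(ValueError):
            actual_range_field(sp, biome_map([[1, 1]]), lu(crop=0.8, past=0.8))

    def test_adding_unsuitable_fraction_never_increases_range(self, rng):
        sp = species([[1.0, 0.8]], {1}, artificial=("pasture",))
        bm = biome_map([[1, 1]])
        base = lu(crop=0.2, past=0.1)
        a0 = range_area(actual_range_field(sp, bm, base), np.ones(GRID.shape))
        for _ in range(100):
            extra = rng.uniform(0, 0.5)
            pert = lu(crop=0.2 + extra, past=0.1)
            a1 = range_area(actual_range_field(sp, bm, pert), np.ones(GRID.shape))
            assert a1 <= a0 + 1e-12


class TestRangeArea:
    def test_zero_field(self):
        assert range_area(np.zeros((1, 2)), np.array([[1000.0, 2000.0]])) == 0.0

    def test_ones_field_gives_total_area(self):
        assert range_area(np.ones((1, 2)), np.array([[1000.0, 2000.0]])) == 3000.0

    def test_hand_sum(self):
        out = range_area(np.array([[0.25, 0.5]]), np.array([[1000.0, 2000.0]]))
        assert out == pytest.approx(1250.0)


class TestNoMigrationFilter:
    def test_vacuous_when_biomes_static(self):
        sp = species([[1.0, 0.5]], {1})
        out = no_migration_filter(sp, biome_map([[1, 1]]))
        np.testing.assert_array_equal(out.eoo_fraction, sp.eoo_fraction)

    def test_unsuitable_present_biome_zeroes_range(self):
        sp = species([[1.0, 0.5]], {1})
        out = no_migration_filter(sp, biome_map([[2, 2]]))
        assert np.all(out.eoo_fraction == 0.0)

    def test_only_cells_suitable_now_and_later_count(self):
        sp = species([[1.0, 1.0]], {1})
        present = biome_map([[1, 2]], year=2016)
        future = biome_map([[1, 1]], year=2100)
        filtered = no_migration_filter(sp, present)
        fut_field = potential_range_field(filtered, future)
        np.testing.assert_array_equal(fut_field, [[1.0, 0.0]])

    def test_filtered_range_subset_pointwise(self, rng):
        for _ in range(20):
            sp = species(rng.random((1, 2)), {1})
            present = biome_map(rng.integers(1, 3, (1, 2)))
            fut = biome_map(rng.integers(1, 3, (1, 2)))
            a = potential_range_field(no_migration_filter(sp, present), fut)
            b = potential_range_field(sp, fut)
            assert np.all(a <= b + 1e-15)


class TestComputeSeries:
    def _landuse(self, crop_by_year):
        years = sorted(crop_by_year)
        T = len(years)
        crop = np.stack([np.broadcast_to(np.asarray(crop_by_year[y], float),
                                         GRID.shape) for y in years])
        data = {("cropland", "baseline"): crop,
                ("pasture", "baseline"): np.zeros((T, *GRID.shape)),
                ("urban", "baseline"): np.zeros((T, *GRID.shape))}
        return LandUseSeries(grid=GRID, years=np.array(years), data=data)

    def test_static_world_gives_constant_equal_series(self):
        sp = species([[1.0, 0.5]], {1})
        landuse = self._landuse({1850: 0.0, 1900: 0.0})
        rs = compute_range_series(sp, [biome_map([[1, 1]])], landuse,
                                  np.ones(GRID.shape))
        assert np.all(rs.a_potential == rs.a_potential[0])
        np.testing.assert_array_equal(rs.a_actual, rs.a_potential)
        assert not rs.excluded

    def test_zero_baseline_flags_exclusion(self):
        sp = species([[1.0, 1.0]], {1})
        landuse = self._landuse({1850: 0.0})
        rs = compute_range_series(sp, [biome_map([[2, 2]])], landuse,
                                  np.ones(GRID.shape))
        assert rs.excluded

    def test_nearest_decade_pairing_prefers_earlier_on_tie(self):
        sp = species([[1.0, 1.0]], {1})
        landuse = self._landuse({1905: 0.0})
        maps = [biome_map([[1, 1]], 1900), biome_map([[2, 2]], 1910)]
        rs = compute_range_series(sp, maps, landuse, np.ones(GRID.shape),
                                  t0=1905)
        # 1905 is equidistant from 1900 and 1910: the earlier map wins
        assert rs.a_potential[0] == pytest.approx(2.0)

    def test_fields_bounded_by_eoo(self, hist_world):
        w = hist_world
        bm = w.biomes_hist[15]
        fields = {c: w.landuse_hist.layer(c, 2016) for c in ("cropland", "pasture", "urban")}
        for sp in w.species[:10]:
            pot = potential_range_field(sp, bm)
            act = actual_range_field(sp, bm, fields)
            assert np.all(pot <= sp.eoo_fraction + 1e-12)
            assert np.all(act <= sp.eoo_fraction + 1e-12)
            assert np.all(act >= -1e-12) and np.all(pot >= -1e-12)

    def test_empty_time_grid_rejected(self):
        sp = species([[1.0, 1.0]], {1})
        landuse = self._landuse({1850: 0.0})
        with pytest.raises(ValueError):
            compute_range_series(sp, [biome_map([[1, 1]])], landuse,
                                 np.ones(GRID.shape), years=[])
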