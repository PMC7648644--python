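"""Model/Results interface over the habitat-range pipeline.

:class:`HabitatRangeModel` bundles the inputs of one analysis scenario —
the species set, the biome-map series, one land-use series/variant and the
analysis options — and its :meth:`~HabitatRangeModel.fit` runs the
area-of-habitat estimation for every species, returning a
:class:`HabitatRangeResults` that carries the per-species range series, the
relative-change table and all derived summaries (percentile fans,
critical-loss shares, marginal-loss curve, bootstrap uncertainties).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats as hstats
from .grid import GridSpec, cell_areas
from .landuse import LandUseSeries, cumulative_converted_area
from .ranges import (
    BiomeMap,
    RangeSeries,
    compute_range_series,
    nearest_biome_map,
    no_migration_filter,
    potential_range_field,
    range_area,
)

SENSITIVITIES = ("main", "no_migration", "static_biomes")


class HabitatRangeModel:
    """Area-of-habitat model for a set of species under one scenario.

    Parameters
    ----------
    species : list of SpeciesRecord
        Rasterized extents of occurrence with habitat preferences.
    biome_maps : list of BiomeMap
        Potential-natural-biome maps; each analysis year is paired with the
        temporally nearest map (ties to the earlier one).
    landuse : LandUseSeries
        Anthropogenic land-cover fractions on the same grid.
    variant : {"baseline", "lower", "upper"}
        Land-use uncertainty variant to analyse.
    mode : {"extended", "strict"}
        Whether tolerated artificial land counts throughout the EOO
        (extended, default) or only inside the potential range (strict).
    t0 : int
        Reference year of the potential natural range (default 1850).
    sensitivity : {"main", "no_migration", "static_biomes"}
        Optional sensitivity analysis. "no_migration" zeroes EOO cells whose
        present-day biome is unsuitable; "static_biomes" freezes the biome
        distribution at the present year for all later times. Both need
        ``present_year`` to resolve the present-day biome map.
    """

    def __init__(
        self,
        species,
        biome_maps,
        landuse: LandUseSeries,
        *,
        years=None,
        variant: str = "baseline",
        mode: str = "extended",
        t0: int = 1850,
        t0_biomes: BiomeMap | None = None,
        sensitivity: str = "main",
        present_year: int = 2016,
        areas: np.ndarray | None = None,
    ) -> None:
        if sensitivity not in SENSITIVITIES:
            raise ValueError(f"unknown sensitivity {sensitivity!r}")
        if not species:
            raise ValueError("no species supplied")
        self.grid: GridSpec = landuse.grid
        self.areas = cell_areas(self.grid) if areas is None else areas
        self.landuse = landuse
        self.variant = variant
        self.mode = mode
        self.t0 = t0
        self.sensitivity = sensitivity
        self.present_year = present_year
        self.years = np.asarray(landuse.years if years is None else years, dtype=int)
        self._t0_biomes = t0_biomes

        if sensitivity == "static_biomes":
            present = nearest_biome_map(biome_maps, present_year)
            biome_maps = [m for m in biome_maps if m.year <= present_year]
            # frozen copies cover the later years so nearest-map pairing
            # always resolves to the present distribution
            for y in self.years[self.years > present_year]:
                biome_maps.append(BiomeMap(int(y), present.grid, present.codes,
                                           present.code_list))
        self.biome_maps = biome_maps

        # the t0 reference range is always that of the main analysis, so the
        # no-migration variant shrinks the numerator only and its losses are
        # at least as large by construction
        self._ref_species = list(species)
        if sensitivity == "no_migration":
            present = nearest_biome_map(biome_maps, present_year)
            self.species = [no_migration_filter(sp, present) for sp in species]
        else:
            self.species = list(species)

    @classmethod
    def from_world(cls, world, *, future_scenario=None, **kwargs) -> "HabitatRangeModel":
        """Build a model from a synthetic :class:`~habrange.synthetic.World`.

        Without ``future_scenario`` the historical reconstruction is used;
        with a ``(rcp, ssp, climate_model)`` triple the corresponding
        harmonised land-use projection and projected biome maps are used
        (historical biome maps stay available for the t0 reference).
        """
        if future_scenario is None:
            return cls(world.species, world.biomes_hist, world.landuse_hist,
                       areas=world.areas, **kwargs)
        rcp, ssp, model = future_scenario
        landuse = world.landuse_future[(rcp, ssp)]
        biomes = world.biomes_hist + world.biomes_future[(rcp, model)]
        kwargs.setdefault("years", landuse.years[landuse.years >= 2020])
        return cls(world.species, biomes, landuse, areas=world.areas, **kwargs)

    def fit(self) -> "HabitatRangeResults":
        """Run the range estimation for every species."""
        ref_bm = self._t0_biomes or nearest_biome_map(self.biome_maps, self.t0)
        series = []
        for sp, sp_ref in zip(self.species, self._ref_species):
            rs = compute_range_series(
                sp, self.biome_maps, self.landuse, self.areas,
                years=self.years, variant=self.variant, mode=self.mode,
                t0=self.t0, t0_biomes=self._t0_biomes,
            )
            if sp_ref is not sp:
                a_ref = range_area(potential_range_field(sp_ref, ref_bm), self.areas)
                rs.a_potential_t0 = a_ref
                rs.excluded = a_ref <= 0.0
            series.append(rs)
        table = hstats.ChangeTable.from_series(series)
        return HabitatRangeResults(model=self, series=series, change_table=table)


@dataclass
class HabitatRangeResults:
    """Fitted per-species range series and derived change statistics."""

    model: HabitatRangeModel
    series: list
    change_table: hstats.ChangeTable = field(repr=False)

    @property
    def n_species(self) -> int:
        return len(self.series)

    @property
    def n_excluded(self) -> int:
        return sum(rs.excluded for rs in self.series)

    def ranges_frame(self) -> pd.DataFrame:
        """Tidy per-species range areas (species_id, year, A_potential_km2,
        A_actual_km2, excluded)."""
        return pd.concat([rs.to_frame() for rs in self.series], ignore_index=True)

    def percentile_curves(self, percentiles=hstats.DEFAULT_PERCENTILES,
                          climate_only: bool = False) -> pd.DataFrame:
        col = "climate_only_pct" if climate_only else "delta_pct"
        return hstats.percentile_curves(self.change_table, percentiles, column=col)

    def median_curve(self, climate_only: bool = False) -> pd.DataFrame:
        df = self.percentile_curves((50,), climate_only=climate_only)
        return df[["year", "value"]].rename(columns={"value": "median_pct"})

    def critical_loss(self, year: int, threshold: float = 50.0,
                      groups: dict | None = None) -> pd.DataFrame:
        return hstats.critical_loss_fraction(self.change_table, year,
                                             threshold=threshold, groups=groups)

    def mega_biome_assignment(self, mega_crosswalk: dict) -> dict:
        """species_id -> primary mega-biome for all included species."""
        t0_map = (self.model._t0_biomes
                  or nearest_biome_map(self.model.biome_maps, self.model.t0))
        out = {}
        for sp, rs in zip(self.model.species, self.series):
            if rs.excluded:
                continue
            out[sp.species_id] = hstats.primary_mega_biome(
                sp, t0_map, mega_crosswalk, self.model.areas)
        return out

    def marginal_loss_curve(self) -> pd.DataFrame:
        """Median range loss vs cumulative converted area over the run years."""
        med = self.median_curve()
        cum = [
            cumulative_converted_area(self.model.landuse, int(y),
                                      self.model.areas, self.model.variant)
            for y in med["year"]
        ]
        return hstats.marginal_loss_curve(med["year"].to_numpy(),
                                          med["median_pct"].to_numpy(), cum)

    def local_mean_range_map(self) -> np.ndarray:
        """Per-cell mean reference potential range size of locally present
        species (km**2), NaN where no species occurs."""
        t0_map = (self.model._t0_biomes
                  or nearest_biome_map(self.model.biome_maps, self.model.t0))
        fields, sizes = [], []
        for sp, rs in zip(self.model.species, self.series):
            if rs.excluded:
                continue
            fld = potential_range_field(sp, t0_map)
            fields.append(fld)
            sizes.append(range_area(fld, self.model.areas))
        return hstats.local_mean_range_map(fields, sizes, self.model.areas)

    def bootstrap(self, year: int, n_boot: int = 10_000, seed: int | None = None,
                  percentiles=hstats.DEFAULT_PERCENTILES) -> pd.DataFrame:
        changes = self.change_table.changes_at(year)
        return hstats.bootstrap_percentiles(changes, percentiles, n_boot, seed)

    def summary(self) -> str:
        """Human-readable run summary."""
        last = int(self.years_max())
        med = self.median_curve()
        med_last = float(med.loc[med["year"] == last, "median_pct"].iloc[0])
        crit = self.critical_loss(last)
        share = float(crit.loc[crit["group"] == "__all__", "share_within"].iloc[0])
        lines = [
            "Habitat range analysis",
            "======================",
            f"species:            {self.n_species} ({self.n_excluded} excluded, zero {self.model.t0} baseline)",
            f"grid:               {self.model.grid.nlat} x {self.model.grid.nlon} at {self.model.grid.resolution_deg} deg",
            f"years:              {self.model.years.min()}-{last} ({len(self.model.years)} points)",
            f"variant/mode:       {self.model.variant}/{self.model.mode} ({self.model.sensitivity})",
            f"median change {last}:  {med_last:.2f}%  (vs potential range in {self.model.t0})",
            f"share lost >50%:    {100 * share:.1f}% of included species",
        ]
        return "\n".join(lines)

    def years_max(self) -> int:
        return int(np.max(self.model.years))
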