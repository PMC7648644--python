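"""Per-species potential-natural and actual habitat ranges through time.

The area-of-habitat procedure works in three steps:

1. A species' extent of occurrence (EOO) polygon is rasterized to a
   per-cell coverage fraction on the analysis grid (see :mod:`.grid`).
2. The *potential natural range* at a time t keeps only the EOO cells whose
   potential natural biome (a categorical map driven by the climate at t)
   is in the species' list of suitable biomes.
3. The *actual range* additionally accounts for the cropland, pasture and
   urban fractions of each cell: unsuitable anthropogenic land is removed,
   while artificial classes the species tolerates still count as habitat.

Range sizes are the area-weighted sums of the resulting fractional fields.
Range changes are expressed relative to the potential natural range at the
pre-industrial reference year t0 = 1850.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .grid import GridSpec
from .landuse import CLASSES, LandUseSeries

T0_DEFAULT = 1850

MODES = ("extended", "strict")


@dataclass(frozen=True)
class HabitatCrosswalk:
    """Mapping from habitat-category codes to biome codes and artificial classes.

    ``natural``: category code -> frozenset of biome codes it legitimises.
    ``artificial``: category code -> frozenset drawn from
    {"cropland", "pasture", "urban"}.
    """

    natural: dict
    artificial: dict

    def suitable_biomes(self, categories) -> frozenset:
        out: set = set()
        for c in categories:
            out |= set(self.natural.get(c, ()))
        return frozenset(out)

    def suitable_artificial(self, categories) -> frozenset:
        out: set = set()
        for c in categories:
            out |= set(self.artificial.get(c, ()))
        bad = out - set(CLASSES)
        if bad:
            raise ValueError(f"unknown artificial classes {sorted(bad)}")
        return frozenset(out)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "HabitatCrosswalk":
        """Build from a table with columns category_code, biome_codes,
        artificial_flags (";"-separated lists; empty allowed)."""
        nat, art = {}, {}

        def cell(row, key):
            v = row.get(key, "")
            return "" if v is None or (isinstance(v, float) and np.isnan(v)) else str(v)

        for _, row in df.iterrows():
            cat = row["category_code"]
            # int(float(.)) tolerates CSV readers that parse lone codes as floats
            nat[cat] = frozenset(
                int(float(b)) for b in cell(row, "biome_codes").split(";") if b.strip())
            art[cat] = frozenset(
                f.strip() for f in cell(row, "artificial_flags").split(";") if f.strip())
        return cls(natural=nat, artificial=art)


@dataclass(frozen=True)
class BiomeMap:
    """Categorical potential-natural-biome codes per cell at one time."""

    year: int
    grid: GridSpec
    codes: np.ndarray  # int (nlat, nlon)
    code_list: tuple = ()

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes)
        object.__setattr__(self, "codes", codes)
        if codes.shape != self.grid.shape:
            raise ValueError("biome codes not aligned to grid")
        if self.code_list:
            unknown = set(np.unique(codes)) - set(self.code_list)
            if unknown:
                raise ValueError(f"biome codes {sorted(unknown)} not in declared code list")

    def suitability(self, suitable: frozenset) -> np.ndarray:
        """Boolean indicator of cells whose biome is in ``suitable``."""
        return np.isin(self.codes, list(suitable))


def nearest_biome_map(maps: list[BiomeMap], year: int) -> BiomeMap:
    """The biome map temporally nearest to ``year``; ties go to the earlier map."""
    if not maps:
        raise ValueError("no biome maps supplied")
    return min(maps, key=lambda m: (abs(m.year - year), m.year))


@dataclass(frozen=True)
class SpeciesRecord:
    """A species' rasterized EOO and habitat preferences."""

    species_id: str
    group: str  # mammal | bird | amphibian
    eoo_fraction: np.ndarray  # (nlat, nlon) in [0, 1]
    suitable_biomes: frozenset
    suitable_artificial: frozenset = frozenset()

    def __post_init__(self) -> None:
        eoo = np.asarray(self.eoo_fraction, dtype=float)
        object.__setattr__(self, "eoo_fraction", eoo)
        if np.any(eoo < -1e-12) or np.any(eoo > 1 + 1e-12):
            raise ValueError("EOO fractions must lie in [0, 1]")
        bad = set(self.suitable_artificial) - set(CLASSES)
        if bad:
            raise ValueError(f"unknown artificial classes {sorted(bad)}")


def potential_range_field(sp: SpeciesRecord, biomes: BiomeMap) -> np.ndarray:
    """EOO fraction masked to cells whose natural biome the species tolerates."""
    if sp.eoo_fraction.shape != biomes.grid.shape:
        raise ValueError("species EOO not aligned to biome grid")
    return sp.eoo_fraction * biomes.suitability(sp.suitable_biomes)


def actual_range_field(
    sp: SpeciesRecord,
    biomes: BiomeMap,
    landuse: dict,
    mode: str = "extended",
) -> np.ndarray:
    """Habitat fraction after accounting for anthropogenic land cover.

    ``landuse`` maps each class name to its fraction field; per cell the
    natural remainder is ``1 - sum_k f_k``.

    extended (default)
        value = eoo * [ (1 - sum f_k) * 1{biome suitable}
                        + sum_{k tolerated} f_k ].
        Tolerated artificial land counts anywhere in the EOO, so conversion
        of unsuitable natural vegetation to, e.g., cropland can *expand* a
        cropland-tolerant species' range.
    strict
        the artificial terms only apply where the natural biome is suitable,
        so the actual range is a subset of the potential range at the same t.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    fr = {c: np.asarray(landuse[c], dtype=float) for c in CLASSES}
    total = sum(fr.values())
    if np.any(total > 1.0 + 1e-6):
        raise ValueError("land-use class fractions sum above 1; ingest should have capped them")
    total = np.minimum(total, 1.0)
    nat = biomes.suitability(sp.suitable_biomes).astype(float)
    art = sum(fr[c] for c in CLASSES if c in sp.suitable_artificial)
    if isinstance(art, int):  # no tolerated classes
        art = np.zeros_like(total)
    if mode == "extended":
        cell = (1.0 - total) * nat + art
    else:
        cell = nat * ((1.0 - total) + art)
    return sp.eoo_fraction * cell


def range_area(field: np.ndarray, areas: np.ndarray) -> float:
    """Area-weighted sum of a fractional habitat field, in km**2."""
    if field.shape != areas.shape:
        raise ValueError("field and cell areas are not aligned")
    return float((field * areas).sum())


def no_migration_filter(
    sp: SpeciesRecord, biomes_present: BiomeMap
) -> SpeciesRecord:
    """Zero the EOO in cells whose present-day biome is unsuitable.

    Under this no-migration assumption a cell only counts toward a future
    range if the species could occupy it both now and then, so the filtered
    range is a subset of the main analysis' range at every cell and time and
    projected losses are, by construction, at least as large.
    """
    mask = biomes_present.suitability(sp.suitable_biomes)
    if sp.eoo_fraction.shape != mask.shape:
        raise ValueError("species EOO not aligned to biome grid")
    return replace(sp, eoo_fraction=sp.eoo_fraction * mask)


@dataclass
class RangeSeries:
    """Potential and actual range sizes of one species through time (km**2)."""

    species_id: str
    years: np.ndarray
    a_potential: np.ndarray
    a_actual: np.ndarray
    t0: int = T0_DEFAULT
    a_potential_t0: float = float("nan")
    excluded: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species_id": self.species_id,
                "year": self.years,
                "A_potential_km2": self.a_potential,
                "A_actual_km2": self.a_actual,
                "excluded": self.excluded,
            }
        )


def compute_range_series(
    sp: SpeciesRecord,
    biome_maps: list[BiomeMap],
    landuse: LandUseSeries,
    areas: np.ndarray,
    *,
    years=None,
    variant: str = "baseline",
    mode: str = "extended",
    t0: int = T0_DEFAULT,
    t0_biomes: BiomeMap | None = None,
) -> RangeSeries:
    """Potential and actual range areas of one species over a time grid.

    Each land-use year is paired with the temporally nearest biome map (ties
    to the earlier map). The reference potential range at ``t0`` is computed
    from ``t0_biomes`` if given, else from the biome map nearest to ``t0``;
    species with a zero reference range are flagged ``excluded`` (relative
    range changes are undefined for them).
    """
    if years is None:
        years = landuse.years
    years = np.asarray(years, dtype=int)
    if len(years) == 0:
        raise ValueError("empty time grid")
    a_pot = np.empty(len(years))
    a_act = np.empty(len(years))
    for i, y in enumerate(years):
        bm = nearest_biome_map(biome_maps, int(y))
        lu = {c: landuse.layer(c, int(y), variant) for c in CLASSES}
        a_pot[i] = range_area(potential_range_field(sp, bm), areas)
        a_act[i] = range_area(actual_range_field(sp, bm, lu, mode=mode), areas)
    ref_bm = t0_biomes if t0_biomes is not None else nearest_biome_map(biome_maps, t0)
    a_ref = range_area(potential_range_field(sp, ref_bm), areas)
    return RangeSeries(
        species_id=sp.species_id,
        years=years,
        a_potential=a_pot,
        a_actual=a_act,
        t0=t0,
        a_potential_t0=a_ref,
        excluded=(a_ref <= 0.0),
    )
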