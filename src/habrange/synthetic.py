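"""Synthetic worlds with the statistical structure the analysis assumes.

The generator emulates the four input data streams of the pipeline —
species extents of occurrence with habitat preferences, a habitat-category
to biome crosswalk, historical and scenario land-use reconstructions with
uncertainty variants, and potential-natural-biome maps driven by a toy
climate — so every pipeline stage can be exercised end to end without any
external download.

Two deliberately different levels of realism are provided:

* :func:`gen_world` draws a random but reproducible world: regionally
  staggered logistic land-use expansion (with a late-onset tropical band
  that also hosts smaller-ranged species), a zonally banded toy climate
  with a secular warming trend, and species with rectangular extents of
  occurrence whose sizes are log-uniform.
* :func:`analytic_fixture` builds a tiny 4x4 world whose every potential
  range, actual range, relative change, percentile and critical-loss share
  is computed by independent closed-form arithmetic and stored in a ledger,
  so pipeline output can be checked for exact agreement.

The threshold biome classifier here is a documented toy — three annual-mean
temperature bands crossed with two moisture bands — and is **not** an
emulation of any process-based vegetation model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import shapely

from .climate import ClimateField, delta_correct, window_average
from .grid import GridSpec, cell_areas, polygon_coverage
from .landuse import CLASSES, LandUseSeries, harmonise_future
from .ranges import BiomeMap, HabitatCrosswalk, SpeciesRecord

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# toy biome classifier

#: annual-mean temperature band edges (degC): T <= 5 cold, 5 < T <= 20
#: temperate, T > 20 warm.  A value exactly on a threshold falls in the
#: lower band.
TEMP_THRESHOLDS = (5.0, 20.0)
#: annual-mean precipitation (mm/month): P <= threshold is dry.
MOISTURE_THRESHOLD = 90.0

#: biome code list for the toy classifier (1..6).
TOY_BIOME_CODES = (1, 2, 3, 4, 5, 6)

#: coarse grouping of the toy biomes used for Fig-1b style breakdowns.
MEGA_BIOMES = {1: "boreal", 2: "boreal", 3: "temperate", 4: "temperate",
               5: "tropical", 6: "tropical"}


def toy_biome_classify(fields: dict) -> BiomeMap:
    """Categorical biome map from annual-mean temperature and precipitation.

    ``fields`` maps variable name -> :class:`ClimateField`; temperature and
    precipitation are required. Codes: 1 cold-dry, 2 cold-moist, 3
    temperate-dry, 4 temperate-moist, 5 warm-dry, 6 warm-moist. Ties on a
    threshold go to the lower band. Deterministic.
    """
    for v in ("temperature", "precipitation"):
        if v not in fields:
            raise ValueError(f"missing climate variable {v!r}")
    temp = fields["temperature"]
    prec = fields["precipitation"]
    if temp.grid != prec.grid:
        raise ValueError("temperature and precipitation grids differ")
    t = temp.annual_mean()
    p = prec.annual_mean()
    t1, t2 = TEMP_THRESHOLDS
    band = np.where(t > t2, 2, np.where(t > t1, 1, 0))
    moist = (p > MOISTURE_THRESHOLD).astype(int)
    codes = 1 + band * 2 + moist
    return BiomeMap(year=temp.year, grid=temp.grid, codes=codes,
                    code_list=TOY_BIOME_CODES)


# ---------------------------------------------------------------------------
# world configuration

HIST_YEARS = tuple(range(1700, 2001, 10)) + tuple(range(2001, 2017))  # 47 points
FUTURE_YEARS = tuple(range(2020, 2101, 10))  # 9 points
BIOME_DECADES_HIST = tuple(range(1700, 2001, 10))
RCPS = ("2.6", "4.5", "6.0", "8.5")
SSPS = ("1", "2", "3", "4", "5")
CLIMATE_MODELS = ("cm-a", "cm-b", "cm-c")

#: end-of-century warming (degC above 1900) by emission pathway.
RCP_WARMING_2100 = {"2.6": 1.5, "4.5": 2.5, "6.0": 3.5, "8.5": 4.5}
#: climate-model spread around the pathway warming (degC).
MODEL_OFFSETS = {"cm-a": -0.3, "cm-b": 0.0, "cm-c": 0.3}
#: global land-demand multiplier at 2100 relative to 2010, by SSP.
SSP_LAND_FACTOR_2100 = {"1": 0.7, "2": 1.1, "3": 1.6, "4": 1.3, "5": 1.2}


@dataclass(frozen=True)
class WorldConfig:
    """Parameters of a synthetic world. The seed is mandatory."""

    seed: int
    resolution_deg: float = 4.0
    lat_min: float = -60.0
    lat_max: float = 60.0
    lon_min: float = -120.0
    lon_max: float = 120.0
    n_species_per_group: int = 40
    #: |latitude| below which the late-onset (tropical) land-use regime and
    #: the small-ranged species pool apply.
    tropic_lat: float = 25.0
    #: logistic land-conversion parameters: midpoint year per regime,
    #: growth rate (1/yr) and asymptotic converted fraction.
    early_midpoint: int = 1880
    late_midpoint: int = 1970
    logistic_rate: float = 0.04
    asymptote: float = 0.65
    #: relative half-width of the lower/upper land-use uncertainty bounds.
    uncertainty_half_width: float = 0.1
    #: historical warming (degC) reached at 2016, linear from 1900.
    hist_warming_2016: float = 0.9
    #: constant simulated-climate bias removed by the delta correction.
    sim_bias_degC: float = 1.5
    sim_bias_precip: float = 15.0
    rcps: tuple = RCPS
    ssps: tuple = SSPS
    climate_models: tuple = CLIMATE_MODELS

    def __post_init__(self) -> None:
        if not (0.0 < self.asymptote <= 1.0):
            raise ValueError("asymptote must be in (0, 1]")
        if not (0.0 <= self.uncertainty_half_width < 1.0):
            raise ValueError("uncertainty half-width must be in [0, 1)")
        if self.logistic_rate <= 0:
            raise ValueError("logistic rate must be positive")

    def grid(self) -> GridSpec:
        return GridSpec(self.resolution_deg, self.lat_min, self.lat_max,
                        self.lon_min, self.lon_max)


@dataclass
class World:
    """A complete synthetic input bundle."""

    config: WorldConfig
    grid: GridSpec
    areas: np.ndarray
    species: list
    crosswalk: HabitatCrosswalk
    mega_crosswalk: dict
    landuse_hist: LandUseSeries
    landuse_future: dict  # (rcp, ssp) -> harmonised LandUseSeries
    biomes_hist: list  # list[BiomeMap], decadal
    biomes_future: dict  # (rcp, model) -> list[BiomeMap]
    n_dropped_species: int = 0
    climate_hist: list = field(default_factory=list)  # window-averaged fields fed to the classifier


# ---------------------------------------------------------------------------
# toy climate truth

def _warming(year: float, cfg: WorldConfig, rcp: str | None, model: str | None) -> float:
    """Global-mean warming (degC above 1900) of the toy climate."""
    if year <= 1900:
        return 0.0
    hist_rate = cfg.hist_warming_2016 / (2016 - 1900)
    if year <= 2016 or rcp is None:
        return hist_rate * (year - 1900)
    w2100 = RCP_WARMING_2100[rcp] + (MODEL_OFFSETS[model] if model else 0.0)
    w2016 = cfg.hist_warming_2016
    return w2016 + (w2100 - w2016) * (year - 2016) / (2100 - 2016)


def _true_climate(year: int, grid: GridSpec, cfg: WorldConfig,
                  rcp: str | None = None, model: str | None = None) -> dict:
    """Analytic monthly climatology: zonal bands plus a warming trend."""
    lat = grid.lat_centers()[:, None] * np.ones((1, grid.nlon))
    months = np.arange(1, 13)
    base = 28.0 - 0.55 * np.abs(lat) + _warming(year, cfg, rcp, model)
    # seasonal cycle, opposite phase per hemisphere; exact zero annual mean
    amp = 10.0 * np.abs(lat) / 60.0
    season = np.cos(2 * np.pi * (months[:, None, None] - 0.5) / 12.0)
    sign = np.where(lat >= 0, 1.0, -1.0)
    temp = base[None] + amp[None] * sign[None] * season
    prec = 60.0 + 120.0 * np.exp(-((lat / 20.0) ** 2)) \
        + 30.0 * np.exp(-(((np.abs(lat) - 50.0) / 12.0) ** 2))
    prec = np.broadcast_to(prec[None], (12, *grid.shape)).copy()
    return {
        "temperature": ClimateField("temperature", year, grid, temp),
        "precipitation": ClimateField("precipitation", year, grid, prec),
    }


def _sim_climate(year: int, grid: GridSpec, cfg: WorldConfig,
                 rcp: str | None, model: str | None) -> dict:
    """Simulated climate = truth plus a constant model bias."""
    f = _true_climate(year, grid, cfg, rcp, model)
    t = f["temperature"]
    p = f["precipitation"]
    return {
        "temperature": ClimateField("temperature", year, grid, t.data + cfg.sim_bias_degC),
        "precipitation": ClimateField("precipitation", year, grid,
                                      np.clip(p.data + cfg.sim_bias_precip, 0, None)),
    }


def _biome_map_for(year: int, grid: GridSpec, cfg: WorldConfig,
                   rcp: str | None = None, model: str | None = None,
                   window: int = 30) -> tuple[BiomeMap, dict]:
    """Delta-corrected, window-averaged climate -> toy biome map at ``year``.

    For years where only "simulated" climate exists (pre-1901 and
    post-2016) each annual field is bias-corrected with the delta method
    before the 30-year averaging; elsewhere the observational truth is used
    directly. References follow the pipeline convention: the 1900-1930 mean
    for the historical correction, the single year 2006 for the future.
    """
    fields: dict = {}
    years = range(year - window, year + 1)
    for var in ("temperature", "precipitation"):
        hist_refs = fut_refs = None
        if any(y <= 1900 for y in years):
            ref_years = range(1900, 1931)
            hist_refs = (
                window_average(
                    [_sim_climate(r, grid, cfg, rcp, model)[var] for r in ref_years],
                    1930, 30),
                window_average(
                    [_true_climate(r, grid, cfg)[var] for r in ref_years], 1930, 30),
            )
        if any(y > 2016 for y in years):
            fut_refs = (_sim_climate(2006, grid, cfg, rcp, model)[var],
                        _true_climate(2006, grid, cfg)[var])
        yearly = []
        for y in years:
            if 1901 <= y <= 2016:
                yearly.append(_true_climate(y, grid, cfg)[var])
                continue
            sim_y = _sim_climate(y, grid, cfg, rcp, model)[var]
            sim_ref, obs_ref = hist_refs if y <= 1900 else fut_refs
            yearly.append(delta_correct(sim_y, sim_ref, obs_ref))
        fields[var] = window_average(yearly, year, window)
    return toy_biome_classify(fields), fields


# ---------------------------------------------------------------------------
# land use

def _logistic_total(years: np.ndarray, grid: GridSpec, cfg: WorldConfig,
                    texture: np.ndarray) -> np.ndarray:
    """Total converted fraction (T, Y, X): staggered logistic expansion."""
    lat = grid.lat_centers()[:, None] * np.ones((1, grid.nlon))
    mid = np.where(np.abs(lat) < cfg.tropic_lat, cfg.late_midpoint, cfg.early_midpoint)
    t = years[:, None, None].astype(float)
    tot = cfg.asymptote / (1.0 + np.exp(-cfg.logistic_rate * (t - mid[None])))
    return tot * texture[None]


_CLASS_SHARES = {"cropland": 0.5, "pasture": 0.4, "urban": 0.1}


def _landuse_from_total(grid: GridSpec, years: np.ndarray, total: np.ndarray,
                        half_width: float, variants=("baseline", "lower", "upper"),
                        ) -> LandUseSeries:
    data = {}
    mult = {"baseline": 1.0, "lower": 1.0 - half_width, "upper": 1.0 + half_width}
    for v in variants:
        for c in CLASSES:
            data[(c, v)] = np.clip(total * _CLASS_SHARES[c] * mult[v], 0.0, 1.0)
    return LandUseSeries(grid=grid, years=years, data=data)


# ---------------------------------------------------------------------------
# species

_ARTIFICIAL_CATEGORIES = {"arable_land": "cropland", "pasture_land": "pasture",
                          "urban_areas": "urban"}


def default_crosswalk() -> HabitatCrosswalk:
    """Toy habitat-category table: one category per toy biome plus the
    three artificial land-cover categories."""
    natural = {f"biome{c}": frozenset({c}) for c in TOY_BIOME_CODES}
    natural.update({k: frozenset() for k in _ARTIFICIAL_CATEGORIES})
    artificial = {k: frozenset() for k in natural}
    artificial.update({k: frozenset({v}) for k, v in _ARTIFICIAL_CATEGORIES.items()})
    return HabitatCrosswalk(natural=natural, artificial=artificial)


def _gen_species(rng: np.random.Generator, cfg: WorldConfig, grid: GridSpec,
                 biomes_1850: BiomeMap, crosswalk: HabitatCrosswalk,
                 ) -> tuple[list, int]:
    """Random species with rectangular EOOs; tropical species are smaller-ranged."""
    fine = grid.refine()
    species: list[SpeciesRecord] = []
    dropped = 0
    for group in ("mammal", "bird", "amphibian"):
        for i in range(cfg.n_species_per_group):
            tropical = rng.random() < 0.5
            if tropical:
                lat0 = rng.uniform(-cfg.tropic_lat, cfg.tropic_lat)
                size = math.exp(rng.uniform(math.log(3.0), math.log(12.0)))
            else:
                band = rng.choice([-1, 1])
                lat0 = band * rng.uniform(cfg.tropic_lat, cfg.lat_max - 5)
                size = math.exp(rng.uniform(math.log(8.0), math.log(50.0)))
            lon0 = rng.uniform(cfg.lon_min, cfg.lon_max)
            aspect = rng.uniform(0.5, 2.0)
            h, w = size, size * aspect
            box = shapely.box(
                max(cfg.lon_min, lon0 - w / 2), max(cfg.lat_min, lat0 - h / 2),
                min(cfg.lon_max, lon0 + w / 2), min(cfg.lat_max, lat0 + h / 2),
            )
            eoo = polygon_coverage(box, fine, grid)
            if eoo.sum() <= 0:
                dropped += 1
                continue
            present = np.unique(biomes_1850.codes[eoo > 0])
            keep = [int(c) for c in present if rng.random() < 0.8]
            if not keep:
                keep = [int(present[rng.integers(len(present))])]
            categories = [f"biome{c}" for c in keep]
            for cat, cls in _ARTIFICIAL_CATEGORIES.items():
                p = {"cropland": 0.35, "pasture": 0.45, "urban": 0.05}[cls]
                if rng.random() < p:
                    categories.append(cat)
            species.append(SpeciesRecord(
                species_id=f"{group[:3]}_{i:03d}",
                group=group,
                eoo_fraction=eoo,
                suitable_biomes=crosswalk.suitable_biomes(categories),
                suitable_artificial=crosswalk.suitable_artificial(categories),
            ))
    if dropped:
        logger.info("dropped %d species whose EOO overlapped no grid cell", dropped)
    return species, dropped


# ---------------------------------------------------------------------------
# the generator

def gen_world(cfg: WorldConfig, *, future: bool = True) -> World:
    """Generate a full synthetic input bundle, reproducible given the seed.

    ``future=False`` skips the scenario land-use and biome projections
    (historical-only worlds are much cheaper and suffice for many tests).
    """
    rng = np.random.default_rng(cfg.seed)
    grid = cfg.grid()
    areas = cell_areas(grid)
    years_hist = np.array(HIST_YEARS)

    texture = rng.uniform(0.5, 1.0, size=grid.shape)
    total_hist = _logistic_total(years_hist, grid, cfg, texture)
    landuse_hist = _landuse_from_total(grid, years_hist, total_hist,
                                       cfg.uncertainty_half_width)

    biomes_hist, climate_hist = [], []
    for year in BIOME_DECADES_HIST:
        bm, fields = _biome_map_for(year, grid, cfg)
        biomes_hist.append(bm)
        climate_hist.append(fields)

    crosswalk = default_crosswalk()
    bm_1850 = next(b for b in biomes_hist if b.year == 1850)
    species, dropped = _gen_species(rng, cfg, grid, bm_1850, crosswalk)

    landuse_future: dict = {}
    biomes_future: dict = {}
    if future:
        j = int(np.flatnonzero(years_hist == 2010)[0])
        hist_2010 = total_hist[j]
        years_fut = np.array((2010,) + FUTURE_YEARS)
        for ssp in cfg.ssps:
            g2100 = SSP_LAND_FACTOR_2100[ssp]
            g = 1.0 + (g2100 - 1.0) * (years_fut - 2010) / (2100 - 2010)
            # raw projection disagrees with the reconstruction at 2010 by a
            # constant factor, so harmonisation has real work to do
            raw = np.clip(0.9 * hist_2010[None] * g[:, None, None], 0.0, 0.95)
            raw_series = _landuse_from_total(grid, years_fut, raw, 0.0,
                                             variants=("baseline",))
            for rcp in cfg.rcps:
                landuse_future[(rcp, ssp)] = harmonise_future(
                    landuse_hist, raw_series, junction_year=2010)
        for rcp in cfg.rcps:
            for model in cfg.climate_models:
                maps = [
                    _biome_map_for(year, grid, cfg, rcp=rcp, model=model)[0]
                    for year in FUTURE_YEARS
                ]
                biomes_future[(rcp, model)] = maps

    return World(
        config=cfg, grid=grid, areas=areas, species=species,
        crosswalk=crosswalk, mega_crosswalk=dict(MEGA_BIOMES),
        landuse_hist=landuse_hist, landuse_future=landuse_future,
        biomes_hist=biomes_hist, biomes_future=biomes_future,
        n_dropped_species=dropped, climate_hist=climate_hist,
    )


# ---------------------------------------------------------------------------
# the exactly solvable fixture

FIXTURE_YEARS = (1850, 1900, 1950)


def _zone_area(lat1: float, lat2: float, dlon_deg: float, radius_km: float = 6371.0) -> float:
    """Independent closed-form cell area used only by the fixture ledger."""
    return radius_km ** 2 * math.radians(dlon_deg) * (
        math.sin(math.radians(lat2)) - math.sin(math.radians(lat1)))


def analytic_fixture() -> tuple[World, dict]:
    """A 4x4-cell world with three species and a hand-computed ledger.

    The world has two biomes (1 forest, 2 grassland) on a 1-degree grid over
    [0, 4]N x [0, 4]E and three time points. Species live on single latitude
    rows so cell areas cancel out of every relative change and the expected
    values are exact rationals:

    * ``natural_only`` tolerates biome 1 only; cropland expands across its
      row (0.25 by 1900, 0.75 by 1950) and one of its cells flips to
      grassland in 1950, so its range contracts.
    * ``cropland_lover`` tolerates biome 1 and cropland; half its row is
      grassland that is fully converted to cropland by 1950, so in the
      default extended mode its range *expands*, while in strict mode its
      change equals the climate-only change (zero).
    * ``no_baseline`` has its whole extent on grassland, a zero reference
      potential range, and is excluded from change statistics.

    Returns the input bundle and a ledger dict of every expected quantity,
    all computed here by direct scalar arithmetic independent of the
    pipeline implementations.
    """
    cfg = WorldConfig(seed=0, resolution_deg=1.0, lat_min=0.0, lat_max=4.0,
                      lon_min=0.0, lon_max=4.0, n_species_per_group=0)
    grid = cfg.grid()
    areas = cell_areas(grid)

    # biomes: row 0 (3-4N) forest, flipping one cell in 1950; row 1 half
    # forest half grassland; row 2 grassland; row 3 forest
    base = np.array([
        [1, 1, 1, 1],
        [1, 1, 2, 2],
        [2, 2, 2, 2],
        [1, 1, 1, 1],
    ])
    codes_1950 = base.copy()
    codes_1950[0, 0] = 2
    biome_maps = [
        BiomeMap(1850, grid, base, code_list=(1, 2)),
        BiomeMap(1900, grid, base, code_list=(1, 2)),
        BiomeMap(1950, grid, codes_1950, code_list=(1, 2)),
    ]

    # cropland: row 0 uniform 0 / 0.25 / 0.75; row 1 grassland cells
    # 0 / 0.5 / 1.0; pasture and urban identically zero
    crop = np.zeros((3, 4, 4))
    crop[1, 0, :] = 0.25
    crop[2, 0, :] = 0.75
    crop[1, 1, 2:] = 0.5
    crop[2, 1, 2:] = 1.0
    data = {("cropland", "baseline"): crop,
            ("pasture", "baseline"): np.zeros_like(crop),
            ("urban", "baseline"): np.zeros_like(crop)}
    landuse = LandUseSeries(grid=grid, years=np.array(FIXTURE_YEARS), data=data)

    row = np.zeros((4, 4))
    crosswalk = default_crosswalk()

    def eoo_row(r):
        e = row.copy()
        e[r, :] = 1.0
        return e

    sp_a = SpeciesRecord("natural_only", "mammal", eoo_row(0),
                         frozenset({1}), frozenset())
    sp_b = SpeciesRecord("cropland_lover", "bird", eoo_row(1),
                         frozenset({1}), frozenset({"cropland"}))
    sp_c = SpeciesRecord("no_baseline", "amphibian", eoo_row(2),
                         frozenset({1}), frozenset())

    world = World(
        config=cfg, grid=grid, areas=areas, species=[sp_a, sp_b, sp_c],
        crosswalk=crosswalk, mega_crosswalk={1: "M1", 2: "M2"},
        landuse_hist=landuse, landuse_future={}, biomes_hist=biome_maps,
        biomes_future={},
    )

    # --- expected-output ledger, independent scalar arithmetic -------------
    a0 = _zone_area(3.0, 4.0, 1.0)   # row-0 cell area
    a1 = _zone_area(2.0, 3.0, 1.0)   # row-1 cell area

    ledger = {
        "years": list(FIXTURE_YEARS),
        "t0": 1850,
        "A_potential": {
            "natural_only": [4 * a0, 4 * a0, 3 * a0],
            "cropland_lover": [2 * a1, 2 * a1, 2 * a1],
            "no_baseline": [0.0, 0.0, 0.0],
        },
        "A_actual": {
            "extended": {
                # 1950: three forest cells at 1-0.75 habitat; flipped cell 0
                "natural_only": [4 * a0, 4 * a0 * 0.75, 3 * a0 * 0.25],
                # grassland cells contribute their cropland fraction
                "cropland_lover": [2 * a1, (2 + 2 * 0.5) * a1, 4 * a1],
                "no_baseline": [0.0, 0.0, 0.0],
            },
            "strict": {
                "natural_only": [4 * a0, 4 * a0 * 0.75, 3 * a0 * 0.25],
                # artificial habitat outside the potential range is ignored
                "cropland_lover": [2 * a1, 2 * a1, 2 * a1],
                "no_baseline": [0.0, 0.0, 0.0],
            },
        },
        "delta_pct": {
            "extended": {"natural_only": [0.0, -25.0, -81.25],
                         "cropland_lover": [0.0, 50.0, 100.0]},
            "strict": {"natural_only": [0.0, -25.0, -81.25],
                       "cropland_lover": [0.0, 0.0, 0.0]},
        },
        "climate_only_pct": {"natural_only": [0.0, 0.0, -25.0],
                             "cropland_lover": [0.0, 0.0, 0.0]},
        "excluded": {"natural_only": False, "cropland_lover": False,
                     "no_baseline": True},
        # median over the two included species (linear interpolation = mean of 2)
        "median_pct": {
            "extended": [0.0, (50.0 - 25.0) / 2, (100.0 - 81.25) / 2],
            "strict": [0.0, -12.5, -40.625],
        },
        # share of included species with delta < -50%
        "critical_share": {"extended": [0.0, 0.0, 0.5],
                           "strict": [0.0, 0.0, 0.5]},
        "primary_mega_biome": {"natural_only": "M1", "cropland_lover": "M1"},
    }
    return world, ledger
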