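"""Time-indexed land-use class fractions with uncertainty variants.

A :class:`LandUseSeries` holds per-cell fractions of the three anthropogenic
land-cover classes (cropland, pasture, urban) on the coarse analysis grid,
for an ordered set of calendar years and up to three uncertainty variants
(baseline plus lower/upper bounds of the reconstruction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .grid import GridSpec

logger = logging.getLogger(__name__)

CLASSES = ("cropland", "pasture", "urban")
VARIANTS = ("baseline", "lower", "upper")


@dataclass
class LandUseSeries:
    """Land-use class fractions indexed by (class, variant) -> (time, lat, lon).

    Fractions are clamped into [0, 1] on ingest; cells whose class sum
    exceeds 1 are rescaled proportionally so the sum is exactly 1, and the
    number of affected cells is logged.
    """

    grid: GridSpec
    years: np.ndarray  # strictly increasing ints
    data: dict = field(default_factory=dict)  # (class, variant) -> ndarray (T, Y, X)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        if self.years.ndim != 1 or len(self.years) == 0:
            raise ValueError("years must be a nonempty 1-D sequence")
        if np.any(np.diff(self.years) <= 0):
            raise ValueError("years must be strictly increasing")
        self._validate()

    def _validate(self) -> None:
        T = len(self.years)
        shape = (T, *self.grid.shape)
        n_clamped = 0
        variants = self.variants
        for v in variants:
            for c in CLASSES:
                if (c, v) not in self.data:
                    raise ValueError(f"missing class {c!r} for variant {v!r}")
                arr = np.asarray(self.data[(c, v)], dtype=float)
                if arr.shape != shape:
                    raise ValueError(f"layer {(c, v)} has shape {arr.shape}, expected {shape}")
                self.data[(c, v)] = np.clip(arr, 0.0, 1.0)
            tot = sum(self.data[(c, v)] for c in CLASSES)
            over = tot > 1.0 + 1e-6
            if np.any(over):
                n_clamped += int(over.sum())
                scale = np.where(tot > 1.0, 1.0 / np.maximum(tot, 1e-300), 1.0)
                for c in CLASSES:
                    self.data[(c, v)] = self.data[(c, v)] * scale
        if n_clamped:
            logger.warning("rescaled %d cell-times whose class sum exceeded 1", n_clamped)
        if {"lower", "baseline", "upper"} <= set(variants):
            for c in CLASSES:
                lo, ba, up = (self.data[(c, v)] for v in ("lower", "baseline", "upper"))
                if np.any(lo > ba + 1e-9) or np.any(ba > up + 1e-9):
                    logger.warning("variant ordering lower <= baseline <= upper violated for %s", c)

    @property
    def variants(self) -> tuple[str, ...]:
        return tuple(sorted({v for (_, v) in self.data}, key=VARIANTS.index))

    def year_index(self, year: int) -> int:
        idx = np.flatnonzero(self.years == year)
        if len(idx) == 0:
            raise KeyError(f"year {year} not in series (have {self.years.min()}..{self.years.max()})")
        return int(idx[0])

    def layer(self, cls: str, year: int, variant: str = "baseline") -> np.ndarray:
        """Fraction field (lat, lon) for one class, year and variant."""
        return self.data[(cls, variant)][self.year_index(year)]

    def converted_fraction(self, year: int, variant: str = "baseline") -> np.ndarray:
        """Total converted (cropland+pasture+urban) fraction, capped at 1."""
        tot = sum(self.layer(c, year, variant) for c in CLASSES)
        return np.minimum(tot, 1.0)


def harmonise_future(
    hist: LandUseSeries, future: LandUseSeries, junction_year: int = 2010
) -> LandUseSeries:
    """Splice a future projection onto a historical reconstruction.

    Per class and cell, the historical-minus-future difference at the
    junction year is added to every future time step, so the output matches
    the historical series exactly at the junction. Results are clamped to
    [0, 1]; if clamping pushes a cell's class sum above 1 the classes are
    rescaled proportionally (handled by series validation).

    Variants present in the future series are harmonised against the same
    variant of the historical series when available, else against baseline.
    """
    out_data: dict = {}
    for v in future.variants:
        hv = v if v in hist.variants else "baseline"
        for c in CLASSES:
            h_j = hist.layer(c, junction_year, hv)
            f_j = future.layer(c, junction_year, v)
            delta = h_j - f_j
            out_data[(c, v)] = np.clip(future.data[(c, v)] + delta[None, :, :], 0.0, 1.0)
    return LandUseSeries(grid=future.grid, years=future.years.copy(), data=out_data)


def cumulative_converted_area(
    series: LandUseSeries, year: int, areas: np.ndarray, variant: str = "baseline"
) -> float:
    """Global converted (agricultural + urban) area in km**2 at ``year``.

    Sum over cells of the total class fraction (capped at 1) times cell area.
    """
    if areas.shape != series.grid.shape:
        raise ValueError("areas not aligned to the land-use grid")
    return float((series.converted_fraction(year, variant) * areas).sum())


#: Sentinel for cells that never experienced net conversion.
NO_CONVERSION = -1


def peak_conversion_time(
    series: LandUseSeries, t_max: int, variant: str = "baseline"
) -> np.ndarray:
    """Per-cell year of the fastest conversion to agricultural/urban land.

    The conversion rate over each interval [t_k, t_{k+1}] with t_{k+1} <=
    ``t_max`` is the change in total converted fraction divided by the
    interval length; the returned map holds the interval *end* year of the
    maximal rate. Ties go to the earliest interval; cells where no interval
    has a positive rate are flagged :data:`NO_CONVERSION`.
    """
    years = series.years[series.years <= t_max]
    if len(years) < 2:
        raise ValueError("need at least two time points at or before t_max")
    conv = np.stack([series.converted_fraction(int(y), variant) for y in years])
    dt = np.diff(years).astype(float)[:, None, None]
    rates = np.diff(conv, axis=0) / dt  # (T-1, Y, X)
    best = rates.argmax(axis=0)  # argmax takes the first maximum -> earliest tie-break
    out = years[1:][best].astype(int)
    out[rates.max(axis=0) <= 0.0] = NO_CONVERSION
    return out
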