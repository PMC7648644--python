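"""Delta-method bias correction and window averaging of monthly climate fields.

Simulated climate is corrected by adding the observed-minus-simulated
difference from a reference period to the simulation, which simultaneously
removes systematic model bias and — because the difference is taken on the
observational grid after nearest-neighbour regridding of the simulation —
downscales the simulation to the observational resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import GridSpec

VARIABLES = ("temperature", "precipitation", "sunshine")
# valid value ranges used to clamp after additive correction
_CLAMP = {"temperature": (None, None), "precipitation": (0.0, None), "sunshine": (0.0, 100.0)}


@dataclass
class ClimateField:
    """One year of monthly climatology for one variable on a grid.

    ``data`` has shape (12, nlat, nlon): temperature in degC, precipitation
    in mm/month, sunshine in percent.
    """

    variable: str
    year: int
    grid: GridSpec
    data: np.ndarray

    def __post_init__(self) -> None:
        if self.variable not in VARIABLES:
            raise ValueError(f"unknown variable {self.variable!r}")
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (12, *self.grid.shape):
            raise ValueError(
                f"expected 12 monthly slices of shape {self.grid.shape}, got {self.data.shape}"
            )
        lo, hi = _CLAMP[self.variable]
        if lo is not None and np.any(self.data < lo - 1e-9):
            raise ValueError(f"{self.variable} below valid minimum {lo}")
        if hi is not None and np.any(self.data > hi + 1e-9):
            raise ValueError(f"{self.variable} above valid maximum {hi}")

    def annual_mean(self) -> np.ndarray:
        return self.data.mean(axis=0)


def regrid_nearest(field: ClimateField, target: GridSpec) -> ClimateField:
    """Nearest-neighbour regridding onto ``target`` by cell-centre lookup."""
    src = field.grid
    lat_idx = np.clip(
        ((src.lat_max - target.lat_centers()) / src.resolution_deg).astype(int),
        0, src.nlat - 1,
    )
    lon_idx = np.clip(
        ((target.lon_centers() - src.lon_min) / src.resolution_deg).astype(int),
        0, src.nlon - 1,
    )
    data = field.data[:, lat_idx[:, None], lon_idx[None, :]]
    return ClimateField(field.variable, field.year, target, data)


def delta_correct(
    sim_t: ClimateField, sim_ref: ClimateField, obs_ref: ClimateField
) -> ClimateField:
    """Additive delta correction: ``sim_t + (obs_ref - sim_ref)``.

    ``obs_ref`` defines the output grid; ``sim_t`` and ``sim_ref`` are
    regridded to it by nearest neighbour first. Precipitation and sunshine
    are clamped to their physical ranges after the shift; temperature is
    unbounded.
    """
    if not (sim_t.variable == sim_ref.variable == obs_ref.variable):
        raise ValueError("variable mismatch between simulation and observations")
    target = obs_ref.grid
    if sim_t.grid != target:
        sim_t = regrid_nearest(sim_t, target)
    if sim_ref.grid != target:
        sim_ref = regrid_nearest(sim_ref, target)
    out = sim_t.data + (obs_ref.data - sim_ref.data)
    lo, hi = _CLAMP[sim_t.variable]
    if lo is not None or hi is not None:
        out = np.clip(out, lo if lo is not None else -np.inf, hi if hi is not None else np.inf)
    return ClimateField(sim_t.variable, sim_t.year, target, out)


def window_average(series: list[ClimateField], t: int, window_years: int = 30) -> ClimateField:
    """Mean climatology over the closed interval [t - window_years, t].

    With the default 30-year window this averages 31 annual fields. Every
    year in the interval must be present; missing years raise an error
    naming them.
    """
    by_year = {f.year: f for f in series}
    wanted = list(range(t - window_years, t + 1))
    missing = [y for y in wanted if y not in by_year]
    if missing:
        raise ValueError(f"window [{t - window_years}, {t}] missing years: {missing}")
    fields = [by_year[y] for y in wanted]
    ref = fields[0]
    for f in fields[1:]:
        if f.variable != ref.variable or f.grid != ref.grid:
            raise ValueError("window fields must share variable and grid")
    data = np.mean([f.data for f in fields], axis=0)
    return ClimateField(ref.variable, t, ref.grid, data)
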