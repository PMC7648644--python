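"""Range-change statistics: percentile fans, critical losses, marginal
losses, bootstrap resampling and multi-model aggregation.

The central quantity is the relative range change of species i at time t,

    dA_i(t) = 100% * (A_i_actual(t) / A_i_potential(t0) - 1),

i.e. the actual habitat range as a percentage change against the species'
potential natural range at the pre-industrial reference year t0 = 1850.
Species with a zero reference range are excluded (the change is undefined).
The climate-only variant substitutes A_potential(t) for A_actual(t) and so
isolates range change driven by biome shifts alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ranges import BiomeMap, RangeSeries, SpeciesRecord, potential_range_field

DEFAULT_PERCENTILES = (10, 20, 30, 40, 50, 60, 70, 80, 90)
CRITICAL_THRESHOLD = 50.0


def range_change(a_actual_t: float, a_potential_t0: float) -> float:
    """Percent range change relative to the reference potential range.

    Returns NaN (excluded) for a zero or negative baseline.
    """
    if a_potential_t0 <= 0.0:
        return float("nan")
    return 100.0 * (a_actual_t / a_potential_t0 - 1.0)


def climate_only_change(a_potential_t: float, a_potential_t0: float) -> float:
    """Percent change of the potential range itself (biome shifts only)."""
    return range_change(a_potential_t, a_potential_t0)


@dataclass
class ChangeTable:
    """Tidy per-species, per-time range changes (percent).

    ``frame`` columns: species_id, year, delta_pct, climate_only_pct,
    excluded. Excluded species carry NaN changes and are dropped from all
    summaries.
    """

    frame: pd.DataFrame
    t0: int

    @classmethod
    def from_series(cls, series_list: list[RangeSeries]) -> "ChangeTable":
        rows = []
        t0 = series_list[0].t0 if series_list else 1850
        for rs in series_list:
            for i, y in enumerate(rs.years):
                rows.append(
                    {
                        "species_id": rs.species_id,
                        "year": int(y),
                        "delta_pct": range_change(rs.a_actual[i], rs.a_potential_t0),
                        "climate_only_pct": climate_only_change(
                            rs.a_potential[i], rs.a_potential_t0
                        ),
                        "excluded": rs.excluded,
                    }
                )
        return cls(frame=pd.DataFrame(rows), t0=t0)

    def included(self) -> pd.DataFrame:
        return self.frame[~self.frame["excluded"]]

    def changes_at(self, year: int, column: str = "delta_pct") -> np.ndarray:
        df = self.included()
        return df.loc[df["year"] == year, column].to_numpy()


def percentile_curves(
    table: ChangeTable,
    percentiles=DEFAULT_PERCENTILES,
    column: str = "delta_pct",
) -> pd.DataFrame:
    """Across-species percentiles of range change per time point.

    Uses the linear-interpolation percentile convention. Returns a tidy
    frame (year, percentile, value).
    """
    df = table.included()
    if df.empty:
        raise ValueError("no included species in the change table")
    rows = []
    for year, grp in df.groupby("year"):
        vals = grp[column].to_numpy()
        qs = np.percentile(vals, percentiles, method="linear")
        rows.extend(
            {"year": int(year), "percentile": int(p), "value": float(q)}
            for p, q in zip(percentiles, qs)
        )
    return pd.DataFrame(rows)


def critical_loss_fraction(
    table: ChangeTable,
    year: int,
    threshold: float = CRITICAL_THRESHOLD,
    groups: dict | None = None,
) -> pd.DataFrame:
    """Share of included species that lost strictly more than ``threshold``
    percent of their reference range (delta < -threshold) at ``year``.

    With ``groups`` (species_id -> mega-biome label) the share is also
    reported per group, under both normalisations: within the group
    (``share_within``) and relative to all included species (``share_of_all``).
    A species at exactly -threshold is not counted. Empty groups are flagged
    with NaN shares.
    """
    df = table.included()
    df = df[df["year"] == year]
    if df.empty:
        raise ValueError(f"no included species at year {year}")
    lost = df["delta_pct"] < -threshold
    n_all = len(df)
    rows = [
        {
            "group": "__all__",
            "n": n_all,
            "n_critical": int(lost.sum()),
            "share_within": float(lost.mean()),
            "share_of_all": float(lost.mean()),
        }
    ]
    if groups is not None:
        labels = df["species_id"].map(groups)
        for g in sorted(set(groups.values())):
            sel = labels == g
            n_g = int(sel.sum())
            n_c = int((lost & sel).sum())
            rows.append(
                {
                    "group": g,
                    "n": n_g,
                    "n_critical": n_c,
                    "share_within": (n_c / n_g) if n_g else float("nan"),
                    "share_of_all": n_c / n_all,
                }
            )
    return pd.DataFrame(rows)


def primary_mega_biome(
    sp: SpeciesRecord,
    biomes_t0: BiomeMap,
    mega_crosswalk: dict,
    areas: np.ndarray,
) -> str:
    """The mega-biome contributing the largest share of the species'
    reference potential range area; ties break to the lowest label.

    ``mega_crosswalk`` maps biome code -> mega-biome label.
    """
    field = potential_range_field(sp, biomes_t0)
    if field.sum() <= 0:
        raise ValueError(f"species {sp.species_id} has zero baseline potential range")
    shares: dict = {}
    for code in np.unique(biomes_t0.codes):
        label = mega_crosswalk.get(int(code))
        if label is None:
            continue
        mask = biomes_t0.codes == code
        shares[label] = shares.get(label, 0.0) + float((field * mask * areas).sum())
    return min(shares.items(), key=lambda kv: (-kv[1], kv[0]))[0]


def marginal_loss_curve(
    years,
    median_losses,
    cumulative_areas,
) -> pd.DataFrame:
    """Median range loss against cumulative converted area, with marginal
    losses per unit newly converted area by successive finite differences.

    Returns a frame (year, cum_area_km2, median_loss_pct, marginal_loss_pct_per_km2);
    the marginal column is NaN for the first point and wherever no new area
    was converted.
    """
    years = np.asarray(years)
    losses = np.asarray(median_losses, dtype=float)
    areas = np.asarray(cumulative_areas, dtype=float)
    if not (len(years) == len(losses) == len(areas)):
        raise ValueError("years, losses and cumulative areas must share a time grid")
    order = np.argsort(years)
    years, losses, areas = years[order], losses[order], areas[order]
    marginal = np.full(len(years), np.nan)
    d_area = np.diff(areas)
    d_loss = np.diff(losses)
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.where(d_area > 0, d_loss / d_area, np.nan)
    marginal[1:] = m
    return pd.DataFrame(
        {
            "year": years,
            "cum_area_km2": areas,
            "median_loss_pct": losses,
            "marginal_loss_pct_per_km2": marginal,
        }
    )


def local_mean_range_map(
    potential_fields: list[np.ndarray],
    global_areas: list[float],
    cell_areas_field: np.ndarray,
) -> np.ndarray:
    """Per-cell mean global potential range size of locally present species.

    A species is locally present where its potential fraction is > 0; the
    map averages the species' *global* reference range sizes (km**2) over
    the species present in each cell, unweighted. Cells hosting no species
    are NaN.
    """
    if len(potential_fields) != len(global_areas):
        raise ValueError("one global area per potential field required")
    if not potential_fields:
        raise ValueError("need at least one species")
    total = np.zeros_like(cell_areas_field, dtype=float)
    count = np.zeros_like(cell_areas_field, dtype=float)
    for fld, a in zip(potential_fields, global_areas):
        present = fld > 0
        total += present * a
        count += present
    with np.errstate(invalid="ignore"):
        out = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return out


def bootstrap_percentiles(
    changes: np.ndarray,
    percentiles=DEFAULT_PERCENTILES,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Bootstrap mean and SD of across-species range-change percentiles.

    Resamples the change vector with replacement (resample size = input
    size) ``n_boot`` times, computes each requested percentile per resample,
    and reports the mean and standard deviation over resamples. Fully
    reproducible given ``seed`` (PCG64 generator, fixed algorithm).
    """
    changes = np.asarray(changes, dtype=float)
    if changes.size == 0:
        raise ValueError("empty change vector")
    if seed is None:
        raise ValueError("an explicit seed is required for reproducibility")
    rng = np.random.default_rng(seed)
    n = changes.size
    idx = rng.integers(0, n, size=(n_boot, n))
    samples = changes[idx]
    qs = np.percentile(samples, percentiles, axis=1, method="linear")  # (P, n_boot)
    return pd.DataFrame(
        {
            "percentile": list(percentiles),
            "mean": qs.mean(axis=1),
            "sd": qs.std(axis=1, ddof=0),
        }
    )


def scenario_aggregate(curves: dict) -> pd.DataFrame:
    """Pointwise mean and sample SD across climate-model curves.

    ``curves`` maps model name -> (years, values); all models must share the
    time grid. SD uses the n-1 denominator; with a single model the SD is
    NaN and flagged.
    """
    if not curves:
        raise ValueError("no model curves supplied")
    items = list(curves.items())
    years0 = np.asarray(items[0][1][0])
    vals = []
    for name, (years, v) in items:
        if not np.array_equal(np.asarray(years), years0):
            raise ValueError(f"model {name!r} is on a different time grid")
        vals.append(np.asarray(v, dtype=float))
    stack = np.vstack(vals)
    n = stack.shape[0]
    sd = stack.std(axis=0, ddof=1) if n >= 2 else np.full(len(years0), np.nan)
    return pd.DataFrame(
        {
            "year": years0,
            "mean": stack.mean(axis=0),
            "sd": sd,
            "n_models": n,
        }
    )
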