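"""Plot helpers mirroring the standard presentations of range-change
results: percentile fan charts, critical-loss bars and the marginal-loss
curve. Each function draws on a provided or fresh matplotlib Axes and
returns it."""

from __future__ import annotations

import numpy as np


def percentile_fan(curves, ax=None):
    """Fan chart of per-time range-change percentiles.

    ``curves`` is the tidy frame from ``percentile_curves`` (year,
    percentile, value); the median is drawn as a black line, symmetric
    percentile pairs as shaded bands.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    wide = curves.pivot(index="year", columns="percentile", values="value")
    ps = sorted(wide.columns)
    pairs = [(p, 100 - p) for p in ps if p < 50 and (100 - p) in ps]
    cmap = plt.get_cmap("coolwarm_r")
    for i, (lo, hi) in enumerate(sorted(pairs)):
        ax.fill_between(wide.index, wide[lo], wide[hi],
                        color=cmap(i / max(len(pairs), 1)), alpha=0.5, lw=0)
    if 50 in ps:
        ax.plot(wide.index, wide[50], color="k", lw=1.5, label="median")
    ax.axhline(0, color="grey", lw=0.5)
    ax.set_xlabel("year")
    ax.set_ylabel("range change (%)")
    return ax


def critical_loss_bars(shares, ax=None, normalisation="share_within"):
    """Bar chart of critical-loss shares per mega-biome group."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    df = shares[shares["group"] != "__all__"]
    ax.bar(df["group"], 100 * df[normalisation])
    ax.set_ylabel("species losing >50% of range (%)")
    return ax


def marginal_loss(curve, ax=None):
    """Median loss against cumulative converted area (Gha)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    gha = np.asarray(curve["cum_area_km2"]) / 1e7  # km^2 -> Gha
    ax.plot(gha, curve["median_loss_pct"], marker=".", lw=1)
    ax.set_xlabel("cumulative converted area (Gha)")
    ax.set_ylabel("median range change (%)")
    return ax
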