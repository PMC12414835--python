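"""Plot helpers for the report tables (matplotlib, no display required)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def density_boxplot(
    density_stats: pd.DataFrame,
    forest_type: str = "all",
    radius_m: float = 3000.0,
    region: int | None = None,
):
    """Boxplots of GI density across scenarios from precomputed statistics.

    Uses the stored quartiles/whiskers (matplotlib ``bxp``), so the figure
    reflects exactly the numbers of the report tables.
    """
    sub = density_stats[
        (density_stats["forest_type"] == forest_type)
        & (density_stats["radius_m"] == radius_m)
    ]
    if region is not None:
        sub = sub[sub["region"] == region]
    if sub.empty:
        raise ValueError("no matching rows in density_stats")
    boxes = [
        {
            "label": f"{r.scenario}" + ("" if region is not None else f" (r{r.region})"),
            "whislo": r.whisker_low, "q1": r.q1, "med": r.median,
            "q3": r.q3, "whishi": r.whisker_high, "fliers": [],
        }
        for r in sub.itertuples()
    ]
    fig, ax = plt.subplots(figsize=(max(6, 0.8 * len(boxes)), 4))
    ax.bxp(boxes, showfliers=False)
    ax.set_ylabel("GI density (%)")
    ax.set_title(f"{forest_type} forest, {radius_m / 1000:.0f}-km window")
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    return fig


def median_increase_bars(median_increases: pd.DataFrame, radius_m: float = 3000.0):
    """Bar chart of median density increases per scenario, type and region."""
    sub = median_increases[median_increases["radius_m"] == radius_m]
    if sub.empty:
        raise ValueError("no matching rows in median_increases")
    pivot = sub.pivot_table(
        index="scenario", columns=["region", "forest_type"],
        values="median_increase_pct",
    )
    fig, ax = plt.subplots(figsize=(8, 4))
    pivot.plot.bar(ax=ax, legend=True)
    ax.set_ylabel("median GI-density increase (%)")
    fig.tight_layout()
    return fig
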