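"""Connectivity-forest extraction, nested classes and area accounting.

Connectivity forest (CF) is forest *outside* the confirmed conservation
baseline whose modeled probability of holding high conservation value is at
least ``tau_min`` (0.4, the reported minimum for protected forest). CF is
divided into nested classes at 0.1 probability steps (>=0.9 down to >=0.4);
inserting successively lower classes onto the baseline yields the stepwise
conservation scenarios the rest of the pipeline evaluates.

Threshold comparisons are inclusive (>=); a pixel at exactly a bin boundary
belongs to the higher class. Probabilities are consumed as-is, with no
re-binning or smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grids import Grid, Mask, assert_aligned
from .landcover import (
    ForestTypeScheme,
    MIXED_TYPES,
    PURE_TYPES,
    forest_mask,
    reallocate_mixed_areas,
)

__all__ = [
    "CFRaster",
    "ScenarioMask",
    "default_thresholds",
    "extract_cf",
    "nested_class_mask",
    "insert_cf",
    "probability_quantiles",
    "area_summary",
    "class_label",
]


def default_thresholds(tau_min: float = 0.4) -> tuple[float, ...]:
    """Descending class thresholds 0.9, 0.8, ... down to ``tau_min``."""
    n = int(round((0.9 - tau_min) / 0.1)) + 1
    return tuple(round(0.9 - 0.1 * i, 10) for i in range(n))


def class_label(tau: float) -> str:
    return f"cf>={tau:.1f}"


@dataclass(eq=False)
class CFRaster:
    """Per-pixel CF class labels.

    ``labels`` stores -1 for non-CF pixels and otherwise the index into
    ``thresholds`` (descending) of the *highest* threshold the pixel's
    probability reaches, so index 0 is the >=0.9 class.
    """

    labels: Grid
    thresholds: tuple[float, ...]
    tau_min: float

    def threshold_index(self, tau: float) -> int:
        for i, t in enumerate(self.thresholds):
            if np.isclose(t, tau, atol=1e-9):
                return i
        raise ValueError(f"tau={tau} is not a configured threshold {self.thresholds}")

    @property
    def cf_members(self) -> np.ndarray:
        return self.labels.values >= 0


def extract_cf(
    probability: Grid,
    baseline: Mask,
    landcover: Grid,
    scheme: ForestTypeScheme,
    tau_min: float = 0.4,
    thresholds: Sequence[float] | None = None,
) -> CFRaster:
    """Delineate CF: forest, outside the baseline, probability >= tau_min.

    Class bins are assigned by inclusive descending thresholds. Raises if
    any in-extent probability falls outside [0, 1].
    """
    if not 0 < tau_min < 1:
        raise ValueError(f"tau_min must lie in (0, 1), got {tau_min}")
    assert_aligned(
        [probability, baseline, landcover], ["probability", "baseline", "landcover"]
    )
    thresholds = (
        default_thresholds(tau_min) if thresholds is None else tuple(thresholds)
    )
    if list(thresholds) != sorted(thresholds, reverse=True):
        raise ValueError("thresholds must be strictly descending")
    if not np.isclose(thresholds[-1], tau_min):
        raise ValueError("lowest threshold must equal tau_min")
    p = probability.values
    pvalid = probability.valid
    if np.any((p[pvalid] < 0) | (p[pvalid] > 1)):
        raise ValueError("probability values outside [0, 1]")
    forest = forest_mask(landcover, scheme)
    cf_sel = forest.members & ~baseline.members & pvalid & (p >= tau_min)
    labels = np.full(probability.shape, -1, dtype=np.int8)
    unassigned = cf_sel.copy()
    for i, thr in enumerate(thresholds):
        sel = unassigned & (p >= thr)
        labels[sel] = i
        unassigned &= ~sel
    return CFRaster(
        labels=probability.like(labels, nodata=None),
        thresholds=thresholds,
        tau_min=tau_min,
    )


def nested_class_mask(cf: CFRaster, tau: float) -> Mask:
    """All CF pixels with probability >= tau (classes are set-nested)."""
    idx = cf.threshold_index(tau)
    lv = cf.labels.values
    return Mask.from_bool((lv >= 0) & (lv <= idx), cf.labels)


@dataclass(eq=False)
class ScenarioMask:
    """Baseline plus one inserted CF class; ``tau=None`` is baseline-only."""

    mask: Mask
    tau: float | None

    @property
    def label(self) -> str:
        return "baseline" if self.tau is None else class_label(self.tau)


def insert_cf(baseline: Mask, cf: CFRaster, tau: float) -> ScenarioMask:
    """Union of the baseline and the nested CF class at ``tau``."""
    cls = nested_class_mask(cf, tau)
    assert_aligned([baseline, cls], ["baseline", "cf_class"])
    return ScenarioMask(
        mask=Mask.from_bool(baseline.members | cls.members, baseline, valid=baseline.valid),
        tau=tau,
    )


def probability_quantiles(
    probability: Grid, masks: Mapping[str, Mask]
) -> pd.DataFrame:
    """Min/quartiles/max of the probability surface over each named mask.

    Empty masks produce a row flagged ``empty`` rather than an exception.
    """
    rows = []
    for name, mask in masks.items():
        assert_aligned([probability, mask], ["probability", name])
        vals = probability.values[mask.members & probability.valid]
        if vals.size == 0:
            rows.append(
                {"mask": name, "n_pixels": 0, "empty": True,
                 "min": np.nan, "q25": np.nan, "median": np.nan,
                 "q75": np.nan, "max": np.nan}
            )
            continue
        q = np.percentile(vals, [0, 25, 50, 75, 100])
        rows.append(
            {"mask": name, "n_pixels": int(vals.size), "empty": False,
             "min": q[0], "q25": q[1], "median": q[2], "q75": q[3], "max": q[4]}
        )
    return pd.DataFrame(rows)


def _raw_area_counts(
    sel: np.ndarray,
    landcover: Grid,
    scheme: ForestTypeScheme,
    region_values: np.ndarray,
    region_codes: Sequence[int],
    cf_class: str,
    pixel_area_ha: float,
) -> list[dict]:
    rows = []
    for rc in region_codes:
        rsel = (region_values == rc) & sel
        for code, name in scheme.codes.items():
            n = int(((landcover.values == code) & rsel).sum())
            rows.append(
                {"region": rc, "forest_type": name, "cf_class": cf_class,
                 "area_ha": n * pixel_area_ha}
            )
    return rows


def area_summary(
    cf: CFRaster,
    baseline: Mask,
    landcover: Grid,
    scheme: ForestTypeScheme,
    regions: Grid,
) -> pd.DataFrame:
    """Nested-class area table by region and forest type.

    For every (region, forest type incl. ``all``, CF class) the table
    reports the area in hectares (after mixed-type reallocation — this path
    never double counts), the share of the type's total forest area in the
    region, and the increase relative to the region's all-forest baseline
    area. Values are unrounded; display rounding happens in the report
    layer. Regions without baseline get the increase column flagged
    undefined (NaN) rather than infinity.
    """
    assert_aligned(
        [cf.labels, baseline, landcover, regions],
        ["cf", "baseline", "landcover", "regions"],
    )
    px_ha = landcover.pixel_area_ha
    region_values = regions.values
    region_codes = sorted(np.unique(region_values[regions.valid]).tolist())
    lv = cf.labels.values
    forest = forest_mask(landcover, scheme).members

    raw_rows: list[dict] = []
    for i, tau in enumerate(cf.thresholds):
        sel = (lv >= 0) & (lv <= i)
        raw_rows += _raw_area_counts(
            sel, landcover, scheme, region_values, region_codes, class_label(tau), px_ha
        )
    raw_rows += _raw_area_counts(
        baseline.members, landcover, scheme, region_values, region_codes, "baseline", px_ha
    )
    raw_rows += _raw_area_counts(
        forest, landcover, scheme, region_values, region_codes, "forest_total", px_ha
    )
    realloc = reallocate_mixed_areas(pd.DataFrame(raw_rows), scheme)

    # per-region pure-type pivots
    out_rows: list[dict] = []
    for rc in region_codes:
        sub = realloc[realloc["region"] == rc]
        by = {
            (r["forest_type"], r["cf_class"]): r["area_ha"] for _, r in sub.iterrows()
        }
        totals = {t: by.get((t, "forest_total"), 0.0) for t in PURE_TYPES}
        totals["all"] = sum(totals.values())
        baseline_by = {t: by.get((t, "baseline"), 0.0) for t in PURE_TYPES}
        baseline_all = sum(baseline_by.values())
        classes = [class_label(t) for t in cf.thresholds] + ["baseline"]
        for ftype in PURE_TYPES + ("all",):
            for cls in classes:
                if ftype == "all":
                    area = sum(by.get((t, cls), 0.0) for t in PURE_TYPES)
                else:
                    area = by.get((ftype, cls), 0.0)
                total = totals[ftype]
                pct_type = 100.0 * area / total if total > 0 else np.nan
                if baseline_all > 0:
                    pct_incr = 100.0 * area / baseline_all
                    undefined = False
                else:
                    pct_incr, undefined = np.nan, True
                out_rows.append(
                    {"region": rc, "forest_type": ftype, "cf_class": cls,
                     "area_ha": area, "pct_of_type": pct_type,
                     "pct_increase": pct_incr, "increase_undefined": undefined}
                )
    return pd.DataFrame(out_rows)
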