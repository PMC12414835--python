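"""Green-infrastructure density: circular moving-window focal statistics.

GI density at a pixel is the percentage of a circular window (default radii
3 km and 1 km) occupied by weighted network membership — the baseline plus
inserted CF, with mixed stands down-weighted. The window is a set of integer
pixel offsets whose center-to-center distance is at most the radius
(inclusive); the denominator is always the full window size, with cells
outside the data extent contributing zero. On real data a 5-km rim of data
around the study area keeps edge windows fully supported; the synthetic
generator produces that rim as part of the analysis frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .cf import CFRaster, class_label, nested_class_mask
from .grids import Grid, Mask, assert_aligned
from .landcover import ForestTypeScheme, PURE_TYPES

__all__ = [
    "KernelFootprint",
    "DensityRaster",
    "circular_kernel",
    "compute_density",
    "density_distribution",
    "median_increase",
    "cumulative_cf_share",
]


@dataclass(frozen=True, eq=False)
class KernelFootprint:
    """Circular window as integer pixel offsets and a boolean footprint."""

    radius_m: float
    pixel_size_m: float
    offsets: np.ndarray  # (k, 2) array of (drow, dcol)
    footprint: np.ndarray  # (2r+1, 2r+1) boolean

    @property
    def size(self) -> int:
        return int(self.footprint.sum())

    @property
    def radius_px(self) -> int:
        return (self.footprint.shape[0] - 1) // 2


def circular_kernel(radius_m: float, pixel_size_m: float = 100.0) -> KernelFootprint:
    """All integer offsets (di, dj) with (di^2 + dj^2) * pixel^2 <= radius^2.

    The boundary is inclusive: at 100 m pixels a 100 m radius yields the
    5-cell plus shape (orthogonal neighbors at exactly 100 m included,
    diagonals at ~141 m excluded).
    """
    if radius_m < 0:
        raise ValueError("radius_m must be >= 0")
    if pixel_size_m <= 0:
        raise ValueError("pixel_size_m must be > 0")
    r_px = int(np.floor(radius_m / pixel_size_m))
    rng = np.arange(-r_px, r_px + 1)
    di, dj = np.meshgrid(rng, rng, indexing="ij")
    footprint = (di**2 + dj**2) * pixel_size_m**2 <= radius_m**2
    offsets = np.stack([di[footprint], dj[footprint]], axis=1)
    return KernelFootprint(
        radius_m=radius_m,
        pixel_size_m=pixel_size_m,
        offsets=offsets,
        footprint=footprint,
    )


@dataclass(eq=False)
class DensityRaster:
    """GI density in percent [0, 100], with the provenance that matters."""

    grid: Grid
    radius_m: float
    tau: float | None = None
    forest_type: str = "all"

    @property
    def values(self) -> np.ndarray:
        return self.grid.values


def compute_density(
    membership: Grid,
    kernel: KernelFootprint,
    study_extent: Mask | None = None,
    outer_buffer_m: float = 5000.0,
) -> DensityRaster:
    """Focal percentage of weighted membership under the circular window.

    ``D(x) = 100 * sum_{o in offsets} w(x + o) / kernel.size`` with w = 0
    outside the data extent. The analysis frame is conceptually extended by
    ``outer_buffer_m`` so no study pixel loses window support; since cells
    beyond the frame carry zero weight this equals zero-padded convolution.
    Density is reported for every pixel of ``study_extent`` (the full frame
    when None).
    """
    if not np.isclose(kernel.pixel_size_m, membership.pixel_size_m, rtol=1e-9):
        raise ValueError(
            f"kernel pixel size {kernel.pixel_size_m} != raster {membership.pixel_size_m}"
        )
    pad = int(np.ceil(outer_buffer_m / membership.pixel_size_m))
    rows, cols = membership.shape
    if kernel.footprint.shape[0] > rows + 2 * pad or kernel.footprint.shape[0] > cols + 2 * pad:
        raise ValueError("kernel is larger than the padded analysis frame")
    w = np.where(membership.valid, membership.values, 0.0).astype(np.float64)
    total = ndimage.correlate(
        w, kernel.footprint.astype(np.float64), mode="constant", cval=0.0
    )
    dens = 100.0 * total / kernel.size
    if study_extent is not None:
        assert_aligned([membership, study_extent], ["membership", "study_extent"])
        dens = np.where(study_extent.members, dens, np.nan)
    return DensityRaster(
        grid=Grid(dens, membership.pixel_size_m, membership.origin, nodata=np.nan),
        radius_m=kernel.radius_m,
    )


def density_distribution(density: DensityRaster, regions: Grid) -> pd.DataFrame:
    """Box statistics of density per region over all defined pixels.

    Whiskers extend to the most extreme values within 1.5x the interquartile
    range of the quartiles; values beyond count as outliers. Zeros are
    included — gaps in the network are part of the distribution.
    """
    assert_aligned([density.grid, regions], ["density", "regions"])
    defined = density.grid.valid
    rows = []
    for rc in sorted(np.unique(regions.values[regions.valid]).tolist()):
        vals = density.values[(regions.values == rc) & defined]
        if vals.size == 0:
            raise ValueError(f"region {rc} has no defined density pixels")
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = vals[(vals >= lo_fence) & (vals <= hi_fence)]
        rows.append(
            {"region": rc, "n_pixels": int(vals.size),
             "min": float(vals.min()), "q1": float(q1), "median": float(med),
             "q3": float(q3),
             "whisker_low": float(inside.min()), "whisker_high": float(inside.max()),
             "n_outliers": int(((vals < lo_fence) | (vals > hi_fence)).sum()),
             "max": float(vals.max())}
        )
    return pd.DataFrame(rows)


def median_increase(
    scenario_stats: pd.DataFrame, baseline_stats: pd.DataFrame
) -> pd.DataFrame:
    """Percent change of the regional density median relative to baseline.

    A zero baseline median yields an undefined flag, not infinity.
    """
    merged = scenario_stats[["region", "median"]].merge(
        baseline_stats[["region", "median"]],
        on="region",
        suffixes=("_scenario", "_baseline"),
        validate="one_to_one",
    )
    base = merged["median_baseline"]
    scen = merged["median_scenario"]
    undefined = base == 0
    incr = np.where(undefined, np.nan, 100.0 * (scen - base) / base.replace(0, np.nan))
    return pd.DataFrame(
        {"region": merged["region"], "median_increase_pct": incr,
         "undefined": undefined}
    )


def cumulative_cf_share(
    cf: CFRaster,
    regions: Grid,
    landcover: Grid,
    scheme: ForestTypeScheme,
    tau: float,
) -> pd.DataFrame:
    """Cumulatively inserted CF area at >=tau as % of the region's total CF.

    Per-type numerators use the density-mode mixed handling: a mixed pixel
    counts (at full pixel area) toward every pure type it maps to, so type
    shares within a region need not sum to 100. The denominator is the
    region's all-forest CF area, each pixel counted once. Regions with no
    CF get an undefined flag.
    """
    assert_aligned([cf.labels, regions, landcover], ["cf", "regions", "landcover"])
    px_ha = landcover.pixel_area_ha
    cls = nested_class_mask(cf, tau).members
    all_cf = cf.cf_members
    code_targets: dict[int, tuple[str, ...]] = {}
    for code, name in scheme.codes.items():
        if name in PURE_TYPES:
            code_targets[code] = (name,)
        else:
            code_targets[code] = tuple(scheme.membership.get(name, ()))
    rows = []
    for rc in sorted(np.unique(regions.values[regions.valid]).tolist()):
        rsel = regions.values == rc
        denom = float((all_cf & rsel).sum()) * px_ha
        for ftype in PURE_TYPES + ("all",):
            if ftype == "all":
                num = float((cls & rsel).sum()) * px_ha
            else:
                codes = [c for c, t in code_targets.items() if ftype in t]
                num = float((cls & rsel & np.isin(landcover.values, codes)).sum()) * px_ha
            share = 100.0 * num / denom if denom > 0 else np.nan
            rows.append(
                {"region": rc, "forest_type": ftype, "cf_class": class_label(tau),
                 "area_ha": num, "share_pct": share, "undefined": denom == 0}
            )
    return pd.DataFrame(rows)
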