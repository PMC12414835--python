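"""Functional habitat delineation and restoration-hotspot identification.

Functional habitat is where GI density reaches the 20% rule-of-thumb
threshold. Habitat patches are 8-connected pixel clusters. Restoration
hotspots are CF pixels that, across the stepwise insertion scenarios, fall
inside functional areas or their 3-km buffer — restoring them adds new
functional habitat rather than isolated forest. Patch statistics (NoPa,
TAr, AAr +- SD, MaAr) are reported per region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .cf import CFRaster, nested_class_mask
from .density import DensityRaster, KernelFootprint, circular_kernel, compute_density
from .grids import Grid, Mask, assert_aligned
from .landcover import ForestTypeScheme, type_membership

__all__ = [
    "PatchLabels",
    "HotspotResult",
    "functional_mask",
    "functional_proportion",
    "label_patches",
    "buffer_mask",
    "patch_statistics",
    "identify_hotspots",
]

_STRUCTURE_8 = np.ones((3, 3), dtype=bool)
_STRUCTURE_4 = ndimage.generate_binary_structure(2, 1)


def functional_mask(density: DensityRaster, threshold_pct: float = 20.0) -> Mask:
    """True where GI density >= threshold (inclusive)."""
    if not 0 < threshold_pct <= 100:
        raise ValueError(f"threshold_pct must lie in (0, 100], got {threshold_pct}")
    defined = density.grid.valid
    members = defined & (density.values >= threshold_pct)
    return Mask.from_bool(members, density.grid, valid=defined)


def functional_proportion(
    density: DensityRaster, threshold_pct: float = 20.0
) -> float:
    """Functional area as % of the area with any density at all (D > 0).

    Returns NaN when no pixel has positive density (undefined).
    """
    defined = density.grid.valid
    positive = int((defined & (density.values > 0)).sum())
    if positive == 0:
        return float("nan")
    functional = int((defined & (density.values >= threshold_pct)).sum())
    return 100.0 * functional / positive


@dataclass(eq=False)
class PatchLabels:
    """Connected-component labels (0 = background, 1..n_patches)."""

    labels: Grid
    n_patches: int
    pixel_counts: np.ndarray  # length n_patches, patch i -> count at [i-1]
    connectivity: int = 8

    @property
    def areas_ha(self) -> np.ndarray:
        return self.pixel_counts * self.labels.pixel_area_ha


def label_patches(mask: Mask, connectivity: int = 8) -> PatchLabels:
    """Label contiguous clusters; 8-connectivity joins diagonal neighbors."""
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    structure = _STRUCTURE_8 if connectivity == 8 else _STRUCTURE_4
    labels, n = ndimage.label(mask.members, structure=structure)
    counts = np.bincount(labels.ravel(), minlength=n + 1)[1:].astype(np.int64)
    return PatchLabels(
        labels=Grid(labels.astype(np.int32), mask.pixel_size_m, mask.origin, nodata=None),
        n_patches=int(n),
        pixel_counts=counts,
        connectivity=connectivity,
    )


def buffer_mask(mask: Mask, width_m: float) -> Mask:
    """Euclidean buffer: pixels whose center lies within ``width_m``
    (inclusive) of any member pixel's center. Always a superset of the
    input; width 0 is the identity."""
    if width_m < 0:
        raise ValueError("width_m must be >= 0")
    fp = circular_kernel(width_m, mask.pixel_size_m).footprint
    if fp.shape == (1, 1):
        grown = mask.members.copy()
    else:
        grown = ndimage.binary_dilation(mask.members, structure=fp)
    return Mask.from_bool(grown, mask, valid=mask.valid)


def patch_statistics(labels: PatchLabels, regions: Grid) -> pd.DataFrame:
    """Per-region patch statistics: NoPa, TAr, AAr (mean +- sample SD), MaAr.

    A patch straddling region borders is assigned to the region holding the
    majority of its pixels, ties to the lower region code. Regions without
    patches appear with zeros.
    """
    assert_aligned([labels.labels, regions], ["labels", "regions"])
    region_codes = sorted(np.unique(regions.values[regions.valid]).tolist())
    lv = labels.labels.values
    px_ha = labels.labels.pixel_area_ha

    patch_region: dict[int, int] = {}
    if labels.n_patches > 0:
        sel = lv > 0
        df = pd.DataFrame({"patch": lv[sel], "region": regions.values[sel]})
        counts = df.groupby(["patch", "region"]).size().reset_index(name="n")
        counts = counts.sort_values(
            ["patch", "n", "region"], ascending=[True, False, True]
        )
        patch_region = dict(
            counts.drop_duplicates("patch")[["patch", "region"]].itertuples(
                index=False, name=None
            )
        )
    rows = []
    for rc in region_codes:
        areas = np.array(
            [
                labels.pixel_counts[p - 1] * px_ha
                for p, r in patch_region.items()
                if r == rc
            ]
        )
        if areas.size == 0:
            rows.append(
                {"region": rc, "NoPa": 0, "TAr_ha": 0.0, "AAr_ha": 0.0,
                 "AAr_sd_ha": 0.0, "MaAr_ha": 0.0}
            )
        else:
            sd = float(np.std(areas, ddof=1)) if areas.size > 1 else 0.0
            rows.append(
                {"region": rc, "NoPa": int(areas.size), "TAr_ha": float(areas.sum()),
                 "AAr_ha": float(areas.mean()), "AAr_sd_ha": sd,
                 "MaAr_ha": float(areas.max())}
            )
    return pd.DataFrame(rows)


@dataclass(eq=False)
class HotspotResult:
    """Hotspot mask, labeled patches, per-region statistics and the
    functional-area check that inserting hotspots never shrinks habitat."""

    mask: Mask
    patches: PatchLabels
    stats: pd.DataFrame
    functional_baseline_ha: float
    functional_with_hotspots_ha: float


def _all_forest_density(
    landcover: Grid,
    scheme: ForestTypeScheme,
    cf_members_mask: Mask,
    baseline: Mask,
    kernel: KernelFootprint,
    study_extent: Mask | None,
    outer_buffer_m: float,
) -> DensityRaster:
    memb = type_membership(landcover, scheme, "all", cf_members_mask, baseline)
    return compute_density(memb, kernel, study_extent, outer_buffer_m)


def identify_hotspots(
    cf: CFRaster,
    baseline: Mask,
    landcover: Grid,
    scheme: ForestTypeScheme,
    regions: Grid,
    kernel: KernelFootprint,
    taus: Sequence[float],
    buffer_m: float = 3000.0,
    threshold_pct: float = 20.0,
    min_area_ha: float = 1.0,
    hotspot_reference: str = "per_step",
    study_extent: Mask | None = None,
    outer_buffer_m: float = 5000.0,
) -> HotspotResult:
    """Restoration hotspots across the stepwise CF insertions.

    For each insertion step tau (descending): compute the all-forest GI
    density of scenario(tau), delineate functional habitat (>= threshold),
    buffer it by ``buffer_m``, and collect the CF pixels of class >= tau
    lying inside that buffered zone. The hotspot set is the union over
    steps; with ``hotspot_reference="baseline_only"`` the functional zone is
    instead fixed at the pre-insertion (baseline) state. Patches below
    ``min_area_ha`` are dropped; statistics are reported per region.
    """
    if len(taus) == 0:
        raise ValueError("taus must be non-empty")
    if hotspot_reference not in ("per_step", "baseline_only"):
        raise ValueError(f"unknown hotspot_reference {hotspot_reference!r}")
    assert_aligned(
        [cf.labels, baseline, landcover, regions],
        ["cf", "baseline", "landcover", "regions"],
    )
    empty_cf = Mask.from_bool(np.zeros(baseline.shape, dtype=bool), baseline)
    dens_base = _all_forest_density(
        landcover, scheme, empty_cf, baseline, kernel, study_extent, outer_buffer_m
    )
    functional_baseline = functional_mask(dens_base, threshold_pct)
    if hotspot_reference == "baseline_only":
        fixed_zone = buffer_mask(functional_baseline, buffer_m)

    hotspot_members = np.zeros(baseline.shape, dtype=bool)
    for tau in sorted(taus, reverse=True):
        cls = nested_class_mask(cf, tau)
        if hotspot_reference == "per_step":
            dens = _all_forest_density(
                landcover, scheme, cls, baseline, kernel, study_extent, outer_buffer_m
            )
            zone = buffer_mask(functional_mask(dens, threshold_pct), buffer_m)
        else:
            zone = fixed_zone
        hotspot_members |= cls.members & zone.members

    raw_mask = Mask.from_bool(hotspot_members, baseline, valid=baseline.valid)
    patches = label_patches(raw_mask, connectivity=8)
    keep = patches.areas_ha >= min_area_ha
    if not keep.all():
        lv = patches.labels.values
        old_to_new = np.zeros(patches.n_patches + 1, dtype=np.int32)
        old_to_new[1:][keep] = np.arange(1, int(keep.sum()) + 1)
        new_labels = old_to_new[lv]
        hotspot_members = new_labels > 0
        raw_mask = Mask.from_bool(hotspot_members, baseline, valid=baseline.valid)
        patches = PatchLabels(
            labels=Grid(new_labels, baseline.pixel_size_m, baseline.origin, nodata=None),
            n_patches=int(keep.sum()),
            pixel_counts=patches.pixel_counts[keep],
            connectivity=8,
        )
    stats = patch_statistics(patches, regions)

    dens_combined = _all_forest_density(
        landcover, scheme, raw_mask, baseline, kernel, study_extent, outer_buffer_m
    )
    functional_combined = functional_mask(dens_combined, threshold_pct)
    px_ha = baseline.pixel_area_ha
    fb_ha = float(functional_baseline.members.sum()) * px_ha
    fc_ha = float(functional_combined.members.sum()) * px_ha
    if fc_ha < fb_ha:
        raise AssertionError(
            "functional area shrank after inserting hotspots "
            f"({fc_ha} < {fb_ha} ha); density monotonicity violated"
        )
    return HotspotResult(
        mask=raw_mask,
        patches=patches,
        stats=stats,
        functional_baseline_ha=fb_ha,
        functional_with_hotspots_ha=fc_ha,
    )
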