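"""Forest-type semantics: reclassification, masks and weighted membership.

The land-cover raster carries five forest-type codes (spruce, pine,
deciduous, and two mixed classes) plus non-forest codes. Two distinct
conventions apply to the mixed classes:

* **Area accounting** reallocates each mixed class into the pure types by
  fixed fractions (:func:`reallocate_mixed_areas`); total area is conserved
  exactly and nothing is double counted.
* **Density membership** (:func:`type_membership`) instead assigns mixed
  pixels *repetitively* to every pure type they may contain (mixed
  coniferous counts for both spruce and pine), each at a reduced weight
  (default 0.5) reflecting the lower habitat quality of mixed stands
  relative to pure ones. The double counting here is intentional and
  confined to the density pathway.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .grids import Grid, Mask, assert_aligned

__all__ = [
    "ForestTypeScheme",
    "PURE_TYPES",
    "MIXED_TYPES",
    "forest_mask",
    "exclude_nonforest_baseline",
    "reallocate_mixed_areas",
    "type_membership",
]

PURE_TYPES = ("spruce", "pine", "deciduous")
MIXED_TYPES = ("mixed_coniferous", "mixed_deciduous_coniferous")

DEFAULT_CODES = {
    1: "spruce",
    2: "pine",
    3: "deciduous",
    4: "mixed_coniferous",
    5: "mixed_deciduous_coniferous",
}
DEFAULT_NONFOREST_CODES = {0: "open_land", 6: "water"}

DEFAULT_REALLOCATION = {
    "mixed_coniferous": {"spruce": 0.5, "pine": 0.5},
    "mixed_deciduous_coniferous": {"deciduous": 0.5, "spruce": 0.25, "pine": 0.25},
}
# Density membership: which pure types a mixed pixel counts toward
# (repetitive assignment; mixed coniferous feeds BOTH conifer types).
DEFAULT_MEMBERSHIP = {
    "mixed_coniferous": ("spruce", "pine"),
    "mixed_deciduous_coniferous": ("deciduous", "spruce", "pine"),
}


@dataclass
class ForestTypeScheme:
    """Code table plus the mixed-stand reallocation and weighting rules."""

    codes: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_CODES))
    nonforest_codes: dict[int, str] = field(
        default_factory=lambda: dict(DEFAULT_NONFOREST_CODES)
    )
    reallocation: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_REALLOCATION.items()}
    )
    membership: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_MEMBERSHIP)
    )
    mixed_weight: float = 0.5
    # "all": mixed pixels weigh mixed_weight wherever they count;
    # "cf_only": mixed pixels inside the baseline keep full weight 1.
    mixed_weight_scope: str = "all"

    def __post_init__(self) -> None:
        if not 0 < self.mixed_weight <= 1:
            raise ValueError(f"mixed_weight must be in (0, 1], got {self.mixed_weight}")
        if self.mixed_weight_scope not in ("all", "cf_only"):
            raise ValueError(f"unknown mixed_weight_scope {self.mixed_weight_scope!r}")
        for mixed, row in self.reallocation.items():
            total = sum(row.values())
            if any(f < 0 for f in row.values()) or not np.isclose(total, 1.0):
                raise ValueError(
                    f"reallocation row for {mixed!r} must be non-negative and sum to 1, "
                    f"got {row}"
                )

    @property
    def code_by_name(self) -> dict[str, int]:
        return {name: code for code, name in self.codes.items()}

    @property
    def forest_codes(self) -> tuple[int, ...]:
        return tuple(self.codes)

    def to_dict(self) -> dict:
        return {
            "codes": dict(self.codes),
            "nonforest_codes": dict(self.nonforest_codes),
            "reallocation": {k: dict(v) for k, v in self.reallocation.items()},
            "membership": {k: list(v) for k, v in self.membership.items()},
            "mixed_weight": self.mixed_weight,
            "mixed_weight_scope": self.mixed_weight_scope,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ForestTypeScheme":
        kwargs = dict(d)
        if "codes" in kwargs:
            kwargs["codes"] = {int(k): v for k, v in kwargs["codes"].items()}
        if "nonforest_codes" in kwargs:
            kwargs["nonforest_codes"] = {
                int(k): v for k, v in kwargs["nonforest_codes"].items()
            }
        if "membership" in kwargs:
            kwargs["membership"] = {k: tuple(v) for k, v in kwargs["membership"].items()}
        return cls(**kwargs)


def forest_mask(landcover: Grid, scheme: ForestTypeScheme) -> Mask:
    """True where the pixel carries any of the five forest-type codes.

    Raises ``ValueError`` listing any code present in the raster that the
    scheme does not know (neither forest nor non-forest).
    """
    valid = landcover.valid
    present = set(np.unique(landcover.values[valid]).tolist())
    known = set(scheme.codes) | set(scheme.nonforest_codes)
    unknown = sorted(present - known)
    if unknown:
        raise ValueError(f"unknown land-cover codes: {unknown}")
    members = np.isin(landcover.values, list(scheme.codes)) & valid
    return Mask.from_bool(members, landcover, valid=valid)


def exclude_nonforest_baseline(
    baseline: Mask, landcover: Grid, scheme: ForestTypeScheme
) -> tuple[Mask, float]:
    """Restrict the baseline to forest pixels.

    The confirmed-HCVF dataset includes areas the land cover classifies as
    non-forest (water, open land); those are dropped from the analysis.
    Returns the forest-only baseline and the excluded area in hectares.
    """
    assert_aligned([baseline, landcover], ["baseline", "landcover"])
    forest = forest_mask(landcover, scheme)
    kept = baseline.members & forest.members
    excluded_ha = float((baseline.members & ~forest.members).sum()) * baseline.pixel_area_ha
    return Mask.from_bool(kept, baseline, valid=baseline.valid), excluded_ha


def reallocate_mixed_areas(raw: pd.DataFrame, scheme: ForestTypeScheme) -> pd.DataFrame:
    """Redistribute mixed-type areas into the pure types.

    ``raw`` must have a ``forest_type`` and an ``area_ha`` column; any other
    columns (region, cf_class, ...) are treated as grouping keys and
    preserved. Mixed rows are split according to ``scheme.reallocation`` and
    summed into the pure-type rows; total area is conserved exactly.
    """
    if "forest_type" not in raw.columns or "area_ha" not in raw.columns:
        raise ValueError("raw table needs 'forest_type' and 'area_ha' columns")
    keys = [c for c in raw.columns if c not in ("forest_type", "area_ha")]
    present_mixed = set(raw["forest_type"]) & set(MIXED_TYPES)
    missing = sorted(present_mixed - set(scheme.reallocation))
    if missing:
        raise ValueError(f"no reallocation row for mixed type(s): {missing}")

    pure = raw[~raw["forest_type"].isin(MIXED_TYPES)].copy()
    pieces = [pure]
    for mixed in sorted(present_mixed):
        rows = raw[raw["forest_type"] == mixed]
        for target, frac in scheme.reallocation[mixed].items():
            if frac == 0:
                continue
            part = rows.copy()
            part["forest_type"] = target
            part["area_ha"] = part["area_ha"] * frac
            pieces.append(part)
    out = pd.concat(pieces, ignore_index=True)
    out = (
        out.groupby(keys + ["forest_type"], as_index=False, sort=True)["area_ha"]
        .sum()
        .reset_index(drop=True)
    )
    return out


def type_membership(
    landcover: Grid,
    scheme: ForestTypeScheme,
    forest_type: str,
    cf_mask: Mask,
    baseline: Mask,
) -> Grid:
    """Per-pixel weighted membership of the scenario (baseline + inserted CF)
    for one forest type, as consumed by the density computation.

    Weights are in {0, mixed_weight, 1}: pure pixels of the requested type
    count 1; mixed pixels that map to the requested type count
    ``scheme.mixed_weight``; for ``forest_type="all"`` every forest pixel of
    the scenario counts, mixed pixels at the mixed weight. Pixels outside
    the scenario (baseline union CF) weigh 0.
    """
    if forest_type not in PURE_TYPES + ("all",):
        raise ValueError(
            f"forest_type must be one of {PURE_TYPES + ('all',)}, got {forest_type!r}"
        )
    assert_aligned(
        [landcover, cf_mask, baseline], ["landcover", "cf_mask", "baseline"]
    )
    scenario = baseline.members | cf_mask.members
    valid = landcover.valid
    w = np.zeros(landcover.shape, dtype=np.float64)
    for code, name in scheme.codes.items():
        sel = (landcover.values == code) & scenario & valid
        if not sel.any():
            continue
        if name in PURE_TYPES:
            if forest_type == "all" or name == forest_type:
                w[sel] = 1.0
        else:
            targets = scheme.membership.get(name, ())
            if forest_type == "all" or forest_type in targets:
                w[sel] = scheme.mixed_weight
                if scheme.mixed_weight_scope == "cf_only":
                    w[sel & baseline.members] = 1.0
    return landcover.like(w)
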