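"""Synthetic boreal-landscape generator.

Produces co-registered probability, land-cover, baseline and region rasters
with the statistical structure the downstream analysis assumes, so the whole
pipeline runs at desk scale without national geodata:

* the conservation-value probability surface is spatially autocorrelated
  (smoothed Gaussian noise, rank-mapped to a configurable marginal — by
  default a right-skewed Beta, since most managed forest has low predicted
  conservation value);
* the land cover is a clumped forest/non-forest mosaic with five forest-type
  codes whose regional proportions emulate a mountain-to-coast gradient
  (deciduous/spruce-rich uplands, pine-dominated lowlands);
* the confirmed-network baseline is grown as patches from local probability
  maxima, preferentially on high-probability forest, so that the median
  probability inside the baseline exceeds the 0.4 connectivity threshold
  while at least three quarters of the remaining forest falls below it;
* regions are contiguous bands, mimicking the mountain/inland/coastal
  partition, with region-specific baseline shares (the baseline concentrates
  in the "mountain" band).

Everything is deterministic given the master seed; per-generator sub-seeds
are derived with ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import heapq
from copy import deepcopy
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import ndimage, stats

from .grids import Grid, Mask, assert_aligned
from .landcover import ForestTypeScheme

__all__ = [
    "LandscapeConfig",
    "LandscapeBundle",
    "generate_probability_surface",
    "generate_landcover",
    "generate_baseline",
    "generate_regions",
    "make_scenario",
]

FOREST_TYPES = (
    "spruce",
    "pine",
    "deciduous",
    "mixed_coniferous",
    "mixed_deciduous_coniferous",
)

DEFAULT_TYPE_PROPORTIONS = {
    "spruce": 0.25,
    "pine": 0.35,
    "deciduous": 0.20,
    "mixed_coniferous": 0.10,
    "mixed_deciduous_coniferous": 0.10,
}

# Mountain-like band: baseline-rich, deciduous (mountain birch) and spruce
# dominated. Inland/coastal bands: baseline-poor, pine dominated.
DEFAULT_REGION_OVERRIDES = {
    1: {
        "baseline_fraction": 0.45,
        "type_proportions": {
            "spruce": 0.30,
            "pine": 0.13,
            "deciduous": 0.37,
            "mixed_coniferous": 0.08,
            "mixed_deciduous_coniferous": 0.12,
        },
    },
    2: {
        "baseline_fraction": 0.10,
        "type_proportions": {
            "spruce": 0.25,
            "pine": 0.45,
            "deciduous": 0.10,
            "mixed_coniferous": 0.12,
            "mixed_deciduous_coniferous": 0.08,
        },
    },
    3: {
        "baseline_fraction": 0.05,
        "type_proportions": {
            "spruce": 0.20,
            "pine": 0.47,
            "deciduous": 0.13,
            "mixed_coniferous": 0.12,
            "mixed_deciduous_coniferous": 0.08,
        },
    },
}


def _check_proportions(props: Mapping[str, float], label: str) -> None:
    unknown = set(props) - set(FOREST_TYPES)
    if unknown:
        raise ValueError(f"{label}: unknown forest types {sorted(unknown)}")
    if any(not 0 <= v <= 1 for v in props.values()):
        raise ValueError(f"{label}: proportions must lie in [0, 1]")
    if not np.isclose(sum(props.values()), 1.0):
        raise ValueError(f"{label}: proportions must sum to 1, got {sum(props.values())}")


@dataclass
class LandscapeConfig:
    """Knobs of the synthetic landscape.

    Defaults emulate the study conditions at desk scale: a 300 x 360 frame
    of 1-ha pixels whose interior (after the 5-km analysis rim) is a
    ~52,000-ha study area; ~60% forest; a baseline holding ~20% of the
    forest, strongly concentrated in the first (mountain-like) region band;
    and a probability surface with a 3-km autocorrelation length plus a
    north-south intactness gradient, so confirmed tracts form contiguous
    areas at the scale of the 3-km analysis window, as intact mountain
    forests do.
    """

    rows: int = 300
    cols: int = 360
    pixel_size_m: float = 100.0
    correlation_length_m: float = 3000.0
    # Weight of a deterministic north-south gradient mixed into the
    # probability latent field: the first (mountain-like) rows carry
    # systematically higher conservation probability, emulating the
    # intactness gradient from subalpine forest down to the managed coast.
    trend_weight: float = 0.35
    forest_fraction: float = 0.6
    type_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_PROPORTIONS)
    )
    baseline_fraction: float = 0.18
    # Imperfection of the confirmed-network survey: 0 grows the baseline
    # strictly on the highest-probability forest (a perfect survey), 1 grows
    # it independently of probability. The confirmed dataset is known to be
    # incomplete, which is exactly why connectivity forest exists: plenty of
    # high-probability forest remains outside the network.
    survey_noise: float = 0.35
    n_regions: int = 3
    marginal: tuple = ("beta", (1.5, 3.5))
    region_overrides: dict[int, dict] = field(
        default_factory=lambda: deepcopy(DEFAULT_REGION_OVERRIDES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows <= 0 or self.cols <= 0:
            raise ValueError(f"extent must be positive, got {self.rows}x{self.cols}")
        if not 0 <= self.forest_fraction <= 1:
            raise ValueError("forest_fraction must lie in [0, 1]")
        if not 0 <= self.baseline_fraction <= 1:
            raise ValueError("baseline_fraction must lie in [0, 1]")
        if not 0 <= self.survey_noise <= 1:
            raise ValueError("survey_noise must lie in [0, 1]")
        if not 0 <= self.trend_weight <= 1:
            raise ValueError("trend_weight must lie in [0, 1]")
        if self.correlation_length_m < 0:
            raise ValueError("correlation_length_m must be >= 0")
        _check_proportions(self.type_proportions, "type_proportions")
        for code, over in self.region_overrides.items():
            if "type_proportions" in over:
                _check_proportions(over["type_proportions"], f"region {code}")

    def to_dict(self) -> dict:
        return {
            "rows": self.rows,
            "cols": self.cols,
            "pixel_size_m": self.pixel_size_m,
            "correlation_length_m": self.correlation_length_m,
            "trend_weight": self.trend_weight,
            "forest_fraction": self.forest_fraction,
            "type_proportions": dict(self.type_proportions),
            "baseline_fraction": self.baseline_fraction,
            "survey_noise": self.survey_noise,
            "n_regions": self.n_regions,
            "marginal": [self.marginal[0], list(self.marginal[1])],
            "region_overrides": deepcopy(self.region_overrides),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "LandscapeConfig":
        kwargs = dict(d)
        if "marginal" in kwargs:
            name, params = kwargs["marginal"]
            kwargs["marginal"] = (name, tuple(params))
        if "region_overrides" in kwargs:
            kwargs["region_overrides"] = {
                int(k): dict(v) for k, v in kwargs["region_overrides"].items()
            }
        return cls(**kwargs)


@dataclass(eq=False)
class LandscapeBundle:
    """The four co-registered rasters the pipeline consumes."""

    probability: Grid
    landcover: Grid
    baseline: Mask
    regions: Grid
    config: LandscapeConfig | None = None

    def __post_init__(self) -> None:
        assert_aligned(
            [self.probability, self.landcover, self.baseline, self.regions],
            ["probability", "landcover", "baseline", "regions"],
        )


# -- field helpers -----------------------------------------------------------


def _sub_rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def _smooth_field(
    rng: np.random.Generator, rows: int, cols: int, correlation_length_m: float,
    pixel_size_m: float,
) -> np.ndarray:
    """White noise smoothed with a Gaussian kernel of scale ~L/2 pixels."""
    noise = rng.standard_normal((rows, cols))
    if correlation_length_m <= 0:
        return noise
    sigma = correlation_length_m / (2.0 * pixel_size_m)
    return ndimage.gaussian_filter(noise, sigma=sigma, mode="reflect")


def _rank_uniform(field_values: np.ndarray) -> np.ndarray:
    """Rank-transform to (0, 1); the mid-rank convention avoids 0 and 1."""
    flat = field_values.ravel()
    ranks = stats.rankdata(flat, method="average")
    return (ranks / (flat.size + 1)).reshape(field_values.shape)


def _apply_marginal(u: np.ndarray, marginal: tuple) -> np.ndarray:
    name, params = marginal
    if name == "uniform":
        return u
    if name == "beta":
        a, b = params
        return stats.beta.ppf(u, a, b)
    raise ValueError(f"unknown marginal distribution {name!r}")


# -- generators --------------------------------------------------------------


def generate_probability_surface(
    config: LandscapeConfig, seed: int | None = None
) -> Grid:
    """Spatially autocorrelated conservation-probability surface in [0, 1].

    Smoothed Gaussian noise, optionally blended with a north-south
    intactness gradient (``trend_weight``), is rank-mapped to the configured
    marginal, so the autocorrelation scale and the value distribution are
    controlled independently. With ``correlation_length_m = 0`` and
    ``trend_weight = 0`` values are spatially independent. Deterministic
    given the seed.
    """
    rng = _sub_rng(config.seed if seed is None else seed, 0)
    fld = _smooth_field(
        rng, config.rows, config.cols, config.correlation_length_m, config.pixel_size_m
    )
    t = config.trend_weight
    if t > 0 and config.rows > 1:
        # north-south intactness gradient: top rows systematically higher
        grad = np.linspace(1.0, -1.0, config.rows)[:, None]
        z = stats.norm.ppf(_rank_uniform(fld))
        fld = (1.0 - t) * z + t * np.broadcast_to(grad, fld.shape)
    p = _apply_marginal(_rank_uniform(fld), config.marginal)
    return Grid(p.astype(np.float64), config.pixel_size_m, (0.0, 0.0), nodata=np.nan)


def generate_regions(config: LandscapeConfig) -> Grid:
    """Contiguous horizontal bands 1..n_regions partitioning the extent."""
    if config.n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    if config.n_regions > config.rows:
        raise ValueError(
            f"n_regions ({config.n_regions}) exceeds row count ({config.rows})"
        )
    codes = np.empty((config.rows, config.cols), dtype=np.int16)
    row_blocks = np.array_split(np.arange(config.rows), config.n_regions)
    for i, block in enumerate(row_blocks, start=1):
        codes[block, :] = i
    return Grid(codes, config.pixel_size_m, (0.0, 0.0), nodata=-1)


def generate_landcover(
    config: LandscapeConfig,
    seed: int | None = None,
    regions: Grid | None = None,
    scheme: ForestTypeScheme | None = None,
) -> Grid:
    """Clumped forest/non-forest mosaic with five forest-type codes.

    Forest cells and forest types are both assigned by thresholding smoothed
    latent fields at empirical quantiles (per region, when a region raster
    and overrides are supplied), so realized proportions track the targets
    closely and types form spatial clumps rather than i.i.d. speckle.
    """
    scheme = scheme or ForestTypeScheme()
    base_seed = config.seed if seed is None else seed
    rng_forest = _sub_rng(base_seed, 1)
    rng_type = _sub_rng(base_seed, 2)
    u_forest = _rank_uniform(
        _smooth_field(
            rng_forest, config.rows, config.cols,
            config.correlation_length_m, config.pixel_size_m,
        )
    )
    u_type = _rank_uniform(
        _smooth_field(
            rng_type, config.rows, config.cols,
            config.correlation_length_m, config.pixel_size_m,
        )
    )
    code_by_name = scheme.code_by_name
    nonforest_codes = sorted(scheme.nonforest_codes)
    out = np.full((config.rows, config.cols), nonforest_codes[0], dtype=np.int16)

    if regions is None:
        region_values = np.ones((config.rows, config.cols), dtype=np.int16)
        region_codes = [1]
        overrides: dict[int, dict] = {}
    else:
        region_values = regions.values
        region_codes = sorted(np.unique(region_values[region_values > 0]).tolist())
        overrides = config.region_overrides

    for rc in region_codes:
        rsel = region_values == rc
        over = overrides.get(rc, {})
        frac = over.get("forest_fraction", config.forest_fraction)
        props = over.get("type_proportions", config.type_proportions)
        _check_proportions(props, f"region {rc}")
        u_r = u_forest[rsel]
        if frac <= 0:
            forest_sel = np.zeros_like(rsel)
        elif frac >= 1:
            forest_sel = rsel
        else:
            thr = np.quantile(u_r, frac)
            forest_sel = rsel & (u_forest <= thr)
        # split the non-forest remainder into open land / water for realism
        nonforest_sel = rsel & ~forest_sel
        if len(nonforest_codes) > 1 and nonforest_sel.any():
            wthr = np.quantile(u_type[nonforest_sel], 0.2)
            out[nonforest_sel & (u_type <= wthr)] = nonforest_codes[1]
        if not forest_sel.any():
            continue
        v = u_type[forest_sel]
        # bin only over types with positive share so zero-width bins cannot
        # swallow boundary values
        positive = [t for t in FOREST_TYPES if props.get(t, 0.0) > 0]
        edges = np.quantile(v, np.cumsum([props[t] for t in positive]))
        assigned = np.searchsorted(edges, v, side="left").clip(0, len(positive) - 1)
        codes = np.array([code_by_name[t] for t in positive], dtype=np.int16)
        out[forest_sel] = codes[assigned]
    return Grid(out, config.pixel_size_m, (0.0, 0.0), nodata=-1)


def _grow_patches(
    probability: np.ndarray, eligible: np.ndarray, target_px: int
) -> np.ndarray:
    """Grow connected patches from local probability maxima until
    ``target_px`` pixels are selected (highest-probability frontier first)."""
    selected = np.zeros_like(eligible, dtype=bool)
    if target_px <= 0 or not eligible.any():
        return selected
    masked = np.where(eligible, probability, -np.inf)
    local_max = (
        ndimage.maximum_filter(masked, size=3, mode="constant", cval=-np.inf) == masked
    ) & eligible
    rows, cols = probability.shape
    heap: list[tuple[float, int, int]] = []
    queued = np.zeros_like(eligible, dtype=bool)
    for r, c in zip(*np.nonzero(local_max)):
        heapq.heappush(heap, (-probability[r, c], int(r), int(c)))
        queued[r, c] = True
    count = 0
    while heap and count < target_px:
        _, r, c = heapq.heappop(heap)
        if selected[r, c]:
            continue
        selected[r, c] = True
        count += 1
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                nr, nc = r + dr, c + dc
                if 0 <= nr < rows and 0 <= nc < cols and eligible[nr, nc] and not queued[nr, nc]:
                    heapq.heappush(heap, (-probability[nr, nc], nr, nc))
                    queued[nr, nc] = True
    return selected


def generate_baseline(
    probability: Grid,
    landcover: Grid,
    config: LandscapeConfig,
    regions: Grid | None = None,
    scheme: ForestTypeScheme | None = None,
    seed: int | None = None,
) -> Mask:
    """Confirmed-network baseline grown on high-probability forest clusters.

    Patches grow from local maxima of a *survey field* — the probability
    surface blended (via normal scores) with an independent autocorrelated
    field weighted by ``survey_noise`` — stopping at the target share of
    forest per region. The noise emulates decades of field surveys without a
    sampling scheme: the baseline preferentially occupies high-probability
    forest but misses part of it, so substantial high-probability forest
    remains outside the network (that remainder is the connectivity forest).
    The resulting bundle shows the quantile structure the 0.4 threshold
    relies on: median probability inside the baseline above 0.4, and at
    least ~75% of the remaining forest below it.
    """
    assert_aligned([probability, landcover], ["probability", "landcover"])
    scheme = scheme or ForestTypeScheme()
    forest = np.isin(landcover.values, list(scheme.codes)) & landcover.valid
    p = probability.values
    if config.baseline_fraction > 0 and forest.any() and np.nanmax(p[forest]) < 0.4:
        raise ValueError(
            "infeasible baseline: no forest pixel reaches probability 0.4 "
            f"(max {np.nanmax(p[forest]):.3f}); the quantile structure "
            "(baseline median > 0.4) cannot hold"
        )
    rng = _sub_rng(config.seed if seed is None else seed, 3)
    w = config.survey_noise
    if w > 0:
        noise = _smooth_field(
            rng, *probability.shape,
            config.correlation_length_m, config.pixel_size_m,
        )
        z_p = stats.norm.ppf(_rank_uniform(p))
        z_n = stats.norm.ppf(_rank_uniform(noise))
        survey = (1.0 - w) * z_p + w * z_n
    else:
        survey = p
    selected = np.zeros(probability.shape, dtype=bool)
    if regions is None:
        target = int(round(config.baseline_fraction * forest.sum()))
        selected = _grow_patches(survey, forest, target)
    else:
        region_values = regions.values
        for rc in sorted(np.unique(region_values[region_values > 0]).tolist()):
            over = config.region_overrides.get(rc, {})
            frac = over.get("baseline_fraction", config.baseline_fraction)
            eligible = forest & (region_values == rc)
            target = int(round(frac * eligible.sum()))
            selected |= _grow_patches(survey, eligible, target)
    return Mask.from_bool(selected, probability, valid=landcover.valid)


def make_scenario(config: LandscapeConfig) -> LandscapeBundle:
    """Generate the full co-registered bundle from one master seed."""
    regions = generate_regions(config)
    probability = generate_probability_surface(config)
    landcover = generate_landcover(config, regions=regions)
    baseline = generate_baseline(probability, landcover, config, regions=regions)
    return LandscapeBundle(probability, landcover, baseline, regions, config=config)
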