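"""End-to-end orchestration: configuration, the full analysis, and reports.

``run_pipeline`` executes the whole workflow — land-cover semantics, CF
extraction, stepwise scenario construction, GI density for every (scenario,
forest type, radius), functional-habitat delineation and restoration
hotspots — on either a synthetic bundle or four co-registered GeoTIFFs, and
returns a :class:`RunReport` of data frames. ``render_report`` writes the
CSVs, a human-readable summary (with the display-rounding conventions of
the area table: "-" for absent classes, "0" for areas under 0.5 ha) and the
key rasters. Runs are deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cf import (
    CFRaster,
    class_label,
    area_summary,
    default_thresholds,
    extract_cf,
    nested_class_mask,
    probability_quantiles,
)
from .density import (
    circular_kernel,
    compute_density,
    cumulative_cf_share,
    density_distribution,
    median_increase,
)
from .grids import Grid, Mask, area_of, read_grid, write_grid
from .hotspots import (
    HotspotResult,
    functional_mask,
    functional_proportion,
    identify_hotspots,
)
from .landcover import (
    ForestTypeScheme,
    PURE_TYPES,
    exclude_nonforest_baseline,
    type_membership,
)
from .synthetic import LandscapeBundle, LandscapeConfig, make_scenario

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "render_report"]

log = logging.getLogger("confor")


@dataclass
class PipelineConfig:
    """All global knobs of the workflow, defaulting to the study values:
    CF threshold 0.4 with 0.1-step classes, window radii 3 km and 1 km,
    5-km outer analysis rim, 20% functionality threshold, 3-km hotspot
    buffer, 1-ha minimum patch, mixed-stand weight 0.5."""

    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    inputs: dict[str, str] | None = None  # probability/landcover/baseline/regions paths
    scheme: ForestTypeScheme = field(default_factory=ForestTypeScheme)
    tau_min: float = 0.4
    thresholds: tuple[float, ...] | None = None
    radii_m: tuple[float, ...] = (3000.0, 1000.0)
    headline_radius_m: float = 3000.0
    outer_buffer_m: float = 5000.0
    hotspot_buffer_m: float = 3000.0
    functional_threshold_pct: float = 20.0
    min_area_ha: float = 1.0
    hotspot_reference: str = "per_step"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.thresholds is None:
            self.thresholds = default_thresholds(self.tau_min)
        self.thresholds = tuple(self.thresholds)
        if list(self.thresholds) != sorted(self.thresholds, reverse=True):
            raise ValueError("thresholds must be descending")
        if any(t < self.tau_min - 1e-9 for t in self.thresholds):
            raise ValueError("all thresholds must be >= tau_min")
        if any(r <= 0 for r in self.radii_m):
            raise ValueError("radii must be positive")
        if self.headline_radius_m not in self.radii_m:
            raise ValueError("headline_radius_m must be one of radii_m")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "landscape": self.landscape.to_dict(),
            "inputs": dict(self.inputs) if self.inputs else None,
            "scheme": self.scheme.to_dict(),
            "tau_min": self.tau_min,
            "thresholds": list(self.thresholds),
            "radii_m": list(self.radii_m),
            "headline_radius_m": self.headline_radius_m,
            "outer_buffer_m": self.outer_buffer_m,
            "hotspot_buffer_m": self.hotspot_buffer_m,
            "functional_threshold_pct": self.functional_threshold_pct,
            "min_area_ha": self.min_area_ha,
            "hotspot_reference": self.hotspot_reference,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        kwargs = dict(d)
        if "landscape" in kwargs and kwargs["landscape"] is not None:
            kwargs["landscape"] = LandscapeConfig.from_dict(kwargs["landscape"])
        if "scheme" in kwargs and kwargs["scheme"] is not None:
            kwargs["scheme"] = ForestTypeScheme.from_dict(kwargs["scheme"])
        for key in ("thresholds", "radii_m"):
            if kwargs.get(key) is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return path


@dataclass(eq=False)
class RunReport:
    """Every table the pipeline produces, regenerable from bundle + config."""

    config: dict
    area_table: pd.DataFrame
    quantiles: pd.DataFrame
    density_stats: pd.DataFrame
    median_increases: pd.DataFrame
    cf_shares: pd.DataFrame
    functional: pd.DataFrame
    hotspot_stats: pd.DataFrame
    hotspot_summary: dict
    provenance: dict
    bundle: LandscapeBundle
    cf: CFRaster
    hotspots: HotspotResult


def load_bundle(config: PipelineConfig) -> LandscapeBundle:
    """Read the four input rasters, or simulate them when none are given."""
    if config.inputs:
        required = ("probability", "landcover", "baseline", "regions")
        missing = [k for k in required if k not in config.inputs]
        if missing:
            raise ValueError(f"missing input raster paths: {missing}")
        probability = read_grid(config.inputs["probability"])
        landcover = read_grid(config.inputs["landcover"])
        baseline = Mask.from_grid(read_grid(config.inputs["baseline"]))
        regions = read_grid(config.inputs["regions"])
        return LandscapeBundle(probability, landcover, baseline, regions)
    return make_scenario(replace(config.landscape, seed=config.seed))


def _study_extent(bundle: LandscapeBundle, outer_buffer_m: float) -> Mask | None:
    """Interior extent after reserving the outer analysis rim.

    The generated (or supplied) frame includes a rim of width
    ``outer_buffer_m`` whose data support edge windows but whose pixels are
    not themselves reported. Frames too small to hold the rim are used
    whole (toy configurations).
    """
    margin = int(round(outer_buffer_m / bundle.probability.pixel_size_m))
    rows, cols = bundle.probability.shape
    if margin <= 0 or rows <= 2 * margin or cols <= 2 * margin:
        return None
    members = np.zeros((rows, cols), dtype=bool)
    members[margin : rows - margin, margin : cols - margin] = True
    return Mask.from_bool(members, bundle.probability)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full workflow and collect every table of the report."""
    t0 = time.time()
    bundle = load_bundle(config)
    scheme = config.scheme
    log.info("bundle: %dx%d pixels", *bundle.probability.shape)

    baseline, excluded_ha = exclude_nonforest_baseline(
        bundle.baseline, bundle.landcover, scheme
    )
    log.info("baseline: %.0f ha (%.0f ha non-forest excluded)", area_of(baseline), excluded_ha)

    cf = extract_cf(
        bundle.probability, baseline, bundle.landcover, scheme,
        tau_min=config.tau_min, thresholds=config.thresholds,
    )
    log.info("CF: %.0f ha", float(cf.cf_members.sum()) * baseline.pixel_area_ha)

    from .landcover import forest_mask  # local to avoid surfacing in module API

    forest = forest_mask(bundle.landcover, scheme)
    masks = {
        "baseline_forest": baseline,
        "nonbaseline_forest": Mask.from_bool(
            forest.members & ~baseline.members, baseline
        ),
    }
    rv = bundle.regions.values
    for rc in sorted(np.unique(rv[bundle.regions.valid]).tolist()):
        masks[f"region{rc}_nonbaseline_forest"] = Mask.from_bool(
            forest.members & ~baseline.members & (rv == rc), baseline
        )
    quantiles = probability_quantiles(bundle.probability, masks)

    area_table = area_summary(cf, baseline, bundle.landcover, scheme, bundle.regions)

    study_extent = _study_extent(bundle, config.outer_buffer_m)
    scenarios: list[tuple[str, float | None]] = [("baseline", None)] + [
        (class_label(t), t) for t in config.thresholds
    ]
    empty_cf = Mask.from_bool(np.zeros(baseline.shape, dtype=bool), baseline)

    dens_rows, func_rows = [], []
    baseline_stats: dict[tuple[float, str], pd.DataFrame] = {}
    incr_frames = []
    for radius in config.radii_m:
        kernel = circular_kernel(radius, bundle.probability.pixel_size_m)
        for ftype in ("all",) + PURE_TYPES:
            for label, tau in scenarios:
                cls = empty_cf if tau is None else nested_class_mask(cf, tau)
                memb = type_membership(bundle.landcover, scheme, ftype, cls, baseline)
                dens = compute_density(memb, kernel, study_extent, config.outer_buffer_m)
                stats = density_distribution(dens, bundle.regions)
                stats.insert(0, "radius_m", radius)
                stats.insert(1, "forest_type", ftype)
                stats.insert(2, "scenario", label)
                dens_rows.append(stats)
                if tau is None:
                    baseline_stats[(radius, ftype)] = stats
                else:
                    inc = median_increase(stats, baseline_stats[(radius, ftype)])
                    inc.insert(0, "radius_m", radius)
                    inc.insert(1, "forest_type", ftype)
                    inc.insert(2, "scenario", label)
                    incr_frames.append(inc)
                if ftype == "all":
                    px_ha = baseline.pixel_area_ha
                    defined = dens.grid.valid
                    func_rows.append(
                        {"radius_m": radius, "scenario": label,
                         "functional_area_ha": float(
                             (defined & (dens.values >= config.functional_threshold_pct)).sum()
                         ) * px_ha,
                         "positive_area_ha": float(
                             (defined & (dens.values > 0)).sum()
                         ) * px_ha,
                         "functional_share_pct": functional_proportion(
                             dens, config.functional_threshold_pct
                         )}
                    )
        log.info("density done for radius %.0f m", radius)

    density_stats = pd.concat(dens_rows, ignore_index=True)
    median_increases = pd.concat(incr_frames, ignore_index=True)
    functional = pd.DataFrame(func_rows)
    cf_shares = pd.concat(
        [
            cumulative_cf_share(cf, bundle.regions, bundle.landcover, scheme, t)
            for t in config.thresholds
        ],
        ignore_index=True,
    )

    kernel = circular_kernel(config.headline_radius_m, bundle.probability.pixel_size_m)
    hotspots = identify_hotspots(
        cf, baseline, bundle.landcover, scheme, bundle.regions,
        kernel, config.thresholds,
        buffer_m=config.hotspot_buffer_m,
        threshold_pct=config.functional_threshold_pct,
        min_area_ha=config.min_area_ha,
        hotspot_reference=config.hotspot_reference,
        study_extent=study_extent,
        outer_buffer_m=config.outer_buffer_m,
    )
    hotspot_summary = {
        "n_hotspots": int(hotspots.patches.n_patches),
        "total_area_ha": float(hotspots.patches.areas_ha.sum()),
        "functional_baseline_ha": hotspots.functional_baseline_ha,
        "functional_with_hotspots_ha": hotspots.functional_with_hotspots_ha,
        "excluded_nonforest_baseline_ha": excluded_ha,
    }
    log.info(
        "hotspots: %d patches, %.0f ha", hotspot_summary["n_hotspots"],
        hotspot_summary["total_area_ha"],
    )
    provenance = {
        "package": "confor",
        "version": __version__,
        "seed": config.seed,
        "runtime_s": round(time.time() - t0, 2),
    }
    return RunReport(
        config=config.to_dict(),
        area_table=area_table,
        quantiles=quantiles,
        density_stats=density_stats,
        median_increases=median_increases,
        cf_shares=cf_shares,
        functional=functional,
        hotspot_stats=hotspots.stats,
        hotspot_summary=hotspot_summary,
        provenance=provenance,
        bundle=bundle,
        cf=cf,
        hotspots=hotspots,
    )


# -- rendering ---------------------------------------------------------------


def format_area_display(area_ha: float) -> str:
    """Display convention of the area table: "-" marks an absent class,
    "0" any area below 0.5 ha; everything else rounds to whole hectares."""
    if np.isnan(area_ha) or area_ha == 0:
        return "-"
    if area_ha < 0.5:
        return "0"
    return f"{area_ha:,.0f}"


def _area_display_table(area_table: pd.DataFrame) -> pd.DataFrame:
    sub = area_table[area_table["cf_class"] != "baseline"].copy()
    sub["display"] = sub["area_ha"].map(format_area_display)
    return sub.pivot_table(
        index=["forest_type", "cf_class"],
        columns="region",
        values="display",
        aggfunc="first",
    )


def render_report(report: RunReport, out_dir: str | Path, write_rasters: bool = True) -> list[Path]:
    """Write CSVs, a markdown summary and (optionally) the key rasters."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    tables = {
        "area_table.csv": report.area_table,
        "probability_quantiles.csv": report.quantiles,
        "density_stats.csv": report.density_stats,
        "median_increase.csv": report.median_increases,
        "cf_shares.csv": report.cf_shares,
        "functional.csv": report.functional,
        "hotspot_stats.csv": report.hotspot_stats,
    }
    for name, df in tables.items():
        path = out / name
        df.to_csv(path, index=False)
        written.append(path)

    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(report.config, fh, sort_keys=True)
    written.append(out / "config.yaml")
    with open(out / "run_info.json", "w") as fh:
        json.dump({**report.provenance, **report.hotspot_summary}, fh, indent=2)
    written.append(out / "run_info.json")

    lines = ["# Connectivity-forest run summary", ""]
    lines.append(f"Seed: {report.provenance['seed']}")
    hs = report.hotspot_summary
    lines += [
        "",
        f"Restoration hotspots: {hs['n_hotspots']} patches, "
        f"{hs['total_area_ha']:,.0f} ha",
        f"Functional habitat (baseline): {hs['functional_baseline_ha']:,.0f} ha; "
        f"with hotspots inserted: {hs['functional_with_hotspots_ha']:,.0f} ha",
        "",
        "## Nested CF class areas (ha) by region",
        "('-' = no area, '0' = below 0.5 ha)",
        "",
        _area_display_table(report.area_table).to_markdown(),
        "",
    ]
    (out / "summary.md").write_text("\n".join(lines))
    written.append(out / "summary.md")

    if write_rasters:
        b = report.bundle
        for name, grid in (
            ("probability.tif", b.probability),
            ("landcover.tif", b.landcover),
            ("baseline.tif", b.baseline),
            ("regions.tif", b.regions),
            ("cf_classes.tif", report.cf.labels),
            ("hotspots.tif", report.hotspots.patches.labels),
        ):
            written.append(write_grid(grid, out / name))
    return written
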