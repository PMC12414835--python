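"""CF extraction, nested classes, scenarios, quantiles and area tables."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from confor import (
    LandscapeConfig,
    area_of,
    area_summary,
    default_thresholds,
    extract_cf,
    forest_mask,
    insert_cf,
    make_scenario,
    nested_class_mask,
    probability_quantiles,
)
from confor.cf import class_label
from conftest import make_grid, make_mask


def simple_inputs(probs, forest=None, baseline=None):
    probs = np.asarray(probs, dtype=float)
    lc = np.where(
        np.ones_like(probs, dtype=bool) if forest is None else np.asarray(forest),
        1, 0,
    ).astype(np.int16)
    bl = np.zeros_like(probs, dtype=bool) if baseline is None else np.asarray(baseline)
    return make_grid(probs, nodata=np.nan), make_mask(bl), make_grid(lc, nodata=-1)


class TestExtractCF:
    def test_threshold_is_inclusive_at_tau_min(self, scheme):
        p, bl, lc = simple_inputs([[0.40, 0.399]])
        cf = extract_cf(p, bl, lc, scheme)
        assert cf.labels.values.tolist() == [[5, -1]]  # class >=0.4 = index 5

    def test_baseline_pixels_are_never_cf(self, scheme):
        p, bl, lc = simple_inputs([[0.95]], baseline=[[True]])
        assert extract_cf(p, bl, lc, scheme).labels.values[0, 0] == -1

    def test_nonforest_pixels_are_never_cf(self, scheme):
        p, bl, lc = simple_inputs([[0.90]], forest=[[False]])
        assert extract_cf(p, bl, lc, scheme).labels.values[0, 0] == -1

    def test_boundary_tie_goes_to_higher_class(self, scheme):
        p, bl, lc = simple_inputs([[0.8, 0.7999]])
        labels = extract_cf(p, bl, lc, scheme).labels.values
        assert labels[0, 0] == 1 and labels[0, 1] == 2  # >=0.8 vs >=0.7

    def test_probability_outside_unit_interval_rejected(self, scheme):
        p, bl, lc = simple_inputs([[1.2]])
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            extract_cf(p, bl, lc, scheme)


class TestNestedClasses:
    def test_class_counts_by_enumeration(self, scheme):
        p, bl, lc = simple_inputs([[0.95, 0.85], [0.45, 0.35]])
        cf = extract_cf(p, bl, lc, scheme)
        assert nested_class_mask(cf, 0.9).members.sum() == 1
        assert nested_class_mask(cf, 0.8).members.sum() == 2
        assert nested_class_mask(cf, 0.4).members.sum() == 3

    def test_unconfigured_threshold_rejected(self, scheme):
        p, bl, lc = simple_inputs([[0.5]])
        cf = extract_cf(p, bl, lc, scheme)
        with pytest.raises(ValueError, match="not a configured threshold"):
            nested_class_mask(cf, 0.45)

    def test_empty_cf_gives_empty_masks(self, scheme):
        p, bl, lc = simple_inputs([[0.1, 0.2]])
        cf = extract_cf(p, bl, lc, scheme)
        for tau in cf.thresholds:
            assert not nested_class_mask(cf, tau).members.any()

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_nestedness_on_random_surfaces(self, seed):
        """mask(>=tau1) must be a subset of mask(>=tau2) whenever tau1 >= tau2,
        and CF must never intersect the baseline."""
        from confor import ForestTypeScheme

        scheme = ForestTypeScheme()
        rng = np.random.default_rng(seed)
        p, bl, lc = simple_inputs(
            rng.random((12, 12)),
            forest=rng.random((12, 12)) < 0.8,
            baseline=rng.random((12, 12)) < 0.3,
        )
        cf = extract_cf(p, bl, lc, scheme)
        assert not (cf.cf_members & bl.members).any()
        prev = None
        for tau in cf.thresholds:  # descending
            cur = nested_class_mask(cf, tau).members
            if prev is not None:
                assert (prev <= cur).all()
            prev = cur


class TestInsertCF:
    def test_empty_class_leaves_baseline(self, scheme):
        p, bl, lc = simple_inputs([[0.45, 0.1]], baseline=[[False, True]])
        cf = extract_cf(p, bl, lc, scheme)
        scen = insert_cf(bl, cf, 0.9)
        assert np.array_equal(scen.mask.members, bl.members)

    def test_scenario_area_is_additive(self, scheme):
        rng = np.random.default_rng(5)
        p, bl, lc = simple_inputs(
            rng.random((20, 20)), baseline=rng.random((20, 20)) < 0.2
        )
        cf = extract_cf(p, bl, lc, scheme)
        scen = insert_cf(bl, cf, 0.4)
        assert area_of(scen.mask) == area_of(bl) + area_of(nested_class_mask(cf, 0.4))

    def test_scenarios_nested_in_tau(self, scheme):
        rng = np.random.default_rng(6)
        p, bl, lc = simple_inputs(
            rng.random((15, 15)), baseline=rng.random((15, 15)) < 0.2
        )
        cf = extract_cf(p, bl, lc, scheme)
        hi = insert_cf(bl, cf, 0.9).mask.members
        lo = insert_cf(bl, cf, 0.4).mask.members
        assert (hi <= lo).all()
        assert (bl.members <= hi).all()


class TestQuantiles:
    def test_median_of_five_values(self):
        p = make_grid(np.array([[0.1, 0.2, 0.3, 0.4, 0.5]]), nodata=np.nan)
        q = probability_quantiles(p, {"m": make_mask(np.ones((1, 5), dtype=bool))})
        assert q.loc[0, "median"] == pytest.approx(0.3)

    def test_constant_surface_collapses_quantiles(self):
        p = make_grid(np.full((3, 3), 0.7), nodata=np.nan)
        q = probability_quantiles(p, {"m": make_mask(np.ones((3, 3), dtype=bool))})
        row = q.iloc[0]
        assert row["min"] == row["q25"] == row["median"] == row["q75"] == row["max"] == 0.7

    def test_empty_mask_flagged_not_raised(self):
        p = make_grid(np.full((2, 2), 0.5), nodata=np.nan)
        q = probability_quantiles(p, {"m": make_mask(np.zeros((2, 2), dtype=bool))})
        assert bool(q.loc[0, "empty"]) and np.isnan(q.loc[0, "median"])

    def test_default_bundle_nonbaseline_forest_below_threshold(self, scheme):
        b = make_scenario(LandscapeConfig(rows=120, cols=150, seed=2))
        forest = forest_mask(b.landcover, scheme)
        from confor import Mask

        outside = Mask.from_bool(forest.members & ~b.baseline.members, b.probability)
        q = probability_quantiles(b.probability, {"out": outside})
        assert q.loc[0, "q75"] < 0.4


def brute_force_area_table(bundle, cf, baseline, scheme):
    """Naive per-pixel loop over regions, raw types and classes, followed
    by a hand-coded reallocation; returns {(region, type, class): area}."""
    lv = cf.labels.values
    lc = bundle.landcover.values
    rg = bundle.regions.values
    name_by_code = scheme.codes
    raw = {}
    rows, cols = lv.shape
    classes = [(class_label(t), i) for i, t in enumerate(cf.thresholds)]
    for i in range(rows):
        for j in range(cols):
            code = lc[i, j]
            if code not in name_by_code:
                continue
            tname, region = name_by_code[code], rg[i, j]
            cells = []
            if baseline.members[i, j]:
                cells.append("baseline")
            if lv[i, j] >= 0:
                cells += [lab for lab, idx in classes if lv[i, j] <= idx]
            for lab in cells:
                raw[(region, tname, lab)] = raw.get((region, tname, lab), 0) + 1
    out = {}
    for (region, tname, lab), n in raw.items():
        if tname in scheme.reallocation:
            for target, frac in scheme.reallocation[tname].items():
                key = (region, target, lab)
                out[key] = out.get(key, 0.0) + n * frac
        else:
            out[(region, tname, lab)] = out.get((region, tname, lab), 0.0) + n
    return out


def test_area_summary_matches_brute_force_pixel_count(scheme):
    bundle = make_scenario(LandscapeConfig(rows=48, cols=64, seed=3))
    from confor import exclude_nonforest_baseline

    baseline, _ = exclude_nonforest_baseline(bundle.baseline, bundle.landcover, scheme)
    cf = extract_cf(bundle.probability, baseline, bundle.landcover, scheme)
    table = area_summary(cf, baseline, bundle.landcover, scheme, bundle.regions)
    expected = brute_force_area_table(bundle, cf, baseline, scheme)
    for row in table.itertuples():
        if row.forest_type == "all":
            want = sum(
                expected.get((row.region, t, row.cf_class), 0.0)
                for t in ("spruce", "pine", "deciduous")
            )
        else:
            want = expected.get((row.region, row.forest_type, row.cf_class), 0.0)
        assert row.area_ha == pytest.approx(want, abs=1e-9), (
            row.region, row.forest_type, row.cf_class
        )


def test_area_summary_percentage_arithmetic(scheme):
    # region with 100 ha all-forest baseline and 9 ha of CF >= 0.7
    probs = np.full((20, 20), 0.1)
    probs[0, :9] = 0.75
    baseline = np.zeros((20, 20), dtype=bool)
    baseline[10:15, :] = True  # 100 pixels
    p, bl, lc = simple_inputs(probs, baseline=baseline)
    cf = extract_cf(p, bl, lc, scheme)
    regions = make_grid(np.ones((20, 20), dtype=np.int16), nodata=-1)
    table = area_summary(cf, bl, lc, scheme, regions)
    row = table[
        (table.forest_type == "all") & (table.cf_class == "cf>=0.7")
    ].iloc[0]
    assert row["area_ha"] == 9.0
    assert row["pct_increase"] == pytest.approx(9.0)


def test_area_summary_zero_rows_kept_and_zero_baseline_flagged(scheme):
    p, bl, lc = simple_inputs(np.full((6, 6), 0.45))
    cf = extract_cf(p, bl, lc, scheme)
    regions = make_grid(np.ones((6, 6), dtype=np.int16), nodata=-1)
    table = area_summary(cf, bl, lc, scheme, regions)
    # classes with no area are present as zero rows
    empty = table[(table.forest_type == "pine") & (table.cf_class == "cf>=0.9")]
    assert len(empty) == 1 and empty.iloc[0]["area_ha"] == 0.0
    # no baseline anywhere: increase column undefined
    assert table["increase_undefined"].all()
    assert table["pct_increase"].isna().all()


def test_default_thresholds_cover_the_six_classes():
    assert default_thresholds(0.4) == (0.9, 0.8, 0.7, 0.6, 0.5, 0.4)
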