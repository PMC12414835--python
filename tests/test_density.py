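"""Circular kernels, moving-window density and distribution statistics."""

import numpy as np
import pandas as pd
import pytest

from confor import (
    DensityRaster,
    Mask,
    circular_kernel,
    compute_density,
    cumulative_cf_share,
    density_distribution,
    extract_cf,
    median_increase,
)
from conftest import make_grid, make_mask
from _oracles import box_stats, enumerate_kernel_offsets, naive_density


class TestCircularKernel:
    def test_radius_zero_is_single_cell(self):
        k = circular_kernel(0.0, 100.0)
        assert k.size == 1 and k.offsets.tolist() == [[0, 0]]

    def test_radius_100m_is_five_cell_plus(self):
        k = circular_kernel(100.0, 100.0)
        got = {tuple(o) for o in k.offsets}
        assert got == {(0, 0), (0, 1), (0, -1), (1, 0), (-1, 0)}

    @pytest.mark.parametrize("radius", [300.0, 1000.0, 3000.0])
    def test_sizes_match_lattice_enumeration(self, radius):
        k = circular_kernel(radius, 100.0)
        oracle = enumerate_kernel_offsets(radius, 100.0)
        assert k.size == len(oracle)
        assert {tuple(o) for o in k.offsets} == set(oracle)

    def test_symmetry_and_center(self):
        k = circular_kernel(450.0, 100.0)
        offs = {tuple(o) for o in k.offsets}
        assert (0, 0) in offs
        assert all((-di, -dj) in offs and (dj, di) in offs for di, dj in offs)


class TestComputeDensity:
    def test_saturated_membership_gives_100_interior(self):
        m = make_grid(np.ones((20, 20)))
        d = compute_density(m, circular_kernel(300.0, 100.0))
        assert d.values[10, 10] == pytest.approx(100.0)

    def test_zero_membership_gives_zero(self):
        m = make_grid(np.zeros((10, 10)))
        d = compute_density(m, circular_kernel(300.0, 100.0))
        assert (d.values == 0).all()

    def test_single_member_with_plus_kernel(self):
        w = np.zeros((9, 9))
        w[4, 4] = 1.0
        d = compute_density(make_grid(w), circular_kernel(100.0, 100.0))
        assert d.values[4, 4] == pytest.approx(20.0)
        assert d.values[4, 5] == pytest.approx(20.0)
        assert d.values[3, 4] == pytest.approx(20.0)
        assert d.values[3, 3] == 0.0  # diagonal outside the plus shape

    def test_half_weight_mixed_pixel(self):
        w = np.zeros((9, 9))
        w[4, 4] = 0.5
        d = compute_density(make_grid(w), circular_kernel(100.0, 100.0))
        assert d.values[4, 4] == pytest.approx(10.0)

    def test_radius_zero_degenerates_to_scaled_membership(self):
        rng = np.random.default_rng(2)
        w = rng.choice([0.0, 0.5, 1.0], size=(12, 12))
        d = compute_density(make_grid(w), circular_kernel(0.0, 100.0))
        assert np.allclose(d.values, 100.0 * w)

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(7)
        w = rng.choice([0.0, 0.5, 1.0], size=(32, 32), p=[0.5, 0.2, 0.3])
        for radius in (200.0, 500.0):
            d = compute_density(make_grid(w), circular_kernel(radius, 100.0))
            assert np.abs(d.values - naive_density(w, radius, 100.0)).max() < 1e-9

    def test_study_extent_masks_output(self):
        w = np.ones((10, 10))
        extent = np.zeros((10, 10), dtype=bool)
        extent[3:7, 3:7] = True
        d = compute_density(
            make_grid(w), circular_kernel(100.0, 100.0),
            study_extent=make_mask(extent),
        )
        assert np.isnan(d.values[0, 0]) and not np.isnan(d.values[4, 4])

    def test_range_bounded(self):
        rng = np.random.default_rng(9)
        w = rng.random((30, 30))
        d = compute_density(make_grid(w), circular_kernel(500.0, 100.0))
        assert d.values.min() >= 0 and d.values.max() <= 100

    def test_monotone_in_membership(self):
        """Growing the membership can only raise density, pixelwise."""
        rng = np.random.default_rng(11)
        small = rng.random((15, 15)) < 0.2
        big = small | (rng.random((15, 15)) < 0.2)
        k = circular_kernel(300.0, 100.0)
        d_small = compute_density(make_grid(small.astype(float)), k)
        d_big = compute_density(make_grid(big.astype(float)), k)
        assert (d_small.values <= d_big.values + 1e-12).all()


def as_density(values, regions=None):
    g = make_grid(np.asarray(values, dtype=float), nodata=np.nan)
    return DensityRaster(grid=g, radius_m=3000.0)


class TestDistribution:
    def test_median_of_three(self):
        d = as_density([[10.0, 20.0, 30.0]])
        regions = make_grid(np.ones((1, 3), dtype=np.int16), nodata=-1)
        stats = density_distribution(d, regions)
        assert stats.loc[0, "median"] == 20.0

    def test_constant_region_has_no_outliers(self):
        d = as_density(np.full((4, 4), 42.0))
        regions = make_grid(np.ones((4, 4), dtype=np.int16), nodata=-1)
        stats = density_distribution(d, regions)
        assert stats.loc[0, "q3"] - stats.loc[0, "q1"] == 0.0
        assert stats.loc[0, "n_outliers"] == 0

    def test_matches_sort_based_oracle(self):
        rng = np.random.default_rng(13)
        vals = rng.gamma(1.2, 10.0, size=(64, 64)).clip(0, 100)
        regions = make_grid(
            np.repeat([1, 2], 32 * 64).reshape(64, 64).astype(np.int16), nodata=-1
        )
        stats = density_distribution(as_density(vals), regions)
        for rc in (1, 2):
            want = box_stats(vals[regions.values == rc])
            row = stats[stats.region == rc].iloc[0]
            for key, val in want.items():
                assert row[key] == pytest.approx(val, abs=1e-12), key


class TestMedianIncrease:
    @staticmethod
    def stats(medians):
        return pd.DataFrame({"region": list(range(1, len(medians) + 1)),
                             "median": medians})

    def test_fifty_percent_increase(self):
        out = median_increase(self.stats([15.0]), self.stats([10.0]))
        assert out.loc[0, "median_increase_pct"] == pytest.approx(50.0)
        assert not out.loc[0, "undefined"]

    def test_identical_medians_give_zero(self):
        out = median_increase(self.stats([7.0]), self.stats([7.0]))
        assert out.loc[0, "median_increase_pct"] == 0.0

    def test_zero_baseline_flagged_undefined(self):
        out = median_increase(self.stats([5.0]), self.stats([0.0]))
        assert bool(out.loc[0, "undefined"])
        assert np.isnan(out.loc[0, "median_increase_pct"])


class TestCumulativeShare:
    def test_single_type_landscape_reaches_100_at_tau_min(self, scheme):
        p = make_grid(np.full((10, 10), 0.55), nodata=np.nan)
        lc = make_grid(np.full((10, 10), 2, dtype=np.int16), nodata=-1)  # pine
        bl = make_mask(np.zeros((10, 10), dtype=bool))
        cf = extract_cf(p, bl, lc, scheme)
        regions = make_grid(np.ones((10, 10), dtype=np.int16), nodata=-1)
        shares = cumulative_cf_share(cf, regions, lc, scheme, 0.4)
        allrow = shares[shares.forest_type == "all"].iloc[0]
        pinerow = shares[shares.forest_type == "pine"].iloc[0]
        assert allrow["share_pct"] == pytest.approx(100.0)
        assert pinerow["share_pct"] == pytest.approx(100.0)

    def test_shares_monotone_as_tau_decreases(self, scheme):
        rng = np.random.default_rng(17)
        p = make_grid(rng.random((20, 20)), nodata=np.nan)
        lc = make_grid(rng.choice([1, 2, 3], size=(20, 20)).astype(np.int16), nodata=-1)
        bl = make_mask(np.zeros((20, 20), dtype=bool))
        cf = extract_cf(p, bl, lc, scheme)
        regions = make_grid(np.ones((20, 20), dtype=np.int16), nodata=-1)
        prev = None
        for tau in cf.thresholds:
            cur = cumulative_cf_share(cf, regions, lc, scheme, tau)
            if prev is not None:
                assert (cur["share_pct"].values >= prev["share_pct"].values - 1e-12).all()
            prev = cur

    def test_no_cf_region_flagged_undefined(self, scheme):
        p = make_grid(np.full((4, 4), 0.1), nodata=np.nan)
        lc = make_grid(np.ones((4, 4), dtype=np.int16), nodata=-1)
        bl = make_mask(np.zeros((4, 4), dtype=bool))
        cf = extract_cf(p, bl, lc, scheme)
        regions = make_grid(np.ones((4, 4), dtype=np.int16), nodata=-1)
        shares = cumulative_cf_share(cf, regions, lc, scheme, 0.4)
        assert shares["undefined"].all()
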