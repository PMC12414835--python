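"""Shared fixtures: tiny grids and the hand-constructed 40x40 bundle."""

from __future__ import annotations

import numpy as np
import pytest

from confor import (
    ForestTypeScheme,
    Grid,
    LandscapeBundle,
    Mask,
)


def make_grid(values, pixel_size_m=100.0, nodata=None) -> Grid:
    return Grid(np.asarray(values), pixel_size_m, (0.0, 0.0), nodata=nodata)


def make_mask(members, pixel_size_m=100.0) -> Mask:
    members = np.asarray(members, dtype=bool)
    return Mask.from_bool(members, make_grid(np.zeros(members.shape), pixel_size_m))


@pytest.fixture
def scheme() -> ForestTypeScheme:
    return ForestTypeScheme()


@pytest.fixture
def hand_bundle() -> LandscapeBundle:
    """A 40x40 bundle with hand-placed baseline block, CF clusters and a
    mixed-stand patch, used for exact end-to-end checks.

    Layout (100 m pixels, all CF probabilities chosen per class):
      * baseline block rows 4-11 x cols 4-11 (one water pixel inside);
      * cluster A rows 13-15 x cols 5-7 at p=0.95 (adjacent to baseline);
      * single pixel (8, 25) at p=0.85;
      * cluster B rows 20-22 x cols 20-22 at p=0.65;
      * mixed-coniferous 2x2 rows 30-31 x cols 4-5 at p=0.55;
      * cluster C rows 34-36 x cols 34-36 at p=0.45 (far from baseline);
      * pine east half, spruce west half; open land strip in the far north.
    """
    shape = (40, 40)
    p = np.full(shape, 0.10)
    lc = np.ones(shape, dtype=np.int16)  # spruce
    lc[:, 20:] = 2  # pine
    lc[0, 0:6] = 0  # open land
    lc[5, 5] = 6  # water inside the baseline block
    lc[30:32, 4:6] = 4  # mixed coniferous

    baseline = np.zeros(shape, dtype=bool)
    baseline[4:12, 4:12] = True
    p[4:12, 4:12] = 0.35  # baseline membership is independent of p

    p[13:16, 5:8] = 0.95  # A
    p[8, 25] = 0.85  # D
    p[20:23, 20:23] = 0.65  # B
    p[30:32, 4:6] = 0.55  # mixed patch
    p[34:37, 34:37] = 0.45  # C

    regions = np.ones(shape, dtype=np.int16)
    regions[20:, :] = 2

    g = lambda v, nd: Grid(v, 100.0, (0.0, 0.0), nodata=nd)
    return LandscapeBundle(
        probability=g(p, np.nan),
        landcover=g(lc, -1),
        baseline=Mask.from_bool(baseline, g(p, np.nan)),
        regions=g(regions, -1),
    )
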