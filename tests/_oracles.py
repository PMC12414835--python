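"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (explicit per-pixel loops, BFS flood
fill, exhaustive distance checks) kept separate from the library code they
verify.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def enumerate_kernel_offsets(radius_m: float, pixel_size_m: float) -> list[tuple[int, int]]:
    """Lattice points within the inclusive circular radius, by double loop."""
    r_px = int(radius_m // pixel_size_m) + 1
    out = []
    for di in range(-r_px, r_px + 1):
        for dj in range(-r_px, r_px + 1):
            if (di * di + dj * dj) * pixel_size_m**2 <= radius_m**2:
                out.append((di, dj))
    return out


def naive_density(w: np.ndarray, radius_m: float, pixel_size_m: float) -> np.ndarray:
    """Per-pixel double-loop moving-window percentage with full-kernel
    denominator and zero weight outside the array."""
    rows, cols = w.shape
    offs = enumerate_kernel_offsets(radius_m, pixel_size_m)
    k = len(offs)
    out = np.zeros((rows, cols), dtype=float)
    for i in range(rows):
        for j in range(cols):
            s = 0.0
            for di, dj in offs:
                ii, jj = i + di, j + dj
                if 0 <= ii < rows and 0 <= jj < cols:
                    s += w[ii, jj]
            out[i, j] = 100.0 * s / k
    return out


def flood_fill_label(members: np.ndarray) -> np.ndarray:
    """8-connected component labels by BFS flood fill (0 = background)."""
    rows, cols = members.shape
    labels = np.zeros((rows, cols), dtype=int)
    nxt = 0
    for i in range(rows):
        for j in range(cols):
            if members[i, j] and labels[i, j] == 0:
                nxt += 1
                q = deque([(i, j)])
                labels[i, j] = nxt
                while q:
                    r, c = q.popleft()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (
                                0 <= rr < rows and 0 <= cc < cols
                                and members[rr, cc] and labels[rr, cc] == 0
                            ):
                                labels[rr, cc] = nxt
                                q.append((rr, cc))
    return labels


def same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    """True if two label images describe the same pixel partition
    (labels may be permuted)."""
    if (a > 0).sum() != (b > 0).sum() or not np.array_equal(a > 0, b > 0):
        return False
    mapping: dict[int, int] = {}
    back: dict[int, int] = {}
    for x, y in zip(a[a > 0], b[a > 0]):
        if mapping.setdefault(x, y) != y or back.setdefault(y, x) != x:
            return False
    return True


def naive_buffer(members: np.ndarray, width_m: float, pixel_size_m: float) -> np.ndarray:
    """Exhaustive pixel-center distance check against every member pixel."""
    rows, cols = members.shape
    pts = np.argwhere(members)
    out = np.zeros((rows, cols), dtype=bool)
    if pts.size == 0:
        return out
    w2 = (width_m / pixel_size_m) ** 2
    for i in range(rows):
        for j in range(cols):
            d2 = ((pts[:, 0] - i) ** 2 + (pts[:, 1] - j) ** 2).min()
            out[i, j] = d2 <= w2
    return out


def box_stats(vals: np.ndarray) -> dict:
    """Sort-based box statistics with hand-coded linear interpolation."""
    v = np.sort(np.asarray(vals, dtype=float))
    n = v.size

    def quantile(q: float) -> float:
        h = (n - 1) * q
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        return v[lo] + (h - lo) * (v[hi] - v[lo])

    q1, med, q3 = quantile(0.25), quantile(0.5), quantile(0.75)
    iqr = q3 - q1
    lo_f, hi_f = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_f) & (v <= hi_f)]
    return {
        "min": v[0], "q1": q1, "median": med, "q3": q3, "max": v[-1],
        "whisker_low": inside[0], "whisker_high": inside[-1],
        "n_outliers": int(((v < lo_f) | (v > hi_f)).sum()),
    }
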