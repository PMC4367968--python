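"""Independent brute-force oracles used by the test suite.

Each oracle implements the mathematical definition of an operation by
direct enumeration, sharing no code path with the package.
"""

from __future__ import annotations

import numpy as np
import scipy.ndimage as ndi

_STRUCT8 = np.ones((3, 3), dtype=bool)


def prominence_maxima_oracle(img: np.ndarray, tolerance: float) -> set[tuple[int, int]]:
    """All (x, y) local maxima with prominence strictly above tolerance.

    Assumes a tie-free image (all pixel values distinct).  For each
    strict local maximum, the saddle is the highest threshold t such
    that the 8-connected component of ``img >= t`` containing the peak
    also contains a strictly higher pixel (binary search over the
    sorted unique values); the global maximum has unbounded prominence
    and is always reported for a non-constant image.
    """
    h, w = img.shape
    vals = np.sort(np.unique(img))
    out: set[tuple[int, int]] = set()
    gmax = img.max()
    for r in range(h):
        for c in range(w):
            v = img[r, c]
            neigh = img[max(0, r - 1):r + 2, max(0, c - 1):c + 2]
            if v < neigh.max():
                continue
            if v == gmax:
                if v > img.min():
                    out.add((c, r))
                continue
            else:
                # largest t <= v with: component of img>=t at (r,c) holds a pixel > v
                lo, hi = 0, int(np.searchsorted(vals, v))  # vals[lo..hi-1] candidates
                saddle = None
                while lo < hi:
                    mid = (lo + hi) // 2
                    t = vals[mid]
                    lab, _ = ndi.label(img >= t, structure=_STRUCT8)
                    comp = lab == lab[r, c]
                    if img[comp].max() > v:
                        saddle = t
                        lo = mid + 1
                    else:
                        hi = mid
                assert saddle is not None, "non-global maximum must connect upward"
            if v - saddle > tolerance:
                out.add((c, r))
    return out


def rolling_ball_apex_oracle(img: np.ndarray, radius: int,
                             rows=None) -> np.ndarray:
    """Ball-apex background by direct enumeration.

    bg(p) = min over ball footprint offsets d of img(p+d) + sag(d),
    sag(d) = radius - sqrt(radius^2 - |d|^2); offsets falling outside
    the frame are ignored.  ``rows`` restricts the output rows computed
    (others stay +inf), to keep the enumeration affordable.
    """
    h, w = img.shape
    r = radius
    bg = np.full((h, w), np.inf)
    for i in (range(h) if rows is None else rows):
        for j in range(w):
            best = np.inf
            for a in range(-r, r + 1):
                for b in range(-r, r + 1):
                    if a * a + b * b > r * r:
                        continue
                    ii, jj = i + a, j + b
                    if 0 <= ii < h and 0 <= jj < w:
                        sag = r - np.sqrt(r * r - a * a - b * b)
                        best = min(best, img[ii, jj] + sag)
            bg[i, j] = best
    return bg


def point_in_polygon_oracle(px: float, py: float, verts: np.ndarray) -> bool:
    """Scalar even-odd ray casting with the half-open crossing rule."""
    inside = False
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            x_at = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_at:
                inside = not inside
    return inside


def nn_distances_oracle(points: np.ndarray) -> np.ndarray:
    """All-pairs O(n^2) nearest-neighbor distances (pixel units)."""
    n = len(points)
    out = np.empty(n)
    for i in range(n):
        best = np.inf
        for j in range(n):
            if i != j:
                d = np.hypot(*(points[i] - points[j]))
                best = min(best, d)
        out[i] = best
    return out


def kruskal_h_by_hand(groups: list[np.ndarray]) -> float:
    """Kruskal-Wallis H from rank sums, no tie handling (tie-free data)."""
    all_vals = np.concatenate(groups)
    n = len(all_vals)
    order = np.argsort(all_vals)
    ranks = np.empty(n)
    ranks[order] = np.arange(1, n + 1)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    return 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
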