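"""Prominence-based local-maxima detection and detection-parameter
calibration.

A local maximum is reported when its *prominence* — its height above the
highest saddle connecting it to a higher maximum — strictly exceeds the
noise tolerance.  Prominence is computed exactly by a union-find sweep
over pixels in descending intensity order (the persistence construction)
with 8-connectivity; equal-valued plateaus yield a single point at the
plateau centroid.  Ties in intensity are broken by raster order, which
makes the procedure fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import DEFAULT_ROLLING_RADIUS_PX, DEFAULT_TOLERANCE
from .imgio import GrayImage, RegionOfInterest
from .preprocess import PreprocessParams, preprocess


@dataclass
class MaximaSet:
    """Detected intensity maxima as planar points inside a ROI.

    ``points`` is an (n, 2) float array of (x, y) pixel coordinates.
    """

    points: np.ndarray
    roi: RegionOfInterest | None = None
    tolerance_used: float = float("nan")

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64).reshape(-1, 2)
        if len(pts) and len(np.unique(pts, axis=0)) != len(pts):
            raise ValueError("duplicate maxima coordinates")
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class DetectionParams:
    """Noise tolerance and background-ball radius for one detection run."""

    tolerance: float = DEFAULT_TOLERANCE
    rolling_radius: int = DEFAULT_ROLLING_RADIUS_PX

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")


_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _prominent_peaks(pixels: np.ndarray, tolerance: float) -> list[int]:
    """Flat indices of peak pixels with prominence strictly above ``tolerance``.

    Union-find over pixels in descending (value, raster-order) order.
    When a pixel joins two or more components the lower peaks die at
    that saddle; a dying peak is kept iff peak - saddle > tolerance.
    The global maximum has no higher maximum, hence unbounded
    prominence: it is always kept unless the image is constant.
    """
    h, w = pixels.shape
    n = h * w
    flat = pixels.ravel()
    order = np.argsort(-flat, kind="stable")  # descending value, ties by index
    rank = np.empty(n, dtype=np.int64)
    rank[order] = np.arange(n)

    parent = np.full(n, -1, dtype=np.int64)
    peak_of = np.empty(n, dtype=np.int64)  # root -> flat index of its peak

    def find(i: int) -> int:
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = root, parent[i]
        return root

    kept: list[int] = []
    for idx in order:
        r, c = divmod(int(idx), w)
        roots = []
        for dr, dc in _NEIGHBORS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w:
                j = rr * w + cc
                if parent[j] >= 0 and rank[j] < rank[idx]:
                    root = find(j)
                    if root not in roots:
                        roots.append(root)
        parent[idx] = idx
        if not roots:
            peak_of[idx] = idx
            continue
        # winner: component whose peak is highest (earliest in order)
        winner = min(roots, key=lambda rt: rank[peak_of[rt]])
        v = flat[idx]
        for root in roots:
            if root is winner or root == winner:
                continue
            if flat[peak_of[root]] - v > tolerance:
                kept.append(int(peak_of[root]))
            parent[root] = winner
        parent[idx] = winner
    final_root = find(int(order[0]))
    if flat[peak_of[final_root]] > flat[order[-1]]:  # non-constant image
        kept.append(int(peak_of[final_root]))
    return kept


def _plateau_centroid(pixels: np.ndarray, peak_flat: int) -> tuple[int, int]:
    """Centroid (x, y) of the 8-connected equal-valued plateau at a peak."""
    h, w = pixels.shape
    v = pixels.ravel()[peak_flat]
    start = (peak_flat // w, peak_flat % w)
    seen = {start}
    stack = [start]
    while stack:
        r, c = stack.pop()
        for dr, dc in _NEIGHBORS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and (rr, cc) not in seen \
                    and pixels[rr, cc] == v:
                seen.add((rr, cc))
                stack.append((rr, cc))
    rows = np.array([p[0] for p in seen], dtype=float)
    cols = np.array([p[1] for p in seen], dtype=float)
    return int(round(cols.mean())), int(round(rows.mean()))


def find_maxima(image: GrayImage, roi: RegionOfInterest | None = None,
                tolerance: float = DEFAULT_TOLERANCE) -> MaximaSet:
    """Detect local maxima with prominence strictly above ``tolerance``.

    Prominence is evaluated on the full image; only maxima whose plateau
    centroid lies inside the ROI mask are returned.  A flat image yields
    an empty set.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    if roi is not None and roi.mask.shape != image.pixels.shape:
        raise ValueError("ROI mask shape does not match image")
    peaks = _prominent_peaks(image.pixels, tolerance)
    pts = []
    for pk in peaks:
        x, y = _plateau_centroid(image.pixels, pk)
        if roi is None or roi.mask[y, x]:
            pts.append((x, y))
    pts_arr = np.asarray(sorted(set(pts)), dtype=np.float64).reshape(-1, 2)
    return MaximaSet(pts_arr, roi=roi, tolerance_used=float(tolerance))


def count_maxima(maxima: MaximaSet) -> int:
    """Number of detected maxima (the TOTMAX variable)."""
    return len(maxima)


@dataclass
class CalibrationResult:
    """Outcome of the detection-parameter search."""

    params: DetectionParams
    achieved_count: int
    target_count: int
    converged: bool
    band: float = 0.05

    @property
    def relative_error(self) -> float:
        return abs(self.achieved_count - self.target_count) / self.target_count


def _count_at(image: GrayImage, region: RegionOfInterest, tolerance: float,
              rolling_radius: int, displacement: int,
              cache: dict) -> int:
    key = rolling_radius
    if key not in cache:
        cache[key] = preprocess(
            image, PreprocessParams(rolling_radius=rolling_radius,
                                    displacement=displacement))
    return count_maxima(find_maxima(cache[key], region, tolerance))


def calibrate_detection(image: GrayImage, region: RegionOfInterest,
                        user_count: int,
                        initial: DetectionParams | None = None,
                        band: float = 0.05,
                        displacement: int = 1,
                        tolerance_bounds: tuple[float, float] = (1.0, 255.0),
                        radius_candidates: tuple[int, ...] = (5, 10, 25, 50, 100, 200),
                        ladder_size: int = 25) -> CalibrationResult:
    """Search detection parameters reproducing a user's manual count.

    For each candidate rolling-ball radius (starting from the initial
    parameters), the noise tolerance is scanned on a logarithmic ladder
    between ``tolerance_bounds``; the detected count is non-increasing
    in tolerance, so the scan brackets the target and the best rung is
    kept.  The search stops at the first parameter pair whose count
    falls within ``band`` (default +-5%) of ``user_count``; otherwise
    the best pair found is returned flagged as unconverged.
    """
    if user_count <= 0:
        raise ValueError("user_count must be positive")
    if region.mask.shape != image.pixels.shape:
        raise ValueError("region mask does not match image")
    initial = initial or DetectionParams()
    lo, hi = tolerance_bounds
    ladder = np.geomspace(lo, hi, ladder_size)
    radii = [initial.rolling_radius] + [r for r in radius_candidates
                                        if r != initial.rolling_radius]
    cache: dict = {}

    # fixed point: the initial parameters already match
    c0 = _count_at(image, region, initial.tolerance, initial.rolling_radius,
                   displacement, cache)
    best = CalibrationResult(initial, c0, user_count,
                             abs(c0 - user_count) <= band * user_count, band)
    if best.converged:
        return best

    for radius in radii:
        for tol in ladder:
            cnt = _count_at(image, region, float(tol), radius, displacement, cache)
            cand = CalibrationResult(
                DetectionParams(tolerance=float(tol), rolling_radius=radius),
                cnt, user_count, abs(cnt - user_count) <= band * user_count, band)
            if cand.relative_error < best.relative_error:
                best = cand
            if cand.converged:
                return cand
    return best
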