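"""The 18 spatial-regularity variables computed from a set of detected
maxima: one ROI-global nearest-neighbor statistic and seventeen
grid-based statistics.

Scale convention: all distances (nearest-neighbor and centroid-to-mass-
center) are expressed in *normalized units* — micrometers divided by the
1.85 um reference pixel pitch — so images of any resolution feed the
built-in classifier on its development scale.

Moment estimators: variance uses denominator n-1; skewness and kurtosis
are the biased (population) standardized third and fourth moments, with
kurtosis non-excess (a normal sample tends to 3).  Within-cell skewness
requires at least 3 points and within-cell kurtosis at least 4;
shorter cells are excluded from the across-cell aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .config import REFERENCE_PIXEL_SIZE_UM
from .imgio import RegionOfInterest
from .maxima import MaximaSet

#: Variance floor substituted when the nearest-neighbor variance is
#: exactly zero (perfectly regular pattern); LOGNNVAR is then
#: ``log(LOGNNVAR_FLOOR)`` and the feature vector is flagged.
LOGNNVAR_FLOOR = float(np.finfo(np.float64).eps)

#: Table-style mnemonic order of the 18 variables.
FEATURE_NAMES = [
    "PCTCELLS_LT2", "PCTCELLS_LT4", "PCTCELLS_LT6", "PCTCELLS_LT8",
    "MPCM", "MPCVAR", "MPCSKEW", "TOTMAX",
    "DISTM", "DISTVAR", "DISTSKEW",
    "KURTM", "KURTVAR", "KURTSKEW",
    "SKEWM", "SKEWVAR", "SKEWSKEW",
    "LOGNNVAR",
]


@dataclass
class GridSpec:
    """Axis-aligned square grid cells fully contained in a ROI.

    ``cells`` holds the top-left corner (x0, y0) of each cell; the grid
    lattice is anchored at the top-left corner of the ROI bounding box.
    """

    cell_size: int
    cells: np.ndarray  # (n, 2) int array of (x0, y0)

    @property
    def n_cells(self) -> int:
        return len(self.cells)


@dataclass
class CellStats:
    """Per-cell point statistics.

    ``dist`` is the distance (normalized units) from the cell's
    geometric centroid to the unweighted mean position of its maxima
    (on a single-pixel maxima image every point carries equal weight,
    so the brightness-weighted center of mass is the plain mean);
    ``skew``/``kurt`` are standardized moments of the within-cell
    point-to-centroid distance distribution, NaN when too few points.
    """

    n_maxima: int
    dist: float
    skew: float
    kurt: float


@dataclass
class FeatureVector18:
    """The 18 regularity variables for one image."""

    pct_cells_lt2: float
    pct_cells_lt4: float
    pct_cells_lt6: float
    pct_cells_lt8: float
    mpc_mean: float
    mpc_var: float
    mpc_skew: float
    totmax: float
    dist_mean: float
    dist_var: float
    dist_skew: float
    kurt_mean: float
    kurt_var: float
    kurt_skew: float
    skew_mean: float
    skew_var: float
    skew_skew: float
    lognnvar: float
    lognnvar_floored: bool = field(default=False)

    def as_series(self) -> pd.Series:
        """The 18 variables as a Series with the mnemonic names."""
        vals = [getattr(self, f.name) for f in fields(self)[:18]]
        return pd.Series(vals, index=FEATURE_NAMES, dtype=float)


@dataclass
class ModelFeatures:
    """The three classifier inputs projected out of the 18-vector."""

    distm: float
    distskew: float
    lognnvar: float
    lognnvar_floored: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.distm, self.distskew, self.lognnvar])


def _skewness(x: np.ndarray) -> float:
    """Population (biased) standardized third moment."""
    x = np.asarray(x, dtype=float)
    m = x.mean()
    s2 = ((x - m) ** 2).mean()
    if s2 == 0:
        return 0.0
    return float(((x - m) ** 3).mean() / s2 ** 1.5)


def _kurtosis(x: np.ndarray) -> float:
    """Population (biased) standardized fourth moment, non-excess."""
    x = np.asarray(x, dtype=float)
    m = x.mean()
    s2 = ((x - m) ** 2).mean()
    if s2 == 0:
        return 0.0
    return float(((x - m) ** 4).mean() / s2 ** 2)


def _variance(x: np.ndarray) -> float:
    """Sample variance (denominator n-1); 0 for n < 2."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        return 0.0
    return float(x.var(ddof=1))


def make_grid(roi: RegionOfInterest, cell_size: int) -> GridSpec:
    """All lattice squares of side ``cell_size`` fully inside the ROI.

    The lattice is anchored at the top-left corner of the ROI bounding
    box; squares overlapping the ROI edge are discarded, mirroring the
    exclusion of partially covered border regions.
    """
    if cell_size < 2:
        raise ValueError("cell_size must be >= 2")
    x0, y0, x1, y1 = roi.bbox
    cells = []
    for cy in range(y0, y1 - cell_size + 1, cell_size):
        for cx in range(x0, x1 - cell_size + 1, cell_size):
            if roi.mask[cy:cy + cell_size, cx:cx + cell_size].all():
                cells.append((cx, cy))
    if not cells:
        raise ValueError(
            f"no {cell_size}x{cell_size} cell fits inside the ROI "
            f"(bounding box {x1 - x0}x{y1 - y0})"
        )
    return GridSpec(cell_size=cell_size, cells=np.asarray(cells, dtype=int))


def nearest_neighbor_distances(maxima: MaximaSet,
                               pixel_size: float = REFERENCE_PIXEL_SIZE_UM) -> np.ndarray:
    """Per-point distance to the closest other point, in normalized units.

    Pixel distances are converted to micrometers via ``pixel_size`` and
    divided by the 1.85 um reference pitch.
    """
    pts = maxima.points
    if len(pts) < 2:
        raise ValueError("need at least 2 maxima for nearest-neighbor distances")
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=2)
    scale = pixel_size / REFERENCE_PIXEL_SIZE_UM
    return d[:, 1] * scale


def cell_statistics(maxima: MaximaSet, grid: GridSpec,
                    pixel_size: float = REFERENCE_PIXEL_SIZE_UM) -> list[CellStats]:
    """Per-cell count, centroid-to-mass-center distance and moments.

    A point (x, y) belongs to the cell with ``x0 <= x < x0 + cell_size``
    and likewise in y.  Distances are in normalized units.
    """
    cs = grid.cell_size
    scale = pixel_size / REFERENCE_PIXEL_SIZE_UM
    out = []
    pts = maxima.points
    for cx, cy in grid.cells:
        if len(pts):
            sel = (pts[:, 0] >= cx) & (pts[:, 0] < cx + cs) & \
                  (pts[:, 1] >= cy) & (pts[:, 1] < cy + cs)
            cell_pts = pts[sel]
        else:
            cell_pts = pts
        n = len(cell_pts)
        if n == 0:
            out.append(CellStats(0, float("nan"), float("nan"), float("nan")))
            continue
        centroid = np.array([cx + (cs - 1) / 2.0, cy + (cs - 1) / 2.0])
        mass_center = cell_pts.mean(axis=0)
        dist = float(np.linalg.norm(mass_center - centroid)) * scale
        radii = np.linalg.norm(cell_pts - centroid, axis=1) * scale
        skew = _skewness(radii) if n >= 3 else float("nan")
        kurt = _kurtosis(radii) if n >= 4 else float("nan")
        out.append(CellStats(n, dist, skew, kurt))
    return out


def extract_features(maxima: MaximaSet, grid: GridSpec,
                     pixel_size: float = REFERENCE_PIXEL_SIZE_UM) -> FeatureVector18:
    """Compute the full 18-variable regularity vector.

    TOTMAX is the total maxima count in the ROI, not only those falling
    inside complete grid cells.  Cells with no maxima enter the
    occupancy percentages and the maxima-per-cell statistics (as zero
    counts) but are excluded from the distance/skewness/kurtosis
    aggregation.
    """
    if len(maxima) < 2:
        raise ValueError("need at least 2 maxima to extract features")
    stats = cell_statistics(maxima, grid, pixel_size)
    counts = np.array([s.n_maxima for s in stats], dtype=float)
    n_cells = len(counts)

    pct = {t: 100.0 * (counts < t).sum() / n_cells for t in (2, 4, 6, 8)}

    dists = np.array([s.dist for s in stats if s.n_maxima >= 1])
    skews = np.array([s.skew for s in stats if s.n_maxima >= 3])
    kurts = np.array([s.kurt for s in stats if s.n_maxima >= 4])

    def agg(x: np.ndarray) -> tuple[float, float, float]:
        if len(x) == 0:
            return float("nan"), float("nan"), float("nan")
        return float(x.mean()), _variance(x), _skewness(x)

    dist_m, dist_v, dist_s = agg(dists)
    kurt_m, kurt_v, kurt_s = agg(kurts)
    skew_m, skew_v, skew_s = agg(skews)

    nn = nearest_neighbor_distances(maxima, pixel_size)
    nn_var = _variance(nn)
    floored = nn_var == 0.0
    lognnvar = float(np.log(nn_var if not floored else LOGNNVAR_FLOOR))

    return FeatureVector18(
        pct_cells_lt2=pct[2], pct_cells_lt4=pct[4],
        pct_cells_lt6=pct[6], pct_cells_lt8=pct[8],
        mpc_mean=float(counts.mean()), mpc_var=_variance(counts),
        mpc_skew=_skewness(counts), totmax=float(len(maxima)),
        dist_mean=dist_m, dist_var=dist_v, dist_skew=dist_s,
        kurt_mean=kurt_m, kurt_var=kurt_v, kurt_skew=kurt_s,
        skew_mean=skew_m, skew_var=skew_v, skew_skew=skew_s,
        lognnvar=lognnvar, lognnvar_floored=floored,
    )


def model_features(fv: FeatureVector18) -> ModelFeatures:
    """Project the three classifier variables out of the 18-vector."""
    return ModelFeatures(
        distm=fv.dist_mean, distskew=fv.dist_skew, lognnvar=fv.lognnvar,
        lognnvar_floored=fv.lognnvar_floored,
    )
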