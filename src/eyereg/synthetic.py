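"""Synthetic eye-surface images with ground truth.

Ommatidia pack hexagonally, so the generator lays bright Gaussian spots
on a hexagonal lattice clipped to an elliptical footprint (the in-focus
region of a curved eye photographed face-on).  Degeneration is emulated
by three knobs applied on top of the regular lattice: positional jitter
(isotropic Gaussian), spot dropout (independent deletion), and spot
broadening — together they reproduce the progressive loss of reflection
regularity of a rough-eye phenotype without modelling optics.  A linear
background gradient and additive Gaussian pixel noise stand in for
uneven illumination and sensor noise.

All randomness flows from the single ``seed`` of the spec, via
``numpy.random.default_rng``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import REFERENCE_PIXEL_SIZE_UM
from .imgio import GrayImage, RegionOfInterest
from .features import FEATURE_NAMES, extract_features, make_grid
from .maxima import MaximaSet, find_maxima
from .preprocess import PreprocessParams, preprocess


@dataclass
class SyntheticEyeSpec:
    """Parameters of one synthetic eye image.

    Defaults depict a healthy eye at the 1.85 um/pixel reference
    resolution: a 256x256 frame, 22 px lattice pitch (about 40 um
    between reflection centers), 3 px spot width, full contrast, a
    mild illumination gradient and moderate sensor noise.
    """

    width: int = 256
    height: int = 256
    lattice_spacing: float = 22.0
    jitter_sd: float = 0.0
    dropout: float = 0.0
    spot_sigma: float = 3.0
    spot_amplitude: float = 180.0
    background_gradient: float = 30.0
    noise_sd: float = 4.0
    seed: int = 0
    pixel_size: float = REFERENCE_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout <= 1.0):
            raise ValueError("dropout must lie in [0, 1]")
        for name in ("lattice_spacing", "spot_sigma", "spot_amplitude"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.jitter_sd < 0 or self.noise_sd < 0:
            raise ValueError("jitter_sd and noise_sd must be non-negative")


@dataclass
class SyntheticGroundTruth:
    """Retained spot centers of a generated image."""

    true_points: np.ndarray  # (n, 2) float (x, y)

    @property
    def n_spots(self) -> int:
        return len(self.true_points)


def hex_lattice_points(spec: SyntheticEyeSpec) -> np.ndarray:
    """Hexagonal lattice nodes inside the elliptical eye footprint.

    The ellipse is centred in the frame with semi-axes 0.45*width and
    0.42*height; rows are spaced ``spacing * sqrt(3)/2`` with alternate
    rows offset by half a pitch.
    """
    s = spec.lattice_spacing
    row_h = s * np.sqrt(3.0) / 2.0
    cx, cy = spec.width / 2.0, spec.height / 2.0
    ax, ay = 0.45 * spec.width, 0.42 * spec.height
    pts = []
    n_rows = int(spec.height / row_h) + 2
    n_cols = int(spec.width / s) + 2
    for i in range(-n_rows, n_rows + 1):
        y = cy + i * row_h
        offset = (i % 2) * s / 2.0
        for j in range(-n_cols, n_cols + 1):
            x = cx + j * s + offset
            if ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 <= 1.0:
                pts.append((x, y))
    return np.asarray(pts, dtype=float).reshape(-1, 2)


def eye_footprint_roi(spec: SyntheticEyeSpec) -> RegionOfInterest:
    """Elliptical ROI polygon matching the generator footprint."""
    cx, cy = spec.width / 2.0, spec.height / 2.0
    ax, ay = 0.45 * spec.width, 0.42 * spec.height
    t = np.linspace(0.0, 2.0 * np.pi, 64, endpoint=False)
    verts = np.column_stack([cx + ax * np.cos(t), cy + ay * np.sin(t)])
    verts = np.clip(verts, 0, [spec.width, spec.height])
    from .imgio import rasterize_polygon

    mask = rasterize_polygon(verts, (spec.height, spec.width))
    return RegionOfInterest(mask, polygon=verts)


def generate_eye_image(spec: SyntheticEyeSpec) -> tuple[GrayImage, SyntheticGroundTruth]:
    """Render one synthetic eye image with its ground-truth spot centers.

    Lattice nodes are independently dropped with probability
    ``dropout``, jittered by N(0, jitter_sd^2) per axis, then rendered
    as Gaussian spots of width ``spot_sigma`` and height
    ``spot_amplitude`` over a linear horizontal background gradient of
    total span ``background_gradient``; Gaussian pixel noise of sd
    ``noise_sd`` is added and the image clipped to [0, 255].
    Deterministic given ``spec.seed``.
    """
    if spec.lattice_spacing < 2.0 * spec.spot_sigma:
        warnings.warn("lattice spacing below 2*spot_sigma: spots merge and "
                      "detection of individual reflections is not guaranteed")
    rng = np.random.default_rng(spec.seed)
    pts = hex_lattice_points(spec)
    if spec.dropout > 0:
        keep = rng.random(len(pts)) >= spec.dropout
        pts = pts[keep]
    if spec.jitter_sd > 0:
        pts = pts + rng.normal(0.0, spec.jitter_sd, size=pts.shape)

    yy, xx = np.mgrid[0:spec.height, 0:spec.width].astype(float)
    img = np.zeros((spec.height, spec.width), dtype=float)
    if spec.background_gradient:
        img += spec.background_gradient * xx / max(1, spec.width - 1)
    sig2 = 2.0 * spec.spot_sigma ** 2
    half = int(np.ceil(4 * spec.spot_sigma))
    for x, y in pts:
        x0, y0 = int(round(x)), int(round(y))
        xs = slice(max(0, x0 - half), min(spec.width, x0 + half + 1))
        ys = slice(max(0, y0 - half), min(spec.height, y0 + half + 1))
        img[ys, xs] += spec.spot_amplitude * np.exp(
            -((xx[ys, xs] - x) ** 2 + (yy[ys, xs] - y) ** 2) / sig2)
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 255.0)
    return (GrayImage(img, pixel_size=spec.pixel_size),
            SyntheticGroundTruth(true_points=pts))


#: Study conditions spanning the regularity gradient, from wild-type-like
#: (class 0) to fully degenerate (class 4): increasing positional jitter,
#: then dropout and spot broadening.
DEFAULT_CLASS_SPECS: list[SyntheticEyeSpec] = [
    SyntheticEyeSpec(jitter_sd=0.5, dropout=0.0),
    SyntheticEyeSpec(jitter_sd=2.0, dropout=0.0),
    SyntheticEyeSpec(jitter_sd=4.0, dropout=0.05),
    SyntheticEyeSpec(jitter_sd=7.0, dropout=0.15, spot_sigma=4.0),
    SyntheticEyeSpec(jitter_sd=10.0, dropout=0.5, spot_sigma=5.0),
]


def features_for_image(image: GrayImage, roi: RegionOfInterest,
                       tolerance: float = 12.0,
                       preprocess_params: PreprocessParams | None = None,
                       cell_size: int = 50) -> pd.Series:
    """Full image -> 18-feature pipeline for one image/ROI pair."""
    pp = preprocess_params or PreprocessParams(rolling_radius=25)
    processed = preprocess(image, pp)
    maxima = find_maxima(processed, roi, tolerance)
    grid = make_grid(roi, cell_size)
    fv = extract_features(maxima, grid, image.pixel_size)
    return fv.as_series()


def generate_feature_table(n_per_class: int,
                           class_specs: list[SyntheticEyeSpec] | None = None,
                           seed: int = 0,
                           tolerance: float = 12.0,
                           cell_size: int = 50):
    """Run the full pipeline on generated images to build a labelled table.

    Returns a :class:`~eyereg.model.TrainingTable` with one row per
    image, 18 feature columns, and the generating class index as both
    group label and class label.
    """
    from .model import TrainingTable

    specs = class_specs if class_specs is not None else DEFAULT_CLASS_SPECS
    if len(specs) < 2:
        raise ValueError("need at least 2 class specs")
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for ci, base in enumerate(specs):
        for _ in range(n_per_class):
            img_seed = int(rng.integers(0, 2**31 - 1))
            spec = replace(base, seed=img_seed)
            image, _gt = generate_eye_image(spec)
            roi = eye_footprint_roi(spec)
            rows.append(features_for_image(image, roi, tolerance,
                                           cell_size=cell_size))
            labels.append(ci)
    data = pd.DataFrame(rows).reset_index(drop=True)[FEATURE_NAMES]
    return TrainingTable(data=data,
                         group=pd.Series(labels, name="group"),
                         cls=pd.Series(labels, name="class"))


#: Feature-space simulation design for training-path validation: one
#: Gaussian component per degeneration class, centered in the region of
#: (DISTM, DISTSKEW, LOGNNVAR) space where that class dominates under
#: the built-in coefficients, with spreads wide enough to cover every
#: between-class boundary and extra weight on the diffuse classes 3/4.
FEATURE_SIM_CENTERS = np.array([
    [2.0, 0.6, -1.0],
    [3.5, 0.5, 1.0],
    [5.0, 0.4, 1.5],
    [7.0, -0.2, 2.0],
    [8.0, 0.8, 3.0],
])
FEATURE_SIM_SDS = np.array([2.5, 0.7, 3.0])
FEATURE_SIM_WEIGHTS = np.array([0.15, 0.10, 0.15, 0.30, 0.30])


def simulate_model_features(n: int, seed: int = 0, params=None):
    """Draw feature triples and class labels from the classifier itself.

    Features come from the stratified Gaussian mixture above; labels
    are sampled from the class probabilities the (built-in by default)
    coefficients assign to each triple.  Returns a
    :class:`~eyereg.model.TrainingTable` whose non-model feature
    columns are zero-filled.
    """
    from .model import TrainingTable, builtin_results, RegularityResults

    results = (RegularityResults.from_parameters(params) if params is not None
               else builtin_results())
    rng = np.random.default_rng(seed)
    comp = rng.choice(5, size=n, p=FEATURE_SIM_WEIGHTS)
    X = FEATURE_SIM_CENTERS[comp] + rng.normal(0.0, 1.0, (n, 3)) * FEATURE_SIM_SDS
    P = results.predict_proba(X)
    u = rng.random(n)
    y = (u[:, None] > np.cumsum(P, axis=1)).sum(axis=1)
    data = pd.DataFrame(0.0, index=range(n), columns=FEATURE_NAMES)
    data["DISTM"], data["DISTSKEW"], data["LOGNNVAR"] = X[:, 0], X[:, 1], X[:, 2]
    return TrainingTable(data=data, group=pd.Series(comp, name="group"),
                         cls=pd.Series(y, name="class"))


def maxima_from_ground_truth(gt: SyntheticGroundTruth,
                             roi: RegionOfInterest | None = None) -> MaximaSet:
    """Ground-truth spot centers as a MaximaSet (rounded to pixels)."""
    pts = np.round(gt.true_points).astype(float)
    pts = np.unique(pts, axis=0)
    if roi is not None:
        h, w = roi.mask.shape
        ok = (pts[:, 0] >= 0) & (pts[:, 0] < w) & (pts[:, 1] >= 0) & (pts[:, 1] < h)
        pts = pts[ok]
        pts = pts[roi.mask[pts[:, 1].astype(int), pts[:, 0].astype(int)]]
    return MaximaSet(pts, roi=roi)
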