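"""Image, region-of-interest and table I/O.

Conventions used throughout the package:

* Pixel coordinates are 0-based ``(x, y)`` = (column, row), origin at the
  top-left corner of the image.
* Images are held as float64 arrays on the 8-bit scale ``[0, 255]``;
  conversion back to integer types happens only on export.
* Polygons are rasterized with an even-odd (ray-casting) rule evaluated
  at pixel centers, with a half-open boundary convention: a pixel center
  lying exactly on the left/bottom boundary of the polygon is inside,
  one on the right/top boundary is outside.  This makes areas exactly
  reproducible.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .config import REFERENCE_PIXEL_SIZE_UM

#: ITU-R BT.709 luminance weights used for RGB -> grayscale conversion.
LUMINANCE_WEIGHTS = (0.2125, 0.7154, 0.0721)


@dataclass
class GrayImage:
    """A 2-D grayscale image on the 8-bit intensity scale.

    Parameters
    ----------
    pixels
        2-D float array, values in ``[0, 255]``.
    pixel_size
        Physical pixel pitch in um/pixel; must be positive.
    """

    pixels: np.ndarray
    pixel_size: float = REFERENCE_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class RegionOfInterest:
    """A region of interest as a boolean mask over the image frame.

    ``polygon`` retains the defining vertices when the ROI came from a
    polygon; it is ``None`` for mask-native ROIs.
    """

    mask: np.ndarray
    polygon: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.area == 0:
            raise ValueError("ROI is empty (zero area)")

    @property
    def area(self) -> int:
        """Number of pixels inside the ROI."""
        return int(self.mask.sum())

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        """Bounding box ``(x0, y0, x1, y1)`` (half-open) of the mask."""
        rows = np.flatnonzero(self.mask.any(axis=1))
        cols = np.flatnonzero(self.mask.any(axis=0))
        return int(cols[0]), int(rows[0]), int(cols[-1]) + 1, int(rows[-1]) + 1


def _to_eight_bit(arr: np.ndarray) -> np.ndarray:
    """Convert an array of any supported dtype to the [0, 255] float scale."""
    if arr.dtype == np.uint8:
        return arr.astype(np.float64)
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) * (255.0 / 65535.0)
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return (arr.astype(np.float64) - info.min) * (255.0 / (info.max - info.min))
    # float input: assume 8-bit scale unless it looks like [0, 1]
    arr = arr.astype(np.float64)
    if arr.size and arr.max() <= 1.0 and arr.min() >= 0.0:
        return arr * 255.0
    return np.clip(arr, 0.0, 255.0)


def load_image(path: str | Path, pixel_size: float = REFERENCE_PIXEL_SIZE_UM) -> GrayImage:
    """Read a TIFF or PNG image as an 8-bit-scale grayscale :class:`GrayImage`.

    RGB(A) images are converted with the BT.709 luminance weights
    (0.2125 R + 0.7154 G + 0.0721 B); 16-bit images are linearly
    rescaled to [0, 255].
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if path.suffix.lower() in {".tif", ".tiff"}:
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise IOError(f"cannot read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[2] not in (3, 4):
            raise IOError(f"unsupported channel layout {arr.shape} in {path}")
        rgb = _to_eight_bit(arr[..., :3])
        w = np.asarray(LUMINANCE_WEIGHTS)
        arr = rgb @ w
    elif arr.ndim == 2:
        arr = _to_eight_bit(arr)
    else:
        raise IOError(f"unsupported image dimensionality {arr.ndim} in {path}")
    if arr.size == 0:
        raise ValueError(f"zero-size image: {path}")
    return GrayImage(arr, pixel_size=pixel_size)


def save_image(path: str | Path, image: GrayImage) -> None:
    """Write a :class:`GrayImage` as an 8-bit TIFF or PNG (by extension)."""
    path = Path(path)
    data = np.clip(np.rint(image.pixels), 0, 255).astype(np.uint8)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, data)
    else:
        iio.imwrite(path, data)


def rasterize_polygon(vertices: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a polygon to a boolean mask by even-odd ray casting.

    A pixel ``(x, y)`` is inside when a horizontal ray from its center
    towards +x crosses the polygon boundary an odd number of times; the
    half-open crossing rule ``(y1 > y) != (y2 > y)`` makes boundary
    handling deterministic (left/bottom edges in, right/top edges out).
    """
    verts = np.asarray(vertices, dtype=np.float64)
    if verts.ndim != 2 or verts.shape[0] < 3 or verts.shape[1] != 2:
        raise ValueError("polygon needs at least 3 (x, y) vertices")
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    px = xs.ravel().astype(np.float64)
    py = ys.ravel().astype(np.float64)
    inside = np.zeros(px.shape, dtype=bool)
    n = verts.shape[0]
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        crosses = (y1 > py) != (y2 > py)
        if not crosses.any():
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            x_at = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (px < x_at)
    return inside.reshape(h, w)


def roi_from_polygon(vertices, image: GrayImage) -> RegionOfInterest:
    """Build a ROI from polygon vertices, validating against image bounds."""
    verts = np.asarray(vertices, dtype=np.float64)
    if verts.size == 0:
        raise ValueError("empty vertex list")
    if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
        raise ValueError("polygon needs at least 3 (x, y) vertices")
    if (verts[:, 0] < 0).any() or (verts[:, 0] > image.width).any() or \
       (verts[:, 1] < 0).any() or (verts[:, 1] > image.height).any():
        raise ValueError("polygon vertices outside image bounds")
    mask = rasterize_polygon(verts, (image.height, image.width))
    return RegionOfInterest(mask, polygon=verts)


def _read_imagej_roi(path: Path) -> np.ndarray:
    """Read polygon vertices from an ImageJ .roi record (polygon types only)."""
    data = path.read_bytes()
    if data[:4] != b"Iout":
        raise IOError(f"{path} is not an ImageJ ROI file")
    roi_type = data[6]
    if roi_type not in (0, 2, 3):  # polygon, polyline treated as closed, freehand
        raise IOError(f"unsupported ImageJ ROI type {roi_type} in {path}")
    top, left, _bottom, _right, n = struct.unpack(">hhhhh", data[8:18])
    xs = struct.unpack(f">{n}h", data[64:64 + 2 * n])
    ys = struct.unpack(f">{n}h", data[64 + 2 * n:64 + 4 * n])
    return np.column_stack([np.asarray(xs) + left, np.asarray(ys) + top]).astype(float)


def write_imagej_roi(path: str | Path, vertices) -> None:
    """Write polygon vertices as a minimal ImageJ .roi polygon record."""
    verts = np.asarray(vertices)
    left, top = int(verts[:, 0].min()), int(verts[:, 1].min())
    right, bottom = int(verts[:, 0].max()), int(verts[:, 1].max())
    n = verts.shape[0]
    header = bytearray(64)
    header[:4] = b"Iout"
    struct.pack_into(">h", header, 4, 227)  # version
    header[6] = 0  # polygon
    struct.pack_into(">hhhhh", header, 8, top, left, bottom, right, n)
    body = struct.pack(f">{n}h", *(int(v) - left for v in verts[:, 0]))
    body += struct.pack(f">{n}h", *(int(v) - top for v in verts[:, 1]))
    Path(path).write_bytes(bytes(header) + body)


def load_roi(path: str | Path, image: GrayImage) -> RegionOfInterest:
    """Load a ROI (JSON polygon or ImageJ .roi) and rasterize it.

    JSON format: ``{"vertices": [[x, y], ...]}``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing ROI file: {path}")
    if path.suffix.lower() == ".roi":
        verts = _read_imagej_roi(path)
    else:
        payload = json.loads(path.read_text())
        verts = np.asarray(payload["vertices"], dtype=np.float64)
    if verts.size == 0:
        raise ValueError(f"empty vertex list in {path}")
    return roi_from_polygon(verts, image)


def save_roi(path: str | Path, roi: RegionOfInterest) -> None:
    """Write a polygon ROI as JSON (vertices required)."""
    if roi.polygon is None:
        raise ValueError("ROI has no polygon; save the mask as an image instead")
    Path(path).write_text(
        json.dumps({"vertices": np.asarray(roi.polygon).tolist()}, indent=1)
    )


def find_roi_for_image(image_path: str | Path, roi_dir: str | Path) -> Path:
    """Locate the ROI file sharing the image's base filename.

    Looks for ``<stem>.json`` then ``<stem>.roi`` in ``roi_dir``; raises
    a :class:`FileNotFoundError` naming the missing base name otherwise.
    """
    stem = Path(image_path).stem
    roi_dir = Path(roi_dir)
    for ext in (".json", ".roi"):
        candidate = roi_dir / f"{stem}{ext}"
        if candidate.exists():
            return candidate
    raise FileNotFoundError(
        f"no ROI named '{stem}.json' or '{stem}.roi' in {roi_dir} "
        f"for image {Path(image_path).name}"
    )
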