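"""Image normalization: rolling-ball background subtraction and the
surface-like contrast filter.

Both operations work in floating point on the 8-bit intensity scale and
preserve image dimensions and pixel calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.restoration import rolling_ball

from .config import DEFAULT_DISPLACEMENT_PX, DEFAULT_ROLLING_RADIUS_PX
from .imgio import GrayImage


@dataclass
class PreprocessParams:
    """Tunable preprocessing parameters.

    ``rolling_radius``: ball radius (px) of the background estimate;
    features narrower than the ball survive subtraction, slow trends do
    not.  ``displacement``: horizontal shift (px) of the inverted copy
    in the surface-like filter.
    """

    rolling_radius: int = DEFAULT_ROLLING_RADIUS_PX
    displacement: int = DEFAULT_DISPLACEMENT_PX

    def __post_init__(self) -> None:
        if self.rolling_radius < 1:
            raise ValueError("rolling_radius must be >= 1")
        if self.displacement < 0:
            raise ValueError("displacement must be >= 0")


def subtract_background(image: GrayImage, rolling_radius: int = DEFAULT_ROLLING_RADIUS_PX) -> GrayImage:
    """Remove smooth background by rolling-ball estimation.

    The background is the surface traced by a ball of the given radius
    rolled under the intensity landscape (equivalently a grayscale
    opening with a ball-shaped structuring element); it is subtracted
    and the result clipped to [0, 255].
    """
    if rolling_radius < 1:
        raise ValueError("rolling_radius must be >= 1")
    if rolling_radius > max(image.height, image.width):
        raise ValueError(
            f"rolling_radius {rolling_radius} exceeds both image dimensions "
            f"({image.width}x{image.height})"
        )
    background = rolling_ball(image.pixels, radius=rolling_radius)
    residual = np.clip(image.pixels - background, 0.0, 255.0)
    return GrayImage(residual, pixel_size=image.pixel_size)


def surface_filter(image: GrayImage, displacement: int = DEFAULT_DISPLACEMENT_PX) -> GrayImage:
    """Average the image with a horizontally shifted, inverted copy.

    ``out(x, y) = (img(x, y) + shifted(255 - img)(x, y)) / 2`` where the
    inverted copy is displaced by ``displacement`` pixels along +x with
    edge replication, so no column is undefined.  The output is centred
    on 127.5: flat regions map to 127.5 exactly, intensity edges become
    symmetric bright/dark ridges, which boosts the contrast of spot-like
    reflections irrespective of the local illumination level.
    """
    if displacement < 0:
        raise ValueError("displacement must be >= 0")
    if displacement >= image.width:
        raise ValueError("displacement must be smaller than the image width")
    inverted = 255.0 - image.pixels
    if displacement == 0:
        shifted = inverted
    else:
        shifted = np.empty_like(inverted)
        shifted[:, displacement:] = inverted[:, :-displacement]
        shifted[:, :displacement] = inverted[:, [0]]
    return GrayImage((image.pixels + shifted) / 2.0, pixel_size=image.pixel_size)


def preprocess(image: GrayImage, params: PreprocessParams | None = None) -> GrayImage:
    """Full normalization: background subtraction then surface filter."""
    params = params or PreprocessParams()
    return surface_filter(
        subtract_background(image, params.rolling_radius), params.displacement
    )
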