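"""Calibration constants and pipeline defaults.

All pixel-based defaults are stated at the reference resolution of
1.85 um/pixel, the resolution at which the built-in classifier was
developed.  Images acquired at other resolutions are rescaled onto this
reference scale at the feature stage (distances are expressed in units
of the reference pixel pitch), so the built-in coefficients remain
applicable.
"""

#: Reference pixel pitch (um per pixel) of the model-development images.
REFERENCE_PIXEL_SIZE_UM = 1.85

#: Default grid-cell side (pixels at reference resolution).
DEFAULT_CELL_SIZE_PX = 50

#: Default rolling-ball radius (pixels) for background subtraction.
DEFAULT_ROLLING_RADIUS_PX = 50

#: Default horizontal displacement (pixels) of the surface-like filter.
DEFAULT_DISPLACEMENT_PX = 1

#: Default noise tolerance (prominence threshold, 8-bit intensity units)
#: for maxima detection.  After background subtraction and the
#: surface-like filter, well-resolved ommatidial reflections retain a
#: prominence of roughly 10-30 gray levels, so 12 separates them from
#: sensor noise; recalibrate per imaging setup with the calibration op.
DEFAULT_TOLERANCE = 12.0


def cell_size_for_pixel_size(pixel_size: float, base: int = DEFAULT_CELL_SIZE_PX) -> int:
    """Grid-cell side in pixels for an image at ``pixel_size`` um/px.

    Scales the reference-resolution default so the physical cell extent
    (about 92.5 um) is preserved across resolutions.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    return max(2, round(base * REFERENCE_PIXEL_SIZE_UM / pixel_size))
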