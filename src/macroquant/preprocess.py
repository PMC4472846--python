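"""Z-collapse and background removal.

The processing order is fixed: maximum-intensity projection, linear 8-bit
conversion, rolling-ball background subtraction. The rolling ball is the
exact grayscale opening with the ball height profile, not the
shrink-and-interpolate approximation found in some interactive tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi

from .errors import ConfigurationError, InputError
from .io import ChannelImage


@dataclass
class ProjectedImage:
    """A projected, 8-bit, optionally background-corrected channel image.

    ``provenance`` records every parameter that affected the pixels so the
    run manifest can reproduce them.
    """

    pixels: np.ndarray
    pixel_size: float
    role: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.dtype != np.uint8:
            raise InputError("ProjectedImage pixels must be uint8 (0-255)")


def max_project(slices: Sequence[ChannelImage]) -> ChannelImage:
    """Collapse a z-stack by per-pixel maximum over slices."""
    if len(slices) == 0:
        raise InputError("cannot project an empty slice sequence")
    first = slices[0]
    for s in slices[1:]:
        if s.pixels.shape != first.pixels.shape:
            raise InputError(
                f"slice shape mismatch: {s.pixels.shape} vs "
                f"{first.pixels.shape}")
        if s.pixel_size != first.pixel_size:
            raise InputError("slices carry different pixel sizes")
    stack = np.stack([s.pixels for s in slices])
    return ChannelImage(pixels=stack.max(axis=0), pixel_size=first.pixel_size,
                        role=first.role, bit_depth=first.bit_depth)


def to_8bit(image: np.ndarray, mode: str = "source_depth",
            vmin: float | None = None, vmax: float | None = None,
            bit_depth: int | None = None) -> np.ndarray:
    """Linearly map an intensity image to uint8.

    ``fixed_range`` maps [vmin, vmax] -> [0, 255] with clipping; the same
    (vmin, vmax) must be applied to every image of an experiment batch.
    ``source_depth`` uses [0, 2**bit_depth - 1]. Rounding is half-up.
    """
    image = np.asarray(image)
    if mode == "source_depth":
        if bit_depth is None:
            bit_depth = image.dtype.itemsize * 8 if image.dtype.kind == "u" else 8
        vmin, vmax = 0.0, float(2 ** bit_depth - 1)
    elif mode == "fixed_range":
        if vmin is None or vmax is None:
            raise ConfigurationError("fixed_range conversion requires vmin and vmax")
    else:
        raise ConfigurationError(f"unknown conversion mode {mode!r}")
    if vmax <= vmin:
        raise ConfigurationError(
            f"conversion range invalid: max ({vmax}) <= min ({vmin})")
    if mode == "source_depth" and image.dtype == np.uint8:
        return image.copy()
    scaled = (image.astype(np.float64) - vmin) * (255.0 / (vmax - vmin))
    scaled = np.clip(scaled, 0.0, 255.0)
    return np.floor(scaled + 0.5).astype(np.uint8)  # round half-up


def ball_structuring_element(radius_px: int) -> tuple[np.ndarray, np.ndarray]:
    """Footprint and height profile h = sqrt(r^2 - dx^2 - dy^2) of a ball."""
    r = int(radius_px)
    y, x = np.mgrid[-r:r + 1, -r:r + 1]
    d2 = (x * x + y * y).astype(np.float64)
    footprint = d2 <= r * r
    heights = np.zeros_like(d2)
    heights[footprint] = np.sqrt(r * r - d2[footprint])
    return footprint, heights


def rolling_ball_subtract(image: np.ndarray, radius_px: int
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Remove smooth continuous background by the rolling-ball algorithm.

    The background is the grayscale opening of the image with a ball-shaped
    structuring element of the given radius (erosion then dilation by the
    ball height profile); it is everywhere <= the image. The corrected image
    is ``clip(image - background, 0, 255)`` as uint8. Borders are
    reflect-padded by the radius before the opening and cropped after, so no
    spurious dark rim appears at the field edge.

    The radius should exceed the largest object of interest in pixels;
    smaller radii treat large objects as background (contract documented,
    not enforced).

    Returns ``(corrected, background)``.
    """
    radius_px = int(radius_px)
    if radius_px < 1:
        raise ConfigurationError(f"rolling-ball radius must be >= 1, got {radius_px}")
    image = np.asarray(image)
    if image.ndim != 2:
        raise InputError("rolling_ball_subtract expects a 2-D image")
    footprint, heights = ball_structuring_element(radius_px)
    # pad by twice the radius: the central crop is then independent of the
    # filters' own boundary handling
    pad = 2 * radius_px
    padded = np.pad(image.astype(np.float64), pad, mode="reflect")
    eroded = ndi.grey_erosion(padded, footprint=footprint, structure=heights)
    opened = ndi.grey_dilation(eroded, footprint=footprint, structure=heights)
    background = opened[pad:-pad, pad:-pad]
    background = np.minimum(background, image)  # guard float round-off
    corrected = np.clip(image.astype(np.float64) - background, 0, 255)
    return np.floor(corrected + 0.5).astype(np.uint8), background


def default_rolling_ball_radius(pixel_size: float,
                                largest_object_um: float = 5.0) -> int:
    """Auto radius: three times the largest object diameter, in pixels."""
    return int(np.ceil(3.0 * largest_object_um / pixel_size))


def preprocess_channel(slices: Sequence[ChannelImage], *,
                       conversion_mode: str = "source_depth",
                       conversion_min: float | None = None,
                       conversion_max: float | None = None,
                       rolling_ball_radius_px: int | str | None = "auto",
                       ) -> ProjectedImage:
    """Project, convert to 8-bit, and background-subtract one channel.

    ``rolling_ball_radius_px`` may be an integer, ``"auto"`` (three times
    the largest macropinosome diameter in pixels), or ``None`` to skip the
    subtraction.
    """
    projected = max_project(slices)
    img8 = to_8bit(projected.pixels, mode=conversion_mode,
                   vmin=conversion_min, vmax=conversion_max,
                   bit_depth=projected.bit_depth)
    provenance = {
        "n_slices_projected": len(slices),
        "conversion_mode": conversion_mode,
        "conversion_min": conversion_min,
        "conversion_max": conversion_max,
        "rolling_ball_radius_px": None,
    }
    if rolling_ball_radius_px is not None:
        if rolling_ball_radius_px == "auto":
            rolling_ball_radius_px = default_rolling_ball_radius(
                projected.pixel_size)
        img8, _ = rolling_ball_subtract(img8, rolling_ball_radius_px)
        provenance["rolling_ball_radius_px"] = int(rolling_ball_radius_px)
    return ProjectedImage(pixels=img8, pixel_size=projected.pixel_size,
                          role=projected.role, provenance=provenance)
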