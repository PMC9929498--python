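"""Image loading and standardisation into the "marking intensity" convention.

Every downstream measurement operates on an :class:`IntensityImage`: a 2-D
scalar field in [0, 1] in which *high* values correspond to pattern markings
(pigmented regions) and low values to the egg background.  Photographs of
dark markings on a light shell therefore need to be inverted once, here,
so that the threshold sweep always retains markings as foreground.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["IntensityImage", "load_image", "to_marking_intensity", "smooth"]

# Rec. 709 luma weights, the fixed RGB -> luminance convention used throughout.
_LUMA = np.array([0.2126, 0.7152, 0.0722])


@dataclass
class IntensityImage:
    """A normalised 2-D intensity field with an optional region-of-interest.

    Attributes
    ----------
    pixels : ndarray of float, shape (H, W)
        Intensities in [0, 1].  High values = markings once
        :func:`to_marking_intensity` has been applied.
    mask : ndarray of bool, shape (H, W), optional
        Region of interest (e.g. the egg ellipse).  ``None`` means the whole
        frame.  Out-of-mask pixels are treated as background by all
        measurements.
    meta : dict
        Provenance: source path, inversion flag, smoothing scale, whether the
        image was degenerate (constant), and any generator parameters.
    """

    pixels: np.ndarray
    mask: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {self.pixels.shape}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.pixels.shape:
                raise ValueError(
                    f"mask shape {self.mask.shape} != pixels shape {self.pixels.shape}"
                )
            if not self.mask.any():
                raise ValueError("mask excludes every pixel")
        vals = self.in_mask_values()
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite in-mask pixel values")
        if vals.min() < -1e-9 or vals.max() > 1 + 1e-9:
            raise ValueError("in-mask pixel values outside [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def in_mask_values(self) -> np.ndarray:
        if self.mask is None:
            return self.pixels.ravel()
        return self.pixels[self.mask]

    def with_pixels(self, pixels: np.ndarray, **meta) -> "IntensityImage":
        """Copy of this image with new pixel data and updated metadata."""
        return IntensityImage(pixels=pixels, mask=self.mask, meta={**self.meta, **meta})


def _normalize(pixels: np.ndarray, mask: Optional[np.ndarray]) -> tuple[np.ndarray, bool]:
    """Min-max rescale within the mask; constant images map to all-zeros."""
    pixels = np.asarray(pixels, dtype=float)
    vals = pixels if mask is None else pixels[mask]
    lo, hi = float(vals.min()), float(vals.max())
    if hi - lo <= 0:
        return np.zeros_like(pixels), True
    out = np.clip((pixels - lo) / (hi - lo), 0.0, 1.0)
    if mask is not None:
        out = np.where(mask, out, 0.0)
    return out, False


def load_image(path: str | Path, roi: str | Path | None = None) -> IntensityImage:
    """Read a PNG/TIFF image and min-max normalise it to [0, 1] within the ROI.

    RGB(A) input is collapsed to luminance with fixed Rec. 709 weights; the
    weighting only rescales contrast and does not move marking boundaries.
    A constant image normalises to all-zeros and is flagged ``degenerate``
    in ``meta`` rather than rejected, so batch runs do not abort.
    """
    path = Path(path)
    raw = np.asarray(iio.imread(path)).astype(float)
    if raw.ndim == 3:
        raw = raw[..., :3] @ _LUMA
    elif raw.ndim != 2:
        raise ValueError(f"unsupported image dimensionality {raw.ndim} in {path}")

    mask = None
    if roi is not None:
        roi = Path(roi)
        m = np.asarray(iio.imread(roi))
        if m.ndim == 3:
            m = m[..., :3].max(axis=-1)
        if m.shape != raw.shape:
            raise ValueError(f"ROI shape {m.shape} does not match image shape {raw.shape}")
        mask = m > 0

    pixels, degenerate = _normalize(raw, mask)
    meta = {
        "source": str(path),
        "roi": str(roi) if roi is not None else None,
        "inverted": False,
        "sigma": 0.0,
        "degenerate": degenerate,
    }
    return IntensityImage(pixels=pixels, mask=mask, meta=meta)


def to_marking_intensity(img: IntensityImage, invert: bool = True) -> IntensityImage:
    """Flip intensity so that markings are the high-intensity regions.

    Photographs typically show dark pigment on a light shell; inverting once
    (``pixels <- 1 - pixels``) puts them in the marking-intensity convention.
    Inversion is an involution; the ``inverted`` meta flag records parity.
    """
    if not invert:
        return img
    out = 1.0 - img.pixels
    if img.mask is not None:
        out = np.where(img.mask, out, 0.0)
    return img.with_pixels(out, inverted=not img.meta.get("inverted", False))


def smooth(img: IntensityImage, sigma: float = 2.0) -> IntensityImage:
    """Gaussian blur (reflect boundary) to suppress pixel noise before the sweep.

    ``sigma`` is in pixels; 0 is the identity.  Reflection at the border
    avoids the dark frame a zero-padded blur would create, which would
    register as spurious perimeter at sweep time.  Output is re-clipped to
    [0, 1].
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return img
    out = gaussian_filter(img.pixels, sigma=sigma, mode="reflect")
    out = np.clip(out, 0.0, 1.0)
    if img.mask is not None:
        out = np.where(img.mask, out, 0.0)
    return img.with_pixels(out, sigma=float(sigma))
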