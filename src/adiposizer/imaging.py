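"""Slide image I/O and grayscale conversion.

The whole pipeline operates on 8-bit grayscale rasters carried together
with a physical pixel size (µm per pixel edge).  Colour slides are reduced
to grayscale before any thresholding; the physical calibration is either
read from the TIFF resolution tags or supplied explicitly by the caller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "CalibratedImage",
    "CalibrationError",
    "load_slide",
    "to_8bit_gray",
    "write_slide",
]

#: ITU-R BT.601 luma weights, offered as an alternative to the plain
#: channel mean for sensitivity analysis.
REC601_WEIGHTS = (0.299, 0.587, 0.114)


class CalibrationError(ValueError):
    """Raised when no µm/pixel calibration can be established for an image."""


@dataclass(frozen=True)
class CalibratedImage:
    """An 8-bit grayscale raster with a physical pixel size.

    Attributes
    ----------
    pixels
        2-D ``uint8`` array of intensities in [0, 255].
    pixel_size
        Physical edge length of one pixel in µm; strictly positive.
    source_id
        Provenance string (file path, or a generator seed tag for
        synthetic images).
    """

    pixels: np.ndarray
    pixel_size: float
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"pixels must be a non-empty 2-D raster, got shape {px.shape}")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)
        if not (math.isfinite(self.pixel_size) and self.pixel_size > 0):
            raise ValueError(f"pixel_size must be positive and finite, got {self.pixel_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


def to_8bit_gray(pixels: np.ndarray, weights: tuple[float, float, float] | None = None) -> np.ndarray:
    """Reduce an RGB raster to 8-bit grayscale; pass grayscale through.

    The default conversion is the unweighted channel mean
    ``round((R + G + B) / 3)`` with half-up rounding, clipped to [0, 255].
    Pass ``weights`` (e.g. :data:`REC601_WEIGHTS`) for a weighted luma
    instead.  Already-grayscale input is returned unchanged (idempotent).
    """
    arr = np.asarray(pixels)
    if arr.ndim == 2:
        if arr.dtype != np.uint8:
            if arr.min() < 0 or arr.max() > 255:
                raise ValueError("grayscale intensities must lie in [0, 255]")
            arr = arr.astype(np.uint8)
        return arr
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        rgb = arr[..., :3].astype(np.float64)
        if rgb.min() < 0 or rgb.max() > 255:
            raise ValueError("channel values must lie in [0, 255]")
        if weights is None:
            gray = rgb.sum(axis=2) / 3.0
        else:
            w = np.asarray(weights, dtype=np.float64)
            gray = rgb @ (w / w.sum())
        # half-up rounding (floor(x + 0.5)), not banker's rounding
        return np.clip(np.floor(gray + 0.5), 0, 255).astype(np.uint8)
    raise ValueError(f"expected a 2-D grayscale or H×W×3 RGB raster, got shape {arr.shape}")


def _pixel_size_from_tags(tif: tifffile.TiffFile) -> float | None:
    """µm per pixel from TIFF XResolution / ResolutionUnit tags, if present."""
    page = tif.pages[0]
    tags = page.tags
    xres = tags.get("XResolution")
    if xres is None:
        return None
    value = xres.value
    if isinstance(value, tuple):
        num, den = value
        if num == 0:
            return None
        res = Fraction(int(num), int(den)) if den else None
    else:
        res = Fraction(value) if value else None
    if res is None or res <= 0:
        return None
    unit_tag = tags.get("ResolutionUnit")
    unit = unit_tag.value if unit_tag is not None else 2
    unit = getattr(unit, "value", unit)  # enum -> int
    # pixels per unit -> µm per pixel
    if unit == 3:  # centimetre
        um_per_unit = 10_000.0
    elif unit == 2:  # inch
        um_per_unit = 25_400.0
    else:  # RESUNIT.NONE carries no physical unit: not a usable calibration
        return None
    return um_per_unit / float(res)


def load_slide(path: str | Path, pixel_size_override: float | None = None) -> CalibratedImage:
    """Read a TIFF slide and return a calibrated 8-bit grayscale image.

    The pixel size is taken from ``pixel_size_override`` when given;
    otherwise from the TIFF resolution tags.  RGB input is converted with
    :func:`to_8bit_gray`.  Tiled/pyramidal files are read at the first
    (highest-resolution) level only.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    CalibrationError
        If the file carries no usable resolution metadata and no override
        is given.
    ValueError
        For sample formats other than 8-bit grayscale/RGB.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such slide image: {path}")
    with tifffile.TiffFile(path) as tif:
        arr = tif.pages[0].asarray()
        tag_size = _pixel_size_from_tags(tif)
    if pixel_size_override is not None:
        if not (math.isfinite(pixel_size_override) and pixel_size_override > 0):
            raise ValueError(f"pixel_size_override must be positive, got {pixel_size_override}")
        pixel_size = float(pixel_size_override)
    elif tag_size is not None:
        pixel_size = tag_size
    else:
        raise CalibrationError(
            f"{path}: no resolution metadata in TIFF tags and no pixel_size_override given"
        )
    if arr.dtype != np.uint8:
        raise ValueError(f"{path}: unsupported sample format {arr.dtype}; expected 8-bit samples")
    gray = to_8bit_gray(arr)
    return CalibratedImage(pixels=gray, pixel_size=pixel_size, source_id=str(path))


def write_slide(image: CalibratedImage, path: str | Path) -> None:
    """Write an 8-bit grayscale TIFF with resolution tags matching the calibration.

    Round-trips exactly through :func:`load_slide`: pixels bit-identical,
    pixel size recovered from the stored pixels-per-centimetre rational.
    """
    path = Path(path)
    px_per_cm = Fraction(10_000) / Fraction(image.pixel_size).limit_denominator(10**9)
    res = (px_per_cm.numerator, px_per_cm.denominator)
    tifffile.imwrite(path, image.pixels, resolution=(res, res), resolutionunit="CENTIMETER")
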