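"""Binary segmentation of adipocyte lumens.

Reproduces, operator by operator, the fixed processing sequence of the
automated sizing macro: triangle (Zack) auto-thresholding with dark
background polarity, conversion to a binary mask, a 3×3 erosion, bright
outlier removal at radius 2.5, a second erosion, and a second bright
outlier removal at radius 5.5.  Lipid lumens appear bright in the 8-bit
image, so with the dark-background polarity they become mask foreground.

Conventions (fixed and documented so oracles can match bit-exactly):

* threshold comparison is strict — a pixel is foreground iff its
  intensity is strictly greater than the threshold level (dark
  background);
* triangle tie-breaks choose the lowest qualifying bin;
* erosion uses a 3×3 square structuring element with out-of-bounds
  neighbours treated as background;
* the outlier filter's circular kernel contains every offset whose
  Euclidean distance from the centre is ≤ radius, the neighbourhood is
  clamped (not padded) at the borders, and the median of an even-sized
  neighbourhood is the lower median.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .imaging import CalibratedImage

__all__ = [
    "BinaryMask",
    "SegmentationParams",
    "DegenerateHistogramError",
    "triangle_threshold",
    "apply_threshold",
    "erode",
    "remove_outliers",
    "disk_offsets",
    "segment",
]


class DegenerateHistogramError(ValueError):
    """Raised when an intensity histogram is empty (all counts zero)."""


@dataclass(frozen=True)
class BinaryMask:
    """Foreground raster (adipocyte lumens) with the source calibration."""

    pixels: np.ndarray  # 2-D bool, True = lumen
    pixel_size: float
    threshold_used: int

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=bool)
        if px.ndim != 2:
            raise ValueError("mask must be 2-D")
        object.__setattr__(self, "pixels", px)
        if not 0 <= self.threshold_used <= 255:
            raise ValueError(f"threshold_used must be in [0, 255], got {self.threshold_used}")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class SegmentationParams:
    """Knobs of the mask-cleanup sequence; defaults mirror the macro."""

    erode_iterations_per_pass: int = 1
    outlier_pass_radii: tuple[float, ...] = (2.5, 5.5)
    outlier_threshold: int = 50
    outlier_which: str = "bright"
    background: str = "dark"
    manual_threshold_override: int | None = None

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.outlier_pass_radii):
            raise ValueError("outlier radii must be positive")
        if not 0 <= self.outlier_threshold <= 255:
            raise ValueError("outlier threshold must be in [0, 255]")
        if self.outlier_which not in ("bright", "dark"):
            raise ValueError("outlier_which must be 'bright' or 'dark'")
        if self.background not in ("dark", "bright"):
            raise ValueError("background must be 'dark' or 'bright'")
        if self.manual_threshold_override is not None and not (
            0 <= self.manual_threshold_override <= 255
        ):
            raise ValueError("manual_threshold_override must be in [0, 255]")


def triangle_threshold(histogram: np.ndarray, background: str = "dark") -> int:
    """Zack triangle threshold on a 256-bin intensity histogram.

    A line is drawn from the histogram peak (modal bin) to the farthest
    nonzero bin on the foreground side — the bright side for a dark
    background, the dark side for a bright one.  The returned level is
    the bin index between the two endpoints whose histogram point lies
    farthest from that line, measured perpendicularly; ties resolve to
    the lowest index.  The result is invariant to uniform positive
    scaling of the counts.

    A histogram with a single nonzero bin returns that bin's index; an
    all-zero histogram raises :class:`DegenerateHistogramError`.
    """
    h = np.asarray(histogram, dtype=np.float64)
    if h.shape != (256,):
        raise ValueError(f"histogram must have 256 bins, got shape {h.shape}")
    if np.any(h < 0):
        raise ValueError("histogram counts must be non-negative")
    nonzero = np.flatnonzero(h)
    if nonzero.size == 0:
        raise DegenerateHistogramError("all-zero histogram")
    if nonzero.size == 1:
        return int(nonzero[0])
    peak = int(np.argmax(h))  # argmax takes the lowest modal bin
    if background == "dark":
        tail = int(nonzero[-1])  # farthest nonzero bin on the bright side
    elif background == "bright":
        tail = int(nonzero[0])
    else:
        raise ValueError("background must be 'dark' or 'bright'")
    if tail == peak:
        return peak
    lo, hi = (peak, tail) if peak < tail else (tail, peak)
    bins = np.arange(lo, hi + 1, dtype=np.float64)
    counts = h[lo : hi + 1]
    # perpendicular distance from (b, h[b]) to the line peak->tail; the
    # denominator is constant over b so the numerator alone decides argmax
    dx = float(tail - peak)
    dy = h[tail] - h[peak]
    num = np.abs(dx * (h[peak] - counts) - (peak - bins) * dy)
    best = int(np.argmax(num))  # lowest index on ties
    return int(bins[best])


def histogram256(pixels: np.ndarray) -> np.ndarray:
    """256-bin intensity histogram of an 8-bit raster."""
    return np.bincount(np.asarray(pixels, dtype=np.uint8).ravel(), minlength=256)


def apply_threshold(image: CalibratedImage, level: int, background: str = "dark") -> BinaryMask:
    """Binarize at ``level``: strictly brighter pixels are foreground (dark
    background); polarity flips for a bright background."""
    if not 0 <= level <= 255:
        raise ValueError(f"level must be in [0, 255], got {level}")
    if background == "dark":
        fg = image.pixels > level
    elif background == "bright":
        fg = image.pixels < level
    else:
        raise ValueError("background must be 'dark' or 'bright'")
    return BinaryMask(pixels=fg, pixel_size=image.pixel_size, threshold_used=int(level))


_SQUARE3 = np.ones((3, 3), dtype=bool)


def erode(mask: BinaryMask, iterations: int = 1) -> BinaryMask:
    """Binary erosion with a 3×3 square, ``iterations`` times.

    Out-of-bounds neighbours count as background, so foreground touching
    the border erodes there too.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    out = ndimage.binary_erosion(
        mask.pixels, structure=_SQUARE3, iterations=iterations, border_value=0
    )
    return BinaryMask(pixels=out, pixel_size=mask.pixel_size, threshold_used=mask.threshold_used)


def disk_offsets(radius: float) -> np.ndarray:
    """Integer offsets (dy, dx) with Euclidean distance ≤ radius from the centre.

    Radius 2.5 yields a 21-pixel kernel, radius 5.5 a 97-pixel kernel.
    """
    r = int(np.floor(radius))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    keep = dy * dy + dx * dx <= radius * radius
    return np.stack([dy[keep], dx[keep]], axis=1)


def _disk_footprint(radius: float) -> np.ndarray:
    r = int(np.floor(radius))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    return dy * dy + dx * dx <= radius * radius


def _clamped_lower_median(pixels: np.ndarray, offsets: np.ndarray, ys: np.ndarray, xs: np.ndarray) -> np.ndarray:
    """Lower median over the in-bounds disk neighbourhood of each (y, x)."""
    h, w = pixels.shape
    ny = ys[:, None] + offsets[:, 0][None, :]
    nx = xs[:, None] + offsets[:, 1][None, :]
    valid = (ny >= 0) & (ny < h) & (nx >= 0) & (nx < w)
    gathered = pixels[np.clip(ny, 0, h - 1), np.clip(nx, 0, w - 1)].astype(np.uint16)
    vals = np.where(valid, gathered, np.uint16(256))  # sentinel sorts last
    vals.sort(axis=1)  # sentinels (256) sort last
    counts = valid.sum(axis=1)
    idx = (counts - 1) // 2  # lower median
    return vals[np.arange(vals.shape[0]), idx].astype(np.uint8)


def remove_outliers(
    pixels: np.ndarray, radius: float, threshold: int, which: str = "bright"
) -> np.ndarray:
    """Despeckle an 8-bit raster the way the macro's outlier removal does.

    Each pixel is compared with the median of its circular neighbourhood
    (Euclidean distance ≤ ``radius``).  A *bright* outlier — pixel minus
    median strictly greater than ``threshold`` — is replaced by the
    median; ``which='dark'`` applies the symmetric rule.  Neighbourhoods
    are clamped to the image at the borders and even-sized clamped
    neighbourhoods take the lower median.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must be in [0, 255]")
    if which not in ("bright", "dark"):
        raise ValueError("which must be 'bright' or 'dark'")
    img = np.asarray(pixels, dtype=np.uint8)
    h, w = img.shape
    footprint = _disk_footprint(radius)
    # interior: full odd-sized kernel, so scipy's rank median == lower median
    med = ndimage.median_filter(img, footprint=footprint, mode="nearest")
    # border band: recompute with the clamped-neighbourhood definition
    r = int(np.floor(radius))
    band = np.zeros((h, w), dtype=bool)
    band[:r, :] = band[h - r :, :] = True
    band[:, :r] = band[:, w - r :] = True
    if band.any():
        ys, xs = np.nonzero(band)
        med[ys, xs] = _clamped_lower_median(img, disk_offsets(radius), ys, xs)
    out = img.copy()
    if which == "bright":
        hit = img.astype(np.int16) - med.astype(np.int16) > threshold
    else:
        hit = med.astype(np.int16) - img.astype(np.int16) > threshold
    out[hit] = med[hit]
    return out


def _mask_to_u8(mask: np.ndarray) -> np.ndarray:
    return np.where(mask, np.uint8(255), np.uint8(0))


def segment(image: CalibratedImage, params: SegmentationParams | None = None) -> BinaryMask:
    """Full mask-producing sequence of the sizing macro.

    Order: triangle threshold (or the manual override) → binarize →
    erode → remove outliers (first radius) → erode → remove outliers
    (second radius), with one erosion per pass by default.  Outlier
    removal operates on the 0/255 rendering of the mask, exactly as the
    original macro applies it to the binarized image.
    """
    if params is None:
        params = SegmentationParams()
    if params.manual_threshold_override is not None:
        level = int(params.manual_threshold_override)
    else:
        level = triangle_threshold(histogram256(image.pixels), background=params.background)
    mask = apply_threshold(image, level, background=params.background)
    fg = mask.pixels
    for radius in params.outlier_pass_radii:
        fg = ndimage.binary_erosion(
            fg, structure=_SQUARE3, iterations=params.erode_iterations_per_pass, border_value=0
        )
        cleaned = remove_outliers(
            _mask_to_u8(fg), radius, params.outlier_threshold, params.outlier_which
        )
        fg = cleaned > 0
    return BinaryMask(pixels=fg, pixel_size=image.pixel_size, threshold_used=level)
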