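"""Raster I/O, white-tile calibration, background segmentation and format comparison.

Images are held as ``numpy`` ``uint8`` arrays of shape (H, W, 3), row-major
with the origin at the top-left; foreground masks are boolean arrays of the
same height and width.  Samples are photographed/scanned on a black
background, so segmentation is a dark-pixel threshold with optional
connected-component speckle removal, and calibration is a per-channel linear
gain that maps the white reference tile to its nominal value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from PIL import Image

from .color_core import ColorConversionConfig, DEFAULT_CONFIG, srgb_to_lab, delta_e2000_batch, _ciede2000_core

__all__ = [
    "CalibrationProfile",
    "FormatComparison",
    "read_image",
    "write_image",
    "compute_calibration",
    "apply_calibration",
    "segment_background",
    "extract_sibling",
    "compare_formats",
    "mismatch_overlay",
]

_FORMATS = {"TIFF": "TIFF", "TIF": "TIFF", "PNG": "PNG", "JPEG": "JPEG", "JPG": "JPEG"}


@dataclass(frozen=True)
class CalibrationProfile:
    """Per-channel multiplicative gains mapping a white patch to its nominal value."""

    gain_r: float
    gain_g: float
    gain_b: float
    reference_white: tuple[int, int, int] = (255, 255, 255)

    @property
    def gains(self) -> np.ndarray:
        return np.array([self.gain_r, self.gain_g, self.gain_b])


@dataclass
class FormatComparison:
    """Per-pixel classification of two encodings of one image.

    identical: bit-equal RGB triplets; different: CIEDE2000 above the
    threshold; similar: everything in between.  Percentages are over the
    compared (optionally masked) pixels and sum to 100.
    """

    identical_pct: float
    similar_pct: float
    different_pct: float
    mismatch_mask: np.ndarray
    threshold: float
    n_compared: int


def _norm_format(fmt: Optional[str], path) -> str:
    if fmt is None:
        fmt = Path(path).suffix.lstrip(".").upper()
    key = fmt.upper()
    if key not in _FORMATS:
        raise ValueError(f"unsupported image format: {fmt!r}")
    return _FORMATS[key]


def read_image(path, format: Optional[str] = None) -> np.ndarray:
    """Decode an image file into an (H, W, 3) uint8 RGB array.

    A fully opaque alpha channel is dropped; anything that is not 8-bit
    RGB(A) or greyscale-promotable raises a format error.
    """
    _norm_format(format, path)
    with Image.open(path) as im:
        if im.mode == "RGBA":
            alpha = np.asarray(im)[..., 3]
            if not np.all(alpha == 255):
                raise ValueError(f"{path}: image carries partial transparency")
            im = im.convert("RGB")
        elif im.mode in ("L", "P"):
            im = im.convert("RGB")
        elif im.mode != "RGB":
            raise ValueError(f"{path}: unsupported colour model {im.mode!r} (need 8-bit RGB)")
        arr = np.asarray(im, dtype=np.uint8)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"{path}: decoded array is not H x W x 3")
    return arr


def write_image(raster: np.ndarray, path, format: Optional[str] = None, jpeg_quality: int = 90) -> None:
    """Encode a raster; TIFF/PNG are bit-exact, JPEG is lossy at ``jpeg_quality``."""
    fmt = _norm_format(format, path)
    arr = np.ascontiguousarray(np.asarray(raster, dtype=np.uint8))
    im = Image.fromarray(arr, mode="RGB")
    if fmt == "JPEG":
        im.save(path, format="JPEG", quality=jpeg_quality, subsampling=0)
    elif fmt == "TIFF":
        im.save(path, format="TIFF", compression=None)
    else:
        im.save(path, format="PNG")


def compute_calibration(
    raster: np.ndarray,
    white_patch: tuple[int, int, int, int],
    reference_white: tuple[int, int, int] = (255, 255, 255),
) -> CalibrationProfile:
    """Linear gains from a rectangular white-tile region.

    ``white_patch`` is (row0, col0, row1, col1), half-open.  Gain for channel
    c is reference_white[c] / mean(channel c over the patch).
    """
    r0, c0, r1, c1 = white_patch
    h, w = raster.shape[:2]
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError(f"white patch {white_patch} empty or outside the {h}x{w} raster")
    means = np.asarray(raster, dtype=np.float64)[r0:r1, c0:c1].reshape(-1, 3).mean(axis=0)
    if np.any(means == 0):
        raise ValueError("degenerate white patch: a channel mean is zero")
    gains = np.asarray(reference_white, dtype=np.float64) / means
    return CalibrationProfile(float(gains[0]), float(gains[1]), float(gains[2]), tuple(reference_white))


def apply_calibration(raster: np.ndarray, profile: CalibrationProfile) -> np.ndarray:
    """Multiply each channel by its gain; round half-up; clip to [0, 255]."""
    scaled = np.asarray(raster, dtype=np.float64) * profile.gains
    return np.clip(np.floor(scaled + 0.5), 0, 255).astype(np.uint8)


def segment_background(
    raster: np.ndarray,
    black_threshold: int = 30,
    min_area: int = 0,
) -> np.ndarray:
    """Foreground mask for samples on a (near-)black background.

    A pixel is background iff max(r, g, b) <= black_threshold.  With
    ``min_area`` > 0, 8-connected foreground components smaller than
    ``min_area`` pixels are dropped as speckle.
    """
    if not (0 <= black_threshold <= 255):
        raise ValueError("black_threshold must lie in [0, 255]")
    mask = np.asarray(raster).max(axis=2) > black_threshold
    if min_area > 0 and mask.any():
        from scipy import ndimage

        labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
        if n:
            areas = np.bincount(labels.ravel())
            keep = areas >= min_area
            keep[0] = False
            mask = keep[labels]
    return mask


def extract_sibling(raster: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Crop to the foreground bounding box, blanking in-box background to black."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != raster.shape[:2]:
        raise ValueError("mask dimensions do not match the raster")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise ValueError("no foreground: the mask is empty")
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    sub = np.array(raster[r0:r1, c0:c1], dtype=np.uint8)
    submask = mask[r0:r1, c0:c1].copy()
    sub[~submask] = 0
    return sub, submask


def compare_formats(
    a: np.ndarray,
    b: np.ndarray,
    threshold: float = 2.0,
    mask: Optional[np.ndarray] = None,
    cfg: ColorConversionConfig = DEFAULT_CONFIG,
) -> FormatComparison:
    """Classify pixels of two encodings as identical / similar / different.

    identical: exact integer RGB equality.  different: CIEDE2000 between the
    two pixels above ``threshold``.  similar: the rest (0 < dE <= threshold).
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    sel = np.ones(a.shape[:2], dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    if sel.shape != a.shape[:2]:
        raise ValueError("mask dimensions do not match the rasters")
    n = int(sel.sum())
    if n == 0:
        raise ValueError("no pixels selected for comparison")

    identical = np.all(a == b, axis=2)
    mismatch = np.zeros(a.shape[:2], dtype=bool)
    todo = sel & ~identical
    if todo.any():
        la = srgb_to_lab(a[todo], cfg)
        lb = srgb_to_lab(b[todo], cfg)
        de = _ciede2000_core(la, lb, cfg.kL, cfg.kC, cfg.kH)
        mm = np.zeros(todo.sum(), dtype=bool)
        mm[de > threshold] = True
        mismatch[todo] = mm
    n_ident = int((identical & sel).sum())
    n_diff = int(mismatch.sum())
    n_sim = n - n_ident - n_diff
    return FormatComparison(
        identical_pct=100.0 * n_ident / n,
        similar_pct=100.0 * n_sim / n,
        different_pct=100.0 * n_diff / n,
        mismatch_mask=mismatch,
        threshold=threshold,
        n_compared=n,
    )


def mismatch_overlay(raster: np.ndarray, comparison: FormatComparison) -> np.ndarray:
    """Copy of the raster with 'different' pixels painted red."""
    out = np.array(raster, dtype=np.uint8)
    out[comparison.mismatch_mask] = (255, 0, 0)
    return out
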