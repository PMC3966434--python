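"""Image and mask input/output.

Reads single-frame grayscale brain MR slices — DICOM (MONOCHROME2, 8/12/16
bit), PNG or TIFF — and maps them onto the unit intensity scale used by every
downstream stage. DICOM pixel data passes through rescale slope/intercept and,
when the file carries them, the linear display window defined by Window
Center / Window Width; files without a window fall back to min-max scaling.
Binary masks are written as 8-bit PNGs with values {0, 255} and round-trip
exactly.

Conventions: arrays are (row, col), 0-based; a ``GrayImage`` is a 2-D float64
array with finite values in [0, 1] and at least 8 rows and 8 columns; a
``BinaryMask`` is a boolean array of the same shape as its source image.
"""

from __future__ import annotations

import os
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import ParameterError, UnsupportedFormatError

_DICOM_SUFFIXES = {".dcm", ".dicom", ".ima"}


def validate_gray_image(pixels: np.ndarray, *, name: str = "image") -> np.ndarray:
    """Check the GrayImage contract and return the array as float64.

    Raises ParameterError on wrong dimensionality, undersized grids
    (fewer than 8 rows or columns) or non-finite values.
    """
    arr = np.asarray(pixels, dtype=float)
    if arr.ndim != 2:
        raise ParameterError(f"{name} must be 2-D, got shape {arr.shape}")
    if arr.shape[0] < 8 or arr.shape[1] < 8:
        raise ParameterError(f"{name} must be at least 8x8, got {arr.shape}")
    if not np.isfinite(arr).all():
        raise ParameterError(f"{name} contains non-finite values")
    return arr


def normalize(pixels: np.ndarray) -> np.ndarray:
    """Min-max scale to [0, 1]; a constant (zero-range) image maps to 0.5.

    Idempotent: applying it twice equals applying it once.
    """
    arr = np.asarray(pixels, dtype=float)
    lo = float(arr.min())
    hi = float(arr.max())
    if hi - lo <= 0.0:
        return np.full_like(arr, 0.5)
    return (arr - lo) / (hi - lo)


def _apply_window(raw: np.ndarray, center: float, width: float) -> np.ndarray:
    """Linear display window: map [center-width/2, center+width/2] -> [0, 1]."""
    if width <= 0:
        raise ParameterError(f"window width must be positive, got {width}")
    lower = center - width / 2.0
    return np.clip((raw - lower) / width, 0.0, 1.0)


def _first_number(value) -> float:
    # DICOM window tags may be multi-valued; the first entry is the default view.
    try:
        return float(value[0])
    except (TypeError, IndexError):
        return float(value)


def _read_dicom(path: Path) -> np.ndarray:
    import pydicom

    ds = pydicom.dcmread(str(path))
    frames = int(getattr(ds, "NumberOfFrames", 1) or 1)
    if frames > 1:
        raise UnsupportedFormatError(f"multi-frame DICOM not supported: {path}")
    if int(getattr(ds, "SamplesPerPixel", 1)) != 1:
        raise UnsupportedFormatError(f"color DICOM not supported: {path}")
    photometric = str(getattr(ds, "PhotometricInterpretation", "MONOCHROME2"))
    if photometric != "MONOCHROME2":
        raise UnsupportedFormatError(
            f"unsupported photometric interpretation {photometric!r}: {path}"
        )
    raw = ds.pixel_array.astype(float)
    slope = float(getattr(ds, "RescaleSlope", 1.0) or 1.0)
    intercept = float(getattr(ds, "RescaleIntercept", 0.0) or 0.0)
    raw = raw * slope + intercept
    center = getattr(ds, "WindowCenter", None)
    width = getattr(ds, "WindowWidth", None)
    if center is not None and width is not None:
        return _apply_window(raw, _first_number(center), _first_number(width))
    return normalize(raw)


def _read_plain(path: Path) -> np.ndarray:
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        # Accept gray-as-RGB(A); reject true color.
        rgb = arr[..., :3]
        if not (rgb[..., 0] == rgb[..., 1]).all() or not (rgb[..., 1] == rgb[..., 2]).all():
            raise UnsupportedFormatError(f"color image not supported: {path}")
        arr = rgb[..., 0]
    return normalize(arr.astype(float))


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read a DICOM/PNG/TIFF slice into a normalized GrayImage in [0, 1]."""
    p = Path(path)
    if not p.is_file():
        raise IOError(f"no such file: {p}")
    if p.suffix.lower() in _DICOM_SUFFIXES:
        pixels = _read_dicom(p)
    else:
        pixels = _read_plain(p)
    return validate_gray_image(pixels, name=str(p))


def write_image(image: np.ndarray, path: str | os.PathLike) -> None:
    """Export a [0, 1] grayscale array as an 8-bit PNG/TIFF panel."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    iio.imwrite(Path(path), np.round(arr * 255).astype(np.uint8))


def write_mask(mask: np.ndarray, path: str | os.PathLike) -> None:
    """Store a boolean mask as an 8-bit PNG with values {0, 255}."""
    arr = np.asarray(mask)
    if arr.dtype != bool:
        raise ParameterError("mask must be a boolean array")
    if arr.ndim != 2:
        raise ParameterError(f"mask must be 2-D, got shape {arr.shape}")
    p = Path(path)
    parent = p.parent
    if not parent.is_dir() or not os.access(parent, os.W_OK):
        raise IOError(f"cannot write mask to {p}: directory not writable")
    iio.imwrite(p, arr.astype(np.uint8) * 255)


def read_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a {0, 255} PNG mask back to boolean; inverse of write_mask."""
    p = Path(path)
    if not p.is_file():
        raise IOError(f"no such file: {p}")
    arr = np.asarray(iio.imread(p))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 127
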