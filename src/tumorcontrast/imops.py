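"""Image arithmetic (T1w − T2w, T1w + T2w) and bit-depth conversion.

Subtraction and addition of the co-registered weighted images is the
post-processing step that amplifies tumor contrast for dual-action agents:
the tumor term grows (T1w signal up, T2w signal down) while the tissue
term shrinks, so the ratio of ROI means on the difference image exceeds
the single-weighting contrast.

All quantitative arithmetic happens on the analog representation (or a
lossless 16-bit working format); conversion to 8-bit is a display export
and must never precede ROI measurement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import FileFormatError, ScaleError, ShapeError, ValidationError
from .phantom import WeightedImage

logger = logging.getLogger(__name__)

MODES = ("subtract", "add")
NEGATIVE_HANDLING = ("keep_signed", "clip_zero")
RESCALES = ("none", "clip", "minmax_8bit")


@dataclass(frozen=True)
class CombinePolicy:
    """How to combine two weighted images and how to export the result.

    ``keep_signed`` preserves exact signed arithmetic (the default for
    analysis); ``clip_zero`` maps negative differences to 0 as an integer
    file format would.  ``export_rescale`` optionally converts the result
    to 8-bit on the way out.
    """

    mode: str = "subtract"
    negative_handling: str = "keep_signed"
    export_rescale: str = "none"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValidationError(f"unknown combine mode {self.mode!r}")
        if self.negative_handling not in NEGATIVE_HANDLING:
            raise ValidationError(
                f"unknown negative handling {self.negative_handling!r}")
        if self.export_rescale not in RESCALES:
            raise ValidationError(f"unknown export rescale {self.export_rescale!r}")

    def with_mode(self, mode: str) -> "CombinePolicy":
        return replace(self, mode=mode)


def combine(t1w: WeightedImage, t2w: WeightedImage,
            policy: CombinePolicy) -> WeightedImage:
    """Pixelwise T1w − T2w (mode ``subtract``) or T1w + T2w (mode ``add``).

    Inputs must share one grid and one scale.  The result carries the
    ``difference`` or ``sum`` weighting tag and stays in analog scale
    unless ``policy.export_rescale`` requests an 8-bit export.
    """
    if t1w.shape != t2w.shape:
        raise ShapeError(f"grid mismatch: {t1w.shape} vs {t2w.shape}")
    if t1w.scale != t2w.scale:
        raise ScaleError(f"mixed scales: {t1w.scale} vs {t2w.scale}")
    a = np.asarray(t1w.pixels, dtype=float)
    b = np.asarray(t2w.pixels, dtype=float)
    if policy.mode == "subtract":
        px = a - b
        if policy.negative_handling == "clip_zero":
            px = np.clip(px, 0.0, None)
        weighting = "difference"
    else:
        px = a + b
        weighting = "sum"
    logger.debug("%s image: min=%.4f max=%.4f", weighting, px.min(), px.max())
    out = WeightedImage(px, weighting, scale="analog_au")
    if policy.export_rescale != "none":
        out = to_uint8(out, policy.export_rescale)
    return out


def to_uint8(img: WeightedImage, rescale: str = "minmax_8bit") -> WeightedImage:
    """Convert an analog or 16-bit image to the 8-bit [0, 255] export scale.

    ``clip`` rounds and clamps to [0, 255]; ``minmax_8bit`` maps the image
    min to 0 and max to 255 affinely (a constant image maps to all zeros —
    a documented convention, not an error).
    """
    if img.scale == "uint8":
        return img
    px = np.asarray(img.pixels, dtype=float)
    if rescale == "clip":
        out = np.clip(np.rint(px), 0, 255)
    elif rescale == "minmax_8bit":
        lo, hi = px.min(), px.max()
        if hi > lo:
            out = np.rint((px - lo) * 255.0 / (hi - lo))
        else:
            out = np.zeros_like(px)
    else:
        raise ValidationError(f"unknown rescale {rescale!r}")
    return WeightedImage(out.astype(np.uint8), img.weighting, scale="uint8")


def to_uint16(img: WeightedImage, clip_negative: bool = True) -> WeightedImage:
    """Round the analog image into the lossless 16-bit working format.

    Signed difference values are clipped at zero (integer formats carry no
    sign); values above 65535 are clamped.
    """
    if img.scale == "uint16":
        return img
    px = np.rint(np.asarray(img.pixels, dtype=float))
    if clip_negative:
        px = np.clip(px, 0, 65535)
    elif px.min() < 0:
        raise ScaleError("negative values cannot enter uint16 without clipping")
    return WeightedImage(px.astype(np.uint16), img.weighting, scale="uint16")


# -- file IO ---------------------------------------------------------------

_SCALE_FOR_DTYPE = {np.dtype(np.uint8): "uint8", np.dtype(np.uint16): "uint16"}


def read_image(path: str | Path, weighting: str = "t1w") -> WeightedImage:
    """Read a grayscale TIFF/PNG/JPEG as a WeightedImage.

    8-/16-bit integer files keep their integer scale tag; floating-point
    TIFFs are read as analog.  RGB inputs and other bit depths are rejected.
    """
    path = Path(path)
    if not path.is_file():
        raise FileFormatError(f"cannot read image file: {path}")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except Exception as exc:  # unreadable / corrupt
        raise FileFormatError(f"unreadable image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise FileFormatError(
            f"{path}: expected a single-channel 2-D image, got shape {arr.shape}"
        )
    if np.issubdtype(arr.dtype, np.floating):
        scale = "analog_au"
    elif arr.dtype in _SCALE_FOR_DTYPE:
        scale = _SCALE_FOR_DTYPE[arr.dtype]
    else:
        raise FileFormatError(f"{path}: unsupported bit depth {arr.dtype}")
    return WeightedImage(arr, weighting, scale=scale)


def write_image(img: WeightedImage, path: str | Path) -> Path:
    """Write a WeightedImage to disk.

    TIFF targets get the 16-bit working format (analog values rounded,
    negatives clipped); PNG/JPEG targets get the 8-bit export (clip for
    already-bounded data would lose nothing, but min-max is the display
    convention used here).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, to_uint16(img).pixels)
    elif suffix in (".png", ".jpg", ".jpeg"):
        iio.imwrite(path, to_uint8(img, "minmax_8bit").pixels)
    else:
        raise FileFormatError(f"unsupported image format: {path}")
    return path


def read_mask(path: str | Path) -> np.ndarray:
    """Read a 0/255 grayscale mask file as a boolean array."""
    path = Path(path)
    if not path.is_file():
        raise FileFormatError(f"cannot read mask file: {path}")
    try:
        arr = np.asarray(iio.imread(path))
    except Exception as exc:
        raise FileFormatError(f"unreadable mask {path}: {exc}") from exc
    if arr.ndim != 2:
        raise FileFormatError(f"{path}: mask must be single-channel 2-D")
    return arr > 0


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Write a boolean mask as an 8-bit 0/255 PNG."""
    path = Path(path)
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))
    return path
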