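"""Grayscale image, mask and report I/O.

Images are held as real-valued 2-D arrays (row, col, 0-based).  8- and
16-bit PNG/TIFF/PGM round-trip losslessly; RGB inputs are collapsed with
the ITU-R BT.601 luminance weights (0.299, 0.587, 0.114).  Binary masks
are written as 8-bit images with foreground 255.  Detection reports are
JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import imageio.v3 as iio
import numpy as np

from .config import PipelineConfig  # noqa: F401  (re-export: config is part of the I/O surface)

if TYPE_CHECKING:  # pragma: no cover
    from .boundary import Detection

logger = logging.getLogger(__name__)

#: BT.601 luminance weights used to collapse RGB inputs to gray.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass
class GrayImage:
    """A single-channel image with nonnegative real intensities.

    ``bit_depth_hint`` (8 or 16) records the intended dynamic range for
    writing and for rules expressed as fractions of the dynamic range.
    """

    pixels: np.ndarray
    bit_depth_hint: int = 8

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("GrayImage requires a nonempty 2-D array")
        if np.any(self.pixels < 0):
            raise ValueError("intensities must be nonnegative")
        if self.bit_depth_hint not in (8, 16):
            raise ValueError("bit_depth_hint must be 8 or 16")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def dynamic_range(self) -> float:
        return 255.0 if self.bit_depth_hint == 8 else 65535.0


def empty_mask(shape: tuple[int, int]) -> np.ndarray:
    """All-background boolean mask of the given (height, width)."""
    return np.zeros(shape, dtype=bool)


def read_gray_image(path: str | Path) -> GrayImage:
    """Read a PNG/TIFF/PGM image as a :class:`GrayImage`.

    16-bit data are preserved without rescaling.  RGB(A) images are
    collapsed to luminance with fixed BT.601 weights; the conversion is
    logged.  Unreadable files raise ``ValueError`` naming the file.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise ValueError(f"cannot read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[2] not in (3, 4):
            raise ValueError(
                f"cannot interpret {path}: {arr.shape[2]}-channel image"
            )
        rgb = arr[..., :3].astype(np.float64)
        arr = rgb @ np.asarray(LUMA_WEIGHTS)
        logger.info(
            "collapsed RGB %s to gray with BT.601 weights %s", path, LUMA_WEIGHTS
        )
    elif arr.ndim != 2:
        raise ValueError(f"cannot interpret {path}: ndim={arr.ndim}")
    hint = 16 if np.asarray(arr).max(initial=0) > 255 else 8
    if arr.dtype == np.uint16:
        hint = 16
    return GrayImage(arr.astype(np.float64), bit_depth_hint=hint)


def write_gray_image(img: GrayImage, path: str | Path) -> None:
    """Write a :class:`GrayImage`, rounding to its hinted bit depth."""
    path = Path(path)
    dtype = np.uint8 if img.bit_depth_hint == 8 else np.uint16
    data = np.clip(np.rint(img.pixels), 0, img.dynamic_range).astype(dtype)
    iio.imwrite(path, data)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as an 8-bit image, foreground=255."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    iio.imwrite(Path(path), np.where(mask, 255, 0).astype(np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a mask image; any nonzero pixel is foreground."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., :3].max(axis=2)
    return np.asarray(arr) > 0


def write_report(
    detections: Sequence["Detection"],
    is_normal: bool,
    path: str | Path,
    image_id: str | None = None,
) -> None:
    """Serialize a per-image detection report to JSON."""
    path = Path(path)
    doc = {
        "image_id": image_id if image_id is not None else path.stem,
        "is_normal": bool(is_normal),
        "detections": [
            {
                "center_row": float(d.center_row),
                "center_col": float(d.center_col),
                "radius": float(d.radius),
                "n_pixels": int(d.cluster.size),
            }
            for d in detections
        ],
    }
    path.write_text(json.dumps(doc, indent=2) + "\n")


def read_report(path: str | Path) -> dict:
    """Parse a detection report written by :func:`write_report`."""
    return json.loads(Path(path).read_text())
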