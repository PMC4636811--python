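"""The ratio-energy blob feature.

The *energy* at a pixel for a window is the sum of intensities the window
covers when centered there.  Ratio energy compares two fixed scales:

    RE(x, y) = 100 * energy_smallwindow(x, y) / energy_largewindow(x, y)

with 3x3 and 11x11 windows by default.  Bright mass concentrated at the
small scale (a blob no larger than the small window) pushes RE toward 100;
smooth neighborhoods sit near the area ratio 100*9/121 ~ 7.4.  The scale is
fixed by design — calcification spots in mammograms are all roughly the
same few-pixel size, so a scale-space search buys nothing.

All window sums come from a summed-area table: one cumulative pass over
the image, then O(1) per query, making the whole feature linear in the
pixel count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig
from .io import GrayImage


class SummedAreaTable:
    """Integral image supporting O(1) rectangular window sums."""

    def __init__(self, img: GrayImage | np.ndarray):
        pixels = img.pixels if isinstance(img, GrayImage) else np.asarray(img, float)
        self.shape = pixels.shape
        self._sat = np.zeros((pixels.shape[0] + 1, pixels.shape[1] + 1))
        np.cumsum(np.cumsum(pixels, axis=0), axis=1, out=self._sat[1:, 1:])

    def window_sum(self, row: int, col: int, half_width: int) -> float:
        """Sum over the (2*half_width+1)^2 window centered at (row, col).

        The window must lie fully inside the image.
        """
        h, w = self.shape
        r0, r1 = row - half_width, row + half_width + 1
        c0, c1 = col - half_width, col + half_width + 1
        if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
            raise ValueError(
                f"window of half-width {half_width} at ({row}, {col}) "
                f"overhangs the {h}x{w} image border"
            )
        s = self._sat
        return float(s[r1, c1] - s[r0, c1] - s[r1, c0] + s[r0, c0])

    def all_window_sums(self, half_width: int) -> np.ndarray:
        """Window sums for every center where the window fits, as an array
        of shape (H - 2*half_width, W - 2*half_width)."""
        w = 2 * half_width + 1
        s = self._sat
        return s[w:, w:] - s[:-w, w:] - s[w:, :-w] + s[:-w, :-w]


def window_sum(img: GrayImage, row: int, col: int, half_width: int) -> float:
    """One-off window energy; builds the table each call.  For repeated
    queries construct a :class:`SummedAreaTable` once."""
    return SummedAreaTable(img).window_sum(row, col, half_width)


@dataclass
class EnergyMap:
    """Per-pixel ratio energy in [0, 100].

    ``valid_region`` is the (row0, row1, col0, col1) half-open rectangle of
    centers where the large window fits fully; values outside it are 0 and
    such pixels can never become foreground.
    """

    values: np.ndarray
    valid_region: tuple[int, int, int, int]

    def valid_slices(self) -> tuple[slice, slice]:
        r0, r1, c0, c1 = self.valid_region
        return slice(r0, r1), slice(c0, c1)

    def validity_mask(self) -> np.ndarray:
        m = np.zeros(self.values.shape, dtype=bool)
        m[self.valid_slices()] = True
        return m


def ratio_energy_map(img: GrayImage, cfg: PipelineConfig) -> EnergyMap:
    """Ratio energy at every pixel (Eq. above); 0 outside the valid region
    and wherever the large-window energy is 0."""
    hs, hl = cfg.small_half_width, cfg.large_half_width
    h, w = img.pixels.shape
    if h <= 2 * hl + 1 or w <= 2 * hl + 1:
        raise ValueError(
            f"image {h}x{w} too small for the "
            f"{2 * hl + 1}x{2 * hl + 1} window"
        )
    sat = SummedAreaTable(img)
    large = sat.all_window_sums(hl)
    # small-window sums at the *same* centers: crop the small-sum map
    d = hl - hs
    small = sat.all_window_sums(hs)[d:-d, d:-d] if d else sat.all_window_sums(hs)

    re = np.zeros((h, w))
    inner = np.zeros_like(large)
    np.divide(small, large, out=inner, where=large > 0)
    re[hl:h - hl, hl:w - hl] = 100.0 * inner
    return EnergyMap(values=re, valid_region=(hl, h - hl, hl, w - hl))


def complement_map(em: EnergyMap, bit_depth_hint: int = 8) -> GrayImage:
    """Visualization image (100 - RE) rescaled to the output bit depth.

    Blobs appear dark on a bright field; purely for inspection, never fed
    back into detection.
    """
    top = 255.0 if bit_depth_hint == 8 else 65535.0
    vis = (100.0 - em.values) * (top / 100.0)
    return GrayImage(vis, bit_depth_hint=bit_depth_hint)
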