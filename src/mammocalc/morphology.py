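"""Grayscale morphology refinement producing the top-hat mask I_t.

Erosion and dilation use a diamond (Manhattan-ball) structuring element;
out-of-image samples are ignored (equivalently padded with +inf / -inf).
The white top-hat, image minus its opening, keeps only bright structures
too small to contain the structuring element — exactly the footprint of a
calcification spot (<= 20 pixels), which is why the diamond radius
defaults to 3 (25 pixels, the smallest diamond above that bound).

The top-hat image is binarized at 4.0 sigma (population standard
deviation of the top-hat image itself, strict inequality) to give I_t;
the final calcification mask is the pixelwise AND I_r = I_e & I_t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import PipelineConfig
from .io import GrayImage


@dataclass(frozen=True)
class StructuringElement:
    """A set of (drow, dcol) offsets containing the origin."""

    offsets: frozenset
    radius: int

    @property
    def footprint(self) -> np.ndarray:
        """Boolean (2r+1)x(2r+1) array for use with scipy.ndimage."""
        r = self.radius
        fp = np.zeros((2 * r + 1, 2 * r + 1), dtype=bool)
        for dr, dc in self.offsets:
            fp[dr + r, dc + r] = True
        return fp


def diamond_se(radius: int) -> StructuringElement:
    """Diamond structuring element: offsets with |drow|+|dcol| <= radius
    (2r^2 + 2r + 1 of them)."""
    if radius < 1:
        raise ValueError("structuring element radius must be >= 1")
    offs = frozenset(
        (dr, dc)
        for dr in range(-radius, radius + 1)
        for dc in range(-radius, radius + 1)
        if abs(dr) + abs(dc) <= radius
    )
    return StructuringElement(offsets=offs, radius=radius)


def erode(img: GrayImage, se: StructuringElement) -> GrayImage:
    """Pointwise minimum over the structuring element; border samples
    outside the image do not participate (+inf padding)."""
    out = ndimage.grey_erosion(
        img.pixels, footprint=se.footprint, mode="constant", cval=np.inf
    )
    return GrayImage(out, bit_depth_hint=img.bit_depth_hint)


def dilate(img: GrayImage, se: StructuringElement) -> GrayImage:
    """Pointwise maximum over the reflected structuring element; -inf
    padding outside the image."""
    out = ndimage.grey_dilation(
        img.pixels, footprint=se.footprint, mode="constant", cval=-np.inf
    )
    return GrayImage(out, bit_depth_hint=img.bit_depth_hint)


def opening(img: GrayImage, se: StructuringElement) -> GrayImage:
    """Erosion followed by dilation with the same element."""
    return dilate(erode(img, se), se)


def tophat(img: GrayImage, se: StructuringElement) -> GrayImage:
    """White top-hat: image minus its opening (nonnegative everywhere)."""
    th = img.pixels - opening(img, se).pixels
    # the opening never exceeds the image; clamp fp dust
    return GrayImage(np.maximum(th, 0.0), bit_depth_hint=img.bit_depth_hint)


def tophat_mask(img: GrayImage, cfg: PipelineConfig) -> np.ndarray:
    """Binarized top-hat I_t: pixels strictly above
    ``tophat_sigma_multiplier`` times the top-hat image's population
    standard deviation."""
    th = tophat(img, diamond_se(cfg.se_radius)).pixels
    sigma = float(th.std())
    return th > cfg.tophat_sigma_multiplier * sigma


def combine_masks(ie: np.ndarray, it: np.ndarray) -> np.ndarray:
    """Final calcification mask I_r = I_e AND I_t."""
    ie = np.asarray(ie, dtype=bool)
    it = np.asarray(it, dtype=bool)
    if ie.shape != it.shape:
        raise ValueError(f"mask shapes differ: {ie.shape} vs {it.shape}")
    return ie & it
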