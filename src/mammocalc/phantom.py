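"""Seeded mammogram-like phantoms with exact ground truth.

A phantom is a bright breast-like field on a darker periphery: uniform
central tissue with a smooth radial falloff toward the corners, plus
additive Gaussian noise.  Abnormal phantoms additionally carry planted
calcification clusters: a few compact bright blobs, each well under the
20-pixel footprint that separates micro- from macrocalcification,
scattered within a small radius of a cluster center inside the central
tissue (calcifications sit in tissue, not on the skin line or the dark
field).  Every planted pixel is recorded, and truth regions are the
planted masks dilated by a small radius to mimic a radiologist's loose
outline around a cluster.

Defaults describe the detector's intended operating conditions — spots
clearly separated in intensity from the tissue and of roughly uniform
size: 256x256 8-bit field, tissue mean 100 with noise sd 5, spots at 245
(~0.96 of the dynamic range), 3 clusters of 4 spots of 7-10 pixels each
within an 18-pixel spread.  Spot pixels get a small +0..2 jitter so the
brightest intensity value is not a single repeated constant, which the
top-two-distinct-value outlier rule would otherwise misread as a lone hot
pixel.

Everything is deterministic given ``seed``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .evaluation import GroundTruth
from .io import GrayImage
from .morphology import diamond_se

#: dilation radius applied to planted masks to form truth regions
TRUTH_DILATE_RADIUS = 3

#: normalized radius (of the image diagonal metric) where shading starts
#: to fall off; the central tissue inside it is flat
_FLAT_RADIUS = 0.32

#: planted cluster centers stay within this fraction of height/width of
#: the image center, safely inside the flat tissue
_PLANT_EXTENT = 0.21


@dataclass
class PhantomSpec:
    height: int = 256
    width: int = 256
    background_mean: float = 100.0
    background_noise_sd: float = 5.0
    n_clusters: int = 3
    spots_per_cluster: int = 4
    spot_min_pixels: int = 7
    spot_max_pixels: int = 10
    spot_intensity: float = 245.0
    cluster_spread: float = 18.0
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.spot_min_pixels <= self.spot_max_pixels <= 20:
            raise ValueError("spot sizes must satisfy 1 <= min <= max <= 20")
        floor = self.background_mean + 4.0 * self.background_noise_sd
        if self.spot_intensity <= floor:
            raise ValueError(
                f"spot_intensity {self.spot_intensity} must exceed "
                f"background mean + 4 sd = {floor}"
            )

    @property
    def dynamic_range(self) -> float:
        return 255.0 if self.bit_depth == 8 else 65535.0


def make_background(spec: PhantomSpec) -> GrayImage:
    """Smooth breast-like field plus seeded Gaussian noise.

    Shading is a flat-top radial profile: full ``background_mean`` in the
    central tissue, easing smoothly to half that at the corners.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
    t = np.sqrt(((rr - h / 2) / h) ** 2 + ((cc - w / 2) / w) ** 2)
    ramp = np.clip((t - _FLAT_RADIUS) / (np.sqrt(0.5) - _FLAT_RADIUS), 0.0, 1.0)
    shading = 1.0 - 0.5 * ramp**2
    field = spec.background_mean * shading
    field += rng.normal(0.0, spec.background_noise_sd, size=(h, w))
    field = np.clip(field, 0.0, spec.dynamic_range)
    return GrayImage(field, bit_depth_hint=spec.bit_depth)


def _grow_blob(
    rng: np.random.Generator, start: tuple[int, int], n_pixels: int,
    shape: tuple[int, int],
) -> list[tuple[int, int]]:
    """Grow a compact connected blob of n_pixels from start by accreting
    the candidate 4-neighbor closest to the start (random tie-break)."""
    blob = {start}
    while len(blob) < n_pixels:
        candidates = {
            (r + dr, c + dc)
            for r, c in blob
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1))
            if 0 <= r + dr < shape[0] and 0 <= c + dc < shape[1]
        } - blob
        if not candidates:
            break
        ordered = sorted(candidates)
        d2 = [
            (r - start[0]) ** 2 + (c - start[1]) ** 2 for r, c in ordered
        ]
        best = min(d2)
        ties = [p for p, dd in zip(ordered, d2) if dd == best]
        blob.add(ties[rng.integers(len(ties))])
    return sorted(blob)


def plant_cluster(
    img: GrayImage, spec: PhantomSpec, center: tuple[int, int],
    rng: np.random.Generator | None = None,
) -> tuple[GrayImage, np.ndarray]:
    """Plant one cluster of bright spots around ``center``.

    Returns the modified image and the binary mask of planted pixels.
    The cluster (including its spread) must fit strictly inside the image
    interior where the ratio-energy window is valid.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    h, w = img.pixels.shape
    margin = int(np.ceil(spec.cluster_spread)) + 8
    if not (margin <= center[0] < h - margin and margin <= center[1] < w - margin):
        raise ValueError(
            f"cluster center {center} too close to the border of the "
            f"{h}x{w} image (margin {margin})"
        )
    pixels = img.pixels.copy()
    planted = np.zeros((h, w), dtype=bool)
    for _ in range(spec.spots_per_cluster):
        offset = rng.uniform(-spec.cluster_spread, spec.cluster_spread, size=2)
        sr = int(round(center[0] + offset[0]))
        sc = int(round(center[1] + offset[1]))
        size = int(rng.integers(spec.spot_min_pixels, spec.spot_max_pixels + 1))
        for r, c in _grow_blob(rng, (sr, sc), size, (h, w)):
            pixels[r, c] = min(
                spec.spot_intensity + rng.integers(0, 3), spec.dynamic_range
            )
            planted[r, c] = True
    return GrayImage(pixels, bit_depth_hint=img.bit_depth_hint), planted


def planted_truth_region(planted: np.ndarray) -> np.ndarray:
    """Truth region: planted mask dilated by a small diamond, standing in
    for a radiologist's loose outline."""
    fp = diamond_se(TRUTH_DILATE_RADIUS).footprint
    return ndimage.binary_dilation(planted, structure=fp)


def make_phantom(spec: PhantomSpec, abnormal: bool) -> tuple[GrayImage, GroundTruth]:
    """One phantom with its ground truth."""
    rng = np.random.default_rng(spec.seed)
    img = make_background(spec)
    if not abnormal:
        return img, GroundTruth(is_abnormal=False, regions=[])
    h, w = spec.height, spec.width
    r_lo = int(h / 2 - _PLANT_EXTENT * h)
    r_hi = int(h / 2 + _PLANT_EXTENT * h)
    c_lo = int(w / 2 - _PLANT_EXTENT * w)
    c_hi = int(w / 2 + _PLANT_EXTENT * w)
    regions = []
    for _ in range(spec.n_clusters):
        center = (
            int(rng.integers(r_lo, r_hi)),
            int(rng.integers(c_lo, c_hi)),
        )
        img, planted = plant_cluster(img, spec, center, rng=rng)
        regions.append(planted_truth_region(planted))
    return img, GroundTruth(is_abnormal=True, regions=regions)


def make_dataset(
    n_normal: int, n_abnormal: int, spec: PhantomSpec
) -> list[tuple[GrayImage, GroundTruth]]:
    """n_normal + n_abnormal phantoms with per-image seeds spawned
    deterministically from ``spec.seed`` (normals first)."""
    if n_normal < 0 or n_abnormal < 0:
        raise ValueError("counts must be nonnegative")
    total = n_normal + n_abnormal
    if total == 0:
        return []
    child_seeds = np.random.SeedSequence(spec.seed).generate_state(total)
    out = []
    for i in range(total):
        sub = dataclasses.replace(spec, seed=int(child_seeds[i] & 0x7FFFFFFF))
        out.append(make_phantom(sub, abnormal=i >= n_normal))
    return out
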