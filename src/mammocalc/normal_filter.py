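"""Normal-image prefilter based on sliding-window shape statistics.

A calcification spot is a handful of very bright pixels inside an otherwise
smooth neighborhood, so the local intensity distribution around it is
heavy-tailed and right-skewed.  The gate slides a 20x20 window over the
image (stride 1, fully-inside placements only) and declares the image
*abnormal* as soon as one window has non-excess kurtosis above 14 and
skewness above 2.3; an image with no such window is reported normal and
skipped by the rest of the pipeline.

Moments use the population convention (divide-by-n central moments,
kurtosis of a Gaussian ~ 3) so the published thresholds keep their meaning.
Zero-variance windows return (0, 0) and can never trigger the gate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .config import PipelineConfig
from .io import GrayImage

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MomentPair:
    skewness: float
    kurtosis: float


def window_moments(values: Sequence[float] | np.ndarray) -> MomentPair:
    """Population skewness and non-excess kurtosis of a sample.

    skewness = m3 / m2^(3/2), kurtosis = m4 / m2^2 with m_k the k-th
    central moment using divisor n.  A zero-variance sample returns
    ``MomentPair(0.0, 0.0)`` by convention.
    """
    arr = np.asarray(values, dtype=np.float64).ravel()
    if arr.size < 2:
        raise ValueError("window_moments requires at least 2 values")
    if np.ptp(arr) == 0.0:
        return MomentPair(0.0, 0.0)
    skew = float(stats.skew(arr, bias=True))
    kurt = float(stats.kurtosis(arr, fisher=False, bias=True))
    return MomentPair(skew, kurt)


def _box_sums(arr: np.ndarray, w: int) -> np.ndarray:
    """Sums over all w x w windows (one per top-left corner), via an
    integral image: a single cumulative pass then O(1) per window."""
    sat = np.zeros((arr.shape[0] + 1, arr.shape[1] + 1), dtype=np.float64)
    np.cumsum(np.cumsum(arr, axis=0), axis=1, out=sat[1:, 1:])
    return sat[w:, w:] - sat[:-w, w:] - sat[w:, :-w] + sat[:-w, :-w]


def sliding_moment_maps(
    img: GrayImage, window: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window (skewness, kurtosis) maps, indexed by top-left corner.

    Computed from integral images of the first four intensity powers; the
    image is standardized globally first (both statistics are invariant
    under positive affine maps) to keep the power sums well conditioned.
    """
    h, w = img.pixels.shape
    if h < window or w < window:
        raise ValueError("image smaller than the sliding window")
    x = img.pixels
    sd = x.std()
    x = (x - x.mean()) / (sd if sd > 0 else 1.0)

    n = float(window * window)
    s1 = _box_sums(x, window)
    s2 = _box_sums(x * x, window)
    s3 = _box_sums(x**3, window)
    s4 = _box_sums(x**4, window)
    mu = s1 / n
    m2 = s2 / n - mu**2
    m3 = s3 / n - 3 * mu * s2 / n + 2 * mu**3
    m4 = s4 / n - 4 * mu * s3 / n + 6 * mu**2 * s2 / n - 3 * mu**4
    # clip tiny negative variances from cancellation before dividing
    m2 = np.maximum(m2, 0.0)
    ok = m2 > 1e-12
    skew = np.zeros_like(m2)
    kurt = np.zeros_like(m2)
    np.divide(m3, m2**1.5, out=skew, where=ok)
    np.divide(m4, m2**2, out=kurt, where=ok)
    return skew, kurt


def is_abnormal_image(img: GrayImage, cfg: PipelineConfig) -> bool:
    """True iff some fully-inside window exceeds both moment thresholds.

    Images smaller than the window are declared normal with a warning:
    the gate has no evidence either way and the pipeline's contract is to
    skip images the prefilter cannot flag.
    """
    w = cfg.prefilter_window
    if img.height < w or img.width < w:
        logger.warning(
            "image %dx%d smaller than %dx%d prefilter window; declared normal",
            img.height, img.width, w, w,
        )
        return False
    skew, kurt = sliding_moment_maps(img, w)
    hit = (kurt > cfg.kurtosis_threshold) & (skew > cfg.skewness_threshold)
    logger.debug(
        "prefilter: max kurtosis %.2f, max skewness %.2f, abnormal=%s",
        kurt.max(), skew.max(), bool(hit.any()),
    )
    return bool(hit.any())
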