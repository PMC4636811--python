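"""Detection scoring against expert-marked ground truth.

Region level: a truth region counts as *hit* when at least
``min_match_pixels`` (default 3) final-mask foreground pixels fall inside
it; a predicted cluster that puts fewer than that many pixels into every
truth region is an *extra* (false) detection.

Image level: an image is predicted abnormal when the prefilter passed it
and at least one cluster was reported.  The per-image 2x2 tally yields

    sensitivity = 100 * TP / (TP + FN)      specificity = 100 * TN / (TN + FP)
    precision   = 100 * TP / (TP + FP)      accuracy    = 100 * (TP + TN) / N

A zero denominator yields NaN with a warning rather than an error.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .boundary import Cluster, cluster_foreground
from .config import PipelineConfig

logger = logging.getLogger(__name__)


@dataclass
class GroundTruth:
    """Expert annotation for one image: abnormality label plus one binary
    region mask per marked calcification cluster."""

    is_abnormal: bool
    regions: list = field(default_factory=list)  # list of bool ndarrays

    def __post_init__(self) -> None:
        if self.is_abnormal and not self.regions:
            raise ValueError("abnormal ground truth requires >= 1 region")
        if not self.is_abnormal and self.regions:
            raise ValueError("normal ground truth must have no regions")


def circles_to_region(
    shape: tuple[int, int], circles: list[tuple[float, float, float]]
) -> np.ndarray:
    """Rasterize (center_row, center_col, radius) circle specs into one
    filled binary region mask."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    mask = np.zeros(shape, dtype=bool)
    for r0, c0, rad in circles:
        mask |= (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
    return mask


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int


@dataclass(frozen=True)
class Metrics:
    sensitivity: float
    specificity: float
    precision: float
    accuracy: float


def match_detections(
    ir: np.ndarray, truth: GroundTruth, cfg: PipelineConfig
) -> tuple[int, int]:
    """Score one image's final mask against its truth regions.

    Returns ``(region_hits, extra_detections)``: the number of truth
    regions with >= ``min_match_pixels`` foreground pixels inside, and the
    number of predicted clusters reaching that overlap in no region.
    """
    ir = np.asarray(ir, dtype=bool)
    for region in truth.regions:
        if np.asarray(region).shape != ir.shape:
            raise ValueError("truth region shape differs from mask shape")
    k = cfg.min_match_pixels
    hits = sum(
        1 for region in truth.regions if (ir & np.asarray(region, bool)).sum() >= k
    )
    extras = 0
    for cluster in cluster_foreground(ir, cfg):
        rows, cols = cluster.pixels[:, 0], cluster.pixels[:, 1]
        inside_any = any(
            np.asarray(region, bool)[rows, cols].sum() >= k
            for region in truth.regions
        )
        if not inside_any:
            extras += 1
    return hits, extras


def image_confusion(
    results: list[tuple[bool, bool]],
) -> ConfusionCounts:
    """Tally (predicted_abnormal, label_abnormal) pairs into image-level
    confusion counts."""
    if not results:
        raise ValueError("image_confusion requires at least one result")
    tp = sum(1 for p, t in results if p and t)
    fn = sum(1 for p, t in results if not p and t)
    tn = sum(1 for p, t in results if not p and not t)
    fp = sum(1 for p, t in results if p and not t)
    return ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp)


def _rate(num: int, den: int, name: str) -> float:
    if den == 0:
        logger.warning("%s undefined (zero denominator); reporting NaN", name)
        return math.nan
    return 100.0 * num / den


def metrics(c: ConfusionCounts) -> Metrics:
    """Sensitivity, specificity, precision, accuracy in percent."""
    total = c.tp + c.fn + c.tn + c.fp
    if total == 0:
        raise ValueError("all confusion counts are zero")
    return Metrics(
        sensitivity=_rate(c.tp, c.tp + c.fn, "sensitivity"),
        specificity=_rate(c.tn, c.tn + c.fp, "specificity"),
        precision=_rate(c.tp, c.tp + c.fp, "precision"),
        accuracy=_rate(c.tp + c.tn, total, "accuracy"),
    )
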