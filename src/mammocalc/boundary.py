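"""Cluster grouping, boundary circles, and the end-to-end detector.

Calcifications present as *clusters* of scattered spots, and the clinical
report is one circle per cluster, not one per spot.  Foreground pixels of
the final mask are therefore grouped as 8-connected components which are
then agglomeratively merged whenever two components come within
``cluster_link_distance`` pixels of each other (minimum inter-pixel
Euclidean distance).  Each cluster is reported as a circle: centroid
center, radius = farthest member distance plus a fixed margin, so the
boundary always lies outside the abnormal area.

:func:`detect` runs the whole pipeline: normal-image gate, ratio-energy
map, intensity/energy thresholds (I_e), top-hat binarization (I_t),
intersection I_r, grouping, circles.  It is fully deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist

from .config import PipelineConfig
from .io import GrayImage, empty_mask
from .morphology import combine_masks, tophat_mask
from .normal_filter import is_abnormal_image
from .ratio_energy import ratio_energy_map
from .threshold_mask import compute_thresholds, energy_mask

logger = logging.getLogger(__name__)


@dataclass
class Cluster:
    """Foreground pixels grouped into one reported abnormality."""

    pixels: np.ndarray  # (n, 2) array of (row, col) coordinates

    @property
    def size(self) -> int:
        return int(self.pixels.shape[0])


@dataclass
class Detection:
    """A boundary circle around one cluster (real-valued pixel units)."""

    center_row: float
    center_col: float
    radius: float
    cluster: Cluster


def cluster_foreground(mask: np.ndarray, cfg: PipelineConfig) -> list[Cluster]:
    """Group mask pixels: 8-connected components, then merge components
    whose minimum inter-pixel distance is <= ``cluster_link_distance``.

    Output order is deterministic: by topmost, then leftmost member pixel.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return []
    comps = [np.argwhere(labels == i + 1) for i in range(n)]

    # union-find over components; components are small so pairwise
    # minimum distances are computed directly
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if find(i) == find(j):
                continue
            if cdist(comps[i], comps[j]).min() <= cfg.cluster_link_distance:
                parent[find(j)] = find(i)

    groups: dict[int, list[np.ndarray]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(comps[i])
    clusters = [Cluster(pixels=np.vstack(g)) for g in groups.values()]

    def anchor(c: Cluster) -> tuple[int, int]:
        top = int(c.pixels[:, 0].min())
        left = int(c.pixels[c.pixels[:, 0] == top, 1].min())
        return top, left

    clusters.sort(key=anchor)
    return clusters


def enclosing_circle(cluster: Cluster, cfg: PipelineConfig) -> Detection:
    """Centroid-centered circle containing every cluster pixel, with
    ``circle_margin`` of clearance."""
    if cluster.size == 0:
        raise ValueError("cannot fit a circle to an empty cluster")
    center = cluster.pixels.mean(axis=0)
    dists = np.hypot(*(cluster.pixels - center).T)
    return Detection(
        center_row=float(center[0]),
        center_col=float(center[1]),
        radius=float(dists.max() + cfg.circle_margin),
        cluster=cluster,
    )


def detect(
    img: GrayImage,
    cfg: PipelineConfig | None = None,
    *,
    skip_prefilter: bool = False,
) -> tuple[bool, list[Detection], np.ndarray]:
    """Full pipeline for one image.

    Returns ``(is_normal, detections, ir)`` where ``ir`` is the final
    foreground mask.  A normal image (per the prefilter) short-circuits
    with an empty mask and no detections; ``skip_prefilter`` forces full
    processing.
    """
    cfg = cfg or PipelineConfig()
    if not skip_prefilter and not is_abnormal_image(img, cfg):
        return True, [], empty_mask(img.pixels.shape)

    em = ratio_energy_map(img, cfg)
    ts = compute_thresholds(img, em, cfg)
    ie = energy_mask(img, em, ts)
    it = tophat_mask(img, cfg)
    ir = combine_masks(ie, it)
    logger.debug(
        "thresholds chi=%.1f epsilon=%.2f delta=%.2f; |I_e|=%d |I_t|=%d |I_r|=%d",
        ts.chi, ts.epsilon, ts.delta, ie.sum(), it.sum(), ir.sum(),
    )
    clusters = cluster_foreground(ir, cfg)
    detections = [enclosing_circle(c, cfg) for c in clusters]
    return False, detections, ir


def draw_overlay(img: GrayImage, detections: list[Detection]) -> GrayImage:
    """Copy of the image with 1-pixel circle outlines at full intensity."""
    out = img.pixels.copy()
    h, w = out.shape
    top = img.dynamic_range
    for d in detections:
        # sample the circle densely enough that the outline is connected
        n = max(16, int(np.ceil(2 * np.pi * d.radius * 2)))
        theta = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
        rr = np.rint(d.center_row + d.radius * np.sin(theta)).astype(int)
        cc = np.rint(d.center_col + d.radius * np.cos(theta)).astype(int)
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        out[rr[keep], cc[keep]] = top
    return GrayImage(out, bit_depth_hint=img.bit_depth_hint)
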