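"""Energy/intensity thresholding producing the foreground mask I_e.

Three global per-image thresholds:

* chi — an intensity floor, 90 % of a robust maximum intensity.  The
  robust maximum looks at the top two *distinct* intensity values; if they
  differ by more than a fraction (default 10 %) of the dynamic range the
  top value is treated as an outlier and the second is used.
* epsilon — the maximum ratio energy among pixels at or above chi (the
  intensity step is applied first, so dark high-RE pixels are ignored).
* delta — 80 % of epsilon.

A pixel joins the foreground mask I_e when its intensity is >= chi, its
ratio energy is >= delta, and it lies where the large window fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig
from .io import GrayImage
from .ratio_energy import EnergyMap


@dataclass(frozen=True)
class ThresholdSet:
    """Per-image thresholds: chi and robust_max in intensity units,
    epsilon and delta in ratio-energy percent."""

    chi: float
    epsilon: float
    delta: float
    robust_max: float


def robust_max_intensity(img: GrayImage, cfg: PipelineConfig) -> float:
    """Maximum intensity with single-outlier rejection.

    Returns the second-highest distinct value when the gap to the highest
    exceeds ``outlier_gap_fraction`` of the dynamic range, else the highest.
    A single-valued image returns that value.
    """
    vals = np.unique(img.pixels)
    v1 = float(vals[-1])
    v2 = float(vals[-2]) if vals.size >= 2 else v1
    gap_limit = cfg.outlier_gap_fraction * img.dynamic_range
    return v2 if v1 - v2 > gap_limit else v1


def compute_thresholds(
    img: GrayImage, em: EnergyMap, cfg: PipelineConfig
) -> ThresholdSet:
    """chi, epsilon, delta for one image (see module docstring).

    If no pixel reaches chi, epsilon = delta = 0 and the mask is empty.
    """
    rmax = robust_max_intensity(img, cfg)
    chi = cfg.intensity_fraction * rmax
    bright = img.pixels >= chi
    if bright.any():
        epsilon = float(em.values[bright].max())
    else:
        epsilon = 0.0
    delta = cfg.energy_fraction * epsilon
    return ThresholdSet(chi=chi, epsilon=epsilon, delta=delta, robust_max=rmax)


def energy_mask(img: GrayImage, em: EnergyMap, ts: ThresholdSet) -> np.ndarray:
    """Foreground mask I_e: intensity >= chi, RE >= delta, inside the
    energy map's valid region."""
    if img.pixels.shape != em.values.shape:
        raise ValueError("image and energy map shapes differ")
    mask = (img.pixels >= ts.chi) & (em.values >= ts.delta)
    mask &= em.validity_mask()
    return mask
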