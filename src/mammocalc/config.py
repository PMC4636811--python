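"""Pipeline configuration.

Every numeric constant of the detection pipeline is collected here so that a
single serializable record fully determines a run.  Defaults follow the
published operating point: 20x20 prefilter window with kurtosis/skewness
gates 14 and 2.3, 3x3 and 11x11 energy windows, a 90 % intensity threshold
and an 80 % ratio-energy threshold, a diamond structuring element with more
than 20 member pixels, and a 4.0-sigma top-hat binarization.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path


@dataclass
class PipelineConfig:
    """All tunable parameters of the calcification detector.

    Attributes
    ----------
    prefilter_window : int
        Side of the sliding window (pixels) used by the normal-image gate.
    kurtosis_threshold, skewness_threshold : float
        An image is processed further only if some window exceeds *both*
        (non-excess kurtosis and standardized skewness).
    small_half_width, large_half_width : int
        Half-widths of the two energy windows; defaults 1 and 5 give the
        3x3 and 11x11 footprints of the ratio-energy feature.
    intensity_fraction : float
        chi = intensity_fraction * (robust maximum intensity).
    energy_fraction : float
        delta = energy_fraction * epsilon (epsilon = max RE over bright pixels).
    outlier_gap_fraction : float
        Fraction of the dynamic range; if the top two distinct intensities
        differ by more than this, the top one is discarded as an outlier.
    se_radius : int
        Radius of the diamond structuring element (2r^2+2r+1 pixels; the
        default 3 gives 25 > 20 pixels, the smallest compliant diamond).
    tophat_sigma_multiplier : float
        Top-hat binarization keeps pixels strictly above this multiple of
        the top-hat image's population standard deviation.
    min_match_pixels : int
        A truth region counts as detected when at least this many final
        foreground pixels fall inside it.
    cluster_link_distance : float
        Connected components closer than this (pixels, minimum inter-pixel
        distance) are merged into one reported cluster.
    circle_margin : float
        Added to the max centroid-to-pixel distance when reporting circles.
    random_seed : int
        Seed for any stochastic helper; the detection pipeline itself is
        deterministic.
    """

    prefilter_window: int = 20
    kurtosis_threshold: float = 14.0
    skewness_threshold: float = 2.3
    small_half_width: int = 1
    large_half_width: int = 5
    intensity_fraction: float = 0.90
    energy_fraction: float = 0.80
    outlier_gap_fraction: float = 0.10
    se_radius: int = 3
    tophat_sigma_multiplier: float = 4.0
    min_match_pixels: int = 3
    cluster_link_distance: float = 30.0
    circle_margin: float = 5.0
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.small_half_width >= self.large_half_width:
            raise ValueError(
                "small_half_width must be strictly less than large_half_width"
            )
        if not 0.0 < self.intensity_fraction <= 1.0:
            raise ValueError("intensity_fraction must lie in (0, 1]")
        if not 0.0 < self.energy_fraction <= 1.0:
            raise ValueError("energy_fraction must lie in (0, 1]")
        r = self.se_radius
        if 2 * r * r + 2 * r + 1 <= 20:
            raise ValueError(
                "diamond structuring element must have more than 20 pixels "
                f"(radius {r} gives {2 * r * r + 2 * r + 1})"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        """Load from JSON or from a ``key=value`` lines file."""
        text = Path(path).read_text()
        try:
            return cls.from_dict(json.loads(text))
        except json.JSONDecodeError:
            pass
        d: dict = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            key = key.strip()
            val = val.strip()
            try:
                parsed: object = json.loads(val)
            except json.JSONDecodeError:
                parsed = val
            d[key] = parsed
        return cls.from_dict(d)
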