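# Methods

## Model and assumptions

`mammocalc` detects calcifications under three assumptions about the
imagery: (i) a calcification is a compact bright blob whose footprint is
small — about 20 pixels or fewer — and roughly the same across lesions, so
one fixed detection scale suffices; (ii) the surrounding tissue is smooth
at that scale, so a blob concentrates the local intensity mass; and
(iii) calcifications cluster spatially, so the clinically useful report is
one boundary per cluster, not per spot.

The core statistic is the ratio energy

RE(x, y) = 100 · Σ₃ₓ₃(x, y) / Σ₁₁ₓ₁₁(x, y),

the percentage of the 11×11 neighborhood's intensity mass held by its 3×3
core. It is scale-free in intensity (RE(c·P) = RE(P) for c > 0), bounded
in [0, 100], equals 100·9/121 ≈ 7.44 on locally uniform images, and
approaches 100 only when essentially all neighborhood mass sits in the
core. The two footprints (3×3, 11×11) are the detector's scale choice: the
small window should cover a spot's core and the large one its smooth
surround.

Decisions are made by global per-image thresholds (intensity floor
χ = 0.9 × robust max; energy floor δ = 0.8 × ε with ε the best RE among
bright pixels), refined by a white top-hat with a 25-pixel diamond
(removing anything too large to be a spot) binarized at 4 σ, and the two
binary masks are intersected. The global-threshold design implicitly
assumes the tissue the spots sit on has roughly uniform brightness; strong
shading across a single image shifts RE between regions and is *not*
compensated (see Limitations).

## Parameters

All constants live in `PipelineConfig`; the defaults are the pipeline's
published operating point and are deliberately not auto-tuned.

| parameter | default | units | meaning |
|---|---|---|---|
| `prefilter_window` | 20 | px | side of the moment-gate sliding window |
| `kurtosis_threshold` | 14 | — | non-excess kurtosis gate (Gaussian ≈ 3) |
| `skewness_threshold` | 2.3 | — | skewness gate (Gaussian ≈ 0) |
| `small_half_width` / `large_half_width` | 1 / 5 | px | 3×3 and 11×11 energy windows |
| `intensity_fraction` | 0.90 | — | χ as a fraction of the robust max |
| `energy_fraction` | 0.80 | — | δ as a fraction of ε |
| `outlier_gap_fraction` | 0.10 | of dynamic range | top-two distinct-value gap that rejects a lone hot pixel |
| `se_radius` | 3 | px | diamond radius; 2r²+2r+1 = 25 > 20 px, the smallest diamond above the spot-size bound |
| `tophat_sigma_multiplier` | 4.0 | σ | top-hat binarization level |
| `min_match_pixels` | 3 | px | region-hit criterion |
| `cluster_link_distance` | 30 | px | component merge radius for reporting |
| `circle_margin` | 5 | px | clearance added to reported radii |

Conventions that the published constants leave open, decided here once:

* **Moments.** Population (divide-by-n) central moments and non-excess
  kurtosis, so the 14/2.3 gates sit on the scale where a Gaussian window
  scores ≈ (3, 0). Zero-variance windows return (0, 0) and never trigger.
  Windows are enumerated at stride 1 over all fully-inside placements; the
  gate is an existence test, so anchoring is immaterial.
* **Borders.** The RE map is zero wherever the 11×11 window overhangs, and
  such pixels can never become foreground; erosion/dilation ignore
  out-of-image samples (±∞ padding). No intensities are fabricated.
* **Zero denominators.** RE := 0 where the large-window sum is 0; an
  all-dark neighborhood carries no blob evidence.
* **Ties.** Pixels exactly at χ or δ are foreground (≥); the top-hat
  binarization is strict (> 4 σ), so a constant image yields an empty
  mask.
* **Outlier gap.** The "certain threshold" for the top-two intensity
  comparison is a fraction of the dynamic range (so it scales with bit
  depth), applied to the top two *distinct* values.
* **ε ordering.** ε is maximized only over pixels that already pass χ:
  the intensity step precedes the energy step.
* **Grouping.** 8-connected components merged transitively whenever their
  minimum inter-pixel distance is ≤ 30 px, output sorted by
  topmost-then-leftmost pixel for determinism. The circle is centroid +
  max member distance + margin — the simplest boundary guaranteed to lie
  outside the cluster.

## Numerical choices

Window sums (energies) and the sliding moment maps are computed from
integral images: one cumulative pass, O(1) per window, which keeps the
whole pipeline linear in pixel count, with a fixed-size structuring
element doing the same for morphology. For the moment maps the image is
standardized globally first (both statistics are affine-invariant), and
tiny negative variances from floating-point cancellation are clamped to
zero; windows with variance ≤ 1e-12 report (0, 0). The runtime-linearity
test measures `detect()` at 128², 256² and 512² and requires per-pixel
time within a factor of two across the 16-fold size range.

## What the phantoms emulate — and what they do not

The generator produces the detector's intended operating conditions, not
difficult screening cases: a breast-like field (flat central tissue at
mean 100, smooth falloff to half brightness at the corners, Gaussian noise
σ = 5, 8-bit) and, in abnormal images, 3 clusters of 4 compact spots of
7–10 px at intensity 245 (+0..2 jitter) scattered within 18 px, planted in
the central tissue. Truth regions are the planted masks dilated by a
3-px diamond, mimicking a radiologist's loose outline. Spot pixels carry a
small intensity jitter because a perfectly constant top value reads as a
single repeated intensity, which the top-two-distinct-value outlier rule
would misinterpret as one hot pixel.

Two generator choices were driven by the method's own assumptions. Spots
are drawn from a narrow size range because the global δ = 0.8 ε band only
tolerates modest RE spread between the strongest and weakest spot. And the
tissue under the clusters is flat because ε is a global maximum: in an
early design with strong shading across the planting area, clusters on
darker tissue set ε high enough that clusters on brighter tissue fell
below δ — a real failure mode of the method, not of the implementation.

Consequently, passing the phantom suite (≥ 90 % image-level sensitivity
and specificity and ≥ 90 % cluster hits on a 50+50 seeded set; in practice
the defaults score 100 % with ~0.02 extra clusters per abnormal image)
shows the pipeline works under its stated assumptions. It does *not* show
robustness to the things real mammograms add: pectoral muscle and skin-line
structure, film artifacts, dense-tissue texture, blobs at the detection
scale that are not calcifications, or lesions at the extreme image border
(outside the RE valid region by construction).

## Evaluation conventions

An image is predicted abnormal when the moment gate passes it *and* at
least one cluster survives to the report. Rates are computed from the 2×2
image-level table using the standard definitions: sensitivity
TP/(TP+FN) over abnormal cases, specificity TN/(TN+FP) over normal cases.
On a published 84-image tally of (TP, FN, TN, FP) = (29, 1, 49, 5) these
definitions give 96.7 % on the abnormal cases and 90.7 % on the normal
cases (93 % accuracy, 85 % precision); reports that quote "91 %
sensitivity, 97 % specificity" for the same table have the two labels
swapped, and this package always computes from the counts rather than
echoing labels.

## Known limitations

* Global thresholds assume per-image uniform tissue brightness; no local
  adaptation or breast segmentation is performed.
* The intensity-fraction threshold is not monotone in its effect on the
  final mask (raising χ can lower ε and δ and admit different bright
  pixels); only the energy fraction has a clean monotone effect.
* A lone bright pixel on an otherwise near-black image is rejected by the
  outlier rule, which then drops χ to the runner-up value — correct for
  hot-pixel artifacts, surprising for genuinely minimal inputs.
* The cluster link distance (30 px) and circle margin (5 px) are reporting
  conventions, not estimates; clusters closer than the link distance merge
  into one circle.
* No malignancy classification, BI-RADS scoring, or mass/calcification
  discrimination; the output is candidate calcification regions only.
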