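# Methods note

`segnew` segments surgical instruments without any instrument annotations.
The premise: instruments are the only image content that is both *new*
relative to an instrument-free reference set and *instrument-like* under a
cheap domain prior. The pipeline is

1. **anomaly localization** against a memory bank of nominal patch features,
2. **domain filtering** to suppress anomalous-but-not-instrument pixels,
3. **point-prompt generation** from the filtered score map,
4. **three mask proposals** from a promptable segmenter backend,
5. **proposal selection** by overlap with the binarized score map.

This note states the model, every parameter with its default and rationale,
what the synthetic generator does and does not emulate, the numerical
choices, and the known limitations. Nothing here claims empirical results
that the test suite or `scripts/acceptance.py` does not compute.

## 1. Anomaly localization (memory bank)

**Features.** Each image is divided into stride-aligned cells (default stride
4). Per cell and per scale (defaults: scales 1 and 2, i.e. the cell and its
2× surround) the extractor records the mean and standard deviation of each
channel plus a gradient-orientation histogram (default 8 bins). Features are
computed exactly with integral images; a neighborhood average over a
`window × window` cell block (default 3, edge-truncated) adds local context,
mirroring the local-aggregation step of patch-based anomaly detection. The
extractor is deliberately weights-free: the package must run without any
pretrained network, so a hand-crafted descriptor replaces deep features. This
is the main fidelity compromise of the re-implementation.

**Bank.** Features from instrument-free ("nominal") images are pooled and
reduced with greedy farthest-point (k-center) coreset selection to a fraction
`coreset_ratio = 0.1` of the pool — the standard memory-bank subsampling
ratio, keeping bank size and query cost roughly an order of magnitude below
the raw pool while preserving coverage of feature space. The greedy start
index defaults to a seeded random draw; fixing the seed (default 0) fixes the
bank bit-for-bit.

**Scoring.** A query patch's anomaly score is its Euclidean distance to the
nearest bank vector (1-NN). A `k`-mean variant (mean distance to the `k`
nearest, default `k_neighbors = 9`, off by default) is exposed because
re-weighting with ~9 neighbors is common in the source method; on the
synthetic study conditions it measured no better than 1-NN, so 1-NN remains
the default. The patch-score grid is bilinearly upsampled to pixel resolution
and smoothed with a Gaussian (`smoothing_sigma = 4` px, the conventional
value for blending patch scores into a per-pixel map).

**Calibration.** Scores are affinely mapped to [0, 1] with min–max bounds
recorded from a few *instrument-containing* calibration images (then
clipped). Using instrument examples to set the max is what makes "1" mean
"as anomalous as an instrument"; no masks are needed, only the knowledge that
the calibration frames contain instruments.

## 2. Domain filters

**Color (`filter = "rgb"`).** Tissue is reddish, bright and saturated;
instruments are gray. With per-image maxima,

F_RGB = 1 − (a*/max a*₊ + V/max V + S/max S) / 3,

where a* is the CIELAB red–green channel (max over pixels with a* > 0) and
V, S are HSV value and saturation. Each ratio is clipped to [0, 1] before
averaging, and a channel with no positive maximum contributes 0; the final F
is clipped to [0, 1]. A pixel attaining all three maxima gets F = 0 exactly.

**Intensity (`filter = "intensity"`).** Reflective instruments cast
near-black shadow columns that are themselves anomalous (absent from nominal
scans). F_intensity = I / max I multiplies the anomaly map by the normalized
signal, so F — and hence the instrument score map — is *exactly* 0 wherever
the recorded signal is 0. Signed acquisitions are offset-shifted to be
non-negative first; an all-zero image maps to an all-zero filter.

**Instrument score map.** SI = A · F, pixel-wise.

## 3. Prompt generation

The SI map is min–max rescaled per image (so any frame with SI contrast can
yield prompts), binarized at a size-derived threshold — 0.65 when instruments
cover roughly 35 % of the frame, 0.85 for roughly 15 % — and split into
8-connected components. Each component contributes one positive prompt at
its (raw-SI) argmax; ties resolve row-major. If binarization is empty the
global argmax serves as a single fallback prompt; an all-zero SI map yields
an empty prompt set flagged `no_instrument`. An optional negative prompt
(off by default) marks the SI argmin inside the centered window covering
`negative_central_fraction = 0.5` of each dimension, for modalities with
dark information borders.

**No-instrument gate.** If the calibrated SI maximum falls below
`min_si = 0.2`, the pipeline emits an empty prompt set and an empty mask.
0.2 is conservative: it prefers occasional false positives on nominal frames
over missed instruments (see limitations).

## 4. Mask proposals and selection

A backend receives the image and the prompts and must return **exactly three**
candidate masks with confidences in [0, 1] — the contract of promptable
foundation segmenters. The shipped reference backend is a deterministic
seeded region grower: mask *i* is the union over positive prompts of the
connected component (8-connectivity) of pixels whose value differs from the
seed value by at most tolerance *i* (Euclidean over channels for RGB), with
tolerances {1, 2, 4} × `base_tolerance_frac = 0.08` of the image value range.
Membership is a global threshold on distance-to-seed-value, so the three
masks are nested by construction. The region grown from the negative prompt
is computed once at the *largest* tolerance and subtracted from all three
masks — subtracting per-tolerance would break nestedness — and positive
prompt pixels are always re-included. Backend confidences are 1/(1 + tol)
rescaled to [0, 1].

The final mask is the proposal with the highest IoU against the binarized SI
support; ties break by backend confidence, then lower index. A both-empty
pair scores 0 here (an empty proposal never wins), deliberately unlike the
evaluation convention below.

## 5. Metrics

IoU and DICE use the evaluation convention both-empty → 1 (agreement on
absence). Boundary pixels are mask pixels with a 4-neighbor outside the mask,
the image border counting as outside. NSD(A, B, τ) is the symmetric fraction
of boundary pixels of each mask lying within exact Euclidean distance τ of
the other's boundary (τ = 10 px default, the tolerance used for color
surgical scenes); both boundaries empty → 1. Prompt accuracy counts a frame
as a hit when any positive prompt lies inside the reference mask, or, for an
empty reference, when no prompt was emitted. Reported spreads are population
standard deviations over frames.

## 6. Synthetic scene generator

The generator replaces external datasets and pretrained weights; **its
defaults are the study conditions** and were not tuned against outcomes.

**Color domain** (128 × 128 × 3, the pipeline's color working resolution):
low-frequency reddish HSV tissue texture (hue ≈ 0.98–1.02, saturation
0.4–0.9, value 0.3–0.8, 16-px texture cells), two white specular highlight
disks, and gray capsule-shaped instruments (saturation < 0.15, value
0.25–0.55 ± 0.04 texture modulation; default width 0.08 and length 0.6 of
√(H·W)).

**Intensity domain** (92 × 256, the B-scan working resolution): background
floor 0.06; one to three curved Gaussian-profile tissue bands (intensity
0.55–0.8) composited with a saturating opacity blend (ceiling 0.82) so that
band crossings stay strictly below the instrument range — with naive additive
compositing crossings saturate and become locally indistinguishable from an
instrument, making localization ill-posed for any method; a bright instrument
arc (level 0.90–0.98) in the upper quarter (rows 0.12–0.24 H); multiplicative
speckle with σ = 0.15 (instruments get σ/4: specular metal returns a cleaner
signal than diffusely scattering tissue); and a shadow column below the
instrument at 0.02 transmission.

**Not emulated:** realistic tissue anatomy and vascularity, instrument
texture/specularity detail, motion blur, occlusions between instruments and
tissue, illumination falloff, sensor vignetting, and inter-frame temporal
coherence. Conclusions from the synthetic study do not transfer to clinical
data; the generator exists to exercise and verify the pipeline's mechanics.

**Reproducibility.** Per-image seeds derive as
`(dataset_seed · 1 000 003 + index · 7 919 + 17) mod (2³¹ − 1)`, so datasets
regenerate byte-identically from their JSON manifest and appending images
never reshuffles earlier ones.

## 7. Numerical choices

- All feature/score arithmetic in float64; exact pairwise distances via
  `scipy.spatial.distance.cdist` in memory-bounded chunks.
- Block statistics via integral images (`cumsum` + `reduceat`), exact up to
  float64 rounding; oracle tests assert 1e-12 absolute agreement with
  brute-force re-computation.
- Distance transforms are exact Euclidean (`distance_transform_edt`), not
  chamfer; boundary erosion uses the 4-connected cross structure.
- Score maps travel as float32 TIFF; masks as {0, 255} PNG; bank as `.npz`
  plus JSON metadata with a SHA-256 content hash recorded in run provenance.
- Images resize to the working resolution bilinearly; the final mask
  upsamples to the input resolution with nearest-neighbor so it stays binary.

## 8. Limitations

- The weights-free descriptor is far weaker than the deep features of the
  source method; absolute scores are not comparable to published numbers.
- The no-instrument gate (`min_si = 0.2`) separates nominal from instrument
  frames in the intensity domain, but in the color domain the nominal and
  instrument SI-maximum distributions overlap under this descriptor — no gate
  value separates them, so nominal color frames may yield spurious masks.
- The region-grow backend assumes instruments are locally homogeneous in
  value; it under-segments textured instruments and can leak through
  low-contrast boundaries. It is a stand-in for a promptable foundation
  segmenter, which can be registered as an external backend.
- Min–max calibration is sensitive to the single most anomalous calibration
  patch; a quantile scheme would be more robust but would depart from the
  method being re-implemented.
- Single-frame only: no temporal smoothing or tracking.
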