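# Methods

This note documents the models, parameter choices and numerical
conventions behind `chromatex`, and what the synthetic benchmarks do and
do not demonstrate about real microscopy data.

## Image model and preprocessing

All analyses operate on single 2-D channels of non-negative integers with
an explicit bit depth (8 or 16). Texture analysis requires 8-bit input;
16-bit acquisitions are converted by a per-image linear min–max rescale
onto [0, 255] with round-half-up. The rescale is monotone (pixel ordering
is preserved) and idempotent on 8-bit input; a constant image maps to the
constant 0 rather than raising, because downstream closed-form checks use
constant inputs. A fixed-range conversion is available where per-image
normalisation is undesirable (e.g. comparing absolute intensities across
images); note that the min–max choice makes texture features invariant to
affine intensity changes that preserve quantization bins, which is usually
what one wants for pattern statistics.

Coordinates are (row, col), 0-based, origin top-left, half-open bounds.

## Grey-level co-occurrence texture

Pixels inside a nuclear ROI are quantized into G uniform bins of the 8-bit
range (level = v·G // 256). The co-occurrence matrix for offset
(distance d, angle θ ∈ {0°, 45°, 90°, 135°}) counts ordered pairs whose
**both** endpoints lie inside the ROI — background around an irregular
nucleus can never leak into the matrix — optionally adding each pair's
reverse (symmetric mode), then normalises to probabilities. Five features
are computed per matrix: ASM, contrast, correlation, IDM and entropy
(log base 2, so entropy is in bits with maximum 2·log₂G). With several
angles, features (not matrices) are averaged with equal weight.

Numerical conventions:

* 0·log 0 := 0 in the entropy sum.
* Correlation is undefined when a marginal standard deviation is zero
  (e.g. a constant ROI). It is flagged and excluded from aggregation, not
  coerced to 0 or 1; per-angle averaging uses only the defined angles.
* Correlation is clipped to [−1, 1] against rounding error.

Defaults: G = 32, d = 1, all four angles, symmetric, features averaged
over angles. G = 256 would use the raw 8-bit levels, but on nuclear ROIs
of a few hundred pixels a 256×256 matrix is extremely sparse and the
correlation estimate unstable; 32 levels keep bin widths (8 grey values)
well below the intensity contrasts of interest. All settings are recorded
in every output.

Per-nucleus profiling erodes each nucleus mask by 1 px before pairing
(`boundary_erosion_px`, settable to 0). Threshold-based segmentation
overshoots the true nuclear outline by about a pixel, and the dark rim of
background pixels this drags in otherwise dominates every second-order
statistic — it is enough to flip the sign of the correlation change
between study arms. Erosion is skipped when it would empty a mask.

Per-sample aggregation is the unweighted mean of per-nucleus features
(undefined correlations excluded and counted). Percent change is
100 × (treated − control) / control per feature, NaN-flagged when the
control mean is 0.

### Pattern interpretation

Three chromatin patterns are called from the per-feature percent changes
via a signed association map:

* homogeneity: ASM (+), entropy (−), IDM (+)
* heterogeneity: correlation (−), entropy (+)
* contrast: contrast (+), IDM (−)

Each feature with |change| ≥ 5% votes through its association sign;
unanimous votes call the pattern increased/decreased, all-below-threshold
calls it unchanged, conflicts give indeterminate, and the votes are
returned with the call. The 5% default is just below the smallest change
treated as meaningful in this literature (≈6%); the association map is a
single table constant that can be replaced wholesale.

## Segmentation

Nuclei: Gaussian smoothing (σ = 2 px) → global Otsu threshold → hole
filling → optional watershed split of touching objects (markers are local
maxima of a lightly smoothed distance transform; the smoothing prevents
the flat ridge of an elongated ellipse from seeding spurious markers) →
area filter [100, 10 000] px² → optional border-object removal → label
compaction. Fully deterministic; a constant image yields zero nuclei
rather than an error. Defaults are sized for nuclei of ~12–18 px radius
and are all overridable.

Compartments: epithelium = Otsu-thresholded, hole-filled cytokeratin mask
(hole filling matters because cytokeratin is cytoplasmic and the nuclei
punch holes in it); nuclear compartment = segmented nuclei ∩ epithelium;
cytoplasmic = epithelium − nuclear. Labels {0 background, 1 cytoplasmic,
2 nuclear}; the two foreground compartments are disjoint by construction.

## Focus detection

Multi-scale Laplacian-of-Gaussian blob detection (σ ∈ [1, 2] px over five
scales) over the whole channel, with detections assigned to the nucleus
containing them; detections outside every nucleus are discarded. The
response threshold is the larger of

* the relative term: `detection_threshold` × channel dynamic range × ½
  (a Gaussian spot of amplitude A peaks at ≈ A/2 in scale-normalised LoG
  response), and
* a robust noise floor: 6 × (1.4826 · MAD of the fine-scale LoG response),
  which keeps a channel containing nothing but read noise at zero
  detections — any purely relative criterion fires on noise maxima there.

Both terms scale linearly with image gain, so counts and the positive
fraction are invariant to global intensity rescaling. Maxima closer than
`min_separation` (3 px) are merged, keeping the brighter; this tolerates
±1 px localisation jitter without merging genuinely distinct spots, whose
generator-enforced spacing is ≥ 4·focus_sigma = 4 px.

A cell is focus-positive when count > cut-point (default 5); exactly 5
counts as negative background. Fewer than 100 analysed nuclei triggers a
warning (not an error) because positivity fractions are unstable below
that.

## Compartment quantification

The score of a compartment is its mean target intensity (total / pixel
count), in arbitrary units. No further normalisation is applied — the
commercial score it stands in for applies an undocumented proprietary
normalisation, so the documented mean is used instead. Empty compartments
score NaN and are flagged. The epithelium fraction is epithelial pixels /
core pixels; the core mask defaults to the whole frame (per-core TMA
images are typically cropped to the core) and can be passed explicitly,
as the pipeline does with the generator's truth core. Cores with fraction
strictly below 0.05 are excluded; exactly 0.05 is retained (literal
reading of a "<5%" rule). The filter is idempotent and partitions its
input.

## Statistics

Mann-Whitney U: midranks for ties; U reported for the first group. With
combined n ≤ 20 and tie-free data the two-tailed p is exact — the null
distribution of U over all C(n_a+n_b, n_a) rank assignments is built by a
subset-sum dynamic program, and p = min(1, 2·min(P(U ≤ u), P(U ≥ u))).
Otherwise the normal approximation with tie correction and 0.5 continuity
correction is used. The switch point suits this domain: xenograft arms
have a handful of samples each, where exactness matters and enumeration
is cheap. No multiple-testing correction is applied by default (per-
feature p-values are reported unadjusted, as is conventional for these
five correlated features); a Holm option exists.

Student's t: pooled variance, two-tailed, df = n_a + n_b − 2. Zero pooled
variance with equal means gives t = 0, p = 1; with unequal means p = 0,
flagged — scipy returns NaN for both, which is useless downstream.

Group comparison of texture tables runs one test per feature on
per-sample means by default (per-nucleus pooling is available but
pseudo-replicates nuclei within a coverslip); NaN correlations are
dropped per group with counts recorded.

## Synthetic scenes

The generator emulates the three study image classes with full ground
truth; one numpy Generator seeded from `SceneSpec.seed` drives every draw,
so equal (spec, seed) gives bit-identical scenes.

**Texture scenes.** Elliptical nuclei (mean radius 12–18 px, eccentricity
1.0–1.6, non-overlapping with 2 px clearance, border-free by default) on a
256² canvas, 12 per scene. Control interiors are base_level (120) plus a
smooth Gaussian random field (correlation length ≈ mean radius/4,
sd `field_sd` = 10 — visible structure a few quantization bins wide,
matching the mild mottling of untreated nuclei). Treated interiors
additionally receive granules of radius 1–2 px: half condensed at
base_level × clump_gain (1.2) and half depleted at base_level × (2 −
clump_gain), each covering clumpiness/2 of the nuclear area. The
symmetric bright/dark split conserves the nuclear mean exactly, so
texture features respond to pattern, not to gain, and it keeps the
feature means monotone in clumpiness through 0.8 — a bright-clumps-on-
dimmed-background binary mixture cannot do that, because a two-level
mixture's disorder peaks at 50% coverage. Granules are deliberately small:
coarse clumps (radius ≳ 2.5 px) make neighbouring pixels *more* similar
and push lag-1 correlation up, the opposite of the condensation
signature. Gaussian read noise (sd 5) is added everywhere; clump_gain is
capped at 2 so the depleted level stays non-negative.

**Foci scenes.** Isotropic Gaussian spots (σ = 1 px, peak 150) at
uniformly drawn in-nucleus positions with pairwise separation
≥ 4σ and 2σ clearance from the nuclear boundary. Placement is greedy
packing over a shuffled list of candidate pixels with retries; σ = 1 was
chosen so that 12 spots fit the smallest default nuclei. Default
peak/noise = 30 is a bright, clean preparation; recovery benchmarks state
results at this SNR only.

**TMA scenes.** A circular core (radius 0.45 × frame); the epithelium is a
smooth random field thresholded at the quantile matching the requested
fraction (so the realised fraction tracks the request to within
discretisation); nuclei are placed inside the eroded epithelium; the
target channel carries the nuclear level on nuclei, the cytoplasmic level
on the remaining epithelium, plus noise.

### What the benchmarks do and do not show

Scenes have no point-spread function, no chromatic aberration, no uneven
illumination, no out-of-focus light, no overlapping nuclei (unless
constructed), and hard-edged geometry. Passing the recovery benchmarks
therefore demonstrates the *algorithms are correctly implemented and
internally consistent* — segmentation recovers the geometry it was
designed for, the focus detector is exact at high SNR, compartment scores
are unbiased under additive noise — not that the defaults are tuned for
any particular microscope. Likewise, the treated-arm percent changes the
texture study reports are properties of the generator's condensation
model; only their *directions* (ASM/correlation/IDM down, entropy/
contrast up, and the reversal when the regimes are swapped) are the
scientifically meaningful reproduction, and their magnitudes should not
be compared to any tissue measurement. Real acquisitions additionally
need per-study choices of quantization, offsets and segmentation
parameters, which every output records for that reason.

### Problem sizes

Study-scale computations use 20 seeds per arm (texture comparison and
monotonicity sweep at clumpiness 0/0.4/0.8), 20 scenes for segmentation
and focus recovery (240 nuclei with planted counts 0–12), 50 random grids
for the GLCM oracle check and 200 random small-sample pairs for the
Mann-Whitney oracle check; the demo pipeline runs 2 arms × 5 coverslips.
These sizes put Monte-Carlo noise well below the effects measured while
keeping a full run around half a minute.

## Known limitations

* 2-D only; no z-stacks, time series or proprietary microscope formats.
* Watershed splitting resolves touching, not overlapping, nuclei.
* The five implemented features are the classic co-occurrence set; the
  remaining Haralick statistics, run-length and wavelet textures are out
  of scope.
* Focus morphometry (size/intensity) and inter-channel colocalisation are
  not measured.
* The compartment score's arbitrary units are comparable within a study
  only; no cross-slide normalisation is attempted.
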