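# Methods

## Overview

The pipeline quantifies immunohistochemical deposit loads in brightfield
H-DAB tiles and compares them across α-synuclein distribution subgroups of
advanced-stage Alzheimer cases. Because the kind of cohort it targets is
not freely downloadable, a first-class synthetic-data module generates both
the imaging inputs (tiles with per-pixel ground truth) and the tabular
inputs (per-subject, per-region covered areas with known group structure),
so every downstream stage is validated against a known truth.

## Forward image model and stain separation

A tile is composed in optical-density (OD) space and rendered through
Beer–Lambert: `I_c = I0_c · 10^(−Σ_s OD_s · v_{s,c})`, quantized to 8 bits.
Stain directions are the standard Ruifrok–Johnston hematoxylin
(0.650, 0.704, 0.286) and DAB (0.268, 0.570, 0.776) unit vectors with a
normalized cross-product residual completing the basis; the mixing matrix
must have condition number below 10³. Deconvolution floors intensities at 1
(finite OD at saturation), applies the inverse matrix, and clips negative
unmixed values to zero. Because generation and deconvolution share one
matrix, deconvolution is the exact algebraic inverse of the forward model
up to 8-bit quantization; the measured mean |ΔOD| is ≈ 0.001, and tests
assert < 0.02.

The DAB OD map is rescaled to [0, 1] by a fixed global constant (OD 2.0 →
1.0, saturating above). The constant is deliberately not per-image so that
classifier inputs are comparable across tiles; only monotonicity of this
mapping matters downstream.

## Synthetic tiles

Per-pixel truth labels are background, nucleus, diffuse physiological
staining, and dense deposit (priority: deposit > nucleus > diffuse when
strokes overlap).

* **Nuclei**: Poisson-placed ellipses, 5–8 µm diameter, hematoxylin OD
  0.5–0.9, default density 1500/mm² (a plausible cortical gray-matter
  figure at 20× scanning).
* **Diffuse staining**: a smooth random field (Gaussian-filtered noise,
  squared) with mean OD equal to `diffuse_background_level` (default 0.08)
  and hotspots up to 3× that level. It is explicitly labeled non-deposit:
  the α-syn classifier must learn to ignore it.
* **Dense deposits**: three morphology classes mixed 0.5/0.3/0.2 —
  filled discs/ellipses of 5–25 µm diameter (Lewy-body analog),
  random-walk tubes 1–3 µm wide and 15–60 µm long (Lewy-neurite analog),
  and annulus-plus-core figures (plaque/tangle analog). These match the
  morphological classes of interest without claiming biological realism.
  Deposit OD is a 0.7–1.3 base modulated by a smooth internal texture in
  [0.18, 1]; parts of each deposit therefore dip toward the diffuse range,
  which is what makes context features genuinely informative (a fixed OD
  threshold cannot label those pixels without also labeling diffuse
  hotspots). A floor keeps every deposit pixel above the diffuse level
  pre-noise. Independent per-pixel OD noise (SD 0.03) is added last.

Shapes are placed until the realized dense-deposit fraction reaches the
target, with late shapes size-capped; the realized fraction stays within
±30% of the target (exactly zero for a zero target). Identical specs
(including seed) give bit-identical tiles.

## Pixel classification

Features: raw intensity plus five operators (Gaussian smoothing, DC-
corrected Laplacian of Gaussian, gradient magnitude, difference of
Gaussians with a 1.6 ratio, local variance) at σ ∈ {0.7, 1.6, 3.5, 7} px —
the ilastik-style family. The truncated discrete LoG kernel leaks a small
DC term at small σ; we subtract it so constant inputs map to exactly zero.

The forest uses 100 trees, unlimited depth, a fixed seed, and balanced
per-class pixel subsampling (deposits are rare; the library default budget
is 200 k px/class, the pipeline's synthetic runs use 20 k). Binary labels:
dense deposit vs everything else, so diffuse staining is a *negative*
training class by construction. The deposit probability is thresholded at
0.7, inclusive (the ≥ convention is asserted by tests). Validation follows
a 10-train / 10-test protocol on independent tiles; we validate against
synthetic ground truth rather than per-image reference classifiers, which
is the appropriate oracle when truth masks exist. The suite asserts
held-out prediction accuracy ≥ 0.9 (measured ≈ 0.9999), diffuse
false-positive rate < 5% (measured ≈ 0.02%), covered-area error at a 5%
target ≤ 1.5 points (measured ≤ 0.05), and strict superiority over the
best fixed OD threshold swept over [0.06, 0.42].

## Tiling and covered area

Annotations (polygons in pixel coordinates, origin top-left) are covered by
a half-open grid of 4096² px tiles anchored at the bounding-box floor.
Partial edge tiles are retained and flagged, and covered-area denominators
use true in-annotation pixel counts (pixel-center-in-polygon rule), so
per-tile counts sum exactly to the annotation's pixel count; dropping or
padding edge tiles would bias small regions. Covered area is
`100 · positives / denominator`; pooling disjoint tiles equals the
pixel-count-weighted aggregate by construction. Synthetic experiments use
192–256 px tiles — at 0.22 µm/px a 42–56 µm field — which keeps the full
train/validate cycle at a few seconds while exercising the identical code
paths as production-size tiles, whose geometry is tested separately.

## Region registry and subgroup assignment

The 28-region registry (shipped as a versioned CSV, fully overridable) maps
regions to five analysis clusters; regions not placed by convention default
to: frontal/cingulate/insular/temporal/parietal/striate gyri and sulci and
the parahippocampal gyrus → cortical; claustrum, putamen, both thalami,
cerebellar cortex, dentate nucleus → subcortical; CA1–CA4 and subiculum →
hippocampal; amygdala and entorhinal cortex → amygdala–entorhinal;
substantia nigra and locus coeruleus → brainstem; olfactory bulb →
unassigned (excluded from cluster regressions, reported separately).
Substantia nigra and locus coeruleus carry two annotations whose mean is
the regional value; aggregation drops QC-failing rows and averages the
rest.

Assignment: max regional load ≥ 0.3% ⇒ αSyn+ (inclusive boundary); else
αSyn− only if the amygdala was stained, otherwise the case is *ineligible*
with a recorded reason. Positives: subgroup C if the cortical mean
(cingulate, superior temporal, middle temporal, insular gyri; mean over
available listed regions) ≥ 0.3%, else B if the brainstem summary (SN, LC,
or their mean) ≥ 0.3%, else A. Precedence C > B > A: cortical spread
dominates because cortical cases typically also carry high brainstem load,
and A is the residual positive class. "Medial temporal gyrus" is read as
the middle temporal gyrus (registry region 10). If no listed cortical
region is available for a positive case, assignment falls through to the
B/A logic with a recorded warning. Assignment is total over eligible
subjects and monotone: raising any regional load never moves a case from
positive to negative (property-tested).

## Synthetic cohorts

Covered areas are log-normal on the percent scale — strictly positive and
right-skewed, matching how such loads distribute — with cluster-specific
medians per subgroup: negatives near zero everywhere; A high only in
amygdala–entorhinal (median 0.7%); B high in brainstem (1.0%); C cortical
spread (0.8%) with the highest amygdala–entorhinal load (1.5%) and
moderate brainstem involvement (0.5%). Tau medians order
amygdala–entorhinal > hippocampal > cortical ≫ brainstem/subcortical, and
amyloid-β is highest cortically, as in advanced-stage disease. These
presets are calibrated qualitatively to the reported load patterns, not
fitted — per-subgroup distribution parameters are not published.

Default subgroup sizes are 29/15/5/22 (negative/A/B/C, n = 71).
Demographics: age ~ N(72.8, 11.5²) truncated to [40, 100]; 56% female;
58% ApoE4 carriers; Braak IV:V:VI = 8:14:50; Thal 3:4:5 = 2:7:60; TDP43
negative:positive:unknown = 25:24:23. Covariate effects (age slope, female
offset, ApoE4 offset per stain) act additively on the log-linear predictor;
the easy preset sets them to zero, the realistic preset uses modest values
in the directions reported for advanced disease (female amyloid-β +0.3,
male tau +0.25, ApoE4 amyloid-β +0.3). Duplicate SN/LC annotations add
log-scale noise of SD 0.1 around the regional latent. Missingness is
missing-completely-at-random per subject × region × stain (0 in the easy
preset, 15% in the realistic one), except that intended-negative subjects
always keep their amygdala α-syn record — the eligibility requirement; no
richer missingness mechanism is assumed because none is documented.
Demographics are drawn complete (missingness applies to measurements only).

The easy preset separates subgroups by ≥ 3.4 log-SD at every decision
threshold, so downstream assignment recovers the generating truth for 100%
of subjects; on the realistic preset, confusions are confined to
threshold-adjacent or missing-region cases.

## Statistics

Responses are regressed on the **fraction** scale (percent / 100); printed
effect magnitudes in the field are consistent with that scale, and only
sign/ordering of effects is treated as transferable. Pairwise contrasts
are fitted on the two-label subset (the simplest faithful reading of
"compared pairwise"), with region as a categorical fixed effect and
optional age/sex (and ApoE4) covariates. Rank-deficient or
zero-residual-df designs return flagged results, never silent drops; a
single-region subset degenerates gracefully (the no-covariate β is exactly
the difference of group means). The mixed control adds a per-subject
random intercept fitted by REML (statsmodels MixedLM, default optimizer);
at zero between-subject variance the variance component sits at the
boundary and β coincides with OLS (asserted to 10⁻⁶), and under strong
subject effects its type-I error is no worse than OLS's (200-replicate
simulation).

χ² tests use Yates continuity correction iff the table is 2×2 and plain
Pearson otherwise — the policy that reproduces all ten published
demographic statistics at one decimal. BH-FDR is applied within one
analysis family, by default the five cluster-level p-values of one contrast
analysis ("for each analysis, respectively"); the family is configurable.
Age bands are < 65, 65 ≤ a < 75, ≥ 75; ApoE4 carriage means ≥ 1 ε4 allele.

Calibration simulations draw two-arm datasets (20 subjects/arm, 4 regions,
baseline fraction 0.01, noise SD 0.005, demographics as in the cohort
generator) from child streams spawned off a single `SeedSequence`, so
replicates are independent and the whole simulation is reproducible from
one integer. Measured: null rejection rate ≈ 0.05–0.06 (binomial 95% band
at 200 replicates is [0.02, 0.08]), effect-sign recovery 100% and ±2 SE
coverage ≈ 0.92–0.94 at an injected +0.01 fraction offset.

## What the synthetic data does not show

Synthetic tiles lack real tissue texture, staining artifacts, section
thickness variation and scanner color response; passing segmentation tests
therefore demonstrates the correctness of the pipeline's mechanics (feature
extraction, training protocol, thresholding, area accounting), not
performance on real slides, where accuracy will be lower and model
retraining per stain is expected. Cohort presets encode qualitative load
patterns, not fitted distributions, so statistical results on synthetic
cohorts validate calibration and recovery properties, not cohort-specific
effect sizes. Cross-stain registration, slide scanning, staging and
variant calling are upstream of this package and consumed as inputs.

## Known limitations

* The area-accuracy formula `1 − |Δ| / max(pred, ref)` is one reasonable
  concretization of a verbally defined metric (degenerate 0/0 case defined
  as 1).
* Whether a case exceeding both cortical and brainstem thresholds should be
  C is implied but not certain; C-precedence is a documented choice.
* Cluster membership of the parahippocampal gyrus, cerebellar regions and
  olfactory bulb is conventional and overridable.
* The mixed model's p-values near the variance boundary rely on asymptotic
  SEs; flagged non-convergence is surfaced, not hidden.
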