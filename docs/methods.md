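# Methods

## The classification procedure

Each field of view (FoV) is one tile of a multiphoton scan, by default
104 × 208 pixels at 1 µm/px (104 µm × 208 µm of tissue). Channels (CARS,
TPEF, SHG) are processed independently and concatenated only at the feature
level.

**Normalization.** Every FoV is min–max normalized, (x − min)/(max − min),
before any statistic is computed. This removes absolute intensity — which
varies with laser power, depth and detector gain — and makes all downstream
features invariant under positive affine transforms of the raw counts. A
constant FoV maps to all zeros and is flagged *degenerate* rather than
producing NaNs; this path is routinely exercised by SHG images of normal
brain parenchyma, which are dark except for rare collagenous structures.

**First-order parameters** (5): mean, standard deviation (sample, N−1),
skewness m₃/m₂^1.5 and kurtosis m₄/m₂² (population central moments,
non-excess: a Gaussian has kurtosis 3, a symmetric two-point distribution 1),
and Shannon entropy −Σ p log₂ p over a 256-bin histogram of [0, 1]
(0 ≤ entropy ≤ 8 bits). A zero-variance FoV returns skewness = kurtosis = 0.

**Second-order parameters** (8): the normalized gray-level co-occurrence
matrix (GLCM) over 8 gray levels is computed at two distances — 6 µm and
40 µm, converted to pixels through the FoV's pixel size — for the four
orientations with offsets 0° → (0,+d), 45° → (−d,+d), 90° → (−d,0),
135° → (−d,−d) (asymmetric counting: each pair counted once, in the stated
direction; out-of-bounds pairs skipped). From each matrix:
contrast Σ p(i,j)(i−j)², correlation Σ p(i,j)(i−μᵣ)(j−μ𝚌)/(σᵣσ𝚌),
energy Σ p(i,j)² and homogeneity Σ p(i,j)/(1+|i−j|), averaged over the four
orientations per distance. The two distances probe cell-scale versus
architecture-scale organization. Conventions follow the MATLAB-style
definitions (energy = angular second moment, homogeneity with |i−j|, diagonal
offsets stepping d pixels per axis); scikit-image differs on all three points
and is used in the tests only where the conventions coincide. A
zero-variance GLCM (all mass on one entry) defines correlation := 1 —
constant texture is perfectly predictable — keeping vectors classifier-safe.

The per-channel vector is 5 + 2·4 = 13 parameters in a frozen, documented
order; combined CARS + TPEF analysis concatenates to 26. The extraction
configuration (levels, distances, orientations, entropy bins, FoV shape) is
hashed and travels with every feature table and trained model; prediction
refuses a feature table whose hash differs from the model's.

**Classifier.** Two-class linear discriminant analysis with pooled
covariance: class means μ₀, μ₁, Σ = within-class scatter/(N−2), priors
empirical by default (uniform available). The reported quantity is the
posterior *probability of class assignment*,
p(1|x) = π₁e^{δ₁(x)} / (π₀e^{δ₀(x)} + π₁e^{δ₁(x)}),
δ_k(x) = xᵀΣ⁻¹μ_k − ½μ_kᵀΣ⁻¹μ_k, with class encoding 0 = nontumor,
1 = tumor. A ridge λI with default λ = 10⁻⁶·tr(Σ)/d keeps Σ invertible when
features are nearly constant (degenerate SHG fields); λ = 0 reproduces the
strict classical estimator and raises a diagnostic error on singularity,
naming the most deficient feature direction. Posteriors are computed with a
max-subtracted softmax, exact to ~10⁻¹⁵ against direct two-Gaussian Bayes
evaluation.

**Splitting.** The train/test split assigns *patients*, never FoVs: texture
parameters of FoVs from one biopsy are strongly correlated, and a FoV-level
split would leak patient identity into the test score (the test suite
demonstrates the inflation). If a split leaves either class empty on either
side, it is rejected with an instruction to re-draw.

**Aggregation.** A sample's diagnostic rating is the median posterior over
its FoVs (mean-of-middle-two for even n): robust, by the median's breakdown
point, to any minority of atypical FoVs. Median > 0.5 → tumor, < 0.5 →
nontumor, = 0.5 → *indeterminate*, surfaced as such and counted as
misclassified in evaluation rather than silently resolved — intermediate
probabilities are exactly the clinically dangerous case. FoV-level
thresholded calls use the same tie rule. Evaluation reports
sensitivity (correct rate among tumor samples), specificity (among nontumor
samples) and the pooled correct rate; display percentages are rounded
half-up to integers, unrounded values retained; a rate whose class is absent
is *undefined*, never 0.

**Probability maps.** Tiled scans are rendered tile-by-tile with a diverging
colormap anchored at blue (p = 0), gray (0.5) and red (1), linearly
interpolated; missing tiles are transparent. Rendering is a pure function of
the grid — identical grids give identical PNG bytes.

## The synthetic-data generator

The generator provides the study conditions under which the pipeline is
validated, since no real images are distributed. Textures are
*phenomenological*: they target the qualitative contrasts reported for this
tissue — not optical image formation.

Per channel (all intensities in arbitrary units, clipped at 0, plus additive
Gaussian detector noise, default sd 0.05 on a ~unit intensity scale):

* **CARS** — nontumor: sinusoidal axon-like strands (wavelength 12 µm,
  amplitude 0.35, random orientation per FoV, smoothly varying phase) and
  ~3 cell blobs / 1000 µm² (Gaussian, σ 3 µm, subtracted: lipid-poor nuclei
  appear dark) on a jittered square lattice (jitter 12 % of spacing) over a
  smooth background. Tumor: strand amplitude → 0.05, density ×2.3,
  placement effectively random, blob size/amplitude heterogeneity up, plus
  low-frequency intensity patches (correlation length 25 µm, amplitude
  0.55) producing within-FoV inhomogeneity.
* **TPEF** — nontumor: sparse regular puncta (1.5 / 1000 µm², σ 1.6 µm).
  Tumor: density ×2.2, 70 % of puncta clustered (cluster σ 10 µm), plus a
  diffuse fluorescence field (amplitude 0.45).
* **SHG** — near-dark background; with probability 0.25 (nontumor) /
  0.75 (tumor) a fibrillar structure is present: a single strongly curved
  arc (corpus amylaceum / vessel wall) in nontumor versus ~6 straighter
  collagen fibers in tumor. With no structure and no noise the channel is
  constant, deliberately exercising the degenerate-FoV path.

Every tumor−nontumor parameter difference is scaled linearly by
`effect_size` (default 1.0); at 0 the classes are identical in distribution
(and bit-identical for equal seeds). Interpatient variability is
multiplicative log-normal jitter (default sd 0.08) of the amplitude/density
parameters, drawn once per patient and identically for both classes — it
carries no class information but makes patient-level splitting load-bearing.
A spec plus seed determines every pixel.

What the generator does **not** emulate: diffraction and coherent imaging
effects, nucleus-level morphology, vasculature, necrosis, fresh-tissue
reflection-mode artifacts, or the real cohort's feature distributions (no
quantitative texture statistics of real tissue are published to calibrate
against). Passing recovery tests therefore demonstrates that the pipeline
*can* recover class structure of the designed kind from images with
realistic nuisance variation — not a clinical performance claim.

## Validation experiments and problem sizes

* **Default recovery cohort:** 20 tumor + 10 nontumor patients × 100 FoVs
  (the typical per-sample FoV count in practice), patient-level 50/50 split.
  Expected at default effect size: ≥ 95 % FoV-level accuracy, 100 %
  sample-level correct rate.
* **Null calibration:** effect size 0 with 400 + 400 patients × 5 FoVs
  (2000 held-out FoVs across ~400 test patients). Accuracy must be 50 ± 5 %.
  Many patients with few FoVs are used because the overfit discriminant
  clusters predictions within patients; the accuracy's sampling variance
  scales with the number of test *patients*, not FoVs.
* **Border mapping:** model trained on a default cohort (8 + 8 × 25); the
  mapped section is 20 × 6 tiles blending the recipes linearly across the
  full width at effect size 0.4 — a *diffusely infiltrating margin*, where
  each tile is a partial mix. This is the regime in which the probability
  map is graded (blue → gray → red) rather than a hard step: at full effect
  size the discriminant scores span ~±700 while the logistic posterior
  saturates outside ±37, so tile probabilities collapse to exact 0/1 and a
  rank statistic on column medians is dominated by ties. Column medians of
  p(tumor) must increase across the transition with Spearman ρ > 0.9.
* **Resolution check:** one cohort (10 + 8 × 30) generated at 0.5 µm/px
  (208 × 416 px FoVs); features extracted natively (distances 12/80 px) and
  after 2× block averaging (1 µm/px, 6/40 px), same patient split. The
  FoV-level accuracy shift must stay below 2 percentage points,
  supporting the use of fast 1 µm-pixel acquisitions.

## Numerical and design notes

* Quantization: ⌊x·L⌋ clipped to L−1 (value 1.0 joins the top level);
  entropy histogram likewise.
* Partial edge tiles of a scan are discarded, not padded — padding would
  inject artificial texture into the statistics. Tiles are assumed to abut
  without overlap.
* GLCM distances in µm are converted to pixels by nearest-integer rounding
  (≥ 1), logged when inexact.
* Even-n medians use the mean of the middle two order statistics.
* Rounding of report percentages is half-up; machine-readable outputs keep
  full precision.
* Priors: empirical by default because clinical cohorts are heavily
  imbalanced and the choice is material; the mode is stored in the model
  file.
* All randomness flows through explicit integer seeds (numpy Generators /
  SeedSequence spawning); reruns are byte-identical, and no timestamps are
  written into outputs.

## Known limitations

* LDA assumes shared within-class covariance; strongly heteroscedastic
  channels (SHG) are only partially captured.
* The 8-level GLCM quantization and the two fixed distances are the
  analysis convention, not optimized values; both are configurable and
  hashed into the model manifest.
* Synthetic effect sizes are calibrated to qualitative orderings and
  separability, not to any real cohort's feature distributions.
* Sensitivity/specificity are reported without confidence intervals; ROC
  analysis and multi-class typing/grading are out of scope.
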