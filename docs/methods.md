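# Methods

`deltarad` implements a longitudinal multiparametric-MRI radiomics analysis
for early prediction of pathologic complete response (pCR) to neoadjuvant
systemic therapy in triple-negative breast cancer. Patients are imaged at
baseline (BL) and after two (C2) and four (C4) treatment cycles; each study
contributes a DCE early-subtraction volume and DWI volumes at b = 100 and
b = 800 s/mm². Because no clinical images ship with the package, a
synthetic-cohort generator provides inputs with the statistical structure
the analysis assumes, and every downstream stage is exercised against it.

## Synthetic cohort model

Each patient carries a binary pCR label (prevalence 78/163 ≈ 48% by
default, assigned by seeded permutation with the pCR count exact) and
clinical covariates (age; histology; clinical stage; T and N category;
surgery type) sampled from category frequencies typical of a stage I–III
TNBC neoadjuvant population, independent of the label — they exist to
exercise the cohort-comparison stage, not to carry signal.

The tumor is an ellipsoid (in-plane semi-axis `base_radius_mm` = 10 mm
median, z semi-axis 0.65× that) on a 44×44×20 grid at 1.0625×1.0625×3 mm
voxels, mirroring an axial breast protocol where slice thickness is ~3×
the in-plane spacing. Response is encoded by two per-cycle-pair
multiplicative factors:

* **volume shrink** — tumor volume × 0.45 per pair for pCR, × 0.80 for
  non-pCR;
* **texture homogenize** — interior texture standard deviation × 0.60 per
  pair for pCR, × 0.90 for non-pCR.

Responders therefore shrink and homogenize at least as much as
non-responders (enforced as a config invariant). Per-patient log-normal
jitters (σ = 0.25 on radius and texture scale, σ = 0.30 on the response
factors) spread the trajectories so the groups overlap rather than separate
deterministically; these jitters are what keep planted-effect model AUCs in
a clinically plausible 0.8–0.95 band instead of at 1.0.

Interior texture is a Gaussian-smoothed white-noise field (correlation
length 2.5 mm), standardized *within the tumor mask* before scaling so the
constructed interior standard deviation is exact — the sample s.d. of a
correlated field over a few hundred voxels otherwise strays far from its
nominal scale. Additive acquisition noise (σ = 8 signal units) rides on
top. A configurable fraction (10%) of tumors carries a low-signal necrotic
core, which the segmentation stage must exclude. DWI b = 100 volumes get
their own correlated texture with the same homogenization trajectory; b =
800 is derived as `S_800 = S_100·exp(−ADC·700)` from a smooth ADC field
(~0.95×10⁻³ mm²/s in tumor, ~1.9×10⁻³ in background), so the stored ADC map
always equals the mono-exponential closed form `ln(S_low/S_high)/(b_high −
b_low)`; non-positive signals yield NaN rather than an error.

When a simulated tumor's in-plane radius falls below one voxel the study is
flagged for tumor-bed contouring and a fixed 4 mm bed mask at the prior
centroid is emitted, mirroring clinical practice when tumors resolve
completely.

All randomness is keyed by `SeedSequence([seed, stream, patient_index,
timepoint_index])`, so a cohort is bitwise reproducible and adding patients
does not reshuffle existing ones.

**What the generator does not emulate:** pulse-sequence physics, contrast
pharmacokinetics, bias fields, motion, irregular tumor shapes, or any
coupling between clinical covariates and outcome. Passing tests therefore
demonstrate that the pipeline recovers effects of the kind it assumes, at
realistic sizes — not that those effects are recoverable from any
particular clinical dataset.

## Segmentation

A reader's rough envelope (simulated as the truth mask dilated by 2
voxels) is refined by histogram thresholding over the envelope
intensities. The threshold rule is Otsu's criterion by default — the
standard parameter-free histogram threshold — with a fixed-quantile
alternative; voxels at or above the threshold are kept, connected
components under 5 voxels are removed, and a constant-intensity envelope
is returned whole (degenerate threshold, documented). Necrotic cores and
clip artifacts are removed by mask subtraction, and with multiple lesions
the largest on DCE is the index carcinoma (ties broken by lexicographic
centroid). An explicit threshold argument makes the operation idempotent
for testing. If nothing survives, the VOI is empty and flagged tumor-bed so
features propagate as missing rather than crashing the pipeline.

## Feature extraction

Per VOI and sequence (DCE uses the early-subtraction volume, DWI the
b = 800 volume) the extractor emits exactly 310 features:

* **10 first-order statistics** of the raw VOI intensities: minimum,
  maximum, mean, standard deviation (n−1 denominator), skewness
  (standardized third moment), kurtosis (Fisher excess, so normal → 0), and
  the 1st/5th/95th/99th percentiles with linear interpolation. Skewness and
  kurtosis of a constant VOI are set to 0 by convention.
* **300 GLCM features**: 25 co-occurrence statistics × 3 distances (1–3
  voxels) × 4 in-plane directions, each offset reported separately —
  the only composition that yields 300 from a standard statistic set.
  Co-occurrence is accumulated per axial slice (2D), because slice
  thickness is ~3× the in-plane spacing; a 13-direction 3D mode is
  available behind `GLCMConfig`.

Gray levels are quantized to 32 equal-width bins over the VOI min–max
range (the common radiomics default), making all GLCM features invariant
to affine intensity rescaling. The 25 statistics are the textbook set
(autocorrelation, joint average, cluster prominence/shade/tendency,
contrast, correlation, difference average/entropy/variance, joint
energy/entropy, IMC1/IMC2, IDM, IDMN, ID, IDN, inverse variance, maximum
probability, sum average/entropy, sum of squares, dissimilarity,
homogeneity), with entropies in bits. Two conventional redundancies are
kept for schema compatibility: `difference_average` ≡ `dissimilarity` on a
symmetric matrix, and `homogeneity` uses the inverse-difference-moment
form, ≡ `idm`. Degenerate matrices take analytic limits where one exists
(correlation of a zero-variance matrix is 1, information measures default
to 0 when a marginal entropy vanishes); offsets with no valid voxel pair
yield missing values.

A note on direction of effect: with min–max-relative quantization, *adding*
correlated texture to a fixed dynamic range raises GLCM contrast, but
*scaling* a unimodal tumor's texture down against fixed acquisition noise
can raise normalized contrast instead (the noise floor occupies more of the
shrunken range). Both directions are monotone in the effect, and univariate
screening orients AUCs, so the pipeline's discrimination is insensitive to
the sign; the monotone-response test pins the range with anchor voxels for
exactly this reason.

## Delta features

For ordered timepoint pairs (C2/BL, C4/BL, C4/C2) each feature yields an
absolute difference `AD = late − early` and a relative difference
`RD = (late − early)/|early|` — the sign-preserving delta-radiomics
convention, under which RD is invariant to positive rescaling of the raw
feature and flips sign under negative rescaling. Early values within 1e-12
of zero give a missing RD rather than an infinity; missingness propagates
feature-wise, never patient-wise. With three timepoints the assembled
per-patient table has 310 × (3 raw + 6 delta) × 2 sequences = 5580 columns.

## Univariate screening

Each feature's discrimination is the Mann–Whitney AUC (ties one half),
oriented as max(AUC, 1−AUC) because effect direction is not of interest at
this stage; significance is the two-sided normal-approximated Mann–Whitney
test with tie correction — the test canonically paired with the AUC. A
feature passes at AUC ≥ 0.7 in *both* the training and testing sets with
training p < 0.001. Screening is monotone in the floor, and missing values
are excluded pairwise.

## Multivariate modeling

Patients are split 2:1 into training and testing sets, stratified by label,
with per-stratum training counts rounded to the nearest integer, halves up —
the one convention that maps 78/85 to exactly 52+57 train and 26+28 test.
The primary learner is logistic regression with an elastic-net penalty:
mixing parameter over {0.1, …, 1.0} and a 25-value logarithmic
regularization path, tuned by stratified 5-fold CV maximizing AUC on
training data only; features are standardized on training statistics, and
nonzero-coefficient features constitute the selected signature. Candidate
features per model are the screened features inside the model's
timepoint/delta × sequence blocks (capped at 40 in screening order); if
fewer than two pass, the top 30 by training AUC are used so null
configurations remain fittable.

Holdout evaluation reports training and testing AUC (unoriented — a
worse-than-chance model reports < 0.5), accuracy at predicted probability
0.5, a 95% DeLong CI, and a DeLong test of AUC = 0.5. An unstratified
3-fold cross-validation alternative pools out-of-fold probabilities into a
single AUC (folds redrawn with an incremented seed if a training part loses
a class). SVM comparators (linear and RBF/Gaussian kernels) tune C by the
same 5-fold AUC protocol and score by decision function. The default model
grid holds one model per timepoint/delta family with DCE+DWI combined
(9 models with three timepoints) plus configured multi-family combinations
(default: C4 together with AD C4/BL); the grid is explicit and serialized
with results.

## Reader agreement

Simulated readers re-contour each tumor: a smooth per-reader bias field
(inter-reader scale, mm of boundary displacement) plus an independent
per-repeat field (intra-reader scale) is added to the truth mask's signed
distance transform, so zero jitter reproduces the truth exactly and Dice
overlap falls monotonically with jitter. The inter scale must be ≥ the
intra scale by construction.

Per feature the module reports the Pearson correlation between the two
readers' repeat-averaged values, a two-sided Wilcoxon signed-rank test of
the paired difference (zero differences dropped; all-zero → p = 1 by
convention; fewer than 5 informative pairs → undefined), and the
inter/intrareader variance ratio from a per-patient one-way random-effects
method-of-moments decomposition: intra = mean within-reader repeat
variance, inter = variance of reader means minus intra/(mean repeats),
floored at zero, ratio = cross-patient mean inter / mean intra, rounded to
4 decimals. With only two readers the between-reader variance estimate has
one degree of freedom, so the zero floor biases null ratios below 1 — the
equal-jitter median lands near 0.2 rather than 1.0, which is why agreement
checks compare medians across jitter settings rather than against 1.
Infinite ratios (repeat-identical but reader-divergent features) are
excluded from summaries with a count. Agreement runs on DCE features by
default.

## Cohort comparisons

Clinical characteristics are compared between response groups with the
two-sided Wilcoxon rank-sum test (continuous) or Fisher's exact test
(categorical; for r×2 tables beyond 2×2, a seeded Monte-Carlo version
samples the conditional null by label permutation and compares
product-hypergeometric table probabilities, 20 000 draws by default).

## Numerical and design choices

* Percentile interpolation is linear; entropies use log₂; quantized levels
  are 1-based with 0 reserved for outside-VOI.
* Residual missing feature values entering a model fit (vanished tumors)
  are median-imputed on the available column values; constant columns are
  dropped before fitting.
* DeLong CIs are clipped to [0, 1]; a zero-variance score vector yields
  p = 0 unless the AUC is exactly 0.5.
* The elastic-net path length (25) and the hyperparameter fold count are
  exposed in `ModelingParams`; experiment problem sizes (163 patients for
  model recovery, 50 patients × 2 readers × 2 repeats for agreement, 5–20
  seed replicates) were chosen as the smallest sizes at which the cohort
  statistics stabilize — notably, the cross-feature median variance ratio
  needs ≳50 patients because all GLCM features share each patient's mask
  realizations and the two-reader inter-variance estimate has one degree
  of freedom per patient.
* Monte-Carlo Fisher p-values use the (hits+1)/(draws+1) estimator, so they
  are never exactly zero.

## Known limitations

* Ellipsoidal tumors and stationary Gaussian texture understate the shape
  and texture complexity of real carcinomas; absolute feature values are
  not comparable to clinical cohorts, only the pipeline's contracts and
  effect-recovery behavior are validated.
* The screening rule conditions on test-set AUC (as specified for the
  analysis it reproduces), which optimistically biases test performance of
  downstream models built on screened features; conclusions about relative
  model ordering (early-change vs baseline) are unaffected because all
  models share the rule.
* The two-reader variance-ratio estimator is noisy and floor-biased (see
  above); with more readers it concentrates near the construction value.
* Intrareader repeats are a modeling device; no claim is made about how
  repeat contours arise in clinical reading sessions.
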