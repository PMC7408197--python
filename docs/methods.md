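# Methods

## Data model and compositional treatment

Flow-injection MRM signal carries no absolute calibration, so a sample is
informative only through the relative amounts of its monitored ions. All
analyses therefore operate on closed compositions and log-ratio
coordinates. The pipeline's invariance contract is that multiplying any
sample's raw intensities by any positive constant changes no reported
number; this holds end to end (including zero replacement, whose imputed
value is a fraction of a *closed* column minimum) and is enforced by
tests.

CLR is the default coordinate system for feature-level work because each
coordinate keeps a one-to-one link to an ion (or CPC), which is what the
selection stages rank; ILR (pivot/sequential-binary-partition basis,
recorded in the output) is available for distance-based analyses. Both
transforms are exposed and config-selectable since either can legitimately
feed the compression stage.

**Zero replacement.** Multiplicative replacement is the default: a zero in
feature *j* becomes `delta_fraction × min positive value of column j`
(default 0.65, the conventional below-detection-limit fraction in
compositional omics), and the positive parts of the row are rescaled so it
still sums to one. A pseudocount alternative exists for comparison.
All-zero columns carry no relative information and are dropped with a
warning.

## mzML extraction

Converted flow-injection SRM runs contain one chromatogram per monitored
transition and no chromatography, so extraction reduces to locating the
chromatogram whose Q1/Q3 isolation targets match a transition within
tolerance (default 0.5 Th each side, unit-resolution triple quadrupole)
and integrating its intensity points over the whole injection window.
Integration uses the **sum** of points (robust for flow-injection
plateaus); a mean option exists. Two matches within a single file signal a
too-wide tolerance and raise an error; matches across a sample's files are
summed, since acquisition methods are disjoint by design and duplicates
indicate reinjection. Sample identity and metadata come from a manifest
file, never from file-name parsing. The reader handles exactly the subset
of mzML that such runs produce (SRM chromatograms, 32/64-bit float arrays,
zlib or none); the writer emits minimal standard-conformant files that
Bioconductor's mzR parses identically, which one test verifies.

## Synthetic cohort

The generator emulates the study design: 6 males + 6 females per genotype
at ages 5, 7 and 10 weeks (72 samples); wild-type samples are "control" at
every age, mutant samples map age onto non-lesional → established →
advanced. 1030 ions are spread over the 10 annotation categories with a
phospholipid-dominated skew; per-category counts are configuration, not
measurements.

Log-intensities are ion baseline + within-category latent structure +
independent noise. The latent factors (12 per category, strengths decaying
geometrically by 0.5 from SD 0.6, per-ion latent variance normalized)
give each category a low effective rank, so the 95%-variance compression
retains a realistic handful of components per category (~10–30 at the
default settings, ~170 features overall) instead of the near-full rank
that independent noise would force. Independent per-ion noise is SD 0.15
on the log scale; baselines are N(11, 1.5), spanning the ~4 orders of
magnitude a validated MRM panel covers.

**Effect calibration.** A factor effect is a multiplicative log-scale
shift δ applied to its target ions along a centered contrast *c*
(sex/genotype indicators; stage uses a monotone profile, default 0,1,2,3).
From the ANOVA identity η² = f²/(1+f²), δ = σ·f/sd(c) with σ² the per-ion
total (noise + latent) variance, which lands the requested large-n per-ion
η² on the CLR scale; up/down signs are balanced across target ions so the
CLR back-reaction through the row geometric mean cancels. Calibration is
exact in isolation (a 20-seed Monte-Carlo test holds the median realized
η² within ±0.1 of target). Under the *joint* default conditions realized
values run ~10% below nominal, because overlapping effects and zero
replacement inflate per-ion variance — as they would in real data; the
defaults (diffuse sex effect: 600 ions at η² 0.20; concentrated genotype
effect: 150 phospholipid/glycerolipid ions at η² 0.50, drawn among
sex-free ions; stage effect: 80 ions at η² 0.45 across five categories)
were chosen once so that the top two global CPCs align with genotype and
sex and the selection landscape (a sex-independent genotype panel of ~100
ions) mirrors the study's. Zeros are injected completely at random (rate
0.01 by default); the real zero pattern is unknown.

What the generator does **not** emulate: instrument noise physics,
isotopic/isobaric interference, chromatographic shape, batch effects, and
any misannotation of categories. Recovery results on synthetic cohorts
therefore bound what the pipeline can do when its model assumptions hold;
they do not certify performance on real acquisitions.

## Univariate stage

Per-feature OLS with the factor entered last in a sequential decomposition
(so partial η² is well defined with covariates; without covariates partial
η² = η²). Progression is coded numerically 0–3 — the ordinal chain implies
order, not spacing, and a linear score acts as a trend test; a
categorical-factor alternative is config-selectable. Sex enters the
genotype analysis as an *exclusion filter* (sex p_adj > 0.05) rather than
a covariate by default, matching the published selection rule; covariate
mode exists. BH adjustment is applied within each factor's family of
tests. Constant features get η² = 0, p = 1, and a flag. Top-k ties break
lexicographically by feature id for determinism.

## Elastic net

The penalty follows the convention in which α = 1 is the pure LASSO and
α = 0 pure ridge. For classification the least-squares loss is replaced by
binomial/multinomial deviance — the standard classification analogue,
required to produce class probabilities — while a gaussian family is kept
so the α = 0 and α = 1 limits can be checked against the ridge closed form
and an independent proximal-gradient L1 solver.

λ (and optionally α over a small grid; default α = 0.5) minimizes the mean
leave-one-out deviance, ties going to the larger λ (sparser model). No
1-SE rule. Inside each fold, features are standardized on the training
rows and imbalance handling is applied to the training rows only (SMOTE
never sees the held-out sample; a structural test asserts this).
Coefficients are reported on the standardized scale so |β| ranks features
comparably. Importance rescales |β| by one common factor so the maximum
*overall* (per-feature, summed over classes) score is 100; per-class
columns therefore sum exactly to Overall.

SMOTE is implemented directly (interpolation between a minority point and
one of its k nearest minority neighbors, k clipped to class size − 1,
deterministic given the seed). Accuracy CIs are Clopper–Pearson exact;
weighted κ uses linear disagreement weights over the stage ordering
(quadratic available). LOO caveat: under a null signal with balanced
classes, the selected model is typically fully penalized and each fold
predicts its training majority — the opposite class — so null accuracies
fall *below* 0.5; this is expected LOO pessimism, not a defect.

## Numerical choices

- CPC: columns are mean-centered before SVD (variance fractions are not
  comparable otherwise); no per-ion unit-variance scaling, which would
  distort the log-ratio covariance geometry. Sign convention: the
  largest-magnitude loading of each component is positive, making CPC
  features reproducible across platforms. Category subcompositions are
  re-closed before CLR by default (each category treated as its own
  composition); slicing a global CLR is available and flagged.
- Degenerate inputs: all-zero samples, constant matrices, single-sample
  classes, and non-orthonormal ILR bases raise typed errors naming the
  offending sample/feature; features constant in the standardization
  reference become NaN with a warning.
- Determinism: every stochastic step (generator, SMOTE, solver) derives
  from the run seed; identical config + seed + data reproduce identical
  reports (timestamps aside).

## Problem sizes

Tests and the acceptance script run the full 72 × 1030 design for
generation, univariate and compression stages, and reduced designs
(≤ 72 samples, ≤ 100 features, lambda grids of 2–9 points) for the
LOO-elastic-net loops; the mzML round trip uses 72 samples × 50 ions
across 432 files. These sizes reproduce every qualitative result at
desk scale.

## Limitations

- The published numeric endpoints (accuracies, κ, CPC variance
  percentages) depend on the real deposited raw data; on synthetic cohorts
  the pipeline reports its own measured values, which track the published
  narrative qualitatively (genotype ≈ 1.00 accuracy, progression high-0.8s
  with SMOTE ≥ weighted, weighted κ > unweighted) but are not expected to
  match numerically.
- Importance scaling before summing per-class scores is constrained, but
  not uniquely determined, by the published tables' additive structure;
  the single-common-factor convention used here reproduces it.
- No mixed-effects modeling, permutation p-values, stability selection, or
  robust/sparse PCA variants.
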