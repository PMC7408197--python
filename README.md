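# lipidsel

Compositional feature selection and disease-stage classification for
MRM-profiling lipidomics.

## The problem

Flow-injection MRM profiling screens tissue extracts against a fixed panel
of precursor→product transitions ("lipid ions") on a triple-quadrupole
instrument. The result — here modeled on an epidermis study of
SHARPIN-deficient (*cpdm*) dermatitis mice versus wild-type littermates —
is a samples × ions matrix of uncalibrated signal whose only meaningful
content is *relative*: each sample is closed to a composition, zeros are
replaced, and analysis happens on log-ratio coordinates
(CLR: `clr(x)_i = log(x_i / g(x))` with `g` the row geometric mean; ILR for
distance-based work). The scientific questions are which lipid categories
and which individual ions carry the sex, genotype, and disease-stage
signal, and how well they classify samples.

The pipeline implements the published two-tier strategy:

1. **Compression** — each annotated lipid category is treated as its own
   subcomposition, CLR-transformed and compressed by SVD into compositional
   principal components ("CPCs") retaining 95% of the category's variance
   (`cpc.compress_categories`), giving a few dozen "`<category> CPC <j>`"
   features.
2. **Tier-1 univariate filter** — one OLS model per feature against the
   factor (sex, genotype, or the ordinal stage coding control=0 <
   non-lesional=1 < established=2 < advanced=3), effect sizes as
   η² = SS_factor/SS_total and partial η², Benjamini–Hochberg adjustment,
   then the published rules: categories keep p_adj < 0.05; individual ions
   keep genotype p_adj < 0.01 AND sex p_adj > 0.05 (sex-independence
   screen), top-100 by partial η².
3. **Tier-2 elastic net** — penalized multinomial/binomial regression

       argmin_β  loss(y, Xβ) + λ((1−α)‖β‖²/2 + α‖β‖₁)

   (α = 1 is the LASSO), tuned by leave-one-out deviance, with class
   imbalance handled inside each training fold by inverse-frequency class
   weights or SMOTE. Features are ranked by |β|, scaled so the largest
   overall importance is 100; multiclass per-stage scores sum to the
   Overall column.

A synthetic-data generator (`synthetic_data`) reproduces the study's
statistical structure — 72 samples (6 males + 6 females per genotype at 3
ages), 1030 ions in 10 categories, correlated within-category structure,
a diffuse sex effect, a concentrated genotype effect in
phospholipids/glycerolipids, and a monotone stage effect with calibrated
per-ion η² — so every stage has a planted-truth test surface, including
mzML fixtures for the extraction path.

## Worked example

```sh
python analysis/01_simulate_cohort.py --seed 1 --out-dir results/cohort
python analysis/05_genotype_ions.py  --seed 1 --out-dir results/genotype_ions
```

prints (abridged):

```
tier 1: 100 ions selected (partial eta2 0.47-0.79); 98% carry the planted genotype effect
tier 2: LOO accuracy 1.00 (95% CI 0.95-1.00)
top univariate ions (genotype vs sex eta2):
    Category         Tentative Attributions         MRM  Genotype (eta2)  Sex (eta2)
glycerolipid synthetic glycerolipid ion 296 450.7→282.2             0.79       0.023
phospholipid synthetic phospholipid ion 531 610.5→369.1             0.77       0.000
...
```

Reading: of the 1030 monitored ions, 100 pass the genotype filter while
remaining unassociated with sex (their sex η² stays below 0.03); 98% of
them are ions into which the generator actually planted the genotype
effect, and the elastic net separates the 36 WT from the 36 mutant samples
perfectly in leave-one-out. The other drivers cover mzML extraction
round-trips (`02`), the global CPC view (`03`), category-level selection
(`04`), and multiclass stage prediction with class weights vs SMOTE,
including weighted/unweighted Cohen's κ (`06`).

## Layout

- `src/lipidsel/` — the library: `mrm_io` (transition tables, mzML SRM
  chromatograms, intensity matrices), `coda` (closure, zero replacement,
  CLR/ILR, reference standardization), `cpc` (compositional PCA and
  per-category compression), `select_univariate` (per-feature models, BH,
  selection rules, effect-size conversions), `enet` (LOO-tuned elastic
  net, SMOTE, importance, metrics), `synthetic_data` (cohort generator and
  mzML fixture writer), `pipeline` (orchestration, manifests, published
  table layouts).
- `analysis/` — numbered narrative drivers writing under `results/`.
- `docs/methods.md` — model assumptions, parameter choices, limitations.
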