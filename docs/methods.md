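# Methods

`evuptake` models the relationship between the membrane composition of
small extracellular vesicles (sEVs) and the endocytic route recipient cells
use to internalize them. The predictor matrix **X** holds log10 lipid and
protein abundances of sEV preparations from four cardiac-relevant parent
cell types (CPC, MSC, CEC, CF) collected under normoxic or hypoxic
conditioning; the response matrix **Y** holds six uptake outcomes —
flow-cytometry sEV uptake under small-molecule inhibition of
clathrin-mediated endocytosis, macropinocytosis, and caveolae/lipid-raft
endocytosis, in CEC and CF recipient cells, each normalized to the
uninhibited control (control = 1; values above 1 are legitimate, because
the uninhibited control is a maximum-uptake reference, not a saturation
point).

## Feature-level quality control (lipidomics)

LC-MS feature tables carry three sample roles: biological injections,
extraction blanks, and pooled-QC injections (a mixture of all samples
injected repeatedly through the run). QC proceeds in acquisition order:

1. **Background filter.** A feature is removed when its *maximum*
   biological abundance is strictly below 5× the *mean* blank abundance.
   Max-over-biological is the permissive reading: it retains features that
   are real in any single condition. Missing blank values count as zero
   background. The comparison is strict, so a feature at exactly 5× is
   kept.
2. **QC presence/CV filter.** Kept iff present in ≥ 50% of pooled-QC
   injections *and* the coefficient of variation over the present QC
   values (sd/mean on the raw scale, n−1 convention — the standard
   metabolomics convention) is strictly below 30%.
3. **Drift correction.** Per feature, a trend is fit to log10 QC abundance
   versus injection order — a locally weighted linear smoother (lowess,
   ~3-point windows, one robustifying iteration) when ≥ 4 QC points are
   present, a Theil–Sen robust line for 2–3 points. Every sample's
   abundance is divided by trend(injection)/median(QC). Windows of about
   three points track a drift that is linear on the raw scale (hence curved
   in log) to well under 1% while still smoothing QC noise; evaluation
   beyond the QC injection range is clamped to the nearest fitted value.
   Features with fewer than two present QC values are left uncorrected and
   flagged (`drift_corrected = False`). Missing cells stay missing.
4. **Duplicate/isomer resolution.** Within an identical lipid annotation,
   peaks are clustered by retention time with single linkage at a 0.3-min
   gap. Peaks inside a cluster are over-segmented duplicates: the one with
   the lowest QC CV represents the cluster (collapse happens before isomer
   summing; ties fall back to the higher mean biological signal). Distinct
   clusters are genuine isomers and are summed sample-wise
   (missing + value = value; all-missing stays missing). The surviving
   feature keeps the lexicographically smallest member id, so ids remain
   traceable. Note the single-linkage chain can, in principle, span more
   than 0.3 min end-to-end; with real chromatography this is the intended
   behavior for a smeared peak group.

Blanks and QC columns are dropped after these stages; downstream stages
see biological samples only. A QC report records, for every input feature,
its blank ratio, QC presence, QC CV and which stage (if any) removed it.

## Matrix preparation

Per omics table, in fixed order: proteins are first filtered to those with
≥ 2 peptide-spectrum matches (PSM) in at least one sample; features missing
in strictly more than 12 of the 24 samples are removed (the threshold is a
parameter for other designs); each remaining missing cell is imputed as
one fifth of the smallest observed abundance *in that sample column* —
a left-censoring interpretation under which imputed values sit strictly
below everything observed in the sample; values are log10-transformed and
each feature is mean-centered and scaled to unit variance (n−1). The
centering/scaling vectors are stored so held-out data can be pushed
through the identical transform; zero-variance features raise an error
rather than being dropped silently, keeping feature counts auditable.
Lipid and protein matrices over the same samples are column-concatenated.

## SIMPLS regression, VIP selection, validation

The regression core is SIMPLS (de Jong's cross-product-deflation PLS),
implemented from first principles; for a single response it coincides with
NIPALS PLS1, which the test suite exploits as an independent oracle along
with ordinary least squares at full rank. Scores are normalized to unit
length; the SVD sign ambiguity is fixed by making the largest-magnitude
entry of each weight vector positive, so fits are bit-reproducible.
Per-component explained variances are ‖pₐ‖²/‖X‖²_F and ‖qₐ‖²/‖Y‖²_F.
Requesting a component beyond the numerical rank of the problem raises an
error: the score norm then vanishes and the rescaled weight would amplify
floating-point noise into arbitrarily large coefficients.

Variable importance in projection for outcome *k* uses
SSₐₖ = qₐₖ²·(tₐᵀtₐ) and the SIMPLS weights; by construction
Σⱼ VIPⱼₖ² = p for every outcome. The multi-response score is the plain
mean over the six outcomes, and selection is strict (mean VIP > 1; a
feature exactly at the threshold is excluded).

The modelling procedure is: (i) a 3-component model on all features with
leave-one-out cross-validation; (ii) VIP selection; (iii) a final
2-component model on the selected features, again with leave-one-out CV;
(iv) evaluation of the reduced model on the held-out hypoxic samples.
Both X and Y are autoscaled before regression. By default the autoscaling
is computed once on the full training set and reused across CV folds;
this mirrors preprocessing-as-frozen-step practice but shares fold-out
statistics across folds, so `loo_cv(..., rescale_within_fold=True)`
provides the leakage-free variant, which is also what
`recovery_simulation` reports as the training R² — a test-vs-training
comparison is only meaningful between two honest predictive estimates.
CV metrics use the PRESS/TSS convention with the training mean as
baseline: R² = 1 − PRESS/TSS, RMSE = √(PRESS/n). Held-out R² uses the
test-set mean as baseline, per outcome and pooled across outcomes.

## Supporting statistics

PCA is SVD-based on the centered (and, matching preparation, scaled)
matrix; variance fractions cover all components and sum to 1.
Differential abundance runs per feature and per group: a single-pass
outlier fence removes points outside mean ± 1.5·IQR (linear-interpolation
quantiles; boundary points are kept), then a two-sided unpaired t-test on
log10 values — Welch by default, pooled-variance Student behind a flag.
Fold change is 10^(Δ mean log10); the pathway-analysis input list keeps
features with fold change strictly above 2 (either direction). No multiple
-testing correction is applied by default (Benjamini–Hochberg is behind a
flag), matching the screening character of the 2-fold rule. The mean-based
fence is kept literally as specified; it is *not* Tukey's median fence,
and on skewed groups a single extreme point can drag the mean so far that
the fence excludes every point — such features are skipped with an
explicit reason rather than silently tested. Fences are computed per
group. Detected-feature overlaps count every exclusive region of the
per-cell-type presence sets (presence = observed pre-imputation in ≥ 1
sample of that cell type). Uptake normalization divides raw fluorescence
by the matched uninhibited control, and cross-condition agreement is the
Pearson product-moment correlation.

## The synthetic study generator

The generator emulates the statistical structure the analysis assumes and
provides the ground truth that parameter-recovery tests need. Defaults are
the study conditions: 4 cell types × 2 oxygen levels × 3 replicates = 24
biological samples, 381 lipid annotations and 483 proteins chosen so that
about 711 combined features survive QC and missing-value filtering,
2 blanks, 6 pooled-QC injections, 30 informative features, replicate
noise 0.1 on the log10 scale, 10% missingness, −0.4% signal drift per
injection.

Log10 abundances follow a cell-type factor model:

* **Shared composition factors** (rank 2 by default): every feature loads
  weakly (SD 0.35) on latent cell-type positions. These drive the overall
  PCA clustering by parent cell type.
* **An uptake-propensity factor** *u*: a scalar per sample, with a
  cell-type-level component orthogonalized against the shared factors (and
  the intercept) across cell types, plus replicate-level biological
  variation with SD = 4 × `noise_sd`. Tying the replicate jitter to
  `noise_sd` makes the no-noise limit exact: with `noise_sd = 0` the
  per-cell-type means of the generated table equal the stored group means
  to machine precision, and QC injections repeat identically.
  Informative features load on *u* with signed magnitudes near 1;
  the remaining features carry weak loadings (SD 0.05) — relevance in real
  membranes is graded, not binary. The orthogonalization encodes the
  modelling assumption that the uptake-relevant composition axis is not
  the same axis as the bulk composition differences; without it, under
  per-feature autoscaling, essentially every latent-structured feature is
  equally correlated with uptake and no ranking method could single out
  the causal set from 12 training samples.
* **Uptake outcomes**: Y = 1 + centered(X)·C + ε with homoscedastic
  Gaussian ε (SD 0.05) and the rank-one coefficient matrix C = h aᵀ/Σh²
  supported on the informative features, so Y is exactly linear in X and
  the per-outcome weights a (magnitudes uniform in [0.15, 0.45], random
  signs, bounded away from zero so every modelled outcome carries real
  signal) map the uptake factor onto the six responses. With the uptake
  noise at zero, ordinary least squares on the informative columns
  recovers C exactly — a generator-level identifiability test.

Measurement artifacts are layered on top: a multiplicative geometric
drift (1 + slope)^(injection−1) across the whole run; left-censoring at a
per-feature intensity threshold whose rate is Beta-distributed around the
configured missing rate (concentration 1.5, so some features exceed the
downstream missing-count filter; informative features are capped at 40%
missing — consistently detected membrane components, and a rate above the
filter threshold would simply delete the ground truth the recovery tests
need); pooled-QC columns equal to the feature's grand mean modulated by
drift and a small lognormal CV (8%, with 5% of features at CV ≈ 60% and 4%
nearly absent from QCs, to exercise the filters); blanks at background
level except for an 8% contaminant fraction placed at half the maximum
biological signal (which the 5× rule then removes); lipid isomer duplicate
peaks for 15% of annotations with retention-time offsets drawn on both
sides of the 0.3-min gap; protein PSM counts Poisson around a per-protein
rate, with a 10% low-evidence fraction never reaching 2 PSM.

What the generator does **not** emulate: peak picking and alignment,
adducts, chromatographic tailing, batch effects beyond monotone drift,
missingness that is not intensity-driven, heavy-tailed abundance noise,
and any real oxygen-conditioning effect (normoxic and hypoxic samples are
exchangeable by construction, which is precisely what makes the
normoxic-train/hypoxic-test split a clean generalization probe). Passing
tests therefore demonstrate correctness of the pipeline's algorithms and
recoverability under the stated noise model — not performance on any real
data set.

## Numerical choices and problem sizes

Quantiles use linear interpolation throughout. Standard deviations use the
n−1 convention. Degenerate inputs raise errors naming the offending
feature or sample (zero-variance features, samples with nothing observed,
non-positive abundances, empty VIP selections). All randomness flows from
a single seed through independent named streams, and equal seeds give
byte-identical pipeline summaries. Test and acceptance runs use the
default study scale (24 samples, ~860 raw features, ~710 post-filter);
the parameter-recovery study repeats the full chain over 20 seeds, which
completes in a few seconds on one core.

## Known limitations

* The blank comparison pools all blanks; per-medium blank matching (PBS
  vs DMEM vs EGM-2) is a config extension, not implemented.
* The default cross-validation reuses global autoscaling across folds
  (see above); the honest per-fold variant is available and used wherever
  training and held-out performance are compared.
* The mean ± 1.5·IQR fence is pathological on skewed groups by design
  fidelity; affected features are skipped and flagged.
* VIP > 1 selection at n = 12 necessarily admits chance-correlated
  features (the VIP identity forces the average squared score to 1);
  the reduced model is therefore larger than the truly informative set,
  and its held-out performance, not its training fit, is the meaningful
  metric.
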