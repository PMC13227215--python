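# Methods

`beemarker` re-implements, as a tested library, the analysis chain of a
cage-level honey bee nutritranscriptomics experiment: two genetic stocks
(Pol-line, Russian) from several source colonies, four diets (sucrose-only
reference plus three protein/lipid diets: pollen, *Chlorella*, spirulina),
bulk RNA-seq of pooled abdomens per cage, and per-cage mean head+thorax dry
mass (mg) as the nutritional phenotype. This note documents the models, the
defaults and why, the numerical choices, and what the synthetic benchmark
does and does not establish.

## Synthetic data generator

The generator is first-class, tested code: it defines the statistical
conditions under which every downstream stage is validated, and it emits
the ground-truth labels those validations score against.

**Design.** Samples are cage pools laid out as stock x colony x diet x
cage. Defaults follow the study design: 4 Pol-line and 3 Russian source
colonies, 4 cages per colony per diet, 4 diets — 64 + 48 = 112 libraries.
`n_colonies_per_stock` accepts either an integer or a per-stock mapping
(the default is the asymmetric mapping above).

**Counts.** Gene g in sample i is drawn
`K_gi ~ NB(mean = s_i * mu_gi, Var = m + alpha m^2)` with
`alpha(mu) = a0 + a1/mu` (defaults a0 = 0.05, a1 = 2 — a typical bulk
RNA-seq dispersion trend) and `s_i` a log-normal library-size factor
(sigma = 0.3). On the log2 scale,

    log2 mu_gi = baseline_g + colony_gc + diet_g * 1[PL diet]
               + stock_g * 1[alt stock] + gamma_g * z_i  (weight program)
               + viral offset (viral genes, alt stock)

- `baseline_g ~ Uniform(1, 9)` log2 units, spanning low- to high-count genes.
- `colony_gc ~ Normal(0, colony_sd)` per gene per colony (default SD 0.2
  log2 units) — gene-specific random intercepts, so colony blocking in the
  design matrix genuinely matters downstream.
- Diet- and stock-program genes get a fixed-magnitude effect
  (`diet_lfc` = 1.0, `stock_lfc` = 0.8 log2 by default) with a random sign
  per gene, mimicking programs with both up- and down-regulated members.
- Stock-program membership is sampled with odds multiplied by `lncRNA_bias`
  (default 4) for lncRNA genes (15% of the transcriptome by default),
  reproducing the lncRNA-skewed stock signature.
- Viral features (5 by default, named after the common bee viruses) are
  ordinary count rows with a -1.5 log2 offset in the Russian stock — no
  genome-scale read simulation.

**Phenotype.** Each cage carries a latent nutritional score
`z_i ~ Normal(1[PL diet], 1)`; sucrose-fed cages center at 0, protein/lipid
cages at 1. Cage dry mass is `weight_mg = 25 + weight_beta * z + Normal(0,
weight_noise_sd)` (defaults beta = 2 mg per unit score, noise 1 mg, floored
at 0.1 mg), and weight-program genes load on z with
`gamma_g ~ Uniform(0.3, 0.7)` log2 per unit score. The same latent score
drives both expression and mass, which is exactly the structure the
random-forest stage is supposed to exploit; the program deliberately
contains weak members (gamma near 0.3) whose signal sits near the detection
floor at 112 cages.

**What it does not emulate.** Within-cage bee-to-bee variation (the unit is
the cage pool, as in the experiment), read-level artifacts (GC bias,
mapping ambiguity), correlated gene programs (planted effects are
independent across genes given the latent score), batch effects beyond
colony, and compositional distortion from very highly expressed genes.
Passing benchmarks on this generator therefore demonstrates correctness of
the estimators under their assumed model, not robustness to the full
messiness of real libraries.

## Preprocessing

Transcripts with fewer than 50 reads summed over all libraries are removed
before any statistics; filtering precedes transformation. Size factors are
median-of-ratios over genes positive in every sample, computed on the log
scale and rescaled to geometric mean 1. Note that any reference estimated
from the data moves when a library is scaled: doubling one library
rescales *all* normalized counts by exactly 2^(1/n), so depth removal is
exact only up to that global factor (the test suite asserts this exact
bound).

Gene-wise dispersions are method-of-moments on normalized counts,
`alpha_g = max(0, (var - mu)/mu^2)` — deterministic and adequate for trend
fitting, though noisier than maximum likelihood. The trend
`alpha = a0 + a1/mu` is fit by iteratively reweighted least squares in
1/mu with gamma-style weights (1/fitted^2) and exclusion of genes whose
ratio to the fitted trend leaves [1e-4, 15]; zero-dispersion genes are
excluded up front; a0 is clamped to 1e-8 if the fit turns non-positive.
No per-gene shrinkage toward the trend is performed (out of scope).

The VST is the closed form for this trend,

    vst(u) = log2( (1 + a1 + 2 a0 u + 2 sqrt(a0 u (1 + a1 + a0 u))) / (4 a0) ),

strictly increasing, finite at u = 0 (`log2((1+a1)/(4 a0))`), and
asymptotically log2(u). It is fit blind to the design (no condition
labels), matching the tool default and avoiding leakage into the ML stages.

## Differential expression

The workflow is the limma-voom one, reimplemented:

1. `log-CPM = log2((K + 0.5)/(L + 1) * 1e6)`.
2. Unweighted gene-wise OLS on a treatment-coded design (sucrose diet as
   reference; source colony as fixed-effect indicator block). A lowess
   (span 0.5, 3 robustifying iterations) of sqrt(residual SD) on average
   log2 count gives the mean-variance trend; each observation's weight is
   trend(fitted log2 count)^-4 with flat extrapolation.
3. Per-gene weighted least squares, batched over genes.
4. Manual contrasts `c'beta` with unscaled variance `c'(X'WX)^-1 c`.
5. Empirical-Bayes moderation: the prior (d0, s0^2) is estimated by
   matching moments of `e_g = log s_g^2 - digamma(d_g/2) + log(d_g/2)`;
   `trigamma(d0/2) = var(e) - mean(trigamma(d_g/2))` is solved by Newton
   iteration (d0 = +inf when the right side is non-positive, in which case
   all variances pool to s0^2 and the statistic is z-like). Posterior
   variances are the usual precision-weighted combination and moderated t
   has d0 + d_g degrees of freedom.
6. Benjamini-Hochberg adjustment; DEGs at FDR < 0.05 and |log2FC| > 0.6,
   both strict inequalities.

Colony blocking is implemented as fixed-effect indicators rather than a
random-effect consensus correlation: it matches the design-matrix approach,
is deterministic, and with colonies nested in stocks it forces the analyst
to fit within-stock models for diet contrasts (the cross-stock fit drops
colony), which is how the per-stock DEG tables are produced here. Since
colony determines stock, a design requesting both raises a rank-deficiency
error naming the aliased columns rather than silently dropping one.

DE runs on voom log-CPM by default; the VST matrix is reserved for the
distance/clustering and machine-learning stages (`voom_pipeline` accepts
any ExprMatrix if the other convention is wanted). The whole stage is
cross-checked against Bioconductor limma in the test suite; agreement is
to ~1e-4 in logFC with prior parameters matching to <0.1%, residual
differences traceable to R's `lowess` vs statsmodels'.

## Distances, MDS, clustering, CV contrast

The between-sample distance is the leading log fold change in pairwise
mode: for each sample pair, the RMS of the `top` (default 300) largest
absolute expression differences, with the top set recomputed per pair.
With `top = n_genes` it reduces to the plain RMS difference. Classical
(Torgerson) MDS double-centers -d^2/2 and takes the top-k eigenpairs;
variance explained is relative to the positive eigenvalue mass and
negative eigenvalues (non-Euclidean input) are truncated and counted in
the result metadata. Axis signs are fixed (first nonzero loading positive)
so results are reproducible across platforms.

Hierarchical clustering is average linkage on 1 - Pearson r (the linkage
method is unstated in the original description; average is the package
default and configurable). The coefficient-of-variation contrast computes
per-gene within-group CV = SD/mean and compares the two groups' CV vectors
with a Welch two-sample t (Welch-Satterthwaite df); zero-mean genes are
dropped and counted.

## Random-forest biomarkers

A `RandomForestRegressor` predicts cage dry mass from VST values. All model
quality is out-of-bag: OOB predictions are averaged over the trees that did
not draw each sample (an error instructs raising `n_trees` if any sample is
never out-of-bag), OOB RMSE/R^2 are computed from them, and the default
importance is **OOB permutation importance** — the mean across trees of the
OOB MSE increase when one feature's values are permuted. This is signed, so
"features that hurt the model" is well defined; a bias-corrected impurity
importance (impurity minus the impurity of a forest refit on permuted
responses) is available as `importance_mode="impurity_corrected"`.

The elimination loop per round: tune `mtry` over {p/10, p/3, p/2, sqrt(p)}
by OOB RMSE; record (feature set, OOB RMSE, OOB R^2) for the tuned model;
drop every feature with importance <= 0 (not a fixed fraction — the
literal reading of removing features that negatively impact performance);
stop when nothing drops, fewer than two features remain, or 50 rounds
elapse. The optimum is the OOB-RMSE-minimizing round, ties resolved toward
the smaller set. `n_trees` defaults to 1000; permutation importance is
evaluated with a block-tiling scheme (all features of a chunk predicted in
one call per tree) so the default is tractable on one CPU.

Triage: Pearson r of each selected feature with weight, two-sided p from
the t distribution with n-2 df; the positive tier is r > 0, p < 0.05
(unadjusted — the multiplicity treatment of the original correlation step
is unstated, so the plain version is the default and the threshold is an
argument); the final panel is r >= 0.75 (inclusive — the published rule is
a cutoff *of* 0.75) and p < 0.05.

## SVM stock classification

Candidate features are the union of the two stocks' core DEG sets. The
ranking loop standardizes features, fits a linear soft-margin SVM (C = 1,
no inner tuning, so the external CV is unambiguous), scores each feature by
|w_j| times the absolute two-sample t statistic of the feature computed on
the current support vectors, and eliminates the lowest ceil(10%) per round;
the reversed elimination order is the ranking. The support-vector-t
composite is a documented stand-in for the referenced sigFeature scoring,
whose exact formula the original text does not restate; plain |w| SVM-RFE
is available via `mode="svmrfe"`. Ties are broken toward ranking the
smaller column index first.

Performance is scored by **external** stratified ten-fold CV: for every
fold the standardization and the entire ranking are recomputed on the
training split, and the held-out error is recorded at each panel size k.
The reported feature list is the full-data ranking (one list, as a single
reported panel requires), while the error curve remains leakage-free; on
label-permuted data the curve stays at chance at every k, which is the
test the internal-CV shortcut would fail. Fold assignments are seeded and
returned.

## DEG set algebra and enrichment

Core sets are intersections of per-diet DEG sets within a stock; Venn
accounting is plain set algebra (the |A| + |B| - |A ∩ B| identity is
property-tested). Biotype enrichment is a 2x2 chi-square with 1 df and no
continuity correction by default (toggleable; the original chi-square
values are uncorrected in style), the background universe being the
post-filter gene list. When any expected cell is below 1 a Fisher exact p
is reported alongside.

## Problem sizes and numerical conventions

The validation suite runs at desk scale, chosen as the package's standard
benchmark sizes: 2,000-gene / 24-sample null and power simulations (20 and
3 seeds), 5,000 genes for dispersion- and prior-recovery checks, 520
features x 112 cages with a 20-gene planted program for the RF stage
(5 seeds, 1000 trees), 300-400 candidate features for the SVM stage, and
1,500 genes for enrichment detection (5 seeds). Reported headline numbers
from the real 11,310-transcript dataset (e.g. the 308-feature optimum or
the 46-gene panel) are properties of that dataset and are not reproduced
by these synthetic runs; the synthetic benchmarks test the machinery, at
matched design shape (112 cages) but reduced gene count.

Other conventions: seeds propagate through `numpy.random.default_rng` and
per-fit integer seeds derived arithmetically from (seed, round, mtry), so
every stage is bit-reproducible; lowess uses delta = 0; BH adjustment is
statsmodels' `fdr_bh`; matrix ranks use numpy's SVD-based rank; all
file formats are plain TSV/CSV/JSON.

## Known limitations

- Dispersion trend recovery is exact only under the null generator
  configuration; planted effects and colony variance inflate the
  method-of-moments dispersions (by design, as in real tools).
- The moderated-t workflow assumes the scaled inverse-chi-square variance
  prior; heavy-tailed variance distributions would call for the robust
  variant, which is not implemented.
- RF feature recovery is bounded by the weakest planted loadings
  (gamma near 0.3 log2 per unit score is close to the noise floor at
  n = 112); the benchmark's ~80% median recovery reflects that floor, not
  an estimator deficiency.
- The SVM stage fixes C = 1; data needing regularization tuning would
  require nesting that tuning inside the external CV.
- No GO/KEGG enrichment, no read-level simulation, no mixed-effect
  consumption/weight models: out of scope.
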