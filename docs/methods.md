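# Methods

This note documents the models and procedures implemented in `histotype`,
the choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate. Everything quantitative here is
computed by the test suite or by `scripts/acceptance.py`; nothing is quoted
from external analyses.

## Problem setting

Invasive lobular (ILC) and invasive ductal (IDC) breast carcinoma are
distinguished histopathologically, but the morphological boundary is fuzzy
and inter-pathologist disagreement is substantial. The package builds a
transcriptomic classifier of histotype from several independent cohorts of
log2-scale expression profiles with pathology labels, then evaluates it
against pathology, tumor grade, outcome, and drug response in cell lines.
The minority (lobular) class is ~11% of samples, which shapes several
choices below.

## Preprocessing

Expression is accepted as an already log2-scale genes x samples matrix (raw
normalization pipelines are out of scope; a `log2(x+1)` flag covers
count-like inputs). Missing values are rejected unless explicit gene-median
imputation is requested. Two transformations are used:

- **Cohort mean adjustment** — every gene is centered to mean zero within
  each cohort (per-gene, per-cohort). This removes additive batch effects
  while leaving within-cohort contrasts untouched. It is applied jointly to
  the discovery cohorts before training. Validation cohorts are scored *as
  measured* by default: the classifier carries its own standardization, and
  a deployed assay cannot re-center a single new sample. `adjust=True`
  performs matched-conditions scoring when a whole cohort is available.
- **Gene standardization** — mean 0 / SD 1 per gene using the sample SD
  (n−1). The per-gene means and SDs estimated on the discovery data are
  stored in the classifier and reused verbatim for any new samples, so
  scoring is reproducible across cohorts and platforms.

## Consensus clustering (structure assessment)

For each cluster count k (default 2..7), 250 resamples (default) of 80% of
samples are clustered and the consensus matrix entry M_k[i,j] is the
fraction of co-sampled resamples in which i and j co-clustered. The phrase
"k-means with hierarchical clustering under Pearson correlation" is
operationalized as a hybrid: per resample, k-means centers are initialized
from the k-cut of an average-linkage tree under (1 − Pearson) distance on
the subsample, then standard k-means runs to convergence on z-scored
features. This honors both ingredients and is deterministic given the
subsample. Pairs never co-sampled are flagged and excluded from the CDF.

Stability is read from the empirical CDF of off-diagonal consensus values on
a 101-point grid: A(k) is the area under the CDF (trapezoidal) and
delta(k) = A(k) − A(k−1). The selected k is the smallest whose successor
adds little area (delta(k+1) < 0.1·A(k)); if no plateau exists the largest
k is returned with a warning. Note that delta(k) has a geometric floor —
refining a partition always moves some consensus mass — so the criterion
detects the *relative* flattening, and the resample count and subsample
fraction are documented choices, not reproductions of any published run.

Gene/sample dendrograms use average linkage under
1 − uncentered correlation (inner product over the product of uncentered
norms), with deterministic leaf ordering.

## Nearest shrunken centroid (feature reduction)

Standard soft-thresholding construction for classes k ∈ {ductal, lobular}:
pooled within-class SD s_i per gene with the fudge constant s0 = median(s_i)
(the usual convention; nothing in the source fixes it), class priors set to
empirical frequencies (appropriate for the 11%/89% imbalance),
m_k = sqrt(1/n_k − 1/n), standardized deviations
d_ik = (x̄_ik − x̄_i)/(m_k (s_i + s0)), shrunken by
d′ = sign(d)·max(|d| − Δ, 0). Classification minimizes
Σ_i (x_i − x̄′_ik)² / (s_i+s0)² − 2 log π_k over surviving genes; exact ties
go to ductal, the diagnosis-of-exclusion majority class (configurable
convention, asserted in tests).

The shrinkage path uses 30 linear Δ values from 0 to max|d_ik| with
stratified k-fold CV (default 10 folds). "The minimal gene set before
lobular error begins to increase" is operationalized as a one-standard-error
rule on the *lobular-class* error: Δ* is the largest Δ (hence smallest gene
set) whose lobular CV error is within one binomial SE of the path minimum,
among Δ values retaining at least one gene (the pipeline requires two, the
minimum for a correlation pattern). The working-set size is data-dependent
and never hard-coded.

## Elastic net (signature selection)

Penalized binomial likelihood
(1/n)·Σ NLL + λ[α‖β‖₁ + (1−α)/2·‖β‖₂²], solved by IRLS with cyclic
coordinate descent on the working weighted least-squares problem
(numba-compiled kernel), warm-started along a 100-knot log-spaced λ path
from λ_max (the smallest λ with all coefficients zero, computed in closed
form) down by a factor 10³. Convergence is max coefficient change < 1e-7;
the intercept is unpenalized; genes are standardized internally and
coefficients are reported on the standardized scale, which the scorer
consumes directly. Correctness is enforced by tests: subgradient (KKT)
stationarity within 1e-4 at every returned λ, and agreement with an
independent convex solver (lasso endpoint) and a direct Newton solve (ridge
endpoint) within 1e-6.

Open parameters and their defaults: α = 0.5 (the mixing weight is not
recorded in the source analysis; it is prominent in the API and CLI);
cross-validated error = mean held-out binomial deviance (not
misclassification), with λ_min = argmin and stratified folds; λ_1se
selection is deliberately not offered. If λ_min keeps fewer than two genes
(possible at weak signal), the pipeline falls back to the best-CV λ with at
least two nonzero coefficients, with a warning — a correlation pattern is
undefined below two genes.

## Correlation-pattern classifier, cutoff and strict band

A sample's **lobular score** is the Pearson correlation between its
standardized signature-gene expression and the signature's coefficient
vector ("the pattern"); scores live in [−1, 1] and are invariant to affine
transforms of the sample's sub-vector, which is what makes cross-platform
application sensible. Scores above the cutoff call lobular.

The **optimal cutoff** c* minimizes the misclassification count over all
discovery samples, searching midpoints of adjacent sorted unique scores plus
all-lobular/all-ductal sentinels; ties resolve toward the candidate nearest
the median score.

The **strict band** contains the cutoffs statistically indistinct from c*:
each candidate's error proportion e(c) is compared with e(c*) by a pooled
two-proportion Z test over the same n samples,
Z = (e(c) − e(c*)) / sqrt(p̄(1−p̄)·2/n), two-sided p > α (default 0.05)
meaning indistinct. When e(c*) = 0 the comparison is exact: a Binomial(n, 0)
null makes any error distinct, so the indistinct set is exactly the
zero-error cutoffs — the between-class gap. The band is the contiguous
indistinct run around c*, widened to the unique scores bounding its
outermost inter-score intervals, so every cutoff value strictly inside the
band is indistinct; with perfectly separated discovery scores the band is
exactly the gap and every discovery sample is still called. Isolated distant
cutoffs that happen to pass the test are ignored (contiguity rule). Under
the strict model, lobular requires score ≥ c_hi, ductal requires ≤ c_lo,
anything between is *indeterminate*.

A consequence worth knowing: in the zero-error regime the band width tracks
the geometric gap between the classes' scores, so indeterminacy on shifted
data is not a monotone function of class separation once discovery is fully
separable. The monotonicity test therefore runs at conditions where the
optimum still makes errors and scores validation cohorts batch-adjusted
(matched conditions), isolating the band's statistical behavior from cohort
shift.

## Marker-negativity mixture

A two-component Gaussian mixture with unequal variances is fit by EM to the
standardized marker (CDH1-like) values: 10 restarts (first quartile-based,
rest random pairs), convergence at log-likelihood change < 1e-8 or 500
iterations, variance floor 1e-4 with a warning, per-iteration monotonicity
asserted. The negativity threshold is the point between the two means where
the posterior probability of the low component crosses 0.5 (closed-form
quadratic root). Component overlap is flagged via Ashman's
D = √2·|μ₂−μ₁|/√(σ₁²+σ₂²) < 2. Single-marker diagnostic rules (mixture
threshold, median, first quartile — low calls lobular, ties to the low
side) are compared against histology.

## Evaluation

Concordance with pathology is reported over all samples forced to a call
(plain) and over called samples only (strict), with the indeterminacy and
reclassification rates; samples whose histology is neither ductal nor
lobular are excluded and counted. Grade is cross-tabulated as pathology x
predicted x grade with an NA column and margins. Survival uses an in-repo
Kaplan-Meier product-limit estimator and a from-scratch logrank O/E/V tally
(both cross-checked against lifelines to 1e-10 and against hand-computed
and permutation oracles), with administrative truncation at 120 months (the
10-year horizon) before testing. Univariate Cox hazard ratios with the
likelihood-ratio p are delegated to lifelines for reporting — the partial
likelihood is routine and not re-derived here; both the logrank and Cox-LRT
p-values are emitted, labeled.

## Drug-sensitivity correlation

Cell lines are scored exactly like tumors. Per compound, the Pearson
correlation between scores and sensitivity is computed pairwise-complete on
−log10 molar GI50, so positive r means more-lobular-like lines are more
sensitive; compounds with fewer than 10 non-missing lines or constant
profiles are dropped with counts reported. Each compound class with ≥3
correlated members is tested by a Welch two-sample T of member vs non-member
correlations (a documented reading of "compared to all compounds");
Bonferroni correction multiplies by the number of classes actually tested in
the run, which is recorded in the output.

## Synthetic data generator

`SimulationSpec` defaults define the reference study: 3 cohorts x 200
samples (6 x 200 when validation cohorts are simulated), lobular prevalence
0.11, 2000 genes of which 100 are informative with class-mean differences
drawn N(0, 1.0²) shared across cohorts, additive per-gene per-cohort batch
shifts N(0, 0.5²), residual noise N(0, 1²). The marker gene is a two-mode
mixture (means ±2, SD 0.5) with low-mode probability 0.45 in lobular vs
0.05 in ductal samples. Grade is class-conditional (lobular skewed to grade
2: 0.17/0.65/0.18; ductal to grade 3: 0.11/0.41/0.48; 5% missing). Survival
is exponential in months with lobular baseline hazard 0.004 and a ductal
hazard ratio of 2 (recurrence 1.5x faster), administratively censored at
120 months. The `rnaseq_like` re-measurement multiplies each gene's dynamic
range by 1.6 about its mean and adds scaled Student-t(4) noise — a stand-in
for a wider-dynamic-range platform, configurable and not calibrated to any
real instrument. The cell-line generator gives each line a latent
lobular-likeness score driving both its expression (through the same
informative-gene effects, so a trained classifier estimates the latent
score) and, for a designated sensitive compound class, its −log10 GI50 at a
chosen coupling strength.

What the generator does **not** emulate: correlated gene-gene structure
(effects are additive and independent), copy-number or mutation events,
non-additive batch effects, platform-specific probe behavior, censoring
mechanisms other than administrative, or the pathologist noise in the labels
themselves. Consequently the synthetic task is *easier* than the real one —
at the reference conditions the signature separates classes almost
perfectly under matched conditions, and realistic concordance/indeterminacy
magnitudes (roughly 96%/99% and 5–10%) appear only when validation cohorts
are scored as measured, with their batch shifts intact. Passing tests
demonstrate the pipeline's internal correctness and the qualitative behavior
of its statistics, not clinical performance.

## Determinism and problem sizes

All randomness descends from one seed; each stage draws its own substream
seed by hashing the stage name, so adding or reordering stages does not
perturb other stages, and identical runs are bit-identical. Tests and the
acceptance script use deliberately scaled problem sizes chosen as the
smallest at which each property is statistically stable: the end-to-end
study at the full reference conditions (6 x 200 samples, 2000 genes);
band-behavior sweeps at 4 x 200 samples with 400 genes / 50 informative;
consensus checks at 60–80 samples with 50–100 resamples; the drug screen at
60 lines x 200–1000 compounds.

## Known limitations

- The strict band's zero-error branch ties band width to the score gap, as
  discussed above; alternatives (e.g. requiring a minimum error increment)
  were not pursued because the exact construction is underdetermined by the
  source description.
- The elastic-net CV standardizes genes once on the full data rather than
  re-estimating within folds; with hundreds of samples per fold the
  optimism is negligible, and the λ path is shared across folds by design.
- Consensus clustering recomputes the hierarchical initialization per
  resample (O(m²) per resample); for cohorts beyond a few thousand samples
  a sparser initialization would be needed.
- The two-component mixture assumes Gaussian modes on the standardized
  scale; markers with skewed high modes would bias the 0.5-posterior
  threshold toward the low mode.
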