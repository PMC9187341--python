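# Methods

## Model

Each feature (miRNA or gene) is treated independently. On the log2 scale
its expression in a cohort is modeled either as a single Gaussian
G(μ, σ²) or as a two-component mixture

    f(x) = π₁ G(μ₁, σ₁²) + π₂ G(μ₂, σ₂²),   π₁ + π₂ = 1,  μ₁ ≤ μ₂.

Bimodality of a feature means the two-component model is the better
description of the tumor cohort *and* both components hold a non-trivial
share of patients. σ denotes a standard deviation throughout (the
bimodality index squares it).

### Estimation

- **Two-component fit.** EM with ten deterministic starts: nine
  quantile splits (the sorted vector cut at the 10%…90% quantiles, each
  half's moments seeding a component) plus the exact 1-D two-means split.
  Convergence when the log-likelihood improves by less than 1e-8, capped
  at 500 iterations; the best start by log-likelihood wins. Initialization
  is deterministic, so fits are reproducible without a seed. The
  log-likelihood is checked to be non-decreasing at every iteration
  (1e-6 relative slack) and a violation is an error, not a warning.
- **Variance floor.** Component variances are floored at
  1e-4·(sample variance + 1e-8). The unconstrained mixture likelihood is
  unbounded (a component can collapse onto a few near-identical points);
  the floor keeps such solutions finite, and they then surface as a tiny
  mixing proportion and are screened out by the proportion constraint
  below. An equal-variance fit (`equal_var=True`, one shared σ², the
  mclust "E" model) is available and removes the collapse pathology
  structurally; the default keeps per-component variances.
- **Model selection.** BIC = −2·loglik + p·ln(n), lower wins; p = 2 for
  one component, p = 5 for the two-component model (two means, two
  variances, one free proportion; p = 4 under the shared-variance
  option). Two-component winners with min(π₁, π₂) ≤ 0.1 are classified
  `excluded_proportion`: a component holding a tenth of the cohort or
  less is an outlier group, not a mode.
- **k-means re-clustering.** Features judged bimodal are re-clustered
  with k = 2 k-means. In one dimension the optimal two-cluster partition
  is a contiguous split of the sorted values, so the split minimizing
  within-cluster SSE is found exactly by a prefix-sum scan — no Lloyd
  iterations, no initialization sensitivity, and the result provably
  attains the SSE optimum (tested against brute force). SSE ties break
  toward the lower-mean cluster. Per-cluster sample mean, SD (n−1
  denominator, floored as above) and proportion become (μ, σ, π). A
  cluster with fewer than two members has no SD; `kmeans_recluster`
  raises, and the scoring pipeline maps such features to score 0 (an
  outlier split, morally the same case as `excluded_proportion`).

### Scoring

The bimodality index of a two-component fit is

    BI = sqrt(π₁π₂) · (μ₂ − μ₁) / sqrt(π₂σ₁² + π₁σ₂²),

zero when μ₁ = μ₂, and invariant to shifting or positively rescaling the
data. By default BI is computed from the k-means-derived parameters
(`bi_source="kmeans"`); `bi_source="em"` uses the EM parameters instead.

Controlled mixture modeling (CM) then consults the control cohort:

- tumor unimodal or `excluded_proportion` → final BI = 0 (the feature
  still appears in the output, one row per input feature);
- tumor bimodal, control unimodal or `excluded_proportion` → final
  BI = raw BI, unpenalized;
- tumor and control both bimodal → both cohorts are re-clustered and

      BI_μ = BI − 1/(|μ₁C−μ₁T| + |μ₂C−μ₂T|),
      BI_π = BI − 1/(|π₁C−π₁T| + |π₂C−π₂T|),

  with the final score max(BI_μ, BI_π) clamped at 0. A zero distance sum
  (identical parameters) makes that penalty fully punitive (−∞ before the
  clamp). Negative scores clamp to 0 so ranked tables stay non-negative.

MM is the uncontrolled variant (no control branch); for every feature
CM ≤ MM.

### Operating characteristics (measured, not assumed)

On unimodal Gaussian nulls at n = 50 the full pipeline (BIC + proportion
constraint + k-means + BI > 1.4) flags ≈ 1.7–1.8% of features; at n = 200,
≈ 0.3%. An independent R implementation of the same procedure (mclust
model "E" + stats::kmeans) reproduces these rates, so they are properties
of the procedure, not of this implementation. Detection of well-separated
planted mixtures (6σ between modes, balanced proportions) is ≈ 100% at
n = 50. For features planted bimodal in *both* cohorts, suppression is
governed by the μ-penalty, whose 1/distance form is not scale-free: with
within-mode σ = 1 and a control cohort of 50, the component-mean distance
sum is pure estimator noise (SE ≈ 0.2 per mean) and ≈ 8–10% of shared
features still exceed BI = 1.4 because the *larger* of the two penalties
is kept. Larger control cohorts or tighter modes shrink this leakage;
users thresholding near 1.4 on small control cohorts should expect it.

## Preprocessing

Inputs are raw normalized expression (RPKM/RPM). The transform is
log2(x + c) with pseudocount c = 1 (zeros map to 0, exactly invertible);
c is configurable. Very lowly expressed features are removed when either
their non-zero fraction is below 0.1 or their mean raw expression is
below 1.0 — both configurable, both logged; filtering is defined on the
tumor cohort and the surviving feature list is applied to the control.
Cohort sizes can be equalized by bootstrap resampling of columns (with
replacement; a subsample mode exists), seeded and reported.

## Modules, survival, drugs

Modules are maximal cliques of size ≥ 3 in the graph whose edges join
feature pairs with Pearson r strictly > 0.5, computed over tumor samples
on the log2 scale; maximal cliques may overlap (a greedy `disjoint`
option keeps the largest non-overlapping ones). Maximality is what makes
"groups whose members are all pairwise correlated" well-defined; output
order is deterministic (size, then lexicographic).

Patients are stratified by agglomerative clustering of module-restricted
expression profiles — Manhattan (L1) dissimilarity, complete linkage,
tree cut at two groups; samples are canonically sorted by id first so the
partition is independent of column order. For single-module analyses the
group with higher mean module expression is labeled "high". An
alternative splitter assigns each patient by majority upper-component
membership across the module's features (`splitter="mixture"`). Group
survival is compared by a Cox proportional-hazards fit on the binary
indicator: HR = exp(β) for high (or group 2) vs low, 95% CI from the
coefficient SE, Wald p, and per-group Kaplan–Meier median survival with
CI (lifelines; Efron tie handling — survival times here are continuous,
so ties are measure-zero and the choice is immaterial). Zero events in a
group or an all-censored cohort are errors, not warnings. Association of
the split with TNM stage uses the classical chi-square test of
independence without continuity correction; all-zero stage columns are
dropped and expected counts below 5 are flagged.

Drug ranking computes, per drug, the Pearson correlation between
per-cell-line expression and log(IC50) over pairwise-complete cell lines
(at least 3; natural log — r is invariant to the base). Negative r marks
drugs more potent in high-expressing lines. Multi-miRNA modules are
summarized per cell line as the mean of member z-scores; per-member
correlations are also emitted.

## Synthetic data

The generator emulates the study design end to end: a tumor cohort with a
smaller control cohort, features drawn on the log2 scale (clipped at 0,
matching log2(raw+1) ≥ 0) from four archetypes — `unimodal`,
`tumor_bimodal` (two components in tumor, unimodal control),
`shared_bimodal` (same mixture in both cohorts), `low_expressed` (≥ 95%
zeros, exercising the filter). Default planted mixtures put modes at 2
and 8 with σ = 1 (6σ separation, a ~64-fold expression switch) and
π = 0.5; defaults are n_tumor = 300, n_control = 50. Bimodal features
sharing a `subgroup` id reuse one per-sample membership vector, making
them concurrently expressed — the planted ground truth for module
detection. Survival times are exponential with baseline hazard 1/1000 per
day, multiplied by the configured hazard ratio (default 2.0) for patients
in the planted upper component — the exponential family makes the true
Cox HR equal the configured multiplier exactly. Censoring is independent
exponential with its rate solved numerically so the expected censored
fraction matches `censor_rate` (default 0.2); censor_rate = 0 yields
all-event data. TNM stages are categorical (0.30/0.30/0.25/0.15 for
I–IV), independent of expression by default; a `stage_coupling` knob
shifts upper-component patients toward late stages to exercise the
chi-square alternative. Sex is balanced and independent. The drug panel
plants a target population correlation ρ per drug via
log(IC50) = ρ·z + sqrt(1−ρ²)·ε with z the standardized expression, so
|ρ| = 1 is exact and empirical r at 13 cell lines is unbiased up to the
usual O(1/n) Pearson bias. One seed determines every output.

What the generator does **not** emulate: count-level noise (negative
binomial read counts), normalization artifacts, batch effects,
heavy-tailed or skewed modes, dependence between censoring and survival,
or correlation structure beyond shared subgroup membership. Passing tests
therefore demonstrate correctness of the machinery and its operating
characteristics under clean Gaussian mixtures, not robustness to
real-data pathologies.

## Problem sizes

The test suite and the acceptance script use: 5,000 features × 50 samples
for the null calibration; 100 features × (300 tumor + 50 control) per
cohort with 25–100 replicate seeds for discrimination; 100 seeds of
n = 500 survival cohorts (50 in the script); 200 random vectors and
50–100 random correlation structures for the optimality and enumeration
checks; 100 drug-panel seeds.

## Known limitations

- The μ-penalty is scale-dependent (see operating characteristics); a
  scale-free penalty (e.g. distances in within-mode SD units) would
  suppress shared bimodality more uniformly but would no longer be the
  method as defined.
- BIC-based selection at n ≈ 50 has a ~2% spurious two-component rate on
  Gaussian nulls; the BI > 1.4 threshold removes only part of it. At
  n ≥ 200 the pipeline is effectively silent on nulls.
- Only k ∈ {1, 2} components are considered; genuinely multi-modal
  features are reported as the best two-mode description.
- The Cox fit uses a single binary covariate; no multivariable
  adjustment, time-varying effects or proportionality diagnostics.
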