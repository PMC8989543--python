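# Methods

## Model

Per-gene weighted rare-allele burdens are modelled as left-truncated
negative binomial. For gene *i* with weighted count yᵢ:

- yᵢ ~ NB(μᵢ, θ), pmf f(y|μ,θ) = Γ(y+θ)/(Γ(θ) y!) · μ^y θ^θ/(μ+θ)^{y+θ},
  so Var[y] = μ + μ²/θ; θ is a single shared dispersion.
- log μᵢ = β₀ + β·xᵢ with eight predictors: x1 coding length (kb),
  x2 frequency score (weighted sum of reference-panel allele frequencies
  over the gene's retained rare variants, panels averaged), x3 = x1·x2,
  x4 oe_mis, x5 mu_mis, x6 oe_lof, x7 mu_lof, x8 exon GC fraction.
- truncation at integer t ≥ 0 restricts the support to y > t:
  g(y|μ,θ,t) = f(y|μ,θ)/(1 − F(t|μ,θ)). Genes with y ≤ t are outside the
  model's support: they are excluded from fitting, background-moment
  estimation and MLFC, and reported with p = 1 and a residual sentinel
  (they cannot display excess burden). t = −1 denotes the untruncated
  model and is internal.

The weight of a variant with functional score s ∈ [0,1] is w = ⌈s/b⌉,
floored at 1 so every retained allele contributes; b ∈ (0,1] is the score
bin length (b = 1, or the equal-weights switch, reproduces the unweighted
count). Scores missing at a variant take the gene mean, then the global
mean; a fully unscored input falls back to 0.5 with a warning.

Variant filters, applied in a fixed order before weighting: consequence
whitelist (missense, start/stop-loss, stop-gain, splicing, frameshift,
non-frameshift) → rarity (max reference-panel AF ≤ 0.01; absence from the
reference counts as AF 0 — absence from a large panel is itself evidence
of rarity) → case-enrichment (with controls present, drop a variant when
AF_control ≥ d·AF_case, d = 2 by default; the stricter reading
"keep only AF_case > d·AF_control" is available as
`enrichment_mode="require_case_enriched"`). Genotype-level QC mirrors
standard practice: GQ < 20 or depth < 8 sets a genotype missing; sites
with > 4 alleles, genotyping rate < 90% or Hardy–Weinberg p ≤ 0.001 are
dropped.

## Estimation

The likelihood is maximized over (β, log θ) — the log re-parameterization
keeps θ > 0 unconstrained. The analytic score stacks the untruncated NB
score with the truncation correction Σ_{j≤t} f(j)·s(j)/(1−F(t)); the
denominator uses the NB log-survival function, which stays exact where
the naive complement of the cdf loses all digits (1 − F(t) ≈ 1e−24 is
unrepresentable next to 1 in double precision). Optimization: BFGS from a
Poisson log-linear fit (statsmodels GLM) with a method-of-moments
dispersion start, followed by a few Newton steps using a
finite-difference Hessian of the analytic gradient. Near the optimum the
objective sits at the float-precision floor, so Newton steps are accepted
on gradient-norm decrease (with a 1e−8 objective-noise allowance);
convergence is declared when the mean-log-likelihood gradient max-norm
falls below 1e−6 (500 iteration cap; a non-converged model is returned
with a warning and `converged=False`). Predictor columns are standardized
internally for conditioning; coefficients are reported on the raw scale
(`beta`) and the standardized scale (`beta_std`), and the covariance is
the inverse observed information mapped through the standardization
Jacobian.

Saturated means μ\*ᵢ (the μ maximizing the truncated likelihood of a
single count) come from bounded 1-D minimization on [1e−8, 10·max(y,1)]
with tolerance 1e−10; the zero-truncated likelihood of small counts is
monotone toward μ → 0, so boundary solutions return the 1e−8 sentinel.
Saturated log-likelihoods are cached per distinct count within a fit.

Per-gene evidence: eᵢ = sign(yᵢ−μ̂ᵢ)·√(2|ℓ(yᵢ|μ\*ᵢ) − ℓ(yᵢ|μ̂ᵢ)|),
standardized by the empirical mean and SD of the residuals over the
converged background set and referred to the upper normal tail. The
standardization moments are global, not gene-specific: no per-gene
estimator is identifiable from a single observation per gene, and a pilot
with exact per-gene moments (computable in simulation) did not improve
calibration — the residual non-uniformity is count discreteness, not
moment error.

## Recursion, FDR and the grid

Background purification: fit on all in-support genes, score, exclude
genes at BH q ≤ 0.1, refit; stop when the excluded set repeats (cap 20
passes). Final scores for *all* genes come from the converged model.
Guards: the in-support set must provide ≥ 10 rows per coefficient, and
the procedure aborts if more than half the in-support genes exceed the
exclusion threshold. A single pass can in fact never exclude > 50% under
global standardization (BH at FDR 0.1 needs most standardized residuals
beyond ~1.6 SD, impossible by Chebyshev); the guard protects against
cumulative collapse across passes and degenerate thresholds.

Grid search: b ∈ {0.05, …, 1.00} step 0.05 × t ∈ {0, …, 5} — 120 cells.
Each cell rebuilds weights, counts and the frequency score at its b, runs
the recursive procedure at its t, and records the MLFC of the
post-exclusion background genes' p-values and the count of genes at
q ≤ 0.05. MLFC = (1/n)Σ|log₂(P₍ᵢ₎/(i/n))|. Cells are competition-ranked
(ties share the smaller rank) on MLFC ascending and significant count
descending; minimal rank sum wins; residual ties break toward smaller
MLFC, then smaller b, then smaller t. Failed cells rank last. The
canonical mode refits recursively in every cell; `fast=True` runs one
non-recursive fit per cell for exploration and is labelled non-canonical.
Reported q-values are Benjamini–Hochberg; exome-wide significance for
reporting is 2.5×10⁻⁶.

## Synthetic data: what it emulates and what it does not

The generator provides the statistical structure the test assumes, at two
levels. The burden level draws y ~ NB(exp(β₀ + z·slopes), θ) on
standardized (sample z-score) features drawn from realistic raw
distributions: coding length 0.2 + Gamma(3, 0.6) kb (median ≈ 1.8 kb),
GC ~ Beta(25, 23), constraint ratios Beta-shaped on [0, 1.6]/[0, 1.8],
mutation rates proportional to length, frequency score Gamma-scaled by
length. The log-baseline excess is winsorized at ln 50 (≈ 50× the median
scale, a TTN-like top gene); unbounded products of skewed features
otherwise imply genes with physically impossible burdens. The variant
level splits each gene's NB total across its variants with a symmetric
Dirichlet-multinomial, attaches Uniform(0,1] scores, two reference panels
with small AFs (30% of variants absent from the reference) and binomial
control counts at the case frequency.

Default study conditions: 300 cases/300 controls; median weighted burden
40 at that size, scaling linearly with cases (raw counts of a few to tens
per gene times mean weight ≈ 10 at b ≈ 0.05); θ = 10 as the residual
dispersion after conditioning on the eight predictors (CV ≈ 35% at the
median burden — a well-fitting background model; θ = 2 serves as the
heavy-overdispersion stress setting in the calibration studies). True
slopes are defined on the standardized feature scale, where a uniform
absolute recovery tolerance is meaningful across predictors; on raw
scales the information content per predictor differs by orders of
magnitude (GC fraction alone spans ~0.07 SD units).

Injected susceptibility genes carry 4–5 risk variants at case allele
frequencies 1.0–1.5% with odds ratios drawn from [2, 5] (controls at
f/OR; an infinite OR zeroes them); burden-level injection adds
Poisson((fold−1)·μ) alleles — risk alleles accumulate near-independently
across patients, so the injected component is not gene-level
overdispersed. Power studies hold one gene design fixed across replicates
and sample sizes (replicates emulate resampling subjects from a cohort),
share random streams across sample sizes, and inject into a
typical-baseline gene.

What passing tests do and do not show: the generator is
model-consistent, so calibration and recovery results demonstrate the
correctness of the machinery, not robustness to real-data misspecification
(relatedness, batch effects, annotation error, predictor-dependent
dispersion). Real genomes also fix the absolute power scale; with this
synthetic background the injected signal saturates power near 1 at all
three canonical sample sizes, so only orderings and calibration are
asserted, not absolute power values.

Two structural facts about calibration discovered during design, worth
knowing when interpreting KS-based checks: (1) p-values inherit the
discreteness of the counts, with uniformity gaps of roughly half the
largest pmf value — at 15,000 genes a KS test at α = 0.01 resolves
D ≈ 0.013, so approximate uniformity in the KS sense requires burden
counts at the weighted scale (median ≈ 40+), which is precisely what
score weighting produces; unweighted counts at median ≈ 6 fail KS under
the *true* model. (2) Empirical global standardization absorbs most
variance misspecification, which is why a truncated-Poisson fit on
overdispersed counts inflates the p < 1e−4 class by "only" ~20× rather
than catastrophically.

## Numerical choices and degenerate inputs

- All likelihood terms via log-gamma; truncation denominators via the NB
  log-survival function; the NB upper-tail comparator uses exact log-space
  summation of the mass below the threshold (Poisson limit when θ is
  omitted — the worked example's dispersion is unspecified).
- Ties in the results table break by gene id (stable sort), making
  re-runs byte-identical.
- Zero-variance or collinear designs raise an identifiability error;
  fits require ≥ 10 rows per coefficient.
- A variant mapped to several genes contributes to each; multi-allelic
  sites are split per alternate allele before QC.
- Missing annotation fields are median-imputed and the gene flagged
  (`annotation_imputed`) rather than dropped, keeping the background
  large while allowing sensitivity analyses.
- MLFC requires p ∈ (0,1]; the engine floors p at 1e−300 before MLFC to
  absorb survival-function underflow at extreme z-scores.

## Known limitations

- No covariate adjustment (confounders must be handled upstream, e.g. by
  patient pre-selection) and no family-relatedness modelling.
- A single shared θ; predictor-dependent dispersion in real data will
  leak into the residual tails.
- The equal-weights mode on sparse counts (median burden below ~20) is
  calibrated in the MLFC sense but not strictly KS-uniform at exome scale,
  as discussed above.
- The case-enrichment filter's two readings differ for variants near
  AF_case ≈ AF_control; both are exposed, the permissive one is default.
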