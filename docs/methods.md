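# Methods

## Model

gruyere is a hierarchy of per-gene Bernoulli GLMs for case-control
rare-variant association. For gene *g* with genotype dosages `G` (n samples ×
p variants), covariates `X` (n × c), and scaled functional annotations `Z`
(p × q):

```
logit μ_ig = X_i α_g + G_ig β_gj
β_gj      = w_g · w_j · (τ₀ + Σ_k Z_jk τ_k)
w_j       = Beta(MAF_j | 1, 25)          # density, up-weights rarer variants
α_g, w_g  ~ Normal(0, 1)
τ         ~ Dirichlet(1/K)               # K weights on a simplex
```

`τ` is shared genome-wide: it expresses which annotation classes (splicing
disruption, conservation, TF-binding deltas, ...) carry trait-relevant
signal. Constraining `τ` to the simplex pins the scale that would otherwise
trade off freely against `w_g` (w_g/c with cτ leaves the likelihood
unchanged). Like a burden test, all variants in a gene share the sign of
`w_g`; dispersion information enters only through the annotations.

The intercept weight `τ₀` is supported throughout (`include_intercept_tau`),
in which case the simplex has K = q+1 components and a pure-burden component
survives even when no annotation is informative. The simulation study
(below) uses the no-intercept construction, K = q.

## Two-step fitting

**Step 1 — joint fit.** Fitting `τ` genome-wide over all genes would be both
slow and statistically wasteful (null genes carry no information about
annotation relevance), so the joint fit runs on a screened subset: genes
passing a lenient p < 0.01 from an external rare-variant test, or from the
built-in covariate-adjusted MAF-weighted burden LRT. Inference is stochastic
variational: mean-field Normal guides for every `α_g` and `w_g`
(initial guide sd 0.1), a point (delta) guide for `τ` parameterized by an
unconstrained softmax initialized uniform. The ELBO gradient is a
single-sample reparameterized Monte Carlo estimate; the Bernoulli-logit
likelihood gradient and Gaussian KL terms are analytic. Optimization is Adam
with learning rate 0.1 for 300 epochs, full batch. Because the effect is
bilinear in `(w_g, τ)`, each gene's genotype contribution collapses to a
fixed n × K matrix `D = [Gw·1, Gw·Z]` (`Gw = G ⊙ w_j`) computed once, making
an epoch O(M·n·(c+K)); a 30-gene, 2,000-sample fit takes about one second on
one CPU core.

Under the alternative Gamma prior on `w_g` (robustness experiments) the
guide is a mean-field Normal on `log w_g`, i.e. log-normal on the positive
scale, with the prior density and Jacobian entering the ELBO explicitly and
posterior means/sds estimated from 50 guide draws.

**Step 2 — per-gene tests.** With `τ` fixed, each gene's model is an
ordinary logistic regression on `[X, G·b]` where
`b_j = w_j (τ₀ + Σ_k Z_jk τ_k)` is a fixed per-variant score. Fits use
IRLS with a ridge of 1e-6 for numerical stability and step halving;
separation is flagged at coefficient norm > 50 and yields an NA p-value
rather than an exception. The gene-level statistic is
`LR = 2(LL_combined − LL_covariate-only)` referred to χ²(1); values in
(−1e-8, 0) are clipped to zero, anything lower is a nested-model violation
and raises. Significance uses Bonferroni per cell type with a strict
inequality. Step 2 runs for all supplied genes, not only the screened
subset.

## Region construction and annotations

Non-coding test sets come from Activity-by-Contact enhancer–gene tables: for
each gene and cell type, all elements with ABC score ≥ 0.02 (inclusive,
configurable) are aggregated and the rare variants inside them form the
gene's set. A variant inside elements of several genes joins every such set.
Coordinates are half-open 0-based internally; VCF positions convert at the
containment check, indels by start position only. Promoters and enhancers
are both included, the class kept for reporting.

Annotation preprocessing: columns with > 5% missingness are dropped;
residual missing entries are imputed as 0 (least functional) after
orientation; every column is min-max scaled to [0, 1] with a direction flag
for lower-raw-is-functional scores. Related columns collapse to one category
score by rank-1 NMF (scikit-learn, multiplicative updates, 500 iterations,
tol 1e-6, deterministic NNDSVDa initialization), scaling raw columns before
factorization and rescaling the factor after. The sparse splice-delta
quartet uses an element-wise maximum instead. Sequence-model delta scores
are Z-scored against supplied background statistics, and the composite "max"
(resp. "min") is the magnitude of the most positive (most negative) Z-score
over the cell type's enriched assays, min-max rescaled — the "absolute
minimum" is interpreted as |most negative|, flagged in reports.

## Genotype QC

Order is fixed: samples with > 10% missingness are removed first, then
variants with call rate < 90% over surviving samples; MAFs are recomputed
after sample removal (configurable). Only biallelic variants with observed
MAF ≤ 0.05 are kept; dosages count the per-site minor allele. Missing
dosages are imputed with the expected dosage 2·MAF (the raw MAF is available
behind a flag; the convention is genuinely ambiguous in common usage). QC
applied to already-clean data removes nothing; with missingness straddling
both thresholds simultaneously a second pass can remove further samples —
realistic missingness patterns (low background, a few clearly bad
samples/variants) make the operation idempotent. The train/test split is
80/20, stratified by ancestry, `round(0.8·size)` per stratum, deterministic
under the seed; strata smaller than two samples go wholly to train.

## Synthetic cohorts and the simulation study

The generator emulates a rare-variant cohort at desk scale. Defaults, chosen
once: n = 2,000 samples; M = 30 genes × 100 variants; MAF ~ Beta(0.5, 50)
truncated to [5e-4, 0.05] (median ≈ 0.004, strongly rare-skewed); genotypes
Binomial(2, MAF); c = 10 covariates = intercept + 9 equicorrelated Gaussians
(ρ = 0.5, min-max scaled) — correlation is what makes `α_g` the
hardest block to recover; q = 6 annotation columns from a sparse mixture
(75% Beta(1, 10) near zero, 25% Beta(4, 2) high), mimicking functional
scores that flag a minority of variants. The generator does **not** emulate
linkage disequilibrium between rare variants, ancestry structure, or
platform batch effects, so passing recovery tests demonstrates correctness
of the estimator under the model, not robustness to those real-data
features.

Phenotypes are drawn from the model itself with
`α_g, w_g ~ Normal(0,1)`, `τ ~ Dirichlet(1/K)`, and one Bernoulli phenotype
vector per gene (a single shared vector cannot satisfy 30 different
per-gene truths). The simulated effect uses the no-intercept construction
`β = w_g w_j Z τ`: with the intercept included, the burden column is nearly
in the span of the annotation-weighted burdens and the `τ₀` direction is too
weakly identified for a 300-epoch fit to resolve, so τ recovery is not a
meaningful measurement there; both constructions remain available via
`include_intercept_tau`.

Heritability is the liability-scale variance share
`Var(Gβ) / (Var(Xα) + Var(Gβ) + π²/3)` — a stand-in definition, stated
explicitly because reasonable alternatives exist. It is controlled by
per-gene rejection: `w_g` is redrawn (up to 2,000 times) until the gene
lands in the configured band, default 5–30%; a whole-simulation redraw would
essentially never accept because the mean over 30 genes concentrates. The
per-simulation heritability reported is the mean over genes.

Recovery is scored per simulation as Pearson R over four blocks: flattened
`α` (M × c values), flattened `β` (reconstructed deterministically from
fitted `w_g`, MAF weights, and `τ̂`), the `w_g` vector, and `τ`. The study
also runs with varied Normal prior scales (0.5, 2.0) and in prior-mismatch
mode (simulate `w_g` ~ Normal, fit with a Gamma(1,1) prior through the
log-normal guide — sign information is unrecoverable for negative-effect
genes, which is the point of the experiment).

## Omnibus combination and evaluation

ACAT combines per-gene p-values across tests through the Cauchy transform
with equal weights by default; `p = 1` is nudged to `1 − 1e-15` with a
warning, `p = 0` raises, and p below 1e-16 uses the standard `1/(pπ)` tail
approximation. Genes missing from some methods are combined over the
available ones. Prediction metrics are AUROC (Mann–Whitney with tie
averaging, via scikit-learn) and accuracy at a 0.5 probability threshold
(the threshold is a package choice), per gene and for the cross-gene average
of predicted probabilities.

## Numerical notes and limitations

- All randomness flows through `numpy.random.default_rng` seeds; study
  seeds are derived as `(seed + 1_000_003·sim) mod 2³¹` and recorded in the
  output tables.
- The delta guide for τ includes the Dirichlet(1/K) log-prior, whose
  concentration < 1 mildly sparsifies the estimate; τ is clipped at 1e-10
  inside the prior gradient.
- The ELBO trace is a 1-sample MC estimate and is noisy; divergence is
  only warned about (50 consecutive worsening epochs), not acted on.
- Posterior sds for the Normal guides are the analytic mean-field scales;
  under the Gamma prior they are estimated from 50 guide draws.
- Relatedness pruning, ancestry PCs, phasing, and liftover between genome
  builds are out of scope; inputs are assumed pre-pruned and on one build
  (a build mismatch between genotype and CRE tables is the caller's
  responsibility to avoid).
- Desk-scale study sizes (10 simulations, 30 genes) were chosen so the full
  study runs in well under a minute per mode on a single core; the scaling
  to more genes/simulations is linear.
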