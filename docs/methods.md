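# Methods

## Model and inference

Enrichment of a GO category is modelled per category by logistic
regression of membership on DE significance:

    logit P(y_i = 1) = β0 + β1·s_i + β2·g(l_i)

with the uncorrected variant omitting the length term. The regression
asks whether, conditional on transcript length, genes with stronger DE
evidence have higher odds of belonging to the category; β1 > 0 is the
enrichment direction. The model treats length bias as ordinary
confounding: length enters both the DE test's power and (for many
categories) membership, and conditioning on it isolates the direct
membership–significance association.

**Fitting.** Maximum quasi-likelihood via iteratively reweighted least
squares (IRLS), initialized at μ = (y + 1/2)/2, at most 25 iterations,
converged when the relative deviance change is below 1e−8 (the classical
GLM criterion). Non-intercept design columns with zero variance are
dropped with a log note (so constant lengths reduce the corrected test
exactly to the uncorrected one); a rank-deficient design after cleaning
is an error. Apparent separation (|β̂| > 15 or an SE > 10³) marks the
fit non-converged; non-converged categories are reported but excluded
from ranking by default.

**Dispersion and covariance.** The Pearson dispersion
φ̂ = Σ(y−μ̂)²/(μ̂(1−μ̂)) / (n−p) is always reported, un-floored, so users
can inspect over/under-dispersion. Two coefficient covariances are
computed: the model-based quasi-likelihood form φ̂·(XᵀWX)⁻¹ and the
sandwich form (XᵀWX)⁻¹(Xᵀdiag((y−μ̂)²)X)(XᵀWX)⁻¹. Wald inference
defaults to the sandwich (`wald_cov="robust"`). Rationale: the
membership–length relation is typically sharp (in the simulation designs
it is a length band; in real data specialised categories can be nearly
length-separated), so the binomial mean model is misspecified in a way
that concentrates lack-of-fit exactly where the IRLS weights are
largest. A single scalar φ̂ — an *average* variance-inflation factor —
cannot absorb covariate-dependent misfit: in null simulations the
model-based Wald statistic for extreme-length categories had roughly
three times its nominal standard deviation while φ̂ stayed near 1,
inflating the pooled type-I error to ~9–10%; with the sandwich the
pooled fraction of p < 0.05 is statistically indistinguishable from 5%.
The two covariances agree when the model is well specified (for a
saturated 2×2 fit they are identical up to the factor n/(n−2)), so
nothing is lost in the benign case; `wald_cov="model"` restores the
classical behaviour.

**Reference distribution and ranking.** t = β̂1/se(β̂1) is referred to a
Student t with n − p degrees of freedom (the convention when dispersion
is estimated). Both the one-sided enrichment p (upper tail) and the
two-sided p are reported; ranking is by ascending one-sided p, ties
broken by |t| descending then term id, for reproducibility. No
multiple-testing adjustment is applied by default — the primary output
is the relative ranking of categories — but BH-adjusted dichotomization
is available where DE calls are needed.

## Significance measures and length transform

Measures of DE significance: −p, −ln p, ln(−ln p) ("d-log"), the log2
fold change, and a 0/1 call at a p cut-off (optionally BH-adjusted).
P-values are clamped to [ε, 1−ε] with ε = 1e−15 before log transforms so
p ∈ {0, 1} cannot produce infinities. The d-log measure is the default
for real analyses (the outer log tames extremely small p-values); −ln p
is the default in the simulation studies, whose moderate fold changes
produce no extreme p-values. The length covariate is log length by
default; identity is available. Note that with exact (discrete) DE tests
the d-log transform maps the common p = 1 atom to ln(ε) ≈ −34.5, a
high-leverage outlier — another reason −ln p (which maps p = 1 to 0) is
preferred when the DE test is discrete.

## Ontology handling

OBO 1.2/1.4 ontologies are parsed (via obonet) into a DAG whose
parenthood follows `is_a` and `part_of` edges — the behaviour of the
GO.db-family annotation packages — and is verified acyclic; other
relations are ignored. Associations (two-column TSV or GAF 2.x) are
deduplicated; pairs naming unknown or obsolete terms are dropped with a
warning (strict mode errors) and recorded. Direct annotations are
propagated to all ancestors (the true-path rule) by a single
child-before-parent topological sweep; the operation is idempotent and
order-independent, and is cross-checked in tests against a brute-force
ancestor-closure oracle on random DAGs. Category-size filtering (default
minimum 10 propagated genes, configurable) selects which categories are
*ranked*; it never shrinks the gene universe. Genes without any
annotation are excluded from the default universe; `--pseudo-category`
retains them as background.

The parent-child-union local test restricts the universe to genes
annotated to the union of a term's direct parents, so a term is tested
*relative to its parents*; namespace roots are skipped, and a term whose
gene set saturates its parent union is flagged degenerate.

## Contingency baselines

`fisher_test` is the upper tail of the central hypergeometric
distribution at the observed table; the sample odds ratio is reported
because it equals exp(β1) of the saturated logistic fit, keeping the
baselines on the same scale as the regression. The PWF (probability of
a DE call as a function of length) is estimated by equal-count binning
(20 bins by default) followed by isotonic regression and linear
interpolation between bin centres, floored at a small positive value and
normalized to mean weight 1; isotonic regression is monotone by
construction and makes no shape assumption beyond that. The Wallenius
test's odds parameter is the ratio of mean PWF weights (category vs
rest); its tail is computed by an exact sequential dynamic program over
the biased-urn draws (probability vector updated draw by draw), which is
exact at every size used here — no asymptotic approximation — and is
verified against an independent implementation of the Wallenius
distribution to ~1e−8 and against the hypergeometric at unit odds.

## Simulation designs

Both designs use 10 426 genes in 40 non-overlapping categories, 12
samples in two groups of 6, NB counts with per-sample mean proportional
to gene length, and gene lengths drawn log-normal (log-mean 6, log-SD
0.7). Genes are sorted by length and filled into the categories in
order — category 1 shortest — then N(0, 0.2²) jitter is added on the log
scale so category length distributions overlap. Category sizes span the
range 101–1252: one category at each extreme and a moderate linear ramp
(~140–340) for the rest, shuffled by a fixed permutation so size is not
coupled to the length gradient; moderate sizes keep the per-category
tests adequately powered. The variance model is Var = μ + φμ^α with
φ = 0.5, α = 1.5 (an NBP-style mean-dependent dispersion typical of
fitted plant RNA-Seq data); the proportionality constant sets the median
per-sample gene mean to 50 counts.

**Scenario 1 (null).** Exactly 20% of genes, drawn without replacement
and independently of length, are DE at an expected |log2 FC| of 0.5 (the
down-regulated group chosen at random per gene). No category is
enriched, so any excess of small enrichment p-values measures length
bias. **Scenario 2 (graded enrichment).** Six fixed categories
(positions 8, 13, 19, 25, 31, 36) hold DE genes with probability 0.40;
all other genes are DE with probability 0.10 at log2 FC 0.5. The six
carry a strictly decreasing log2 FC grid 1.0, 0.9, …, 0.5 (grade 1
strongest). The six positions are spread along the length gradient and
chosen so their effective detection power — approximately
(mean count)^(1/4)·√size — is equal within ±3%; otherwise nuisance power
differences between the chosen categories, not the fold-change grading,
would dominate their relative ranks. The modest fold-change grid keeps
the exact test away from p-value saturation, where the linear-in-s
logistic slope stops growing with the degree of DE and the grading would
no longer be reflected in the ranking.

**DE testing.** A self-contained exact NB test conditions, per gene, on
the total count across samples (equal library sizes by design): under
the equal-mean null with NB2 dispersion φ the group-1 sum given the
total is negative-hypergeometric with shapes n_j/φ, reducing to
Binomial(T, n1/n) at φ = 0. Two-sided p-values sum the probabilities of
all outcomes no more likely than the one observed. The dispersion used
by the pipeline is a moment fit of the mean-variance trend
Var = μ + φμ^α (α from a log–log regression of excess variance on mean,
φ from the pooled moment ratio) evaluated per gene — NB-based RNA-Seq DE
tests share this exact test and differ precisely in how they model
dispersion as a function of the mean. A single pooled NB2 dispersion is
also provided (`estimate_common_dispersion`); with the mean-dependent
generative variance it is anticonservative for low-count (short) genes,
which distorts the very length–significance relation under study, so the
trend fit is the pipeline default.

## What the simulations do and do not show

The generator reproduces the features that matter for length bias —
power increasing with transcript length, membership tied to length,
graded fold changes, biological overdispersion — but not other
properties of real data: overlapping categories linked by a DAG,
unequal library sizes, GC or mappability bias, annotation errors, or
correlated expression between genes. Calibration and recovery results
on these designs therefore demonstrate the mechanism of the correction,
not performance guarantees on any particular dataset. Real-data analyses
should start from the diagnostics module (length-association prevalence,
cut-off sensitivity, rank–length profiles) before interpreting
rankings.

## Numerical and degenerate-input conventions

* Categories whose membership is constant over the universe raise a
  degenerate-category error in the single tests and are reported
  unranked by the table runner.
* Zero-variance significance gives a flagged (non-converged) result
  rather than an error.
* IRLS weights are floored at 1e−10; deviance logs are clamped.
* Fisher/Wallenius report p = 1 for degenerate margins; the sample odds
  ratio is +inf when its denominator vanishes.
* All randomness flows through a single integer seed (numpy
  `SeedSequence`-derived substreams per replicate); every simulated
  dataset records its seed.
* Study sizes used by the packaged experiments: 25 replicate datasets
  pooled for the null calibration study, 10 for the graded-enrichment
  recovery study, 500 replicate categories for the KS uniformity check.

## Known limitations

* The Wald t reference with n − p degrees of freedom is an
  approximation; for categories of only a handful of genes the
  enrichment p is volatile (hence the default size filter of 10).
* The sandwich covariance is itself finite-sample noisy for very small
  effective sample sizes (categories nearly determined by length).
* The PWF uses equal-count bins + isotonic regression rather than a
  spline; the resulting weight function is piecewise linear.
* The exact NB test assumes equal library sizes and is intended for the
  simulation designs; real analyses should bring their own DE p-values.
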