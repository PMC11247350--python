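# Methods

## Statistical model

The unit of analysis is a gene × trait matrix of gene-level association
p-values of the kind produced by SNP-aggregation methods (MAGMA, VEGAS).
A single conversion is used everywhere between the p and z scales: the
one-sided upper-tail standard-normal quantile z = Φ⁻¹(1 − p), under which
the genome-wide threshold p < 2.84 × 10⁻⁶ corresponds to z > 4.5. Three
significance thresholds are deliberately kept as separate configuration
keys because they play different roles: the genome-wide cutoff 2.84 × 10⁻⁶
defines "associated" for the resampling null and trait eligibility; a
relaxed cutoff 2.8 × 10⁻⁵ defines the larger associated sets aggregated by
the loess-residual, purifying-fraction and direction-of-selection
analyses; and a stringent 10⁻⁷ defines per-gene trait counts in the
pleiotropy trend.

**Partial correlations.** Per trait, R_exp is the partial Spearman
correlation of −log₁₀(p) with log expression controlling for evolutionary
rate and gene length, and R_rate the analogous correlation with log dN/dS
controlling for expression and length. Expression and rate are mutually
controlled because highly expressed proteins evolve slowly (translational
selection), and gene length is controlled because longer genes accrue
smaller gene-level p-values. The implementation rank-transforms all
variables (average ranks on ties), residualizes the two focal variables on
the covariate ranks with an intercept, and correlates the residuals; the
p-value uses the t distribution with n − 2 − k degrees of freedom. With no
covariates this reduces exactly to ordinary Spearman correlation (tested
to 1e−12). Using −log₁₀(p) rather than z as the association variable is
immaterial for any rank-based statistic. Bonferroni correction is over the
number of traits. Quadrants are assigned by sign only when both
correlations meet the requested tier; an exactly zero correlation is a
flagged boundary case mapping to "none".

**Resampling null.** For each eligible trait (≥ 50 genome-wide-significant
genes; the bound is inclusive) and each property/direction combination,
the associated set is compared against draws of equally many nonassociated
genes sampled without replacement, each draw scored by a one-tailed
rank-sum test at 0.05. The inner test is a vectorized asymptotic
Mann–Whitney (normal approximation with tie and continuity correction)
that agrees with the reference implementation to 1e−12 and is the only
hand-written statistical primitive in the package — it makes
1,000-draw × 4-combination × hundreds-of-traits runs feasible in seconds.
Draw streams are seeded per (trait, property, direction) from the master
seed, so any single trait is reproducible in isolation. Trait ranking
within the four groups breaks ties lexicographically; note that when
planted effects are strong, many traits reject every draw and the ranking
among them carries no signal (see Limitations).

**Domain enrichment.** All enrichment stages share one procedure: a
per-domain one-vs-rest goodness-of-fit χ² with df = 1 (observed foreground
counts vs expected counts from background proportions, no continuity
correction), plus the observed-minus-expected foreground fraction. The χ²
is large for both over- and under-representation; consumers that want
"most enriched" filter on a positive fraction difference.

**Selection signatures.** The loess stage fits log₁₀ dN/dS on mean log₁₀
expression (statsmodels lowess, locally linear, span 0.75 by default — the
span is exposed and results were spot-checked at 0.5/0.75/0.9) and
aggregates per-gene residuals over each trait's associated genes with a
one-sample t test; a positive mean residual marks excess evolutionary rate
beyond what expression predicts. The purifying-site fraction of a gene is
the mixture mass of site classes with ω < 1, consumed from a site-class
table rather than estimated (codon model fitting is out of scope). The
direction-of-selection statistic DoS = Dn/(Dn+Ds) − Pn/(Pn+Ps) is left
missing when either denominator is zero (never imputed 0, since the
statistic is undefined there), and genes enter the trait ranking only when
their derived allele frequency exceeds the chosen floor (0.60 and 0.30
supported as the primary grid, 0.01 as the permissive extreme); high
floors guard against segregating slightly deleterious variants biasing the
statistic downward.

**Tissue enrichment.** A gene is tissue-specific to its highest-TPM tissue
when that TPM is ≥ 1 and ≥ 5× the mean of the other tissues — a
single-rule simplification of the tissue-enriched/group-enriched/enhanced
taxonomy that keeps the per-tissue sets disjoint and the behavior easy to
test; fold and floor are configurable. Enrichment of the top-associated
genes is an upper-tail hypergeometric test against the whole gene
universe. Correlation differences across tissues are tested with the
standard two-sample Fisher-z statistic
(atanh(r₁) − atanh(r₂))/√(1/(n₁−3) + 1/(n₂−3)); an alternative t-based
flavor was considered and rejected as nonstandard for two independent
correlations.

**Bias audits.** GWAS power is operationalized as log₁₀ of the participant
count. The power audit reports Spearman correlations of R_exp and R_rate
with power over all profiled traits and over the significant subset (both
universes, since the choice is not obvious); the power-adjusted enrichment
removes a loess trend of each correlation on power before ranking
foregrounds by residual-product magnitude.

## The synthetic cohort generator

The generator targets the gene-level statistical structure the analyses
assume — not sequence-level realism. Defaults (the study conditions):

- 15,000 genes, 29 tissues, 200 traits over eight domains;
- gene covariates from a Gaussian copula with planted Spearman
  correlations: expression↔rate −0.30, length↔rate −0.08,
  length↔expression −0.07 (planted values pass through the
  2·sin(πρ/6) rank-to-latent map so realized Spearman matches the plan);
- marginals: log-normal gene length (median ≈ 18 kb), log-normal TPM with
  a shared gene-level component plus per-tissue wobble, and dN/dS as a
  clipped log-normal on [0.01, 3] calibrated so ~10% of genes exceed 1;
- per-trait z-scores z = a_exp·s(expr) + a_rate·s(rate) + b_len·s(len) + ε
  on rank-normal scores s(·), so planted coefficients are (approximately)
  partial rank correlations and parameter recovery is analytically clean;
  Var(ε) scales inversely with log₁₀(participants), which produces the
  power bias the audits look for;
- ~100 causal genes per trait, sampled with weights exponential in the
  planted direction and boosted past the genome-wide threshold, so trait
  eligibility and the resampling/DoS stages have realistic set sizes;
- polymorphism counts Poisson with rates (Dn, Ds, Pn, Ps) =
  (8,10,8,10) for neutral genes, (12,10,5,10) for planted-positive DoS
  (E[DoS] ≈ +0.21) and the mirror for planted-negative; derived allele
  frequencies are independent Uniform(0,1);
- two-class site mixtures whose purifying mass decreases with the gene's
  rate score, so slow-evolving genes carry high purifying fractions.

The default trait plan encodes the sign patterns under study: metabolic
traits (+expression, −rate), immunological (+,+ with positive planted
DoS), psychiatric (−expression with the strongest gene-length bias, 0.3),
neurological/cardiovascular/body-structure (mild +,−), reproduction
(−,−), and a near-null "other" block. Everything is reproducible from one
seed, and `PlantedTruth` records the quadrant, group and DoS sign each
inference should recover.

What the generator does **not** emulate: linkage disequilibrium and
SNP-level structure, realistic allele-frequency spectra, tissue-private
association signals (expression is dominated by a shared component, so
few tissue-specific genes arise and cross-tissue contrasts are null by
construction), and correlated traits within a domain. Passing tests
therefore demonstrate that the statistical machinery recovers planted
gene-level structure at realistic sizes — not that any particular real
trait behaves this way.

## Numerical choices and degenerate inputs

- log-expression pseudocount 1 (log₁₀(TPM+1)); deciles use a stable
  sort so ties resolve by input order and blocks balance to within one
  element; boundary ties in top/bottom-k sets resolve by gene id.
- Missing dN/dS or expression excludes a gene from any statistic needing
  it (exclusion counts logged), and traits with fewer than 30 complete
  genes get missing profiles; fewer than 50 associated genes skips the
  residual aggregation; fewer than 10 DoS-scored genes skips the DoS
  ranking.
- KDE modes use Silverman's bandwidth on log₁₀ values; a constant sample
  is its own single mode.
- The Bonferroni divisor for tissue tests is the number of non-excluded
  tissues, logged next to the flags.
- Master-seed → child-seed derivation hashes the stage/trait labels
  (SHA-256, reduced below 2³¹), so no global random state exists and any
  stage reruns identically in isolation.

## Problem sizes used by the shipped runs

The default `--desk` pipeline profile analyses the full 15,000 × 200
cohort but runs the 1,000-draw resampling at full rate for 50 traits and
200 draws for the rest; the acceptance script uses 1,000 draws for all
eligible traits of one cohort plus a 600 × 100-draw exchangeability
calibration. These sizes were chosen so a complete run stays in the
tens-of-seconds range on a single CPU while leaving every estimate's
Monte-Carlo error well inside the tolerances the tests assert.

## Known limitations

- The resampling trait ranking saturates when planted effects are strong:
  many traits reject all draws and their relative order is the
  lexicographic tie rule, not evidence. Real compendia with graded power
  are unlikely to saturate, but comparisons downstream of the ranking
  should check `frac_significant` dispersion first.
- The hypergeometric p-value is conservative for small margins
  (discreteness); calibration is near-uniform only when overlap support is
  wide.
- Partial Spearman p-values rely on the t approximation on ranks; at very
  small n (tens of genes) they are approximate.
- The loess residual analysis assumes the expression–rate trend is shared
  across domains; a domain-specific trend would masquerade as excess
  selection.
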