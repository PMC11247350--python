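# polyevo

Genome-wide analysis of how gene-level GWAS association relates to
**evolutionary rate** (dN/dS) and **expression level** across polygenic
traits.

## The scientific problem

Whether disease-associated genes evolve faster or slower than other genes
has long been contested, partly because the answer is trait-specific and
partly because expression level — the strongest known determinant of
protein evolutionary rate — confounds any naive comparison. `polyevo`
implements a trait-by-trait pipeline over gene-level association
statistics (MAGMA-style p-values, converted to z-scores via
z = Φ⁻¹(1 − p)) that:

- compares the k most vs least associated genes of a trait
  (two-sample Kolmogorov–Smirnov on dN/dS; per-tissue Wilcoxon rank-sum
  with Bonferroni correction; expression/rate decile profiling; variance
  and KDE-bimodality comparison against a monogenic-disease gene list);
- builds a **matched resampling null**: for each trait with ≥ 50
  genome-wide-significant genes (p < 2.84 × 10⁻⁶, z > 4.5), the associated
  set is compared against 1,000 equally sized random draws of
  nonassociated genes with one-tailed rank-sum tests, ranking traits into
  four groups (higher/lower rate, higher/lower expression) with per-domain
  χ² enrichment;
- computes per-trait **partial Spearman correlations** R_exp and R_rate
  between −log₁₀(p) and expression / dN/dS — each controlling for the
  other variable and for gene length — and classifies traits into the
  quadrants A (+,−), B (+,+), C (−,−), D (−,+) with domain enrichment and
  a pleiotropy trend;
- scores **selection signatures**: loess residuals of log dN/dS on log
  expression aggregated over associated genes, purifying-site fractions
  (mixture mass with ω < 1 from codon site-model output), and the
  direction-of-selection statistic DoS = Dn/(Dn+Ds) − Pn/(Pn+Ps) under
  derived-allele-frequency filters;
- runs **tissue enrichment** (hypergeometric tests of top-associated genes
  in tissue-specific gene sets; Fisher-z comparison of correlations across
  tissues) and **bias audits** (gene length, ascertainment, GWAS power).

Because the original trait compendium, expression atlas and primate
ortholog tables are external resources, the package ships a synthetic
cohort generator (`polyevo.synthetic_data`) that reproduces the
statistical structure these analyses assume — including a planted truth
file for every downstream inference — and all tests run against it.

## Worked example

```bash
polyevo run --desk --seed 42 --out runs/demo
cat runs/demo/report.md
```

prints (abridged):

```
# polyevo run report

- **metabolic_003**: KS D = 0.262 (p = 8.98e-31), 29 tissues significant (Bonferroni line at -log10 p = 2.76)
- **immunological_019**: KS D = 0.112 (p = 6.42e-06), 29 tissues significant (Bonferroni line at -log10 p = 2.76)

Significant traits: 175; quadrant shares A: 60%, B: 17%, C: 23%, D: 0%.

Most enriched domain per resampling group: group 1: immunological, group 2: metabolic, group 3: immunological, group 4: psychiatric

Planted-quadrant recovery (|effects| >= 0.1): 100% of 70 traits.
```

Reading this: for the focus traits the top-1,000 and bottom-1,000 gene
sets differ in their dN/dS distributions (KS D with its p-value), and
every tissue shows an expression difference beyond the Bonferroni line
−log₁₀(0.05/29) = 2.76. Of 200 simulated traits, 175 have both partial
correlations Bonferroni-significant; 60% land in quadrant A (highly
expressed, slowly evolving genes drive association) — and the four
resampling groups recover exactly the domains the generator planted
(immunological traits' genes evolve faster, metabolic slower, psychiatric
genes are expressed lower). The last line confirms the planted quadrant
label was recovered for every trait with planted effect sizes ≥ 0.1.

Individual stages are available as
`polyevo analyze (group-compare | resampling | correlation-map | selection
| tissue | bias)` on any cohort directory written by `polyevo simulate`,
and the same functionality is importable from `polyevo.*` modules.

## Layout

```
src/polyevo/
  io_model.py              data model, TSV I/O, p↔z, deciles, thresholds
  synthetic_data.py        cohort generator + planted truth
  group_compare.py         top/bottom sets, KS, tissue tests, deciles, modes
  resampling.py            matched resampling null, groups, χ² enrichment
  correlation_map.py       partial Spearman profiles, quadrants, pleiotropy
  selection_signatures.py  loess residuals, purifying fractions, DoS
  tissue_enrichment.py     tissue-specific sets, hypergeometric, Fisher z
  bias_audit.py            length / ascertainment / power audits
  pipeline.py, cli.py      orchestration and the `polyevo` command
docs/methods.md            model, parameters and design notes
```
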