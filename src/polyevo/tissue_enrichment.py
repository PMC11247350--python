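"""Tissue-specific gene calling and enrichment of top-associated genes.

A gene is called specific to its highest-expressing tissue when that
tissue's TPM passes an absolute floor and exceeds a fold multiple of the
mean TPM over the remaining tissues — a single-rule simplification of the
tissue-enriched/enhanced taxonomy that keeps the sets disjoint across
tissues.  For each trait, the overlap of the top associated genes with
every tissue set is scored by an upper-tail hypergeometric test against the
whole gene universe.  Cross-tissue consistency compares the association-
expression correlation between the most- and least-enriched tissue via
Fisher's z-transformation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import Cohort, log_expression

logger = logging.getLogger(__name__)


def tissue_specific_genes(tpm: pd.DataFrame, fold: float = 5.0,
                          min_tpm: float = 1.0) -> dict[str, set[str]]:
    """Per-tissue sets of specifically expressed genes (disjoint by argmax).

    Gene g is specific to tissue t iff t is its highest-TPM tissue (ties go
    to the first tissue in column order), TPM(g, t) >= min_tpm, and
    TPM(g, t) >= fold * mean TPM over the other tissues.
    """
    if tpm.shape[1] < 2:
        raise ValueError("need at least 2 tissues")
    arr = tpm.to_numpy(dtype=float)
    best = arr.argmax(axis=1)
    best_val = arr[np.arange(len(arr)), best]
    other_mean = (arr.sum(axis=1) - best_val) / (arr.shape[1] - 1)
    ok = (best_val >= min_tpm) & (best_val >= fold * other_mean)
    sets: dict[str, set[str]] = {t: set() for t in tpm.columns}
    for gene, t_idx, passed in zip(tpm.index, best, ok):
        if passed:
            sets[tpm.columns[t_idx]].add(gene)
    return sets


def tissue_hypergeom(top_genes, tissue_sets: dict[str, set[str]],
                     background, alpha: float = 0.05) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of top genes in each tissue set.

    Returns one row per tissue with the overlap, the p-value, and a
    Bonferroni flag over the number of tissues; an empty tissue set scores
    p = 1 and is flagged.
    """
    bg = set(background)
    top = set(top_genes) & bg
    N, n = len(bg), len(top)
    rows = []
    for tissue, genes in tissue_sets.items():
        K = len(genes & bg)
        k = len(top & genes)
        if K == 0:
            rows.append((tissue, 0, 0, 1.0, True))
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((tissue, K, k, p, False))
    out = pd.DataFrame(rows, columns=["tissue", "set_size", "overlap", "p", "empty_set"])
    out = out.set_index("tissue")
    m = len(out)
    out["enriched"] = (out["p"] < alpha / m) & ~out["empty_set"]
    return out


def enriched_tissue_counts(cohort: Cohort, top_k: int = 1000, fold: float = 5.0,
                           min_tpm: float = 1.0, alpha: float = 0.05,
                           panel: list[str] | None = None,
                           exclude: list[str] | None = None) -> pd.DataFrame:
    """Number of significantly enriched tissues per trait (and raw tables)."""
    tpm = cohort.tpm(panel, exclude=exclude)
    sets = tissue_specific_genes(tpm, fold=fold, min_tpm=min_tpm)
    background = cohort.genes.index
    rows = []
    for trait_id in cohort.assoc.columns:
        top = cohort.assoc[trait_id].nsmallest(top_k).index
        table = tissue_hypergeom(top, sets, background, alpha=alpha)
        rows.append((trait_id, int(table["enriched"].sum())))
    return pd.DataFrame(rows, columns=["trait_id", "n_enriched_tissues"]).set_index("trait_id")


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Two-sample comparison of correlation coefficients via Fisher's z.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)), with a
    two-sided standard-normal p-value.
    """
    if abs(r1) >= 1.0 or abs(r2) >= 1.0:
        raise ValueError("correlations must have magnitude < 1")
    if n1 <= 3 or n2 <= 3:
        raise ValueError("both sample sizes must exceed 3")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return float(z), p


def cross_tissue_consistency(cohort: Cohort, trait_id: str, top_k: int = 1000,
                             fold: float = 5.0, min_tpm: float = 1.0,
                             panel: list[str] | None = None,
                             exclude: list[str] | None = None) -> dict:
    """Does tissue specificity change the association-expression correlation?

    Computes the Spearman correlation between -log10(gene p) and log
    expression in the most-enriched tissue, the least-enriched tissue, and
    the all-tissue average, then compares most vs least and most vs average
    with Fisher's z.  Ties on enrichment break by tissue name (logged).
    """
    tpm = cohort.tpm(panel, exclude=exclude)
    sets = tissue_specific_genes(tpm, fold=fold, min_tpm=min_tpm)
    top = cohort.assoc[trait_id].nsmallest(top_k).index
    enrich = tissue_hypergeom(top, sets, cohort.genes.index)
    ranked = enrich.reset_index().sort_values(["p", "tissue"], kind="stable")
    most = ranked.iloc[0]["tissue"]
    least = ranked.iloc[-1]["tissue"]
    if (enrich["p"] == enrich.loc[most, "p"]).sum() > 1:
        logger.info("tie for most-enriched tissue; chose %s by name order", most)

    p_gene = cohort.assoc[trait_id].dropna()
    x = -np.log10(p_gene)

    def _corr(values: pd.Series) -> tuple[float, int]:
        common = x.index.intersection(values.dropna().index)
        r, _ = stats.spearmanr(x.loc[common], values.loc[common])
        return float(r), len(common)

    lx = log_expression(tpm)
    r_most, n_most = _corr(lx[most])
    r_least, n_least = _corr(lx[least])
    r_avg, n_avg = _corr(lx.mean(axis=1))

    z_ml, p_ml = fisher_z_compare(r_most, n_most, r_least, n_least)
    z_ma, p_ma = fisher_z_compare(r_most, n_most, r_avg, n_avg)
    return {
        "trait_id": trait_id,
        "most_enriched": most, "least_enriched": least,
        "r_most": r_most, "r_least": r_least, "r_average": r_avg,
        "most_vs_least": {"z": z_ml, "p": p_ml, "n": (n_most, n_least)},
        "most_vs_average": {"z": z_ma, "p": p_ma, "n": (n_most, n_avg)},
    }
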