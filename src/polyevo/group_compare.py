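"""Trait-specific comparisons of highly versus lowly associated gene sets.

These are the single-trait analyses: distributional comparison of
evolutionary rate between the k most and k least associated genes
(two-sample Kolmogorov-Smirnov), per-tissue expression comparisons with
Bonferroni correction, decile-similarity profiling of a z-threshold
selection, variance comparison against a monogenic-disease gene list, and
kernel-density mode detection for bimodality of dN/dS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import Cohort, assign_deciles, log_expression, pz_transform

logger = logging.getLogger(__name__)


def top_bottom_sets(assoc: pd.DataFrame, trait_id: str, k: int
                    ) -> tuple[pd.Index, pd.Index]:
    """The ``k`` most and ``k`` least associated genes for one trait.

    Ranking is by z-score (equivalently, ascending p-value); boundary ties
    are broken by lexicographic gene id, so the sets are stable across runs.
    """
    if trait_id not in assoc.columns:
        raise KeyError(f"unknown trait_id {trait_id!r}")
    col = assoc[trait_id].dropna()
    if k > len(col) // 2:
        raise ValueError(f"k={k} exceeds half the {len(col)} ranked genes")
    frame = col.rename("p").rename_axis("gene_id").reset_index()
    frame = frame.sort_values(["p", "gene_id"], kind="stable")
    order = pd.Index(frame["gene_id"])
    return order[:k], order[-k:]


def ks_compare(values_top, values_bottom) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p-value)."""
    a = np.asarray(values_top, dtype=float)
    b = np.asarray(values_bottom, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need at least 2 non-missing values")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def tissue_wise_tests(cohort: Cohort, top: pd.Index, bottom: pd.Index,
                      alpha: float = 0.05, panel: list[str] | None = None
                      ) -> pd.DataFrame:
    """Two-sided rank-sum test of expression between the sets, per tissue.

    Returns one row per tissue with the statistic, p-value, and a Bonferroni
    flag at ``alpha / m`` where ``m`` counts the non-excluded tissues (an
    all-missing tissue is excluded and logged).
    """
    tpm = cohort.tpm(panel)
    rows = []
    for tissue in tpm.columns:
        a = tpm.loc[tpm.index.intersection(top), tissue].dropna()
        b = tpm.loc[tpm.index.intersection(bottom), tissue].dropna()
        if a.empty or b.empty:
            logger.warning("tissue %s excluded: all-missing expression", tissue)
            continue
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append((tissue, float(stat), float(p)))
    out = pd.DataFrame(rows, columns=["tissue", "W", "p"]).set_index("tissue")
    m = len(out)
    out["bonferroni_m"] = m
    out["significant"] = out["p"] < alpha / m
    return out


def decile_similarity(values: pd.Series, z: pd.Series, z_cut: float,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Which genome deciles are indistinguishable from a z-threshold selection.

    ``values`` is the per-gene quantity under study (e.g. mean log
    expression or log dN/dS); the selection is ``z > z_cut``.  Each decile of
    ``values`` is compared with the selection by a two-sided rank-sum test;
    a decile is "similar" when its Bonferroni-adjusted p is >= alpha.
    Rank-based, so invariant to monotone transforms of ``values``.
    """
    common = values.dropna().index.intersection(z.dropna().index)
    values, z = values.loc[common], z.loc[common]
    selected = values[z > z_cut]
    if selected.empty:
        raise ValueError(f"no genes pass z_cut={z_cut}; lower the cutoff")
    deciles = pd.Series(assign_deciles(values.to_numpy()), index=values.index)
    rows = []
    for d in range(1, 11):
        pool = values[deciles == d]
        _, p = stats.mannwhitneyu(selected, pool, alternative="two-sided")
        rows.append((d, float(p), min(p * 10, 1.0)))
    out = pd.DataFrame(rows, columns=["decile", "p", "p_adj"]).set_index("decile")
    out["similar"] = out["p_adj"] >= alpha
    return out


def variance_compare(values_a, values_b) -> tuple[float, float]:
    """F-ratio of sample variances with its two-sided p-value."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("both samples need at least 3 values")
    vb = b.var(ddof=1)
    if vb == 0:
        raise ValueError("zero variance in denominator sample")
    f = a.var(ddof=1) / vb
    dist = stats.f(len(a) - 1, len(b) - 1)
    p = 2.0 * min(dist.cdf(f), dist.sf(f))
    return float(f), float(min(p, 1.0))


def density_modes(values, grid_size: int = 512) -> list[float]:
    """Local maxima of a Gaussian KDE of log10(values), back-transformed.

    Bandwidth follows Silverman's rule on the log scale.  Values must be
    positive (dN/dS ratios are); a constant sample returns its single value.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 10:
        raise ValueError("need at least 10 values")
    if np.any(v <= 0):
        raise ValueError("values must be positive for the log-scale KDE")
    x = np.log10(v)
    if np.ptp(x) == 0:
        return [float(v[0])]
    kde = stats.gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(x.min() - 0.5, x.max() + 0.5, grid_size)
    dens = kde(grid)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] > dens[2:])
    modes = grid[1:-1][interior]
    order = np.argsort(-dens[1:-1][interior])
    return [float(10.0 ** m) for m in modes[order]]


@dataclass
class MonogenicComparison:
    overlap: pd.Index
    rank_sum: tuple[float, float]
    variance: tuple[float, float]
    rank_sum_excluded: tuple[float, float]
    variance_excluded: tuple[float, float]


def monogenic_overlap(cohort: Cohort, selection: pd.Index,
                      value_column: str = "dnds") -> MonogenicComparison:
    """Compare a selection's dN/dS with monogenic-disease genes.

    Reports the overlap of the selection with the monogenic list and the
    rank-sum / F-test comparisons both with and without the overlapping
    genes removed from the selection.
    """
    mono = cohort.monogenic_genes
    if mono.empty:
        raise ValueError("the monogenic gene list is empty")
    overlap = pd.Index(selection).intersection(mono)
    vals_mono = cohort.genes.loc[mono, value_column].dropna()

    def _tests(sel: pd.Index):
        vals = cohort.genes.loc[sel, value_column].dropna()
        w, p_rs = stats.mannwhitneyu(vals, vals_mono, alternative="two-sided")
        f, p_f = variance_compare(vals, vals_mono)
        return (float(w), float(p_rs)), (f, p_f)

    rs, var = _tests(pd.Index(selection))
    reduced = pd.Index(selection).difference(overlap)
    if len(overlap) and len(reduced) >= 3:
        rs_ex, var_ex = _tests(reduced)
    else:
        rs_ex, var_ex = rs, var
    return MonogenicComparison(overlap=overlap, rank_sum=rs, variance=var,
                               rank_sum_excluded=rs_ex, variance_excluded=var_ex)


def trait_summary(cohort: Cohort, trait_id: str, k: int = 1000,
                  alpha: float = 0.05, panel: list[str] | None = None) -> dict:
    """End-to-end single-trait report used by the command line interface."""
    top, bottom = top_bottom_sets(cohort.assoc, trait_id, k)
    dnds_top = cohort.genes.loc[top, "dnds"].dropna()
    dnds_bot = cohort.genes.loc[bottom, "dnds"].dropna()
    D, p_ks = ks_compare(dnds_top, dnds_bot)
    tissue = tissue_wise_tests(cohort, top, bottom, alpha=alpha, panel=panel)
    modes = density_modes(dnds_top)
    return {
        "trait_id": trait_id,
        "k": k,
        "ks_D": D,
        "ks_p": p_ks,
        "n_significant_tissues": int(tissue["significant"].sum()),
        "bonferroni_line": float(-np.log10(alpha / len(tissue))),
        "dnds_modes": modes[:2],
        "tissue_table": tissue,
    }
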