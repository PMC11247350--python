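"""Selection-signature statistics beyond the whole-gene dN/dS average.

Three complementary views of selection on trait-associated genes:

* loess residuals — the expression/rate dependency is removed with a loess
  fit of log dN/dS on log expression; a trait whose associated genes sit
  above the curve shows excess evolutionary rate beyond what expression
  predicts (positive-selection tendency), below the curve excess
  conservation;
* purifying-site fraction — the mixture mass of codon site classes with
  omega < 1 from a site-model fit; traits are ranked by the mean fraction
  over their associated genes;
* direction of selection (DoS) — Dn/(Dn+Ds) - Pn/(Pn+Ps), a
  McDonald-Kreitman-derived statistic: positive values suggest adaptive
  fixation excess, negative values segregating weakly deleterious
  variation.  Genes are filtered by derived allele frequency so that
  slightly deleterious polymorphisms do not dominate.

A power-adjusted enrichment removes the loess trend of the correlation
profiles on GWAS sample size before ranking trait domains.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io_model import Cohort, ASSOCIATED_P, significant_genes
from .resampling import domain_enrichment

logger = logging.getLogger(__name__)


def loess_rate_on_expression(cohort: Cohort, span: float = 0.75,
                             panel: list[str] | None = None) -> pd.DataFrame:
    """Loess fit of log10(dN/dS) on mean log10 expression, with residuals.

    Returns a frame indexed by gene with ``x`` (log expression), ``y``
    (log10 dN/dS), ``fitted`` and ``residual`` columns; genes missing either
    value are excluded.  Residuals average to approximately zero over the
    fit set.
    """
    if not 0.0 < span <= 1.0:
        raise ValueError("span must lie in (0, 1]")
    expr = cohort.mean_log_expression(panel)
    rate = cohort.genes["dnds"]
    mask = expr.notna() & rate.notna() & (rate > 0)
    if mask.sum() < 100:
        raise ValueError("need at least 100 genes with both values")
    x = expr[mask].to_numpy()
    y = np.log10(rate[mask].to_numpy())
    fitted = lowess(y, x, frac=span, return_sorted=False)
    out = pd.DataFrame({"x": x, "y": y, "fitted": fitted, "residual": y - fitted},
                       index=expr.index[mask])
    return out


def trait_mean_residual(residuals: pd.Series, cohort: Cohort, trait_id: str,
                        p_cut: float = ASSOCIATED_P, min_genes: int = 50
                        ) -> dict | None:
    """Mean loess residual of a trait's associated genes, tested against 0.

    Returns ``None`` (and logs) for traits with fewer than ``min_genes``
    associated genes carrying a residual.
    """
    assoc = significant_genes(cohort.assoc, trait_id, p_cut)
    vals = residuals.reindex(assoc).dropna()
    if len(vals) < min_genes:
        logger.info("trait %s skipped: %d < %d associated genes with residuals",
                    trait_id, len(vals), min_genes)
        return None
    t, p = stats.ttest_1samp(vals, 0.0)
    return {"trait_id": trait_id, "n_genes": len(vals),
            "mean_residual": float(vals.mean()), "t": float(t), "p": float(p)}


def residual_summary(cohort: Cohort, span: float = 0.75,
                     p_cut: float = ASSOCIATED_P, min_genes: int = 50,
                     panel: list[str] | None = None) -> pd.DataFrame:
    """Per-trait mean residual table over all traits with enough genes."""
    res = loess_rate_on_expression(cohort, span=span, panel=panel)["residual"]
    rows = [r for t in cohort.assoc.columns
            if (r := trait_mean_residual(res, cohort, t, p_cut, min_genes))]
    out = pd.DataFrame(rows).set_index("trait_id") if rows else pd.DataFrame()
    if len(out):
        out["domain"] = cohort.traits["domain"].reindex(out.index)
    return out


def purifying_fraction(classes) -> float:
    """Mixture mass of site classes with omega < 1.

    ``classes`` is an iterable of (proportion, omega) pairs whose
    proportions must sum to 1 within 1e-6.
    """
    props = np.array([c[0] for c in classes], dtype=float)
    omegas = np.array([c[1] for c in classes], dtype=float)
    if len(props) == 0 or abs(props.sum() - 1.0) > 1e-6:
        raise ValueError("site-class proportions must sum to 1")
    if (props < 0).any() or (omegas < 0).any():
        raise ValueError("proportions and omega values must be non-negative")
    return float(props[omegas < 1.0].sum())


def purifying_fractions(site_classes: pd.DataFrame) -> pd.Series:
    """Per-gene purifying-site fraction from the long-format site-class table."""
    sums = site_classes.groupby("gene_id")["proportion"].sum()
    off = sums[(sums - 1.0).abs() > 1e-6]
    if len(off):
        raise ValueError(f"proportions do not sum to 1 for {list(off.index)[:5]}")
    mass = site_classes[site_classes["omega"] < 1.0].groupby("gene_id")["proportion"].sum()
    return mass.reindex(sums.index, fill_value=0.0).rename("purifying_fraction")


def rank_traits_by_purifying(cohort: Cohort, p_cut: float = ASSOCIATED_P,
                             top_n_grid: tuple[int, ...] = (100, 200, 300),
                             min_genes: int = 1) -> dict:
    """Rank traits by the mean purifying-site fraction of associated genes.

    Returns the ranked score table and, for each requested foreground size,
    the domain enrichment against all scored traits.
    """
    frac = purifying_fractions(cohort.site_classes)
    rows = []
    for trait_id in cohort.assoc.columns:
        genes = significant_genes(cohort.assoc, trait_id, p_cut)
        vals = frac.reindex(genes).dropna()
        if len(vals) < min_genes:
            logger.info("trait %s excluded from purifying ranking: no scored genes", trait_id)
            continue
        rows.append((trait_id, len(vals), float(vals.mean())))
    scores = pd.DataFrame(rows, columns=["trait_id", "n_genes", "mean_purifying"])
    scores = scores.sort_values(["mean_purifying", "trait_id"],
                                ascending=[False, True], kind="stable").reset_index(drop=True)
    domains = cohort.traits["domain"]
    enrich = {}
    for top_n in top_n_grid:
        if top_n > len(scores):
            logger.warning("top_n=%d exceeds %d scored traits; truncating", top_n, len(scores))
        fg = scores.head(top_n)["trait_id"]
        enrich[top_n] = domain_enrichment(domains.loc[fg], domains.loc[scores["trait_id"]])
    return {"scores": scores, "enrichment": enrich}


def direction_of_selection(Dn, Ds, Pn, Ps):
    """DoS = Dn/(Dn+Ds) - Pn/(Pn+Ps); NaN where a denominator is zero.

    Accepts scalars or aligned arrays; negative counts raise.
    """
    Dn, Ds, Pn, Ps = (np.asarray(a, dtype=float) for a in (Dn, Ds, Pn, Ps))
    if any((a < 0).any() for a in (Dn, Ds, Pn, Ps)):
        raise ValueError("counts must be non-negative")
    div = Dn + Ds
    poly = Pn + Ps
    with np.errstate(invalid="ignore", divide="ignore"):
        dos = np.where((div > 0) & (poly > 0), Dn / np.where(div > 0, div, 1)
                       - Pn / np.where(poly > 0, poly, 1), np.nan)
    return float(dos) if dos.ndim == 0 else dos


def gene_dos(polymorphism: pd.DataFrame) -> pd.Series:
    """Per-gene DoS from the polymorphism table (NaN where undefined)."""
    dos = direction_of_selection(polymorphism["Dn"], polymorphism["Ds"],
                                 polymorphism["Pn"], polymorphism["Ps"])
    return pd.Series(dos, index=polymorphism.index, name="dos")


def dos_trait_ranking(cohort: Cohort, p_cut: float = ASSOCIATED_P,
                      daf_min: float = 0.60, min_genes: int = 10,
                      top_n: int = 100) -> dict:
    """Per-trait fraction of associated genes with positive DoS, plus enrichment.

    Genes failing the derived-allele-frequency filter (daf <= daf_min) or
    with undefined DoS are excluded; traits with fewer than ``min_genes``
    scored genes are skipped with a warning.
    """
    dos = gene_dos(cohort.polymorphism)
    keep = cohort.polymorphism["daf"] > daf_min
    dos = dos[keep].dropna()
    rows = []
    skipped = []
    for trait_id in cohort.assoc.columns:
        genes = significant_genes(cohort.assoc, trait_id, p_cut)
        vals = dos.reindex(genes.intersection(dos.index)).dropna()
        if len(vals) < min_genes:
            skipped.append(trait_id)
            continue
        rows.append((trait_id, len(vals), float((vals > 0).mean())))
    if skipped:
        logger.warning("%d traits skipped in DoS ranking (fewer than %d scored genes)",
                       len(skipped), min_genes)
    scores = pd.DataFrame(rows, columns=["trait_id", "n_genes", "frac_positive_dos"])
    scores = scores.sort_values(["frac_positive_dos", "trait_id"],
                                ascending=[False, True], kind="stable").reset_index(drop=True)
    enrich = pd.DataFrame()
    if len(scores) >= 2 and cohort.traits["domain"].loc[scores["trait_id"]].nunique() >= 2:
        domains = cohort.traits["domain"]
        fg = scores.head(top_n)["trait_id"]
        enrich = domain_enrichment(domains.loc[fg], domains.loc[scores["trait_id"]])
    return {"scores": scores, "enrichment": enrich, "skipped": skipped}


def power_adjusted_enrichment(profiles: pd.DataFrame, traits: pd.DataFrame,
                              top_n: int = 100, span: float = 0.75) -> dict:
    """Domain enrichment after removing the loess trend on GWAS power.

    ``R_exp`` and ``R_rate`` are residualized on log10(n_participants) with
    separate loess fits.  Two foregrounds are ranked by residual-product
    magnitude: traits with high residual R_exp and high residual R_rate
    (positive-selection-like) and traits with high residual R_exp and low
    residual R_rate (purifying-like).  Traits without a recorded sample size
    are excluded and logged.
    """
    prof = profiles.dropna(subset=["R_exp", "R_rate"]).copy()
    power = np.log10(traits["n_participants"].reindex(prof.index).astype(float))
    missing = power.isna()
    if missing.any():
        logger.warning("%d traits excluded from power adjustment (missing sample size)",
                       int(missing.sum()))
    prof = prof[~missing]
    power = power[~missing]
    if prof.empty:
        raise ValueError("no traits with GWAS sample size available")
    x = power.to_numpy()
    if np.ptp(x) == 0:
        res_exp = prof["R_exp"] - prof["R_exp"].mean()
        res_rate = prof["R_rate"] - prof["R_rate"].mean()
    else:
        res_exp = prof["R_exp"] - lowess(prof["R_exp"].to_numpy(), x, frac=span,
                                         return_sorted=False)
        res_rate = prof["R_rate"] - lowess(prof["R_rate"].to_numpy(), x, frac=span,
                                           return_sorted=False)
    prof["res_exp"], prof["res_rate"] = res_exp, res_rate
    prof["score"] = (prof["res_exp"] * prof["res_rate"]).abs()
    bg_domains = prof["domain"]
    out = {"residuals": prof[["res_exp", "res_rate", "domain"]]}
    for name, mask in [("high_exp_high_rate", (prof["res_exp"] > 0) & (prof["res_rate"] > 0)),
                       ("high_exp_low_rate", (prof["res_exp"] > 0) & (prof["res_rate"] < 0))]:
        fg = (prof[mask].rename_axis("trait_id").reset_index()
              .sort_values(["score", "trait_id"], ascending=[False, True], kind="stable")
              .head(top_n))
        out[name] = domain_enrichment(fg["domain"], bg_domains) if len(fg) else pd.DataFrame()
    return out
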