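"""Per-trait partial correlations and the quadrant diagram.

For every trait we compute two partial Spearman correlations over genes:

* ``R_exp`` — between -log10(gene p-value) and log expression, controlling
  for evolutionary rate and gene length;
* ``R_rate`` — between -log10(gene p-value) and log dN/dS, controlling for
  expression and gene length.

Expression and rate are mutually controlled because of the well-known
negative dependency between the two (highly expressed proteins evolve
slowly); gene length is controlled because it biases gene-level GWAS
statistics.  Traits with both correlations significant are placed in a
quadrant by sign: A = (+, -), B = (+, +), C = (-, -), D = (-, +).  Quadrant
foregrounds ranked by |R_exp * R_rate| feed a domain enrichment, and a
pleiotropy trend relates per-gene trait counts to expression and rate.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import Cohort, PLEIOTROPY_P
from .resampling import domain_enrichment

logger = logging.getLogger(__name__)

QUADRANTS = ("A", "B", "C", "D")
TIERS = ("ns", "nominal", "bonferroni")


def _rank(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, method="average")


def partial_spearman(x, y, covariates=None) -> tuple[float, float]:
    """Partial Spearman correlation of x and y given covariates.

    All variables are rank-transformed (average ranks on ties); x and y are
    residualized on the covariate ranks (with intercept) and the Pearson
    correlation of the residuals is returned with a t-distribution p-value
    on n - 2 - k degrees of freedom.  With no covariates this reduces to the
    ordinary Spearman correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    covs = [np.asarray(c, dtype=float) for c in (covariates or [])]
    k = len(covs)
    n = len(x)
    if n < k + 3:
        raise ValueError(f"need at least {k + 3} complete cases, got {n}")
    rx, ry = _rank(x), _rank(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("constant variable after rank transform")
    if covs:
        design = np.column_stack([np.ones(n)] + [_rank(c) for c in covs])
        rx = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
        ry = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
    else:
        rx, ry = rx - rx.mean(), ry - ry.mean()
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    if denom == 0:
        raise ValueError("constant residuals; correlation undefined")
    r = float(np.clip((rx @ ry) / denom, -1.0, 1.0))
    df = n - 2 - k
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p


def classify_quadrant(r_exp: float, r_rate: float, significant: bool
                      ) -> tuple[str, bool]:
    """Quadrant label by sign pattern; "none" unless both tests significant.

    Returns (label, boundary_flag); an exact zero correlation is a boundary
    case and maps to "none".
    """
    boundary = (r_exp == 0.0) or (r_rate == 0.0)
    if not significant or boundary:
        return "none", boundary
    if r_exp > 0:
        return ("B", False) if r_rate > 0 else ("A", False)
    return ("D", False) if r_rate > 0 else ("C", False)


def trait_profiles(cohort: Cohort, alpha: float = 0.05, min_genes: int = 30,
                   panel: list[str] | None = None,
                   quadrant_tier: str = "bonferroni") -> pd.DataFrame:
    """Correlation profile of every trait: R_exp, R_rate, p-values, quadrant.

    Bonferroni correction is over the number of traits.  A trait with fewer
    than ``min_genes`` complete genes is reported with missing values and
    logged.  Quadrants are assigned at ``quadrant_tier`` ("nominal" or
    "bonferroni").
    """
    if quadrant_tier not in ("nominal", "bonferroni"):
        raise ValueError("quadrant_tier must be 'nominal' or 'bonferroni'")
    expr = cohort.mean_log_expression(panel)
    rate = cohort.genes["dnds"]
    length = cohort.genes["length"].astype(float)
    m = len(cohort.assoc.columns)
    rows = []
    for trait_id in cohort.assoc.columns:
        p_gene = cohort.assoc[trait_id]
        mask = p_gene.notna() & expr.notna() & rate.notna() & length.notna()
        n = int(mask.sum())
        if n < min_genes:
            logger.warning("trait %s: only %d complete genes, profile missing", trait_id, n)
            rows.append((trait_id, np.nan, np.nan, np.nan, np.nan, n, "ns", "none"))
            continue
        x = -np.log10(p_gene[mask].to_numpy())
        e, r, ln = expr[mask].to_numpy(), rate[mask].to_numpy(), length[mask].to_numpy()
        r_exp, p_exp = partial_spearman(x, e, [r, ln])
        r_rate, p_rate = partial_spearman(x, r, [e, ln])
        if p_exp < alpha / m and p_rate < alpha / m:
            tier = "bonferroni"
        elif p_exp < alpha and p_rate < alpha:
            tier = "nominal"
        else:
            tier = "ns"
        significant = (tier == "bonferroni") if quadrant_tier == "bonferroni" \
            else (tier in ("nominal", "bonferroni"))
        quadrant, _ = classify_quadrant(r_exp, r_rate, significant)
        rows.append((trait_id, r_exp, r_rate, p_exp, p_rate, n, tier, quadrant))
    out = pd.DataFrame(rows, columns=["trait_id", "R_exp", "R_rate", "p_exp",
                                      "p_rate", "n_genes", "tier", "quadrant"])
    out = out.set_index("trait_id")
    out["domain"] = cohort.traits["domain"].reindex(out.index)
    return out


def quadrant_shares(profiles: pd.DataFrame) -> pd.Series:
    """Fraction of significant traits in each quadrant."""
    sig = profiles[profiles["quadrant"].isin(QUADRANTS)]
    if sig.empty:
        return pd.Series(0.0, index=list(QUADRANTS))
    return sig["quadrant"].value_counts(normalize=True).reindex(QUADRANTS, fill_value=0.0)


def quadrant_enrichment(profiles: pd.DataFrame, quadrant: str, top_n: int = 100
                        ) -> pd.DataFrame:
    """Domain enrichment of a quadrant's strongest traits.

    Foreground: the ``top_n`` traits of the quadrant ranked by the magnitude
    of R_exp * R_rate (descending); background: all traits with a significant
    profile (any quadrant).  Returns an empty frame for an empty quadrant.
    """
    if quadrant not in QUADRANTS:
        raise ValueError(f"quadrant must be one of {QUADRANTS}")
    sig = profiles[profiles["quadrant"].isin(QUADRANTS)]
    sub = sig[sig["quadrant"] == quadrant].copy()
    if sub.empty:
        return pd.DataFrame(columns=["observed", "expected", "frac_difference", "chi2", "p"])
    if len(sub) < top_n:
        logger.warning("quadrant %s has %d traits < top_n=%d; truncating",
                       quadrant, len(sub), top_n)
    sub["score"] = (sub["R_exp"] * sub["R_rate"]).abs()
    fg = (sub.rename_axis("trait_id").reset_index()
             .sort_values(["score", "trait_id"], ascending=[False, True], kind="stable")
             .head(top_n))
    return domain_enrichment(fg["domain"], sig["domain"])


def pleiotropy_trend(cohort: Cohort, p_cut: float = PLEIOTROPY_P,
                     panel: list[str] | None = None) -> dict:
    """Trait counts per gene and their rank correlation with expression/rate.

    A gene's pleiotropy is the number of traits for which its p-value passes
    ``p_cut``.  Returns the counts plus Spearman correlations with mean log
    expression and with dN/dS; flagged undefined when no gene passes.
    """
    counts = (cohort.assoc < p_cut).sum(axis=1)
    out = {"counts": counts, "defined": bool((counts > 0).any())}
    if not out["defined"]:
        logger.warning("no gene passes p_cut=%g anywhere; trend undefined", p_cut)
        out.update(r_expression=np.nan, p_expression=np.nan,
                   r_rate=np.nan, p_rate=np.nan)
        return out
    expr = cohort.mean_log_expression(panel)
    rate = cohort.genes["dnds"]
    me = expr.notna()
    mr = rate.notna()
    re_, pe = stats.spearmanr(counts[me], expr[me])
    rr, pr = stats.spearmanr(counts[mr], rate[mr])
    out.update(r_expression=float(re_), p_expression=float(pe),
               r_rate=float(rr), p_rate=float(pr))
    return out


def plot_quadrants(profiles: pd.DataFrame, path) -> None:
    """Scatter of (R_exp, R_rate) per trait colored by significance tier."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"ns": "0.7", "nominal": "lightblue", "bonferroni": "darkblue"}
    fig, ax = plt.subplots(figsize=(5, 5))
    for tier, grp in profiles.dropna(subset=["R_exp", "R_rate"]).groupby("tier"):
        ax.scatter(grp["R_exp"], grp["R_rate"], s=8, c=colors.get(tier, "k"), label=tier)
    ax.axhline(0, color="k", lw=0.5)
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel("R_exp (association vs expression)")
    ax.set_ylabel("R_rate (association vs dN/dS)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
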