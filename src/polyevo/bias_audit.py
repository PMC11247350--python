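"""Audits of three systematic biases in gene-based GWAS compendia.

* gene-length bias — longer genes carry more markers and accrue smaller
  gene-level p-values; the audit reports the per-trait Spearman correlation
  between -log10(p) and gene length and ranks trait domains by it;
* ascertainment bias — popular traits are studied by many GWASs; the audit
  correlates per-domain trait counts with the domain-mean correlation
  profiles;
* power bias — larger GWASs recover stronger correlation profiles; the
  audit correlates R_exp and R_rate with log10 of the participant count.

All audits are pure, rank-based functions of their inputs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import Cohort


def gene_length_bias(cohort: Cohort) -> dict:
    """Per-trait Spearman of -log10(p) with gene length, plus domain summary."""
    length = cohort.genes["length"].astype(float)
    rows = []
    for trait_id in cohort.assoc.columns:
        p_gene = cohort.assoc[trait_id]
        mask = p_gene.notna() & length.notna()
        r, p = stats.spearmanr(-np.log10(p_gene[mask]), length[mask])
        rows.append((trait_id, float(r), float(p)))
    per_trait = pd.DataFrame(rows, columns=["trait_id", "R_length", "p"]).set_index("trait_id")
    per_trait["domain"] = cohort.traits["domain"].reindex(per_trait.index)
    domain = (per_trait.groupby("domain")["R_length"].mean()
              .sort_values(ascending=False).rename("mean_R_length").to_frame())
    domain["rank"] = np.arange(1, len(domain) + 1)
    return {"per_trait": per_trait, "per_domain": domain}


def ascertainment_audit(profiles: pd.DataFrame) -> dict:
    """Correlate per-domain trait counts with domain-mean R_exp and R_rate.

    Non-significance indicates that how often a domain was studied does not
    drive its correlation profile.  Undefined (flagged) with < 3 domains.
    """
    prof = profiles.dropna(subset=["R_exp", "R_rate", "domain"])
    grouped = prof.groupby("domain").agg(
        n_traits=("R_exp", "size"), mean_R_exp=("R_exp", "mean"),
        mean_R_rate=("R_rate", "mean"))
    if len(grouped) < 3 or grouped["n_traits"].nunique() < 2:
        return {"per_domain": grouped, "defined": False,
                "r_exp": np.nan, "p_exp": np.nan, "r_rate": np.nan, "p_rate": np.nan}
    re_, pe = stats.spearmanr(grouped["n_traits"], grouped["mean_R_exp"])
    rr, pr = stats.spearmanr(grouped["n_traits"], grouped["mean_R_rate"])
    return {"per_domain": grouped, "defined": True,
            "r_exp": float(re_), "p_exp": float(pe),
            "r_rate": float(rr), "p_rate": float(pr)}


def power_audit(profiles: pd.DataFrame, traits: pd.DataFrame) -> dict:
    """Spearman of R_exp and R_rate with GWAS power (log10 participants).

    Reported both over all profiled traits and over the subset with a
    significant profile; undefined (flagged) when power is constant.
    """
    prof = profiles.dropna(subset=["R_exp", "R_rate"]).copy()
    power = np.log10(traits["n_participants"].reindex(prof.index).astype(float))
    prof = prof[power.notna()]
    power = power.dropna()

    def _pair(sub: pd.DataFrame, pw: pd.Series) -> dict:
        if len(sub) < 3 or np.ptp(pw.to_numpy()) == 0:
            return {"defined": False, "r_exp": np.nan, "p_exp": np.nan,
                    "r_rate": np.nan, "p_rate": np.nan, "n": len(sub)}
        re_, pe = stats.spearmanr(sub["R_exp"], pw)
        rr, pr = stats.spearmanr(sub["R_rate"], pw)
        return {"defined": True, "r_exp": float(re_), "p_exp": float(pe),
                "r_rate": float(rr), "p_rate": float(pr), "n": len(sub)}

    sig_mask = prof["tier"].isin(["nominal", "bonferroni"]) if "tier" in prof else \
        pd.Series(True, index=prof.index)
    return {
        "all_traits": _pair(prof, power),
        "significant_traits": _pair(prof[sig_mask], power[sig_mask]),
    }
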