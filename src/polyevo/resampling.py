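"""Matched resampling null over nonassociated genes and domain enrichment.

For each eligible trait (>= 50 genome-wide-significant genes by default) the
associated gene set is compared, for a property of interest (evolutionary
rate or expression level) and a direction (higher / lower), against 1,000
random draws of equally many nonassociated genes.  Each draw runs a
one-tailed rank-sum test at 0.05 and the number of rejections ranks the
traits.  The top 100 traits per property/direction combination form a
foreground whose domain composition is tested against the full eligible
background with a per-domain one-vs-rest chi-square goodness-of-fit test.

Group labels follow the convention: 1 = associated genes evolve faster,
2 = slower, 3 = expressed higher, 4 = expressed lower.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import Cohort, GENOMEWIDE_P, significant_genes

logger = logging.getLogger(__name__)

#: (property, direction) layout of the four trait groups.
GROUPS = {
    1: ("rate", "higher"),
    2: ("rate", "lower"),
    3: ("expression", "higher"),
    4: ("expression", "lower"),
}


@dataclass
class ResamplingResult:
    trait_id: str
    property: str       # "rate" | "expression"
    direction: str      # "higher" | "lower"
    n_draws: int
    n_significant: int

    def __post_init__(self):
        if not 0 <= self.n_significant <= self.n_draws:
            raise ValueError("n_significant must lie in [0, n_draws]")


def child_seed(master_seed: int, *labels) -> int:
    """Stable per-(trait, property, ...) seed below 2**31."""
    digest = hashlib.sha256(("|".join(map(str, labels)) + f"|{master_seed}").encode())
    return int.from_bytes(digest.digest()[:4], "little") % (2**31)


def eligible_traits(assoc: pd.DataFrame, p_threshold: float = GENOMEWIDE_P,
                    min_genes: int = 50) -> list[str]:
    """Traits with at least ``min_genes`` genes below the threshold (inclusive)."""
    counts = (assoc < p_threshold).sum(axis=0)
    return [t for t in assoc.columns if counts[t] >= min_genes]


def _ranksum_p_batch(x: np.ndarray, samples: np.ndarray, alternative: str) -> np.ndarray:
    """One-tailed asymptotic rank-sum p-values of ``x`` vs each row of ``samples``.

    Normal approximation with tie correction and continuity correction,
    matching the asymptotic two-sample Mann-Whitney U test.  ``x`` has shape
    (m,) and ``samples`` (B, n); returns (B,) p-values for the alternative
    that x is stochastically greater ("greater") or less ("less").
    """
    m = x.size
    B, n = samples.shape
    combined = np.concatenate([np.broadcast_to(x, (B, m)), samples], axis=1)
    ranks = stats.rankdata(combined, axis=1)
    u1 = ranks[:, :m].sum(axis=1) - m * (m + 1) / 2.0
    mu = m * n / 2.0

    # tie correction per row
    s = np.sort(combined, axis=1)
    ties_present = (s[:, 1:] == s[:, :-1]).any(axis=1)
    tie_term = np.zeros(B)
    if ties_present.any():
        for i in np.flatnonzero(ties_present):
            _, counts = np.unique(s[i], return_counts=True)
            tie_term[i] = np.sum(counts**3 - counts)
    N = m + n
    sigma2 = m * n / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    sigma = np.sqrt(sigma2)
    if alternative == "greater":
        z = (u1 - mu - 0.5) / sigma
        return stats.norm.sf(z)
    elif alternative == "less":
        z = (u1 - mu + 0.5) / sigma
        return stats.norm.cdf(z)
    raise ValueError(f"unknown alternative {alternative!r}")


def _sample_without_replacement(rng: np.random.Generator, n_pool: int, k: int,
                                n_draws: int) -> np.ndarray:
    """(n_draws, k) index matrix, each row drawn without replacement.

    Uses rejection sampling when k is small relative to the pool (the common
    case here), falling back to per-row permutations otherwise.
    """
    if k * k > n_pool:  # rejection would loop too often
        return np.stack([rng.permutation(n_pool)[:k] for _ in range(n_draws)])
    idx = rng.integers(0, n_pool, size=(n_draws, k))
    while True:
        s = np.sort(idx, axis=1)
        bad = (s[:, 1:] == s[:, :-1]).any(axis=1)
        if not bad.any():
            return idx
        idx[bad] = rng.integers(0, n_pool, size=(int(bad.sum()), k))


def resample_and_test(values: pd.Series, associated: pd.Index, trait_id: str,
                      property_name: str, direction: str, n_draws: int = 1000,
                      alpha: float = 0.05, seed: int = 0) -> ResamplingResult:
    """Count draws on which the associated set beats a matched random set.

    Each of ``n_draws`` draws samples ``len(associated)`` genes without
    replacement from the nonassociated pool and runs a one-tailed rank-sum
    test of the associated values against the draw at level ``alpha``.
    """
    if direction not in ("higher", "lower"):
        raise ValueError("direction must be 'higher' or 'lower'")
    vals = values.dropna()
    assoc_ids = pd.Index(associated).intersection(vals.index)
    if assoc_ids.empty:
        raise ValueError(f"no associated genes with values for {trait_id}")
    pool = vals.index.difference(assoc_ids)
    k = len(assoc_ids)
    if len(pool) <= k:
        raise ValueError(f"nonassociated pool ({len(pool)}) not larger than set ({k})")

    rng = np.random.default_rng(seed)
    pool_vals = vals.loc[pool].to_numpy()
    x = vals.loc[assoc_ids].to_numpy()
    draws = pool_vals[_sample_without_replacement(rng, len(pool_vals), k, n_draws)]
    alt = "greater" if direction == "higher" else "less"
    p = _ranksum_p_batch(x, draws, alt)
    return ResamplingResult(trait_id=trait_id, property=property_name,
                            direction=direction, n_draws=n_draws,
                            n_significant=int((p < alpha).sum()))


def resampling_analysis(cohort: Cohort, p_threshold: float = GENOMEWIDE_P,
                        min_genes: int = 50, n_draws: int = 1000,
                        alpha: float = 0.05, seed: int = 0,
                        panel: list[str] | None = None,
                        traits: list[str] | None = None,
                        draws_per_trait: dict[str, int] | None = None
                        ) -> pd.DataFrame:
    """Run the resampling null for every eligible trait and combination.

    ``draws_per_trait`` can lower ``n_draws`` for selected traits (used by
    the desk profile to keep a full run fast).  Seeds are derived per
    (trait, property, direction) so any single trait reproduces in isolation.
    """
    if traits is None:
        traits = eligible_traits(cohort.assoc, p_threshold, min_genes)
    values = {
        "rate": cohort.genes["dnds"],
        "expression": cohort.mean_log_expression(panel),
    }
    rows = []
    for trait_id in traits:
        assoc_ids = significant_genes(cohort.assoc, trait_id, p_threshold)
        nd = (draws_per_trait or {}).get(trait_id, n_draws)
        for prop, vals in values.items():
            for direction in ("higher", "lower"):
                res = resample_and_test(
                    vals, assoc_ids, trait_id, prop, direction, n_draws=nd,
                    alpha=alpha, seed=child_seed(seed, trait_id, prop, direction),
                )
                rows.append((trait_id, prop, direction, res.n_draws, res.n_significant))
    return pd.DataFrame(rows, columns=["trait_id", "property", "direction",
                                       "n_draws", "n_significant"])


def rank_and_group(results: pd.DataFrame, top_n: int = 100) -> dict[int, pd.DataFrame]:
    """Rank traits within each of the four groups by significant-draw fraction.

    Returns, per group, the full ranked table with a ``foreground`` flag on
    the top ``top_n`` traits.  Ties break by trait id, so rankings are
    stable.  A short foreground (< top_n eligible traits) is logged.
    """
    out = {}
    for group, (prop, direction) in GROUPS.items():
        sub = results[(results["property"] == prop) & (results["direction"] == direction)].copy()
        sub["frac_significant"] = sub["n_significant"] / sub["n_draws"]
        sub = sub.sort_values(["frac_significant", "trait_id"],
                              ascending=[False, True], kind="stable").reset_index(drop=True)
        if len(sub) < top_n:
            logger.warning("group %d: only %d eligible traits for top_n=%d",
                           group, len(sub), top_n)
        sub["foreground"] = np.arange(len(sub)) < top_n
        out[group] = sub
    return out


def domain_enrichment(foreground_domains, background_domains) -> pd.DataFrame:
    """Per-domain one-vs-rest chi-square goodness-of-fit enrichment (df = 1).

    Observed counts are (k, n_fg - k) in the foreground; expected counts come
    from the background domain proportions.  Also reports the observed minus
    expected foreground fraction, the quantity usually plotted.
    """
    fg = pd.Series(list(foreground_domains), dtype=object)
    bg = pd.Series(list(background_domains), dtype=object)
    missing = set(fg) - set(bg)
    if missing:
        raise ValueError(f"foreground domain(s) absent from background: {sorted(missing)}")
    if bg.nunique() < 2:
        raise ValueError("background must contain at least 2 domains")
    n_fg = len(fg)
    bg_prop = bg.value_counts(normalize=True)
    rows = []
    for domain, q in bg_prop.items():
        k = int((fg == domain).sum())
        expected = n_fg * q
        obs = np.array([k, n_fg - k])
        exp = np.array([expected, n_fg - expected])
        chi2 = float(((obs - exp) ** 2 / exp).sum())
        p = float(stats.chi2.sf(chi2, df=1))
        rows.append((domain, k, expected, k / n_fg - q, chi2, p))
    return pd.DataFrame(rows, columns=["domain", "observed", "expected",
                                       "frac_difference", "chi2", "p"]).set_index("domain")


def group_enrichments(groups: dict[int, pd.DataFrame], trait_domains: pd.Series
                      ) -> dict[int, pd.DataFrame]:
    """Domain enrichment of each group's foreground against the background."""
    out = {}
    for group, table in groups.items():
        fg = trait_domains.loc[table.loc[table["foreground"], "trait_id"]]
        bg = trait_domains.loc[table["trait_id"]]
        out[group] = domain_enrichment(fg, bg)
    return out
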