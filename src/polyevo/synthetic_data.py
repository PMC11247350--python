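"""Synthetic cohort generator with machine-readable planted truth.

The generator emulates the gene-level statistical structure the analyses
assume, without any SNP-level detail:

* gene covariates (log expression, log dN/dS, gene length) drawn from a
  Gaussian copula with planted rank correlations — by default a negative
  expression/rate dependency (Spearman -0.3) and weak negative length
  correlations with both (-0.08 and -0.07);
* per-trait gene z-scores built from rank-normal scores of the covariates,
  ``z_g = a_exp*s(expr) + a_rate*s(rate) + b_len*s(len) + eps``, with noise
  variance inversely proportional to log10 of the GWAS sample size, so
  better-powered studies recover their planted correlations more strongly;
* a set of "causal" genes per trait, sampled preferentially along the
  planted directions and given a large z boost, so that a realistic number
  of genes passes the genome-wide threshold;
* polymorphism counts drawn Poisson with rates tuned so the expected sign
  of the direction-of-selection statistic matches the per-domain plan;
* two-class codon site mixtures whose purifying mass decreases with the
  gene's evolutionary rate.

Everything is reproducible from a single seed, and :class:`PlantedTruth`
records what each downstream inference should recover.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import Cohort, TPM_PREFIX, log_expression

#: 29 main-tissue panel used for genome-wide analyses.
DEFAULT_TISSUES: tuple[str, ...] = (
    "adipose", "adrenal_gland", "artery", "bladder", "brain", "breast",
    "cervix", "colon", "esophagus", "fallopian_tube", "heart", "kidney",
    "liver", "lung", "muscle", "nerve", "ovary", "pancreas", "pituitary",
    "prostate", "salivary_gland", "skin", "small_intestine", "spleen",
    "stomach", "testis", "thyroid", "uterus", "vagina",
)


@dataclass
class TraitPlanRow:
    """One block of traits sharing a domain and planted effect sizes.

    ``a_exp``/``a_rate`` are the planted partial rank correlations between
    the gene z-score and expression/evolutionary rate; ``length_bias`` is the
    planted raw rank correlation with gene length; ``dos_sign`` plants the
    sign of the direction-of-selection statistic among the trait's causal
    genes (+1, -1 or 0 for neutral).
    """

    domain: str
    n_traits: int
    a_exp: float
    a_rate: float
    n_participants: int = 100_000
    length_bias: float = 0.05
    dos_sign: int = 0
    n_causal: int = 100


def default_trait_plan() -> list[TraitPlanRow]:
    """200 traits over eight domains with the sign patterns under study.

    Metabolic-like domains associate with highly expressed, slowly evolving
    genes; immunological traits with highly expressed but fast-evolving
    genes (and a positive planted direction of selection); psychiatric
    traits with lowly expressed genes and the strongest gene-length bias.
    """
    return [
        TraitPlanRow("metabolic", 40, +0.15, -0.10, 200_000, 0.05, 0),
        TraitPlanRow("immunological", 30, +0.12, +0.10, 300_000, 0.05, +1),
        TraitPlanRow("psychiatric", 25, -0.10, -0.08, 150_000, 0.30, 0),
        TraitPlanRow("neurological", 25, +0.10, -0.08, 100_000, 0.10, 0),
        TraitPlanRow("cardiovascular", 20, +0.10, -0.05, 250_000, 0.05, 0),
        TraitPlanRow("reproduction", 15, -0.08, -0.08, 80_000, 0.05, -1),
        TraitPlanRow("body_structure", 20, +0.08, -0.06, 400_000, 0.05, 0),
        TraitPlanRow("other", 25, +0.05, 0.0, 120_000, 0.05, 0),
    ]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults are the study conditions."""

    n_genes: int = 15_000
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    trait_plan: list[TraitPlanRow] = field(default_factory=default_trait_plan)
    rho_expr_rate: float = -0.30
    rho_len_rate: float = -0.08
    rho_len_expr: float = -0.07
    n_monogenic: int = 800
    causal_gain: float = 10.0
    boost_mean: float = 6.0
    ref_participants: int = 100_000
    seed: int = 0

    def __post_init__(self):
        for name in ("rho_expr_rate", "rho_len_rate", "rho_len_expr"):
            if abs(getattr(self, name)) >= 1:
                raise ValueError(f"{name} must have magnitude < 1")
        for row in self.trait_plan:
            if row.n_traits < 1:
                raise ValueError("each trait-plan row needs n_traits >= 1")

    def trait_rows(self):
        """Yield (trait_id, plan row) pairs in deterministic order."""
        counts: dict[str, int] = {}
        for row in self.trait_plan:
            for _ in range(row.n_traits):
                k = counts.get(row.domain, 0) + 1
                counts[row.domain] = k
                yield f"{row.domain}_{k:03d}", row


@dataclass
class PlantedTruth:
    """What each downstream inference should recover, by construction."""

    trait_signs: dict          # trait_id -> {"a_exp":…, "a_rate":…, "length_bias":…}
    trait_quadrant: dict       # trait_id -> "A" | "B" | "C" | "D" | "none"
    domain_groups: dict        # domain -> list of resampling groups (1..4)
    dos_domain_sign: dict      # domain -> -1 | 0 | +1
    gene_dos_sign: dict | None = None    # gene_id -> -1 | 0 | +1 (sampled)
    causal_genes: dict | None = None     # trait_id -> list of gene ids (sampled)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def _quadrant_of(a_exp: float, a_rate: float) -> str:
    if a_exp > 0 and a_rate < 0:
        return "A"
    if a_exp > 0 and a_rate > 0:
        return "B"
    if a_exp < 0 and a_rate < 0:
        return "C"
    if a_exp < 0 and a_rate > 0:
        return "D"
    return "none"


def planted_truth(config: SimulationConfig) -> PlantedTruth:
    """Deterministic trait/domain-level truth implied by the config alone."""
    signs, quadrants, groups, dos = {}, {}, {}, {}
    for trait_id, row in config.trait_rows():
        signs[trait_id] = {"a_exp": row.a_exp, "a_rate": row.a_rate,
                           "length_bias": row.length_bias}
        quadrants[trait_id] = _quadrant_of(row.a_exp, row.a_rate)
    for row in config.trait_plan:
        g = []
        if row.a_rate > 0:
            g.append(1)      # associated genes evolve faster
        elif row.a_rate < 0:
            g.append(2)      # associated genes evolve slower
        if row.a_exp > 0:
            g.append(3)      # associated genes expressed higher
        elif row.a_exp < 0:
            g.append(4)      # associated genes expressed lower
        groups[row.domain] = g
        dos[row.domain] = row.dos_sign
    return PlantedTruth(trait_signs=signs, trait_quadrant=quadrants,
                        domain_groups=groups, dos_domain_sign=dos)


def spearman_to_pearson(rho):
    """Pearson correlation of the latent normals giving Spearman ``rho``."""
    return 2.0 * np.sin(np.pi * np.asarray(rho, dtype=float) / 6.0)


def _rank_normal(values: np.ndarray) -> np.ndarray:
    """Rank-normal (van der Waerden) scores; average ranks on ties."""
    r = stats.rankdata(values, method="average")
    return stats.norm.ppf((r - 0.5) / len(values))


# Poisson rates (Dn, Ds, Pn, Ps) by planted direction-of-selection sign.
_DOS_RATES = {
    0: (8.0, 10.0, 8.0, 10.0),
    +1: (12.0, 10.0, 5.0, 10.0),
    -1: (5.0, 10.0, 12.0, 10.0),
}


def generate_cohort(config: SimulationConfig, seed: int | None = None
                    ) -> tuple[Cohort, PlantedTruth]:
    """Draw one complete synthetic cohort plus its planted truth."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_genes

    # --- gene covariates via a Gaussian copula ---------------------------
    corr = np.array([
        [1.0, spearman_to_pearson(config.rho_expr_rate), spearman_to_pearson(config.rho_len_expr)],
        [spearman_to_pearson(config.rho_expr_rate), 1.0, spearman_to_pearson(config.rho_len_rate)],
        [spearman_to_pearson(config.rho_len_expr), spearman_to_pearson(config.rho_len_rate), 1.0],
    ])
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals.min() < -1e-10:
        raise ValueError(
            "planted correlation matrix is not positive semidefinite for "
            f"(rho_expr_rate={config.rho_expr_rate}, rho_len_rate={config.rho_len_rate}, "
            f"rho_len_expr={config.rho_len_expr})"
        )
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(3))
    latent = rng.standard_normal((n, 3)) @ chol.T
    u_expr, u_rate, u_len = latent.T

    gene_ids = np.array([f"g{i + 1:05d}" for i in range(n)])
    length = np.maximum(np.exp(9.8 + 1.1 * u_len), 200.0).round().astype(int)
    dnds = np.clip(np.exp(-1.03 + 0.8 * u_rate), 0.01, 3.0)

    # shared log10-TPM component plus per-tissue wobble
    mu_expr = 0.8 + 0.9 * u_expr
    tpm = 10.0 ** (mu_expr[:, None] + 0.25 * rng.standard_normal((n, len(config.tissues))))
    tpm = np.round(tpm, 4)

    genes = pd.DataFrame({"length": length, "dnds": dnds}, index=pd.Index(gene_ids, name="gene_id"))
    for j, t in enumerate(config.tissues):
        genes[TPM_PREFIX + t] = tpm[:, j]

    # monogenic genes: biased toward slow-evolving genes, narrower dN/dS spread
    w_mono = np.exp(-0.8 * u_rate)
    mono_idx = rng.choice(n, size=min(config.n_monogenic, n), replace=False,
                          p=w_mono / w_mono.sum())
    genes["is_monogenic"] = False
    genes.iloc[mono_idx, genes.columns.get_loc("is_monogenic")] = True

    # rank-normal scores actually used in the z model (based on observables)
    s_e = _rank_normal(log_expression(tpm).mean(axis=1))
    s_r = _rank_normal(dnds)
    s_l = _rank_normal(length.astype(float))

    # --- per-trait association z-scores ----------------------------------
    truth = planted_truth(config)
    truth.causal_genes = {}
    pw_ref = np.log10(config.ref_participants)
    p_cols = {}
    gene_dos_sign = np.zeros(n, dtype=int)

    for trait_id, row in config.trait_rows():
        b_e = spearman_to_pearson(row.a_exp)
        b_r = spearman_to_pearson(row.a_rate)
        b_l = spearman_to_pearson(row.length_bias)
        power = np.log10(row.n_participants)
        base_var = max(1.0 - b_e**2 - b_r**2 - b_l**2, 0.05)
        noise_sd = np.sqrt(base_var * pw_ref / power)
        z = b_e * s_e + b_r * s_r + b_l * s_l + noise_sd * rng.standard_normal(n)

        # causal genes: sampled along the planted directions, boosted past
        # the genome-wide threshold (boost grows with GWAS power)
        n_causal = min(row.n_causal, n)
        logit = config.causal_gain * (row.a_exp * s_e + row.a_rate * s_r)
        w = np.exp(logit - logit.max())
        causal = rng.choice(n, size=n_causal, replace=False, p=w / w.sum())
        boost = config.boost_mean * np.sqrt(power / pw_ref) + rng.standard_normal(n_causal)
        z[causal] += np.clip(boost, 0.0, None)
        truth.causal_genes[trait_id] = sorted(gene_ids[causal])
        if row.dos_sign != 0:
            fresh = causal[gene_dos_sign[causal] == 0]
            gene_dos_sign[fresh] = row.dos_sign

        p_cols[trait_id] = np.clip(stats.norm.sf(z), 1e-300, 1.0 - 1e-16)

    assoc = pd.DataFrame(p_cols, index=genes.index)

    traits = pd.DataFrame(
        [(tid, row.domain, row.n_participants) for tid, row in config.trait_rows()],
        columns=["trait_id", "domain", "n_participants"],
    ).set_index("trait_id")
    from .io_model import count_associated
    traits["n_associated"] = count_associated(assoc)

    # --- polymorphism counts with planted DoS sign -----------------------
    rates = np.array([_DOS_RATES[s] for s in gene_dos_sign])
    counts = rng.poisson(rates)
    polymorphism = pd.DataFrame(counts, columns=["Dn", "Ds", "Pn", "Ps"], index=genes.index)
    polymorphism["daf"] = np.round(rng.uniform(0.0, 1.0, size=n), 6)
    truth.gene_dos_sign = dict(zip(gene_ids, (int(s) for s in gene_dos_sign)))

    # --- two-class site mixtures: purifying mass decreases with dN/dS ----
    p_pur = np.clip(0.85 - 0.5 * stats.norm.cdf(s_r) + 0.05 * rng.standard_normal(n),
                    0.02, 0.995)
    omega_pur = rng.uniform(0.05, 0.8, size=n)
    omega_pos = rng.uniform(1.05, 2.5, size=n)
    site_classes = pd.DataFrame({
        "gene_id": np.repeat(gene_ids, 2),
        "class_index": np.tile([1, 2], n),
        "proportion": np.stack([p_pur, 1.0 - p_pur], axis=1).ravel(),
        "omega": np.stack([omega_pur, omega_pos], axis=1).ravel(),
    })

    cohort = Cohort(genes=genes, assoc=assoc, traits=traits,
                    polymorphism=polymorphism, site_classes=site_classes)
    return cohort, truth
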