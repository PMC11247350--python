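"""Gene-level data model, TSV input/output, and elementary transforms.

The pipeline operates on plain tab-separated tables describing a cohort of
genes and traits:

* ``genes.tsv`` — one row per gene: ``gene_id``, ``length`` (bp), ``dnds``
  (pairwise dN/dS ratio, may be ``NA``), and one ``tpm_<tissue>`` column of
  median expression per tissue (transcripts per million).
* ``assoc.tsv`` — gene-level association p-values (MAGMA-style), one column
  per trait.
* ``traits.tsv`` — trait catalog: ``trait_id``, ``domain``, ``n_participants``.
* ``polymorphism.tsv`` — per-gene divergence/polymorphism counts
  (``Dn``, ``Ds``, ``Pn``, ``Ps``) and the derived allele frequency ``daf``.
* ``siteclasses.tsv`` — per-gene codon site-class mixtures
  (``class_index``, ``proportion``, ``omega``) from a site model fit.
* ``monogenic.txt`` — one gene id per line flagging genes implicated in
  monogenic disease.

All downstream statistics are rank-based or count-based, so the containers
are ordinary :class:`pandas.DataFrame` objects bundled in :class:`Cohort`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Closed vocabulary of trait domains.
DOMAINS: tuple[str, ...] = (
    "metabolic",
    "immunological",
    "psychiatric",
    "neurological",
    "cardiovascular",
    "reproduction",
    "body_structure",
    "other",
)

#: Genome-wide significance threshold on the gene-level p-value
#: (equivalent to a one-sided z-score of about 4.5).
GENOMEWIDE_P: float = 2.84e-6

#: Relaxed "associated" threshold used by the loess-residual and
#: direction-of-selection analyses.
ASSOCIATED_P: float = 2.8e-5

#: Stringent per-gene threshold used when counting pleiotropic associations.
PLEIOTROPY_P: float = 1e-7

TPM_PREFIX = "tpm_"
NA_TOKEN = "NA"

TABLE_FILES = {
    "genes": "genes.tsv",
    "assoc": "assoc.tsv",
    "traits": "traits.tsv",
    "polymorphism": "polymorphism.tsv",
    "site_classes": "siteclasses.tsv",
    "monogenic": "monogenic.txt",
}


@dataclass
class Cohort:
    """All input tables of one analysis run, cross-referenced by gene id.

    ``genes`` is indexed by ``gene_id`` and carries ``length``, ``dnds``,
    ``is_monogenic`` and the ``tpm_*`` columns.  ``assoc`` is indexed by
    ``gene_id`` with one p-value column per trait.  Side tables
    (``polymorphism``, ``site_classes``) may cover only a subset of genes.
    """

    genes: pd.DataFrame
    assoc: pd.DataFrame
    traits: pd.DataFrame
    polymorphism: pd.DataFrame = field(default_factory=pd.DataFrame)
    site_classes: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def tissues(self) -> list[str]:
        return [c[len(TPM_PREFIX):] for c in self.genes.columns if c.startswith(TPM_PREFIX)]

    def tpm(self, panel: list[str] | None = None, exclude: list[str] | None = None) -> pd.DataFrame:
        """Expression matrix (genes x tissues, TPM), optionally restricted."""
        tissues = list(panel) if panel is not None else self.tissues
        if exclude:
            tissues = [t for t in tissues if t not in set(exclude)]
        cols = [TPM_PREFIX + t for t in tissues]
        missing = [c for c in cols if c not in self.genes.columns]
        if missing:
            raise KeyError(f"unknown tissue columns: {missing}")
        out = self.genes[cols].copy()
        out.columns = tissues
        return out

    def mean_log_expression(self, panel: list[str] | None = None,
                            pseudocount: float = 1.0) -> pd.Series:
        """Per-gene mean of log10(TPM + pseudocount) over the tissue panel."""
        lx = log_expression(self.tpm(panel), pseudocount=pseudocount)
        return lx.mean(axis=1)

    @property
    def monogenic_genes(self) -> pd.Index:
        return self.genes.index[self.genes["is_monogenic"].astype(bool)]


# ---------------------------------------------------------------------------
# elementary transforms
# ---------------------------------------------------------------------------

def pz_transform(p=None, z=None):
    """Convert between a gene p-value and its one-sided normal z-score.

    The single conversion used throughout the package is the upper-tail
    standard-normal quantile, ``z = Phi^-1(1 - p)``; a genome-wide p-value
    of 2.84e-6 corresponds to z ~ 4.5.  Exactly one of ``p`` and ``z`` must
    be given; the function returns the other scale.
    """
    if (p is None) == (z is None):
        raise ValueError("give exactly one of p or z")
    if p is not None:
        p = np.asarray(p, dtype=float)
        if np.any((p <= 0.0) | (p >= 1.0)):
            raise ValueError("p-values must lie strictly in (0, 1)")
        out = stats.norm.isf(p)
    else:
        z = np.asarray(z, dtype=float)
        if not np.all(np.isfinite(z)):
            raise ValueError("z-scores must be finite")
        out = stats.norm.sf(z)
    return out.item() if out.ndim == 0 else out


def log_expression(tpm, pseudocount: float = 1.0):
    """log10(TPM + pseudocount); strictly increasing, finite for TPM >= 0."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    arr = np.asarray(tpm, dtype=float)
    if np.any(arr[np.isfinite(arr)] < 0):
        raise ValueError("TPM values must be non-negative")
    out = np.log10(arr + pseudocount)
    if isinstance(tpm, pd.DataFrame):
        return pd.DataFrame(out, index=tpm.index, columns=tpm.columns)
    if isinstance(tpm, pd.Series):
        return pd.Series(out, index=tpm.index, name=tpm.name)
    return out


def assign_deciles(values) -> np.ndarray:
    """Assign decile labels 1..10 by value rank, balanced to within one element.

    Missing values get NaN labels.  Ties are broken by stable input order
    (mergesort), so labels are deterministic for any input.
    """
    v = np.asarray(values, dtype=float)
    mask = np.isfinite(v)
    n = int(mask.sum())
    if n < 10:
        raise ValueError(f"need at least 10 non-missing values, got {n}")
    labels = np.full(v.shape, np.nan)
    idx = np.flatnonzero(mask)
    order = idx[np.argsort(v[idx], kind="stable")]
    labels[order] = np.arange(n) * 10 // n + 1
    return labels


def significant_genes(assoc: pd.DataFrame, trait_id: str,
                      p_threshold: float = GENOMEWIDE_P) -> pd.Index:
    """Genes whose p-value for ``trait_id`` falls strictly below the threshold."""
    if not 0.0 < p_threshold < 1.0:
        raise ValueError("p_threshold must lie in (0, 1)")
    if trait_id not in assoc.columns:
        raise KeyError(f"unknown trait_id {trait_id!r}")
    col = assoc[trait_id]
    return assoc.index[col < p_threshold]


def count_associated(assoc: pd.DataFrame, p_threshold: float = GENOMEWIDE_P) -> pd.Series:
    """Number of genes below the significance threshold, per trait."""
    return (assoc < p_threshold).sum(axis=0)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _check_unique_gene_ids(frame: pd.DataFrame, name: str) -> None:
    dup = frame.index[frame.index.duplicated()]
    if len(dup):
        raise ValueError(f"{name}: duplicated gene_id {sorted(set(dup))[:5]}")


def read_tables(directory, files: dict[str, str] | None = None) -> Cohort:
    """Read the cohort tables from ``directory`` and cross-reference them.

    Raises on duplicated gene ids, association p-values outside (0, 1], and
    trait domains outside the declared vocabulary.  Genes absent from the
    side tables simply carry missing values there; a manifest of row counts
    is logged.
    """
    directory = Path(directory)
    files = {**TABLE_FILES, **(files or {})}

    genes = pd.read_csv(directory / files["genes"], sep="\t", na_values=[NA_TOKEN])
    genes = genes.set_index("gene_id")
    _check_unique_gene_ids(genes, files["genes"])
    if (genes["length"] < 1).any():
        raise ValueError("gene length must be >= 1")
    dnds = genes["dnds"].dropna()
    if (dnds < 0).any():
        raise ValueError("dN/dS must be non-negative")
    tpm_cols = [c for c in genes.columns if c.startswith(TPM_PREFIX)]
    if (genes[tpm_cols].to_numpy() < 0).any():
        raise ValueError("TPM values must be non-negative")

    assoc = pd.read_csv(directory / files["assoc"], sep="\t", na_values=[NA_TOKEN])
    assoc = assoc.set_index("gene_id")
    _check_unique_gene_ids(assoc, files["assoc"])
    pvals = assoc.to_numpy(dtype=float)
    bad = np.argwhere(~np.isnan(pvals) & ((pvals <= 0) | (pvals > 1)))
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"association p-value out of (0, 1] at row {r} "
            f"(gene {assoc.index[r]!r}, trait {assoc.columns[c]!r})"
        )

    traits = pd.read_csv(directory / files["traits"], sep="\t", na_values=[NA_TOKEN])
    traits = traits.set_index("trait_id")
    unknown = set(traits["domain"]) - set(DOMAINS)
    if unknown:
        raise ValueError(
            f"unknown trait domain(s) {sorted(unknown)}; vocabulary is {list(DOMAINS)}"
        )

    poly_path = directory / files["polymorphism"]
    if poly_path.exists():
        polymorphism = pd.read_csv(poly_path, sep="\t", na_values=[NA_TOKEN]).set_index("gene_id")
        _check_unique_gene_ids(polymorphism, files["polymorphism"])
        counts = polymorphism[["Dn", "Ds", "Pn", "Ps"]]
        if (counts.to_numpy() < 0).any():
            raise ValueError("polymorphism counts must be non-negative")
        daf = polymorphism["daf"].dropna()
        if ((daf < 0) | (daf > 1)).any():
            raise ValueError("derived allele frequency must lie in [0, 1]")
    else:
        polymorphism = pd.DataFrame()

    sc_path = directory / files["site_classes"]
    if sc_path.exists():
        site_classes = pd.read_csv(sc_path, sep="\t", na_values=[NA_TOKEN])
        sums = site_classes.groupby("gene_id")["proportion"].sum()
        off = sums[(sums - 1.0).abs() > 1e-6]
        if len(off):
            raise ValueError(f"site-class proportions do not sum to 1 for {list(off.index)[:5]}")
    else:
        site_classes = pd.DataFrame()

    mono_path = directory / files["monogenic"]
    if mono_path.exists():
        mono = {line.strip() for line in mono_path.read_text().splitlines() if line.strip()}
    else:
        mono = set()
    genes["is_monogenic"] = genes.index.isin(mono)

    common = [t for t in traits.index if t in assoc.columns]
    traits["n_associated"] = (
        count_associated(assoc[common]).reindex(traits.index).fillna(0).astype(int)
    )

    logger.info(
        "read cohort: %d genes, %d traits, %d polymorphism rows, %d site-class rows, "
        "%d monogenic ids (%d matched)",
        len(genes), len(traits), len(polymorphism), len(site_classes),
        len(mono), int(genes["is_monogenic"].sum()),
    )
    return Cohort(genes=genes, assoc=assoc, traits=traits,
                  polymorphism=polymorphism, site_classes=site_classes)


def write_tables(cohort: Cohort, directory, float_format: str = "%.17g") -> None:
    """Write the cohort back to TSV files (inverse of :func:`read_tables`)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    genes = cohort.genes.drop(columns=["is_monogenic"])
    genes.to_csv(directory / TABLE_FILES["genes"], sep="\t", na_rep=NA_TOKEN,
                 float_format=float_format)
    cohort.assoc.to_csv(directory / TABLE_FILES["assoc"], sep="\t", na_rep=NA_TOKEN,
                        float_format="%.17g")
    traits = cohort.traits.drop(columns=["n_associated"], errors="ignore")
    traits.to_csv(directory / TABLE_FILES["traits"], sep="\t", na_rep=NA_TOKEN)
    if len(cohort.polymorphism):
        cohort.polymorphism.to_csv(directory / TABLE_FILES["polymorphism"], sep="\t",
                                   na_rep=NA_TOKEN, float_format=float_format)
    if len(cohort.site_classes):
        cohort.site_classes.to_csv(directory / TABLE_FILES["site_classes"], sep="\t",
                                   na_rep=NA_TOKEN, index=False, float_format=float_format)
    mono = cohort.monogenic_genes
    (directory / TABLE_FILES["monogenic"]).write_text("\n".join(mono) + ("\n" if len(mono) else ""))
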