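import numpy as np
import pandas as pd
import pytest

from polyevo.synthetic_data import SimulationConfig, TraitPlanRow, generate_cohort


def compact_plan():
    """Four-domain plan small enough for unit tests, signs as in the defaults."""
    return [
        TraitPlanRow("metabolic", 5, +0.15, -0.10, 200_000, 0.05, 0),
        TraitPlanRow("immunological", 5, +0.12, +0.10, 300_000, 0.05, +1),
        TraitPlanRow("psychiatric", 3, -0.10, -0.08, 150_000, 0.30, 0),
        TraitPlanRow("other", 3, +0.05, 0.0, 120_000, 0.05, 0),
    ]


@pytest.fixture(scope="session")
def small_cohort():
    """3,000-gene, 16-trait cohort shared by the unit tests."""
    cfg = SimulationConfig(n_genes=3000, trait_plan=compact_plan(), seed=11)
    cohort, truth = generate_cohort(cfg)
    return cohort, truth, cfg


@pytest.fixture(scope="session")
def toy_dir(tmp_path_factory):
    """Hand-written 3-gene, 2-trait table set exercising the readers."""
    d = tmp_path_factory.mktemp("toy")
    (d / "genes.tsv").write_text(
        "gene_id\tlength\tdnds\ttpm_brain\ttpm_liver\n"
        "gA\t1000\t0.25\t10.0\t1.0\n"
        "gB\t2500\t1.10\t0.0\t5.0\n"
        "gC\t500\tNA\t3.0\t3.0\n"
    )
    (d / "assoc.tsv").write_text(
        "gene_id\ttrait1\ttrait2\n"
        "gA\t0.5\t1e-7\n"
        "gB\t0.001\t0.2\n"
        "gC\t1.0\t0.03\n"
    )
    (d / "traits.tsv").write_text(
        "trait_id\tdomain\tn_participants\n"
        "trait1\tmetabolic\t100000\n"
        "trait2\timmunological\t250000\n"
    )
    (d / "polymorphism.tsv").write_text(
        "gene_id\tDn\tDs\tPn\tPs\tdaf\n"
        "gA\t2\t2\t2\t2\t0.7\n"
        "gB\t10\t5\t2\t8\t0.4\n"
    )
    (d / "siteclasses.tsv").write_text(
        "gene_id\tclass_index\tproportion\tomega\n"
        "gA\t1\t0.7\t0.1\n"
        "gA\t2\t0.3\t2.0\n"
        "gB\t1\t1.0\t0.5\n"
    )
    (d / "monogenic.txt").write_text("gA\n")
    return d
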