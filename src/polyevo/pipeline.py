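"""End-to-end orchestration: simulate, run every analysis stage, report.

The pipeline config collects the thresholds shared by all stages (the
genome-wide p-value cutoff, the relaxed "associated" cutoff, the stringent
pleiotropy cutoff, and alpha), the resampling and enrichment sizes, and the
tissue panel.  ``run_pipeline`` writes every intermediate table as TSV, a
machine-readable ``summary.json``, a human-readable ``report.md`` and a run
manifest with the config hash, seed and per-stage exclusion counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io_model import (ASSOCIATED_P, GENOMEWIDE_P, PLEIOTROPY_P, Cohort,
                       read_tables, write_tables)
from .synthetic_data import SimulationConfig, generate_cohort
from . import bias_audit, correlation_map, group_compare, resampling, selection_signatures
from . import tissue_enrichment as tissue_mod

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    genomewide_p: float = GENOMEWIDE_P
    associated_p: float = ASSOCIATED_P
    pleiotropy_p: float = PLEIOTROPY_P
    alpha: float = 0.05
    n_draws: int = 1000
    min_associated: int = 50
    top_n: int = 100
    top_n_grid: tuple[int, ...] = (100, 200, 300)
    top_k: int = 1000
    daf_grid: tuple[float, ...] = (0.60, 0.30, 0.01)
    loess_span: float = 0.75
    quadrant_tier: str = "bonferroni"
    tissue_panel: list[str] | None = None
    exclude_tissues: list[str] | None = None
    desk: bool = False          # cap full-rate resampling at 50 traits
    desk_full_traits: int = 50
    desk_reduced_draws: int = 200

    def validate(self) -> None:
        if not (0 < self.genomewide_p < self.associated_p < 1):
            raise ValueError(
                "thresholds must satisfy 0 < genomewide_p < associated_p < 1 "
                f"(got {self.genomewide_p} and {self.associated_p})")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_draws < 1 or self.top_n < 1:
            raise ValueError("n_draws and top_n must be positive")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg


def _top_enriched(table: pd.DataFrame):
    """Domain with the largest chi-square among over-represented domains."""
    over = table[table["frac_difference"] > 0]
    return over["chi2"].idxmax() if len(over) else None


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.reset_index().to_dict(orient="list"))
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if isinstance(obj, pd.Index):
        return [str(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def run_pipeline(output_dir, config: PipelineConfig | None = None,
                 seed: int = 0, simulate: bool = True,
                 sim_config: SimulationConfig | None = None,
                 input_dir=None) -> dict:
    """Run every analysis stage and write the report bundle.

    With ``simulate=True`` a synthetic cohort is generated from ``seed`` and
    the summary additionally compares recovered quadrants against the
    planted truth.  Otherwise ``input_dir`` must hold the cohort tables.
    """
    config = config or PipelineConfig()
    config.validate()
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": seed,
        "config_hash": _config_hash(config),
        "config": dataclasses.asdict(config),
        "stages": {},
    }
    summary: dict = {"seed": seed}
    truth = None

    stage = "load"
    try:
        if simulate:
            sim = sim_config or SimulationConfig(seed=seed)
            cohort, truth = generate_cohort(sim, seed=seed)
            write_tables(cohort, out / "input")
            truth.to_json(out / "input" / "truth.json")
        else:
            if input_dir is None:
                raise ValueError("input_dir required when simulate=False")
            cohort = read_tables(input_dir)
        manifest["stages"][stage] = {"n_genes": len(cohort.genes),
                                     "n_traits": len(cohort.traits)}

        # --- group compare on the two best-powered traits ----------------
        stage = "group_compare"
        counts = cohort.traits["n_associated"].sort_values(ascending=False)
        focus = list(counts.index[:2])
        gc = {}
        k_gc = min(config.top_k, len(cohort.assoc) // 2)
        for trait_id in focus:
            s = group_compare.trait_summary(cohort, trait_id, k=k_gc,
                                            alpha=config.alpha,
                                            panel=config.tissue_panel)
            s["tissue_table"].to_csv(out / f"group_compare_{trait_id}.tsv", sep="\t")
            s.pop("tissue_table")
            gc[trait_id] = s
        summary["group_compare"] = gc
        manifest["stages"][stage] = {"focus_traits": focus}

        # --- resampling ---------------------------------------------------
        stage = "resampling"
        eligible = resampling.eligible_traits(cohort.assoc, config.genomewide_p,
                                              config.min_associated)
        draws_per_trait = None
        if config.desk and len(eligible) > config.desk_full_traits:
            draws_per_trait = {t: config.desk_reduced_draws
                               for t in eligible[config.desk_full_traits:]}
        results = resampling.resampling_analysis(
            cohort, p_threshold=config.genomewide_p, min_genes=config.min_associated,
            n_draws=config.n_draws, alpha=config.alpha, seed=seed,
            panel=config.tissue_panel, traits=eligible, draws_per_trait=draws_per_trait)
        results.to_csv(out / "resampling.tsv", sep="\t", index=False)
        groups = resampling.rank_and_group(results, top_n=config.top_n)
        enrich = resampling.group_enrichments(groups, cohort.traits["domain"])
        for g, table in enrich.items():
            table.to_csv(out / f"resampling_enrichment_group{g}.tsv", sep="\t")
        summary["resampling"] = {
            "n_eligible": len(eligible),
            "top_domain_per_group": {g: _top_enriched(t) for g, t in enrich.items()},
            "enrichment": {g: t for g, t in enrich.items()},
        }
        manifest["stages"][stage] = {"n_eligible": len(eligible)}

        # --- correlation map ----------------------------------------------
        stage = "correlation_map"
        profiles = correlation_map.trait_profiles(
            cohort, alpha=config.alpha, panel=config.tissue_panel,
            quadrant_tier=config.quadrant_tier)
        profiles.to_csv(out / "profiles.tsv", sep="\t")
        shares = correlation_map.quadrant_shares(profiles)
        quad_enrich = {q: correlation_map.quadrant_enrichment(profiles, q, config.top_n)
                       for q in correlation_map.QUADRANTS
                       if (profiles["quadrant"] == q).any()}
        pleio = correlation_map.pleiotropy_trend(cohort, config.pleiotropy_p,
                                                 panel=config.tissue_panel)
        summary["correlation_map"] = {
            "quadrant_shares": shares,
            "n_significant": int(profiles["quadrant"].isin(correlation_map.QUADRANTS).sum()),
            "quadrant_enrichment": quad_enrich,
            "pleiotropy": {k: v for k, v in pleio.items() if k != "counts"},
        }
        manifest["stages"][stage] = {
            "n_profiled": int(profiles["R_exp"].notna().sum()),
            "n_missing": int(profiles["R_exp"].isna().sum()),
        }

        # --- selection signatures -----------------------------------------
        stage = "selection"
        resid = selection_signatures.residual_summary(
            cohort, span=config.loess_span, p_cut=config.associated_p,
            panel=config.tissue_panel)
        if len(resid):
            resid.to_csv(out / "loess_residuals.tsv", sep="\t")
        purifying = selection_signatures.rank_traits_by_purifying(
            cohort, p_cut=config.associated_p, top_n_grid=config.top_n_grid)
        purifying["scores"].to_csv(out / "purifying_scores.tsv", sep="\t", index=False)
        dos_results = {}
        for daf_min in config.daf_grid:
            dos_results[daf_min] = selection_signatures.dos_trait_ranking(
                cohort, p_cut=config.associated_p, daf_min=daf_min, top_n=config.top_n)
        dos_results[config.daf_grid[0]]["scores"].to_csv(
            out / "dos_scores.tsv", sep="\t", index=False)
        power_adj = selection_signatures.power_adjusted_enrichment(
            profiles, cohort.traits, top_n=config.top_n, span=config.loess_span)
        summary["selection"] = {
            "residual_sign_by_domain": (resid.groupby("domain")["mean_residual"].mean()
                                        if len(resid) else pd.Series(dtype=float)),
            "purifying_top_domain": {n: (_top_enriched(t) if len(t) else None)
                                     for n, t in purifying["enrichment"].items()},
            "dos_enrichment": {d: r["enrichment"] for d, r in dos_results.items()},
            "power_adjusted": {k: v for k, v in power_adj.items() if k != "residuals"},
        }
        manifest["stages"][stage] = {
            "n_resid_traits": len(resid),
            "dos_skipped": {d: len(r["skipped"]) for d, r in dos_results.items()},
        }

        # --- tissue enrichment --------------------------------------------
        stage = "tissue"
        t_counts = tissue_mod.enriched_tissue_counts(
            cohort, top_k=config.top_k, alpha=config.alpha,
            panel=config.tissue_panel, exclude=config.exclude_tissues)
        t_counts.to_csv(out / "tissue_counts.tsv", sep="\t")
        consistency = tissue_mod.cross_tissue_consistency(
            cohort, focus[0], top_k=config.top_k,
            panel=config.tissue_panel, exclude=config.exclude_tissues)
        summary["tissue"] = {
            "mean_enriched_tissues": float(t_counts["n_enriched_tissues"].mean()),
            "consistency_focus_trait": consistency,
        }
        manifest["stages"][stage] = {"n_traits": len(t_counts)}

        # --- bias audits ---------------------------------------------------
        stage = "bias"
        length_bias = bias_audit.gene_length_bias(cohort)
        length_bias["per_trait"].to_csv(out / "bias_length.tsv", sep="\t")
        ascert = bias_audit.ascertainment_audit(profiles)
        power = bias_audit.power_audit(profiles, cohort.traits)
        summary["bias"] = {
            "length_bias_top_domain": length_bias["per_domain"].index[0],
            "length_bias_per_domain": length_bias["per_domain"],
            "ascertainment": {k: v for k, v in ascert.items() if k != "per_domain"},
            "power": power,
        }
        manifest["stages"][stage] = {"done": True}

        # --- truth comparison (simulation only) ----------------------------
        if truth is not None:
            stage = "truth"
            planted = pd.Series(truth.trait_quadrant)
            recovered = profiles["quadrant"].reindex(planted.index)
            effects = pd.DataFrame(truth.trait_signs).T
            strong = (effects["a_exp"].abs() >= 0.1) & (effects["a_rate"].abs() >= 0.1)
            match = (recovered[strong] == planted[strong])
            summary["truth"] = {
                "quadrant_match_strong_effects": float(match.mean()) if strong.any() else None,
                "n_strong_effects": int(strong.sum()),
                "recovered_quadrants": recovered,
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "summary.json").write_text(json.dumps(_jsonable(summary), indent=1))
    (out / "manifest.json").write_text(json.dumps(_jsonable(manifest), indent=1))
    (out / "report.md").write_text(_render_report(summary))
    return summary


def _render_report(summary: dict) -> str:
    lines = ["# polyevo run report", ""]
    gc = summary.get("group_compare", {})
    for trait, s in gc.items():
        lines.append(f"- **{trait}**: KS D = {s['ks_D']:.3f} (p = {s['ks_p']:.2e}), "
                     f"{s['n_significant_tissues']} tissues significant "
                     f"(Bonferroni line at -log10 p = {s['bonferroni_line']:.2f})")
    cm = summary.get("correlation_map", {})
    if cm:
        shares = cm["quadrant_shares"]
        share_txt = ", ".join(f"{q}: {float(v):.0%}" for q, v in dict(shares).items())
        lines += ["", f"Significant traits: {cm['n_significant']}; quadrant shares {share_txt}."]
    rs = summary.get("resampling", {})
    if rs:
        tops = rs["top_domain_per_group"]
        lines += ["", "Most enriched domain per resampling group: "
                  + ", ".join(f"group {g}: {d}" for g, d in tops.items())]
    tr = summary.get("truth")
    if tr and tr.get("quadrant_match_strong_effects") is not None:
        lines += ["", f"Planted-quadrant recovery (|effects| >= 0.1): "
                  f"{tr['quadrant_match_strong_effects']:.0%} of {tr['n_strong_effects']} traits."]
    return "\n".join(lines) + "\n"
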