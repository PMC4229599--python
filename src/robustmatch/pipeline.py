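"""End-to-end orchestration: simulate/load -> phenotype -> preprocess -> DE ->
signature matching -> linkage, with a machine-readable run report.

Every stage writes its TSV output under the configured output directory and
contributes counts to the report; the report is reproducible bit-for-bit for
a fixed configuration and seed (all randomness flows from the single seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .diffexpr import de_all_factors, overlap_matrix
from .linkage import annotate_signature, find_linked_groups, groups_to_frame, read_gene_models
from .phenotype import (
    compute_robustness,
    correlate_profiles,
    growth_summaries,
    test_parameter_effect,
)
from .preprocess import preprocess_probes
from .signatures import (
    SelectionCriterion,
    build_signature,
    intersect_signatures,
    summarize_signs,
)
from .simulate import STRESSES, SimulationConfig, simulate_study, write_study

__all__ = ["PipelineConfig", "run_pipeline", "summarize_design_table"]

log = logging.getLogger("robustmatch")


@dataclass
class PipelineConfig:
    """Everything a run needs: either a simulation block or real input paths."""

    outdir: str | Path = "robustmatch_out"
    simulation: SimulationConfig | None = None
    design_path: str | None = None
    curves_path: str | None = None
    cfu_path: str | None = None
    probes_path: str | None = None
    gff_path: str | None = None
    alpha: float = 0.05
    product_cutoff: float = 5e-5
    lowess_span: float = 0.4
    mu_window: int = 4
    max_spacing: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        have_paths = all(p is not None
                         for p in (self.design_path, self.cfu_path, self.probes_path))
        if self.simulation is None and not have_paths:
            raise ValueError(
                "config needs either a simulation block or design/cfu/probes paths"
            )
        if not 0 < self.alpha <= 1 or not 0 < self.product_cutoff <= 1:
            raise ValueError("alpha and product_cutoff must lie in (0, 1]")
        if self.lowess_span <= 0 or self.lowess_span > 1:
            raise ValueError("lowess_span must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        if sim is not None:
            if "probes_per_gene" in sim:
                sim["probes_per_gene"] = tuple(sim["probes_per_gene"])
            if "factor_levels" in sim:
                sim["factor_levels"] = {k: tuple(v) for k, v in sim["factor_levels"].items()}
            sim = SimulationConfig(**sim)
        return cls(simulation=sim, **raw)

    def digest(self) -> str:
        payload = dataclasses.asdict(self)
        if self.simulation is not None:
            payload["simulation"] = dataclasses.asdict(self.simulation)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def summarize_design_table(table: pd.DataFrame,
                           columns: tuple[str, str] = ("od_final", "mu_max")) -> dict:
    """Column extrema of a design+growth table with the attaining fermentations."""
    if table.empty:
        raise ValueError("empty table")
    out = {}
    for col in columns:
        if col not in table.columns:
            raise KeyError(f"missing column {col!r}")
        vals = table[col].astype(float)
        out[col] = {
            "min": float(vals.min()),
            "min_fermentation": int(table.loc[vals.idxmin(), "fermentation_id"]),
            "max": float(vals.max()),
            "max_fermentation": int(table.loc[vals.idxmax(), "fermentation_id"]),
        }
    return out


def _phenotype_effects(design: pd.DataFrame, summaries: pd.DataFrame,
                       profile: pd.DataFrame) -> pd.DataFrame:
    """Welch t-tests of every factor level pair on every phenotype."""
    phenos: dict[str, pd.Series] = {}
    if summaries is not None and not summaries.empty:
        s = summaries.set_index("fermentation_id")
        phenos["mu_max"] = s["mu_max"]
        phenos["od_final"] = s["od_final"]
    for stress in STRESSES:
        for t in (30, 60):
            sub = profile[(profile["stress"] == stress) & (profile["time_min"] == t)]
            phenos[f"robustness_{stress}_{t}"] = (
                sub.set_index("fermentation_id")["robustness_log10"].dropna()
            )
    rows = []
    factors = [c for c in design.columns if c != "fermentation_id"]
    for name, values in phenos.items():
        for factor in factors:
            levels = sorted(design[factor].unique(), key=str)
            for la, lb in itertools.combinations(levels, 2):
                eff = test_parameter_effect(design, values, factor, la, lb)
                rows.append({
                    "phenotype": name, "factor": factor,
                    "level_a": la, "level_b": lb,
                    "t_statistic": eff.t_statistic, "p_value": eff.p_value,
                    "direction": eff.direction, "significant": eff.significant,
                })
    return pd.DataFrame(rows)


def _profile_correlations(profile: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for stress in STRESSES:
        sub = profile[profile["stress"] == stress]
        wide = sub.pivot(index="fermentation_id", columns="time_min",
                         values="robustness_log10").dropna()
        if {30, 60} <= set(wide.columns) and len(wide) >= 3:
            r, p = correlate_profiles(wide[30], wide[60])
            rows.append({"stress": stress, "comparison": "30_vs_60",
                         "pearson_r": r, "p_value": p})
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the run report (also written as JSON)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "version": __version__,
            "seed": config.seed,
            "config_digest": config.digest(),
        },
        "stages": {},
    }

    truth = None
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        study = simulate_study(sim)
        write_study(study, outdir / "simulated_inputs")
        design, curves, cfu, probes = study.design, study.growth, study.cfu, study.probes
        truth = study.truth
        log.info("simulate: %d fermentations, %d probe rows", len(design), len(probes))
    else:
        design = pd.read_csv(config.design_path, sep="\t", dtype={"aeration": str})
        cfu = pd.read_csv(config.cfu_path, sep="\t")
        probes = pd.read_csv(config.probes_path, sep="\t")
        curves = (pd.read_csv(config.curves_path, sep="\t")
                  if config.curves_path else None)
    report["stages"]["inputs"] = {
        "n_fermentations": int(len(design)),
        "n_probe_rows": int(len(probes)),
        "n_cfu_rows": int(len(cfu)),
    }

    summaries = (growth_summaries(curves, window=config.mu_window)
                 if curves is not None else pd.DataFrame())
    if not summaries.empty:
        summaries.to_csv(outdir / "growth_summary.tsv", sep="\t", index=False)
    profile = compute_robustness(cfu)
    profile.to_csv(outdir / "robustness.tsv", sep="\t", index=False)
    effects = _phenotype_effects(design, summaries, profile)
    effects.to_csv(outdir / "parameter_effects.tsv", sep="\t", index=False)
    prof_corr = _profile_correlations(profile)
    prof_corr.to_csv(outdir / "profile_correlations.tsv", sep="\t", index=False)
    report["stages"]["phenotype"] = {
        "n_robustness_rows": int(len(profile)),
        "n_significant_effects": int(effects["significant"].sum()),
    }
    log.info("phenotype: %d effect tests, %d significant",
             len(effects), int(effects["significant"].sum()))

    expr = preprocess_probes(probes, span=config.lowess_span)
    expr.to_csv(outdir / "expression_matrix.tsv", sep="\t")
    report["stages"]["preprocess"] = {
        "n_orfs": int(expr.shape[0]), "n_arrays": int(expr.shape[1]),
    }
    log.info("preprocess: %d ORFs x %d arrays", *expr.shape)

    de_results = de_all_factors(expr, design, alpha=config.alpha)
    de_long = pd.concat([
        pd.DataFrame({
            "factor": r.factor, "level_a": r.level_a, "level_b": r.level_b,
            "gene": r.p_values.index, "p": r.p_values.to_numpy(),
            "is_de": [g in r.de_set for g in r.p_values.index],
        }) for r in de_results
    ], ignore_index=True)
    de_long.to_csv(outdir / "de_genes.tsv", sep="\t", index=False)
    counts, pct = overlap_matrix(de_results)
    counts.to_csv(outdir / "de_overlap_counts.tsv", sep="\t")
    pct.to_csv(outdir / "de_overlap_pct.tsv", sep="\t")
    report["stages"]["differential_expression"] = {
        r.label: len(r.de_set) for r in de_results
    }
    log.info("de: %s", report["stages"]["differential_expression"])

    crit = SelectionCriterion(alpha=config.alpha,
                              product_cutoff=config.product_cutoff)
    sigs = {}
    sig_report = {}
    for stress in STRESSES:
        sig = build_signature(expr, profile, stress, crit)
        sigs[stress] = sig
        sig.table.to_csv(outdir / f"signature_{stress}.tsv", sep="\t", index=False)
        pos, neg = summarize_signs(sig)
        sig_report[stress] = {"n_genes": len(sig), "n_positive": pos, "n_negative": neg}
        if truth is not None:
            planted = truth.planted_ids(stress)
            hit = planted & set(sig.gene_ids)
            sig_report[stress]["recovered_planted"] = len(hit)
            sig_report[stress]["n_planted"] = len(planted)
            sig_report[stress]["false_positives"] = len(sig) - len(hit)
    cross = intersect_signatures(sigs["heat"], sigs["oxidative"])
    cross.to_csv(outdir / "signature_cross_stress.tsv", sep="\t", index=False)
    sig_report["cross_stress_n"] = int(len(cross))
    report["stages"]["signatures"] = sig_report
    log.info("signatures: %s", sig_report)

    if config.gff_path:
        genes = read_gene_models(config.gff_path)
        groups = find_linked_groups(genes, max_spacing=config.max_spacing)
        groups_to_frame(groups).to_csv(outdir / "linkage_groups.tsv",
                                       sep="\t", index=False)
        ann = pd.concat([
            annotate_signature(sigs[s], groups).assign(stress=s) for s in STRESSES
        ], ignore_index=True)
        ann.to_csv(outdir / "signature_linkage.tsv", sep="\t", index=False)
        report["stages"]["linkage"] = {
            "n_groups": len(groups),
            "n_annotated": int(ann["in_annotation"].sum()),
        }

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
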