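"""End-to-end orchestration of the matched-pair analysis.

Stage order: read -> diversity on the UNFILTERED table -> rare-taxon
filter -> zero replacement -> CLR -> PCA -> component selection ->
nearest-neighbor matching -> paired differential abundance -> group-wise
dispersion diagnostic -> effect size & power -> biomarker association.
Diversity deliberately precedes filtering: rare taxa count toward
Shannon and Bray-Curtis but are discarded before everything else.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .biomarkers import (
    BiomarkerPanel,
    classify_calprotectin,
    kendall_matrix,
    rda_rank,
    screen_blood_biomarkers,
    taxon_biomarker_glm,
)
from .diversity import compare_group_diversity, diversity, pca, select_components
from .groupwise import dirichlet_instances, effect_analysis
from .io import read_metadata, read_profile_table
from .matching import match_nearest_neighbor, paired_da
from .power import cohens_d, min_total_n, power_curve
from .preprocess import FilterRule, clr_transform, filter_rare_taxa, filter_report, replace_zeros
from .tables import CALPROTECTIN

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("micropair")


@dataclass
class PipelineConfig:
    """Everything a full run needs; mirrors the YAML config."""

    profile_path: str
    metadata_path: str
    out_dir: str = "micropair_out"
    value_scale: str = "auto"
    max_prevalence: int = 3
    min_abundance: float = 1e-4
    delta: float | str = "auto"
    target_cum_evr: float = 0.70
    da_p_threshold: float = 0.05
    fdr: float = 0.10
    calprotectin_threshold: float = 35.0
    power_alpha: float = 0.05
    power_d: float = 0.37
    power_target: float = 0.8
    power_grid: tuple[int, int] = (10, 400)
    groupwise_n_mc: int = 16
    groupwise_depth: int = 100_000
    run_biomarkers: bool = True
    seed: int = 0

    def validate(self) -> None:
        for name, lo, hi in (
            ("target_cum_evr", 0.0, 1.0),
            ("da_p_threshold", 0.0, 1.0),
            ("fdr", 0.0, 1.0),
            ("power_alpha", 0.0, 1.0),
            ("power_target", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not (lo < v <= hi):
                raise ValueError(f"{name}={v} outside ({lo}, {hi}]")
        for p in (self.profile_path, self.metadata_path):
            if not Path(p).exists():
                raise FileNotFoundError(p)

    def analysis_parameters(self) -> dict:
        """Everything that determines the results (output location excluded)."""
        params = asdict(self)
        params.pop("out_dir")
        return params

    def config_hash(self) -> str:
        payload = json.dumps(self.analysis_parameters(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _log(stage: str, msg: str) -> None:
    logger.info("[%s] %s", stage, msg)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write a report bundle under ``config.out_dir``.

    Returns the in-memory report dict; identical config and seed give an
    identical bundle.  Any stage failure aborts with the stage named.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "parameters": config.analysis_parameters(),
    }

    stage = "read"
    try:
        table = read_profile_table(config.profile_path, value_scale=config.value_scale)
        meta = read_metadata(config.metadata_path)
        meta.check_alignment(table)
        _log(stage, f"{table.n_samples} samples x {table.n_taxa} taxa; "
                    f"{len(meta.cases)} cases / {len(meta.controls)} controls")

        stage = "diversity"  # on the UNFILTERED table
        div = diversity(table)
        div_cmp = compare_group_diversity(div, meta)
        pd.DataFrame({"shannon": div.shannon, "group": meta.groups}).to_csv(
            out / "diversity.tsv", sep="\t", float_format="%.10g")
        report["diversity"] = div_cmp
        _log(stage, f"alpha KS p={div_cmp['alpha']['p']:.3g}, "
                    f"beta KS p={div_cmp['beta']['p']:.3g}")

        stage = "filter"
        rule = FilterRule(config.max_prevalence, config.min_abundance)
        filter_report(table, rule).to_csv(out / "filter_report.tsv", sep="\t",
                                          float_format="%.10g")
        filtered, removed = filter_rare_taxa(table, rule)
        report["filter"] = {"n_input": table.n_taxa, "n_removed": len(removed),
                            "n_kept": filtered.n_taxa}
        _log(stage, f"{table.n_taxa} -> {filtered.n_taxa} taxa "
                    f"({len(removed)} removed)")

        stage = "clr"
        clr = clr_transform(replace_zeros(filtered, config.delta))

        stage = "pca"
        ordn = pca(clr)
        k = select_components(ordn, config.target_cum_evr)
        ordn.scores.to_csv(out / "pca_scores.tsv", sep="\t", float_format="%.10g")
        ordn.loadings.to_csv(out / "pca_loadings.tsv", sep="\t", float_format="%.10g")
        report["pca"] = {"k_selected": k, "cum_evr_at_k": ordn.cum_evr_at_k,
                         "evr_first_two": float(ordn.evr[:2].sum())}
        _log(stage, f"k={k} components capture {ordn.cum_evr_at_k:.1%}")

        stage = "match"
        pairs = match_nearest_neighbor(ordn.selected_scores(), meta)
        pairs.to_frame().to_csv(out / "pairs.tsv", sep="\t", index=False,
                                float_format="%.10g")
        report["matching"] = {"n_pairs": pairs.n_pairs,
                              "n_unmatched_cases": len(pairs.unmatched_cases),
                              "k_components": pairs.k_components}
        _log(stage, f"{pairs.n_pairs} pairs, {len(pairs.unmatched_cases)} unmatched cases")

        stage = "paired-da"
        da = paired_da(filtered, pairs, report_p=config.da_p_threshold)
        da.to_csv(out / "paired_da.tsv", sep="\t", float_format="%.10g")
        n_hits = int((da["p"] <= config.da_p_threshold).sum())
        hits = da[da["p"] <= config.da_p_threshold]
        report["paired_da"] = {
            "n_taxa_tested": int((~da["degenerate"]).sum()),
            "n_hits_at_p": n_hits,
            "n_case_enriched": int((hits["direction"] == "case-enriched").sum()),
            "n_control_enriched": int((hits["direction"] == "control-enriched").sum()),
        }
        _log(stage, f"{n_hits} taxa at p<={config.da_p_threshold}")

        stage = "groupwise-da"
        instances = dirichlet_instances(filtered, depth=config.groupwise_depth,
                                        n_mc=config.groupwise_n_mc, seed=config.seed)
        effects = effect_analysis(instances, meta)
        effects.to_csv(out / "groupwise_effects.tsv", sep="\t", float_format="%.10g")
        report["groupwise"] = {
            "n_exceeding_dispersion": int(effects["exceeds_dispersion"].sum())}
        _log(stage, f"{report['groupwise']['n_exceeding_dispersion']} taxa exceed dispersion")

        stage = "power"
        h = diversity(filtered).shannon
        d_obs = cohens_d(h.loc[meta.cases], h.loc[meta.controls],
                         summary_metric="shannon")
        curve = power_curve(config.power_d, config.power_alpha,
                            np.arange(config.power_grid[0], config.power_grid[1] + 1, 2))
        pd.DataFrame({"N_total": curve.grid, "power": curve.power}).to_csv(
            out / "power_curve.tsv", sep="\t", index=False, float_format="%.10g")
        n_min = min_total_n(config.power_d, config.power_alpha, config.power_target)
        report["power"] = {"d_assumed": config.power_d, "d_observed_shannon": d_obs.d,
                           "min_total_n": n_min}
        _log(stage, f"min total N for d={config.power_d}: {n_min}")

        if config.run_biomarkers and CALPROTECTIN in meta.biomarker_columns:
            stage = "biomarkers"
            panel = BiomarkerPanel.from_metadata(meta, config.calprotectin_threshold)
            flags = classify_calprotectin(panel)
            candidates = list(hits.index) if n_hits else list(da.nsmallest(14, "p").index)
            assoc = taxon_biomarker_glm(filtered, panel, meta, candidates,
                                        biomarkers=[CALPROTECTIN], fdr=config.fdr)
            assoc.to_csv(out / "biomarker_assoc.tsv", sep="\t", index=False,
                         float_format="%.10g")
            kendall = kendall_matrix(filtered, panel, candidates)
            kendall.to_csv(out / "kendall_tau.tsv", sep="\t", float_format="%.10g")
            covariate = np.log(panel.frame[CALPROTECTIN].where(
                panel.frame[CALPROTECTIN] > 0))
            rda = rda_rank(clr, covariate)
            rda.ranking.to_csv(out / "rda_ranking.tsv", sep="\t", float_format="%.10g")
            screen = screen_blood_biomarkers(panel, meta)
            screen.to_csv(out / "blood_screen.tsv", sep="\t", index=False,
                          float_format="%.10g")
            n_sig = int(assoc["significant_at_10pct_fdr"].sum())
            report["biomarkers"] = {
                "n_elevated_cases": int(flags.reindex(meta.cases).sum()),
                "n_elevated_controls": int(flags.reindex(meta.controls).sum()),
                "n_candidates": len(candidates),
                "n_significant_assoc": n_sig,
                "rda_top5": rda.top(5),
                "rda_constrained_fraction": rda.constrained_variance_fraction,
            }
            _log(stage, f"{n_sig} significant taxon-calprotectin associations")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True,
                                                default=str))
    _log("done", f"report bundle written to {out}")
    return report
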