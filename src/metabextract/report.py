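"""End-to-end evaluation: per-method metrics and the ordinal decision matrix.

Each extraction group gets three metrics -- mean detected-feature count, mean
normalized target-panel (MoInt) area, and mean panel CV -- expressed as a
ratio to the cross-group median and binned into ordinal arrows.  Thresholds
are documented and configurable; a value exactly on a band edge falls into
the lower band.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import qc_correction, targeted_eval, univariate_stats
from .feature_io import (STUDY_GROUPS, FeatureTable, read_feature_table,
                         read_registry, load_pathways, write_feature_table)
from .pathway_enrichment import analyze_pathways
from .pcdfa import fit_pcdfa, mccv, select_features_anova
from .synthetic_data import SimulationConfig, simulate
from .targeted_eval import PanelSummary, match_compounds, summarize_compounds
from .univariate_stats import (DetectionRule, FeatureCountResult, anova_matrix,
                               bonferroni, count_detected_features,
                               significance_category)

__all__ = ["MethodScorecard", "build_scorecards", "PipelineConfig",
           "ReportBundle", "run_pipeline", "ARROW_BANDS"]

logger = logging.getLogger(__name__)

#: Upper edges (inclusive, tie goes to the lower band) of the ratio-to-median
#: bands for the five arrows.
ARROW_BANDS: tuple[tuple[float, str], ...] = (
    (0.5, "↘↘"),   # strongly below median
    (0.9, "↘"),
    (1.1, "→"),
    (2.0, "↗"),
    (float("inf"), "↗↗"),
)


def _arrow(ratio: float) -> str:
    if np.isnan(ratio):
        return "?"
    for edge, arrow in ARROW_BANDS:
        if ratio <= edge:
            return arrow
    return ARROW_BANDS[-1][1]  # pragma: no cover


@dataclass
class MethodScorecard:
    group: str
    feature_count: float
    moint_area: float
    moint_cv: float
    ratios: dict[str, float]
    arrows: dict[str, str]


def build_scorecards(feature_counts: FeatureCountResult | Mapping[str, float],
                     panel: PanelSummary, reference: str = "I",
                     groups: Sequence[str] = STUDY_GROUPS) -> list[MethodScorecard]:
    """Assemble the per-method ordinal decision matrix.

    ``feature_counts`` may be the full counting result or a plain
    group -> mean-count mapping.  All requested groups (including the
    reference) must be present in every metric.
    """
    if isinstance(feature_counts, FeatureCountResult):
        counts = {g: float(v) for g, v in feature_counts.group_mean.items()}
    else:
        counts = {g: float(v) for g, v in feature_counts.items()}
    metrics = {
        "feature_count": counts,
        "moint_area": panel.mean_of_means,
        "moint_cv": panel.mean_cv_pct,
    }
    wanted = list(groups)
    if reference not in wanted:
        wanted = [reference] + wanted
    missing = sorted({g for m in metrics.values() for g in wanted if g not in m
                      or np.isnan(m[g])})
    if missing:
        raise ValueError(f"metrics missing for group(s): {missing}")
    medians = {name: float(np.median([vals[g] for g in wanted]))
               for name, vals in metrics.items()}
    cards = []
    for g in wanted:
        ratios = {name: (vals[g] / medians[name] if medians[name] > 0 else float("nan"))
                  for name, vals in metrics.items()}
        cards.append(MethodScorecard(
            group=g,
            feature_count=metrics["feature_count"][g],
            moint_area=metrics["moint_area"][g],
            moint_cv=metrics["moint_cv"][g],
            ratios=ratios,
            arrows={name: _arrow(r) for name, r in ratios.items()},
        ))
    return cards


def scorecards_frame(cards: Sequence[MethodScorecard]) -> pd.DataFrame:
    rows = []
    for c in cards:
        row = {"group": c.group, "feature_count": c.feature_count,
               "moint_area": c.moint_area, "moint_cv": c.moint_cv}
        for name in ("feature_count", "moint_area", "moint_cv"):
            row[f"{name}_ratio"] = c.ratios[name]
            row[f"{name}_arrow"] = c.arrows[name]
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


# -- pipeline ----------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Parameters for the umbrella run; everything is logged as provenance."""

    out_dir: str | Path = "results"
    seed: int = 0
    # input: either paths to an existing table or a simulation config
    areas_path: str | Path | None = None
    samples_path: str | Path | None = None
    simulation: SimulationConfig | None = None
    registry_path: str | Path | None = None   # None -> bundled registry
    pathways_path: str | Path | None = None   # None -> bundled pathway set
    skip_correction: bool = False
    correction_method: str = "auto"
    alpha: float = 0.05
    reference: str = "I"
    mz_tol_ppm: float = targeted_eval.DEFAULT_MZ_TOL_PPM
    rt_tol_s: float = targeted_eval.DEFAULT_RT_TOL_S
    mccv_iterations: int = 300
    mccv_test_fraction: float = 0.3
    detection_min_area: float = 0.0


@dataclass
class ReportBundle:
    table: FeatureTable
    feature_counts: FeatureCountResult
    anova_results: pd.DataFrame
    compound_summaries: list
    panel: PanelSummary
    selected_features: list[str]
    pcdfa_model: object
    mccv_result: object
    pathway_results: list
    scorecards: list[MethodScorecard]
    provenance: dict


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    return wrap


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute correct -> stats -> targeted -> pcdfa -> pathways -> scorecards.

    Intermediate CSVs and a provenance record are written to
    ``config.out_dir``.  Any stage error aborts with the stage name and cause.
    Outputs are deterministic for a fixed seed (no timestamps).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from .data import pathways_path as bundled_pathways
    from .data import registry_path as bundled_registry

    # load / simulate
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        table, _truth = _stage("simulate")(simulate, sim)
    elif config.areas_path and config.samples_path:
        table = _stage("load")(read_feature_table, config.areas_path, config.samples_path)
    else:
        raise RuntimeError("pipeline stage 'load' failed: no input configured")

    # QC correction
    if config.skip_correction:
        fits = []
    else:
        table, fits = _stage("correct")(qc_correction.correct_table, table,
                                        config.correction_method)
        qc_correction.drift_report(fits).to_csv(out / "drift_report.csv")
    write_feature_table(table, out / "corrected_areas.csv", out / "corrected_samples.csv")

    # feature counts + per-feature ANOVA
    rule = DetectionRule(min_area=config.detection_min_area)
    counts = _stage("stats")(count_detected_features, table, rule)
    counts.per_sample.to_frame().assign(
        group=table.samples.loc[counts.per_sample.index, "group"]
    ).to_csv(out / "feature_counts.csv")

    study = table.study_sample_ids
    labels = table.samples.loc[study, "group"].to_numpy()
    f, p = anova_matrix(table.areas[study].to_numpy(dtype=float).T, labels)
    tested = ~np.isnan(p)
    p_adj = np.full_like(p, np.nan)
    if tested.any():
        p_adj[tested] = bonferroni(p[tested], int(tested.sum()))
    anova_df = pd.DataFrame({
        "unit_id": table.feature_ids, "contrast": "ANOVA:groups",
        "statistic": f, "p_raw": p, "p_adj": p_adj,
        "category": [significance_category(v) if not np.isnan(v) else "ns"
                     for v in p_adj],
    }).set_index("unit_id")
    anova_df.to_csv(out / "anova_results.csv")

    # targeted evaluation
    registry = _stage("targeted")(read_registry,
                                  config.registry_path or bundled_registry())
    matches, unmatched = _stage("targeted")(match_compounds, table, registry,
                                            config.mz_tol_ppm, config.rt_tol_s)
    summaries, panel = _stage("targeted")(summarize_compounds, table, registry,
                                          matches, config.reference)
    rows = []
    for s in summaries:
        for g in sorted(s.mean_norm):
            rows.append({"compound": s.compound, "group": g,
                         "mean_norm": s.mean_norm[g], "sd_norm": s.sd_norm[g],
                         "cv_pct": s.cv_pct[g]})
    pd.DataFrame(rows).to_csv(out / "targeted_summary.csv", index=False)
    pd.DataFrame({
        "group": list(panel.mean_of_means),
        "mean_of_means": list(panel.mean_of_means.values()),
        "sd_of_means": list(panel.sd_of_means.values()),
        "mean_cv_pct": list(panel.mean_cv_pct.values()),
    }).to_csv(out / "targeted_aggregate.csv", index=False)

    # PC-DFA
    selected = _stage("pcdfa")(select_features_anova, table, config.alpha)
    model = None
    cv_res = None
    if len(selected) >= 2:
        mat = table.areas.loc[selected, study].to_numpy(dtype=float).T
        mat = np.nan_to_num(mat, nan=0.0)  # undetected -> 0 signal for projection
        model = _stage("pcdfa")(fit_pcdfa, mat, labels)
        cv_res = _stage("pcdfa")(mccv, mat, labels, config.mccv_iterations,
                                 config.mccv_test_fraction, config.seed)
        pd.DataFrame(model.df_scores[:, :2], index=pd.Index(study, name="sample_id"),
                     columns=["DF1", "DF2"][: model.df_scores.shape[1]]) \
            .assign(group=labels).to_csv(out / "pcdfa_scores.csv")
        cv_res.confusion.to_csv(out / "pcdfa_confusion.csv")
        (out / "pcdfa_summary.json").write_text(json.dumps({
            "n_selected_features": len(selected),
            "n_components": model.n_components,
            "mean_accuracy": cv_res.mean_accuracy,
            "kappa": cv_res.kappa,
            "n_iterations": cv_res.n_iterations,
        }, indent=2))
    else:
        logger.warning("fewer than 2 significant features; PC-DFA skipped")

    # pathway analysis on KEGG ids of matched MoInt
    library = _stage("pathways")(load_pathways,
                                 config.pathways_path or bundled_pathways())
    matched_names = {m.compound for m in matches}
    kegg_query = sorted({r.kegg_id for r in registry.moint()
                         if r.kegg_id and r.name in matched_names})
    pathway_results = _stage("pathways")(analyze_pathways, kegg_query, library)
    pd.DataFrame([dataclasses.asdict(r) for r in pathway_results]) \
        .to_csv(out / "pathway_results.csv", index=False)

    # decision matrix
    present = table.study_groups_present
    cards = _stage("report")(build_scorecards, counts, panel, config.reference, present)
    scorecards_frame(cards).to_csv(out / "scorecards.csv")

    provenance = {
        "seed": config.seed,
        "skip_correction": config.skip_correction,
        "correction_method": config.correction_method,
        "alpha": config.alpha,
        "reference": config.reference,
        "mz_tol_ppm": config.mz_tol_ppm,
        "rt_tol_s": config.rt_tol_s,
        "mccv_iterations": config.mccv_iterations,
        "mccv_test_fraction": config.mccv_test_fraction,
        "detection_min_area": config.detection_min_area,
        "n_features": table.n_features,
        "n_samples": table.n_samples,
        "n_selected_features": len(selected),
        "n_matched_compounds": len(matches),
        "n_unmatched_compounds": len(unmatched),
        "arrow_bands": [[e, a] for e, a in ARROW_BANDS[:-1]] + [["inf", ARROW_BANDS[-1][1]]],
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))
    return ReportBundle(table, counts, anova_df, summaries, panel, selected,
                        model, cv_res, pathway_results, cards, provenance)
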