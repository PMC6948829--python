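"""End-to-end orchestration: cohort -> preprocess -> factors -> models -> networks.

One YAML config and one root seed drive the whole analysis; the root seed
deterministically spawns per-stage sub-seeds so any stage can be re-run in
isolation and reproduce the same numbers.  The report is machine-readable
JSON first; every number in it comes from a serialized stage output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort_model import (
    GROUPS,
    VISITS,
    AnalysisConfig,
    CohortTable,
    default_registry,
    load_cohort,
    start_run_log,
    write_cohort,
    write_results,
    _jsonable,
)
from .factor_reduction import fit_factor_model, score_subjects
from .network_analysis import (
    binarize_top,
    correlation_matrix,
    louvain_modularity,
    make_clustering_delta_stat,
    make_modularity_delta_stat,
    mean_clustering,
    mean_delta_r,
    permute_between_group,
    permute_within_subject,
    stat_mean_delta_r,
)
from .outcome_models import apply_model, stepwise_with_outliers
from .preprocess import harmonize, pain_trajectories
from .synthetic_cohort import SyntheticSpec, generate_cohort

logger = logging.getLogger("painnet")

COVARIATES = ["age", "gender", "education", "bmi", "pain_duration", "kl_grade"]


@dataclass
class RunReport:
    config: dict
    seed: int
    pain_summary: dict = field(default_factory=dict)
    trajectories: dict = field(default_factory=dict)
    factor_model: dict = field(default_factory=dict)
    stepwise_models: dict = field(default_factory=dict)
    hoa_models: dict = field(default_factory=dict)
    networks: dict = field(default_factory=dict)
    comparisons: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        import dataclasses

        return dataclasses.asdict(self)


def _load_config(config_path) -> dict:
    with open(config_path) as fh:
        return yaml.safe_load(fh) or {}


def _resolve_cohort(doc: dict, seed: int,
                    force_seed: bool = False) -> tuple[CohortTable, object]:
    registry = default_registry()
    if doc.get("cohort_csv"):
        return load_cohort(doc["cohort_csv"], registry), None
    if "synthetic" in doc:
        spec_kw = dict(doc["synthetic"] or {})
        if force_seed:
            spec_kw["rng_seed"] = seed
        else:
            spec_kw.setdefault("rng_seed", seed)
        cohort, truth = generate_cohort(SyntheticSpec(**spec_kw), registry)
        return cohort, truth
    raise ValueError("config provides neither 'cohort_csv' nor a 'synthetic' section")


def run_full_analysis(config_path, seed: int | None = None,
                      out_dir=None) -> RunReport:
    """Execute every stage from one config; deterministic given config + seed."""
    doc = _load_config(config_path)
    config = AnalysisConfig(**(doc.get("analysis") or {}))
    if seed is not None:
        config.rng_seed = seed
    root = np.random.SeedSequence(config.rng_seed)
    stage_seed = {name: int(s.generate_state(1)[0] % (2 ** 31))
                  for name, s in zip(
                      ("cohort", "louvain", "permutation"), root.spawn(3))}

    out_dir = Path(out_dir) if out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        start_run_log(out_dir / "run.log", config)

    cohort, truth = _resolve_cohort(doc, stage_seed["cohort"],
                                    force_seed=seed is not None)
    registry = cohort.registry
    report = RunReport(config=config.to_dict(), seed=config.rng_seed)

    # --- pain outcome summary (published-table layout) and trajectories ----
    traj = pain_trajectories(cohort, config)
    pain_harm = harmonize(cohort, config, measure_ids=registry.pain_outcome_ids)
    summary: dict = {}
    for group in GROUPS:
        summary[group] = {}
        for visit in VISITS:
            mat = pain_harm.matrix(visit)
            mat = mat.loc[[s for s in mat.index if cohort.group_of()[s] == group]]
            summary[group][visit] = {
                "n": int(len(mat)),
                "mean": mat.mean().round(10).to_dict(),
                "sd": mat.std(ddof=1).round(10).to_dict(),
                "correlations": mat.corr().round(10).to_dict(),
            }
    report.pain_summary = summary
    tab = traj.table
    report.trajectories = {
        "mean_residual_m3": tab.groupby(["group", "scale"])["residual_m3"]
                               .mean().unstack().to_dict(),
        "mean_residual_m6": tab.groupby(["group", "scale"])["residual_m6"]
                               .mean().unstack().to_dict(),
    }

    # --- factor reduction on the knee arm at baseline ----------------------
    harm = harmonize(cohort, config, measure_ids=registry.network_ids)
    group_of = cohort.group_of()
    base = harm.matrix("baseline")
    koa_base = base.loc[[s for s in base.index if group_of[s] == "KOA"]]
    model = fit_factor_model(koa_base, config, community_labels=registry.communities)
    report.factor_model = {
        "retained_k": model.retained_k,
        "kmo_overall": model.kmo_overall,
        "variance_explained_pct": float(model.variance_explained[:model.retained_k].sum()),
        "component_labels": model.component_labels,
        "membership": model.membership,
        "multi_loading": model.multi_loading,
    }

    # --- stepwise outcome models (knee arm), re-tested on the hip arm ------
    scores_by_visit = {v: score_subjects(model, harm.matrix(v)) for v in VISITS}
    X_all = scores_by_visit["baseline"].join(cohort.covariates[
        [c for c in COVARIATES if c in cohort.covariates.columns]], how="left")
    ttab = traj.table.set_index(["subject_id", "scale"])
    scales = registry.pain_outcome_ids + ["aggregate"]
    stepwise, hoa_models = {}, {}
    for scale in scales:
        for kind, col in (("pain_m6", "post6"), ("residual_m6", "residual_m6"),
                          ("pain_baseline", "pre")):
            y = ttab.xs(scale, level="scale")[col].dropna()
            for grp, store in (("KOA", stepwise),):
                ids = [s for s in y.index if group_of.get(s) == grp and s in X_all.index]
                Xg = X_all.loc[ids].dropna()
                yg = y.loc[Xg.index]
                fit = stepwise_with_outliers(Xg, yg, config, outcome=f"{scale}:{kind}")
                store[f"{scale}:{kind}"] = fit
            koa_fit = stepwise[f"{scale}:{kind}"]
            if koa_fit.predictors:
                ids = [s for s in y.index if group_of.get(s) == "HOA" and s in X_all.index]
                Xg = X_all.loc[ids].dropna()
                if len(Xg) > len(koa_fit.predictors) + 2:
                    hoa_models[f"{scale}:{kind}"] = apply_model(
                        koa_fit.predictors, Xg, y.loc[Xg.index],
                        outcome=f"HOA:{scale}:{kind}")
    report.stepwise_models = {k: v.to_dict() for k, v in stepwise.items()}
    report.hoa_models = {k: v.to_dict() for k, v in hoa_models.items()}

    # --- networks per group x visit ----------------------------------------
    nets, corrs = {}, {}
    for group in GROUPS:
        for visit in VISITS:
            mat = harm.matrix(visit)
            mat = mat.loc[[s for s in mat.index if group_of[s] == group]]
            corr = correlation_matrix(mat, group=group, visit=visit)
            net = binarize_top(corr, config.binarize_fraction, model.membership)
            metrics = louvain_modularity(net, reps=config.louvain_reps,
                                         seed=stage_seed["louvain"])
            corrs[(group, visit)] = (mat, corr)
            nets[(group, visit)] = (net, metrics)
            report.networks[f"{group}:{visit}"] = {
                "edges": net.edge_count,
                "mean_clustering": metrics.mean_clustering,
                "modularity_mean": metrics.modularity_mean,
                "modularity_sd": metrics.modularity_sd,
            }
            if out_dir:
                write_results(net, out_dir / f"network_{group}_{visit}.graphml")
                write_results(net, out_dir / f"network_{group}_{visit}.edges")

    # --- change statistics with permutation inference ----------------------
    reps = config.permutation_reps
    cc_stat = make_clustering_delta_stat(config.binarize_fraction)
    comparisons: dict = {}
    for group in GROUPS:
        for visit_a, visit_b in (("baseline", "m3"), ("baseline", "m6"), ("m3", "m6")):
            mat_a, corr_a = corrs[(group, visit_a)]
            mat_b, corr_b = corrs[(group, visit_b)]
            comp = mean_delta_r(corr_a, corr_b)
            net_a, met_a = nets[(group, visit_a)]
            net_b, met_b = nets[(group, visit_b)]
            comp.delta_clustering = met_b.mean_clustering - met_a.mean_clustering
            comp.delta_modularity = met_b.modularity_mean - met_a.modularity_mean
            key = f"{group}:{visit_a}->{visit_b}"
            q_stat = make_modularity_delta_stat(
                config.binarize_fraction, louvain_reps=3, seed=stage_seed["louvain"])
            comp.permutation_results = {
                "mean_delta_r": permute_within_subject(
                    mat_a, mat_b, stat_mean_delta_r, reps, stage_seed["permutation"]),
                "clustering_delta": permute_within_subject(
                    mat_a, mat_b, cc_stat, reps, stage_seed["permutation"] + 1),
                "modularity_delta": permute_within_subject(
                    mat_a, mat_b, q_stat, reps, stage_seed["permutation"] + 2),
            }
            comparisons[key] = comp
            if out_dir:
                comp.delta_r.to_csv(out_dir / f"delta_r_{group}_{visit_a}_{visit_b}.csv")
    # between-group contrast of mean delta-r at each post-surgery visit
    for visit in ("m3", "m6"):
        pre = pd.concat([corrs[(g, "baseline")][0] for g in GROUPS])
        post = pd.concat([corrs[(g, visit)][0] for g in GROUPS])
        res = permute_between_group(pre, post, group_of, stat_mean_delta_r,
                                    reps, stage_seed["permutation"] + 3)
        comparisons[f"between_group:{visit}"] = res
    report.comparisons = {
        k: (v.to_dict() if hasattr(v, "to_dict") else v) for k, v in comparisons.items()
    }

    # --- persist ------------------------------------------------------------
    if out_dir:
        from .viz import plot_loading_heatmap, plot_scree

        write_cohort(cohort, out_dir / "cohort.csv")
        write_results(model, out_dir / "factor_model.json")
        plot_scree(model, out_dir / "scree.png")
        plot_loading_heatmap(model, out_dir / "loadings.png")
        _write_model_tables(stepwise, hoa_models, out_dir / "model_tables.csv")
        report.outputs = {"dir": str(out_dir)}
        with open(out_dir / "report.json", "w") as fh:
            json.dump(_jsonable(report.to_dict()), fh, indent=1, sort_keys=True)
    return report


def _write_model_tables(stepwise: dict, hoa: dict, path) -> None:
    rows = []
    for source, models in (("KOA_stepwise", stepwise), ("HOA_applied", hoa)):
        for key, fit in models.items():
            for pred in fit.predictors:
                rows.append({
                    "source": source, "model": key, "predictor": pred,
                    "b": fit.b[pred], "SE": fit.se[pred], "beta": fit.beta[pred],
                    "t": fit.t[pred], "p": fit.p[pred],
                    "adj_r2": fit.adj_r2, "F": fit.fvalue, "df_model": fit.df_model,
                    "df_resid": fit.df_resid, "n": fit.n,
                })
    pd.DataFrame(rows).to_csv(path, index=False)
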