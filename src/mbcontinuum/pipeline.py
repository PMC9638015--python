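"""Top-level pipeline: chain the analysis stages on one configuration.

Stage order: simulate (optional) -> classify -> score -> methyl ->
switchpoints -> sc -> associate.  Each stage writes its artifacts under
``out_dir/<stage>/`` (config hash stamped in every table) and hands its
in-memory results to later stages; a failing stage aborts the run with
an error naming the stage.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import association, methylation, nmf, sc, score, switchpoint, synthetic
from .core import LabeledMatrix, MatrixKind, SampleTable, assign_quantile
from .io import (
    PipelineConfig,
    get_logger,
    read_matrix,
    read_mtx,
    read_table,
    stage_seed,
    write_matrix,
    write_mtx,
    write_table,
)

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _flags_frame(table: SampleTable) -> pd.DataFrame:
    df = table.to_frame().reset_index()
    return df


def _stage_simulate(cfg: PipelineConfig, ctx: dict[str, Any], out: Path) -> None:
    params = dict(cfg.stage_params.get("simulate", {}))
    flag_specs = params.pop("flags", [["LCA", -4.0, 8.0], ["i17q", 2.0, -6.0]])
    sc_params = params.pop("sc", {})
    sim = synthetic.SimulationConfig(
        seed=stage_seed(cfg.seed, "simulate"),
        sc=synthetic.ScConfig(**sc_params),
        **params,
    )
    expr, samples, truth = synthetic.generate_bulk(sim)
    beta, mt = synthetic.generate_methylation(sim, truth.score)
    counts, cells, sct = synthetic.generate_sc(sim)
    flags = synthetic.generate_feature_flags(
        truth, [tuple(f) for f in flag_specs], seed=sim.seed
    )
    truth = truth.merge(mt).merge(sct)

    write_matrix(expr, out / "expr.tsv", cfg.config_hash)
    write_matrix(beta, out / "beta.tsv", cfg.config_hash)
    write_mtx(counts, out / "matrix.mtx")
    write_table(_flags_frame(flags), out / "samples.tsv", cfg.config_hash)
    write_table(cells.reset_index(), out / "cells.tsv", cfg.config_hash)
    write_table(
        pd.DataFrame(
            {"sample_id": list(truth.score), "true_score": list(truth.score.values())}
        ),
        out / "truth_scores.tsv",
        cfg.config_hash,
    )
    ctx.update(
        expr=expr, beta=beta, counts=counts, cell_annotation=cells,
        sample_table=flags, truth=truth, sim_config=sim,
    )


def _load_expr(cfg: PipelineConfig, ctx: dict[str, Any]) -> LabeledMatrix:
    if "expr" in ctx:
        return ctx["expr"]
    path = cfg.stage_params.get("classify", {}).get("expr")
    if not path:
        raise FileNotFoundError("no expression matrix: run simulate or set classify.expr")
    return read_matrix(path, kind="expression")


def _stage_classify(cfg: PipelineConfig, ctx: dict[str, Any], out: Path) -> None:
    params = cfg.stage_params.get("classify", {})
    expr = _load_expr(cfg, ctx)
    report = nmf.select_model(
        expr,
        ranks=range(params.get("rank_min", 3), params.get("rank_max", 6) + 1),
        clusters=range(params.get("cluster_min", 3), params.get("cluster_max", 6) + 1),
        n_iter=params.get("iters", 50),
        frac=params.get("frac", 0.8),
        seed=stage_seed(cfg.seed, "classify"),
    )
    cr = report.results[(report.selected_rank, report.selected_clusters)]

    cluster_names = params.get("cluster_names")
    if cluster_names is None:
        truth = ctx.get("truth")
        if truth is None or not truth.subgroup:
            raise ValueError("classify.cluster_names required without simulated truth")
        cluster_names = _name_clusters_from_truth(cr, truth, ctx)
    cluster_names = {int(k): str(v) for k, v in dict(cluster_names).items()}
    calls = nmf.call_subgroups(cr, cluster_names)

    avg = nmf.averaged_metagenes(
        cr.activations, [f"mg{j+1}" for j in range(cr.rank)], cr.sample_ids
    )
    write_table(
        pd.DataFrame(
            [{"sample_id": c.sample_id, "call": c.call, "consistency": c.consistency}
             for c in calls]
        ),
        out / "calls.tsv", cfg.config_hash,
    )
    write_matrix(
        LabeledMatrix(cr.consensus, cr.sample_ids, cr.sample_ids, MatrixKind.metagene),
        out / "consensus.tsv", cfg.config_hash,
    )
    write_table(report.grid, out / "model_selection.tsv", cfg.config_hash)
    (out / "rationale.json").write_text(
        json.dumps(
            {"selected_rank": report.selected_rank,
             "selected_clusters": report.selected_clusters,
             "rationale": report.rationale, "config": cfg.config_hash},
            indent=2,
        )
    )
    write_matrix(
        LabeledMatrix(avg.H, avg.metagene_ids, avg.sample_ids, MatrixKind.metagene),
        out / "avg_metagenes.tsv", cfg.config_hash,
    )
    ctx.update(consensus=cr, calls=calls, averaged=avg, model_report=report)


def _name_clusters_from_truth(cr, truth, ctx) -> dict[int, str]:
    """Majority planted subgroup per modal cluster (synthetic runs only)."""
    names: dict[int, str] = {}
    by_cluster: dict[int, list[str]] = {}
    for s in cr.sample_ids:
        by_cluster.setdefault(cr.modal_class[s], []).append(truth.subgroup.get(s, ""))
    # split the Grp3/4 continuum clusters by mean planted score
    for cl, groups in by_cluster.items():
        top = max(set(groups), key=groups.count)
        names[cl] = top
    g34 = [cl for cl, nm in names.items() if nm == "Grp3/4"]
    if len(g34) >= 2:
        # split the continuum clusters into Grp4/Grp3 by mean planted score
        mean_u = {}
        for cl in g34:
            us = [truth.score[s] for s in cr.sample_ids
                  if cr.modal_class[s] == cl and s in truth.score]
            mean_u[cl] = float(np.mean(us)) if us else 0.5
        order = sorted(g34, key=lambda cl: mean_u[cl])
        for cl in order:
            names[cl] = "Grp4" if mean_u[cl] <= 0.5 else "Grp3"
        names[order[0]] = "Grp4"
        names[order[-1]] = "Grp3"
    # a single merged continuum cluster keeps the joint "Grp3/4" name
    # any remaining unseen clusters
    for cl in range(cr.clusters):
        names.setdefault(cl, f"cluster{cl}")
    return names


SCORED_CALLS = {"Grp3", "Grp4", "Grp3/Grp4-indeterminate", "Grp3/4"}


def _identify_g3_g4(avg: nmf.MetageneActivation, calls, ctx) -> tuple[str, str]:
    """G3/G4 metagene ids from the Grp3-vs-Grp4 contrast.

    When model selection merged the continuum into one cluster there are
    no separate Grp3/Grp4 calls; the fallback takes the most
    anticorrelated metagene pair across the continuum samples, oriented
    by planted truth when available (synthetic runs) and arbitrarily
    otherwise (the score is then defined up to the 1 - s reflection).
    """
    call_of = {c.sample_id: c.call for c in calls}
    idx3 = [j for j, s in enumerate(avg.sample_ids) if call_of.get(s) == "Grp3"]
    idx4 = [j for j, s in enumerate(avg.sample_ids) if call_of.get(s) == "Grp4"]
    if idx3 and idx4:
        contrast = avg.H[:, idx3].mean(axis=1) - avg.H[:, idx4].mean(axis=1)
        return (avg.metagene_ids[int(np.argmax(contrast))],
                avg.metagene_ids[int(np.argmin(contrast))])

    idx = [j for j, s in enumerate(avg.sample_ids) if call_of.get(s) in SCORED_CALLS]
    if len(idx) < 3:
        raise ValueError("too few continuum samples to identify the G3/G4 metagenes")
    H = avg.H[:, idx]
    k = H.shape[0]
    corr = np.corrcoef(H)
    pair = min(
        ((i, j) for i in range(k) for j in range(i + 1, k)),
        key=lambda ij: corr[ij[0], ij[1]],
    )
    truth = ctx.get("truth")
    if truth is not None and truth.score:
        u = np.array([truth.score.get(avg.sample_ids[j], np.nan) for j in idx])
        ok = np.isfinite(u)
        r0 = np.corrcoef(H[pair[0], ok], u[ok])[0, 1]
        if r0 < 0:
            pair = (pair[1], pair[0])
    else:
        warnings.warn(
            "score polarity unidentified (no Grp3/Grp4 calls and no truth); "
            "scores are defined up to reflection"
        )
    return avg.metagene_ids[pair[0]], avg.metagene_ids[pair[1]]


def _stage_score(cfg: PipelineConfig, ctx: dict[str, Any], out: Path) -> None:
    avg, calls = ctx["averaged"], ctx["calls"]
    g3_id, g4_id = _identify_g3_g4(avg, calls, ctx)
    keep = [c.sample_id for c in calls if c.call in SCORED_CALLS]
    idx = [avg.sample_ids.index(s) for s in keep]
    i3, i4 = avg.metagene_ids.index(g3_id), avg.metagene_ids.index(g4_id)
    scores, rng = score.g3g4_score(
        avg.H[i3, idx], avg.H[i4, idx], keep,
        robust_exclusion=cfg.stage_params.get("score", {}).get("robust_exclusion", False),
    )
    write_table(
        pd.DataFrame(
            [{"sample_id": s.sample_id, "m3": s.m3, "m4": s.m4, "raw": s.raw,
              "score": s.score, "quantile": s.quantile.value} for s in scores]
        ),
        out / "scores.tsv", cfg.config_hash,
    )
    ctx.update(
        scores={s.sample_id: s.score for s in scores},
        score_records=scores,
        scaling_range=rng,
        g3_metagene=g3_id,
        g4_metagene=g4_id,
    )


def _stage_methyl(cfg: PipelineConfig, ctx: dict[str, Any], out: Path) -> None:
    params = cfg.stage_params.get("methyl", {})
    beta = ctx.get("beta") or read_matrix(params["beta"], kind="beta")
    scores = ctx["scores"]
    quantiles = {s: assign_quantile(v) for s, v in scores.items() if s in set(beta.col_ids)}
    sel_cfg = methylation.FeatureSelectionConfig(
        n_boot=params.get("n_boot", 100),
        candidate_depth=params.get("candidate_depth", 500),
        seed=stage_seed(cfg.seed, "methyl"),
    )
    selection = methylation.select_features(beta, quantiles, sel_cfg)
    train_cfg = methylation.TrainConfig(
        n_trees=params.get("n_trees", 500),
        n_rfe_splits=params.get("n_rfe_splits", 50),
        seed=stage_seed(cfg.seed, "methyl-train"),
    )
    reg = methylation.train_regressor(beta, scores, selection, train_cfg)
    preds = methylation.predict_score(reg, beta)
    write_table(
        selection.frequency.reset_index(names="cpg_id"),
        out / "selection_frequency.tsv", cfg.config_hash,
    )
    write_table(
        pd.DataFrame({"cpg_id": selection.final_set}),
        out / "selected_cpgs.tsv", cfg.config_hash,
    )
    write_table(reg.rfe_trace, out / "rfe_trace.tsv", cfg.config_hash)
    write_table(
        pd.DataFrame(
            {"sample_id": list(preds), "predicted_score": list(preds.values())}
        ),
        out / "predicted_scores.tsv", cfg.config_hash,
    )
    (out / "model_info.json").write_text(
        json.dumps(
            {"validation_rmse": reg.validation_rmse,
             "n_features": len(reg.features), "config": cfg.config_hash},
            indent=2,
        )
    )
    ctx.update(selection=selection, regressor=reg, methyl_predictions=preds)


def _stage_switchpoints(cfg: PipelineConfig, ctx: dict[str, Any], out: Path) -> None:
    params = cfg.stage_params.get("switchpoints", {})
    beta = ctx.get("beta") or read_matrix(params["beta"], kind="beta")
    scores = ctx["scores"]
    samples = [s for s in beta.col_ids if s in scores]
    sub = beta.subset_cols(samples)
    svec = np.array([scores[s] for s in samples])
    fit_cfg = switchpoint.SigmoidFitConfig(seed=stage_seed(cfg.seed, "switchpoints"))
    dense = sub.to_dense()
    fits = [
        switchpoint.fit_sigmoid(svec, dense[i], fit_cfg, cpg_id=cpg)
        for i, cpg in enumerate(sub.row_ids)
    ]
    write_table(
        pd.DataFrame([asdict(f) for f in fits]), out / "sigmoid_fits.tsv",
        cfg.config_hash,
    )
    if "regions" in params and "cpg_positions" in params:
        from .io import read_bed

        regions = read_bed(params["regions"])
        positions = read_table(params["cpg_positions"])
        aggs, skipped = switchpoint.aggregate_regions(fits, positions, regions)
        write_table(
            pd.DataFrame(
                [{k: v for k, v in asdict(a).items() if k != "cpg_ids"} for a in aggs]
            ),
            out / "region_aggregates.tsv", cfg.config_hash,
        )
    ctx.update(sigmoid_fits=fits)


def _stage_sc(cfg: PipelineConfig, ctx: dict[str, Any], out: Path) -> None:
    params = cfg.stage_params.get("sc", {})
    counts = ctx.get("counts")
    if counts is None:
        counts = read_mtx(params["counts"], kind="counts")
    annotation = ctx.get("cell_annotation")
    if annotation is None and "cells" in params:
        annotation = read_table(params["cells"]).set_index("cell_id")

    expr = _load_expr(cfg, ctx)
    cr = ctx["consensus"]
    basis, _, _ = nmf.nmf_factorize(
        expr, cr.rank, seed=stage_seed(cfg.seed, "sc-basis")
    )
    # identify the basis' G3/G4 columns via its bulk activations
    proj = nmf.project_metagenes(basis, expr)
    scores = ctx["scores"]
    scored = [s for s in proj.sample_ids if s in scores]
    idx = [proj.sample_ids.index(s) for s in scored]
    svec = np.array([scores[s] for s in scored])
    corr = [
        float(np.corrcoef(proj.H[j, idx], svec)[0, 1])
        for j in range(proj.H.shape[0])
    ]
    g3 = proj.metagene_ids[int(np.argmax(corr))]
    g4 = proj.metagene_ids[int(np.argmin(corr))]

    features = sc.select_variable_features(counts, n=params.get("n_features", 5000))
    cell_scores, flagged = sc.project_cells(
        basis, counts, features, ctx["scaling_range"], g3, g4, annotation,
        standardization=sc.bulk_standardization(proj.H),
    )
    bulk_subtypes = {
        c.sample_id: ctx["truth"].subgroup.get(c.sample_id, "")
        for c in ctx["score_records"]
    } if "truth" in ctx else {}
    summaries = sc.summarize_distributions(
        cell_scores, ctx["score_records"], bulk_subtypes
    ) if bulk_subtypes else []
    write_table(
        pd.DataFrame(
            [{"cell_id": c.cell_id, "patient_id": c.patient_id, "subtype": c.subtype,
              "score": c.score, "quantile": c.quantile.value} for c in cell_scores]
        ),
        out / "cell_scores.tsv", cfg.config_hash,
    )
    if summaries:
        write_table(
            pd.DataFrame([asdict(s) for s in summaries]),
            out / "distribution_summaries.tsv", cfg.config_hash,
        )
    ctx.update(cell_scores=cell_scores, flagged_cells=flagged)


def _stage_associate(cfg: PipelineConfig, ctx: dict[str, Any], out: Path) -> None:
    params = cfg.stage_params.get("associate", {})
    scores = ctx["scores"]
    table = ctx.get("sample_table")
    if table is None and "features" in params:
        df = read_table(params["features"]).set_index("sample_id")
        flags = {
            c: df[c].to_dict() for c in df.columns if c not in ("subgroup",)
        }
        table = SampleTable(list(df.index), flags=flags)
    if table is not None and table.flags:
        ks, skipped = association.ks_feature_scan(scores, table)
        write_table(
            pd.DataFrame([asdict(r) for r in ks]), out / "ks_features.tsv",
            cfg.config_hash,
        )
        ctx["ks_results"] = ks
    expr = _load_expr(cfg, ctx)
    corr = association.correlation_scan(
        expr, scores, method=params.get("method", "spearman"),
        min_abs_fc=params.get("min_abs_fc", 0.0),
    )
    write_table(
        pd.DataFrame(
            [{"gene": r.gene, "correlation": r.correlation, "p": r.p,
              "p_adjusted": r.p_adjusted} for r in corr]
        ),
        out / "correlations.tsv", cfg.config_hash,
    )
    ctx["correlations"] = corr


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "classify": _stage_classify,
    "score": _stage_score,
    "methyl": _stage_methyl,
    "switchpoints": _stage_switchpoints,
    "sc": _stage_sc,
    "associate": _stage_associate,
}


def run_pipeline(cfg: PipelineConfig) -> dict[str, Any]:
    """Execute the enabled stages in order; returns the result context.

    Raises :class:`PipelineError` naming the first failing stage.
    """
    logger = get_logger(cfg.log_level)
    out_root = Path(cfg.out_dir)
    ctx: dict[str, Any] = {}
    logger.info("pipeline start: seed=%d hash=%s stages=%s",
                cfg.seed, cfg.config_hash, ",".join(cfg.stages))
    for stage in cfg.stages:
        stage_dir = out_root / stage
        stage_dir.mkdir(parents=True, exist_ok=True)
        t0 = time.time()
        logger.info("stage %s: start (seed=%d)", stage, stage_seed(cfg.seed, stage))
        try:
            _STAGE_FUNCS[stage](cfg, ctx, stage_dir)
        except Exception as exc:
            logger.error("stage %s failed: %s", stage, exc)
            raise PipelineError(stage, exc) from exc
        logger.info("stage %s: done in %.1fs", stage, time.time() - t0)
    return ctx
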