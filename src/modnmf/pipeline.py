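"""Stage orchestration: preprocess -> factorize -> modules -> score.

Every stage is a deterministic function of the validated
:class:`~modnmf.config.RunConfig`, so a stage command recomputes from the
inputs up to its stage and writes that stage's artifacts; the run manifest
(config echo + seeds + per-stage counts + package version) suffices to
reproduce any run bit-identically.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from . import io_formats as iof
from . import preprocess as pp
from . import joint_nmf as jn
from . import module_extraction as mx
from . import scoring as sc

__all__ = ["PipelineState", "run_pipeline"]

STAGES = ("preprocess", "factorize", "modules", "score")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineState:
    config: RunConfig
    X: list[pp.BinaryRelationMatrix] = field(default_factory=list)
    kscan: jn.KScanResult | None = None
    factorization: jn.JointFactorization | None = None
    modules: mx.ModuleSet | None = None
    ntos: list[sc.NtoScore] = field(default_factory=list)
    candidates: list[sc.CandidateReport] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)


def _stage_preprocess(state: PipelineState) -> None:
    cfg = state.config
    if cfg.has_expression_inputs:
        circ = iof.read_expression(cfg.inputs["circ_expr"], cfg.inputs["groups"],
                                   impute_zero=cfg.impute_zero)
        mirna = iof.read_expression(cfg.inputs["mirna_expr"], cfg.inputs["groups"],
                                    impute_zero=cfg.impute_zero)
        mrna = iof.read_expression(cfg.inputs["mrna_expr"], cfg.inputs["groups"],
                                   impute_zero=cfg.impute_zero)

        expressed = pp.expressed_fraction_filter(circ, cfg.min_expressed_fraction)
        circ = circ.subset_features(expressed)
        circ_de = [r.feature_id for r in pp.differential_screen(
            circ, cfg.fc_low, cfg.fc_high, p_cut=None,
            pseudocount=cfg.pseudocount,
            min_expressed_fraction=cfg.min_expressed_fraction) if r.passed]
        if not circ_de:
            raise StageError("preprocess", "no differential circRNAs")
        circ = circ.subset_features(circ_de)
        edges = pp.coexpression_edges(circ, mrna, cfg.pcc_cut, cfg.pcc_p_cut)
        x1 = pp.degree_filter(edges, cfg.min_degree, layer="circRNA")

        mirna_expressed = pp.expressed_fraction_filter(
            mirna, cfg.min_expressed_fraction)
        mirna = mirna.subset_features(mirna_expressed)
        mirna_de = {r.feature_id for r in pp.differential_screen(
            mirna, cfg.fc_low, cfg.fc_high, p_cut=cfg.mirna_p_cut,
            pseudocount=cfg.pseudocount,
            min_expressed_fraction=cfg.min_expressed_fraction,
            paired=cfg.paired_test) if r.passed}
        targets = iof.read_edge_list(cfg.inputs["mirna_targets"], "miRNA")
        kept = iof.EdgeList(
            pairs={(s, t) for s, t in targets.pairs if s in mirna_de},
            source_kind="miRNA")
        if not kept.pairs:
            raise StageError("preprocess",
                             "no targets left for differential miRNAs")
        x2 = pp.degree_filter(kept, cfg.min_degree, layer="miRNA")
        x1_min, x2_min = cfg.min_degree, cfg.min_degree
    elif cfg.has_relation_inputs:
        x1 = pp.degree_filter(iof.read_edge_list(cfg.inputs["x1_edges"], "circRNA"),
                              cfg.relation_min_degree, layer="circRNA")
        x2 = pp.degree_filter(iof.read_edge_list(cfg.inputs["mirna_targets"], "miRNA"),
                              cfg.relation_min_degree, layer="miRNA")
    else:
        raise StageError(
            "preprocess",
            "config must provide either expression inputs "
            "(circ_expr, mirna_expr, mrna_expr, groups, mirna_targets, "
            "pathways_gmt) or relation inputs (x1_edges, mirna_targets, "
            "pathways_gmt)")

    pathway_sets = iof.read_gmt(cfg.inputs["pathways_gmt"])
    pw_edges = iof.EdgeList(
        pairs={(sid, g) for sid, genes in pathway_sets.sets.items() for g in genes},
        source_kind="pathway")
    x3 = pp.degree_filter(pw_edges, cfg.pathway_min_degree, layer="pathway")

    if "mrna_universe" in cfg.inputs:
        universe = sorted(iof.read_id_list(cfg.inputs["mrna_universe"]))
        x1 = pp.expand_columns(x1, universe)
        x2 = pp.expand_columns(x2, universe)
        x3 = pp.expand_columns(x3, universe)

    try:
        state.X = list(pp.align_common_mrnas(x1, x2, x3))
    except ValueError as exc:
        raise StageError("preprocess", str(exc)) from exc
    state.counts.update({
        "n_common_mrnas": len(state.X[0].col_ids),
        "n_circrnas": len(state.X[0].row_ids),
        "n_mirnas": len(state.X[1].row_ids),
        "n_pathways": len(state.X[2].row_ids),
    })


def _stage_factorize(state: PipelineState) -> None:
    cfg = state.config
    if cfg.k is not None:
        state.factorization = jn.fit_joint_nmf(
            state.X, cfg.k, n_restarts=cfg.n_restarts, max_iter=cfg.max_iter,
            tol=cfg.tol, seed=cfg.seed)
    else:
        state.kscan = jn.scan_k(
            state.X, cfg.k_min, cfg.k_max, n_restarts=cfg.n_restarts,
            max_iter=cfg.max_iter, tol=cfg.tol, seed=cfg.seed)
        state.factorization = state.kscan.chosen_factorization
    state.counts["chosen_k"] = state.factorization.K


def _stage_modules(state: PipelineState) -> None:
    cfg = state.config
    if "go_bp_gmt" not in cfg.inputs:
        raise StageError("modules", "config must provide go_bp_gmt")
    annotation = iof.read_gmt(cfg.inputs["go_bp_gmt"])
    mods = mx.assign_members(
        state.factorization, annotation,
        percents=range(cfg.top_percent_min, cfg.top_percent_max + 1),
        enrichment_fdr=cfg.enrichment_fdr,
        min_set_size=cfg.min_set_size, max_set_size=cfg.max_set_size)
    mods = mx.collect_edges(mods, state.X)
    state.modules = mx.screen_functional(mods, cfg.functional_min_terms,
                                         cfg.enrichment_fdr)
    state.counts["n_modules"] = len(mods.modules)
    state.counts["n_functional_modules"] = len(mods.functional)


def _stage_score(state: PipelineState) -> None:
    cfg = state.config
    known_genes = iof.read_id_list(cfg.inputs["known_genes"]) \
        if "known_genes" in cfg.inputs else set()
    known_mirnas = iof.read_id_list(cfg.inputs["known_mirnas"]) \
        if "known_mirnas" in cfg.inputs else set()
    known_pathways = iof.read_id_list(cfg.inputs["known_pathways"]) \
        if "known_pathways" in cfg.inputs else None
    state.ntos = sc.score_pairs(state.modules, state.X, cfg.min_nto)
    state.candidates = sc.prioritize_candidates(
        state.modules, state.X, state.ntos, known_genes, known_mirnas,
        min_partners=cfg.min_partners, known_pathways=known_pathways,
        per_module=cfg.per_module_partners)
    state.counts["n_nto_pairs"] = len(state.ntos)
    state.counts["n_candidates"] = sum(c.is_candidate for c in state.candidates)


_RUNNERS = {
    "preprocess": _stage_preprocess,
    "factorize": _stage_factorize,
    "modules": _stage_modules,
    "score": _stage_score,
}


def run_pipeline(config: RunConfig, out_dir: str | os.PathLike,
                 upto: str = "score") -> PipelineState:
    """Execute the pipeline through stage ``upto`` and write its artifacts."""
    if upto not in STAGES:
        raise ValueError(f"unknown stage {upto!r}")
    state = PipelineState(config=config)
    os.makedirs(out_dir, exist_ok=True)
    for stage in STAGES:
        try:
            _RUNNERS[stage](state)
        except StageError:
            raise
        except (OSError, ValueError, FloatingPointError) as exc:
            raise StageError(stage, str(exc)) from exc
        if stage == upto:
            break
    _write_outputs(state, str(out_dir), upto)
    return state


def _write_outputs(state: PipelineState, out_dir: str, upto: str) -> None:
    done = STAGES[:STAGES.index(upto) + 1]
    if "preprocess" in done:
        for x, name in zip(state.X, ("x1_circ_mrna", "x2_mirna_mrna",
                                     "x3_pathway_mrna")):
            pd.DataFrame(x.cells.astype(int), index=x.row_ids,
                         columns=x.col_ids).to_csv(
                os.path.join(out_dir, f"{name}.tsv"), sep="\t")
    if "factorize" in done:
        fact = state.factorization
        pd.DataFrame(fact.W, index=fact.mrna_ids,
                     columns=[f"k{j}" for j in range(fact.K)]).to_csv(
            os.path.join(out_dir, "W.tsv"), sep="\t", float_format="%.8g")
        for Hi, ids, layer in zip(fact.H, fact.entity_ids, fact.layers):
            pd.DataFrame(Hi, index=[f"k{j}" for j in range(fact.K)],
                         columns=ids).to_csv(
                os.path.join(out_dir, f"H_{layer}.tsv"), sep="\t",
                float_format="%.8g")
        if state.kscan is not None:
            pd.DataFrame(sorted(state.kscan.per_k.items()),
                         columns=["K", "best_objective"]).to_csv(
                os.path.join(out_dir, "kscan.tsv"), sep="\t", index=False,
                float_format="%.8g")
    if "modules" in done:
        iof.write_module_report(state.modules, out_dir)
    if "score" in done:
        pd.DataFrame(
            [(s.circ_id, s.partner_id, s.partner_kind, s.nto, s.overlap)
             for s in state.ntos],
            columns=["circ_id", "partner_id", "partner_kind", "nto", "overlap"],
        ).to_csv(os.path.join(out_dir, "nto_scores.tsv"), sep="\t",
                 index=False, float_format="%.6g")
        pd.DataFrame(
            [(c.circ_id, c.partner_count, int(c.is_candidate),
              ",".join(map(str, c.module_indices)),
              ";".join(f"{p}:{k}" for p, k in c.partners))
             for c in state.candidates],
            columns=["circ_id", "partner_count", "is_candidate", "modules",
                     "partners"],
        ).to_csv(os.path.join(out_dir, "candidates.tsv"), sep="\t", index=False)

    manifest = {
        "modnmf_version": __version__,
        "config": state.config.to_dict(),
        "stages_run": list(done),
        "counts": state.counts,
    }
    if state.factorization is not None:
        manifest["best_restart_seed"] = state.factorization.restart_seed
        manifest["best_objective"] = state.factorization.final_objective
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
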