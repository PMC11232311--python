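"""End-to-end orchestration: classify → extract → reporter → subnetwork →
topology → metabolomics, with per-stage TSV/JSON outputs and full seed
determinism.

The pipeline can run from files (paths in the config) or from the built-in
synthetic scenario (``synthetic: true``), in which case the generated truth
records are written alongside the stage outputs and a recovery report
compares the planted hub against the analysis results.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os

import networkx as nx
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import expression as ex
from . import extraction as xt
from . import metabolomics as mx
from . import reporter as rp
from . import subnetwork as sn
from . import synth
from . import topology as tp
from .model import read_model, write_model

__all__ = ["PipelineConfig", "load_config", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    # inputs (ignored when synthetic)
    model_path: str | None = None
    expression_paths: list[str] = field(default_factory=list)
    deg_path: str | None = None
    protein_path: str | None = None
    metabolomics_path: str | None = None
    categories_path: str | None = None
    tasks_path: str | None = None
    synthetic: bool = False
    # thresholds
    q_low: float = 0.25
    q_high: float = 0.75
    absent_sample_frac: float = 0.80
    p_adj_force: float = 0.001
    p_adj_sig: float = 0.01
    reporter_alpha: float = 0.1
    metabolomics_alpha_adj: float = 0.1
    epsilon: float = 1e-4
    n_background: int = 10000
    n_perm: int = 100000
    top_k: int = 5
    reaction_penalty: float = -0.1
    annealing_iterations: int = 20000
    annealing_t0: float = 1.0
    annealing_cooling: float = 0.9995
    tier_scores: dict = field(
        default_factory=lambda: dict(ex.DEFAULT_TIER_SCORES))
    currency: list[str] = field(
        default_factory=lambda: list(sn.DEFAULT_CURRENCY))
    groups: list[str] = field(default_factory=lambda: ["IPH-", "IPH+"])
    seed: int = 0
    run_extraction: bool = True

    def __post_init__(self):
        for name in ("q_low", "q_high", "absent_sample_frac", "p_adj_force",
                     "p_adj_sig", "reporter_alpha", "metabolomics_alpha_adj"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"config {name}={v} must lie in (0, 1)")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


def _write_tsv(df: pd.DataFrame, path: str, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def run_pipeline(config: PipelineConfig, outdir: str) -> dict:
    """Run every applicable stage; returns a summary dict (also written as
    summary.json).  Re-running with the same config and seed reproduces the
    outputs."""
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "config.yaml"), "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    summary: dict = {"seed": config.seed}

    # ---- inputs -----------------------------------------------------------
    truth: dict = {}
    tasks = []
    if config.synthetic:
        scenario = synth.SyntheticScenario(seed=config.seed)
        model, truth_model = synth.generate_toy_model(scenario)
        primary, second, deg, truth_expr = synth.generate_expression(
            model, scenario)
        cohorts = [primary, second]
        proteins: list[str] = []
        metabolomics, categories, truth_met = synth.generate_metabolomics(
            model, scenario)
        truth = {"model": truth_model, "expression": truth_expr,
                 "metabolomics": truth_met}
        with open(os.path.join(outdir, "truth.json"), "w") as fh:
            json.dump(truth, fh, indent=1, default=str)
        tasks = [xt.MetabolicTask(id="glutamine_synthesis",
                                  required_production={"glutamine[c]": 0.1})]
    else:
        if not config.model_path:
            raise ValueError("model_path required for a non-synthetic run")
        model = read_model(config.model_path)
        cohorts = [ex.read_expression(p) for p in config.expression_paths]
        deg = ex.read_deg_table(config.deg_path) if config.deg_path else None
        proteins = []
        if config.protein_path:
            proteins = [line.strip() for line
                        in open(config.protein_path, encoding="utf-8")
                        if line.strip()]
        metabolomics = categories = None
        if config.metabolomics_path:
            metabolomics = mx.read_metabolomics(config.metabolomics_path)
            categories = (mx.read_categories(config.categories_path)
                          if config.categories_path else {})
        if config.tasks_path:
            tasks = xt.read_tasks(config.tasks_path)
    write_model(model, os.path.join(outdir, "reference_model"))

    # ---- expression tiers -------------------------------------------------
    if not cohorts:
        raise ValueError("at least one expression matrix is required")
    per_cohort = [ex.classify_genes(c, config.absent_sample_frac,
                                    config.q_low, config.q_high)
                  for c in cohorts]
    classes = ex.combine_cohorts(*per_cohort)
    classes = ex.force_high(classes, deg, config.p_adj_force, proteins)
    _write_tsv(classes.to_frame(), os.path.join(outdir, "gene_classes.tsv"))
    summary["tier_counts"] = classes.counts()

    # ---- extraction -------------------------------------------------------
    weights = ex.reaction_weights(model, classes, config.tier_scores)
    if config.run_extraction:
        result = xt.extract_context_model(model, weights, tasks,
                                          epsilon=config.epsilon)
        sub_model = result.sub_model
        write_model(sub_model, os.path.join(outdir, "context_model"))
        with open(os.path.join(outdir, "extraction.json"), "w") as fh:
            json.dump({"kept": sorted(result.kept),
                       "objective": result.objective,
                       "task_report": result.task_report,
                       "perturbation": result.perturbation}, fh, indent=1)
        summary["extraction"] = {"n_kept": len(result.kept),
                                 "objective": result.objective,
                                 "tasks_feasible": all(
                                     result.task_report.values())}
    else:
        sub_model = model

    if deg is not None:
        up, down = xt.gem_signature(sub_model, deg, config.p_adj_sig)
        with open(os.path.join(outdir, "gem_signature.json"), "w") as fh:
            json.dump({"up": up, "down": down}, fh, indent=1)
        summary["gem_signature"] = {"n_up": len(up), "n_down": len(down)}

    # ---- reporter metabolites (three directional modes) -------------------
    records_by_mode: dict[str, list] = {}
    if deg is not None:
        for mode in rp.MODES:
            scores = rp.directional_pvalues(deg, mode)
            records, _null = rp.reporter_scores(
                sub_model, scores, n_background=config.n_background,
                seed=np.random.default_rng((config.seed, 5,
                                            rp.MODES.index(mode))))
            records_by_mode[mode] = records
            _write_tsv(rp.records_to_frame(records),
                       os.path.join(outdir, f"reporter_{mode}.tsv"))
        summary["n_significant_reporters"] = {
            mode: len(rp.significant_reporters(recs, config.reporter_alpha))
            for mode, recs in records_by_mode.items()}

    # ---- subnetwork + topology -------------------------------------------
    graph = sn.build_graph(sub_model, tuple(config.currency))
    if records_by_mode:
        sn.score_nodes(graph, records_by_mode["all"],
                       config.reaction_penalty)
    else:
        for _n, d in graph.nodes(data=True):
            d["score"] = 0.0
    search = sn.search_subnetwork(graph,
                                  iterations=config.annealing_iterations,
                                  t0=config.annealing_t0,
                                  cooling_rate=config.annealing_cooling,
                                  seed=config.seed + 1)
    comp_rows = [{"component": i, "size": len(c),
                  "nodes": ";".join(sorted(c))}
                 for i, c in enumerate(search.components)]
    _write_tsv(pd.DataFrame(comp_rows,
                            columns=["component", "size", "nodes"]),
               os.path.join(outdir, "subnetwork_components.tsv"))
    sn.export_subnetwork(search, graph,
                         graphml_path=os.path.join(outdir, "subnetwork.graphml"),
                         sif_path=os.path.join(outdir, "subnetwork.sif"))
    # topology substrate: selected nodes plus the reactions bridging them,
    # so the reporter subnetwork regains its metabolite-reaction structure
    augmented = sn.augment_with_bridging_reactions(graph, search.selected)
    aug_graph = graph.subgraph(augmented)
    comps = sorted(nx.connected_components(aug_graph),
                   key=lambda c: (-len(c), min(c)))
    major = comps[0] if comps else set()
    summary["subnetwork"] = {
        "score": search.score, "n_selected": len(search.selected),
        "n_components": len(search.components),
        "major_size": len(search.major),
        "n_augmented": len(augmented),
        "major_augmented_size": len(major)}

    major_graph = graph.subgraph(major).copy()
    table = tp.centrality(major_graph)
    _write_tsv(table, os.path.join(outdir, "centrality.tsv"), index=True)
    hubs = tp.top_hubs(table, k=config.top_k) if len(table) else []
    directional = [r for mode in ("up", "down")
                   for r in records_by_mode.get(mode, [])]
    hub_report = tp.annotate_hubs(hubs, table, directional) if hubs \
        else pd.DataFrame()
    _write_tsv(hub_report, os.path.join(outdir, "hub_report.tsv"))
    summary["top_hubs"] = hubs

    # ---- metabolomics arm -------------------------------------------------
    if metabolomics is not None:
        filtered, qc_log = mx.qc_filter(metabolomics)
        _write_tsv(qc_log, os.path.join(outdir, "qc_exclusions.tsv"))
        corrected = mx.batch_correct(filtered)
        mx.write_metabolomics(corrected,
                              os.path.join(outdir, "metabolomics_corrected.tsv"))
        calls = mx.differential_abundance(
            corrected, config.metabolomics_alpha_adj,
            groups=tuple(config.groups))
        _write_tsv(calls, os.path.join(outdir, "differential_abundance.tsv"),
                   index=True)
        cat_frames = []
        for direction in ("up", "down"):
            cat_frames.append(mx.category_permutation_test(
                calls, categories or {}, direction=direction,
                n_perm=config.n_perm,
                seed=np.random.default_rng((config.seed, 7,
                                            0 if direction == "up" else 1))))
        cat = pd.concat(cat_frames, ignore_index=True)
        _write_tsv(cat, os.path.join(outdir, "category_enrichment.tsv"))
        summary["metabolomics"] = {
            "n_tested": int(len(calls)),
            "n_up": int((calls["call"] == "up").sum()),
            "n_down": int((calls["call"] == "down").sum()),
        }
    else:
        logger.info("metabolomics inputs absent; arm skipped")

    # ---- truth comparison (synthetic runs) --------------------------------
    if truth:
        hub = truth["model"]["hub"]
        hub_rec = None
        for r in records_by_mode.get("up", []):
            if r.metabolite == hub:
                hub_rec = r
        summary["recovery"] = {
            "hub": hub,
            "hub_in_top_hubs": hub in hubs,
            "hub_reporter_p_up": hub_rec.p_reporter if hub_rec else None,
            "hub_in_major_component": hub in search.major,
        }

    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, default=str)
    return summary
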