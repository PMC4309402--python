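"""End-to-end orchestration: simulate/load -> preprocess -> univariate ->
direction -> coordination -> classifiers, with seeds, logging and a
machine-readable manifest.

Every stage writes plain TSV tables (with a provenance comment line) into
the output directory; the manifest records the fully-defaulted config, its
hash, per-stage seeds and wall times, and library versions, so a rerun with
the same config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import (
    MetaboliteMatrix,
    PathwayMap,
    SampleDesign,
    canonical_comparisons,
    load_design,
    load_matrix,
    load_pathways,
    scale_and_impute,
    write_matrix,
    write_table,
)
from .coordination import cluster_subpathways, scan_subpathways, subpathway_mean_profiles
from .direction import direction_profiles, pathway_direction_scan, profile_bits
from .simulate import GeneratorConfig, generate_study, preset_paper_like
from .univariate import anova_all, compare_all
from . import classifiers as clf

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


@dataclass
class RunConfig:
    """Fully-defaulted run configuration.

    Either ``matrix_path``/``design_path``/``pathways_path`` point at input
    tables, or ``simulate=True`` generates a study-shaped dataset with
    ``seed``.
    """

    out_dir: str = "results/run"
    simulate: bool = True
    matrix_path: str | None = None
    design_path: str | None = None
    pathways_path: str | None = None
    preprocess: str = "median_scale_min_impute"
    alpha: float = 0.05
    sided: str = "one"
    yates: bool = True
    permutations: int = 10_000
    tail: str = "low"
    linkage: str = "average"
    coordination_alpha: float = 0.05
    n_trees: int = 200
    top_fraction: float = 0.10
    knn_k: int = 3
    max_panel: int = 2
    max_candidates: int = 25
    seed: int = 0
    stages: tuple[str, ...] = ("univariate", "direction", "coordination", "classifiers")

    def hash(self) -> str:
        fields = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        payload = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _load_inputs(cfg: RunConfig) -> tuple[MetaboliteMatrix, SampleDesign, PathwayMap, pd.DataFrame | None]:
    if cfg.simulate:
        matrix, design, pathways, truth = generate_study(preset_paper_like(cfg.seed))
        return matrix, design, pathways, truth
    if not (cfg.matrix_path and cfg.design_path and cfg.pathways_path):
        raise StageError("load: matrix_path, design_path and pathways_path are all required "
                         "when simulate is off")
    return (load_matrix(cfg.matrix_path), load_design(cfg.design_path),
            load_pathways(cfg.pathways_path), None)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all enabled stages; returns the summary dict (also written as
    ``manifest.json`` / ``summary.json`` in the output directory)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": cfg.hash(), "seed": cfg.seed, "version": __version__}
    manifest: dict = {
        "config": asdict(cfg), "config_hash": cfg.hash(), "version": __version__,
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "stages": {},
    }
    summary: dict = {}

    def stage(name, fn):
        if name not in ("load", "preprocess") and name not in cfg.stages:
            logger.info("stage %s disabled", name)
            return None
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # annotate with the failing stage
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
            raise StageError(f"{name}: {exc}") from exc
        manifest["stages"][name] = {"status": "ok",
                                    "seconds": round(time.perf_counter() - t0, 3)}
        return result

    matrix, design, pathways, truth = stage("load", lambda: _load_inputs(cfg))
    design.check_matches(matrix)
    logger.info("loaded %d samples x %d metabolites", *matrix.shape)
    if truth is not None:
        write_table(truth, out / "truth.tsv", meta=meta, index=False)
        write_matrix(matrix, out / "matrix.tsv", meta=meta)
        write_table(design.table, out / "design.tsv", meta=meta, index_label="sample_id")
        write_table(pathways.table, out / "pathways.tsv", meta=meta,
                    index_label="metabolite_id")

    matrix = stage("preprocess", lambda: scale_and_impute(matrix, cfg.preprocess))
    specs = canonical_comparisons(design)

    def univariate_stage():
        frames = []
        counts = {}
        for spec in specs:
            tab = compare_all(matrix, spec, alpha=cfg.alpha)
            counts[spec.label] = tab.attrs["n_significant"]
            frames.append(tab.reset_index())
        allt = pd.concat(frames, ignore_index=True)
        write_table(allt, out / "univariate.tsv", meta=meta, index=False)
        av = anova_all(matrix, design)
        write_table(av, out / "anova.tsv", meta=meta, index_label="metabolite_id")
        return counts

    counts = stage("univariate", univariate_stage)
    if counts is not None:
        summary["n_altered_p05"] = counts

    profiles = direction_profiles(matrix, specs)

    def direction_stage():
        res = {}
        for level in ("superpathway", "subpathway"):
            scan = pathway_direction_scan(profiles, pathways, level=level,
                                          sided=cfg.sided)
            write_table(scan, out / f"direction_{level}.tsv", meta=meta, index=False)
            res[level] = int(scan["flag_05"].sum())
        return res

    dres = stage("direction", direction_stage)
    if dres is not None:
        summary["n_pathway_flags_p05"] = dres

    def coordination_stage():
        coord = scan_subpathways(profiles, pathways, m=cfg.permutations,
                                 seed=cfg.seed, tail=cfg.tail)
        write_table(coord, out / "coordination.tsv", meta=meta, index=False)
        hits = coord[coord["p"] <= cfg.coordination_alpha]
        nres = {"n_coordinated": int(len(hits))}
        if len(hits) >= 2:
            prof = subpathway_mean_profiles(profiles, pathways,
                                            subpathways=list(hits["subpathway"]))
            z, newick = cluster_subpathways(prof, linkage=cfg.linkage)
            (out / "dendrogram.nwk").write_text(newick + "\n")
            merge = pd.DataFrame(z, columns=["left", "right", "height", "size"])
            write_table(merge, out / "dendrogram_merges.tsv", meta=meta, index=False)
        return nres

    cres = stage("coordination", coordination_stage)
    if cres is not None:
        summary.update(cres)

    def classifier_stage():
        # AggE vs Ctrl at the acute time point, regimens combined
        acute = design.table.index[design.table["timepoint"] == "acute"]
        sub = MetaboliteMatrix(matrix.data.loc[acute])
        labels = design.table.loc[acute, "treatment"]
        mda = clf.rf_mda_rank(sub, labels, n_trees=cfg.n_trees, seed=cfg.seed)
        tables = {m: clf.univariate_scores(sub, labels, m) for m in clf.METHODS[1:]}
        scores = pd.concat([mda] + list(tables.values()), ignore_index=True)
        write_table(scores, out / "scores.tsv", meta=meta, index=False)
        candidates = clf.candidate_pipeline(sub, labels, score_tables=tables)
        if len(candidates) > cfg.max_candidates:
            keep = mda[mda["metabolite_id"].isin(candidates)]
            candidates = list(keep.sort_values("rank")["metabolite_id"].iloc[:cfg.max_candidates])
        best = clf.ddknn_panel_search(sub, labels, candidates, k=cfg.knn_k,
                                      max_panel=cfg.max_panel)
        rows = [{
            "panel_size": size, "members": ";".join(r.members),
            "classifier": r.classifier, "sensitivity": r.sensitivity,
            "specificity": r.specificity, "tp": r.tp, "fn": r.fn,
            "tn": r.tn, "fp": r.fp,
        } for size, r in sorted(best.items())]
        write_table(pd.DataFrame(rows), out / "panels.tsv", meta=meta, index=False)
        top = best[0]
        return {"best_panel": list(top.members),
                "loo_sensitivity": top.sensitivity,
                "loo_specificity": top.specificity,
                "n_candidates": len(candidates)}

    kres = stage("classifiers", classifier_stage)
    if kres is not None:
        summary["classifiers"] = kres

    manifest["summary"] = summary
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary
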