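"""End-to-end pipeline orchestration.

``run_pipeline`` executes: simulate (optional) -> QC -> normalize ->
[diffusion imputation] -> differential expression for every configured
(cell type, contrast) -> DEG summary -> [ORA against a GMT collection] ->
population distances, writing each stage's outputs plus a manifest into a run
directory. Every stochastic step draws its stream from the global seed plus a
fixed per-stage offset, so reruns with the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import io as eio
from .containers import validate_metadata
from .de import Contrast, EMDDifferentialExpression, summarize_deg_counts
from .distance import PopulationDistance
from .enrich import ora_gmt
from .graph import build_knn_graph, compute_pca, diffusion_impute
from .qc import apply_qc_filters, normalize_sqrt
from .simulate import SimConfig, generate_dataset

logger = logging.getLogger(__name__)

_STAGE_SEEDS = {"simulate": 11, "subsample": 23, "de": 37}


@dataclass
class PipelineConfig:
    out_dir: str
    input_dir: str = None          # 10x directory; ignored when simulate is set
    metadata_path: str = None
    gmt_path: str = None
    simulate: dict = None          # SimConfig fields (seed derived from global)
    min_cells_per_gene: int = 3
    min_genes_per_cell: int = 500
    max_mito_frac: float = 0.05
    target_sum: object = "median"
    use_imputed: bool = False
    n_pcs: int = 50
    k_per_group: int = 3
    balanced: bool = True
    diffusion_t: int = 3
    contrasts: list = field(default_factory=list)  # {cell_type?, group_ref, group_alt}
    emd_min: float = 0.1
    p_max: float = 0.01
    pseudocount: float = 0.01
    min_cells_per_group: int = 20
    subsample: bool = False
    alpha: float = 0.05
    distance_pcs: int = 50
    linkage: str = "average"
    seed: int = 0

    def validate(self):
        if not (0 < self.max_mito_frac < 1):
            raise ValueError("max_mito_frac must be in (0, 1)")
        if self.emd_min < 0 or not (0 < self.p_max <= 1):
            raise ValueError("DE thresholds out of range")
        if self.simulate is None:
            if not self.input_dir or not os.path.isdir(self.input_dir):
                raise ValueError(f"input_dir missing: {self.input_dir!r}")
            if not self.metadata_path or not os.path.exists(self.metadata_path):
                raise ValueError(f"metadata path missing: {self.metadata_path!r}")
        if self.gmt_path and not os.path.exists(self.gmt_path):
            raise ValueError(f"GMT path missing: {self.gmt_path!r}")
        if not self.contrasts:
            raise ValueError("at least one contrast is required")


def load_config(path: str) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return PipelineConfig(**raw)


def _stage_seed(global_seed: int, stage: str) -> int:
    return int((global_seed * 1_000_003 + _STAGE_SEEDS[stage]) % (2**31 - 1))


def _config_digest(cfg: PipelineConfig) -> str:
    # out_dir is excluded: the same analysis into two directories is the same run
    blob = json.dumps({k: v for k, v in cfg.__dict__.items() if k != "out_dir"},
                      sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> str:
    """Run every configured stage; returns the run directory.

    On stage failure a FAILED marker naming the stage is written next to the
    partial outputs and the exception propagates.
    """
    cfg.validate()
    os.makedirs(cfg.out_dir, exist_ok=True)
    stage = "init"
    manifest = {
        "config": {k: v for k, v in cfg.__dict__.items() if k != "out_dir"},
        "config_digest": _config_digest(cfg),
        "stages": {},
    }
    try:
        t0 = time.time()
        if cfg.simulate is not None:
            stage = "simulate"
            sim_kwargs = dict(cfg.simulate)
            sim_kwargs.setdefault("seed", _stage_seed(cfg.seed, "simulate"))
            sim_cfg = SimConfig(**sim_kwargs)
            cm, metadata, truth = generate_dataset(sim_cfg)
            sim_dir = os.path.join(cfg.out_dir, "simulated")
            eio.write_tenx_mtx(cm, sim_dir)
            eio.write_cell_metadata(metadata, os.path.join(sim_dir, "metadata.tsv"))
            truth.to_csv(os.path.join(sim_dir, "truth.tsv"), sep="\t", index=False)
            manifest["stages"]["simulate"] = {
                "n_cells": cm.n_cells, "n_genes": cm.n_genes,
                "n_effects": len(truth), "seed": sim_kwargs["seed"],
            }
        else:
            stage = "load"
            cm = eio.read_tenx_mtx(cfg.input_dir)
            metadata = eio.read_cell_metadata(cfg.metadata_path,
                                              barcodes=cm.cell_barcodes)
            manifest["stages"]["load"] = {
                "n_cells": cm.n_cells, "n_genes": cm.n_genes,
                "n_unknown_barcodes": metadata.attrs.get("n_unknown_barcodes", 0),
            }

        stage = "qc"
        cm_qc, report = apply_qc_filters(
            cm, cfg.min_cells_per_gene, cfg.min_genes_per_cell, cfg.max_mito_frac
        )
        eio.write_qc_report(report, os.path.join(cfg.out_dir, "qc_report.json"))
        bc_keep = set(cm_qc.cell_barcodes)
        metadata = validate_metadata(
            metadata[metadata["barcode"].isin(bc_keep)], cm_qc.cell_barcodes
        )
        # align metadata rows to matrix order
        order = {b: i for i, b in enumerate(metadata["barcode"])}
        metadata = metadata.iloc[
            [order[b] for b in cm_qc.cell_barcodes]
        ].reset_index(drop=True)
        manifest["stages"]["qc"] = {
            "n_cells": cm_qc.n_cells, "n_genes": cm_qc.n_genes,
        }

        stage = "normalize"
        expr = normalize_sqrt(cm_qc, target_sum=cfg.target_sum)
        layer = "normalized_sqrt"
        if cfg.use_imputed:
            stage = "impute"
            emb = compute_pca(expr, n_components=min(cfg.n_pcs,
                                                     expr.n_cells - 1,
                                                     expr.n_genes))
            graph = build_knn_graph(emb, metadata, k_per_group=cfg.k_per_group,
                                    balanced=cfg.balanced)
            expr = diffusion_impute(expr, graph, t=cfg.diffusion_t)
            layer = "imputed"
            manifest["stages"]["impute"] = {
                "n_pcs": emb.n_components, "k_per_group": cfg.k_per_group,
                "t": cfg.diffusion_t,
            }

        stage = "de"
        cell_types = sorted(metadata["cell_type"].unique())
        results = []
        de_dir = os.path.join(cfg.out_dir, "de")
        os.makedirs(de_dir, exist_ok=True)
        sub_seed = _stage_seed(cfg.seed, "subsample") if cfg.subsample else None
        for spec in cfg.contrasts:
            cts = [spec["cell_type"]] if spec.get("cell_type") else cell_types
            for ct in cts:
                contrast = Contrast(
                    cell_type=ct,
                    group_ref=spec["group_ref"],
                    group_alt=spec["group_alt"],
                    layer=layer,
                    subsample_seed=sub_seed,
                    min_cells_per_group=cfg.min_cells_per_group,
                )
                res = EMDDifferentialExpression(
                    expr, metadata, contrast,
                    emd_min=cfg.emd_min, p_max=cfg.p_max,
                    pseudocount=cfg.pseudocount,
                ).fit()
                if res is None:
                    continue
                results.append(res)
                eio.write_de_table(
                    res.table, os.path.join(de_dir, f"{contrast.name}.tsv")
                )
        summary = summarize_deg_counts(results)
        summary.to_csv(os.path.join(cfg.out_dir, "deg_summary.tsv"),
                       sep="\t", index=False)
        manifest["stages"]["de"] = {
            "n_contrasts": len(results),
            "n_degs_total": int(summary["n_total"].sum()) if len(summary) else 0,
        }

        if cfg.gmt_path:
            stage = "enrich"
            collection = eio.read_gmt(cfg.gmt_path)
            enr_dir = os.path.join(cfg.out_dir, "enrichment")
            os.makedirs(enr_dir, exist_ok=True)
            n_sig = 0
            for res in results:
                universe = set(res.table["gene_name"])
                degs = set(res.degs["gene_name"])
                enr = ora_gmt(degs, universe, collection, alpha=cfg.alpha)
                enr.to_csv(
                    os.path.join(enr_dir, f"{res.contrast.name}.tsv"),
                    sep="\t", index=False, float_format="%.17g",
                )
                n_sig += int(enr["significant"].sum()) if len(enr) else 0
            manifest["stages"]["enrich"] = {"n_significant_terms": n_sig}

        stage = "distance"
        emb_d = compute_pca(expr, n_components=min(cfg.distance_pcs,
                                                   expr.n_cells - 1,
                                                   expr.n_genes))
        pop = PopulationDistance.from_embedding(emb_d, metadata,
                                                linkage=cfg.linkage)
        pop.distance_frame().to_csv(
            os.path.join(cfg.out_dir, "population_distance.tsv"), sep="\t",
            float_format="%.17g",
        )
        pop.merge_frame().to_csv(
            os.path.join(cfg.out_dir, "population_merges.tsv"), sep="\t",
            index=False, float_format="%.17g",
        )
        with open(os.path.join(cfg.out_dir, "population_tree.nwk"), "w") as fh:
            fh.write(pop.to_newick() + "\n")
        manifest["stages"]["distance"] = {"n_populations": len(pop.labels)}

        logger.info("pipeline finished in %.1fs", time.time() - t0)
        with open(os.path.join(cfg.out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
        return cfg.out_dir
    except Exception:
        with open(os.path.join(cfg.out_dir, "FAILED"), "w") as fh:
            fh.write(f"stage: {stage}\n")
        raise
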