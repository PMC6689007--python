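"""End-to-end orchestration of the potency-landscape workflow.

Stages run in a fixed order — QC, normalization, entropy rates,
potency states, embedding + clustering + cell-states + densities,
root + diffusion pseudotime, optional potency-associated differential
expression — each stage recording its parameters, shapes and headline
numbers in a machine-readable report.  All randomness is governed by
explicit per-stage seeds, so a config reruns to identical results.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as _io
from .entropy import sr_profile
from .landscape import (
    cell_state_table,
    cluster_embedding,
    density_surface,
    embed_cells,
)
from .network import read_edge_list
from .potency import infer_potency_states
from .preprocess import normalize_fpkm, normalize_library, qc_filter, select_hvg
from .signatures import de_vs_potency
from .trajectory import diffusion_map, diffusion_pseudotime, find_tips, select_root

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "StageRecord", "run_pipeline", "export_report"]


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    expression_path: str | None = None
    network_path: str | None = None
    output_dir: str = "pipeline_out"
    input_kind: str = "counts"           # counts | fpkm | normalized
    mito: str = "MT-"
    min_genes: int = 1000
    max_mito: float = 0.05
    hvg_mean: float = 1.0
    hvg_sd: float = 1.0
    k_max: int = 6
    initial_dims: int = 30
    perplexity: float = 30.0
    tsne_max_iter: int = 1000
    eps: float = 5.0
    min_pts: int = 15
    min_cells: int = 5
    grid_size: int = 100
    k_neighbors: int = 30
    n_dcs: int = 10
    run_signatures: bool = False
    seed: int = 0
    seeds: dict = field(default_factory=dict)  # per-stage overrides

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def stage_seed(self, stage: str) -> int:
        return int(self.seeds.get(stage, self.seed))

    def validate(self) -> None:
        if self.expression_path is None:
            raise ValueError("expression_path is required")
        if not Path(self.expression_path).exists():
            raise ValueError(f"expression path not found: {self.expression_path}")
        if self.network_path is None:
            raise ValueError("network_path is required (entropy-rate stage)")
        if not Path(self.network_path).exists():
            raise ValueError(f"network path not found: {self.network_path}")
        if self.input_kind not in ("counts", "fpkm", "normalized"):
            raise ValueError(f"unknown input_kind {self.input_kind!r}")
        if self.min_genes < 0 or not 0 <= self.max_mito <= 1:
            raise ValueError("invalid QC thresholds")
        if self.k_max < 1 or self.k_neighbors < 1 or self.n_dcs < 1:
            raise ValueError("k_max, k_neighbors and n_dcs must be positive")


@dataclass
class StageRecord:
    name: str
    params: dict
    shapes: dict
    headline: dict
    runtime_s: float
    status: str = "ok"
    warnings: list = field(default_factory=list)


@dataclass
class RunReport:
    stages: list = field(default_factory=list)
    headline: dict = field(default_factory=dict)
    failed_stage: str | None = None

    def add(self, record: StageRecord) -> None:
        self.stages.append(record)

    def to_dict(self) -> dict:
        return {
            "headline": self.headline,
            "failed_stage": self.failed_stage,
            "stages": [asdict(s) for s in self.stages],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunReport":
        rep = cls(headline=data["headline"], failed_stage=data["failed_stage"])
        rep.stages = [StageRecord(**s) for s in data["stages"]]
        return rep


class _Timer:
    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, *exc):
        self.elapsed = time.perf_counter() - self.t0


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full workflow described by ``config``.

    Artifacts (TSV tables, density grids) are written under
    ``config.output_dir``.  A stage failure stops execution, leaves the
    completed stages' artifacts on disk, and is recorded in the
    returned report.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    state: dict = {}

    stages = [
        ("qc", _stage_qc),
        ("normalize", _stage_normalize),
        ("entropy", _stage_entropy),
        ("potency", _stage_potency),
        ("landscape", _stage_landscape),
        ("trajectory", _stage_trajectory),
    ]
    if config.run_signatures:
        stages.append(("signatures", _stage_signatures))

    for name, fn in stages:
        with _Timer() as timer:
            try:
                record = fn(config, state, outdir)
            except Exception as exc:  # noqa: BLE001 - report and stop
                logger.exception("stage %s failed", name)
                report.add(
                    StageRecord(
                        name=name,
                        params={},
                        shapes={},
                        headline={"error": str(exc)},
                        runtime_s=time.perf_counter() - timer.t0,
                        status="failed",
                    )
                )
                report.failed_stage = name
                export_report(report, outdir / "report.json", "json")
                return report
        record.runtime_s = timer.elapsed
        report.add(record)

    report.headline = {
        "cells_kept": state.get("cells_kept"),
        "n_hvg": state.get("n_hvg"),
        "K": state.get("K"),
        "state_sizes": state.get("state_sizes"),
        "root_cell": state.get("root_cell"),
        "tip_cells": state.get("tip_cells"),
    }
    export_report(report, outdir / "report.json", "json")
    return report


def _stage_qc(config: RunConfig, state: dict, outdir: Path) -> StageRecord:
    if config.input_kind != "counts":
        expr = _io.read_expression(config.expression_path)
        state["raw"] = expr
        state["cells_kept"] = expr.shape[1]
        return StageRecord(
            name="qc",
            params={"skipped": f"input_kind={config.input_kind}"},
            shapes={"input": list(expr.shape)},
            headline={"cells_kept": expr.shape[1]},
            runtime_s=0.0,
        )
    cm = _io.read_counts(config.expression_path, mito=config.mito)
    filtered, qcrep = qc_filter(cm, min_genes=config.min_genes, max_mito=config.max_mito)
    qcrep.to_tsv(outdir / "qc_report.tsv")
    state["counts"] = filtered
    state["cells_kept"] = filtered.n_cells
    return StageRecord(
        name="qc",
        params={"min_genes": config.min_genes, "max_mito": config.max_mito},
        shapes={"input": [cm.n_genes, cm.n_cells], "output": [filtered.n_genes, filtered.n_cells]},
        headline={"cells_kept": filtered.n_cells},
        runtime_s=0.0,
    )


def _stage_normalize(config: RunConfig, state: dict, outdir: Path) -> StageRecord:
    if config.input_kind == "counts":
        expr = normalize_library(state["counts"])
    elif config.input_kind == "fpkm":
        expr = normalize_fpkm(state["raw"])
    else:
        raw = state["raw"]
        from .preprocess import NormalizedExpressionMatrix

        expr = NormalizedExpressionMatrix.from_frame(raw, provenance="precomputed")
    state["expr"] = expr
    return StageRecord(
        name="normalize",
        params={"input_kind": config.input_kind, "provenance": expr.provenance},
        shapes={"output": [expr.n_genes, expr.n_cells]},
        headline={},
        runtime_s=0.0,
    )


def _stage_entropy(config: RunConfig, state: dict, outdir: Path) -> StageRecord:
    net = read_edge_list(config.network_path)
    profile = sr_profile(state["expr"], net)
    profile.to_frame().to_csv(outdir / "sr_profile.tsv", sep="\t", index=False)
    state["sr"] = profile
    return StageRecord(
        name="entropy",
        params={"network": config.network_path},
        shapes={"network_nodes": profile.n_genes_used, "cells": len(profile.sr)},
        headline={"max_sr": profile.max_sr, "mean_SR": float(np.mean(profile.srn))},
        runtime_s=0.0,
    )


def _stage_potency(config: RunConfig, state: dict, outdir: Path) -> StageRecord:
    profile = state["sr"]
    model = infer_potency_states(
        profile.logit_sr, k_max=config.k_max, seed=config.stage_seed("potency")
    )
    df = model.to_frame(profile.logit_sr)
    df.insert(0, "cell_id", profile.cell_ids)
    df.to_csv(outdir / "potency_states.tsv", sep="\t", index=False)
    sizes = {f"PS{k}": int((model.labels == k).sum()) for k in range(1, model.k + 1)}
    state["potency"] = model
    state["K"] = model.k
    state["state_sizes"] = sizes
    return StageRecord(
        name="potency",
        params={"k_max": config.k_max, "seed": config.stage_seed("potency")},
        shapes={"cells": len(model.labels)},
        headline={"K": model.k, "state_sizes": sizes},
        runtime_s=0.0,
    )


def _stage_landscape(config: RunConfig, state: dict, outdir: Path) -> StageRecord:
    expr = state["expr"]
    hvg = select_hvg(expr, mean_thresh=config.hvg_mean, sd_thresh=config.hvg_sd)
    if len(hvg) < 2:
        hvg = list(expr.gene_ids)  # degenerate fixtures: fall back to all genes
    expr_hvg = expr.subset_genes(hvg)
    state["n_hvg"] = len(hvg)
    state["expr_hvg"] = expr_hvg
    perplexity = min(config.perplexity, max(2.0, (expr.n_cells - 1) / 3.0))
    emb = embed_cells(
        expr_hvg,
        initial_dims=config.initial_dims,
        perplexity=perplexity,
        max_iter=config.tsne_max_iter,
        seed=config.stage_seed("embedding"),
    )
    labels = cluster_embedding(emb.coords, eps=config.eps, min_pts=config.min_pts)
    model = state["potency"]
    table = cell_state_table(labels, model.labels, min_cells=config.min_cells)
    pd.DataFrame(
        {"cell_id": state["sr"].cell_ids, "x": emb.coords[:, 0], "y": emb.coords[:, 1],
         "cluster": labels}
    ).to_csv(outdir / "embedding.tsv", sep="\t", index=False)
    table.counts.to_csv(outdir / "cell_state_table.tsv", sep="\t")
    grids = {}
    for k in range(1, model.k + 1):
        mask = model.labels == k
        if mask.sum() >= 2:
            grids[f"PS{k}"] = density_surface(
                emb.coords, mask, grid_size=config.grid_size
            )
    np.savez(
        outdir / "density_grids.npz",
        **{name: g.grid for name, g in grids.items()},
    )
    state["embedding"] = emb
    state["clusters"] = labels
    state["cell_states"] = table
    return StageRecord(
        name="landscape",
        params={**emb.params, "eps": config.eps, "min_pts": config.min_pts,
                "min_cells": config.min_cells},
        shapes={"hvg": len(hvg), "cells": len(labels)},
        headline={
            "n_clusters": int(labels.max()),
            "n_peripheral": int((labels == 0).sum()),
            "n_cell_states": len(table.cell_states),
        },
        runtime_s=0.0,
    )


def _stage_trajectory(config: RunConfig, state: dict, outdir: Path) -> StageRecord:
    profile = state["sr"]
    root = select_root(profile)
    k = min(config.k_neighbors, state["expr_hvg"].n_cells - 1)
    dmap = diffusion_map(state["expr_hvg"], k=k, n_dcs=config.n_dcs)
    dpt = diffusion_pseudotime(dmap, root)
    tips = find_tips(dpt, state.get("clusters"))
    pd.DataFrame(
        {
            "cell_id": profile.cell_ids,
            "dpt": dpt,
            **{f"DC{i+1}": dmap.components[:, i] for i in range(dmap.components.shape[1])},
        }
    ).to_csv(outdir / "trajectory.tsv", sep="\t", index=False)
    state["root"] = root
    state["root_cell"] = str(profile.cell_ids[root])
    state["tip_cells"] = {
        "global": str(profile.cell_ids[tips.global_tip]),
        **{str(c): str(profile.cell_ids[i]) for c, i in tips.cluster_tips.items()},
    }
    state["dpt"] = dpt
    return StageRecord(
        name="trajectory",
        params={"k": k, "n_dcs": config.n_dcs},
        shapes={"cells": len(dpt), "n_dcs": dmap.components.shape[1]},
        headline={"root_cell": state["root_cell"], "tip_cells": state["tip_cells"]},
        runtime_s=0.0,
    )


def _stage_signatures(config: RunConfig, state: dict, outdir: Path) -> StageRecord:
    expr = state["expr"]
    de = de_vs_potency(expr, state["sr"].srn, min_cells=min(10, expr.n_cells))
    de.to_csv(outdir / "de_vs_potency.tsv", sep="\t")
    n_sig = int((de["p_bonf"] < 0.05).sum())
    return StageRecord(
        name="signatures",
        params={"response": "SR"},
        shapes={"genes_tested": int(np.isfinite(de["p"]).sum())},
        headline={"n_significant_bonf": n_sig},
        runtime_s=0.0,
    )


def export_report(report: RunReport, path: str | Path, fmt: str = "json") -> Path:
    """Serialize a run report to JSON (lossless) or TSV (one stage/row)."""
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(report.to_dict(), indent=2, default=_json_default))
    elif fmt == "tsv":
        rows = [
            {
                "stage": s.name,
                "status": s.status,
                "runtime_s": round(s.runtime_s, 4),
                "params": json.dumps(s.params, default=_json_default),
                "headline": json.dumps(s.headline, default=_json_default),
            }
            for s in report.stages
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown report format {fmt!r}")
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
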