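"""End-to-end pipeline: score → regress → cluster → rank.

A :class:`RunConfig` (YAML-loadable, unknown keys rejected) drives the full
analysis and writes a deterministic artefact set: score matrices, switch
points, therapeutic-cluster labels, the 2-D embedding, the rank table, plots
and a JSON manifest recording package version, parameters, seed and input
checksums.  Re-running the same configuration reproduces every numeric
output bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import find_clusters, reduce_scores
from .io import read_expression, read_gmt, save_scores
from .rank import bc_stats, four_squares, rank_differential
from .regress import regress_out
from .scoring import bc_score

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Parameters for every pipeline stage.

    ``expression``/``gmt`` are input paths; ``metadata`` an optional per-cell
    TSV (cell_id column first) carrying covariates and condition labels.
    ``covariates`` empty disables regression (the rank stage then falls back
    to scaled scores with a warning).
    """

    expression: str = ""
    gmt: str = ""
    output_dir: str = "therascore_out"
    metadata: str | None = None
    expression_format: str = "tsv"
    cells_in_rows: bool | None = None
    seed: int = 0
    # scoring
    winsor: tuple[float, float] = (1.0, 99.0)
    coverage_floor: float = 0.1
    # regression
    covariates: list[str] = field(default_factory=list)
    knn_k: int = 10
    # clustering
    cluster_on: str = "auto"  # residuals when regression ran, else scaled
    n_pcs: int = 20
    cluster_method: str = "graph_community"
    resolution: float = 0.4
    kmeans_k: int | None = None
    n_neighbors: int = 15
    embed: bool = True
    # ranking
    condition: str | None = None  # metadata column with 2 levels
    sp_cuts: tuple[float, float] = (0.1, 0.9)
    res_quantile: float = 0.9
    n_perm: int = 1000
    plots: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["winsor"] = list(self.winsor)
        d["sp_cuts"] = list(self.sp_cuts)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _plot_embedding(embedding: pd.DataFrame, labels: pd.Series, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for lbl in sorted(pd.unique(labels)):
        pts = embedding[labels == lbl]
        ax.scatter(pts.iloc[:, 0], pts.iloc[:, 1], s=8, label=f"TC{lbl}")
    ax.set_xlabel(embedding.columns[0])
    ax.set_ylabel(embedding.columns[1])
    ax.legend(markerscale=2, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_four_squares(table: pd.DataFrame, group, sp_cuts, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    colors = {
        "bottom_right_most_sensitive": "tab:green",
        "top_left_least_sensitive": "tab:red",
        "differentially_sensitive": "tab:blue",
        "differentially_insensitive": "tab:orange",
        "unclassified": "lightgrey",
    }
    for quadrant, sub in table.groupby("quadrant"):
        ax.scatter(
            sub["residuals_mean"], sub["switch_point"],
            s=14, c=colors.get(quadrant, "black"), label=quadrant,
        )
    for y in sp_cuts:
        ax.axhline(y, ls="--", lw=0.6, c="grey")
    ax.set_xlabel("residuals' mean")
    ax.set_ylabel("switch point")
    ax.set_ylim(-0.05, 1.05)
    ax.set_title(f"group {group}")
    ax.legend(fontsize=6, loc="center left", bbox_to_anchor=(1.0, 0.5))
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> Path:
    """Run score → regress → cluster → rank and write all artefacts.

    Inputs are validated before any computation; a failing stage aborts with
    the stage name in the exception message.  Returns the output directory.
    """
    expr_path = Path(config.expression)
    gmt_path = Path(config.gmt)
    for label, p in (("expression", expr_path), ("gmt", gmt_path)):
        if not p.exists():
            raise FileNotFoundError(f"{label} input not found: {p}")
    meta = None
    if config.metadata:
        meta_path = Path(config.metadata)
        if not meta_path.exists():
            raise FileNotFoundError(f"metadata input not found: {meta_path}")
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        meta.index = meta.index.astype(str)
    if config.covariates and meta is None:
        raise ValueError("covariates requested but no metadata table given")
    if config.condition and meta is None:
        raise ValueError("condition requested but no metadata table given")

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("score")
        expr = read_expression(
            expr_path, config.expression_format, cells_in_rows=config.cells_in_rows
        )
        collection = read_gmt(gmt_path)
        scores = bc_score(
            expr, collection, tuple(config.winsor),
            coverage_floor=config.coverage_floor,
        )
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage 'score': {e}") from e

    regressed = False
    if config.covariates:
        try:
            stage("regress")
            scores = regress_out(scores, meta, list(config.covariates),
                                 k=config.knn_k)
            regressed = True
        except Exception as e:
            raise RuntimeError(f"pipeline failed at stage 'regress': {e}") from e

    try:
        stage("cluster")
        use = config.cluster_on
        if use == "auto":
            use = "residuals" if regressed else "scaled"
        reduction = reduce_scores(
            scores, use=use, n_pcs=config.n_pcs, seed=config.seed,
            embed=config.embed, n_neighbors=config.n_neighbors,
        )
        tcs = find_clusters(
            reduction, method=config.cluster_method,
            resolution=config.resolution, k=config.kmeans_k,
            seed=config.seed, n_neighbors=config.n_neighbors,
        )
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage 'cluster': {e}") from e

    try:
        stage("rank")
        table = bc_stats(scores, tcs.labels)
        if regressed:
            for g in sorted(pd.unique(tcs.labels)):
                table = four_squares(
                    table, g, tuple(config.sp_cuts), config.res_quantile
                )
        differential = None
        if config.condition:
            cond = meta[config.condition].reindex(scores.cell_ids)
            if not regressed:
                warnings.warn(
                    "regression disabled: differential ranking falls back to "
                    "scaled scores"
                )
            differential = rank_differential(
                scores, cond, n_perm=config.n_perm, seed=config.seed
            )
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage 'rank': {e}") from e

    stage("write")
    save_scores(scores, outdir)
    tcs.labels.to_frame().to_csv(outdir / "tc_labels.tsv", sep="\t",
                                 index_label="cell_id")
    if tcs.embedding is not None:
        tcs.embedding.to_csv(outdir / "embedding.tsv", sep="\t",
                             index_label="cell_id")
    table.table.to_csv(outdir / "rank_table.tsv", sep="\t")
    if differential is not None:
        differential.to_csv(outdir / "differential.tsv", sep="\t")
    if config.plots:
        if tcs.embedding is not None:
            _plot_embedding(tcs.embedding, tcs.labels, outdir / "umap_tc.png")
        if regressed:
            g0 = sorted(pd.unique(tcs.labels))[0]
            _plot_four_squares(
                table.for_group(g0), g0, config.sp_cuts,
                outdir / f"four_squares_tc{g0}.png",
            )

    manifest = {
        "package": "therascore",
        "version": __version__,
        "seed": config.seed,
        "parameters": config.to_dict(),
        "inputs": {
            "expression": {"path": str(expr_path), "sha256": _sha256(expr_path)},
            "gmt": {"path": str(gmt_path), "sha256": _sha256(gmt_path)},
            **(
                {"metadata": {"path": str(config.metadata),
                              "sha256": _sha256(Path(config.metadata))}}
                if config.metadata else {}
            ),
        },
        "n_cells": len(scores.cell_ids),
        "n_signatures": len(scores.signature_names),
        "n_clusters": int(tcs.n_clusters),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir
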