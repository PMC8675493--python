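"""Readers and writers for expression matrices and signature collections.

Supported formats: dense TSV (cells × genes, or transposed), MatrixMarket
coordinate triplets with ``genes.txt``/``barcodes.txt`` sidecars, and standard
GMT (one gene set per line: name, description, genes, tab-separated).
Bidirectional signatures are stored as two GMT lines sharing a base name with
``_UP``/``_DN`` suffixes.

Gene identifier matching throughout the package is exact and case-sensitive;
an optional ``uppercase`` flag folds ids to upper case at read time for users
mixing symbol conventions.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datatypes import (
    ExpressionMatrix,
    GeneSignature,
    ScoreMatrix,
    SignatureCollection,
    SignatureMode,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_ranked_matrix",
    "save_scores",
    "load_scores",
]


def _read_id_file(path: Path) -> list[str]:
    with open(path) as fh:
        ids = [line.strip() for line in fh if line.strip()]
    if not ids:
        raise ValueError(f"empty identifier file: {path}")
    return ids


def read_expression(
    path,
    fmt: str = "tsv",
    *,
    cells_in_rows: bool | None = None,
    genes_file=None,
    cells_file=None,
    uppercase: bool = False,
) -> ExpressionMatrix:
    """Read a normalised expression matrix from TSV or MatrixMarket triplet.

    Parameters
    ----------
    path
        TSV file with row/column labels, or a ``.mtx`` coordinate file with
        ``genes.txt`` and ``barcodes.txt`` sidecars next to it (override with
        ``genes_file``/``cells_file``).
    fmt
        ``"tsv"`` or ``"mtx_triplet"``.
    cells_in_rows
        Orientation of the input.  Defaults to ``True`` for TSV and ``False``
        for MatrixMarket (genes × cells, the usual 10x layout).  The returned
        matrix is always cells × genes.
    uppercase
        Fold gene ids to upper case (default off; matching is exact).

    Raises
    ------
    ValueError
        On duplicate identifiers (the duplicates are named) or non-numeric
        entries (the offending row/column is reported).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "tsv":
        if cells_in_rows is None:
            cells_in_rows = True
        # pandas silently renames duplicate header fields; check them raw
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
        from .datatypes import _find_duplicates

        dup_cols = _find_duplicates(header)
        if dup_cols:
            raise ValueError(f"duplicate column ids in {path}: {dup_cols[:10]}")
        # keep_default_na=False so "NA"/"" surface as validation errors with
        # coordinates instead of silently becoming NaN
        df = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False, dtype=str)
        values = np.empty(df.shape, dtype=float)
        for j, col in enumerate(df.columns):
            raw = df[col].to_numpy()
            try:
                # str->float via float(): exact round-trip of written values
                values[:, j] = raw.astype(np.float64)
            except ValueError:
                for i, entry in enumerate(raw):
                    try:
                        float(entry)
                    except ValueError:
                        raise ValueError(
                            f"non-numeric entry {entry!r} at row "
                            f"{df.index[i]!r}, column {col!r} in {path}"
                        ) from None
                raise
        row_ids, col_ids = list(df.index.astype(str)), list(df.columns.astype(str))
    elif fmt == "mtx_triplet":
        if cells_in_rows is None:
            cells_in_rows = False
        genes_file = Path(genes_file) if genes_file else path.parent / "genes.txt"
        cells_file = Path(cells_file) if cells_file else path.parent / "barcodes.txt"
        for side in (genes_file, cells_file):
            if not side.exists():
                raise FileNotFoundError(f"missing sidecar file: {side}")
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        values = np.asarray(mat, dtype=float)
        genes = _read_id_file(genes_file)
        cells = _read_id_file(cells_file)
        if cells_in_rows:
            row_ids, col_ids = cells, genes
        else:
            row_ids, col_ids = genes, cells
        if values.shape != (len(row_ids), len(col_ids)):
            raise ValueError(
                f"matrix shape {values.shape} does not match sidecars "
                f"({len(genes)} genes, {len(cells)} cells)"
            )
    else:
        raise ValueError(f"unknown expression format: {fmt!r}")

    if not cells_in_rows:
        values = values.T
        row_ids, col_ids = col_ids, row_ids
    if uppercase:
        col_ids = [g.upper() for g in col_ids]
    return ExpressionMatrix(values, row_ids, col_ids)


def write_expression(expr: ExpressionMatrix, path) -> None:
    """Write an expression matrix as a cells × genes TSV."""
    expr.to_frame().to_csv(path, sep="\t", index_label="cell_id")


def _strip_suffix(name: str, suffixes: tuple[str, str]) -> tuple[str, str | None]:
    up_sfx, dn_sfx = suffixes
    if name.endswith(up_sfx) and len(name) > len(up_sfx):
        return name[: -len(up_sfx)], "up"
    if name.endswith(dn_sfx) and len(name) > len(dn_sfx):
        return name[: -len(dn_sfx)], "dn"
    return name, None


def read_gmt(
    path,
    pairing_suffixes: tuple[str, str] = ("_UP", "_DN"),
    *,
    collection_tag: str = "custom",
    name: str | None = None,
    uppercase: bool = False,
) -> SignatureCollection:
    """Read a GMT file, pairing ``_UP``/``_DN`` gene sets into signatures.

    Gene sets whose names differ only by the pairing suffix are merged into a
    bidirectional signature; unpaired sets become ``up_only`` (``dn_only``
    when carrying the DN suffix).  Duplicate genes within a set are removed
    with a warning; a line with fewer than three fields is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # base name -> {"up": set|None, "dn": set|None}; dict preserves order
    parsed: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one gene ({len(fields)} fields found)"
                )
            set_name, _desc, *genes = fields
            genes = [g for g in genes if g]
            if uppercase:
                genes = [g.upper() for g in genes]
            if len(set(genes)) < len(genes):
                dup = sorted({g for g in genes if genes.count(g) > 1})
                warnings.warn(
                    f"{path}:{lineno}: duplicate genes in {set_name!r} "
                    f"deduplicated: {dup[:5]}"
                )
            base, side = _strip_suffix(set_name, pairing_suffixes)
            entry = parsed.setdefault(base, {"up": None, "dn": None})
            slot = "dn" if side == "dn" else "up"
            if entry[slot] is not None:
                raise ValueError(
                    f"{path}:{lineno}: signature name collision for {base!r} "
                    f"({slot.upper()} set defined twice)"
                )
            entry[slot] = frozenset(genes)
            entry.setdefault("side", side)

    signatures = []
    for base, entry in parsed.items():
        up, dn = entry["up"], entry["dn"]
        if up and dn:
            mode = SignatureMode.BIDIRECTIONAL
        elif dn:
            mode = SignatureMode.DN_ONLY
        else:
            mode = SignatureMode.UP_ONLY
        signatures.append(
            GeneSignature(base, up or frozenset(), dn or frozenset(), mode,
                          collection_tag)
        )
    return SignatureCollection(signatures, name=name or path.stem)


def write_gmt(
    collection: SignatureCollection,
    path,
    pairing_suffixes: tuple[str, str] = ("_UP", "_DN"),
) -> None:
    """Write a collection as GMT; a bidirectional signature spans two lines.

    Round-trips with :func:`read_gmt` up to gene ordering (genes are written
    sorted for determinism).
    """
    up_sfx, dn_sfx = pairing_suffixes
    with open(path, "w") as fh:
        for sig in collection:
            desc = sig.collection_tag
            if sig.mode is SignatureMode.BIDIRECTIONAL:
                fh.write("\t".join([sig.name + up_sfx, desc, *sorted(sig.up_genes)]) + "\n")
                fh.write("\t".join([sig.name + dn_sfx, desc, *sorted(sig.dn_genes)]) + "\n")
            elif sig.mode is SignatureMode.UP_ONLY:
                fh.write("\t".join([sig.name, desc, *sorted(sig.up_genes)]) + "\n")
            else:
                fh.write("\t".join([sig.name + dn_sfx, desc, *sorted(sig.dn_genes)]) + "\n")


def cut_top_bottom(
    stats: pd.Series, n_top: int
) -> tuple[frozenset[str], frozenset[str]]:
    """Top/bottom ``n_top`` gene ids of a ranking statistic.

    NaN statistics are excluded.  Ties at the top cut are broken towards the
    lexicographically smaller gene id, ties at the bottom cut towards the
    larger one, so the two tails stay disjoint even under mass ties.
    """
    finite = stats[np.isfinite(stats.to_numpy(dtype=float))]
    if 2 * n_top > len(finite):
        raise ValueError(
            f"need at least {2 * n_top} genes with finite statistics, "
            f"have {len(finite)}"
        )
    order_up = finite.to_frame("stat").assign(gene=finite.index.astype(str))
    up = order_up.sort_values(["stat", "gene"], ascending=[False, True])
    dn = order_up.sort_values(["stat", "gene"], ascending=[True, False])
    up_genes = frozenset(up.index[:n_top].astype(str))
    dn_genes = frozenset(dn.index[:n_top].astype(str))
    return up_genes, dn_genes


def read_ranked_matrix(
    path,
    n_top: int,
    *,
    collection_tag: str = "custom",
    name: str | None = None,
) -> SignatureCollection:
    """Cut top-N UP / bottom-N DN gene sets from a genes × signatures TSV.

    The TSV holds a ranking statistic per (gene, signature) — larger means
    more upregulated.  Genes with NaN statistics are excluded per signature;
    a signature with fewer than ``2·n_top`` finite genes is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    dups = df.index[df.index.duplicated()].unique().tolist()
    if dups:
        raise ValueError(f"duplicate gene ids in ranked matrix: {dups[:10]}")
    signatures = []
    for col in df.columns:
        up, dn = cut_top_bottom(df[col].astype(float), n_top)
        signatures.append(
            GeneSignature(str(col), up, dn, SignatureMode.BIDIRECTIONAL,
                          collection_tag)
        )
    return SignatureCollection(signatures, name=name or path.stem)


# -- score-matrix persistence (TSV artefacts used by the CLI stages) ---------

_SCORE_FILES = {
    "scaled": "scores_scaled.tsv",
    "normalised": "scores_normalised.tsv",
    "residuals": "scores_residuals.tsv",
    "stats": "signature_stats.tsv",
}


def save_scores(scores: ScoreMatrix, outdir) -> None:
    """Write a ScoreMatrix as a directory of TSV artefacts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scores.scaled.to_csv(outdir / _SCORE_FILES["scaled"], sep="\t",
                         index_label="cell_id")
    scores.normalised.to_csv(outdir / _SCORE_FILES["normalised"], sep="\t",
                             index_label="cell_id")
    if scores.residuals is not None:
        scores.residuals.to_csv(outdir / _SCORE_FILES["residuals"], sep="\t",
                                index_label="cell_id")
    stats = pd.DataFrame({"switch_point": scores.switch_points})
    if scores.coverage is not None:
        stats["coverage"] = scores.coverage
    stats["flagged"] = [s in set(scores.flagged) for s in stats.index]
    stats.to_csv(outdir / _SCORE_FILES["stats"], sep="\t", index_label="signature")


def load_scores(outdir) -> ScoreMatrix:
    """Read back a ScoreMatrix written by :func:`save_scores`."""
    outdir = Path(outdir)
    scaled = pd.read_csv(outdir / _SCORE_FILES["scaled"], sep="\t", index_col=0)
    normalised = pd.read_csv(outdir / _SCORE_FILES["normalised"], sep="\t",
                             index_col=0)
    stats = pd.read_csv(outdir / _SCORE_FILES["stats"], sep="\t", index_col=0)
    residuals = None
    res_path = outdir / _SCORE_FILES["residuals"]
    if res_path.exists():
        residuals = pd.read_csv(res_path, sep="\t", index_col=0)
    scaled.index = scaled.index.astype(str)
    normalised.index = normalised.index.astype(str)
    return ScoreMatrix(
        scaled=scaled,
        normalised=normalised,
        switch_points=stats["switch_point"],
        coverage=stats["coverage"] if "coverage" in stats else None,
        flagged=list(stats.index[stats.get("flagged", False) == True]),  # noqa: E712
        residuals=residuals,
    )
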