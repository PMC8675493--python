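"""Core data containers.

The containers here are deliberately thin: an expression matrix is a numpy
array plus cell/gene identifiers, a signature is a pair of gene sets, a score
matrix bundles the scaled scores with their switch points.  Validation happens
at construction so downstream numerical code can assume clean inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SignatureMode",
    "GeneSignature",
    "SignatureCollection",
    "ExpressionMatrix",
    "ScoreMatrix",
    "TherapeuticClusters",
    "RankTable",
    "PharmacoTable",
    "DrugSpecificity",
]


def _find_duplicates(ids: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for x in ids:
        if x in seen and x not in dups:
            dups.append(x)
        seen.add(x)
    return dups


class SignatureMode(str, Enum):
    """Directionality of a gene signature."""

    BIDIRECTIONAL = "bidirectional"
    UP_ONLY = "up_only"
    DN_ONLY = "dn_only"


@dataclass(frozen=True)
class GeneSignature:
    """A named signature with up- and/or down-regulated gene sets.

    Parameters
    ----------
    name
        Signature identifier, unique within a collection.
    up_genes, dn_genes
        Gene symbols most up-/down-regulated in the phenotype the signature
        describes.  For a drug-sensitivity signature "up" means higher in
        resistant (high-AUC) samples.
    mode
        Directionality; inferred from the gene sets when omitted.
    collection_tag
        Provenance of the signature: ``perturbation`` (control-vs-treated
        contrast), ``sensitivity`` (response-correlated), ``functional``
        (pathway) or ``custom``.
    """

    name: str
    up_genes: frozenset[str] = frozenset()
    dn_genes: frozenset[str] = frozenset()
    mode: SignatureMode | None = None
    collection_tag: str = "custom"

    def __post_init__(self) -> None:
        object.__setattr__(self, "up_genes", frozenset(self.up_genes))
        object.__setattr__(self, "dn_genes", frozenset(self.dn_genes))
        if self.mode is None:
            if self.up_genes and self.dn_genes:
                inferred = SignatureMode.BIDIRECTIONAL
            elif self.up_genes:
                inferred = SignatureMode.UP_ONLY
            elif self.dn_genes:
                inferred = SignatureMode.DN_ONLY
            else:
                raise ValueError(f"signature {self.name!r} has no genes")
            object.__setattr__(self, "mode", inferred)
        else:
            object.__setattr__(self, "mode", SignatureMode(self.mode))
        if self.mode is SignatureMode.BIDIRECTIONAL and not (
            self.up_genes and self.dn_genes
        ):
            raise ValueError(
                f"bidirectional signature {self.name!r} needs non-empty UP and DN sets"
            )
        if self.mode is SignatureMode.UP_ONLY and self.dn_genes:
            raise ValueError(f"up_only signature {self.name!r} has DN genes")
        if self.mode is SignatureMode.DN_ONLY and self.up_genes:
            raise ValueError(f"dn_only signature {self.name!r} has UP genes")
        overlap = self.up_genes & self.dn_genes
        if overlap:
            raise ValueError(
                f"signature {self.name!r}: genes in both UP and DN sets: "
                f"{sorted(overlap)[:5]}"
            )

    @property
    def genes(self) -> frozenset[str]:
        return self.up_genes | self.dn_genes

    def flipped(self) -> "GeneSignature":
        """Swap the UP and DN sets (direction antisymmetry helper)."""
        mode = {
            SignatureMode.BIDIRECTIONAL: SignatureMode.BIDIRECTIONAL,
            SignatureMode.UP_ONLY: SignatureMode.DN_ONLY,
            SignatureMode.DN_ONLY: SignatureMode.UP_ONLY,
        }[self.mode]
        return GeneSignature(
            self.name, self.dn_genes, self.up_genes, mode, self.collection_tag
        )


@dataclass
class SignatureCollection:
    """Ordered collection of uniquely named signatures."""

    signatures: list[GeneSignature]
    name: str = "collection"

    def __post_init__(self) -> None:
        dups = _find_duplicates([s.name for s in self.signatures])
        if dups:
            raise ValueError(f"duplicate signature names in {self.name!r}: {dups}")
        self._by_name = {s.name: s for s in self.signatures}

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.signatures]

    def __len__(self) -> int:
        return len(self.signatures)

    def __iter__(self) -> Iterator[GeneSignature]:
        return iter(self.signatures)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, key: str | int) -> GeneSignature:
        if isinstance(key, int):
            return self.signatures[key]
        return self._by_name[key]

    def subset(self, names: Sequence[str], name: str | None = None) -> "SignatureCollection":
        """Sub-collection restricted to ``names``, original order preserved."""
        missing = [n for n in names if n not in self._by_name]
        if missing:
            raise KeyError(f"signatures not in collection {self.name!r}: {missing}")
        keep = set(names)
        return SignatureCollection(
            [s for s in self.signatures if s.name in keep],
            name=name or f"{self.name}_subset",
        )


@dataclass
class ExpressionMatrix:
    """Cells × genes matrix of normalised (log-scale) expression.

    ``values[i, j]`` is the expression of gene ``gene_ids[j]`` in cell
    ``cell_ids[i]``.  Values must be finite; negative values are allowed
    (scaled data), zeros are meaningful (used for the dropout penalty).
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n_cells, n_genes = self.values.shape
        if n_cells != len(self.cell_ids) or n_genes != len(self.gene_ids):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cell ids × {len(self.gene_ids)} gene ids"
            )
        for label, ids in (("cell", self.cell_ids), ("gene", self.gene_ids)):
            dups = _find_duplicates(ids)
            if dups:
                raise ValueError(f"duplicate {label} ids: {dups[:10]}")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite expression value at cell {self.cell_ids[bad[0]]!r}, "
                f"gene {self.gene_ids[bad[1]]!r}"
            )
        self._gene_index = {g: j for j, g in enumerate(self.gene_ids)}

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_columns(self, genes) -> np.ndarray:
        """Column indices of the given genes that are present in the matrix."""
        return np.array(
            sorted(self._gene_index[g] for g in genes if g in self._gene_index),
            dtype=int,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))


@dataclass
class ScoreMatrix:
    """Per-cell, per-signature scores plus switch points.

    Attributes
    ----------
    scaled
        Cells × signatures scores rescaled to [0, 1] per signature (NaN when a
        signature has no gene in the matrix).
    normalised
        The signed net scores before rescaling: positive means above-typical
        activity of the UP direction.
    switch_points
        Per-signature value in [0, 1] where cells cross from the
        down-regulated to the up-regulated status.  0 = uniformly sensitive
        population, 1 = uniformly resistant, intermediate = heterogeneous.
    coverage
        Fraction of each signature's genes present in the expression matrix.
    flagged
        Signatures whose coverage fell below the configured floor.
    residuals
        Covariate-regressed scores (filled by :func:`therascore.regress.regress_out`).
    provenance
        Free-form parameter record (collection name, winsor limits, ...).
    """

    scaled: pd.DataFrame
    normalised: pd.DataFrame
    switch_points: pd.Series
    coverage: pd.Series | None = None
    flagged: list[str] = field(default_factory=list)
    residuals: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.scaled.columns) != list(self.normalised.columns):
            raise ValueError("scaled and normalised must share signature columns")
        if list(self.scaled.index) != list(self.normalised.index):
            raise ValueError("scaled and normalised must share cell index")
        if list(self.switch_points.index) != list(self.scaled.columns):
            raise ValueError("switch_points index must match signature columns")

    @property
    def cell_ids(self) -> list[str]:
        return list(self.scaled.index)

    @property
    def signature_names(self) -> list[str]:
        return list(self.scaled.columns)

    def validate(self) -> None:
        """Check the scoring invariants; raise AssertionError on violation."""
        s = self.scaled.to_numpy()
        finite = np.isfinite(s)
        if finite.any():
            assert (s[finite] >= -1e-12).all() and (s[finite] <= 1 + 1e-12).all(), (
                "scaled scores outside [0, 1]"
            )
        sp = self.switch_points.to_numpy()
        sp_fin = np.isfinite(sp)
        assert (sp[sp_fin] >= 0).all() and (sp[sp_fin] <= 1).all(), (
            "switch points outside [0, 1]"
        )
        net = self.normalised.to_numpy()
        assert (np.isnan(s) == np.isnan(net)).all(), (
            "scaled and normalised NaN patterns differ"
        )
        # net > 0 ⇔ scaled > SP, strict for interior SPs; at a clamped endpoint
        # (homogeneous population) the extreme cell sits exactly on the SP.
        for j, name in enumerate(self.signature_names):
            if not np.isfinite(sp[j]):
                continue
            col_fin = finite[:, j]
            if not col_fin.any():
                continue
            if 0.0 < sp[j] < 1.0:
                assert (
                    (net[col_fin, j] > 0) == (s[col_fin, j] > sp[j] + 1e-12)
                ).all() or np.allclose(net[col_fin, j], 0), (
                    f"sign consistency violated for {name!r}"
                )

    def replace(self, **kwargs) -> "ScoreMatrix":
        return replace(self, **kwargs)


@dataclass
class TherapeuticClusters:
    """Therapeutic clusters: cells grouped by shared drug response.

    ``labels`` holds integer cluster ids per cell (relabelled by decreasing
    cluster size; −1 is reserved for unassigned cells), ``embedding`` the 2-D
    coordinates used for visualisation.
    """

    labels: pd.Series
    embedding: pd.DataFrame | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.embedding is not None:
            if list(self.embedding.index) != list(self.labels.index):
                raise ValueError("embedding and labels must share the cell index")
            if not np.isfinite(self.embedding.to_numpy()).all():
                raise ValueError("embedding contains non-finite coordinates")

    @property
    def n_clusters(self) -> int:
        return int((pd.unique(self.labels[self.labels >= 0])).size)


QUADRANTS = (
    "top_left_least_sensitive",
    "bottom_right_most_sensitive",
    "differentially_insensitive",
    "differentially_sensitive",
    "unclassified",
)


@dataclass
class RankTable:
    """Per (signature, group) summary statistics with optional quadrant calls.

    ``table`` is indexed by (signature, group) and carries the nine summary
    statistics: switch_point, mean, median, sd, variance, min, max, prop_nan,
    residuals_mean; plus a ``quadrant`` column once classification has run.
    """

    table: pd.DataFrame

    STATS = (
        "switch_point",
        "mean",
        "median",
        "sd",
        "variance",
        "min",
        "max",
        "prop_nan",
        "residuals_mean",
    )

    def __post_init__(self) -> None:
        missing = [c for c in self.STATS if c not in self.table.columns]
        if missing:
            raise ValueError(f"rank table missing statistics: {missing}")

    def for_group(self, group) -> pd.DataFrame:
        return self.table.xs(group, level="group")


@dataclass
class PharmacoTable:
    """Bulk pharmacogenomic input: cell-line expression + drug response.

    ``expression`` holds samples × genes profiles, ``response`` one row per
    (sample, drug) with either a continuous ``auc`` column (area under the
    dose-response curve; higher = more resistant) or a categorical ``arm``
    column (control/treated).  ``confounder`` is an optional per-sample label
    (tissue / site of origin) adjusted for in the differential model.
    """

    expression: ExpressionMatrix
    response: pd.DataFrame
    confounder: pd.Series | None = None

    def __post_init__(self) -> None:
        required = {"sample", "drug"}
        if not required <= set(self.response.columns):
            raise ValueError("response table needs 'sample' and 'drug' columns")
        if not ({"auc", "arm"} & set(self.response.columns)):
            raise ValueError("response table needs an 'auc' or 'arm' column")
        samples = set(self.expression.cell_ids)
        unknown = set(self.response["sample"]) - samples
        if unknown:
            raise ValueError(
                f"response rows reference unknown samples: {sorted(unknown)[:5]}"
            )
        if "auc" in self.response.columns:
            auc = self.response["auc"].dropna()
            if not np.isfinite(auc.to_numpy(dtype=float)).all():
                raise ValueError("non-finite AUC values in response table")
        if self.confounder is not None:
            missing = samples - set(self.confounder.index)
            if missing:
                raise ValueError(
                    f"confounder missing for samples: {sorted(missing)[:5]}"
                )

    @property
    def drugs(self) -> list[str]:
        return list(pd.unique(self.response["drug"]))


@dataclass
class DrugSpecificity:
    """Drug specificity scores and the decile-based background selection.

    ``dss`` is 1 for a signature whose cross-cell-type score pattern is
    identical in every cell type and 0 for the most discordant signature.  The
    first and last deciles by DSS form the reduced drug background.
    """

    dss: pd.Series
    decile_low: set[str]
    decile_high: set[str]

    def __post_init__(self) -> None:
        names = set(self.dss.index)
        if not (set(self.decile_low) | set(self.decile_high)) <= names:
            raise ValueError("decile members must be scored signatures")
        n_dec = math.ceil(0.1 * len(self.dss))
        if len(self.decile_low) != n_dec or len(self.decile_high) != n_dec:
            raise ValueError(
                f"decile sizes must be ceil(0.1·n) = {n_dec}, got "
                f"{len(self.decile_low)}/{len(self.decile_high)}"
            )

    @property
    def background_names(self) -> set[str]:
        return set(self.decile_low) | set(self.decile_high)
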