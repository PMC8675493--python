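"""Synthetic data with planted therapeutic structure.

The single-cell generator emulates the regime the scoring pipeline operates
in: a normalised log-scale expression matrix with per-gene baseline means,
unit-variance cell noise (so planted effects are in σ units), planted clones
whose signature UP genes are shifted up and DN genes down, Bernoulli dropout
zeroing entries, and a per-cell library-size factor that leaks into every
gene and is recorded as an ``nUMI`` covariate.  The bulk pharmacogenomic
generator plants resistance genes whose expression tracks the drug-response
AUC, plus a tissue confounder that shifts both AUC and a disjoint set of
offset genes, so that confounder adjustment is exercised.

Everything is deterministic under the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (
    ExpressionMatrix,
    GeneSignature,
    PharmacoTable,
    SignatureCollection,
    SignatureMode,
)

__all__ = ["CloneSpec", "SignatureSpec", "SimConfig", "simulate", "simulate_pharmaco"]

#: standard deviation of the per-cell expression noise; planted effects are
#: expressed as multiples of this unit
NOISE_SD = 1.0


@dataclass(frozen=True)
class CloneSpec:
    """A planted subpopulation: its cell fraction and per-signature response.

    ``response_profile[s]`` is the shift (in σ units) applied to signature
    ``s``'s UP genes (and, negated, to its DN genes) in this clone's cells.
    ``offtarget_shift`` shifts a dedicated block of non-signature genes,
    planting expression structure that the score matrix cannot see — used to
    show that therapeutic clusters can cut across expression clusters.
    """

    fraction: float
    response_profile: tuple[float, ...]
    offtarget_shift: float = 0.0


@dataclass(frozen=True)
class SignatureSpec:
    """Planted signature sizes: number of UP and DN genes."""

    n_up: int = 25
    n_dn: int = 25


@dataclass
class SimConfig:
    """Configuration of the single-cell simulation."""

    n_cells: int = 500
    n_genes: int = 2000
    # default study condition: a 6-drug panel where the responsive clone
    # differs on a 3-drug family (effect 3σ), 50/50 clone mix
    clones: tuple[CloneSpec, ...] = (
        CloneSpec(0.5, (3.0, 3.0, 3.0, 0.0, 0.0, 0.0)),
        CloneSpec(0.5, (0.0, 0.0, 0.0, 0.0, 0.0, 0.0)),
    )
    signatures: tuple[SignatureSpec, ...] = tuple(
        SignatureSpec() for _ in range(6)
    )
    dropout_rate: float = 0.3
    libsize_sd: float = 0.2
    nuisance_coeff: float = 0.0
    n_offtarget_genes: int = 100
    baseline_mean: float = 2.0
    baseline_sd: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isclose(sum(c.fraction for c in self.clones), 1.0):
            raise ValueError("clone fractions must sum to 1")
        if any(len(c.response_profile) != len(self.signatures) for c in self.clones):
            raise ValueError(
                "each clone's response_profile must have one entry per signature"
            )
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must be in [0, 1]")
        if self.libsize_sd < 0:
            raise ValueError("libsize_sd must be >= 0")
        planted = sum(s.n_up + s.n_dn for s in self.signatures)
        if planted + self.n_offtarget_genes > self.n_genes:
            raise ValueError(
                f"planted genes ({planted} signature + {self.n_offtarget_genes} "
                f"off-target) exceed n_genes ({self.n_genes})"
            )


def _clone_sizes(fractions: list[float], n_cells: int) -> list[int]:
    """Integer clone sizes summing exactly to n_cells (largest-remainder)."""
    raw = [f * n_cells for f in fractions]
    sizes = [int(np.floor(r)) for r in raw]
    remainder = n_cells - sum(sizes)
    order = np.argsort([-(r - np.floor(r)) for r in raw], kind="stable")
    for i in range(remainder):
        sizes[order[i]] += 1
    return sizes


def simulate(
    cfg: SimConfig,
) -> tuple[ExpressionMatrix, SignatureCollection, pd.Series, pd.DataFrame]:
    """Generate (expression, signatures, clone labels, covariate table).

    Cells are drawn clone by clone in a fixed order and then left in that
    order (cell ids ``cell0001``...); genes ``g0001``... are assigned to the
    planted signatures first, the rest are nulls.  The covariate table holds
    ``nUMI`` (the library-size factor applied to each cell, times the
    baseline total) and ``nGene`` (detected genes per cell).
    """
    rng = np.random.default_rng(cfg.seed)
    n, g = cfg.n_cells, cfg.n_genes

    mu = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=g)
    X = mu[None, :] + rng.normal(0.0, NOISE_SD, size=(n, g))

    # planted gene assignment: consecutive disjoint blocks
    sig_genes: list[tuple[np.ndarray, np.ndarray]] = []
    cursor = 0
    for spec in cfg.signatures:
        up = np.arange(cursor, cursor + spec.n_up)
        cursor += spec.n_up
        dn = np.arange(cursor, cursor + spec.n_dn)
        cursor += spec.n_dn
        sig_genes.append((up, dn))

    offtarget = np.arange(cursor, cursor + cfg.n_offtarget_genes)

    sizes = _clone_sizes([c.fraction for c in cfg.clones], n)
    labels = np.repeat(np.arange(len(cfg.clones)), sizes)
    for ci, clone in enumerate(cfg.clones):
        cells = labels == ci
        for s, effect in enumerate(clone.response_profile):
            if effect == 0.0:
                continue
            up, dn = sig_genes[s]
            X[np.ix_(cells, up)] += effect * NOISE_SD
            X[np.ix_(cells, dn)] -= effect * NOISE_SD
        if clone.offtarget_shift != 0.0 and cfg.n_offtarget_genes:
            X[np.ix_(cells, offtarget)] += clone.offtarget_shift * NOISE_SD

    libsize = np.exp(rng.normal(0.0, cfg.libsize_sd, size=n))
    X = X * libsize[:, None]
    if cfg.nuisance_coeff != 0.0:
        planted = np.concatenate([np.r_[u, d] for u, d in sig_genes])
        X[:, planted] += cfg.nuisance_coeff * np.log(libsize)[:, None]
    if cfg.dropout_rate > 0:
        X[rng.random(size=(n, g)) < cfg.dropout_rate] = 0.0

    gene_ids = [f"g{j + 1:04d}" for j in range(g)]
    cell_ids = [f"cell{i + 1:04d}" for i in range(n)]
    expr = ExpressionMatrix(X, cell_ids, gene_ids)

    signatures = [
        GeneSignature(
            f"sig{s}",
            frozenset(gene_ids[j] for j in up),
            frozenset(gene_ids[j] for j in dn),
            SignatureMode.BIDIRECTIONAL,
            "custom",
        )
        for s, (up, dn) in enumerate(sig_genes)
    ]
    collection = SignatureCollection(signatures, name="planted")

    truth = pd.Series(labels, index=cell_ids, name="clone")
    covars = pd.DataFrame(
        {
            "nUMI": libsize * np.abs(X).sum(axis=1).mean(),
            "nGene": (X != 0).sum(axis=1),
        },
        index=cell_ids,
    )
    return expr, collection, truth, covars


def simulate_pharmaco(
    n_samples: int = 50,
    n_genes: int = 1000,
    n_drugs: int = 3,
    effect: float = 5.0,
    seed: int = 0,
    *,
    n_resistance_genes: int = 10,
    n_tissues: int = 3,
    confounder_offset: float = 0.0,
    n_offset_genes: int = 10,
) -> tuple[PharmacoTable, dict]:
    """Bulk pharmacogenomic table with planted resistance genes.

    Per drug, the AUC is Uniform(0, 1) plus a tissue-specific shift (so the
    tissue confounds the response); each drug owns ``n_resistance_genes``
    whose expression gains ``effect · (AUC − 0.5)``.  When
    ``confounder_offset`` is non-zero a disjoint set of ``n_offset_genes``
    gains a tissue-specific additive offset with no drug effect — those genes
    correlate with AUC only through the tissue, so they vanish from the
    statistic once the confounder is adjusted for.

    Returns the table and a truth dict with the planted gene ids per drug and
    the offset gene ids.
    """
    needed = n_drugs * n_resistance_genes + n_offset_genes
    if needed > n_genes:
        raise ValueError(
            f"n_genes={n_genes} too small for {needed} planted/offset genes"
        )
    rng = np.random.default_rng(seed)
    samples = [f"s{i + 1:03d}" for i in range(n_samples)]
    gene_ids = [f"g{j + 1:04d}" for j in range(n_genes)]
    tissue = pd.Series(
        [f"tissue{rng.integers(n_tissues)}" for _ in samples],
        index=samples, name="tissue",
    )
    tissue_shift = {f"tissue{t}": (t - (n_tissues - 1) / 2) * 0.2
                    for t in range(n_tissues)}

    X = rng.normal(0.0, 1.0, size=(n_samples, n_genes))
    rows = []
    planted: dict[str, list[str]] = {}
    cursor = 0
    for d in range(n_drugs):
        drug = f"drug{d}"
        auc = rng.random(n_samples) + tissue.map(tissue_shift).to_numpy()
        genes = list(range(cursor, cursor + n_resistance_genes))
        cursor += n_resistance_genes
        planted[drug] = [gene_ids[j] for j in genes]
        X[:, genes] += effect * (auc - 0.5)[:, None]
        rows.extend(
            {"sample": s, "drug": drug, "auc": a} for s, a in zip(samples, auc)
        )

    offset_genes = list(range(cursor, cursor + n_offset_genes))
    if confounder_offset != 0.0:
        offsets = tissue.map(
            {f"tissue{t}": confounder_offset * (t - (n_tissues - 1) / 2)
             for t in range(n_tissues)}
        ).to_numpy()
        X[:, offset_genes] += offsets[:, None]

    table = PharmacoTable(
        expression=ExpressionMatrix(X, samples, gene_ids),
        response=pd.DataFrame(rows),
        confounder=tissue,
    )
    truth = {
        "resistance_genes": planted,
        "offset_genes": [gene_ids[j] for j in offset_genes],
    }
    return table, truth
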