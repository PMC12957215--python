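"""Rank-based AUC scoring of functional gene sets per cell.

Each cell's genes are ordered by decreasing expression and a gene set is
scored by the area under its recovery curve — the cumulative count of set
members encountered while walking down the top fraction of the ranking —
normalized to the maximum achievable area.  The score is in [0, 1], is
invariant to any strictly monotone transform of a cell's expression, and
measures how concentrated the set is at the top of the cell's ranking.
Classic use: M1/M2/angiogenesis/phagocytosis states for macrophages and
naive/activation/cytotoxicity/exhaustion states for T cells.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .containers import GeneSet, LabeledExpression


def build_rankings(expr: LabeledExpression, seed: int = 0) -> pd.DataFrame:
    """Per-cell 1-based rank of every gene (rank 1 = highest expression).

    Ties are broken by a single seeded random permutation of the gene
    order, fixed for the whole run, so tied genes receive an exchangeable
    but reproducible order.
    """
    if expr.n_genes < 2:
        raise ValueError("need at least 2 genes to rank")
    rng = np.random.default_rng(seed)
    tiebreak = rng.permutation(expr.n_genes)
    n_genes, n_cells = expr.counts.shape
    ranks = np.empty((n_genes, n_cells), dtype=np.int64)
    for c in range(n_cells):
        order = np.lexsort((tiebreak, -expr.counts[:, c].astype(float)))
        ranks[order, c] = np.arange(1, n_genes + 1)
    return pd.DataFrame(ranks, index=expr.gene_ids, columns=expr.cell_meta.index)


def _max_area(n_members: int, window: int) -> float:
    """Area when all members sit at the very top of the window."""
    s = min(n_members, window)
    return s * (s + 1) / 2 + (window - s) * s


def auc_score(
    rankings: pd.DataFrame, gene_set: GeneSet, top_fraction: float = 0.05
) -> pd.Series:
    """Recovery-curve AUC of ``gene_set`` for every cell.

    The recovery curve at rank position k is the number of set members
    with rank <= k; the AUC sums the curve over k = 1..window with
    ``window = ceil(top_fraction * n_genes)`` and divides by the maximum
    achievable area.  Set members absent from the matrix are ignored with
    a warning; a fully absent set scores 0 everywhere.
    """
    n_genes = rankings.shape[0]
    window = math.ceil(top_fraction * n_genes)
    if window < 2:
        raise ValueError("top_fraction * n_genes must be >= 2")
    present = [g for g in gene_set if g in rankings.index]
    absent = len(gene_set) - len(present)
    if absent:
        warnings.warn(
            f"{absent} member(s) of set {gene_set.name!r} absent from the matrix",
            stacklevel=2,
        )
    if not present:
        warnings.warn(f"gene set {gene_set.name!r} entirely absent; scores are 0",
                      stacklevel=2)
        return pd.Series(0.0, index=rankings.columns, name=gene_set.name)

    member_ranks = rankings.loc[present].to_numpy()  # members x cells
    in_window = member_ranks <= window
    # each member at rank r contributes (window - r + 1) to the area
    area = np.where(in_window, window - member_ranks + 1, 0).sum(axis=0)
    score = area / _max_area(len(present), window)
    return pd.Series(score, index=rankings.columns, name=gene_set.name)


def score_states(
    expr: LabeledExpression,
    gene_sets: list[GeneSet],
    top_fraction: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Cells x gene-sets AUC score matrix (each entry in [0, 1])."""
    rankings = build_rankings(expr, seed=seed)
    cols = {gs.name: auc_score(rankings, gs, top_fraction) for gs in gene_sets}
    return pd.DataFrame(cols, index=rankings.columns)
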