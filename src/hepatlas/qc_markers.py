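"""Cell quality control and cluster signature-gene selection.

QC keeps cells with a mitochondrial fraction strictly below the cutoff and
a detected-gene count inside an inclusive window, then keeps genes detected
in strictly more than ``min_cells_per_gene`` of the surviving cells.

Signature genes are selected per cluster from one-vs-rest Wilcoxon
rank-sum differential expression with class-specific thresholds, then
ranked by an entropy-difference specificity score: genes whose normalized
mean expression concentrates in few clusters carry low Shannon entropy and
hence a large difference from the maximum-entropy (uniform) profile.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import LabeledExpression

DEFAULT_EXCLUDE = ("ALB", "ATP5F1E")


def qc_filter(
    expr: LabeledExpression,
    min_genes: int = 200,
    max_genes: int = 4000,
    max_mito: float = 0.10,
    min_cells_per_gene: int = 3,
) -> LabeledExpression:
    """Apply cell then gene quality filters.

    Cells are retained when ``mito_fraction < max_mito`` (strict) and
    ``min_genes <= n_detected_genes <= max_genes`` (inclusive).  Genes are
    retained when detected in strictly more than ``min_cells_per_gene`` of
    the retained cells.  Input order is preserved; idempotent.
    """
    meta = expr.cell_meta
    cell_mask = (
        (meta["mito_fraction"].to_numpy() < max_mito)
        & (meta["n_detected_genes"].to_numpy() >= min_genes)
        & (meta["n_detected_genes"].to_numpy() <= max_genes)
    )
    if not cell_mask.any():
        warnings.warn("qc_filter removed every cell", stacklevel=2)
        return expr.subset(np.zeros(expr.n_genes, bool), cell_mask)
    detected = (expr.counts[:, cell_mask] > 0).sum(axis=1)
    gene_mask = detected > min_cells_per_gene
    return expr.subset(gene_mask, cell_mask)


def normalize_cp10k(counts: np.ndarray) -> np.ndarray:
    """Library-size normalization to counts-per-10k per cell."""
    lib = counts.sum(axis=0, keepdims=True).astype(float)
    lib[lib == 0] = 1.0
    return counts / lib * 1e4


def entropy_specificity(mean_expr_by_cluster, eps_rel: float = 1e-9):
    """Entropy-difference specificity D = log2 K - H(p) in bits.

    ``mean_expr_by_cluster`` is a length-K vector (one gene) or a
    genes x K matrix of non-negative cluster means.  The profile is
    normalized to a distribution p over clusters with a small additive
    pseudo-mass (``eps_rel`` relative to the total) to avoid log 0; D = 0
    for a uniform profile, log2 K for a one-hot profile, and an all-zero
    profile returns 0 by convention.
    """
    m = np.atleast_2d(np.asarray(mean_expr_by_cluster, dtype=float))
    if (m < 0).any():
        raise ValueError("cluster means must be non-negative")
    k = m.shape[1]
    if k < 2:
        raise ValueError("need at least 2 clusters")
    total = m.sum(axis=1, keepdims=True)
    eps = np.where(total > 0, total, 1.0) * eps_rel
    p = (m + eps) / (m + eps).sum(axis=1, keepdims=True)
    h = -(p * np.log2(p)).sum(axis=1)
    d = np.log2(k) - h
    d = np.where(total.ravel() > 0, np.maximum(d, 0.0), 0.0)
    if np.ndim(mean_expr_by_cluster) == 1:
        return float(d[0])
    return d


def de_stats(expr: LabeledExpression, cluster_key: str = "subtype") -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum DE statistics per (cluster, gene).

    Returns the signature table with columns cluster, gene, avg_log2FC
    (log2((m1+1)/(m2+1)) on counts-per-10k means), pct1/pct2 (detection
    fraction inside/outside the cluster), U statistic, p, BH-adjusted p
    (within cluster, across genes) and the cluster-free entropy_diff
    specificity of each gene.
    """
    labels = expr.cell_meta[cluster_key].to_numpy()
    clusters = pd.unique(labels)
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters for one-vs-rest DE")
    for c in clusters:
        if (labels == c).sum() < 3:
            raise ValueError(f"cluster {c!r} has fewer than 3 cells")

    norm = normalize_cp10k(expr.counts)
    cluster_means = np.column_stack(
        [norm[:, labels == c].mean(axis=1) for c in clusters]
    )
    ent = entropy_specificity(cluster_means)

    frames = []
    for ci, c in enumerate(clusters):
        in_c = labels == c
        x1, x2 = norm[:, in_c], norm[:, ~in_c]
        m1, m2 = cluster_means[:, ci], norm[:, ~in_c].mean(axis=1)
        lfc = np.log2((m1 + 1.0) / (m2 + 1.0))
        pct1 = (expr.counts[:, in_c] > 0).mean(axis=1)
        pct2 = (expr.counts[:, ~in_c] > 0).mean(axis=1)

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.mannwhitneyu(x1, x2, axis=1, method="asymptotic")
        u, p = np.asarray(res.statistic, float), np.asarray(res.pvalue, float)
        # constant genes (identical everywhere): no evidence, p = 1, lfc = 0
        constant = expr.counts.max(axis=1) == expr.counts.min(axis=1)
        p = np.where(constant | ~np.isfinite(p), 1.0, p)
        lfc = np.where(constant, 0.0, lfc)
        u = np.where(np.isfinite(u), u, x1.shape[1] * x2.shape[1] / 2.0)
        p_adj = multipletests(p, method="fdr_bh")[1]
        frames.append(
            pd.DataFrame(
                {
                    "cluster": c,
                    "gene": expr.gene_ids,
                    "avg_log2FC": lfc,
                    "pct1": pct1,
                    "pct2": pct2,
                    "statistic": u,
                    "p": p,
                    "p_adj": p_adj,
                    "entropy_diff": ent,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def select_signatures(
    table: pd.DataFrame,
    cell_class: str,
    exclude: tuple[str, ...] = DEFAULT_EXCLUDE,
    top_n_by_entropy: int | None = None,
    min_pct: float | None = None,
) -> dict[str, list[str]]:
    """Per-cluster signature gene lists under class-specific thresholds.

    macrophage rule: p_adj < 0.01 and pct1 > 0.5 and pct2 < 0.5 and
    avg_log2FC > 1.  tcell rule: p_adj < 0.01 and avg_log2FC > 0.5 (no
    detection-fraction rule).  ``exclude`` removes curated non-specific
    genes (liver background ALB and the ubiquitous ATP5F1E by default).
    Survivors are ranked by entropy_diff descending; ``top_n_by_entropy``
    truncates each list.  ``min_pct`` optionally adds a pct1 > min_pct
    prefilter for classes whose rule has no detection threshold.
    """
    if cell_class not in ("macrophage", "tcell"):
        raise ValueError("cell_class must be 'macrophage' or 'tcell'")
    t = table[~table["gene"].isin(exclude)]
    if cell_class == "macrophage":
        keep = (
            (t["p_adj"] < 0.01)
            & (t["pct1"] > 0.5)
            & (t["pct2"] < 0.5)
            & (t["avg_log2FC"] > 1.0)
        )
    else:
        keep = (t["p_adj"] < 0.01) & (t["avg_log2FC"] > 0.5)
        if min_pct is not None:
            keep &= t["pct1"] > min_pct
    t = t[keep]

    out: dict[str, list[str]] = {}
    for cluster in pd.unique(table["cluster"]):
        sub = t[t["cluster"] == cluster].sort_values(
            ["entropy_diff", "gene"], ascending=[False, True]
        )
        genes = sub["gene"].tolist()
        if top_n_by_entropy is not None:
            genes = genes[:top_n_by_entropy]
        if not genes:
            warnings.warn(f"no signature genes survive for cluster {cluster!r}",
                          stacklevel=2)
        out[str(cluster)] = genes
    return out


def signature_passed(table: pd.DataFrame, cell_class: str,
                     exclude: tuple[str, ...] = DEFAULT_EXCLUDE) -> pd.DataFrame:
    """Return the table with a boolean ``passed`` column for the class rule."""
    selected = select_signatures(table, cell_class, exclude=exclude)
    out = table.copy()
    key = list(zip(out["cluster"].astype(str), out["gene"]))
    chosen = {(c, g) for c, genes in selected.items() for g in genes}
    out["passed"] = [k in chosen for k in key]
    return out
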