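"""Per-sample gene-set enrichment scores on bulk cohorts.

The core statistic is a single-sample GSEA (ssGSEA) running sum: within
each sample genes are ranked by expression, and the enrichment score ES is
the sum over rank positions of the difference between a rank-weighted
in-set ECDF and the uniform out-of-set ECDF.  ES values are min-max
rescaled across the cohort to (0, 1] with a small floor so ratios are
always defined.

The composite scores correct a subtype signature's enrichment for overall
immune abundance:

    Mscore = ES / IS            (macrophage-subtype signature)
    Tscore = ES * CA / IS       (T-subtype signature, cytotoxic-T deviation CA)

where IS is the mean rescaled enrichment over a panel of immune cell-type
signature sets and CA is the rescaled enrichment of the cytotoxic-T set.
Scores are comparable within one cohort only (cohort-relative rescaling).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import GeneSet

RESCALE_FLOOR = 0.01


def ssgsea_es(
    expression: pd.DataFrame,
    gene_set: GeneSet,
    alpha: float = 0.25,
    rescale: bool = True,
) -> pd.Series:
    """ssGSEA enrichment score of ``gene_set`` for every sample (column).

    Per sample: order genes by decreasing expression; walking down the
    list, the in-set ECDF accumulates weight ``rank_value ** alpha``
    (rank_value = n at the top down to 1, weights normalized over set
    members) while the out-of-set ECDF accumulates 1/(n - s); ES is the
    sum of (in - out) over all positions.  With ``rescale`` the cohort's
    ES vector is min-max mapped to [0, 1] and floored at 0.01.
    """
    n = expression.shape[0]
    if n < 2:
        raise ValueError("need at least 2 genes")
    in_set = expression.index.isin(gene_set.members)
    s = int(in_set.sum())
    if s == 0:
        raise ValueError(f"gene set {gene_set.name!r} has no overlap with the matrix")
    if s == n:
        raise ValueError(f"gene set {gene_set.name!r} covers the whole matrix")

    x = expression.to_numpy(dtype=float)
    order = np.argsort(-x, axis=0, kind="stable")  # genes by decreasing expr
    in_sorted = in_set[order]                      # positions x? shape (n, m)
    rank_value = np.arange(n, 0, -1, dtype=float)[:, None]
    w = rank_value ** alpha
    w_in = np.where(in_sorted, w, 0.0)
    p_in = np.cumsum(w_in, axis=0) / w_in.sum(axis=0, keepdims=True)
    p_out = np.cumsum(~in_sorted, axis=0) / (n - s)
    es = (p_in - p_out).sum(axis=0)
    out = pd.Series(es, index=expression.columns, name=gene_set.name)
    return rescale_scores(out) if rescale else out


def rescale_scores(es: pd.Series, floor: float = RESCALE_FLOOR) -> pd.Series:
    """Min-max rescale across the cohort to (0, 1] with a strict floor."""
    lo, hi = float(es.min()), float(es.max())
    if hi == lo:
        return pd.Series(1.0, index=es.index, name=es.name)
    return ((es - lo) / (hi - lo)).clip(lower=floor)


def immune_infiltration_is(
    expression: pd.DataFrame, immune_sets: list[GeneSet], alpha: float = 0.25
) -> pd.Series:
    """Immune abundance score IS: mean rescaled enrichment over the panel.

    Strictly positive by the rescaling floor; used as the denominator that
    corrects subtype enrichment for overall immune infiltration.
    """
    if not immune_sets:
        raise ValueError("need at least one immune gene set")
    stacked = pd.concat(
        [ssgsea_es(expression, gs, alpha=alpha, rescale=True) for gs in immune_sets],
        axis=1,
    )
    out = stacked.mean(axis=1)
    out.name = "IS"
    return out


def tc_abundance_ca(
    expression: pd.DataFrame, tc_set: GeneSet, alpha: float = 0.25
) -> pd.Series:
    """Cytotoxic-T abundance score CA (rescaled ssGSEA of the Tc signature)."""
    out = ssgsea_es(expression, tc_set, alpha=alpha, rescale=True)
    out.name = "CA"
    return out


def mscore(es, is_):
    """Mscore = ES / IS (immune-abundance-corrected subtype enrichment)."""
    is_arr = np.asarray(is_, dtype=float)
    if (is_arr <= 0).any():
        raise ValueError("IS must be strictly positive")
    return es / is_


def tscore(es, ca, is_):
    """Tscore = ES * CA / IS."""
    is_arr = np.asarray(is_, dtype=float)
    if (is_arr <= 0).any():
        raise ValueError("IS must be strictly positive")
    return es * ca / is_


def score_cohort(
    expression: pd.DataFrame,
    signature_set: GeneSet,
    immune_sets: list[GeneSet],
    tc_set: GeneSet | None = None,
    alpha: float = 0.25,
) -> pd.DataFrame:
    """Per-sample ES, IS, CA, Mscore and Tscore table.

    ``signature_set`` is the subtype signature being evaluated; ``tc_set``
    defaults to the signature set itself when scoring the cytotoxic-T
    signature.  Output columns: ES, IS, CA, Mscore, Tscore.
    """
    es = ssgsea_es(expression, signature_set, alpha=alpha)
    is_ = immune_infiltration_is(expression, immune_sets, alpha=alpha)
    ca = tc_abundance_ca(expression, tc_set or signature_set, alpha=alpha)
    return pd.DataFrame(
        {
            "ES": es,
            "IS": is_,
            "CA": ca,
            "Mscore": mscore(es, is_),
            "Tscore": tscore(es, ca, is_),
        }
    )
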