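"""Cell-type composition with BCa bootstrap confidence intervals.

Per disease stage the proportion of each cell type is estimated by
pooling cells, and uncertainty is quantified with the bias-corrected and
accelerated (BCa) bootstrap: cells are resampled with replacement, the
percentile interval is shifted by a bias term z0 (from the fraction of
bootstrap statistics below the point estimate) and an acceleration term a
(from the skewness of jackknife leave-one-out statistics).  Stage pairs
are contrasted by the difference of proportions with a BCa interval built
from independent within-stage resampling.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri


def _jackknife(data: np.ndarray, statistic) -> np.ndarray:
    n = len(data)
    idx = np.arange(n)
    return np.array([statistic(data[idx != i]) for i in range(n)])


def _acceleration(jack: np.ndarray) -> float:
    d = jack.mean() - jack
    denom = (d ** 2).sum() ** 1.5
    if denom == 0:
        return 0.0
    return float((d ** 3).sum() / (6.0 * denom))


def bca_interval(
    theta_hat: float,
    boot_stats: np.ndarray,
    jack_stats: np.ndarray,
    level: float = 0.95,
) -> tuple[float, float]:
    """BCa endpoints from precomputed bootstrap and jackknife statistics.

    z0 = Phi^-1(fraction of bootstrap statistics strictly below the point
    estimate); a = jackknife skewness.  With z0 = 0 and a = 0 this reduces
    exactly to the plain percentile interval (same quantile rule).
    """
    boot = np.asarray(boot_stats, dtype=float)
    if boot.max() == boot.min():
        warnings.warn("degenerate bootstrap distribution; CI collapses to the "
                      "point estimate", stacklevel=2)
        return float(theta_hat), float(theta_hat)
    b = len(boot)
    frac = np.clip((boot < theta_hat).mean(), 1.0 / (b + 1), 1.0 - 1.0 / (b + 1))
    z0 = ndtri(frac)
    a = _acceleration(np.asarray(jack_stats, dtype=float))
    alpha = 1.0 - level
    z_lo, z_hi = ndtri(alpha / 2.0), ndtri(1.0 - alpha / 2.0)
    q_lo = ndtr(z0 + (z0 + z_lo) / (1.0 - a * (z0 + z_lo)))
    q_hi = ndtr(z0 + (z0 + z_hi) / (1.0 - a * (z0 + z_hi)))
    lo, hi = np.quantile(boot, [q_lo, q_hi])
    return float(lo), float(hi)


def bca_ci(
    data,
    statistic,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
    cluster=None,
) -> tuple[float, float]:
    """BCa bootstrap CI of ``statistic(data)`` over cell-level resampling.

    ``data`` is any 1-D array (e.g. cell type labels or indicators);
    ``statistic`` maps a 1-D array to a scalar (e.g. proportion of a
    type).  Requires >= 10 observations.  When ``cluster`` (an array of
    per-observation sample IDs) is given, whole samples are resampled and
    jackknifed instead of cells — the stratified option guarding against
    pseudo-replication when cells from one donor are not independent.
    """
    data = np.asarray(data)
    if len(data) < 10:
        raise ValueError("need at least 10 observations for a bootstrap CI")
    rng = np.random.default_rng(seed)
    theta_hat = statistic(data)
    if cluster is None:
        idx = rng.integers(0, len(data), size=(n_boot, len(data)))
        boot = np.array([statistic(data[row]) for row in idx])
        jack = _jackknife(data, statistic)
    else:
        cluster = np.asarray(cluster)
        units = pd.unique(cluster)
        member = {u: np.flatnonzero(cluster == u) for u in units}
        draws = rng.integers(0, len(units), size=(n_boot, len(units)))
        boot = np.array([
            statistic(data[np.concatenate([member[units[j]] for j in row])])
            for row in draws
        ])
        jack = np.array([
            statistic(data[cluster != u]) for u in units
        ])
    return bca_interval(theta_hat, boot, jack, level=level)


def proportion_of(cell_type) -> callable:
    """Statistic factory: fraction of labels equal to ``cell_type``."""
    def stat(labels: np.ndarray) -> float:
        return float(np.mean(labels == cell_type))
    return stat


def estimate_composition(
    cell_meta: pd.DataFrame,
    stage_key: str = "stage",
    type_key: str = "subtype",
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-(stage, type) proportions with BCa CIs.

    Within each stage the proportions sum to 1 and lo <= point <= hi for
    every interval (BCa endpoints are clipped to the point estimate if the
    bootstrap quantiles fall on one side, which can occur only in
    degenerate resamples).
    """
    rows = []
    types = pd.unique(cell_meta[type_key])
    for si, (stage, sub) in enumerate(cell_meta.groupby(stage_key, sort=False)):
        labels = sub[type_key].to_numpy()
        for ti, cell_type in enumerate(types):
            stat = proportion_of(cell_type)
            point = stat(labels)
            lo, hi = bca_ci(
                labels, stat, n_boot=n_boot, level=level,
                seed=seed + 7919 * si + ti,
            )
            rows.append(
                {
                    "stage": stage,
                    "cell_type": cell_type,
                    "proportion": point,
                    "ci_lo": min(lo, point),
                    "ci_hi": max(hi, point),
                    "n_cells": len(labels),
                }
            )
    return pd.DataFrame(rows)


def stage_contrast(
    cell_meta: pd.DataFrame,
    stage_a: str,
    stage_b: str,
    cell_type,
    stage_key: str = "stage",
    type_key: str = "subtype",
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> dict:
    """Difference of ``cell_type`` proportions (stage_a - stage_b) with BCa CI.

    Each stage's cells are resampled independently; the jackknife for the
    acceleration leaves out one cell at a time across both stages.
    """
    stages = cell_meta[stage_key]
    a = cell_meta.loc[stages == stage_a, type_key].to_numpy()
    b = cell_meta.loc[stages == stage_b, type_key].to_numpy()
    if len(a) == 0 or len(b) == 0:
        raise ValueError(f"both stages must be present ({stage_a!r}, {stage_b!r})")
    stat = proportion_of(cell_type)
    if stat(a) == 0 and stat(b) == 0:
        raise ValueError(f"cell type {cell_type!r} absent from both stages")
    rng = np.random.default_rng(seed)
    point = stat(a) - stat(b)
    ia = rng.integers(0, len(a), size=(n_boot, len(a)))
    ib = rng.integers(0, len(b), size=(n_boot, len(b)))
    boot = np.array([stat(a[ra]) - stat(b[rb]) for ra, rb in zip(ia, ib)])
    jack_a = _jackknife(a, stat) - stat(b)
    jack_b = stat(a) - _jackknife(b, stat)
    jack = np.concatenate([jack_a, jack_b])
    lo, hi = bca_interval(point, boot, jack, level=level)
    return {
        "stage_a": stage_a,
        "stage_b": stage_b,
        "cell_type": cell_type,
        "difference": point,
        "ci_lo": lo,
        "ci_hi": hi,
        "n_a": len(a),
        "n_b": len(b),
    }
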