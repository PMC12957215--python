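"""Score-stratified survival analysis and univariate Cox screening.

Samples are split into high/low groups at a cutpoint (cohort median by
default, ties to low), compared with Kaplan-Meier curves and the log-rank
test, and the high-vs-low hazard ratio is estimated from a Cox
proportional-hazards fit with patient age as a covariate (the age
correction).  A univariate screen fits one Cox model per signature gene on
standardized expression and adjusts Wald p-values by Benjamini-Hochberg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from statsmodels.stats.multitest import multipletests

from .containers import BulkCohort


@dataclass
class SurvivalResult:
    score_name: str
    cutpoint: float
    km_curves: dict[str, pd.DataFrame]
    logrank_stat: float
    logrank_p: float
    hr: float | None = None
    hr_ci: tuple[float, float] | None = None
    cox_summary: pd.DataFrame | None = field(default=None, repr=False)


def _check_cohort_for_survival(clinical: pd.DataFrame) -> None:
    if int(clinical["event"].sum()) == 0:
        raise ValueError("no events observed; survival contrast undefined")


def _age_usable(clinical: pd.DataFrame) -> bool:
    if clinical["age"].nunique() < 2:
        warnings.warn("age is constant; age correction skipped", stacklevel=3)
        return False
    return True


def km_curve(times: np.ndarray, events: np.ndarray, label: str) -> pd.DataFrame:
    """Product-limit survival curve with at-risk counts."""
    kmf = KaplanMeierFitter()
    kmf.fit(times, events, label=label)
    out = kmf.survival_function_.rename(columns={label: "survival"})
    out["at_risk"] = [kmf.event_table.loc[t, "at_risk"] for t in out.index]
    out.index.name = "time"
    return out.reset_index()


def stratify_and_test(
    cohort: BulkCohort,
    score: pd.Series,
    cutpoint: str | float = "median",
    score_name: str = "score",
    adjust_age: bool = True,
    fit_cox: bool = True,
) -> SurvivalResult:
    """High/low stratification with KM curves, log-rank test and age-adjusted HR.

    ``cutpoint`` is either 'median' or an explicit value; samples with
    score <= cutpoint form the low group.  The hazard ratio compares high
    vs low from a Cox fit with age as covariate when ``adjust_age``.
    """
    clin = cohort.clinical
    score = score.reindex(clin.index)
    cut = float(score.median()) if cutpoint == "median" else float(cutpoint)
    high = (score > cut).to_numpy()
    if high.all() or not high.any():
        raise ValueError(
            f"cutpoint {cut:g} puts every sample in one group for {score_name!r}"
        )
    _check_cohort_for_survival(clin)

    t = clin["OS_time"].to_numpy(float)
    e = clin["event"].to_numpy(int)
    lr = logrank_test(t[high], t[~high], e[high], e[~high])
    curves = {
        "high": km_curve(t[high], e[high], "high"),
        "low": km_curve(t[~high], e[~high], "low"),
    }

    hr = hr_ci = summary = None
    if fit_cox:
        df = pd.DataFrame({"OS_time": t, "event": e, "high": high.astype(int)})
        if adjust_age and _age_usable(clin):
            df["age"] = clin["age"].to_numpy(float)
        cph = CoxPHFitter()
        cph.fit(df, duration_col="OS_time", event_col="event")
        summary = cph.summary
        hr = float(np.exp(summary.loc["high", "coef"]))
        hr_ci = (
            float(np.exp(summary.loc["high", "coef lower 95%"])),
            float(np.exp(summary.loc["high", "coef upper 95%"])),
        )
    return SurvivalResult(
        score_name=score_name,
        cutpoint=cut,
        km_curves=curves,
        logrank_stat=float(lr.test_statistic),
        logrank_p=float(lr.p_value),
        hr=hr,
        hr_ci=hr_ci,
        cox_summary=summary,
    )


def cox_continuous(
    cohort: BulkCohort,
    score: pd.Series,
    adjust_age: bool = True,
    score_name: str = "score",
) -> pd.Series:
    """Cox fit on the standardized continuous score (age-adjusted).

    Returns log_hr, se, p, hr for one SD of the score — the per-SD effect
    size companion to the median-split stratification.
    """
    clin = cohort.clinical
    _check_cohort_for_survival(clin)
    z = (score - score.mean()) / score.std(ddof=0)
    df = pd.DataFrame(
        {
            "OS_time": clin["OS_time"].to_numpy(float),
            "event": clin["event"].to_numpy(int),
            score_name: z.reindex(clin.index).to_numpy(float),
        }
    )
    if adjust_age and _age_usable(clin):
        df["age"] = clin["age"].to_numpy(float)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="OS_time", event_col="event")
    row = cph.summary.loc[score_name]
    return pd.Series(
        {
            "log_hr": float(row["coef"]),
            "se": float(row["se(coef)"]),
            "p": float(row["p"]),
            "hr": float(np.exp(row["coef"])),
        }
    )


def univariate_screen(cohort: BulkCohort, genes: list[str]) -> pd.DataFrame:
    """Single-gene Cox screen on standardized expression with BH adjustment.

    Returns one row per tested gene: log_hr, se, p, p_adj and a direction
    flag ('risk' for positive log-HR, 'protective' otherwise).  Constant
    genes are excluded with a warning.
    """
    missing = [g for g in genes if g not in cohort.expression.index]
    if missing:
        raise KeyError(f"genes absent from the expression matrix: {missing[:5]}")
    _check_cohort_for_survival(cohort.clinical)
    t = cohort.clinical["OS_time"].to_numpy(float)
    e = cohort.clinical["event"].to_numpy(int)

    rows = []
    for g in genes:
        x = cohort.expression.loc[g].to_numpy(float)
        if x.std(ddof=0) == 0:
            warnings.warn(f"gene {g!r} is constant; excluded from the screen",
                          stacklevel=2)
            continue
        z = (x - x.mean()) / x.std(ddof=0)
        df = pd.DataFrame({"OS_time": t, "event": e, "expr": z})
        cph = CoxPHFitter()
        cph.fit(df, duration_col="OS_time", event_col="event")
        row = cph.summary.loc["expr"]
        rows.append(
            {
                "gene": g,
                "log_hr": float(row["coef"]),
                "se": float(row["se(coef)"]),
                "p": float(row["p"]),
            }
        )
    if not rows:
        raise ValueError("no testable (non-constant) genes")
    out = pd.DataFrame(rows).set_index("gene")
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    out["direction"] = np.where(out["log_hr"] > 0, "risk", "protective")
    return out
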