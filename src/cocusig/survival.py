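"""Quartile stratification, Kaplan-Meier, log-rank, Cox regression and
auxiliary two-sample statistics for scored cohorts.

Cox models use lifelines' partial-likelihood Newton fit with Efron tie
handling; hazard ratios are exp(beta) with 95% Wald confidence
intervals. Quartile boundaries use type-7 quantiles with ties assigned
to the lower group, so stratification is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from scipy import stats

logger = logging.getLogger(__name__)

QUARTILE_LABELS = ("Q1", "Q2", "Q3", "Q4")


class StratificationError(ValueError):
    pass


class CoxSeparationError(RuntimeError):
    """Monotone likelihood: the exposure perfectly orders events."""


def quartile_stratify(scores: pd.Series) -> pd.Series:
    """Assign Q1 (lowest) .. Q4 (highest) by type-7 quantile boundaries.

    A score exactly on a boundary goes to the lower group. Raises
    :class:`StratificationError` for fewer than 4 samples or all-equal
    scores.
    """
    scores = pd.Series(scores).astype(float)
    if len(scores) < 4:
        raise StratificationError("need >= 4 samples to form quartiles")
    if scores.nunique() == 1:
        raise StratificationError("degenerate stratification: all scores identical")
    bounds = np.quantile(scores.to_numpy(), [0.25, 0.5, 0.75])  # type 7 (linear)
    idx = np.searchsorted(bounds, scores.to_numpy(), side="left")  # ties -> lower
    return pd.Series([QUARTILE_LABELS[i] for i in idx], index=scores.index, name="quartile")


def km_estimate(cohort: pd.DataFrame, time_grid=None) -> pd.DataFrame:
    """Product-limit survival estimate with an at-risk/events table.

    ``cohort`` needs columns time and event. Returns a frame indexed by
    event time with columns at_risk, events, survival; if ``time_grid``
    is given, rows are evaluated at those times instead (numbers at risk
    as displayed under a KM plot).
    """
    kmf = KaplanMeierFitter()
    kmf.fit(cohort["time"], cohort["event"])
    table = kmf.event_table
    out = pd.DataFrame(
        {
            "at_risk": table["at_risk"],
            "events": table["observed"],
            "survival": kmf.survival_function_["KM_estimate"].reindex(table.index).ffill(),
        }
    )
    if time_grid is not None:
        grid = np.asarray(time_grid, dtype=float)
        surv = kmf.survival_function_at_times(grid).to_numpy()
        at_risk = [(cohort["time"].to_numpy() >= t).sum() for t in grid]
        out = pd.DataFrame({"at_risk": at_risk, "survival": surv}, index=pd.Index(grid, name="time"))
    return out


def logrank(cohort: pd.DataFrame, group_col: str = "group") -> tuple[float, float]:
    """Two-group log-rank test; returns (chi2, p)."""
    groups = cohort[group_col].unique()
    if len(groups) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {len(groups)}")
    a = cohort[cohort[group_col] == groups[0]]
    b = cohort[cohort[group_col] == groups[1]]
    for label, grp in zip(groups, (a, b)):
        if grp["event"].sum() == 0:
            logger.warning("group %r has zero events", label)
    res = logrank_test(a["time"], b["time"], a["event"], b["event"])
    return float(res.test_statistic), float(res.p_value)


@dataclass
class SurvivalFit:
    """Cox fit summary for one exposure (plus optional covariates)."""

    exposure: str
    log_hr: float
    hr: float
    ci95_low: float
    ci95_high: float
    wald_p: float
    n: int
    n_events: int
    covariates: list[str] = field(default_factory=list)
    logrank_chi2: float | None = None
    logrank_p: float | None = None

    def __post_init__(self) -> None:
        if not (self.ci95_low <= self.hr <= self.ci95_high):
            raise ValueError("hazard ratio must lie inside its confidence interval")


def cox_fit(
    cohort: pd.DataFrame,
    exposure: str,
    covariates: list[str] | None = None,
) -> SurvivalFit:
    """Cox proportional-hazards fit with Efron tie handling.

    ``exposure`` names a numeric or two-level column of ``cohort``; a
    two-level column is coded 0/1 (first level by sort order = 0).
    Constant covariates are dropped with a warning; separation surfaces
    as :class:`CoxSeparationError`.
    """
    covariates = list(covariates or [])
    df = cohort[["time", "event", exposure, *covariates]].copy()
    if df[exposure].dtype == object or str(df[exposure].dtype) == "category":
        levels = sorted(df[exposure].unique())
        if len(levels) != 2:
            raise ValueError(f"categorical exposure must have 2 levels, got {levels}")
        df[exposure] = (df[exposure] == levels[1]).astype(float)
    if df[exposure].nunique() < 2:
        raise ValueError("exposure must take >= 2 distinct values")
    if df["event"].sum() < 1:
        raise ValueError("cohort has no events")
    for cov in list(covariates):
        if df[cov].nunique() < 2:
            logger.warning("dropping constant covariate %r", cov)
            covariates.remove(cov)
            df = df.drop(columns=cov)
    cph = CoxPHFitter()  # Efron ties are lifelines' default
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as exc:
        raise CoxSeparationError(
            "Cox fit failed to converge; with a binary exposure this usually "
            "indicates monotone-likelihood separation — consider penalization "
            "or merging groups"
        ) from exc
    row = cph.summary.loc[exposure]
    return SurvivalFit(
        exposure=exposure,
        log_hr=float(row["coef"]),
        hr=float(np.exp(row["coef"])),
        ci95_low=float(np.exp(row["coef lower 95%"])),
        ci95_high=float(np.exp(row["coef upper 95%"])),
        wald_p=float(row["p"]),
        n=len(df),
        n_events=int(df["event"].sum()),
        covariates=covariates,
    )


def quartile_survival_analysis(
    cohort: pd.DataFrame, score_col: str = "score"
) -> tuple[SurvivalFit, pd.DataFrame]:
    """Top-vs-bottom-quartile survival contrast (Q4 vs Q1).

    Stratifies the cohort by score quartile, restricts to Q1 and Q4,
    and reports the Cox hazard ratio of Q4 relative to Q1 together with
    the log-rank test. Returns (fit, stratified subset).
    """
    labels = quartile_stratify(cohort[score_col])
    sub = cohort.loc[labels.isin(["Q1", "Q4"])].copy()
    sub["group"] = labels.loc[sub.index]
    fit = cox_fit(sub, "group")
    chi2, p = logrank(sub, "group")
    fit.logrank_chi2, fit.logrank_p = chi2, p
    return fit, sub


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties; (rho, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors with >= 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def group_compare(values, labels, paired: bool = False) -> tuple[float, float]:
    """Two-tailed Student t test between two groups; (t, p).

    Equal-variance independent test by default; ``paired=True`` pairs
    observations by order within group.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = sorted(pd.unique(labels))
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(uniq)}")
    a = values[labels == uniq[0]]
    b = values[labels == uniq[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 observations per group")
    if np.var(np.concatenate([a - a.mean(), b - b.mean()])) == 0 and not paired:
        raise ValueError("zero pooled variance")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test needs equal group sizes")
        res = stats.ttest_rel(a, b)
    else:
        res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)
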