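"""Response and survival association statistics.

Fisher exact tests on DCB/ORR contingency tables, Kaplan-Meier medians,
log-rank tests, univariable Cox hazard ratios with Wald CIs, the TMBxITH
interaction term, and Spearman rank correlation.  Survival machinery is
delegated to lifelines (Efron tie handling in Cox fits); the two-sided
Fisher p follows the probability-mass convention so printed p-values can
be matched.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows = group (e.g. ITH-L / ITH-H), columns = outcome yes / no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass(frozen=True)
class SurvivalSummary:
    """Two-group survival comparison as the field reports it."""

    groups: tuple[str, str]
    median: dict
    logrank_p: float
    hr: float
    hr_ci: tuple[float, float]


def fisher_exact(
    table: ContingencyTable2x2, or_method: str = "sample"
) -> tuple[float, float]:
    """Two-sided Fisher exact test: (odds ratio, p).

    p sums hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed the observed table's
    (probability-mass definition).  The odds ratio is the sample ad/bc by
    default, or the conditional MLE with ``or_method="cmle"``.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a + b, c + d, a + c, b + d) == 0:
        warnings.warn("a margin of the 2x2 table is zero; p = 1 by convention")
        return math.nan, 1.0
    _, p = sps.fisher_exact(table.array, alternative="two-sided")
    if or_method == "cmle":
        odds = float(sps.contingency.odds_ratio(table.array).statistic)
    elif or_method == "sample":
        odds = math.inf if b * c == 0 else (a * d) / (b * c)
    else:
        raise ValueError(f"unknown odds-ratio method {or_method!r}")
    return float(odds), float(p)


def km_median(
    times: Sequence[float], events: Sequence[bool]
) -> Optional[float]:
    """Kaplan-Meier median: smallest time with estimated S(t) <= 0.5.

    None when the survival curve never reaches 0.5 (median not reached).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty group; cannot estimate a survival median")
    if np.any(times <= 0):
        raise ValueError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    med = kmf.median_survival_time_
    return None if math.isinf(med) else float(med)


def km_survival_function(
    times: Sequence[float], events: Sequence[bool]
) -> pd.DataFrame:
    """Product-limit estimate S(t) as a step function (index = event times)."""
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(times, float), event_observed=np.asarray(events, bool))
    return kmf.survival_function_


def logrank(
    times: Sequence[float], events: Sequence[bool], groups: Sequence
) -> float:
    """Two-group log-rank test p-value (chi-square, 1 df)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError(f"log-rank needs exactly 2 non-empty groups, got {labels.size}")
    if not events.any():
        raise ValueError("log-rank needs at least one observed event")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.p_value)


def _prepare_cox_frame(times, events, covariates: dict) -> pd.DataFrame:
    df = pd.DataFrame({"time": np.asarray(times, float)})
    df["event"] = np.asarray(events, bool).astype(int)
    for name, vals in covariates.items():
        df[name] = np.asarray(vals, float)
    return df


def cox_hr(
    times: Sequence[float], events: Sequence[bool], indicator: Sequence
) -> tuple[float, float, float]:
    """Univariable Cox PH fit for a binary indicator: (HR, CI low, CI high).

    Efron tie handling; Wald 95% CI = exp(beta +/- 1.96 * SE).  The HR is
    the hazard of indicator == 1 relative to indicator == 0, so pass the
    unfavorable group as 1 to match an HR > 1 presentation.
    """
    ind = np.asarray(indicator, float)
    if np.unique(ind).size < 2:
        raise ValueError("indicator is constant; hazard ratio undefined")
    events_arr = np.asarray(events, bool)
    for level in np.unique(ind):
        if events_arr[ind == level].sum() < 5:
            warnings.warn(
                f"fewer than 5 events at indicator level {level:g}; "
                "hazard-ratio estimate will be unstable"
            )
    df = _prepare_cox_frame(times, events, {"x": ind})
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:
        raise RuntimeError(f"Cox fit did not converge: {exc}") from exc
    beta = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    return math.exp(beta), math.exp(beta - 1.96 * se), math.exp(beta + 1.96 * se)


def interaction_p(
    times: Sequence[float],
    events: Sequence[bool],
    tmb_group: Sequence,
    ith_group: Sequence,
) -> float:
    """Wald p of the TMB x ITH product term in a Cox main-effects model."""
    tmb = np.asarray(tmb_group, float)
    ith = np.asarray(ith_group, float)
    if np.unique(tmb).size < 2 or np.unique(ith).size < 2:
        raise ValueError("both group indicators must vary")
    prod = tmb * ith
    X = np.column_stack([tmb, ith, prod])
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < 3:
        raise ValueError("group indicators are collinear; interaction unidentifiable")
    df = _prepare_cox_frame(times, events, {"tmb": tmb, "ith": ith, "tmb_x_ith": prod})
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:
        raise RuntimeError(f"Cox interaction fit did not converge: {exc}") from exc
    return float(cph.summary.loc["tmb_x_ith", "p"])


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties: (rho, p).

    p is exact (enumeration of all rank permutations) for n <= 9, else the
    usual t-approximation.  A constant vector makes rho undefined (NaN).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        warnings.warn("constant input; Spearman rho undefined")
        return math.nan, math.nan
    rho = float(sps.spearmanr(x, y).statistic)
    if n <= 9:
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        obs = abs(_pearson(rx, ry))
        count = 0
        total = 0
        for perm in permutations(ry):
            total += 1
            if abs(_pearson(rx, np.asarray(perm))) >= obs - 1e-12:
                count += 1
        return rho, count / total
    return rho, float(sps.spearmanr(x, y).pvalue)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    return float(a @ b / math.sqrt((a @ a) * (b @ b)))
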