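"""Kaplan-Meier estimation, log-rank tests, two-group Cox hazard ratios,
and score dichotomization at the median or a maximally selected cutpoint.

Times are in months. Tied event/censoring times at one instant are
resolved events-first (the product-limit convention). The two-group Cox
model maximizes the Breslow-ties partial likelihood by Newton-Raphson and
reports a Wald CI; a monotone-likelihood flag replaces the estimate when
one group has no events. Confidence bands for survival probabilities use
the log(-log) (exponential Greenwood) transform.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from escctme.core_io import SurvivalTable, ValidationError


@dataclass
class KMCurve:
    """Product-limit survival curve with at-risk counts and censor marks."""

    times: np.ndarray
    at_risk: np.ndarray
    survival: np.ndarray
    censor_times: np.ndarray
    lower_ci: np.ndarray
    upper_ci: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t) of the right-continuous step function (S(0) = 1)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "at_risk": self.at_risk,
                "survival": self.survival,
                "lower_ci": self.lower_ci,
                "upper_ci": self.upper_ci,
            }
        )


def km_estimate(records: SurvivalTable) -> KMCurve:
    """Kaplan-Meier product-limit estimate of the survival function."""
    if not len(records):
        raise ValidationError("empty survival table")
    kmf = KaplanMeierFitter()
    kmf.fit(records.time, records.event)
    sf = kmf.survival_function_
    ci = kmf.confidence_interval_survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy()
    ev = kmf.event_table
    at_risk = ev["at_risk"].reindex(sf.index).to_numpy(dtype=float)
    censor = records.time[records.event == 0]
    keep = times > 0
    return KMCurve(
        times=times[keep],
        at_risk=at_risk[keep],
        survival=surv[keep],
        censor_times=np.sort(censor),
        lower_ci=ci.iloc[:, 0].to_numpy()[keep],
        upper_ci=ci.iloc[:, 1].to_numpy()[keep],
    )


class LogrankResult(NamedTuple):
    statistic: float
    df: int
    p_value: float


def logrank_test(records: SurvivalTable, group_key: str = "group") -> LogrankResult:
    """Log-rank test across the groups of ``records`` (hypergeometric variance)."""
    groups = records.data[group_key]
    if groups.isna().any():
        raise ValidationError("every subject needs a group label")
    labels = groups.unique()
    if len(labels) < 2:
        raise ValidationError("log-rank needs >= 2 groups")
    res = multivariate_logrank_test(records.time, groups, records.event)
    return LogrankResult(
        statistic=float(res.test_statistic),
        df=int(len(labels) - 1),
        p_value=float(res.p_value),
    )


class CoxResult(NamedTuple):
    hazard_ratio: float
    ci_lower: float
    ci_upper: float
    p_value: float
    log_hr: float
    se: float
    diverged: bool


def _breslow_loglik(beta: float, time, event, x) -> float:
    order = np.argsort(-time, kind="stable")
    t, d, xv = time[order], event[order], x[order]
    eta = xv * beta
    ll = 0.0
    cum = 0.0
    i = 0
    n = len(t)
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        cum += np.sum(np.exp(eta[i:j]))
        ev = slice(i, j)
        d_here = d[ev].sum()
        if d_here:
            ll += np.sum(eta[ev][d[ev] == 1]) - d_here * np.log(cum)
        i = j
    return float(ll)


def cox_hr(records: SurvivalTable, group_key: str = "group") -> CoxResult:
    """Two-group Cox proportional-hazards fit (Breslow ties, Newton-Raphson).

    The binary covariate is 1 for the lexicographically larger group label,
    so HR > 1 means that group has the higher hazard. When either group
    has zero events the partial likelihood is monotone and a divergence
    flag is returned instead of an estimate.
    """
    groups = records.data[group_key]
    labels = sorted(groups.dropna().unique())
    if len(labels) != 2:
        raise ValidationError(f"cox_hr needs exactly 2 groups, got {labels}")
    x = (groups == labels[1]).to_numpy(dtype=float)
    time = records.time
    event = records.event
    if event.sum() == 0:
        raise ValidationError("no events in the survival table")
    if event[x == 1].sum() == 0 or event[x == 0].sum() == 0:
        return CoxResult(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, diverged=True)

    # Newton-Raphson on the Breslow partial likelihood
    beta = 0.0
    for _ in range(50):
        order = np.argsort(-time, kind="stable")
        t, d, xv = time[order], event[order], x[order]
        eta = np.exp(xv * beta)
        U = 0.0
        I = 0.0
        cum0 = cum1 = 0.0  # running sums of exp(eta) and x*exp(eta)
        i = 0
        n = len(t)
        while i < n:
            j = i
            while j < n and t[j] == t[i]:
                j += 1
            cum0 += eta[i:j].sum()
            cum1 += (xv[i:j] * eta[i:j]).sum()
            d_here = d[i:j].sum()
            if d_here:
                xbar = cum1 / cum0
                U += (xv[i:j][d[i:j] == 1]).sum() - d_here * xbar
                I += d_here * (xbar - xbar**2)
            i = j
        if I <= 0:
            return CoxResult(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, diverged=True)
        step = U / I
        beta += step
        if abs(step) < 1e-10:
            break
    se = 1.0 / np.sqrt(I)
    z = beta / se
    p = 2 * stats.norm.sf(abs(z))
    return CoxResult(
        hazard_ratio=float(np.exp(beta)),
        ci_lower=float(np.exp(beta - 1.959963984540054 * se)),
        ci_upper=float(np.exp(beta + 1.959963984540054 * se)),
        p_value=float(p),
        log_hr=float(beta),
        se=float(se),
        diverged=False,
    )


@dataclass(frozen=True)
class CutpointParams:
    """Dichotomization settings: median split or maximally selected cutpoint."""

    method: str = "median"
    min_prop: float = 0.1

    def __post_init__(self) -> None:
        if self.method not in ("median", "best"):
            raise ValidationError("method must be 'median' or 'best'")
        if not 0 < self.min_prop < 0.5:
            raise ValidationError("min_prop must lie in (0, 0.5)")


class CutpointResult(NamedTuple):
    cutpoint: float
    labels: pd.Series  # "high" / "low" per subject
    statistic: float  # |standardized log-rank| at the chosen cut (best method)
    p_value_uncorrected: float


def _standardized_logrank(time, event, high) -> float:
    """|O - E| / sqrt(V) for the two-group log-rank split."""
    order = np.argsort(time, kind="stable")
    t, d, g = time[order], event[order], high[order]
    O = E = V = 0.0
    n = len(t)
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        at_risk = n - i
        at_risk_high = g[i:].sum()
        d_here = d[i:j].sum()
        if d_here and 0 < at_risk_high < at_risk:
            d_high = d[i:j][g[i:j] == 1].sum()
            O += d_high
            E += d_here * at_risk_high / at_risk
            V += (
                d_here
                * (at_risk_high / at_risk)
                * (1 - at_risk_high / at_risk)
                * (at_risk - d_here)
                / max(at_risk - 1, 1)
            )
        i = j
    return abs(O - E) / np.sqrt(V) if V > 0 else 0.0


def dichotomize(
    scores: pd.Series,
    records: SurvivalTable,
    params: CutpointParams = CutpointParams(),
) -> CutpointResult:
    """Split subjects into high/low score groups for survival contrasts.

    median: "high" means score strictly above the median. best: the
    candidate cutpoint (each side keeping >= min_prop of subjects)
    maximizing the absolute standardized log-rank statistic; ties break to
    the lower cutpoint. The reported p-value is the naive log-rank p at the
    chosen cut, uncorrected for the cutpoint search.
    """
    scores = pd.Series(scores)
    if len(scores) < 4:
        raise ValidationError("dichotomization needs >= 4 subjects")
    vals = scores.to_numpy(dtype=float)
    if np.ptp(vals) == 0:
        raise ValidationError("all scores identical; no cutpoint exists")
    time, event = records.time, records.event

    if params.method == "median":
        cut = float(np.median(vals))
    else:
        if event.sum() == 0:
            raise ValidationError("best-cutpoint search needs >= 1 event")
        n = len(vals)
        min_side = max(1, int(np.ceil(params.min_prop * n)))
        candidates = np.unique(vals)[:-1]  # splitting above the max is empty
        best_stat, cut = -1.0, None
        for c in candidates:
            high = vals > c
            if high.sum() < min_side or (~high).sum() < min_side:
                continue
            stat = _standardized_logrank(time, event, high.astype(int))
            if stat > best_stat + 1e-12:
                best_stat, cut = stat, float(c)
        if cut is None:
            raise ValidationError("no admissible cutpoint under min_prop")

    high = vals > cut
    labels = pd.Series(np.where(high, "high", "low"), index=scores.index, name="group")
    stat = _standardized_logrank(time, event, high.astype(int))
    p = 2 * stats.norm.sf(stat) if stat > 0 else 1.0
    return CutpointResult(
        cutpoint=float(cut), labels=labels, statistic=float(stat), p_value_uncorrected=float(p)
    )


def efs_table(clinical: pd.DataFrame) -> SurvivalTable:
    """Event-free survival: first of progression, recurrence, metastasis or
    death; otherwise censored at the last follow-up.

    ``clinical`` columns: subject_id, optional time_progression,
    time_recurrence, time_metastasis, time_death, and time_last_followup
    (all in months from treatment initiation; NaN = did not occur).
    """
    event_cols = [
        c
        for c in ("time_progression", "time_recurrence", "time_metastasis", "time_death")
        if c in clinical.columns
    ]
    if "time_last_followup" not in clinical.columns:
        raise ValidationError("clinical table needs a time_last_followup column")
    first_event = clinical[event_cols].min(axis=1) if event_cols else pd.Series(
        np.nan, index=clinical.index
    )
    has_event = first_event.notna()
    time = np.where(has_event, first_event, clinical["time_last_followup"])
    return SurvivalTable.from_records(
        clinical["subject_id"],
        time,
        has_event.astype(int),
        groups=clinical["group"] if "group" in clinical.columns else None,
    )


def os_table(clinical: pd.DataFrame) -> SurvivalTable:
    """Overall survival: death from any cause; survivors censored at cutoff."""
    if "time_last_followup" not in clinical.columns:
        raise ValidationError("clinical table needs a time_last_followup column")
    death = clinical.get("time_death", pd.Series(np.nan, index=clinical.index))
    has_event = death.notna()
    time = np.where(has_event, death, clinical["time_last_followup"])
    return SurvivalTable.from_records(
        clinical["subject_id"],
        time,
        has_event.astype(int),
        groups=clinical["group"] if "group" in clinical.columns else None,
    )
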