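"""Overall-survival construction, Kaplan–Meier curves, log-rank tests and
Cox proportional-hazards models.

Overall survival (OS) runs from diagnosis to any-cause death or last
follow-up (censored).  TIL % enters the Cox model untransformed, so its
hazard ratio is per percentage point.  Ties use the Efron approximation.
lifelines backs the estimators; this module fixes the conventions and the
result containers.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .cohort_stats import DegenerateDataError, TestResult

DateLike = Union[_dt.date, _dt.datetime, str, pd.Timestamp]

DAYS_PER_YEAR = 365.25


class ConvergenceError(RuntimeError):
    """The partial-likelihood maximisation did not converge."""


@dataclass
class SurvCurve:
    """Product-limit survival curve."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: Optional[float]

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class CoxFit:
    """Per-covariate log-hazard coefficients with Wald CIs."""

    terms: list[str]
    beta: np.ndarray
    hr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p: np.ndarray
    ties: str = "efron"
    converged: bool = True
    n: int = 0
    n_events: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "beta": self.beta,
                "HR": self.hr,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p": self.p,
            }
        )


def make_os(
    diagnosis_date: DateLike,
    death_date: Optional[DateLike] = None,
    last_followup: Optional[DateLike] = None,
) -> tuple[float, int]:
    """(time in years, event) from diagnosis to death or last follow-up.

    event = 1 iff a death date is given.  Raises on follow-up before
    diagnosis.
    """
    d0 = pd.Timestamp(diagnosis_date)
    if death_date is not None:
        d1, event = pd.Timestamp(death_date), 1
    elif last_followup is not None:
        d1, event = pd.Timestamp(last_followup), 0
    else:
        raise ValueError("need death_date or last_followup")
    days = (d1 - d0).days
    if days < 0:
        raise ValueError("follow-up precedes diagnosis")
    return days / DAYS_PER_YEAR, event


def kaplan_meier(times: Sequence[float], events: Sequence[int]) -> SurvCurve:
    """Product-limit estimator.

    Median survival = earliest time with S(t) <= 0.5; ``None`` if the curve
    never reaches 0.5.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("need >= 1 subject")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    grid = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = (
        kmf.event_table["at_risk"].reindex(kmf.survival_function_.index).to_numpy()
    )
    below = np.nonzero(surv <= 0.5)[0]
    median = float(grid[below[0]]) if len(below) else None
    return SurvCurve(times=grid, survival=surv, at_risk=at_risk, median=median)


def log_rank(
    groups: Sequence, times: Sequence[float], events: Sequence[int]
) -> TestResult:
    """Log-rank chi-square across >= 2 groups, df = groups - 1."""
    groups = np.asarray(groups)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    if events.sum() == 0:
        raise DegenerateDataError("no events in any group")
    res = multivariate_logrank_test(times, groups, events)
    return TestResult(
        statistic=float(res.test_statistic), df=len(uniq) - 1, p=float(res.p_value)
    )


def cox_fit(
    design: pd.DataFrame,
    times: Sequence[float],
    events: Sequence[int],
    ties: str = "efron",
) -> CoxFit:
    """Cox proportional-hazards fit with Wald CIs (exp(beta +/- 1.96 SE)).

    Complete-case: rows with missing covariates are dropped.  Raises a
    degenerate-data error with no events, and a convergence error on
    monotone likelihood (perfect separation).
    """
    design = design.copy()
    df = design.assign(
        _time=np.asarray(times, dtype=float), _event=np.asarray(events, dtype=int)
    ).dropna()
    if df["_event"].sum() == 0:
        raise DegenerateDataError("no events: Cox model undefined")
    cph = CoxPHFitter()
    try:
        import warnings

        from lifelines.exceptions import ConvergenceWarning

        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            cph.fit(
                df,
                duration_col="_time",
                event_col="_event",
                fit_options={"step_size": 0.5},
            )
    except Exception as exc:  # lifelines raises ConvergenceError/Warning variants
        raise ConvergenceError(str(exc)) from exc
    terms = list(cph.params_.index)
    beta = cph.params_.to_numpy()
    se = cph.standard_errors_.to_numpy()
    z = 1.959963984540054
    return CoxFit(
        terms=terms,
        beta=beta,
        hr=np.exp(beta),
        ci_low=np.exp(beta - z * se),
        ci_high=np.exp(beta + z * se),
        p=cph.summary["p"].to_numpy(),
        ties="efron",
        converged=True,
        n=len(df),
        n_events=int(df["_event"].sum()),
    )


def univariable_cox(
    design: pd.DataFrame, times: Sequence[float], events: Sequence[int]
) -> dict[str, CoxFit]:
    """One single-covariate Cox fit per column of the design."""
    return {
        col: cox_fit(design[[col]], times, events) for col in design.columns
    }
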