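"""Right-censored survival machinery: Kaplan-Meier curves and the log-rank test.

Thin, typed wrappers over lifelines.  Time is measured in months from surgery;
the binary one-year endpoint used elsewhere in the package is "death within
12.0 months" (boundary inclusive), so the survival fields determine it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = ["SurvivalCurve", "km_estimate", "logrank_test", "ONE_YEAR_MONTHS", "dead_within_one_year"]

ONE_YEAR_MONTHS = 12.0


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate: event times, survival, at-risk and event counts."""

    times: np.ndarray          # distinct observed times, ascending (0 first)
    survival: np.ndarray       # S(t) at each time, starts at 1, non-increasing
    at_risk: np.ndarray        # number at risk just before each time
    n_events: np.ndarray       # deaths at each time
    n_censored: np.ndarray     # censorings at each time

    def survival_at(self, t: float) -> float:
        """Step-function evaluation of S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[max(idx, 0)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "n_events": self.n_events,
                "n_censored": self.n_censored,
            }
        )


def km_estimate(followup_months, event_flags) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator.

    ``event_flags`` marks deaths (1) vs censorings (0).  Ties at a time are
    handled the standard way: deaths are processed before censorings, so a
    patient censored at t still counts as at risk for deaths at t.
    """
    t = np.asarray(followup_months, dtype=float)
    e = np.asarray(event_flags).astype(int)
    if np.any(t < 0):
        raise ValueError("follow-up times must be non-negative")
    if t.shape != e.shape or t.size == 0:
        raise ValueError("times and event flags must be equal-length and non-empty")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table  # indexed by time, includes t=0 row
    times = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].reindex(table.index).to_numpy(dtype=float)
    return SurvivalCurve(
        times=times,
        survival=surv,
        at_risk=table["at_risk"].to_numpy(dtype=int),
        n_events=table["observed"].to_numpy(dtype=int),
        n_censored=table["censored"].to_numpy(dtype=int),
    )


def logrank_test(
    times_a, events_a, times_b, events_b
) -> tuple[float, float]:
    """Two-group log-rank test (1 df); returns ``(chi_square, p)``."""
    ta, tb = np.asarray(times_a, dtype=float), np.asarray(times_b, dtype=float)
    ea, eb = np.asarray(events_a).astype(int), np.asarray(events_b).astype(int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def dead_within_one_year(followup_months: float, event: bool) -> bool:
    """The binary one-year endpoint: death at or before 12.0 months."""
    return bool(event) and followup_months <= ONE_YEAR_MONTHS
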