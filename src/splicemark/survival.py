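"""Median-split survival association: Kaplan-Meier and log-rank.

Patients are split into low/high groups at the median of a junction's usage
(ties at the median go low), overall survival is summarized per group with
the product-limit estimator (Greenwood variance), and the groups are
compared with the standard log-rank test (chi-square, 1 df).  Deaths are
taken to precede censorings at tied times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank

__all__ = [
    "SurvivalError",
    "KMEstimate",
    "LogrankResult",
    "median_split",
    "km_estimate",
    "logrank_test",
    "survival_by_usage",
]


class SurvivalError(ValueError):
    pass


def median_split(values: pd.Series) -> pd.Series:
    """Assign "high" to values above the median, "low" otherwise.

    Requires >= 2 non-missing values and at least two distinct values (an
    all-identical vector has no defined split).
    """
    clean = values.dropna()
    if len(clean) < 2:
        raise SurvivalError("need at least 2 non-missing values to split")
    if clean.nunique() == 1:
        raise SurvivalError("all values identical; median split undefined")
    median = float(np.median(clean.to_numpy()))
    labels = pd.Series(
        np.where(clean > median, "high", "low"), index=clean.index, name="group"
    )
    return labels


@dataclass
class KMEstimate:
    """Product-limit curve: survival and Greenwood variance at event times."""

    times: np.ndarray       # distinct observed event times
    survival: np.ndarray    # S(t) just after each event time
    variance: np.ndarray    # Greenwood variance of S(t)
    n: int
    n_events: int

    def __post_init__(self) -> None:
        s = self.survival
        if s.size and (np.any(s < -1e-12) or np.any(s > 1 + 1e-12)):
            raise SurvivalError("survival outside [0, 1]")
        if s.size and np.any(np.diff(s) > 1e-12):
            raise SurvivalError("survival curve must be non-increasing")

    def survival_at(self, t: float) -> float:
        """S(t); 1 before the first event."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> KMEstimate:
    """Kaplan-Meier estimate with Greenwood variance.

    ``times`` are follow-up durations (>= 0), ``events`` 1 for an observed
    death and 0 for censoring.  A fully censored sample yields a flat curve
    at 1 with no steps.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise SurvivalError("no records")
    if (times < 0).any():
        raise SurvivalError("negative follow-up time")
    if not np.isin(events, (0, 1)).all():
        raise SurvivalError("event indicator must be 0 or 1")

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table  # deaths precede censorings at tied times
    steps = table[table["observed"] > 0]
    if steps.empty:
        return KMEstimate(
            np.array([]), np.array([]), np.array([]),
            n=int(times.size), n_events=0,
        )
    event_times = steps.index.to_numpy(dtype=float)
    d = steps["observed"].to_numpy(dtype=float)
    at_risk = steps["at_risk"].to_numpy(dtype=float)
    surv = np.array(
        [float(kmf.survival_function_at_times(t).iloc[0]) for t in event_times]
    )
    # Greenwood: Var(S) = S^2 * cumsum(d / (n (n - d))); terms with n == d
    # (curve hits zero) contribute an undefined term -> variance 0 there.
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = d / (at_risk * (at_risk - d))
    terms = np.where(np.isfinite(terms), terms, 0.0)
    var = surv**2 * np.cumsum(terms)
    return KMEstimate(event_times, surv, var, n=int(times.size), n_events=int(d.sum()))


@dataclass(frozen=True)
class LogrankResult:
    statistic: float | None
    p_value: float | None
    n_a: int
    n_b: int
    reason: str | None = None


def logrank_test(
    times_a, events_a, times_b, events_b
) -> LogrankResult:
    """Two-group log-rank test (observed - expected, hypergeometric variance)."""
    times_a = np.asarray(times_a, dtype=float)
    times_b = np.asarray(times_b, dtype=float)
    events_a = np.asarray(events_a, dtype=int)
    events_b = np.asarray(events_b, dtype=int)
    if times_a.size == 0 or times_b.size == 0:
        raise SurvivalError("both groups must be non-empty")
    if events_a.sum() + events_b.sum() == 0:
        return LogrankResult(
            None, None, times_a.size, times_b.size, reason="no events observed"
        )
    res = _lifelines_logrank(
        times_a, times_b, event_observed_A=events_a, event_observed_B=events_b
    )
    return LogrankResult(
        float(res.test_statistic), float(res.p_value), times_a.size, times_b.size
    )


def survival_by_usage(
    clinical: pd.DataFrame,
    usage: pd.Series,
    time_col: str = "time",
    event_col: str = "event",
) -> dict:
    """Median-split patients on a junction's usage and compare survival.

    ``clinical`` is indexed by person id with follow-up time and event
    columns; ``usage`` is the junction's per-person usage.  Duplicate person
    ids are collapsed to their first record (collisions are reported in the
    output).  Returns the group labels, per-group KM estimates, and the
    log-rank result.
    """
    dup = clinical.index.duplicated()
    n_collisions = int(dup.sum())
    clinical = clinical.loc[~dup]
    shared = clinical.index.intersection(usage.dropna().index)
    if len(shared) < 2:
        raise SurvivalError("fewer than 2 patients with usage and OS data")
    groups = median_split(usage.loc[shared])
    out: dict = {"groups": groups, "n_collisions": n_collisions, "km": {}}
    per_group = {}
    for label in ("low", "high"):
        ids = groups.index[groups == label]
        sub = clinical.loc[ids]
        per_group[label] = (sub[time_col].to_numpy(), sub[event_col].to_numpy())
        out["km"][label] = km_estimate(*per_group[label])
    out["logrank"] = logrank_test(
        *per_group["low"], *per_group["high"]
    )
    return out
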