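"""Kaplan–Meier, log-rank, reverse-KM follow-up and multivariable Cox models.

Endpoints are disease-specific survival (DSS, time to disease-specific
death) and disease-free survival (DFS, time to recurrence/metastasis), in
months. The product-limit estimator is implemented directly (the
:class:`KMCurve` contract, including at-risk counts, is part of this
package's interface); log-rank testing and proportional-hazards fitting
delegate to lifelines. Multivariable Cox models adjust the indicator of
interest for the standard clinico-pathological covariates: pT stage, pN
stage, lymphovascular invasion, age, gender, margin status, adjuvant
platinum chemotherapy and grade. Ties are handled by the Efron
approximation (the lifelines default).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import multivariate_logrank_test

from .io_model import COVARIATE_KEYS, PatientAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "KMCurve",
    "HazardEstimate",
    "NOT_REACHED",
    "km_estimate",
    "survival_at",
    "five_year_rate",
    "logrank_test",
    "reverse_km_followup",
    "cox_multivariable",
    "survival_frame",
    "DEFAULT_COVARIATES",
]

#: sentinel for a median that is never reached by the curve
NOT_REACHED = math.inf

DEFAULT_COVARIATES = tuple(COVARIATE_KEYS.values())


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate: survival steps at the distinct event times."""

    times: np.ndarray      # distinct event times, ascending
    survival: np.ndarray   # S(t) just after each event time
    at_risk: np.ndarray    # risk-set size at each event time
    n_events: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be non-increasing")


@dataclass(frozen=True)
class HazardEstimate:
    variable: str
    hr: float
    ci_low: float
    ci_high: float
    p_value: float


def _as_arrays(times, events) -> Tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.ndim != 1 or t.shape != e.shape:
        raise ValueError("times and events must be 1-D and of equal length")
    if t.size == 0:
        raise ValueError("empty survival input")
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    return t, e


def km_estimate(times: Sequence[float], events: Sequence[bool]) -> KMCurve:
    """Kaplan–Meier product-limit estimator.

    Subjects censored exactly at an event time are counted in the risk set
    at that time (events-first convention).
    """
    t, e = _as_arrays(times, events)
    event_times = np.unique(t[e])
    survival = np.empty(event_times.shape)
    at_risk = np.empty(event_times.shape, dtype=int)
    s = 1.0
    for i, et in enumerate(event_times):
        n_risk = int(np.sum(t >= et))
        d = int(np.sum(e & (t == et)))
        s *= 1.0 - d / n_risk
        survival[i] = s
        at_risk[i] = n_risk
    return KMCurve(event_times, survival, at_risk, int(e.sum()))


def survival_at(curve: KMCurve, t: float) -> float:
    """Right-continuous step-function value S(t); S(t) = 1 before the first
    event and stays at the last value beyond the final event time."""
    if t < 0:
        raise ValueError("t must be non-negative")
    idx = np.searchsorted(curve.times, t, side="right") - 1
    return 1.0 if idx < 0 else float(curve.survival[idx])


def five_year_rate(curve: KMCurve) -> float:
    """Survival probability at 60 months."""
    return survival_at(curve, 60.0)


def logrank_test(
    groups: Mapping[str, Tuple[Sequence[float], Sequence[bool]]],
) -> Tuple[float, float]:
    """k-group log-rank test; returns (chi-square statistic, p-value)."""
    if len(groups) < 2:
        raise ValueError("log-rank test requires at least two groups")
    all_t, all_e, labels = [], [], []
    for name, (t, e) in groups.items():
        t, e = np.asarray(t, dtype=float), np.asarray(e, dtype=bool)
        if t.size == 0:
            raise ValueError(f"group {name!r} has zero members")
        all_t.append(t)
        all_e.append(e)
        labels.extend([name] * t.size)
    t = np.concatenate(all_t)
    e = np.concatenate(all_e)
    if not e.any():
        raise ValueError("log-rank test requires at least one event")
    res = multivariate_logrank_test(t, np.asarray(labels), e)
    return float(res.test_statistic), float(res.p_value)


def reverse_km_followup(
    times: Sequence[float], events: Sequence[bool]
) -> float:
    """Median potential follow-up by reverse Kaplan–Meier.

    The event indicator is inverted (censorings become the events of
    interest) and the median of that curve is returned; ``NOT_REACHED``
    (inf) when the reversed curve never drops to 0.5.
    """
    t, e = _as_arrays(times, events)
    curve = km_estimate(t, ~e)
    below = np.nonzero(curve.survival <= 0.5)[0]
    if below.size == 0:
        return NOT_REACHED
    return float(curve.times[below[0]])


def survival_frame(
    annotations: Iterable[PatientAnnotation], endpoint: str = "dss"
) -> pd.DataFrame:
    """Patient-level survival frame (time, event, covariates) for one
    endpoint ('dss' or 'dfs')."""
    if endpoint not in ("dss", "dfs"):
        raise ValueError("endpoint must be 'dss' or 'dfs'")
    rows = []
    for a in annotations:
        row = {
            "patient_id": a.patient_id,
            "time": getattr(a, f"{endpoint}_time"),
            "event": getattr(a, f"{endpoint}_event"),
        }
        for key in DEFAULT_COVARIATES:
            row[key] = a.covariates.get(key)
        rows.append(row)
    return pd.DataFrame(rows)


def cox_multivariable(
    frame: pd.DataFrame,
    indicator: str,
    duration_col: str = "time",
    event_col: str = "event",
    covariates: Optional[Sequence[str]] = None,
) -> list[HazardEstimate]:
    """Multivariable Cox proportional-hazards model.

    Fits ``indicator`` plus the adjustment covariates (default: the eight
    clinico-pathological variables present in the frame). Categorical
    columns are dummy-encoded with the first level as reference; rows with
    missing values are complete-case excluded with a logged count. Returns
    one :class:`HazardEstimate` per model term, the indicator's first.
    Non-convergence surfaces as a RuntimeError with the fitter's diagnosis.
    """
    if covariates is None:
        covariates = [c for c in DEFAULT_COVARIATES if c in frame.columns]
    cols = [duration_col, event_col, indicator, *covariates]
    missing_cols = [c for c in cols if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"frame lacks column(s): {missing_cols}")
    df = frame[cols].copy()
    n0 = len(df)
    df = df.dropna()
    if len(df) < n0:
        logger.info(
            "cox_multivariable: excluded %d row(s) with missing covariates",
            n0 - len(df),
        )
    df[event_col] = df[event_col].astype(bool)

    model_terms: list[str] = []
    design = df[[duration_col, event_col]].copy()
    for col in [indicator, *covariates]:
        series = df[col]
        if series.dtype == object or isinstance(
            series.dtype, pd.CategoricalDtype
        ):
            dummies = pd.get_dummies(series, prefix=col, drop_first=True)
            for d in dummies.columns:
                design[d] = dummies[d].astype(float)
                model_terms.append(d)
        else:
            design[col] = series.astype(float)
            model_terms.append(col)

    fitter = CoxPHFitter()
    try:
        fitter.fit(design, duration_col=duration_col, event_col=event_col)
    except Exception as exc:  # lifelines ConvergenceError and kin
        raise RuntimeError(
            f"Cox model did not converge ({type(exc).__name__}): {exc}"
        ) from exc

    summary = fitter.summary
    estimates = []
    # indicator terms first, then adjustment terms, in design order
    ordered = sorted(
        model_terms,
        key=lambda term: not (term == indicator or term.startswith(f"{indicator}_")),
    )
    for term in ordered:
        row = summary.loc[term]
        estimates.append(HazardEstimate(
            variable=term,
            hr=float(row["exp(coef)"]),
            ci_low=float(row["exp(coef) lower 95%"]),
            ci_high=float(row["exp(coef) upper 95%"]),
            p_value=float(row["p"]),
        ))
    return estimates
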