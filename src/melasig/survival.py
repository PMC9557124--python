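"""Survival comparison of UV-high vs UV-low clusters.

Kaplan-Meier estimation, the two-group log-rank test, Cox proportional
hazards regression (Efron tie handling; lifelines does the partial-
likelihood maximization) and 1-year landmark analysis.  Covariates follow
the melanoma convention: cluster (UV-low vs UV-high reference), age
(continuous), sex (male vs female), stage (III/IV vs I/II) and mutation
class (non-BRAF vs BRAF hotspot).  Times are in days by default (TCGA
clinical convention); nothing below depends on the unit as long as it is
cohort-wide consistent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank

from .errors import (
    DataIntegrityError,
    DegenerateInputError,
    EmptyResultError,
    NumericalError,
    ParameterError,
)

DAYS_PER_YEAR = 365.25

#: Reference-level coding of the categorical covariates (reference -> 0).
CATEGORY_CODING: dict[str, dict[str, int]] = {
    "cluster": {"UV-high": 0, "UV-low": 1},
    "sex": {"female": 0, "male": 1},
    "stage": {"I/II": 0, "III/IV": 1},
    "mutation_class": {"BRAF hotspot": 0, "non-BRAF": 1},
}


def _check_times(times: np.ndarray) -> None:
    if np.any(times <= 0):
        raise DataIntegrityError("survival times must be strictly positive")


def km_estimate(times, events=None) -> pd.DataFrame:
    """Product-limit (Kaplan-Meier) survival estimate.

    Returns a step-function table with columns ``time, at_risk, survival``
    (one row per distinct observed time, plus t=0 with survival 1).
    ``events`` defaults to all-observed.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ParameterError("no subjects")
    _check_times(times)
    events = np.ones_like(times) if events is None else np.asarray(events, dtype=int)
    kmf = KaplanMeierFitter().fit(times, events)
    table = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    return pd.DataFrame(
        {
            "time": table.index.to_numpy(dtype=float),
            "at_risk": table["at_risk"].to_numpy(dtype=int),
            "survival": surv.reindex(table.index).to_numpy(dtype=float),
        }
    ).reset_index(drop=True)


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-tailed two-group log-rank test.

    Observed-minus-expected with hypergeometric variance at each distinct
    event time; returns (chi-square statistic, p) with 1 df.
    """
    times_a, times_b = np.asarray(times_a, float), np.asarray(times_b, float)
    events_a = np.asarray(events_a, int)
    events_b = np.asarray(events_b, int)
    if times_a.size == 0 or times_b.size == 0:
        raise ParameterError("both groups must be non-empty")
    _check_times(times_a)
    _check_times(times_b)
    if events_a.sum() + events_b.sum() == 0:
        raise ParameterError("log-rank test undefined with zero events")
    res = _ll_logrank(times_a, times_b, event_observed_A=events_a, event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxFit:
    """A fitted Cox proportional hazards model."""

    coefficients: dict[str, float]
    se: dict[str, float]
    hr: dict[str, float]                       # exp(coefficient)
    ci95: dict[str, tuple[float, float]]       # exp(coef -/+ 1.96 SE)
    p_values: dict[str, float]                 # Wald
    n: int
    n_events: int
    log_likelihood: float

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "se": self.se,
                "hr": self.hr,
                "hr_ci_low": {k: v[0] for k, v in self.ci95.items()},
                "hr_ci_high": {k: v[1] for k, v in self.ci95.items()},
                "p": self.p_values,
            }
        )


def encode_covariates(records: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    """Code categorical covariates 0/1 per :data:`CATEGORY_CODING`."""
    out = pd.DataFrame(index=records.index)
    for cov in covariates:
        if cov not in records.columns:
            raise ParameterError(f"covariate {cov!r} not in table")
        col = records[cov]
        if cov in CATEGORY_CODING:
            coding = CATEGORY_CODING[cov]
            bad = set(col.unique()) - set(coding)
            if bad:
                raise DataIntegrityError(f"covariate {cov!r} has unknown level(s): {bad}")
            out[cov] = col.map(coding).astype(float)
        else:
            out[cov] = pd.to_numeric(col)
    return out


def cox_fit(records: pd.DataFrame, covariates: Sequence[str]) -> CoxFit:
    """Fit a Cox PH model by partial likelihood (Efron tie handling).

    ``records`` needs ``time`` and ``event`` columns plus the listed
    covariates.  Standard errors come from the inverse observed
    information; per-covariate p-values are Wald tests and the 95% CI is
    exp(coef +/- 1.96 SE).
    """
    times = records["time"].to_numpy(dtype=float)
    _check_times(times)
    events = records["event"].to_numpy(dtype=int)
    if len(np.unique(times[events == 1])) < 2:
        raise DegenerateInputError("need at least two distinct event times")
    X = encode_covariates(records, covariates)
    const = [c for c in X.columns if X[c].nunique() <= 1]
    if const:
        raise DegenerateInputError(f"covariate(s) constant across samples: {const}")
    df = X.assign(time=times, event=events)
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as exc:
        raise NumericalError(f"Cox partial-likelihood fit did not converge: {exc}") from exc
    coef = cph.params_.to_dict()
    se = cph.standard_errors_.to_dict()
    ci95 = {
        k: (float(np.exp(coef[k] - 1.96 * se[k])), float(np.exp(coef[k] + 1.96 * se[k])))
        for k in coef
    }
    return CoxFit(
        coefficients={k: float(v) for k, v in coef.items()},
        se={k: float(v) for k, v in se.items()},
        hr={k: float(np.exp(v)) for k, v in coef.items()},
        ci95=ci95,
        p_values={k: float(v) for k, v in cph.summary["p"].to_dict().items()},
        n=len(records),
        n_events=int(events.sum()),
        log_likelihood=float(cph.log_likelihood_),
    )


def landmark_filter(records: pd.DataFrame, landmark_time: float = DAYS_PER_YEAR) -> pd.DataFrame:
    """Restrict to subjects still under follow-up at the landmark.

    Subjects whose event or censoring time does not exceed
    ``landmark_time`` are removed; remaining times are re-origined at the
    landmark (time -> time - landmark_time).
    """
    if landmark_time <= 0:
        raise ParameterError("landmark_time must be positive")
    kept = records[records["time"] > landmark_time].copy()
    if kept.empty:
        raise EmptyResultError("no subject remains at the landmark")
    kept["time"] = kept["time"] - landmark_time
    return kept
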