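"""Nonparametric estimators: Kaplan-Meier, naive 1-KM per cause, Aalen-Johansen.

Tie convention throughout: events at a time t are processed before censorings
at the same t (censored subjects leave the risk set after the events).
The Aalen-Johansen overall survival uses the product-limit form over the
summed per-cause increments, so the conservation identity

    sum_k CIF_k(t) + S(t) = 1

holds exactly (to machine precision) at every event time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .cohort import Cohort, ValidationError
from .stepfun import StepFunction

__all__ = ["CIFEstimate", "kaplan_meier", "naive_one_minus_km", "aalen_johansen"]


@dataclass(frozen=True)
class CIFEstimate:
    """Cumulative incidence curves for each cause plus the overall survival."""

    per_cause: Mapping[int, StepFunction]
    overall_survival: StepFunction
    at_risk: np.ndarray  # risk-set size just before each jump of overall_survival

    def cif(self, cause: int) -> StepFunction:
        return self.per_cause[cause]


def _risk_table(times, statuses):
    """Distinct event times with event counts and at-risk counts.

    Returns (uniq_times, n_at_risk, d) where d is the all-status event count
    at each distinct time among `uniq_times` (times with at least one event).
    """
    times = np.asarray(times, dtype=float)
    statuses = np.asarray(statuses)
    order = np.argsort(times, kind="stable")
    t = times[order]
    s = statuses[order]
    uniq = np.unique(t[s > 0])
    # at risk at u: subjects with time >= u
    n_at_risk = times.size - np.searchsorted(t, uniq, side="left")
    d = np.zeros(uniq.size)
    np.add.at(d, np.searchsorted(uniq, t[s > 0]), 1.0)
    return uniq, n_at_risk, d


def kaplan_meier(times, events) -> StepFunction:
    """Product-limit survival estimate with Greenwood standard errors.

    Parameters
    ----------
    times
        Positive follow-up times.
    events
        0/1 indicators (1 = event, 0 = censored).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValidationError("empty input")
    if np.any(times <= 0):
        raise ValidationError("times must be strictly positive")
    if not np.all(np.isin(events, [0, 1])):
        raise ValidationError("events must be 0/1 indicators")
    if events.sum() == 0:
        warnings.warn("no events: survival curve is constant at 1", UserWarning, stacklevel=2)
        return StepFunction(np.empty(0), np.empty(0), 1.0)
    uniq, n_at_risk, d = _risk_table(times, events)
    frac = 1.0 - d / n_at_risk
    surv = np.cumprod(frac)
    # Greenwood: var = S^2 * cumsum(d / (n (n - d)))
    with np.errstate(divide="ignore", invalid="ignore"):
        gw = np.cumsum(np.where(n_at_risk > d, d / (n_at_risk * (n_at_risk - d)), np.inf))
        se = np.where(np.isfinite(gw), surv * np.sqrt(gw), 0.0)
    return StepFunction(uniq, surv, 1.0, se=se)


def naive_one_minus_km(cohort: Cohort, cause: int) -> StepFunction:
    """The biased per-cause curve 1 - S_KM treating other causes as censored.

    Provided for bias demonstrations only: in the presence of competing
    events it overestimates the cumulative incidence of `cause`.
    """
    if not (1 <= cause <= cohort.n_causes):
        raise ValidationError(f"cause must be in 1..{cohort.n_causes}")
    ind = (cohort.events == cause).astype(int)
    km = kaplan_meier(cohort.times, ind)
    return StepFunction(km.times, 1.0 - km.values, 0.0, se=km.se)


def aalen_johansen(cohort: Cohort) -> CIFEstimate:
    """Aalen-Johansen plug-in estimate of all K cumulative incidence curves.

    CIF_k(t) = sum over event times u <= t of S(u-) d_k(u) / n(u), with S the
    product-limit estimate over all-cause events.
    """
    if len(cohort) == 0:
        raise ValidationError("empty cohort")
    times = cohort.times
    events = cohort.events
    K = cohort.n_causes
    any_event = (events > 0).astype(int)
    if any_event.sum() == 0:
        warnings.warn("no events: all CIFs are zero", UserWarning, stacklevel=2)
        empty = StepFunction(np.empty(0), np.empty(0), 0.0)
        return CIFEstimate(
            {k: empty for k in range(1, K + 1)},
            StepFunction(np.empty(0), np.empty(0), 1.0),
            np.empty(0),
        )
    uniq, n_at_risk, d_all = _risk_table(times, any_event)
    d_k = np.zeros((K, uniq.size))
    for k in range(1, K + 1):
        np.add.at(d_k[k - 1], np.searchsorted(uniq, times[events == k]), 1.0)
    surv = np.cumprod(1.0 - d_all / n_at_risk)
    s_left = np.concatenate([[1.0], surv[:-1]])
    incr = s_left * d_k / n_at_risk  # (K, m)
    cifs = np.cumsum(incr, axis=1)
    # delta-method variance of the AJ CIF (Aalen 1978 form)
    var_k = _aj_variance(uniq, n_at_risk, d_all, d_k, s_left, cifs)
    per_cause = {
        k: StepFunction(uniq, cifs[k - 1], 0.0, se=np.sqrt(var_k[k - 1]))
        for k in range(1, K + 1)
    }
    return CIFEstimate(per_cause, StepFunction(uniq, surv, 1.0), n_at_risk)


def _aj_variance(t, n, d_all, d_k, s_left, cifs):
    """Counting-process (delta-method) variance of the AJ CIF.

    Standard estimator (e.g. the one etm/cmprsk report):
      var{F_k(t)} = sum_{u<=t} [F_k(t) - F_k(u)]^2 d.(u) / n(u)^2
                  + sum_{u<=t} S(u-)^2 [1 - 2(F_k(t)-F_k(u))... ] -- we use the
    common simplified form with terms
      a = [F_k(t)-F_k(u)]^2 * d.(u)/(n(u)(n(u)-d.(u)))   (approximated with /n^2)
      b = S(u-)^2 (n(u)-d_k(u)) d_k(u) / n(u)^3
      c = -2 [F_k(t)-F_k(u)] S(u-) d_k(u) / n(u)^2
    """
    K, m = d_k.shape
    out = np.zeros((K, m))
    with np.errstate(divide="ignore", invalid="ignore"):
        for k in range(K):
            Fk = cifs[k]
            for j in range(m):
                diff = Fk[j] - Fk[: j + 1]
                a = diff**2 * d_all[: j + 1] / n[: j + 1] ** 2
                b = (
                    s_left[: j + 1] ** 2
                    * (n[: j + 1] - d_k[k, : j + 1])
                    * d_k[k, : j + 1]
                    / n[: j + 1] ** 3
                )
                c = -2.0 * diff * s_left[: j + 1] * d_k[k, : j + 1] / n[: j + 1] ** 2
                out[k, j] = np.sum(a + b + c)
    return np.clip(out, 0.0, None)
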