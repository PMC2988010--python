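"""Cause-specific Cox models and covariate-conditional CIF prediction.

One Cox model is fitted per cause, with events of all other causes treated
as censoring.  The K fitted hazards are then combined into cumulative
incidence curves by the discrete plug-in

    I_k(t; z) = sum_{t_j <= t} S(t_j-; z) dL_k(t_j; z)

where dL_k are the Breslow baseline increments of cause k scaled by
exp(beta_k'z) and S is the product-limit survival over the summed per-cause
increments.  The product-limit form (rather than exp of minus the summed
cumulative hazard) makes the conservation identity sum_k I_k + S = 1 exact
on the event grid and makes the null-model prediction coincide with the
Aalen-Johansen estimator.

Note: exp(-L_k(t; z)) for a single cause is deliberately not exposed — it is
not a marginal survival function in the presence of competing risks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .cohort import Cohort, DesignMatrix, ValidationError, encode, encode_profile
from .cox import CoxFit, fit_cox, rows_from_simple
from .nonparametric import CIFEstimate
from .stepfun import StepFunction

__all__ = ["CauseSpecificFit", "MinorRiskWarning", "fit_cause_specific", "predict_cif_cs"]

MINOR_RISK_EVENT_THRESHOLD = 10


class MinorRiskWarning(UserWarning):
    """A cause has very few events; regression output is unreliable."""


@dataclass
class CauseSpecificFit:
    per_cause: Mapping[int, CoxFit]
    cohort: Cohort
    covariate_names: tuple[str, ...]
    design: DesignMatrix
    skipped_causes: tuple[int, ...] = ()

    @property
    def n_causes(self) -> int:
        return self.cohort.n_causes


def fit_cause_specific(
    cohort: Cohort,
    covariates: Sequence[str],
    *,
    ties: str = "breslow",
) -> CauseSpecificFit:
    """Fit one Cox model per cause, censoring the other causes.

    A cause with no events is skipped (with a warning); a cause with fewer
    than 10 events is fitted but flagged as a minor risk.
    """
    design = encode(cohort, covariates)
    fits: dict[int, CoxFit] = {}
    skipped: list[int] = []
    for k in range(1, cohort.n_causes + 1):
        status = (cohort.events == k).astype(int)
        n_ev = int(status.sum())
        if n_ev == 0:
            warnings.warn(f"cause {k} has no events; fit skipped", UserWarning, stacklevel=2)
            skipped.append(k)
            continue
        if n_ev < MINOR_RISK_EVENT_THRESHOLD:
            warnings.warn(
                f"cause {k} has only {n_ev} events (minor risk); "
                "estimates may be unreliable",
                MinorRiskWarning,
                stacklevel=2,
            )
        rows = rows_from_simple(
            cohort.times, status, design.matrix, subject=cohort.ids,
            column_names=design.column_names,
        )
        fits[k] = fit_cox(rows, ties=ties)
    return CauseSpecificFit(fits, cohort, tuple(covariates), design, tuple(skipped))


def _scaled_increments(fit: CoxFit, z_row: np.ndarray):
    """Jump times and exp(beta'z)-scaled baseline hazard increments."""
    base = fit.baseline_cumhaz[fit.strata[0]]
    incr = np.diff(base.values, prepend=0.0)
    scale = float(np.exp(z_row @ fit.beta)) if fit.beta.size else 1.0
    return base.times, incr * scale


def combine_cause_hazards(
    jump_sets: Mapping[int, tuple[np.ndarray, np.ndarray]],
    at_risk_times: np.ndarray | None = None,
    survival: str = "product-limit",
) -> CIFEstimate:
    """Combine per-cause hazard increments into CIF curves.

    ``jump_sets`` maps cause -> (times, increments).  Survival is computed
    over the pooled event grid either as the product-limit over summed
    increments (default, conservation-exact) or as exp(-cumulative sum)
    (available for cross-checks).
    """
    pooled = np.unique(np.concatenate([t for t, _ in jump_sets.values()]))
    m = pooled.size
    dL = np.zeros((len(jump_sets), m))
    causes = sorted(jump_sets)
    for row, k in enumerate(causes):
        t, inc = jump_sets[k]
        pos = np.searchsorted(pooled, t)
        dL[row, pos] = inc
    total = dL.sum(axis=0)
    if survival == "product-limit":
        surv = np.cumprod(np.clip(1.0 - total, 0.0, None))
    elif survival == "exp":
        surv = np.exp(-np.cumsum(total))
    else:
        raise ValueError(f"unknown survival form {survival!r}")
    s_left = np.concatenate([[1.0], surv[:-1]])
    cifs = np.cumsum(s_left * dL, axis=1)
    per_cause = {k: StepFunction(pooled, cifs[i], 0.0) for i, k in enumerate(causes)}
    if at_risk_times is None:
        at_risk = np.full(m, np.nan)
    else:
        ts = np.sort(np.asarray(at_risk_times, dtype=float))
        at_risk = ts.size - np.searchsorted(ts, pooled, side="left")
    return CIFEstimate(per_cause, StepFunction(pooled, surv, 1.0), at_risk)


def predict_cif_cs(
    fit: CauseSpecificFit,
    profile: Mapping[str, object],
    grid: np.ndarray | None = None,
    *,
    survival: str = "product-limit",
) -> CIFEstimate:
    """Covariate-conditional CIF curves from the cause-specific fits.

    ``profile`` maps covariate names to raw values (e.g.
    ``{"sex": "male", "agegrp": "<40"}``).  With an empty covariate list the
    result equals the Aalen-Johansen estimate exactly.  If ``grid`` is given,
    the step functions are evaluated there (snapping down to the latest event
    time); otherwise curves live on the pooled event grid.
    """
    if fit.skipped_causes:
        raise ValidationError(
            f"cannot predict CIFs: cause(s) {fit.skipped_causes} were not fitted"
        )
    z = encode_profile(fit.cohort.schema, fit.covariate_names, profile)
    jump_sets = {k: _scaled_increments(f, z) for k, f in fit.per_cause.items()}
    est = combine_cause_hazards(jump_sets, at_risk_times=fit.cohort.times, survival=survival)
    if grid is None:
        return est
    grid = np.asarray(grid, dtype=float)
    per_cause = {
        k: StepFunction(grid, np.asarray(sf(grid), dtype=float).reshape(-1), 0.0)
        for k, sf in est.per_cause.items()
    }
    surv = StepFunction(grid, np.asarray(est.overall_survival(grid), dtype=float).reshape(-1), 1.0)
    ts = np.sort(fit.cohort.times)
    at_risk = ts.size - np.searchsorted(ts, grid, side="left")
    return CIFEstimate(per_cause, surv, at_risk)
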