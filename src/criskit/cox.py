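"""Cox proportional-hazards engine on counting-process rows.

This is the shared fitting machinery for the cause-specific, Fine-Gray and
Lunn-McNeil models.  Rows are (start, stop] intervals with a 0/1 status at
``stop``, a non-negative case weight, a stratum label and a design row.
The weighted log partial likelihood with Breslow tie handling is

    l(b) = sum_{events i} w_i x_i'b  -  sum_{event times j} dw_j log D_j(b)

with ``dw_j`` the summed weight of events at t_j and ``D_j`` the weighted
risk-set sum of exp(x'b).  Newton-Raphson with step-halving maximizes it;
risk-set sums are accumulated in sorted-time order so fits are deterministic
given the input order.

Breslow tie handling makes two exact invariants hold: duplicating a row is
identical to doubling its weight, and strata contribute additively to the
likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .stepfun import StepFunction

__all__ = [
    "CountingProcessRows",
    "CoxFit",
    "ConvergenceWarning",
    "SingularInformationError",
    "fit_cox",
    "breslow_baseline",
    "hazard_ratio_table",
    "check_proportionality",
    "rows_from_simple",
]


class ConvergenceWarning(UserWarning):
    pass


class SingularInformationError(ValueError):
    pass


@dataclass
class CountingProcessRows:
    """Counting-process data: one row per at-risk interval (start, stop]."""

    subject: np.ndarray
    start: np.ndarray
    stop: np.ndarray
    status: np.ndarray
    x: np.ndarray
    weight: np.ndarray | None = None
    stratum: np.ndarray | None = None
    column_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.subject = np.asarray(self.subject)
        self.start = np.asarray(self.start, dtype=float)
        self.stop = np.asarray(self.stop, dtype=float)
        self.status = np.asarray(self.status, dtype=int)
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
        if self.x.shape[0] != self.start.size and self.x.shape[1] == self.start.size:
            self.x = self.x.T
        n = self.start.size
        if self.weight is None:
            self.weight = np.ones(n)
        self.weight = np.asarray(self.weight, dtype=float)
        if self.stratum is None:
            self.stratum = np.zeros(n, dtype=int)
        self.stratum = np.asarray(self.stratum)
        if np.any(self.start >= self.stop):
            raise ValueError("need start < stop for every row")
        if np.any(self.weight < 0):
            raise ValueError("weights must be non-negative")
        if not self.column_names:
            self.column_names = tuple(f"x{j}" for j in range(self.x.shape[1]))

    @property
    def n(self) -> int:
        return int(self.start.size)

    @property
    def p(self) -> int:
        return int(self.x.shape[1])


def rows_from_simple(times, status, x, weight=None, subject=None, column_names=()) -> CountingProcessRows:
    """Build rows from plain right-censored data (start = 0 for everyone)."""
    times = np.asarray(times, dtype=float)
    n = times.size
    if subject is None:
        subject = np.arange(n)
    return CountingProcessRows(
        subject, np.zeros(n), times, status, np.asarray(x, dtype=float).reshape(n, -1),
        weight=weight, column_names=tuple(column_names),
    )


@dataclass
class CoxFit:
    beta: np.ndarray
    covariance: np.ndarray
    robust_covariance: np.ndarray | None
    loglik: float
    loglik_null: float
    baseline_cumhaz: Mapping[object, StepFunction]
    n_events: int
    iterations: int
    converged: bool
    ties_method: str
    column_names: tuple[str, ...]
    flags: tuple[str, ...] = ()
    strata: tuple = field(default_factory=tuple)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))

    @property
    def robust_se(self) -> np.ndarray | None:
        if self.robust_covariance is None:
            return None
        return np.sqrt(np.diag(self.robust_covariance))


class _StratumWork:
    """Pre-sorted views of one stratum, reused across Newton iterations."""

    def __init__(self, rows: CountingProcessRows, idx: np.ndarray):
        self.idx = idx
        self.start = rows.start[idx]
        self.stop = rows.stop[idx]
        self.status = rows.status[idx]
        self.w = rows.weight[idx]
        self.x = rows.x[idx]
        ev = self.status == 1
        if np.any(ev & (self.w > 0)):
            self.event_times = np.unique(self.stop[ev & (self.w > 0)])
        else:
            self.event_times = np.empty(0)
        m = self.event_times.size
        # weighted event count and weighted event x-sum per distinct event time
        self.dw = np.zeros(m)
        self.dwx = np.zeros((m, rows.p))
        if m:
            pos = np.searchsorted(self.event_times, self.stop[ev])
            np.add.at(self.dw, pos, self.w[ev])
            np.add.at(self.dwx, pos, self.w[ev, None] * self.x[ev])
        self.stop_order = np.argsort(self.stop, kind="stable")
        self.start_order = np.argsort(self.start, kind="stable")
        self.stop_sorted = self.stop[self.stop_order]
        self.start_sorted = self.start[self.start_order]
        # indices into suffix-cumsum arrays for each event time
        self.stop_pos = np.searchsorted(self.stop_sorted, self.event_times, side="left")
        self.start_pos = np.searchsorted(self.start_sorted, self.event_times, side="left")

    def _suffix(self, arr, order):
        """Suffix sums of arr (n, ...) in the given sort order; returns padded
        array where suffix[i] = sum of sorted arr[i:]."""
        a = arr[order]
        c = np.cumsum(a[::-1], axis=0)[::-1]
        pad = np.zeros((1,) + a.shape[1:])
        return np.concatenate([c, pad], axis=0)

    def risk_sums(self, r):
        """Weighted risk-set sums at each event time for r, r*x and r*x x'."""
        p = self.x.shape[1]
        rx = r[:, None] * self.x
        rxx = rx[:, :, None] * self.x[:, None, :]
        d0 = self._suffix(r, self.stop_order)[self.stop_pos] - self._suffix(r, self.start_order)[self.start_pos]
        d1 = self._suffix(rx, self.stop_order)[self.stop_pos] - self._suffix(rx, self.start_order)[self.start_pos]
        d2 = self._suffix(rxx, self.stop_order)[self.stop_pos] - self._suffix(rxx, self.start_order)[self.start_pos]
        m = self.event_times.size
        return d0, d1.reshape(m, p), d2.reshape(m, p, p)


def _loglik_score_info(works, rows, beta, ties):
    eta = rows.x @ beta
    # guard overflow for diverging coefficients during step-halving
    r_all = rows.weight * np.exp(np.clip(eta, -500, 500))
    p = rows.p
    ll, U, I = 0.0, np.zeros(p), np.zeros((p, p))
    for work in works:
        r = r_all[work.idx]
        if work.event_times.size == 0:
            continue
        d0, d1, d2 = work.risk_sums(r)
        if ties == "breslow":
            ll += float(np.sum(work.dwx @ beta) - np.sum(work.dw * np.log(d0)))
            xbar = d1 / d0[:, None]
            U += work.dwx.sum(axis=0) - (work.dw[:, None] * xbar).sum(axis=0)
            I += np.einsum("j,jab->ab", work.dw, d2 / d0[:, None, None]) - np.einsum(
                "j,ja,jb->ab", work.dw, xbar, xbar
            )
        elif ties == "efron":
            ll += float(np.sum(work.dwx @ beta))
            for j, t in enumerate(work.event_times):
                tied = (work.stop == t) & (work.status == 1) & (work.w > 0)
                wt = work.w[tied]
                rt = r[tied]
                xt = work.x[tied]
                d = wt.size
                wbar = wt.mean()
                s0t = rt.sum()
                s1t = (rt[:, None] * xt).sum(axis=0)
                s2t = ((rt[:, None] * xt)[:, :, None] * xt[:, None, :]).sum(axis=0)
                U += (wt[:, None] * xt).sum(axis=0)
                for el in range(d):
                    f = el / d
                    den = d0[j] - f * s0t
                    num1 = d1[j] - f * s1t
                    num2 = d2[j] - f * s2t
                    ll -= wbar * np.log(den)
                    U -= wbar * num1 / den
                    I += wbar * (num2 / den - np.outer(num1, num1) / den**2)
        else:
            raise ValueError(f"unknown ties method {ties!r}")
    return ll, U, I


def fit_cox(
    rows: CountingProcessRows,
    init: Sequence[float] | None = None,
    *,
    ties: str = "breslow",
    tol: float = 1e-9,
    max_iter: int = 50,
    robust: bool = False,
    compute_baseline: bool = True,
) -> CoxFit:
    """Maximize the weighted log partial likelihood by Newton-Raphson.

    Convergence: relative change in log-likelihood below ``tol`` (default
    1e-9), at most ``max_iter`` iterations, with up to 5 step-halvings per
    iteration.  The covariance is the inverse observed information; with
    ``robust=True`` a sandwich estimate from subject-level score residuals is
    added (mandatory for IPCW-weighted fits).
    """
    if rows.status.sum() == 0:
        raise ValueError("no events in the data")
    p = rows.p
    strata_labels = tuple(np.unique(rows.stratum))
    works = [_StratumWork(rows, np.nonzero(rows.stratum == s)[0]) for s in strata_labels]
    beta = np.zeros(p) if init is None else np.asarray(init, dtype=float).copy()

    ll_null = _loglik_score_info(works, rows, np.zeros(p), ties)[0]
    ll, U, I = _loglik_score_info(works, rows, beta, ties) if p else (ll_null, np.zeros(0), np.zeros((0, 0)))
    flags: list[str] = []
    converged = p == 0
    it = 0
    for it in range(1, max_iter + 1):
        if p == 0:
            break
        try:
            cond = np.linalg.cond(I)
        except np.linalg.LinAlgError:
            cond = np.inf
        if not np.isfinite(cond) or cond > 1e12:
            raise SingularInformationError(
                "information matrix is singular or ill-conditioned; "
                f"check columns {list(rows.column_names)} for collinearity"
            )
        step = np.linalg.solve(I, U)
        new_beta = beta + step
        new_ll, new_U, new_I = _loglik_score_info(works, rows, new_beta, ties)
        slack = tol * (abs(ll) + tol)
        halvings = 0
        while (not np.isfinite(new_ll) or new_ll < ll - slack) and halvings < 5:
            step *= 0.5
            new_beta = beta + step
            new_ll, new_U, new_I = _loglik_score_info(works, rows, new_beta, ties)
            halvings += 1
        if np.isfinite(new_ll) and new_ll >= ll - slack:
            delta = new_ll - ll
            if delta > 0:
                beta, ll, U, I = new_beta, new_ll, new_U, new_I
            if abs(delta) < slack:
                converged = True
                break
        else:
            flags.append("step_halving_failed")
            break
    if np.any(np.abs(beta) > 15):
        warnings.warn(
            "a coefficient exceeds 15 in absolute value: likely monotone "
            "partial likelihood (infinite MLE)",
            ConvergenceWarning,
            stacklevel=2,
        )
        flags.append("monotone_likelihood")
    if not converged:
        warnings.warn("Newton-Raphson did not converge", ConvergenceWarning, stacklevel=2)

    if p:
        cov = np.linalg.inv(I)
        cov = (cov + cov.T) / 2
    else:
        cov = np.zeros((0, 0))

    baseline: dict[object, StepFunction] = {}
    if compute_baseline:
        baseline = _baseline_from_works(works, strata_labels, rows, beta)

    robust_cov = None
    if robust and p:
        scores = _subject_score_residuals(works, rows, beta, baseline, strata_labels)
        meat = scores.T @ scores
        robust_cov = cov @ meat @ cov
        robust_cov = (robust_cov + robust_cov.T) / 2

    return CoxFit(
        beta=beta,
        covariance=cov,
        robust_covariance=robust_cov,
        loglik=float(ll),
        loglik_null=float(ll_null),
        baseline_cumhaz=baseline,
        n_events=int(rows.status.sum()),
        iterations=it,
        converged=converged,
        ties_method=ties,
        column_names=rows.column_names,
        flags=tuple(flags),
        strata=strata_labels,
    )


def _baseline_from_works(works, strata_labels, rows, beta):
    """Breslow baseline cumulative hazard per stratum: dL0_j = dw_j / D_j."""
    r_all = rows.weight * np.exp(np.clip(rows.x @ beta, -500, 500))
    out = {}
    for label, work in zip(strata_labels, works):
        if work.event_times.size == 0:
            out[label] = StepFunction(np.empty(0), np.empty(0), 0.0)
            continue
        d0 = work.risk_sums(r_all[work.idx])[0]
        incr = work.dw / d0
        out[label] = StepFunction(work.event_times, np.cumsum(incr), 0.0)
    return out


def breslow_baseline(fit: CoxFit, rows: CountingProcessRows) -> Mapping[object, StepFunction]:
    """Recompute the per-stratum Breslow baseline cumulative hazard."""
    strata_labels = tuple(np.unique(rows.stratum))
    works = [_StratumWork(rows, np.nonzero(rows.stratum == s)[0]) for s in strata_labels]
    return _baseline_from_works(works, strata_labels, rows, fit.beta)


def _subject_score_residuals(works, rows, beta, baseline, strata_labels):
    """Per-subject score residuals (Lin-Wei), for the sandwich variance.

    Row residual: w_i [ d_i (x_i - xbar(T_i)) - e^{eta_i} ( x_i {A(stop)-A(start)}
    - {B(stop)-B(start)} ) ] with A the baseline cumhaz and B the cumulative
    xbar-weighted baseline, both within the row's stratum.
    """
    p = rows.p
    resid = np.zeros((rows.n, p))
    eta = rows.x @ beta
    r_all = rows.weight * np.exp(np.clip(eta, -500, 500))
    for label, work in zip(strata_labels, works):
        idx = work.idx
        if work.event_times.size == 0:
            continue
        d0, d1, _ = work.risk_sums(r_all[idx])
        xbar = d1 / d0[:, None]
        dL = work.dw / d0
        A = np.concatenate([[0.0], np.cumsum(dL)])
        B = np.vstack([np.zeros(p), np.cumsum(xbar * dL[:, None], axis=0)])
        te = work.event_times
        a_stop = A[np.searchsorted(te, work.stop, side="right")]
        a_start = A[np.searchsorted(te, work.start, side="right")]
        b_stop = B[np.searchsorted(te, work.stop, side="right")]
        b_start = B[np.searchsorted(te, work.start, side="right")]
        expected = np.exp(np.clip(eta[idx], -500, 500))[:, None] * (
            work.x * (a_stop - a_start)[:, None] - (b_stop - b_start)
        )
        ev_term = np.zeros((idx.size, p))
        ev = work.status == 1
        if np.any(ev):
            pos = np.searchsorted(te, work.stop[ev])
            pos = np.clip(pos, 0, te.size - 1)
            ev_term[ev] = work.x[ev] - xbar[pos]
        resid[idx] = work.w[:, None] * (ev_term * ev[:, None] - expected)
    # collapse to one score per subject
    subj, inv = np.unique(rows.subject, return_inverse=True)
    out = np.zeros((subj.size, p))
    np.add.at(out, inv, resid)
    return out


def hazard_ratio_table(fit: CoxFit, level: float = 0.95, robust: bool | None = None):
    """Wald hazard-ratio table: HR, CI, two-sided p, percent change.

    Uses the robust standard errors when available unless ``robust=False``.
    """
    import pandas as pd

    if not fit.converged:
        warnings.warn("hazard ratios from a non-converged fit", ConvergenceWarning, stacklevel=2)
    if robust is None:
        robust = fit.robust_covariance is not None
    se = fit.robust_se if robust else fit.se
    if se is None:
        se = fit.se
    z = stats.norm.ppf(0.5 + level / 2)
    beta = fit.beta
    hr = np.exp(beta)
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = np.where(se > 0, beta / se, 0.0)
    pvals = 2 * stats.norm.sf(np.abs(zstat))
    pvals = np.where((beta == 0), np.minimum(pvals, 1.0), pvals)
    return pd.DataFrame(
        {
            "term": list(fit.column_names),
            "beta": beta,
            "se": se,
            "hr": hr,
            "lcl": np.exp(beta - z * se),
            "ucl": np.exp(beta + z * se),
            "p": pvals,
            "pct_change": (hr - 1.0) * 100.0,
        }
    )


def _split_at_event_times(rows: CountingProcessRows):
    """Episode-split every row at the distinct event times it spans.

    Returns (new_rows_without_x_change, split_stop_times) where each output
    row ends at an event time; intervals after the last spanned event time
    carry no partial-likelihood information and are dropped.
    """
    te = np.unique(rows.stop[rows.status == 1])
    subj, start, stop, status, weight, stratum, xs = [], [], [], [], [], [], []
    for i in range(rows.n):
        lo, hi = rows.start[i], rows.stop[i]
        inside = te[(te > lo) & (te <= hi)]
        prev = lo
        for t in inside:
            subj.append(rows.subject[i])
            start.append(prev)
            stop.append(t)
            status.append(int(rows.status[i] == 1 and t == hi))
            weight.append(rows.weight[i])
            stratum.append(rows.stratum[i])
            xs.append(rows.x[i])
            prev = t
    return CountingProcessRows(
        np.array(subj, dtype=object),
        np.array(start),
        np.array(stop),
        np.array(status),
        np.array(xs),
        weight=np.array(weight),
        stratum=np.array(stratum),
        column_names=rows.column_names,
    )


def check_proportionality(fit: CoxFit, rows: CountingProcessRows):
    """Proportional-hazards diagnostics.

    Returns a dict with:

    - ``"interactions"``: a table with one row per covariate giving the Wald
      p-value of an added covariate-by-log(time) interaction (time-dependent
      covariate refit on episode-split rows);
    - ``"cloglog"``: for each binary design column, log(-log S_KM) curves of
      the two groups as :class:`StepFunction` objects.
    """
    import pandas as pd

    from .nonparametric import kaplan_meier

    split = _split_at_event_times(rows)
    results = []
    for j, name in enumerate(fit.column_names):
        inter = split.x[:, j] * np.log(split.stop)
        x_aug = np.column_stack([split.x, inter])
        aug = CountingProcessRows(
            split.subject, split.start, split.stop, split.status, x_aug,
            weight=split.weight, stratum=split.stratum,
            column_names=fit.column_names + (f"{name}:log(t)",),
        )
        try:
            f2 = fit_cox(aug, init=np.append(fit.beta, 0.0), ties=fit.ties_method,
                         compute_baseline=False)
            b = f2.beta[-1]
            se = f2.se[-1]
            pv = 2 * stats.norm.sf(abs(b) / se) if se > 0 else np.nan
            results.append((name, b, se, pv))
        except (SingularInformationError, ValueError):
            results.append((name, np.nan, np.nan, np.nan))
    table = pd.DataFrame(results, columns=["term", "beta_logt", "se", "p"])

    cloglog: dict[str, dict[object, StepFunction]] = {}
    base = rows  # group KM uses the unsplit rows (start==0 expected)
    for j, name in enumerate(fit.column_names):
        vals = np.unique(base.x[:, j])
        if vals.size != 2:
            continue
        curves = {}
        for v in vals:
            m = base.x[:, j] == v
            km = kaplan_meier(base.stop[m], base.status[m])
            keep = km.values > 0
            with np.errstate(divide="ignore"):
                curves[v] = StepFunction(
                    km.times[keep], np.log(-np.log(np.clip(km.values[keep], 1e-300, 1 - 1e-16))),
                    initial_value=-np.inf,
                )
        cloglog[name] = curves
    return {"interactions": table, "cloglog": cloglog}
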