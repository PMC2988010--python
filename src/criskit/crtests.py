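"""K-sample tests: Gray's test for equality of CIFs and the log-rank test.

Gray's test compares weighted averages of subdistribution hazards across
groups.  With weight (1 - F_1(t-))^rho on the pooled CIF, the group-g score
is

    z_g = sum_j W_j [ d_1g(t_j) - R_g(t_j) d_1.(t_j) / R_.(t_j) ]

where R_g(t) = Y_g(t) (1 - F_1g(t-)) / S_g(t-) is the subdistribution risk
set (identically the IPCW-weighted Fine-Gray risk set with group-wise
censoring weights).  The covariance estimator is the counting-process one:
writing the score as sums of integrals against the cause-1 and
competing-cause martingales of each group,

    z_g = sum_h int A_gh dM_1h + B_gh dM_2h,
    A_gh(t) = W(t) c_gh(t) - eta_gh(t) F_2h(t-) / Y_h(t),
    B_gh(t) = -eta_gh(t) (1 - F_1h(t-)) / Y_h(t),
    c_gh(t) = 1{g=h} - R_g(t)/R_.(t),
    eta_gh(t) = sum_{t_l > t} W_l c_gh(t_l) (Y_h(t_l)/S_h(t_l-)) dLam*(t_l),

with dLam*(t_l) = d_1.(t_l)/R_.(t_l), and plug-ins dN_1h and dN_2h for the
martingale variation.  The eta terms account for the estimation of the
group-wise subdistribution risk sets; they vanish when there are no
competing events, and the statistic then reduces exactly to the log-rank
statistic (with its tie-uncorrected variance), which is also the convention
:func:`logrank_test` uses so the K=1 equivalence is exact.

A label-permutation p-value is available as an internal cross-check of the
analytic variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort import Cohort, ValidationError
from .nonparametric import aalen_johansen

__all__ = ["CRTestResult", "gray_test", "logrank_test"]


@dataclass(frozen=True)
class CRTestResult:
    statistic: float
    df: int
    p_value: float
    method: str
    rho: float = 0.0
    per_group: dict | None = None
    permutation_p: float | None = None


def _group_arrays(cohort: Cohort, group: str):
    if group not in cohort.covariates:
        raise ValidationError(f"unknown group covariate {group!r}")
    raw = cohort.covariates[group].astype(str)
    labels = sorted(set(raw))
    if len(labels) < 2:
        raise ValidationError("need at least two groups")
    return raw, labels


def _gray_statistic(times, events, raw, labels, cause, rho, n_causes):
    """Score vector, covariance and chi-square statistic of Gray's test."""
    G = len(labels)
    grid = np.unique(times[events > 0])
    m = grid.size
    # pooled target-cause CIF left limits for the rho-weight
    pooled = aalen_johansen(
        Cohort(np.arange(times.size), times, events, n_causes=n_causes)
    )
    F1_pool = np.asarray(pooled.per_cause[cause].left_limit(grid), dtype=float)
    W = (1.0 - F1_pool) ** rho

    Y = np.zeros((G, m))
    d1 = np.zeros((G, m))
    d2 = np.zeros((G, m))
    F1m = np.zeros((G, m))  # F_1h(t-)
    F2m = np.zeros((G, m))  # sum of competing-cause CIFs at t-
    Sm = np.ones((G, m))  # S_h(t-)
    for h, lab in enumerate(labels):
        sel = raw == lab
        t_h, e_h = times[sel], events[sel]
        ts = np.sort(t_h)
        Y[h] = ts.size - np.searchsorted(ts, grid, side="left")
        m1 = e_h == cause
        np.add.at(d1[h], np.searchsorted(grid, t_h[m1]), 1.0)
        m2 = (e_h > 0) & ~m1
        np.add.at(d2[h], np.searchsorted(grid, t_h[m2]), 1.0)
        if (e_h > 0).any():
            aj = aalen_johansen(Cohort(np.arange(t_h.size), t_h, e_h, n_causes=n_causes))
            F1m[h] = np.asarray(aj.per_cause[cause].left_limit(grid), dtype=float)
            for k in aj.per_cause:
                if k != cause:
                    F2m[h] += np.asarray(aj.per_cause[k].left_limit(grid), dtype=float)
            Sm[h] = np.asarray(aj.overall_survival.left_limit(grid), dtype=float)

    with np.errstate(divide="ignore", invalid="ignore"):
        R = np.where(Sm > 0, Y * (1.0 - F1m) / Sm, 0.0)
    Rtot = R.sum(axis=0)
    d1tot = d1.sum(axis=0)
    ok = Rtot > 0
    dLam = np.zeros(m)
    dLam[ok] = d1tot[ok] / Rtot[ok]

    c = np.zeros((G, G, m))  # c[g, h, j]
    for g in range(G):
        for h in range(G):
            with np.errstate(divide="ignore", invalid="ignore"):
                c[g, h] = np.where(ok, (1.0 if g == h else 0.0) - R[g] / Rtot, 0.0)

    z = np.array([np.sum(W * (d1[g] - np.where(ok, R[g] * dLam, 0.0))) for g in range(G)])

    # eta_gh(t_j) = sum_{l > j} W_l c_gh(l) q_h(l) dLam_l, exclusive suffix sum
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(Sm > 0, Y / Sm, 0.0)
    eta = np.zeros((G, G, m))
    for g in range(G):
        for h in range(G):
            a = W * c[g, h] * q[h] * dLam
            suf = np.concatenate([np.cumsum(a[::-1])[::-1][1:], [0.0]])
            eta[g, h] = suf

    with np.errstate(divide="ignore", invalid="ignore"):
        invY = np.where(Y > 0, 1.0 / Y, 0.0)
    V = np.zeros((G, G))
    for h in range(G):
        A = W[None, :] * c[:, h, :] - eta[:, h, :] * (F2m[h] * invY[h])[None, :]
        B = -eta[:, h, :] * ((1.0 - F1m[h]) * invY[h])[None, :]
        # cause-1 martingale variation uses the pooled-compensator plug-in
        # R_h dLam*, so with no competing events the statistic reduces
        # exactly to the log-rank chi-square of logrank_test
        V += (A[:, None, :] * A[None, :, :] * (R[h] * dLam)[None, None, :]).sum(axis=2)
        V += (B[:, None, :] * B[None, :, :] * d2[h][None, None, :]).sum(axis=2)

    z1 = z[1:]
    V11 = V[1:, 1:]
    try:
        stat = float(z1 @ np.linalg.solve(V11, z1))
    except np.linalg.LinAlgError:
        stat = float(z1 @ np.linalg.pinv(V11) @ z1)
    return max(stat, 0.0), z, V


def gray_test(
    cohort: Cohort,
    group: str,
    cause: int = 1,
    rho: float = 0.0,
    permutations: int = 0,
    seed: int = 0,
) -> CRTestResult:
    """Gray's K-sample test for equality of cause-``cause`` CIFs across groups.

    ``permutations > 0`` additionally computes a label-permutation p-value
    (seeded), reported in ``permutation_p``.
    """
    if not (1 <= cause <= cohort.n_causes):
        raise ValidationError(f"cause must be in 1..{cohort.n_causes}")
    if not np.any(cohort.events == cause):
        raise ValidationError(f"no events of cause {cause}")
    raw, labels = _group_arrays(cohort, group)
    stat, z, V = _gray_statistic(
        cohort.times, cohort.events, raw, labels, cause, rho, cohort.n_causes
    )
    df = len(labels) - 1
    p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    perm_p = None
    if permutations > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(permutations):
            perm = rng.permutation(raw)
            s_perm, _, _ = _gray_statistic(
                cohort.times, cohort.events, perm, labels, cause, rho, cohort.n_causes
            )
            if s_perm >= stat:
                count += 1
        perm_p = (1 + count) / (1 + permutations)
    per_group = {lab: {"score": float(z[i]), "n": int(np.sum(raw == lab))} for i, lab in enumerate(labels)}
    return CRTestResult(stat, df, p, "gray", rho, per_group, perm_p)


def logrank_test(cohort: Cohort, group: str, cause: int | None = None) -> CRTestResult:
    """Log-rank test for group differences in the (cause-specific) hazard.

    ``cause=None`` uses all-cause events; otherwise only events of the given
    cause count and other causes are treated as censored.  The variance is
    the martingale (tie-uncorrected) form

        V_gg' = sum_j d_j (1{g=g'} Y_g/Y - Y_g Y_g' / Y^2),

    which is what Gray's test reduces to in the absence of competing risks.
    """
    raw, labels = _group_arrays(cohort, group)
    if cause is None:
        status = (cohort.events > 0).astype(int)
    else:
        if not (1 <= cause <= cohort.n_causes):
            raise ValidationError(f"cause must be in 1..{cohort.n_causes}")
        status = (cohort.events == cause).astype(int)
    if status.sum() == 0:
        raise ValidationError("no qualifying events")
    times = cohort.times
    grid = np.unique(times[status == 1])
    G = len(labels)
    m = grid.size
    Y = np.zeros((G, m))
    d = np.zeros((G, m))
    for h, lab in enumerate(labels):
        sel = raw == lab
        ts = np.sort(times[sel])
        Y[h] = ts.size - np.searchsorted(ts, grid, side="left")
        np.add.at(d[h], np.searchsorted(grid, times[sel & (status == 1)]), 1.0)
    Ytot = Y.sum(axis=0)
    dtot = d.sum(axis=0)
    frac = Y / Ytot
    z = (d - frac * dtot).sum(axis=1)
    V = np.zeros((G, G))
    for g in range(G):
        for g2 in range(G):
            V[g, g2] = np.sum(dtot * (((g == g2) * frac[g]) - frac[g] * frac[g2]))
    z1, V11 = z[1:], V[1:, 1:]
    try:
        stat = float(z1 @ np.linalg.solve(V11, z1))
    except np.linalg.LinAlgError:
        stat = float(z1 @ np.linalg.pinv(V11) @ z1)
    stat = max(stat, 0.0)
    df = G - 1
    p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    per_group = {
        lab: {"observed": float(d[i].sum()), "expected": float((frac[i] * dtot).sum())}
        for i, lab in enumerate(labels)
    }
    return CRTestResult(stat, df, p, "logrank", 0.0, per_group)
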