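"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorized code paths: plain loops
over subjects and a grid/golden-section maximizer, so that agreement with
the Newton-Raphson engine is a genuine dual-route check.
"""

from __future__ import annotations

import numpy as np


def breslow_loglik(times, status, x, beta, weights=None, starts=None):
    """Weighted Breslow log partial likelihood by explicit loops."""
    times = np.asarray(times, dtype=float)
    status = np.asarray(status, dtype=int)
    x = np.asarray(x, dtype=float).reshape(len(times), -1)
    w = np.ones(len(times)) if weights is None else np.asarray(weights, dtype=float)
    s = np.zeros(len(times)) if starts is None else np.asarray(starts, dtype=float)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    ll = 0.0
    for t in np.unique(times[status == 1]):
        denom = 0.0
        for i in range(len(times)):
            if s[i] < t <= times[i]:
                denom += w[i] * np.exp(x[i] @ beta)
        for i in range(len(times)):
            if times[i] == t and status[i] == 1:
                ll += w[i] * (x[i] @ beta - np.log(denom))
    return ll


def grid_maximize_1d(times, status, x, lo=-5.0, hi=5.0, coarse=1e-2, fine=1e-6):
    """Grid search for the 1-covariate Breslow MLE, then local refinement."""
    grid = np.arange(lo, hi + coarse, coarse)
    lls = np.array([breslow_loglik(times, status, x, b) for b in grid])
    b0 = grid[np.argmax(lls)]
    lo2, hi2 = b0 - 2 * coarse, b0 + 2 * coarse
    while hi2 - lo2 > fine:
        grid = np.linspace(lo2, hi2, 21)
        lls = np.array([breslow_loglik(times, status, x, b) for b in grid])
        b0 = grid[np.argmax(lls)]
        step = (hi2 - lo2) / 20
        lo2, hi2 = b0 - step, b0 + step
    return b0


def logrank_by_hand(times, status, group):
    """Two-sample log-rank score and martingale variance by explicit loops.

    Returns (score for group 1, variance, chi-square).
    """
    times = np.asarray(times, dtype=float)
    status = np.asarray(status, dtype=int)
    group = np.asarray(group)
    labels = sorted(set(group.tolist()))
    assert len(labels) == 2
    z = 0.0
    v = 0.0
    for t in np.unique(times[status == 1]):
        at_risk = times >= t
        y = at_risk.sum()
        y1 = (at_risk & (group == labels[1])).sum()
        d = ((times == t) & (status == 1)).sum()
        d1 = ((times == t) & (status == 1) & (group == labels[1])).sum()
        z += d1 - y1 * d / y
        v += d * (y1 / y) * (1 - y1 / y)
    chi2 = z**2 / v if v > 0 else 0.0
    return z, v, chi2


def aalen_johansen_by_hand(times, events, cause):
    """CIF of one cause by an explicit product-limit loop.

    Returns (event_times, cif_values).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    ts = np.unique(times[events > 0])
    surv = 1.0
    cif = 0.0
    out = []
    for t in ts:
        n_at = (times >= t).sum()
        d_all = ((times == t) & (events > 0)).sum()
        d_c = ((times == t) & (events == cause)).sum()
        cif += surv * d_c / n_at
        surv *= 1 - d_all / n_at
        out.append(cif)
    return ts, np.array(out)
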