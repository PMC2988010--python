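import numpy as np
import pytest

from criskit import (
    CountingProcessRows,
    breslow_baseline,
    check_proportionality,
    fit_cox,
    hazard_ratio_table,
    rows_from_simple,
)
from criskit.cox import ConvergenceWarning, SingularInformationError

from .oracles import breslow_loglik, grid_maximize_1d


def three_subject_rows():
    # (t=1, event, z=1), (t=2, event, z=0), (t=3, censored, z=1)
    return rows_from_simple([1, 2, 3], [1, 1, 0], np.array([[1.0], [0.0], [1.0]]))


class TestFit:
    def test_symmetric_groups_give_zero(self):
        rows = rows_from_simple(
            [1, 2, 1, 2], [1, 1, 1, 1], np.array([[0.0], [0.0], [1.0], [1.0]])
        )
        f = fit_cox(rows)
        assert f.beta[0] == pytest.approx(0.0, abs=1e-10)

    def test_stationary_point_closed_form(self):
        # score numerator 1 - 2 x^2 with x = e^beta => beta = -ln(2)/2
        f = fit_cox(three_subject_rows())
        assert f.converged
        assert f.beta[0] == pytest.approx(-np.log(2) / 2, abs=1e-9)

    def test_loglik_exceeds_null(self):
        f = fit_cox(three_subject_rows())
        assert f.loglik >= f.loglik_null

    def test_covariance_symmetric_psd(self):
        f = fit_cox(three_subject_rows())
        np.testing.assert_allclose(f.covariance, f.covariance.T)
        assert np.all(np.linalg.eigvalsh(f.covariance) >= 0)

    def test_no_events_raises(self):
        rows = rows_from_simple([1, 2], [0, 0], np.array([[1.0], [0.0]]))
        with pytest.raises(ValueError):
            fit_cox(rows)

    def test_monotone_likelihood_flagged(self):
        # perfectly separated covariate
        rows = rows_from_simple(
            [1, 2, 3, 4], [1, 1, 0, 0], np.array([[1.0], [1.0], [0.0], [0.0]])
        )
        with pytest.warns(ConvergenceWarning):
            f = fit_cox(rows)
        assert "monotone_likelihood" in f.flags

    def test_singular_information_raises(self):
        x = np.array([[1.0, 2.0], [0.0, 0.0], [1.0, 2.0], [0.0, 0.0]])
        rows = rows_from_simple([1, 2, 3, 4], [1, 1, 1, 0], x)
        with pytest.raises(SingularInformationError):
            fit_cox(rows)

    def test_matches_grid_oracle_small_fixtures(self):
        rng = np.random.default_rng(0)
        for trial in range(6):
            n = int(rng.integers(4, 9))
            times = np.sort(rng.exponential(2, n)).round(2) + 0.01
            status = rng.integers(0, 2, n)
            if status.sum() == 0:
                status[0] = 1
            x = rng.integers(0, 2, n).astype(float).reshape(-1, 1)
            if len(np.unique(x[status == 1])) < 2 or len(np.unique(x)) < 2:
                continue
            rows = rows_from_simple(times, status, x)
            try:
                f = fit_cox(rows)
            except SingularInformationError:
                continue
            if "monotone_likelihood" in f.flags or not (-5 < f.beta[0] < 5):
                continue
            b_grid = grid_maximize_1d(times, status, x)
            assert f.beta[0] == pytest.approx(b_grid, abs=1e-6)

    def test_loglik_agrees_with_bruteforce(self, sim_cohort):
        from criskit import encode

        d = encode(sim_cohort, ["male"])
        idx = slice(0, 40)
        t, s, x = sim_cohort.times[idx], (sim_cohort.events[idx] == 1).astype(int), d.matrix[idx]
        rows = rows_from_simple(t, s, x)
        f = fit_cox(rows)
        ll = breslow_loglik(t, s, x, f.beta)
        assert f.loglik == pytest.approx(ll, abs=1e-10)

    def test_score_norm_small_at_optimum(self):
        from criskit.cox import _loglik_score_info, _StratumWork

        rows = three_subject_rows()
        f = fit_cox(rows)
        works = [_StratumWork(rows, np.arange(rows.n))]
        _, U, _ = _loglik_score_info(works, rows, f.beta, "breslow")
        assert np.linalg.norm(U) < 1e-6 * rows.p

    def test_weight_invariance_exact(self):
        rows_dup = rows_from_simple(
            [1, 2, 3, 3], [1, 1, 0, 0], np.array([[1.0], [0.0], [1.0], [1.0]])
        )
        rows_w = CountingProcessRows(
            np.arange(3), np.zeros(3), np.array([1.0, 2.0, 3.0]), np.array([1, 1, 0]),
            np.array([[1.0], [0.0], [1.0]]), weight=np.array([1.0, 1.0, 2.0]),
        )
        f1, f2 = fit_cox(rows_dup), fit_cox(rows_w)
        assert f1.beta[0] == f2.beta[0]
        b1 = f1.baseline_cumhaz[f1.strata[0]]
        b2 = f2.baseline_cumhaz[f2.strata[0]]
        np.testing.assert_array_equal(b1.values, b2.values)

    def test_stratified_copies_equal_single(self):
        x = np.array([[1.0], [0.0], [1.0]])
        single = fit_cox(rows_from_simple([1, 2, 3], [1, 1, 0], x))
        two = CountingProcessRows(
            np.arange(6), np.zeros(6), np.tile([1.0, 2.0, 3.0], 2),
            np.tile([1, 1, 0], 2), np.vstack([x, x]), stratum=np.repeat([0, 1], 3),
        )
        strat = fit_cox(two)
        assert strat.beta[0] == pytest.approx(single.beta[0], abs=1e-12)

    def test_ties_match_r_survival(self):
        # frozen reference: R survival 3.8-3 coxph on this tied dataset
        times = [1, 1, 2, 2, 2, 3, 4, 4, 5, 6]
        status = [1, 1, 1, 1, 0, 1, 1, 0, 1, 0]
        x = np.array([1, 0, 1, 1, 0, 0, 1, 0, 1, 0], dtype=float).reshape(-1, 1)
        rows = rows_from_simple(times, status, x)
        assert fit_cox(rows, ties="breslow").beta[0] == pytest.approx(0.9782706981, abs=1e-8)
        assert fit_cox(rows, ties="efron").beta[0] == pytest.approx(1.0205973308, abs=1e-8)

    def test_matches_lifelines(self, sim_cohort):
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd

        from criskit import encode

        d = encode(sim_cohort, ["male", "x"])
        rows = rows_from_simple(
            sim_cohort.times, (sim_cohort.events == 1).astype(int), d.matrix
        )
        f = fit_cox(rows)
        df = pd.DataFrame(d.matrix, columns=["male", "x"])
        df["T"] = sim_cohort.times
        df["E"] = (sim_cohort.events == 1).astype(int)
        cph = lifelines.CoxPHFitter().fit(df, "T", "E")
        np.testing.assert_allclose(f.beta, cph.params_.values, atol=2e-5)
        np.testing.assert_allclose(f.se, cph.standard_errors_.values, atol=2e-5)


class TestBaseline:
    def test_null_model_is_nelson_aalen(self):
        rows = CountingProcessRows(
            np.arange(4), np.zeros(4), np.array([1.0, 1.0, 2.0, 3.0]),
            np.array([1, 1, 1, 0]), np.zeros((4, 0)),
        )
        f = fit_cox(rows)
        base = breslow_baseline(f, rows)[0]
        np.testing.assert_allclose(np.diff(base.values, prepend=0), [2 / 4, 1 / 2])

    def test_three_subject_breslow_increments(self):
        rows = three_subject_rows()
        f = fit_cox(rows)
        x = np.exp(f.beta[0])
        base = f.baseline_cumhaz[f.strata[0]]
        np.testing.assert_allclose(
            np.diff(base.values, prepend=0), [1 / (2 * x + 1), 1 / (1 + x)], atol=1e-12
        )

    def test_strata_independent(self):
        rows = CountingProcessRows(
            np.arange(6), np.zeros(6), np.array([1.0, 2.0, 3.0, 10.0, 20.0, 30.0]),
            np.array([1, 1, 0, 1, 0, 1]), np.zeros((6, 0)), stratum=np.repeat(["a", "b"], 3),
        )
        f = fit_cox(rows)
        base = f.baseline_cumhaz
        np.testing.assert_array_equal(base["a"].times, [1.0, 2.0])
        np.testing.assert_array_equal(base["b"].times, [10.0, 30.0])


class TestHazardRatioTable:
    def test_percent_changes_from_printed_hrs(self):
        rows = three_subject_rows()
        f = fit_cox(rows)
        for hr, pct in [(1.513, 51), (1.323, 32), (2.65, 165), (1.377, 38)]:
            f.beta = np.array([np.log(hr)])
            tab = hazard_ratio_table(f)
            assert round(tab["pct_change"].iloc[0]) == pct
            assert tab["hr"].iloc[0] == pytest.approx(hr)

    def test_null_beta(self):
        f = fit_cox(three_subject_rows())
        f.beta = np.array([0.0])
        tab = hazard_ratio_table(f)
        assert tab["hr"].iloc[0] == 1.0
        assert tab["pct_change"].iloc[0] == 0.0
        assert tab["p"].iloc[0] == 1.0

    def test_ci_contains_hr(self, sim_cohort):
        from criskit import encode

        d = encode(sim_cohort, ["male", "x"])
        rows = rows_from_simple(sim_cohort.times, (sim_cohort.events == 1).astype(int), d.matrix)
        tab = hazard_ratio_table(fit_cox(rows))
        assert np.all(tab["lcl"] <= tab["hr"]) and np.all(tab["hr"] <= tab["ucl"])
        assert np.all(tab["hr"] > 0)

    def test_nonconverged_warns(self):
        f = fit_cox(three_subject_rows())
        f.converged = False
        with pytest.warns(ConvergenceWarning):
            hazard_ratio_table(f)


class TestProportionality:
    def _sim_rows(self, crossing: bool, n=600, seed=2):
        rng = np.random.default_rng(seed)
        z = (rng.random(n) < 0.5).astype(float)
        beta = 0.8
        if crossing:
            # effect reverses sign at t=5: invert piecewise-exponential hazard
            h = 0.15
            t = np.empty(n)
            for i in range(n):
                r1 = h * np.exp(beta * z[i])
                e = rng.exponential(1.0)
                if e / r1 <= 5.0:
                    t[i] = e / r1
                else:
                    r2 = h * np.exp(-beta * z[i])
                    t[i] = 5.0 + (e - 5.0 * r1) / r2
        else:
            t = rng.exponential(1.0, n) / (0.15 * np.exp(beta * z))
        cens = np.full(n, 30.0)
        status = (t <= cens).astype(int)
        t = np.minimum(t, cens)
        return rows_from_simple(t, status, z.reshape(-1, 1), column_names=("z",))

    def test_null_interaction_not_significant(self):
        rows = self._sim_rows(crossing=False)
        res = check_proportionality(fit_cox(rows), rows)
        assert res["interactions"]["p"].iloc[0] > 0.01

    def test_crossing_hazard_detected(self):
        rows = self._sim_rows(crossing=True)
        res = check_proportionality(fit_cox(rows), rows)
        assert res["interactions"]["p"].iloc[0] < 0.01

    def test_cloglog_structure(self):
        rows = self._sim_rows(crossing=False, n=80)
        res = check_proportionality(fit_cox(rows), rows)
        curves = res["cloglog"]["z"]
        assert set(curves) == {0.0, 1.0}
        from criskit import kaplan_meier

        for v, sf in curves.items():
            m = rows.x[:, 0] == v
            km = kaplan_meier(rows.stop[m], rows.status[m])
            assert sf.n_jumps == int(np.sum(km.values > 0))
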