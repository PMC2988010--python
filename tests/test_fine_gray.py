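import numpy as np
import pytest

from criskit import (
    Cohort,
    ValidationError,
    censoring_km,
    encode,
    expand_fg_rows,
    fit_cox,
    fit_fine_gray,
    kaplan_meier,
    predict_cif_fg,
    rows_from_simple,
)
from criskit.fine_gray import bootstrap_fine_gray_se
from criskit.simulate import CauseSpec, SimSpec, simulate_cause_specific, simulate_fine_gray


class TestCensoringKM:
    def test_no_censoring_constant_one(self):
        c = Cohort([1, 2], [1.0, 2.0], [1, 2], n_causes=2)
        G = censoring_km(c)
        assert G(100.0) == 1.0

    def test_single_censoring(self, toy_cohort):
        G = censoring_km(toy_cohort)
        np.testing.assert_array_equal(G.times, [3.0])
        assert G(3.0) == 0.0
        assert G.left_limit(3.0) == 1.0

    def test_duality_with_km(self, sim_cohort):
        G = censoring_km(sim_cohort)
        swapped = kaplan_meier(sim_cohort.times, (sim_cohort.events == 0).astype(int))
        np.testing.assert_array_equal(G.times, swapped.times)
        np.testing.assert_array_equal(G.values, swapped.values)


class TestExpansion:
    def test_modified_risk_set_toy(self):
        # {(1, c2), (2, c1), (3, cens)}: the cause-2 subject stays at risk at t=2
        c = Cohort([1, 2, 3], [1.0, 2.0, 3.0], [2, 1, 0], {"z": [1.0, 0.0, 1.0]}, n_causes=2)
        rows = expand_fg_rows(c, 1, covariates=["z"])
        in_risk = (rows.start < 2.0) & (rows.stop >= 2.0)
        assert in_risk.sum() == 3  # vs 2 under cause-specific censoring
        # follow-on row belongs to subject 1 and has weight G(2-)/G(1-) = 1
        follow = rows.subject[(rows.start == 1.0)]
        assert list(follow) == [1]

    def test_riskset_superset_of_cause_specific(self, sim_cohort):
        rows = expand_fg_rows(sim_cohort, 1)
        te = np.unique(sim_cohort.times[sim_cohort.events == 1])
        for t in te[:: max(1, te.size // 10)]:
            fg_n = np.sum((rows.start < t) & (rows.stop >= t))
            cs_n = np.sum(sim_cohort.times >= t)
            assert fg_n >= cs_n
        # strictly larger after the first competing event
        t2 = sim_cohort.times[sim_cohort.events == 2].min()
        later = te[te > t2]
        if later.size:
            t = later[0]
            assert np.sum((rows.start < t) & (rows.stop >= t)) > np.sum(sim_cohort.times >= t)

    def test_k1_identity(self):
        c = Cohort([1, 2, 3, 4], [1, 2, 3, 4], [1, 1, 0, 1], {"z": [1.0, 0.0, 1.0, 0.0]}, n_causes=1)
        rows = expand_fg_rows(c, 1, covariates=["z"])
        assert rows.n == 4
        np.testing.assert_array_equal(rows.weight, 1.0)
        fg = fit_fine_gray(c, 1, ["z"])
        plain = fit_cox(rows_from_simple(c.times, c.events, encode(c, ["z"]).matrix))
        np.testing.assert_allclose(fg.beta, plain.beta, atol=1e-12)

    def test_no_cause_events_raises(self):
        c = Cohort([1, 2], [1.0, 2.0], [2, 0], n_causes=2)
        with pytest.raises(ValidationError):
            expand_fg_rows(c, 1)


class TestFit:
    def test_uncensored_equals_recode_oracle(self):
        spec = SimSpec(
            n=300, causes=(CauseSpec(0.05, (0.4,)), CauseSpec(0.1, (-0.3,))),
            covariates={"male": ("bernoulli", 0.5)}, seed=4,
        )
        c = simulate_cause_specific(spec)
        assert (c.events > 0).all()
        fg = fit_fine_gray(c, 1, ["male"])
        rec_times = np.where(c.events == 2, c.times.max() + 1.0, c.times)
        oracle = fit_cox(
            rows_from_simple(rec_times, (c.events == 1).astype(int), encode(c, ["male"]).matrix)
        )
        np.testing.assert_allclose(fg.beta, oracle.beta, atol=1e-8)

    def test_matches_reference_implementation(self):
        # frozen reference: R cmprsk 2.2-12 crr() on this exact cohort
        spec = SimSpec(
            n=400, causes=(CauseSpec(1.0, (0.5,)), CauseSpec(1.0, (-0.2,))),
            mechanism="fine_gray", fg_p=0.35,
            covariates={"male": ("bernoulli", 0.5)}, censor_rate=0.25, seed=9,
        )
        c = simulate_fine_gray(spec)
        fg = fit_fine_gray(c, 1, ["male"])
        assert fg.beta[0] == pytest.approx(0.402919, abs=2e-6)
        assert fg.cox.robust_se[0] == pytest.approx(0.162087, abs=3e-4)

    def test_parameter_recovery(self):
        true_b = 0.5
        est = []
        for s in range(40):
            spec = SimSpec(
                n=1000, causes=(CauseSpec(1.0, (true_b,)), CauseSpec(1.0, (0.0,))),
                mechanism="fine_gray", fg_p=0.3,
                covariates={"z": ("bernoulli", 0.5)}, censor_rate=0.25, seed=4000 + s,
            )
            c = simulate_fine_gray(spec)
            est.append(fit_fine_gray(c, 1, ["z"]).beta[0])
        est = np.array(est)
        assert abs(est.mean() - true_b) < 3 * est.std(ddof=1) / np.sqrt(len(est))

    def test_baseline_cumhaz_nondecreasing(self, sim_cohort):
        fg = fit_fine_gray(sim_cohort, 1, ["male"])
        assert np.all(np.diff(fg.baseline_subdist_cumhaz.values) >= 0)
        G = fg.censoring_km
        assert np.all(np.diff(G.values) <= 0)

    def test_bootstrap_se_agrees_with_sandwich(self):
        spec = SimSpec(
            n=400, causes=(CauseSpec(1.0, (0.5,)), CauseSpec(1.0, (0.0,))),
            mechanism="fine_gray", fg_p=0.35,
            covariates={"z": ("bernoulli", 0.5)}, censor_rate=0.2, seed=15,
        )
        c = simulate_fine_gray(spec)
        fg = fit_fine_gray(c, 1, ["z"])
        boot = bootstrap_fine_gray_se(c, 1, ["z"], n_boot=60, seed=2)
        assert boot[0] == pytest.approx(fg.cox.robust_se[0], rel=0.35)


class TestPredict:
    def test_reference_profile_uses_baseline(self, sim_cohort):
        fg = fit_fine_gray(sim_cohort, 1, ["male"])
        sf = predict_cif_fg(fg, {"male": 0.0})
        np.testing.assert_allclose(
            sf.values, 1.0 - np.exp(-fg.baseline_subdist_cumhaz.values), atol=1e-14
        )

    def test_extreme_negative_predictor_gives_zero(self, sim_cohort):
        fg = fit_fine_gray(sim_cohort, 1, ["x"])
        sf = predict_cif_fg(fg, {"x": -200.0 / max(abs(fg.beta[0]), 1e-3) * np.sign(fg.beta[0])})
        assert np.all(np.asarray(sf.values) < 1e-10)

    def test_bounds_and_monotone(self, sim_cohort):
        fg = fit_fine_gray(sim_cohort, 1, ["male", "x"])
        sf = predict_cif_fg(fg, {"male": 1.0, "x": 1.0})
        assert np.all(np.diff(sf.values) >= 0)
        assert sf.values[0] >= 0 and sf.values[-1] < 1

    def test_k1_null_approaches_one_minus_km(self):
        spec = SimSpec(n=4000, causes=(CauseSpec(0.1, ()),), covariates={}, censor_rate=0.05, seed=21)
        c = simulate_cause_specific(spec)
        fg = fit_fine_gray(c, 1, [])
        sf = predict_cif_fg(fg, {})
        km = kaplan_meier(c.times, (c.events == 1).astype(int))
        grid = np.quantile(c.times, [0.2, 0.5, 0.8])
        d = np.abs(np.asarray(sf(grid)) - (1 - np.asarray(km(grid))))
        assert d.max() < 0.01  # Breslow-vs-product-limit gap, shrinking in n


def test_minor_risk_phenomenon():
    """A covariate raising only the dominant cause-2 hazard drives the FG
    cause-1 HR below 1 while the cause-specific HR stays near 1."""
    from criskit import fit_cause_specific

    spec = SimSpec(
        n=4000, causes=(CauseSpec(0.01, (0.0,)), CauseSpec(0.04, (1.0,))),
        covariates={"z": ("bernoulli", 0.5)}, censor_horizon=26.0, seed=42,
    )
    c = simulate_cause_specific(spec)
    cs_b = fit_cause_specific(c, ["z"]).per_cause[1].beta[0]
    fg_b = fit_fine_gray(c, 1, ["z"]).beta[0]
    assert abs(cs_b) < 0.15
    assert fg_b < -0.2
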