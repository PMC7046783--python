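"""Transition-probability estimates, CIs, trend tests and the bootstrap."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from statsmodels.stats.proportion import proportion_confint

import _oracles as oracle
from conftest import diary_strategy
from migrainechain import (
    ChainParams,
    Cohort,
    CohortSpec,
    Diary,
    ProportionEstimate,
    TransitionCounts,
    UndefinedEstimateError,
    at_risk_day_table,
    bootstrap_tps,
    diary_counts,
    estimate_omnibus,
    estimate_tps,
    impute,
    individual_tps,
    simulate_cohort,
    trend_test_logistic,
    trend_test_wls,
    wilson_cc_interval,
    worked_example,
)


class TestWilsonCC:
    @pytest.mark.parametrize(
        "x,n,low,high",
        [(3, 3, 0.310, 1.000), (0, 3, 0.000, 0.690), (0, 1, 0.000, 0.945)],
    )
    def test_reference_endpoints_to_three_decimals(self, x, n, low, high):
        got = wilson_cc_interval(x, n, 0.95)
        assert round(got[0], 3) == low
        assert round(got[1], 3) == high

    @given(st.integers(min_value=1, max_value=400), st.data())
    def test_bracketing_and_boundary_invariants(self, n, data):
        x = data.draw(st.integers(min_value=0, max_value=n))
        low, high = wilson_cc_interval(x, n)
        assert 0 <= low <= x / n <= high <= 1
        if x == 0:
            assert low == 0.0
        if x == n:
            assert high == 1.0

    @given(st.integers(min_value=1, max_value=300), st.data())
    def test_contains_uncorrected_wilson_interval(self, n, data):
        x = data.draw(st.integers(min_value=0, max_value=n))
        low, high = wilson_cc_interval(x, n)
        ref_low, ref_high = proportion_confint(x, n, method="wilson")
        assert low <= ref_low + 1e-12
        assert high >= ref_high - 1e-12

    def test_empty_denominator_rejected(self):
        with pytest.raises(UndefinedEstimateError):
            wilson_cc_interval(0, 0)


class TestPointEstimates:
    def test_worked_example_estimates(self, worked):
        ests = {e.label: e for e in estimate_tps(diary_counts(worked, "fill48"))}
        assert round(ests["mu"].p_hat, 2) == 0.67
        assert ests["delta_1"].p_hat == 1.0
        assert ests["delta_2"].p_hat == 0.5
        assert ests["delta_3"].p_hat == 0.0

    def test_zero_onsets_give_zero_with_zero_lower_bound(self):
        c = TransitionCounts(0, 10, (), ())
        (mu,) = estimate_tps(c)
        assert mu.p_hat == 0.0 and mu.ci_low == 0.0

    def test_zero_denominators_are_skipped(self):
        c = TransitionCounts(1, 4, (1, 0), (2, 0))
        labels = [e.label for e in estimate_tps(c)]
        assert labels == ["mu", "delta_1"]

    def test_omnibus_on_worked_example(self, worked):
        omni = estimate_omnibus(diary_counts(worked, "fill48"))
        assert omni.p_hat == pytest.approx(0.6)
        assert (omni.x, omni.n) == (3, 5)

    def test_omnibus_all_continuations(self):
        omni = estimate_omnibus(TransitionCounts(0, 1, (2, 1), (2, 1)))
        assert omni.p_hat == 1.0 and omni.ci_high == 1.0

    def test_omnibus_single_zero_observation(self):
        omni = estimate_omnibus(TransitionCounts(0, 1, (0,), (1,)))
        assert omni.p_hat == 0.0
        assert round(omni.ci_high, 3) == 0.945

    def test_omnibus_requires_observations(self):
        with pytest.raises(UndefinedEstimateError):
            estimate_omnibus(TransitionCounts(0, 5, (), ()))

    @given(diary_strategy(min_size=2))
    def test_omnibus_equals_collapsed_two_state_tally(self, d):
        # collapsing all attack-day states before tallying must give the
        # same x/n: the naive oracle counts days preceded by a migraine day
        imp = impute(d)
        c = diary_counts(d, "fill48")
        x, n = oracle.omnibus_naive(list(imp.migraine))
        if n == 0:
            with pytest.raises(UndefinedEstimateError):
                estimate_omnibus(c)
        else:
            omni = estimate_omnibus(c)
            assert (omni.x, omni.n) == (x, n)


def _delta_estimates(values, ns):
    return [
        ProportionEstimate(f"delta_{i}", round(v * n), n, v, 0.0, 1.0)
        for i, (v, n) in enumerate(zip(values, ns), start=1)
    ]


class TestWLSTrend:
    def test_flat_deltas_give_zero_slope_p_one(self):
        res = trend_test_wls(_delta_estimates([0.4] * 5, [10] * 5))
        assert res.slope == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    def test_linear_deltas_recover_slope(self):
        res = trend_test_wls(_delta_estimates([0.2, 0.4, 0.6, 0.8], [10] * 4))
        assert res.slope == pytest.approx(0.2)

    def test_weight_scale_invariance(self):
        vals, ns = [0.5, 0.35, 0.6, 0.2], [30, 20, 10, 5]
        a = trend_test_wls(_delta_estimates(vals, ns))
        b = trend_test_wls(_delta_estimates(vals, [2 * n for n in ns]))
        assert a.slope == pytest.approx(b.slope)

    def test_requires_three_distinct_states(self):
        with pytest.raises(UndefinedEstimateError):
            trend_test_wls(_delta_estimates([0.2, 0.3], [5, 5]))

    def test_ignores_mu_and_omnibus_entries(self):
        ests = _delta_estimates([0.2, 0.4, 0.6], [8] * 3)
        ests.append(ProportionEstimate("mu", 1, 10, 0.1, 0.0, 1.0))
        ests.append(ProportionEstimate("delta_omni", 4, 10, 0.4, 0.0, 1.0))
        assert trend_test_wls(ests).slope == pytest.approx(0.2)


def _simulated_day_table(delta, seed, n_patients=25, n_days=90, mu=0.12):
    spec = CohortSpec(
        n_patients=n_patients, n_days=n_days,
        params=ChainParams(mu=mu, delta=delta), seed=seed,
    )
    return at_risk_day_table(simulate_cohort(spec), mode="fill48")


class TestLogisticTrend:
    def test_type_i_error_near_nominal_under_constant_delta(self):
        # constant continuation probability: the k coefficient is null
        n_reps, rejections = 100, 0
        for seed in range(n_reps):
            res = trend_test_logistic(_simulated_day_table(0.5, seed))
            if np.isfinite(res.p_value) and res.p_value < 0.05:
                rejections += 1
        # 3 sigma above Binomial(100, 0.05): 0.05 + 3*0.0218
        assert rejections / n_reps <= 0.12

    def test_power_exceeds_type_i_rate_for_rising_deltas(self):
        rising = (0.15, 0.35, 0.55, 0.75, 0.9)
        n_reps, rejections, coefs = 40, 0, []
        for seed in range(n_reps):
            res = trend_test_logistic(_simulated_day_table(rising, seed))
            coefs.append(res.slope)
            if np.isfinite(res.p_value) and res.p_value < 0.05:
                rejections += 1
        assert np.nanmean(coefs) > 0
        assert rejections / n_reps > 0.12

    def test_single_duration_state_has_no_contrast(self):
        t = at_risk_day_table(Cohort([Diary.from_symbols("p", "-M--M-")]), "fill48")
        assert set(t["k"]) == {1}
        with pytest.raises(UndefinedEstimateError, match="contrast"):
            trend_test_logistic(t)

    def test_categorical_coding_reports_lr_test(self):
        res = trend_test_logistic(_simulated_day_table(0.5, 3), coding="categorical")
        assert res.method == "logistic"
        assert np.isnan(res.slope)
        assert 0 <= res.p_value <= 1


class TestIndividualTPs:
    def test_identical_diaries_have_zero_spread(self, worked):
        cohort = Cohort(worked.replace(patient_id=f"p{i}") for i in range(6))
        res = individual_tps(cohort, mode="fill48")
        assert res.summary.loc["mu", "p2.5"] == res.summary.loc["mu", "p97.5"]

    def test_worked_example_alone(self, worked):
        res = individual_tps(Cohort([worked]), mode="fill48")
        assert res.table["mu_hat"].iloc[0] == pytest.approx(2 / 3)
        assert res.table["delta_omni_hat"].iloc[0] == pytest.approx(0.6)

    def test_diary_without_attacks_reported_missing(self, worked):
        cohort = Cohort([worked, Diary("free", np.zeros(8, bool))])
        res = individual_tps(cohort, mode="fill48")
        assert np.isnan(res.table.set_index("patient_id")
                        .loc["free", "delta_omni_hat"])
        assert res.summary.loc["delta_omni", "n_missing"] == 1
        assert res.summary.loc["delta_omni", "n_defined"] == 1

    def test_heterogeneous_cohort_range_covers_true_quantiles(self):
        # delta_j ~ U(0.2, 0.8): with long diaries the central-95% range of
        # the individual estimates must cover the true 2.5%/97.5% quantiles
        # (sampling noise can only widen the empirical spread)
        def draw(rng):
            return ChainParams(mu=0.1, delta=float(rng.uniform(0.2, 0.8)))

        spec = CohortSpec(n_patients=150, n_days=1000, params=draw, seed=11)
        res = individual_tps(simulate_cohort(spec), mode="fill48")
        true_lo = 0.2 + 0.025 * 0.6
        true_hi = 0.8 - 0.025 * 0.6
        assert res.summary.loc["delta_omni", "p2.5"] <= true_lo + 0.05
        assert res.summary.loc["delta_omni", "p97.5"] >= true_hi - 0.05


class TestBootstrap:
    def test_identical_diaries_yield_zero_width(self, worked):
        cohort = Cohort(worked.replace(patient_id=f"p{i}") for i in range(5))
        res = bootstrap_tps(cohort, B=200, seed=4, mode="fill48")
        lo, hi = res.intervals["mu"]
        assert lo == hi == pytest.approx(2 / 3)

    def test_same_seed_reproduces_exactly(self, worked):
        cohort = Cohort([worked, Diary("b", np.zeros(12, bool)),
                         Diary.from_symbols("c", "-MMM--M-")])
        a = bootstrap_tps(cohort, B=500, seed=9)
        b = bootstrap_tps(cohort, B=500, seed=9)
        assert a == b
        c = bootstrap_tps(cohort, B=500, seed=10)
        assert a.intervals != c.intervals

    def test_replicates_without_attack_days_are_excluded(self, worked):
        cohort = Cohort([worked, Diary("free", np.zeros(10, bool))])
        res = bootstrap_tps(cohort, B=400, seed=2)
        # a replicate drawing the all-free diary twice has no delta data
        assert res.n_excluded["delta_omni"] > 0
        assert res.n_excluded["mu"] == 0

    def test_empty_cohort_and_bad_b_rejected(self, worked):
        with pytest.raises(ValueError):
            bootstrap_tps(Cohort([]), B=10, seed=0)
        with pytest.raises(ValueError):
            bootstrap_tps(Cohort([worked]), B=0, seed=0)
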