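"""Cohort engine: transitions, conservation, reward accumulation, strategies."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad

import nsclc_cea as nc
from nsclc_cea import CHEMO_ARM, HealthState
from nsclc_cea.markov import STRATEGY_ARMS

ARMS = list(nc.ARMS)


def override_or(params, arm, or_pfs, or_os):
    p = params.with_base(f"or_pfs_{arm}", or_pfs)
    return p.with_base(f"or_os_{arm}", or_os)


class TestTransitionMatrix:
    @pytest.mark.parametrize("arm", ARMS)
    @pytest.mark.parametrize("t", [1, 7, 60, 120])
    def test_rows_stochastic_death_absorbing(self, params, arm, t):
        m = nc.transition_matrix_at(arm, t, params)
        np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)
        assert np.all((m >= 0) & (m <= 1))
        np.testing.assert_array_equal(m[HealthState.DEATH], [0, 0, 1])
        assert m[HealthState.PD, HealthState.PFS] == 0.0

    def test_death_entries_increase_with_increasing_hazard(self, params):
        # OS shape 1.4499 > 1: monthly death probability rises with t
        deaths = [
            nc.transition_matrix_at(CHEMO_ARM, t, params)[HealthState.PFS, HealthState.DEATH]
            for t in range(1, 121)
        ]
        assert np.all(np.diff(deaths) > 0)

    def test_infinite_pfs_or_suppresses_progression(self, params):
        p = override_or(params, "erlotinib", 1e12, 1.0)
        m = nc.transition_matrix_at("erlotinib", 12, p)
        assert m[HealthState.PFS, HealthState.PD] == pytest.approx(0.0, abs=1e-9)

    def test_gefitinib_os_or_below_one_raises_death(self, params):
        m_gef = nc.transition_matrix_at("gefitinib", 24, params)
        m_chemo = nc.transition_matrix_at(CHEMO_ARM, 24, params)
        assert (
            m_gef[HealthState.PFS, HealthState.DEATH]
            > m_chemo[HealthState.PFS, HealthState.DEATH]
        )

    def test_cycle_index_bounds(self, params):
        with pytest.raises(ValueError):
            nc.transition_matrix_at(CHEMO_ARM, 0, params)
        with pytest.raises(ValueError):
            nc.transition_matrix_at(CHEMO_ARM, 121, params)


class TestRunCohort:
    @pytest.mark.parametrize("arm", ARMS)
    def test_conservation_and_monotone_states(self, params, arm):
        trace = nc.run_cohort(arm, params)
        assert trace.shape == (121, 3)
        np.testing.assert_array_equal(trace[0], [1, 0, 0])
        np.testing.assert_allclose(trace.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(np.diff(trace[:, HealthState.DEATH]) >= 0)
        assert np.all(np.diff(trace[:, HealthState.PFS]) <= 0)

    @given(or_pfs=st.floats(0.1, 30), or_os=st.floats(0.3, 3))
    def test_conservation_for_random_odds_ratios(self, params, or_pfs, or_os):
        p = override_or(params, "afatinib", or_pfs, or_os)
        trace = nc.run_cohort("afatinib", p)
        np.testing.assert_allclose(trace.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(np.diff(trace[:, HealthState.DEATH]) >= -1e-15)

    def test_alive_fraction_tracks_os_weibull(self, params):
        # marginal death is driven by the OS curve alone
        trace = nc.run_cohort(CHEMO_ARM, params)
        alive = trace[:, :2].sum(axis=1)
        expected = nc.weibull_survival(params.chemo_os, np.arange(121))
        np.testing.assert_allclose(alive, expected, atol=1e-9)

    def test_certain_death_empties_cohort(self, params):
        p = dataclasses.replace(params, chemo_os=nc.WeibullCurve(50.0, 1.0))
        trace = nc.run_cohort(CHEMO_ARM, p)
        out = nc.accumulate_outcomes(trace, CHEMO_ARM, p)
        assert trace[1, HealthState.DEATH] == pytest.approx(1.0, abs=1e-9)
        assert out.os_months == pytest.approx(1.0, abs=1e-6)  # only the entry cycle


class TestOutcomeAccumulation:
    def test_chemo_os_months_match_restricted_mean(self, params):
        # closed-form limit: truncated Weibull restricted mean at the horizon
        out = nc.evaluate_strategy("empirical", params)
        rmst, _ = quad(
            lambda t: nc.weibull_survival(params.chemo_os, t), 0, 120, limit=200
        )
        assert out.os_months == pytest.approx(rmst, rel=0.05)

    def test_zero_utilities_and_costs_vanish(self, params):
        p = params
        for name, spec in params.specs.items():
            if name.startswith(("utility_", "cost_", "disutility_")):
                p = p.with_base(name, 0.0)
        out = nc.evaluate_strategy("empirical", p)
        assert out.qaly == 0.0 and out.cost == 0.0

    def test_qaly_equals_life_months_without_discount_or_weights(self, params):
        p = dataclasses.replace(params, discount_rate_annual=0.0)
        p = p.with_base("utility_pfs", 1.0).with_base("utility_pd", 1.0)
        for e in nc.SAE_EVENTS:
            p = p.with_base(f"disutility_{e}", 0.0)
        out = nc.evaluate_strategy("empirical", p)
        assert out.qaly == pytest.approx(out.os_months / 12.0, rel=1e-12)

    def test_outcome_ordering_invariants(self, base_outcomes, params):
        for out in base_outcomes.values():
            assert 0 <= out.pfs_months <= out.os_months <= params.horizon_months
            assert out.cost > 0 and out.qaly > 0

    def test_qaly_monotone_in_utility_and_cost_monotone_in_prices(self, params):
        base = nc.evaluate_strategy("guided_erlotinib", params)
        up = nc.evaluate_strategy("guided_erlotinib", params.with_base("utility_pfs", 0.84))
        assert up.qaly > base.qaly
        pricier = nc.evaluate_strategy(
            "guided_erlotinib", params.with_base("cost_month_palliative", 1013)
        )
        assert pricier.cost > base.cost


class TestSaeBurden:
    def test_erlotinib_hand_computed(self, params):
        # diarrhea 1.0% x 153 + rash 2.0% x 155
        cost, qaly_loss = nc.sae_burden("erlotinib", params)
        assert cost == pytest.approx(0.01 * 153 + 0.02 * 155)
        assert qaly_loss == pytest.approx((0.01 * 0.047 + 0.02 * 0.032) / 12)

    def test_chemo_dominated_by_neutropenic_fever(self, params):
        cost, _ = nc.sae_burden(CHEMO_ARM, params)
        assert cost > 800  # 18% x 4479 alone is 806

    def test_zero_incidence_means_zero_burden(self, params):
        p = params
        for e in nc.SAE_EVENTS:
            p = p.with_base(f"sae_incidence_erlotinib_{e}", 0.0)
        assert nc.sae_burden("erlotinib", p) == (0.0, 0.0)


class TestStrategies:
    def test_unknown_strategy_rejected(self, params):
        with pytest.raises(ValueError):
            nc.evaluate_strategy("guided_osimertinib", params)

    def test_zero_prevalence_reduces_to_chemo_plus_test(self, params, base_outcomes):
        p = params.with_base("prevalence_egfr_pos", 0.0)
        out = nc.evaluate_strategy("guided_erlotinib", p)
        chemo = base_outcomes["empirical"]
        assert out.cost == pytest.approx(chemo.cost + params.value("cost_egfr_test"))
        assert out.qaly == pytest.approx(chemo.qaly)

    def test_full_prevalence_is_pure_tki_arm_plus_test(self, params):
        p = params.with_base("prevalence_egfr_pos", 1.0)
        out = nc.evaluate_strategy("guided_erlotinib", p)
        tki = nc.accumulate_outcomes(
            nc.run_cohort("erlotinib", params), "erlotinib", params
        )
        assert out.cost == pytest.approx(tki.cost + params.value("cost_egfr_test"))
        assert out.qaly == pytest.approx(tki.qaly)

    @pytest.mark.parametrize("q", [0.0, 0.25, 0.501, 1.0])
    def test_mixture_linearity_in_prevalence(self, params, q):
        chemo = nc.accumulate_outcomes(nc.run_cohort(CHEMO_ARM, params), CHEMO_ARM, params)
        tki = nc.accumulate_outcomes(nc.run_cohort("gefitinib", params), "gefitinib", params)
        out = nc.evaluate_strategy(
            "guided_gefitinib", params.with_base("prevalence_egfr_pos", q)
        )
        expected_q = q * tki.qaly + (1 - q) * chemo.qaly
        expected_c = q * tki.cost + (1 - q) * chemo.cost + params.value("cost_egfr_test")
        assert out.qaly == pytest.approx(expected_q, rel=1e-12)
        assert out.cost == pytest.approx(expected_c, rel=1e-12)

    def test_partial_compliance_shifts_weight_to_chemo(self, params):
        half = nc.evaluate_strategy(
            "guided_erlotinib", params.with_base("tki_compliance", 0.5)
        )
        full = nc.evaluate_strategy("guided_erlotinib", params)
        chemo = nc.evaluate_strategy("empirical", params)
        assert chemo.qaly < half.qaly < full.qaly

    def test_vectorized_engine_matches_trace_reference(self, params, base_outcomes):
        vec = nc.evaluate_all_strategies(params)
        for s, ref in base_outcomes.items():
            for field in ("cost", "qaly", "pfs_months", "os_months"):
                assert float(getattr(vec[s], field)) == pytest.approx(
                    getattr(ref, field), rel=1e-10
                ), (s, field)

    def test_vectorized_overrides_broadcast(self, params):
        prev = np.array([0.0, 0.501, 1.0])
        out = nc.evaluate_all_strategies(params, {"prevalence_egfr_pos": prev})
        qalys = np.asarray(out["guided_erlotinib"].qaly)
        assert qalys.shape == (3,)
        assert qalys[0] < qalys[1] < qalys[2]  # PFS OR > 1 helps with prevalence
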