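"""Decision-tree evaluation against an independent path-enumeration oracle."""

import numpy as np
import pytest

from ohca_cea.parameters import sample_parameters
from ohca_cea.pathway import (
    CohortConfig,
    InfeasibleStrategyError,
    Strategy,
    achievable,
    als_strategy,
    conditional_discharge_probability,
    evaluate_strategy,
    five_year_phase,
    inhospital_cost,
    no_treatment_strategy,
)
from ohca_cea.sensitivity import proportional_scaling

from _oracle import expected_outcome


class TestConditionalDischargeProbability:
    def test_worked_example(self):
        """A 10% overall discharge rate through 25.8% arrival and 65% ICU
        admission requires a 59.6% per-node discharge probability."""
        assert conditional_discharge_probability(0.10, 0.258, 0.65) == pytest.approx(
            0.5963, abs=5e-5
        )

    def test_als_base_case(self):
        assert conditional_discharge_probability(0.09, 0.258, 0.65) == pytest.approx(
            0.5367, abs=5e-5
        )

    def test_saturation(self):
        assert conditional_discharge_probability(0.258 * 0.65, 0.258, 0.65) == 1.0

    def test_infeasible_raises_or_clamps(self):
        with pytest.raises(InfeasibleStrategyError):
            conditional_discharge_probability(0.2, 0.258, 0.65)
        assert conditional_discharge_probability(0.2, 0.258, 0.65, clamp=True) == 1.0

    def test_zero_denominator(self):
        with pytest.raises(InfeasibleStrategyError):
            conditional_discharge_probability(0.1, 0.0, 0.65)


class TestAchievable:
    @pytest.mark.parametrize(
        "dh, dd, expected",
        [
            (-5, 5, False),
            (-5, 6, False),
            (-5, 4, True),
            (0, 6, True),
            (0, 1, True),
            (20, 6, True),
        ],
    )
    def test_feasibility_bound(self, dh, dd, expected, means):
        assert achievable(dh, dd, means) is expected

    def test_replicates_grid_pattern(self, means):
        """Exactly two combinations in the -5 row are unachievable."""
        pattern = {
            (dh, dd): achievable(dh, dd, means)
            for dh in (-5, 0, 5, 10, 15, 20)
            for dd in (1, 2, 3, 4, 5, 6)
        }
        unachievable = {k for k, ok in pattern.items() if not ok}
        assert unachievable == {(-5, 5), (-5, 6)}


class TestInhospitalCost:
    def test_ed_death(self, means):
        assert inhospital_cost("ed_death", means) == 377.0

    def test_icu_death(self, means):
        """ICU non-survivor: ED + 2.4 ICU days at £1768 + non-ICU £3835."""
        assert inhospital_cost("icu_death", means) == pytest.approx(8455.2)

    def test_icu_survivor(self, means):
        assert inhospital_cost("icu_survivor", means) == pytest.approx(23146.5)

    def test_unknown_path(self, means):
        with pytest.raises(ValueError):
            inhospital_cost("ward_death", means)


class TestFiveYearPhase:
    def test_undiscounted_closed_form(self, means):
        """Expected person-years (0.740*5 + 0.260*1.827) times utility/cost."""
        result = five_year_phase("cpc12", means, CohortConfig(discount_rate=0.0))
        epy = 0.740 * 5 + 0.260 * 1.827
        assert result.qaly == pytest.approx(epy * 0.75, rel=1e-12)
        assert result.cost == pytest.approx(epy * 3358.0, rel=1e-12)
        assert result.p_alive_at_5 == 0.74

    def test_zero_utility(self, means, config):
        zero = means.replace(utility_cpc34=0.0)
        assert five_year_phase("cpc34", zero, config).qaly == 0.0

    def test_all_survive_no_discount(self, means):
        full = means.replace(p_5yr_cpc12=1.0)
        result = five_year_phase("cpc12", full, CohortConfig(discount_rate=0.0))
        assert result.qaly == pytest.approx(5 * 0.75, rel=1e-12)

    def test_person_years_beyond_horizon_rejected(self, means, config):
        with pytest.raises(ValueError):
            five_year_phase("cpc12", means.replace(py_death_cpc12=5.5), config)


class TestEvaluateStrategy:
    def test_no_treatment_is_empty_pathway(self, means, config, table):
        outcome = evaluate_strategy(no_treatment_strategy(), means, config, table)
        assert outcome.expected_cost == 0.0
        assert outcome.expected_qaly == 0.0
        assert outcome.terminal_probabilities["prehospital_death"] == 1.0

    def test_terminal_probabilities_close(self, means, config, table):
        outcome = evaluate_strategy(als_strategy(means), means, config, table)
        assert sum(outcome.terminal_probabilities.values()) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_cost_with_post_discharge_payoffs_zeroed(self, means, config, table):
        """Hand-enumerable four cost-bearing terminal nodes at the means."""
        zeroed = means.replace(
            utility_cpc12=0.0,
            utility_cpc34=0.0,
            annual_cost_cpc12=0.0,
            annual_cost_cpc34=0.0,
            py_death_cpc12=0.0,
            py_death_cpc34=0.0,
        )
        outcome = evaluate_strategy(als_strategy(zeroed), zeroed, config, table)
        expected = (
            347.0
            + 0.258 * 0.35 * 377.0
            + 0.258 * 0.65 * (1 - 0.09 / (0.258 * 0.65)) * 8455.2
            + 0.09 * 23146.5
        )
        assert expected == pytest.approx(3121.197, abs=5e-3)
        assert outcome.expected_cost == pytest.approx(expected, rel=1e-12)
        assert outcome.expected_qaly == 0.0

    def test_oracle_equivalence_on_random_parameter_sets(
        self, specs, config, table
    ):
        """Brute-force enumeration of every root-to-leaf path agrees with the
        tree evaluation to 1e-9 relative, over random parameter draws."""
        rng = np.random.default_rng(2718)
        for _ in range(300):
            params = sample_parameters(specs, rng)
            for strat in (als_strategy(params), proportional_scaling(3.0, params)):
                outcome = evaluate_strategy(strat, params, config, table)
                cost, qaly = expected_outcome(strat, params, config, table)
                assert outcome.expected_cost == pytest.approx(cost, rel=1e-9)
                assert outcome.expected_qaly == pytest.approx(qaly, rel=1e-9)

    def test_qaly_monotone_in_discharge_survival(self, means, config, table):
        qalys = []
        for p_dis in (0.07, 0.09, 0.11, 0.13):
            strat = Strategy("als", 347.0, 0.258, p_dis)
            out = evaluate_strategy(strat, means, config, table)
            qalys.append(out.expected_qaly)
        assert all(a <= b for a, b in zip(qalys, qalys[1:]))

    def test_discounting_never_increases_payoffs(self, means, table):
        undiscounted = evaluate_strategy(
            als_strategy(means), means, CohortConfig(discount_rate=0.0), table
        )
        discounted = evaluate_strategy(
            als_strategy(means), means, CohortConfig(discount_rate=0.035), table
        )
        assert discounted.expected_qaly <= undiscounted.expected_qaly
        assert discounted.expected_cost <= undiscounted.expected_cost

    def test_infeasible_strategy_raises(self, means, config, table):
        strat = Strategy("als_plus_ccm", 2058.0, 0.258, 0.2)
        with pytest.raises(InfeasibleStrategyError):
            evaluate_strategy(strat, means, config, table)
        clamped = evaluate_strategy(
            strat, means, config, table, clamp_infeasible=True
        )
        # clamped to the feasibility boundary: everyone reaching ICU is discharged
        assert clamped.terminal_probabilities["icu_death"] == 0.0


class TestStrategyInvariants:
    def test_discharge_cannot_exceed_hospital_survival(self):
        with pytest.raises(InfeasibleStrategyError):
            Strategy("als", 347.0, 0.1, 0.2)

    def test_probability_bounds(self):
        with pytest.raises(InfeasibleStrategyError):
            Strategy("als", 347.0, 1.2, 0.1)
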