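"""Cohort propagation, payoff accrual, and discounting."""

import numpy as np
import pytest

from cavte_cea.cohort import (
    CohortResult,
    PayoffSpec,
    discount_factor,
    event_flow,
    run_cohort,
    run_strategy,
)
from cavte_cea.markov import EVENTS, HealthState, TransitionModel


class TinyModel:
    """Three-state stand-in (healthy, sick, dead) with a fixed matrix."""

    def __init__(self, matrix, intensity=None):
        self.states = [
            HealthState("no_complication"),
            HealthState("dvt", 1),
            HealthState("death"),
        ]
        self.strategy = "tiny"
        self.n_states = 3
        self._P = np.asarray(matrix, dtype=float)
        self._E = (
            np.zeros((3, len(EVENTS))) if intensity is None else np.asarray(intensity)
        )
        self.overflow_count = 0

    def matrix_at(self, cycle=0):
        return self._P

    def intensity_at(self, cycle=0):
        return self._E


def tiny_payoffs(model, utility=(0.65, 0.61, 0.0), cost=(10.0, 50.0, 0.0), tolls=None):
    return PayoffSpec(
        states=model.states,
        state_utility=np.array(utility),
        state_cost=np.array(cost),
        event_cost=tolls or {},
        event_disutility={},
        strategy="tiny",
    )


IDENTITY = np.eye(3)
SICKNESS = np.array([[0.9, 0.08, 0.02], [0.0, 0.85, 0.15], [0.0, 0.0, 1.0]])


class TestDiscounting:
    def test_cycle_zero_is_one(self):
        assert discount_factor(0, 0.05) == 1.0

    def test_five_years_at_five_percent(self):
        assert discount_factor(60, 0.05) == pytest.approx(1.05 ** -5, abs=1e-12)

    def test_zero_rate(self):
        assert discount_factor(123, 0.0) == 1.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(-1, 0.05)
        with pytest.raises(ValueError):
            discount_factor(3, -0.01)


class TestEngineOracles:
    def test_zero_event_year_yields_baseline_utility(self):
        model = TinyModel(IDENTITY)
        result = run_cohort(model, tiny_payoffs(model), 12, discount=0.0)
        assert result.total_qaly == pytest.approx(0.65, abs=1e-12)

    def test_zero_event_discounted_geometric_sum(self):
        model = TinyModel(IDENTITY)
        result = run_cohort(model, tiny_payoffs(model), 60, discount=0.05)
        expected = 0.65 * sum(1.05 ** (-t / 12) for t in range(60)) / 12
        assert result.total_qaly == pytest.approx(expected, abs=1e-12)

    def test_matrix_power_oracle_equivalence(self):
        """Trace and totals agree with an explicit matrix-power computation."""
        model = TinyModel(SICKNESS)
        payoffs = tiny_payoffs(model)
        result = run_cohort(model, payoffs, 24, discount=0.05)
        x0 = np.array([1.0, 0.0, 0.0])
        cost = qaly = 0.0
        for t in range(24):
            x = x0 @ np.linalg.matrix_power(SICKNESS, t)
            assert np.abs(result.trace[t] - x).max() < 1e-12
            df = 1.05 ** (-t / 12)
            cost += df * (x @ payoffs.state_cost)
            qaly += df * (x @ payoffs.state_utility) / 12
        assert result.total_cost == pytest.approx(cost, abs=1e-10)
        assert result.total_qaly == pytest.approx(qaly, abs=1e-10)

    def test_tolls_charged_on_flows(self):
        """A one-time toll is charged on the expected event flow, not on
        state occupancy."""
        intensity = np.zeros((3, len(EVENTS)))
        intensity[0, EVENTS.index("dvt_entry")] = 0.08
        model = TinyModel(SICKNESS, intensity)
        payoffs = tiny_payoffs(model, cost=(0.0, 0.0, 0.0), tolls={"dvt_entry": 693.0})
        result = run_cohort(model, payoffs, 2, discount=0.0)
        expected = 693.0 * 0.08 * (1.0 + SICKNESS[0, 0])
        assert result.total_cost == pytest.approx(expected, abs=1e-10)

    def test_bad_horizon_rejected(self):
        model = TinyModel(IDENTITY)
        with pytest.raises(ValueError):
            run_cohort(model, tiny_payoffs(model), 0)
        with pytest.raises(ValueError):
            run_cohort(model, tiny_payoffs(model), 12.5)


class TestFullModelInvariants:
    def test_mass_conservation_over_ten_years(self, params):
        result = run_strategy(params, "doacs", 120)
        assert np.abs(result.trace.sum(axis=1) - 1.0).max() < 1e-10

    def test_death_occupancy_monotone(self, results_5y):
        for result in results_5y.values():
            death = result.trace[:, -1]
            assert np.all(np.diff(death) >= -1e-15)

    def test_discounted_not_above_undiscounted(self, results_5y):
        for result in results_5y.values():
            assert result.total_cost <= result.undiscounted_cost + 1e-9
            assert result.total_qaly <= result.undiscounted_qaly + 1e-9

    @pytest.mark.parametrize("strategy", ["placebo", "doacs", "lmwhs"])
    def test_totals_monotone_in_horizon(self, params, strategy):
        qalys, costs = [], []
        for horizon in (36, 60, 120):
            r = run_strategy(params, strategy, horizon)
            qalys.append(r.total_qaly)
            costs.append(r.total_cost)
        assert qalys[0] < qalys[1] < qalys[2]
        assert costs[0] < costs[1] < costs[2]

    def test_discounting_monotone_in_rate(self, params):
        model = TransitionModel.from_parameters(params, "doacs")
        payoffs = PayoffSpec.from_parameters(params, "doacs", model.states)
        totals = [
            run_cohort(model, payoffs, 60, discount=r).total_qaly
            for r in (0.0, 0.03, 0.05, 0.08)
        ]
        assert all(a > b for a, b in zip(totals, totals[1:]))

    def test_base_case_cost_ordering(self, results_5y):
        assert (
            results_5y["placebo"].total_cost
            < results_5y["doacs"].total_cost
            < results_5y["lmwhs"].total_cost
        )

    def test_prophylaxis_gains_health_over_no_prophylaxis(self, results_5y):
        assert results_5y["placebo"].total_qaly < results_5y["doacs"].total_qaly
        assert results_5y["placebo"].total_qaly < results_5y["lmwhs"].total_qaly

    def test_half_cycle_correction_brackets_default(self, params):
        model = TransitionModel.from_parameters(params, "doacs")
        payoffs = PayoffSpec.from_parameters(params, "doacs", model.states)
        plain = run_cohort(model, payoffs, 60, discount=0.05)
        corrected = run_cohort(model, payoffs, 60, discount=0.05, half_cycle=True)
        # occupancy declines over time, so mid-cycle averaging lowers totals
        assert corrected.total_qaly < plain.total_qaly
        assert abs(corrected.total_qaly - plain.total_qaly) < 0.05

    def test_event_counts_reported(self, results_5y):
        counts = results_5y["placebo"].event_counts
        assert set(counts) == set(EVENTS)
        assert all(c >= 0 for c in counts.values())
        assert counts["dvt_entry"] > counts["ich_entry"]


class TestEventFlow:
    def test_flow_equals_occupancy_times_probability(self):
        flows = event_flow(np.array([1.0, 0.0, 0.0]), SICKNESS, {"dvt": [(0, 1)]})
        assert flows["dvt"] == pytest.approx(0.08, abs=1e-15)

    def test_absorbing_state_has_no_outflow(self):
        flows = event_flow(np.array([0.0, 0.0, 1.0]), SICKNESS, {"out": [(2, 0), (2, 1)]})
        assert flows["out"] == 0.0

    def test_flow_conservation(self):
        """Summed flows over all edges reproduce the occupancy update."""
        x = np.array([0.5, 0.3, 0.2])
        edges = {f"{i}->{j}": [(i, j)] for i in range(3) for j in range(3)}
        flows = event_flow(x, SICKNESS, edges)
        x_next = np.zeros(3)
        for (name, mass) in flows.items():
            j = int(name.split("->")[1])
            x_next[j] += mass
        assert np.abs(x_next - x @ SICKNESS).max() < 1e-14

    def test_unknown_edge_rejected(self):
        with pytest.raises(ValueError):
            event_flow(np.array([1.0, 0.0, 0.0]), SICKNESS, {"bad": [(0, 7)]})


def test_payoff_spec_validation():
    model = TinyModel(IDENTITY)
    with pytest.raises(ValueError):
        PayoffSpec(
            states=model.states,
            state_utility=np.array([0.5, 1.2, 0.0]),
            state_cost=np.zeros(3),
            event_cost={},
            event_disutility={},
        )
    with pytest.raises(ValueError):
        PayoffSpec(
            states=model.states,
            state_utility=np.array([0.5, 0.5, 0.0]),
            state_cost=np.array([-1.0, 0.0, 0.0]),
            event_cost={},
            event_disutility={},
        )


def test_cohort_result_records_run_metadata(results_5y):
    r: CohortResult = results_5y["doacs"]
    assert r.horizon_months == 60
    assert r.discount_rate == 0.05
    assert r.trace.shape == (61, len(r.states))
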