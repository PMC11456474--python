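"""State expansion, monthly conversion, and transition-matrix structure."""

import numpy as np
import pytest

from cavte_cea.markov import (
    TUNNEL_MONTHS,
    EVENTS,
    HealthState,
    MarkovOptions,
    StrategyInputs,
    TransitionModel,
    build_transition_matrix,
    expand_states,
    period_prob_to_cycle,
)

STRATEGIES = ("placebo", "doacs", "lmwhs", "apixaban", "rivaroxaban")


class TestPeriodConversion:
    # frozen from direct evaluation of 1 - (1-p)^(1/m)
    @pytest.mark.parametrize(
        "p,months,expected",
        [
            (0.194, 12, 0.0178121),  # no-prophylaxis annual first-VTE risk
            (0.153, 12, 0.0137426),  # annual cancer mortality
            (0.0, 12, 0.0),
            (1.0, 12, 1.0),
            (0.327, 3, 0.1236619),   # early CTEPH death, 90-day window
        ],
    )
    def test_examples(self, p, months, expected):
        assert period_prob_to_cycle(p, months) == pytest.approx(expected, abs=1e-6)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            period_prob_to_cycle(-0.1)
        with pytest.raises(ValueError):
            period_prob_to_cycle(1.1)
        with pytest.raises(ValueError):
            period_prob_to_cycle(0.5, 0)

    def test_monotone_in_period(self):
        qs = [period_prob_to_cycle(0.3, m) for m in (1, 3, 6, 12, 24)]
        assert all(a > b for a, b in zip(qs, qs[1:]))


class TestStateSpace:
    def test_ordering_and_bookends(self):
        states = expand_states()
        assert states[0].base == "no_complication"
        assert states[-1].base == "death"

    def test_therapeutic_window_is_three_months(self):
        states = expand_states()
        on_dose = [s for s in states if s.on_therapeutic_dose]
        assert {(s.base, s.tunnel_index) for s in on_dose} == {
            ("dvt", 1), ("dvt", 2), ("dvt", 3), ("pe", 1), ("pe", 2), ("pe", 3),
        }

    def test_tunnels_disabled_gives_base_states(self):
        assert len(expand_states(tunnels=False)) == 8

    def test_cteph_death_schedule_has_four_periods(self, params):
        model = TransitionModel.from_parameters(params, "placebo")
        death = model.index["death"]
        probs = {
            round(model.matrix_at(0)[model.index[s.label], death], 12)
            for s in model.states
            if s.base == "cteph"
        }
        assert len(probs) == 4

    def test_death_has_no_tunnel(self):
        with pytest.raises(ValueError):
            HealthState("death", 3)


class TestTransitionMatrix:
    @pytest.mark.parametrize("strategy", STRATEGIES)
    def test_row_stochastic_over_horizon(self, params, strategy):
        model = TransitionModel.from_parameters(params, strategy)
        for cycle in range(0, 120, 7):
            P = model.matrix_at(cycle)
            assert np.abs(P.sum(axis=1) - 1.0).max() < 1e-12
            assert P.min() >= 0.0 and P.max() <= 1.0

    def test_death_row_absorbing(self, params):
        model = TransitionModel.from_parameters(params, "doacs")
        row = model.matrix_at(0)[model.index["death"]]
        expected = np.zeros(model.n_states)
        expected[model.index["death"]] = 1.0
        assert np.array_equal(row, expected)

    def test_first_vte_split_matches_pe_share(self, params):
        """From the complication-free state the monthly VTE mass splits
        between PE and DVT by the strategy's PE share."""
        model = TransitionModel.from_parameters(params, "placebo")
        P = model.matrix_at(0)
        src = model.index["no_complication"]
        q_vte = period_prob_to_cycle(0.194)
        assert P[src, model.index["pe_m1"]] == pytest.approx(q_vte * 0.456, abs=1e-12)
        assert P[src, model.index["dvt_m1"]] == pytest.approx(q_vte * 0.544, abs=1e-12)

    def test_ich_entry_splits_on_discontinuation(self, params):
        model = TransitionModel.from_parameters(params, "doacs")
        P = model.matrix_at(0)
        src = model.index["no_complication"]
        ich_mass = (
            period_prob_to_cycle(0.144) * 0.357 * 0.125
        )
        assert P[src, model.index["ich_off_treatment"]] == pytest.approx(
            ich_mass * 0.657, abs=1e-12
        )
        assert P[src, model.index["ich_on_treatment"]] == pytest.approx(
            ich_mass * 0.343, abs=1e-12
        )

    def test_transient_bleeds_do_not_change_state(self, params):
        """CRNMB and GI bleeding stay with the residual flow but appear as
        toll events in the intensity matrix."""
        model = TransitionModel.from_parameters(params, "doacs")
        E = model.intensity_at(0)
        src = model.index["no_complication"]
        q_bleed = period_prob_to_cycle(0.144)
        assert E[src, EVENTS.index("crnmb")] == pytest.approx(q_bleed * (1 - 0.357), abs=1e-12)
        assert E[src, EVENTS.index("gib")] == pytest.approx(
            q_bleed * 0.357 * (1 - 0.125), abs=1e-12
        )

    def test_zero_event_inputs_are_identity_dynamics(self, params):
        ps = params
        for name in ("prob_first_vte", "prob_bleeding"):
            ps = ps.replace_parameter(name, 0.0, "doacs")
        ps = ps.replace_parameter("annual_death_rate_cancer", 0.0)
        model = TransitionModel.from_parameters(ps, "doacs")
        src = model.index["no_complication"]
        assert model.matrix_at(0)[src, src] == 1.0

    def test_branch_overflow_raises_naming_state(self, params):
        ps = params.replace_parameter("prob_death_pe", 1.0)
        ps = ps.replace_parameter("prob_recurrent_vte_pe", 0.9)
        ps = ps.replace_parameter("prob_bleeding_pe", 0.9)
        with pytest.raises(ValueError, match="pe_m"):
            TransitionModel.from_parameters(ps, "doacs")

    def test_overflow_rescale_mode_counts(self, params):
        ps = params.replace_parameter("prob_death_pe", 1.0)
        ps = ps.replace_parameter("prob_recurrent_vte_pe", 0.9)
        ps = ps.replace_parameter("prob_bleeding_pe", 0.9)
        model = TransitionModel.from_parameters(
            ps, "doacs", MarkovOptions(on_overflow="rescale")
        )
        assert model.overflow_count > 0
        assert np.abs(model.matrix_at(0).sum(axis=1) - 1.0).max() < 1e-12

    def test_additive_mortality_exceeds_total_mode(self, params):
        total = TransitionModel.from_parameters(params, "doacs")
        additive = TransitionModel.from_parameters(
            params, "doacs", MarkovOptions(mortality_mode="additive")
        )
        death = total.index["death"]
        src = total.index["pts"]
        assert additive.matrix_at(0)[src, death] > total.matrix_at(0)[src, death]

    def test_build_transition_matrix_facade(self, params):
        P1 = build_transition_matrix(params, 0, strategy="doacs")
        P2 = TransitionModel.from_parameters(params, "doacs").matrix_at(0)
        assert np.array_equal(P1, P2)
        inputs = StrategyInputs.from_parameters(params, "doacs")
        assert np.array_equal(build_transition_matrix(inputs), P2)

    def test_off_treatment_ich_uses_no_prophylaxis_splits(self, params):
        """After stopping anticoagulation the bleeding severity mix reverts
        to the no-prophylaxis proportions."""
        model = TransitionModel.from_parameters(params, "doacs")
        E = model.intensity_at(0)
        q = period_prob_to_cycle(0.086)
        src = model.index["ich_off_treatment"]
        assert E[src, EVENTS.index("gib")] == pytest.approx(
            q * 0.285 * (1 - 0.231), abs=1e-12
        )

    def test_debug_dump_round_trips(self, params, tmp_path):
        import json

        import pandas as pd

        model = TransitionModel.from_parameters(params, "doacs")
        model.dump_debug(tmp_path)
        frame = pd.read_csv(tmp_path / "transition_doacs.csv", index_col=0)
        assert frame.shape == (model.n_states, model.n_states)
        assert np.abs(frame.to_numpy() - model.matrix_at(0)).max() < 1e-12
        states = json.loads((tmp_path / "states_doacs.json").read_text())
        assert [s["label"] for s in states] == [s.label for s in model.states]

    @pytest.mark.parametrize("strategy", ["doacs", "placebo"])
    def test_tunnel_advance(self, params, strategy):
        """Survivors of an acute-event month move to the next tunnel month;
        the late tail absorbs its own survivors."""
        model = TransitionModel.from_parameters(params, strategy)
        P = model.matrix_at(0)
        for base in ("dvt", "pe", "cteph"):
            for m in range(1, TUNNEL_MONTHS):
                src = model.index[f"{base}_m{m}"]
                assert P[src, model.index[f"{base}_m{m + 1}"]] > 0
            late = model.index[f"{base}_late"]
            assert P[late, late] > 0
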