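"""Cohort propagation and discounted payoff accrual.

The engine starts the whole cohort complication-free, advances it by
matrix multiplication for a fixed monthly horizon, and accrues costs and
QALYs per cycle:

* occupancy payoffs — per-cycle drug and chronic-management costs and
  annual state utilities divided by 12;
* flow payoffs — one-time event costs (acute DVT/PE management, ICH, GI
  bleed, CRNMB) and one-time bleeding disutilities, charged on the expected
  event flow out of each state.

Both streams are discounted at an annual rate converted per cycle.  Drug
costs are multiplied by the self-paid share of the drug bill (Medicare
reimbursement); event-management costs are not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .markov import EVENTS, HealthState, MarkovOptions, TransitionModel
from .parameters import ParameterSet

__all__ = [
    "PayoffSpec",
    "CohortResult",
    "discount_factor",
    "run_cohort",
    "run_strategy",
    "event_flow",
]

_STATE_UTILITY_KEY = {
    "no_complication": "utility_cancer_no_vte",
    "dvt": "utility_dvt",
    "pe": "utility_pe",
    "ich_on_treatment": "utility_ich",
    "ich_off_treatment": "utility_ich",
    "pts": "utility_pts",
    "cteph": "utility_cteph",
    "death": "utility_death",
}


def discount_factor(cycle: int, annual_rate: float) -> float:
    """Discount factor ``(1 + r)^(-cycle/12)`` for a monthly cycle index."""
    if cycle < 0:
        raise ValueError("cycle must be non-negative")
    if annual_rate < 0:
        raise ValueError("annual_rate must be non-negative")
    return float((1.0 + annual_rate) ** (-cycle / 12.0))


@dataclass
class PayoffSpec:
    """Per-state and per-event payoffs for one strategy.

    ``state_utility`` is per year of occupancy; ``state_cost`` per cycle.
    ``event_cost`` / ``event_disutility`` are one-time tolls charged on the
    transition flow into the event, keyed by the labels in
    :data:`cavte_cea.markov.EVENTS`.
    """

    states: list[HealthState]
    state_utility: np.ndarray
    state_cost: np.ndarray
    event_cost: dict[str, float]
    event_disutility: dict[str, float]
    strategy: str = ""

    def __post_init__(self) -> None:
        n = len(self.states)
        if len(self.state_utility) != n or len(self.state_cost) != n:
            raise ValueError("payoff vectors must match the state list")
        if np.any(self.state_utility < 0) or np.any(self.state_utility > 1):
            raise ValueError("state utilities must lie in [0, 1]")
        if np.any(self.state_cost < 0) or any(c < 0 for c in self.event_cost.values()):
            raise ValueError("costs must be non-negative")

    def toll_vectors(self) -> tuple[np.ndarray, np.ndarray]:
        cost = np.array([self.event_cost.get(e, 0.0) for e in EVENTS])
        dis = np.array([self.event_disutility.get(e, 0.0) for e in EVENTS])
        return cost, dis

    @classmethod
    def from_parameters(
        cls,
        ps: ParameterSet,
        strategy: str,
        states: list[HealthState],
    ) -> "PayoffSpec":
        """Wire the packaged parameter table into per-state payoffs.

        Drug cost: prophylactic dose in every alive anticoagulated state,
        therapeutic dose (the 3-month course spread over its three cycles)
        in the acute VTE window, nothing once treatment stopped after ICH;
        all drug costs carry the Medicare self-paid share.  Annual chronic
        costs (post-ICH care, PTS, CTEPH) are spread per cycle.
        """
        v = ps.value
        self_pay = v("self_pay_ratio")
        prophylaxis = v("cost_prophylaxis_cycle", strategy) * self_pay
        treatment_cycle = v("cost_treatment_3mo", strategy) / 3.0 * self_pay
        # after a VTE every arm continues anticoagulation at prophylactic
        # dose; the no-prophylaxis arm prices it separately (its primary
        # prophylaxis costs nothing)
        try:
            secondary = v("cost_secondary_prophylaxis_cycle", strategy) * self_pay
        except KeyError:
            secondary = prophylaxis
        chronic = {
            "ich_on_treatment": v("cost_post_ich_annual") / 12.0,
            "ich_off_treatment": v("cost_post_ich_annual") / 12.0,
            "pts": v("cost_pts_annual") / 12.0,
            "cteph": v("cost_cteph_annual") / 12.0,
        }
        n = len(states)
        utility = np.zeros(n)
        cost = np.zeros(n)
        for i, st in enumerate(states):
            utility[i] = v(_STATE_UTILITY_KEY[st.base])
            if st.base == "death":
                continue
            if st.on_therapeutic_dose:
                cost[i] += treatment_cycle
            elif st.base == "no_complication":
                cost[i] += prophylaxis
            elif st.base != "ich_off_treatment":
                cost[i] += secondary
            cost[i] += chronic.get(st.base, 0.0)
        return cls(
            states=list(states),
            state_utility=utility,
            state_cost=cost,
            event_cost={
                "dvt_entry": v("cost_event_dvt"),
                "pe_entry": v("cost_event_pe"),
                "ich_entry": v("cost_event_ich"),
                "gib": v("cost_event_gib"),
                "crnmb": v("cost_event_crnmb"),
            },
            event_disutility={
                "ich_entry": v("disutility_major_bleed"),
                "gib": v("disutility_major_bleed"),
                "crnmb": v("disutility_crnmb"),
            },
            strategy=strategy,
        )


@dataclass
class CohortResult:
    """Occupancy trace and discounted totals for one strategy run."""

    strategy: str
    states: list[HealthState]
    trace: np.ndarray            # (horizon + 1, n_states)
    total_cost: float
    total_qaly: float
    undiscounted_cost: float
    undiscounted_qaly: float
    horizon_months: int
    discount_rate: float
    event_counts: dict[str, float] = field(default_factory=dict)

    @property
    def cost_qaly(self) -> tuple[float, float]:
        return (self.total_cost, self.total_qaly)


def run_cohort(
    model: TransitionModel,
    payoffs: PayoffSpec,
    horizon_months: int,
    discount: float = 0.05,
    half_cycle: bool = False,
) -> CohortResult:
    """Propagate the cohort and accrue discounted costs and QALYs.

    The cohort starts fully complication-free.  Occupancy payoffs are
    charged on the start-of-cycle occupancy (or, with ``half_cycle=True``,
    on the average of start- and end-of-cycle occupancy); one-time tolls on
    the event flow during the cycle.
    """
    if not isinstance(horizon_months, (int, np.integer)) or horizon_months <= 0:
        raise ValueError("horizon_months must be a positive integer")
    if [s.label for s in model.states] != [s.label for s in payoffs.states]:
        raise ValueError("model and payoffs must share the same state list")

    n = model.n_states
    P = model.matrix_at(0)
    intensity = model.intensity_at(0)
    toll_cost, toll_dis = payoffs.toll_vectors()
    state_toll_cost = intensity @ toll_cost        # expected $ per person-cycle
    state_toll_dis = intensity @ toll_dis

    x = np.zeros(n)
    x[0] = 1.0
    trace = np.empty((horizon_months + 1, n))
    trace[0] = x
    total_cost = total_qaly = undisc_cost = undisc_qaly = 0.0
    event_counts = np.zeros(len(EVENTS))

    for t in range(horizon_months):
        x_next = x @ P
        occ = 0.5 * (x + x_next) if half_cycle else x
        df = discount_factor(t, discount)
        cost_t = occ @ payoffs.state_cost + x @ state_toll_cost
        qaly_t = occ @ payoffs.state_utility / 12.0 - x @ state_toll_dis
        total_cost += df * cost_t
        total_qaly += df * qaly_t
        undisc_cost += cost_t
        undisc_qaly += qaly_t
        event_counts += x @ intensity
        x = x_next
        trace[t + 1] = x

    return CohortResult(
        strategy=model.strategy,
        states=model.states,
        trace=trace,
        total_cost=float(total_cost),
        total_qaly=float(total_qaly),
        undiscounted_cost=float(undisc_cost),
        undiscounted_qaly=float(undisc_qaly),
        horizon_months=int(horizon_months),
        discount_rate=float(discount),
        event_counts=dict(zip(EVENTS, event_counts.tolist())),
    )


def run_strategy(
    ps: ParameterSet,
    strategy: str,
    horizon_months: int = 60,
    options: MarkovOptions | None = None,
    half_cycle: bool = False,
) -> CohortResult:
    """Build the transition model and payoffs for one strategy and run it."""
    model = TransitionModel.from_parameters(ps, strategy, options)
    payoffs = PayoffSpec.from_parameters(ps, strategy, model.states)
    return run_cohort(
        model,
        payoffs,
        horizon_months,
        discount=ps.value("discount_rate_annual"),
        half_cycle=half_cycle,
    )


def event_flow(
    trace_row: np.ndarray,
    matrix: np.ndarray,
    event_edges: dict[str, list[tuple[int, int]]],
) -> dict[str, float]:
    """Per-event transition flow: occupancy × transition probability.

    ``event_edges`` maps an event label to the (source, destination) index
    pairs that realize it.  Unknown indices raise.
    """
    n = matrix.shape[0]
    flows: dict[str, float] = {}
    for event, edges in event_edges.items():
        mass = 0.0
        for i, j in edges:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"edge ({i}, {j}) outside the state space")
            mass += trace_row[i] * matrix[i, j]
        flows[event] = mass
    return flows
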