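"""State space and transition structure of the thromboprophylaxis model.

The cohort moves monthly between health states of a cancer population under
primary VTE prophylaxis: complication-free, acute/post-acute DVT and PE,
intracranial haemorrhage (on or off continued anticoagulation), the chronic
sequelae PTS (post-thrombotic syndrome, after DVT) and CTEPH (chronic
thromboembolic pulmonary hypertension, after PE), and death.

Time-since-event dependence — the 3-month therapeutic anticoagulation window
after a VTE, the year-indexed PTS/CTEPH incidence schedules, and the
period-indexed CTEPH death schedule — is encoded with month-level tunnel
states (months 1..24 since entry, then a pooled "year 3+" tail).  Because
all time dependence is time-since-entry, the transition matrix itself does
not vary with the global cycle index.

Competing events within a cycle (VTE, bleeding, death, progression) are
mutually exclusive branch masses of a single chance node; an error is raised
if they sum above one — inputs are never silently renormalized.  Clinically
relevant non-major bleeding and gastrointestinal bleeding are transient
tolls (cost/QALY decrements on the flow) rather than states.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .parameters import ParameterSet

__all__ = [
    "HealthState",
    "StrategyInputs",
    "TransitionModel",
    "MarkovOptions",
    "EVENTS",
    "period_prob_to_cycle",
    "expand_states",
    "build_transition_matrix",
]

#: number of month-level tunnel cycles tracked after an acute event; time
#: since entry beyond this is pooled into a "late" (year 3+) tail state
TUNNEL_MONTHS = 24

BASE_STATES = (
    "no_complication",
    "dvt",
    "pe",
    "ich_on_treatment",
    "ich_off_treatment",
    "pts",
    "cteph",
    "death",
)

#: transition-event labels, in the column order of the event-intensity matrix
EVENTS = ("dvt_entry", "pe_entry", "ich_entry", "gib", "crnmb")


@dataclass(frozen=True)
class HealthState:
    """One expanded state: a base state plus months since entry.

    ``tunnel_index`` is 0 for states without a clock, 1..TUNNEL_MONTHS for
    month tunnels, and TUNNEL_MONTHS + 1 for the pooled year-3+ tail.
    """

    base: str
    tunnel_index: int = 0

    def __post_init__(self) -> None:
        if self.base not in BASE_STATES:
            raise ValueError(f"unknown base state {self.base!r}")
        if self.base == "death" and self.tunnel_index:
            raise ValueError("death carries no tunnel index")

    @property
    def is_late(self) -> bool:
        return self.tunnel_index == TUNNEL_MONTHS + 1

    @property
    def on_therapeutic_dose(self) -> bool:
        """True during the 3-month therapeutic window after a VTE."""
        return self.base in ("dvt", "pe") and 1 <= self.tunnel_index <= 3

    @property
    def label(self) -> str:
        if self.tunnel_index == 0:
            return self.base
        if self.is_late:
            return f"{self.base}_late"
        return f"{self.base}_m{self.tunnel_index}"


def period_prob_to_cycle(p: float, period_months: float = 12.0) -> float:
    """Convert a probability over ``period_months`` to a 1-month probability.

    Uses the constant-rate assumption ``1 - (1 - p)**(1/period_months)``.
    ``p == 1`` maps to 1 for any finite period.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p} outside [0, 1]")
    if period_months <= 0:
        raise ValueError("period_months must be positive")
    if p == 1.0:
        return 1.0
    return 1.0 - (1.0 - p) ** (1.0 / period_months)


def expand_states(tunnels: bool = True, tunnel_months: int = TUNNEL_MONTHS) -> list[HealthState]:
    """Deterministically ordered expanded state list.

    Complication-free first, death last; tunnels enumerated contiguously
    (months 1..``tunnel_months``, then the pooled late tail).  With
    ``tunnels=False`` the eight base states are returned (debug mode).
    """
    if not tunnels:
        return [HealthState(b) for b in BASE_STATES]
    states = [HealthState("no_complication")]
    for base in ("dvt", "pe"):
        states += [HealthState(base, m) for m in range(1, tunnel_months + 1)]
        states.append(HealthState(base, tunnel_months + 1))
    states += [HealthState("ich_on_treatment"), HealthState("ich_off_treatment"), HealthState("pts")]
    states += [HealthState("cteph", m) for m in range(1, tunnel_months + 1)]
    states.append(HealthState("cteph", tunnel_months + 1))
    states.append(HealthState("death"))
    return states


@dataclass(frozen=True)
class StrategyInputs:
    """Event rates, branching proportions and drug costs for one strategy.

    Probabilities are stored on their native period (annual unless noted)
    and converted per cycle inside the matrix builder.  The off-treatment
    branch proportions are the no-prophylaxis values, used for patients who
    stopped anticoagulation after an intracranial haemorrhage.
    """

    strategy: str
    first_vte_annual: float
    bleeding_annual: float
    pe_share: float
    mb_share: float
    ich_share: float
    ich_discontinue: float
    death_cancer_annual: float
    rec_dvt_annual: float
    bleed_dvt_annual: float
    death_dvt_annual: float
    rec_pe_annual: float
    bleed_pe_annual: float
    death_pe_annual: float
    rec_ich_annual: float
    bleed_ich_on_annual: float
    bleed_ich_off_annual: float
    death_ich_on_annual: float
    death_ich_off_annual: float
    death_pts_annual: float
    pts_schedule: tuple[float, float, float]      # year 1, year 2, year 3+
    cteph_schedule: tuple[float, float]           # year 1, year 2 (0 after)
    cteph_death: tuple[float, float, float, float]        # per-period probs
    cteph_death_periods: tuple[float, float, float, float]  # period lengths, months
    off_pe_share: float
    off_mb_share: float
    off_ich_share: float

    @classmethod
    def from_parameters(cls, ps: ParameterSet, strategy: str) -> "StrategyInputs":
        v = ps.value
        return cls(
            strategy=strategy,
            first_vte_annual=v("prob_first_vte", strategy),
            bleeding_annual=v("prob_bleeding", strategy),
            pe_share=v("prop_first_vte_pe", strategy),
            mb_share=v("prop_major_bleed", strategy),
            ich_share=v("prop_ich_in_mb", strategy),
            ich_discontinue=v("prop_ich_discontinue"),
            death_cancer_annual=v("annual_death_rate_cancer"),
            rec_dvt_annual=v("prob_recurrent_vte_dvt"),
            bleed_dvt_annual=v("prob_bleeding_dvt"),
            death_dvt_annual=v("prob_death_dvt"),
            rec_pe_annual=v("prob_recurrent_vte_pe"),
            bleed_pe_annual=v("prob_bleeding_pe"),
            death_pe_annual=v("prob_death_pe"),
            rec_ich_annual=v("prob_recurrent_vte_ich"),
            bleed_ich_on_annual=v("prob_bleeding_ich_on"),
            bleed_ich_off_annual=v("prob_bleeding_ich_off"),
            death_ich_on_annual=v("prob_death_ich_on"),
            death_ich_off_annual=v("prob_death_ich_off"),
            death_pts_annual=v("prob_death_pts"),
            pts_schedule=(
                v("prob_pts_dvt_year1"),
                v("prob_pts_dvt_year2"),
                v("prob_pts_dvt_year3plus"),
            ),
            cteph_schedule=(v("prob_cteph_pe_year1"), v("prob_cteph_pe_year2")),
            cteph_death=(
                v("prob_death_cteph_days_1_90"),
                v("prob_death_cteph_days_91_365"),
                v("prob_death_cteph_year2"),
                v("prob_death_cteph_year3plus"),
            ),
            cteph_death_periods=(3.0, 9.0, 12.0, 12.0),
            off_pe_share=v("prop_first_vte_pe", "placebo"),
            off_mb_share=v("prop_major_bleed", "placebo"),
            off_ich_share=v("prop_ich_in_mb", "placebo"),
        )


@dataclass(frozen=True)
class MarkovOptions:
    """Structural switches of the transition model.

    mortality_mode
        ``"total"`` (default): the state-specific death probabilities are
        total mortality in that state (they come from cohort studies of
        cancer patients in that state).  ``"additive"``: combined with
        background cancer mortality as independent risks.
    on_overflow
        ``"error"`` raises when competing branch masses exceed 1 (default);
        ``"rescale"`` proportionally rescales the event masses — used by the
        probabilistic analysis, which counts such draws.
    """

    mortality_mode: str = "total"
    on_overflow: str = "error"

    def __post_init__(self) -> None:
        if self.mortality_mode not in ("total", "additive"):
            raise ValueError(f"unknown mortality_mode {self.mortality_mode!r}")
        if self.on_overflow not in ("error", "rescale"):
            raise ValueError(f"unknown on_overflow {self.on_overflow!r}")


def _cteph_period_of_month(month: int) -> int:
    """Map months since CTEPH entry (1-based) to the 4-period death schedule."""
    if month <= 3:
        return 0
    if month <= 12:
        return 1
    if month <= 24:
        return 2
    return 3


class TransitionModel:
    """Cycle-indexed row-stochastic transition matrix for one strategy.

    The matrix is constant across cycles (all time dependence lives in the
    tunnel states), so :meth:`matrix_at` returns a cached array.  Alongside
    the matrix, a per-state event-intensity matrix records the expected
    number of toll events (DVT/PE/ICH entry, GI bleed, CRNMB) per person in
    each source state per cycle, used by the cohort engine to charge
    one-time costs and disutilities on transition flows.
    """

    def __init__(
        self,
        inputs: StrategyInputs,
        options: MarkovOptions | None = None,
        states: Sequence[HealthState] | None = None,
    ) -> None:
        self.inputs = inputs
        self.options = options or MarkovOptions()
        self.states = list(states) if states is not None else expand_states()
        self.strategy = inputs.strategy
        self.index = {s.label: i for i, s in enumerate(self.states)}
        self.overflow_count = 0
        self._matrix, self._intensity = self._build()

    @property
    def n_states(self) -> int:
        return len(self.states)

    def matrix_at(self, cycle: int = 0) -> np.ndarray:
        """Transition matrix for ``cycle`` (cycle-invariant, cached)."""
        if cycle < 0:
            raise ValueError("cycle must be non-negative")
        return self._matrix

    def intensity_at(self, cycle: int = 0) -> np.ndarray:
        """Event-intensity matrix (n_states × len(EVENTS)) for ``cycle``."""
        if cycle < 0:
            raise ValueError("cycle must be non-negative")
        return self._intensity

    def dump_debug(self, directory) -> None:
        """Write the transition matrix (CSV) and state list (JSON)."""
        import json
        from pathlib import Path

        import pandas as pd

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        labels = [s.label for s in self.states]
        pd.DataFrame(self._matrix, index=labels, columns=labels).to_csv(
            directory / f"transition_{self.strategy}.csv"
        )
        (directory / f"states_{self.strategy}.json").write_text(
            json.dumps(
                [
                    {"label": s.label, "base": s.base, "tunnel_index": s.tunnel_index}
                    for s in self.states
                ],
                indent=2,
            )
        )

    # ---- construction ------------------------------------------------------

    def _death_prob(self, state_annual: float) -> float:
        """Monthly death probability in an event state, per mortality mode."""
        q = period_prob_to_cycle(state_annual)
        if self.options.mortality_mode == "additive":
            q_bg = period_prob_to_cycle(self.inputs.death_cancer_annual)
            q = 1.0 - (1.0 - q) * (1.0 - q_bg)
        return q

    def _row(
        self,
        P: np.ndarray,
        E: np.ndarray,
        src: int,
        stay: int,
        q_death: float,
        q_vte: float,
        pe_share: float,
        q_bleed: float,
        mb_share: float,
        ich_share: float,
        extra: dict[int, float] | None = None,
        new_ich_to_off: bool = True,
    ) -> None:
        """Fill one source row from its competing branch masses.

        ``stay`` is the destination of the residual mass (the next tunnel
        month for clocked states).  ``extra`` carries additional exclusive
        branches (PTS/CTEPH progression).  Transient bleeds (CRNMB, GIB)
        remain with the residual flow but are recorded as toll events.
        """
        ix = self.index
        extra = extra or {}
        total = q_death + q_vte + q_bleed + sum(extra.values())
        if total > 1.0:
            if self.options.on_overflow == "error":
                raise ValueError(
                    f"branch masses sum to {total:.6f} > 1 in state "
                    f"{self.states[src].label!r} (strategy {self.strategy!r})"
                )
            self.overflow_count += 1
            scale = 1.0 / total
            q_death *= scale
            q_vte *= scale
            q_bleed *= scale
            extra = {k: v * scale for k, v in extra.items()}
            total = 1.0

        crnmb = q_bleed * (1.0 - mb_share)
        gib = q_bleed * mb_share * (1.0 - ich_share)
        ich = q_bleed * mb_share * ich_share

        P[src, ix["death"]] += q_death
        if q_vte:
            P[src, ix["pe_m1"]] += q_vte * pe_share
            P[src, ix["dvt_m1"]] += q_vte * (1.0 - pe_share)
            E[src, EVENTS.index("pe_entry")] += q_vte * pe_share
            E[src, EVENTS.index("dvt_entry")] += q_vte * (1.0 - pe_share)
        if ich:
            if new_ich_to_off:
                disc = self.inputs.ich_discontinue
                P[src, ix["ich_off_treatment"]] += ich * disc
                P[src, ix["ich_on_treatment"]] += ich * (1.0 - disc)
            else:
                # already off treatment: a further ICH does not move the cohort
                P[src, stay] += ich
            E[src, EVENTS.index("ich_entry")] += ich
        for dest, mass in extra.items():
            P[src, dest] += mass
        # residual mass, including the transient bleeding flows
        P[src, stay] += 1.0 - total + crnmb + gib
        E[src, EVENTS.index("gib")] += gib
        E[src, EVENTS.index("crnmb")] += crnmb

    def _build(self) -> tuple[np.ndarray, np.ndarray]:
        n = self.n_states
        s = self.inputs
        ix = self.index
        P = np.zeros((n, n))
        E = np.zeros((n, len(EVENTS)))
        m = period_prob_to_cycle

        # complication-free, on prophylaxis
        self._row(
            P, E,
            src=ix["no_complication"], stay=ix["no_complication"],
            q_death=m(s.death_cancer_annual),
            q_vte=m(s.first_vte_annual), pe_share=s.pe_share,
            q_bleed=m(s.bleeding_annual), mb_share=s.mb_share, ich_share=s.ich_share,
        )

        # DVT tunnels: recurrence, bleeding, death, PTS progression
        for st in self.states:
            if st.base != "dvt":
                continue
            src = ix[st.label]
            year = 2 if st.is_late else min((st.tunnel_index - 1) // 12, 2)
            nxt = "dvt_late" if st.tunnel_index >= TUNNEL_MONTHS else f"dvt_m{st.tunnel_index + 1}"
            self._row(
                P, E, src=src, stay=ix[nxt],
                q_death=self._death_prob(s.death_dvt_annual),
                q_vte=m(s.rec_dvt_annual), pe_share=s.pe_share,
                q_bleed=m(s.bleed_dvt_annual), mb_share=s.mb_share, ich_share=s.ich_share,
                extra={ix["pts"]: m(s.pts_schedule[year])},
            )

        # PE tunnels: recurrence, bleeding, death, CTEPH progression
        for st in self.states:
            if st.base != "pe":
                continue
            src = ix[st.label]
            nxt = "pe_late" if st.tunnel_index >= TUNNEL_MONTHS else f"pe_m{st.tunnel_index + 1}"
            if st.is_late:
                q_cteph = 0.0
            else:
                year = min((st.tunnel_index - 1) // 12, 1)
                q_cteph = m(s.cteph_schedule[year])
            extra = {ix["cteph_m1"]: q_cteph} if q_cteph else None
            self._row(
                P, E, src=src, stay=ix[nxt],
                q_death=self._death_prob(s.death_pe_annual),
                q_vte=m(s.rec_pe_annual), pe_share=s.pe_share,
                q_bleed=m(s.bleed_pe_annual), mb_share=s.mb_share, ich_share=s.ich_share,
                extra=extra,
            )

        # ICH, still anticoagulated: a further ICH may stop treatment
        self._row(
            P, E, src=ix["ich_on_treatment"], stay=ix["ich_on_treatment"],
            q_death=self._death_prob(s.death_ich_on_annual),
            q_vte=m(s.rec_ich_annual), pe_share=s.pe_share,
            q_bleed=m(s.bleed_ich_on_annual), mb_share=s.mb_share, ich_share=s.ich_share,
        )
        # ICH, off anticoagulation: no-prophylaxis event profile
        self._row(
            P, E, src=ix["ich_off_treatment"], stay=ix["ich_off_treatment"],
            q_death=self._death_prob(s.death_ich_off_annual),
            q_vte=m(s.rec_ich_annual), pe_share=s.off_pe_share,
            q_bleed=m(s.bleed_ich_off_annual), mb_share=s.off_mb_share,
            ich_share=s.off_ich_share,
            new_ich_to_off=False,
        )

        # chronic sequelae
        P[ix["pts"], ix["death"]] = self._death_prob(s.death_pts_annual)
        P[ix["pts"], ix["pts"]] = 1.0 - P[ix["pts"], ix["death"]]
        for st in self.states:
            if st.base != "cteph":
                continue
            src = ix[st.label]
            nxt = "cteph_late" if st.tunnel_index >= TUNNEL_MONTHS else f"cteph_m{st.tunnel_index + 1}"
            period = 3 if st.is_late else _cteph_period_of_month(st.tunnel_index)
            q_d = m(s.cteph_death[period], s.cteph_death_periods[period])
            if self.options.mortality_mode == "additive":
                q_d = 1.0 - (1.0 - q_d) * (1.0 - m(s.death_cancer_annual))
            P[src, ix["death"]] = q_d
            P[src, ix[nxt]] += 1.0 - q_d

        P[ix["death"], ix["death"]] = 1.0  # absorbing

        if np.any(P < -1e-15):
            i, j = np.argwhere(P < -1e-15)[0]
            raise ValueError(
                f"negative transition mass {P[i, j]:.3e} from "
                f"{self.states[i].label!r} (strategy {self.strategy!r})"
            )
        np.clip(P, 0.0, 1.0, out=P)
        row_err = np.abs(P.sum(axis=1) - 1.0).max()
        if row_err > 1e-12:
            raise AssertionError(f"row sums deviate from 1 by {row_err:.3e}")
        return P, E

    @classmethod
    def from_parameters(
        cls,
        ps: ParameterSet,
        strategy: str,
        options: MarkovOptions | None = None,
    ) -> "TransitionModel":
        return cls(StrategyInputs.from_parameters(ps, strategy), options=options)


def build_transition_matrix(
    params: StrategyInputs | ParameterSet,
    cycle: int = 0,
    strategy: str | None = None,
    options: MarkovOptions | None = None,
) -> np.ndarray:
    """Square transition matrix over the expanded states for one cycle."""
    if isinstance(params, ParameterSet):
        if strategy is None:
            raise ValueError("strategy required when passing a ParameterSet")
        model = TransitionModel.from_parameters(params, strategy, options)
    else:
        model = TransitionModel(params, options=options)
    return model.matrix_at(cycle)
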