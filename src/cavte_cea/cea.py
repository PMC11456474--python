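"""Incremental cost-effectiveness statistics and scenario grid.

Comparisons follow standard decision-analytic practice: pairwise ICERs
against named reference strategies (the layout of the result tables),
plus a proper efficiency-frontier analysis with strict and extended
dominance, net monetary benefit, and cost-effectiveness acceptability
curves across willingness-to-pay values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortResult, run_strategy
from .markov import MarkovOptions
from .parameters import ParameterSet

__all__ = [
    "CeaComparison",
    "CeacCurve",
    "compute_icer",
    "nmb",
    "incremental_frontier",
    "FrontierEntry",
    "ceac",
    "run_scenarios",
    "evaluate_strategies",
]


@dataclass(frozen=True)
class CeaComparison:
    """Incremental comparison of ``comparator`` against ``reference``.

    ``icer`` is None when the QALY difference is zero (cost-minimization
    case) or when a dominance flag makes the ratio uninformative on its own.
    ``dominant`` means the comparator saves money AND gains health;
    ``dominated`` the reverse.
    """

    reference: str
    comparator: str
    delta_cost: float
    delta_qaly: float
    icer: float | None
    dominant: bool
    dominated: bool


def compute_icer(
    ref: tuple[float, float],
    comp: tuple[float, float],
    ref_name: str = "reference",
    comp_name: str = "comparator",
) -> CeaComparison:
    """ICER of ``comp`` (cost, qaly) versus ``ref`` (cost, qaly)."""
    for pair in (ref, comp):
        if not all(np.isfinite(pair)):
            raise ValueError("cost/QALY inputs must be finite")
    dc = comp[0] - ref[0]
    dq = comp[1] - ref[1]
    icer = dc / dq if dq != 0.0 else None
    return CeaComparison(
        reference=ref_name,
        comparator=comp_name,
        delta_cost=dc,
        delta_qaly=dq,
        icer=icer,
        dominant=dc < 0 and dq > 0,
        dominated=dc > 0 and dq < 0,
    )


def nmb(cost: float, qaly: float, wtp: float) -> float:
    """Net monetary benefit ``qaly * wtp - cost``."""
    if wtp < 0:
        raise ValueError("wtp must be non-negative")
    return qaly * wtp - cost


@dataclass
class FrontierEntry:
    strategy: str
    cost: float
    qaly: float
    dominated: bool = False
    extended_dominated: bool = False
    icer_vs_previous: float | None = None


def incremental_frontier(
    results: Sequence[CohortResult] | Sequence[tuple[str, float, float]],
) -> list[FrontierEntry]:
    """Efficiency-frontier analysis of two or more strategies.

    Strategies are ordered by cost; strictly dominated entries (more costly,
    fewer QALYs than some other strategy) are flagged, then extended
    dominance removes entries off the convex frontier (their incremental
    ICER exceeds that of the next more effective option).  Sequential ICERs
    are reported along the surviving frontier.
    """
    rows: list[FrontierEntry] = []
    for r in results:
        if isinstance(r, CohortResult):
            rows.append(FrontierEntry(r.strategy, r.total_cost, r.total_qaly))
        else:
            name, cost, qaly = r
            rows.append(FrontierEntry(name, cost, qaly))
    if len(rows) < 2:
        raise ValueError("frontier analysis needs at least two strategies")
    names = [r.strategy for r in rows]
    if len(set(names)) != len(names):
        raise ValueError("duplicate strategy names")

    rows.sort(key=lambda r: (r.cost, -r.qaly))
    for r in rows:
        r.dominated = any(
            o.cost <= r.cost and o.qaly > r.qaly or o.cost < r.cost and o.qaly >= r.qaly
            for o in rows
            if o is not r
        )
    # extended dominance: repeatedly drop frontier entries whose sequential
    # ICER exceeds the next one's
    active = [r for r in rows if not r.dominated]
    changed = True
    while changed:
        changed = False
        for k in range(1, len(active) - 1):
            icer_in = (active[k].cost - active[k - 1].cost) / (active[k].qaly - active[k - 1].qaly)
            icer_out = (active[k + 1].cost - active[k].cost) / (active[k + 1].qaly - active[k].qaly)
            if icer_in > icer_out:
                active[k].extended_dominated = True
                active.pop(k)
                changed = True
                break
    for k, r in enumerate(active):
        if k == 0:
            r.icer_vs_previous = None
        else:
            prev = active[k - 1]
            r.icer_vs_previous = (r.cost - prev.cost) / (r.qaly - prev.qaly)
    return rows


@dataclass
class CeacCurve:
    """Acceptance probability per strategy along a willingness-to-pay grid."""

    wtp_grid: np.ndarray
    prob_accept: dict[str, np.ndarray]
    n_draws: int

    def to_frame(self) -> pd.DataFrame:
        records = []
        for strategy, probs in self.prob_accept.items():
            for wtp, p in zip(self.wtp_grid, probs):
                records.append({"wtp": wtp, "strategy": strategy, "probability": p})
        return pd.DataFrame(records)


def ceac(
    draws: np.ndarray,
    strategies: Sequence[str],
    wtp_grid: Iterable[float],
) -> CeacCurve:
    """Cost-effectiveness acceptability curves from PSA draws.

    ``draws`` has shape (n_draws, n_strategies, 2) with (cost, qaly) pairs.
    At each willingness-to-pay, a strategy is accepted in a draw when it
    attains the maximum net monetary benefit; exact ties go to the cheaper
    strategy (deterministic tie-break).
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 3 or draws.shape[2] != 2:
        raise ValueError("draws must have shape (n_draws, n_strategies, 2)")
    if draws.shape[0] == 0:
        raise ValueError("no draws supplied")
    if draws.shape[1] != len(strategies):
        raise ValueError("strategy list does not match draws")
    wtp_grid = np.asarray(list(wtp_grid), dtype=float)
    cost = draws[:, :, 0]
    qaly = draws[:, :, 1]
    prob = {s: np.zeros(len(wtp_grid)) for s in strategies}
    for w, wtp in enumerate(wtp_grid):
        benefit = qaly * wtp - cost
        best = benefit.max(axis=1, keepdims=True)
        is_best = benefit >= best - 1e-12
        # tie-break toward the cheaper strategy
        tied_cost = np.where(is_best, cost, np.inf)
        winner = np.argmin(tied_cost, axis=1)
        counts = np.bincount(winner, minlength=len(strategies))
        for k, s in enumerate(strategies):
            prob[s][w] = counts[k] / draws.shape[0]
    return CeacCurve(wtp_grid=wtp_grid, prob_accept=prob, n_draws=draws.shape[0])


def evaluate_strategies(
    ps: ParameterSet,
    strategies: Sequence[str],
    horizon_months: int = 60,
    options: MarkovOptions | None = None,
) -> dict[str, CohortResult]:
    """Run the cohort engine for every strategy in the list."""
    return {s: run_strategy(ps, s, horizon_months, options) for s in strategies}


#: scenario grid defaults: horizons (months), price variants, strategy sets
SCENARIO_HORIZONS = (36, 60, 120)
PRICE_VARIANTS = {
    "pooled": {"doacs": "doacs", "lmwhs": "lmwhs"},
    "original": {"doacs": "doacs_original", "lmwhs": "lmwhs_original"},
    "generic": {"doacs": "doacs_generic", "lmwhs": "lmwhs_generic"},
}


def run_scenarios(
    ps: ParameterSet,
    horizons: Sequence[int] = SCENARIO_HORIZONS,
    price_variants: Sequence[str] = ("pooled", "original", "generic"),
    include_subgroups: bool = True,
    options: MarkovOptions | None = None,
) -> pd.DataFrame:
    """Scenario grid over time horizon and drug-price variant.

    Returns one row per (horizon, price variant, strategy) with discounted
    cost and QALYs plus pairwise ICERs against the no-prophylaxis arm and
    against the LMWH arm of the same scenario.
    """
    for variant in price_variants:
        if variant not in PRICE_VARIANTS:
            raise KeyError(f"unknown price variant {variant!r}")
    for h in horizons:
        if h not in SCENARIO_HORIZONS and (not isinstance(h, int) or h <= 0):
            raise KeyError(f"unknown scenario horizon {h!r}")
    records = []
    for h in horizons:
        for variant in price_variants:
            mapping = PRICE_VARIANTS[variant]
            strategies = ["placebo", mapping["doacs"], mapping["lmwhs"]]
            if include_subgroups and variant == "pooled":
                strategies += ["apixaban", "rivaroxaban"]
            results = evaluate_strategies(ps, strategies, h, options)
            placebo = results["placebo"].cost_qaly
            lmwh = results[mapping["lmwhs"]].cost_qaly
            for s in strategies:
                cq = results[s].cost_qaly
                icer_pl = compute_icer(placebo, cq).icer if s != "placebo" else None
                icer_lm = (
                    compute_icer(lmwh, cq).icer if s != mapping["lmwhs"] else None
                )
                records.append(
                    {
                        "horizon_months": h,
                        "price_variant": variant,
                        "strategy": s,
                        "cost": cq[0],
                        "qaly": cq[1],
                        "icer_vs_placebo": icer_pl,
                        "icer_vs_lmwhs": icer_lm,
                    }
                )
    return pd.DataFrame(records)
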