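"""Result tables and figures in the layout of the published analyses.

Monetary values are reported in USD with 3 decimals; internal math is full
precision.  Plot helpers use a non-interactive backend and write files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cea import CeacCurve, compute_icer
from .cohort import CohortResult
from .sensitivity import PsaResult, TornadoEntry

__all__ = [
    "base_case_table",
    "tornado_frame",
    "trace_frame",
    "plot_tornado",
    "plot_ceac",
    "plot_psa_scatter",
]


def base_case_table(
    results: dict[str, CohortResult],
    reference: str = "placebo",
    second_reference: str | None = "lmwhs",
) -> pd.DataFrame:
    """Cost / QALY / pairwise-ICER table, strategies ordered by cost."""
    ordered = sorted(results.values(), key=lambda r: r.total_cost)
    ref = results[reference].cost_qaly if reference in results else None
    ref2 = (
        results[second_reference].cost_qaly
        if second_reference and second_reference in results
        else None
    )
    rows = []
    for r in ordered:
        def _icer(base: tuple[float, float] | None, name: str) -> float | None:
            if base is None or r.strategy == name:
                return None
            return compute_icer(base, r.cost_qaly).icer

        rows.append(
            {
                "strategy": r.strategy,
                "cost": round(r.total_cost, 3),
                "qaly": round(r.total_qaly, 3),
                f"icer_vs_{reference}": _icer(ref, reference),
                **(
                    {f"icer_vs_{second_reference}": _icer(ref2, second_reference)}
                    if second_reference
                    else {}
                ),
            }
        )
    return pd.DataFrame(rows)


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [e.parameter for e in entries],
            "low_value": [e.low_value for e in entries],
            "high_value": [e.high_value for e in entries],
            "low_icer": [e.low_icer for e in entries],
            "high_icer": [e.high_icer for e in entries],
            "swing": [e.swing for e in entries],
        }
    )


def trace_frame(result: CohortResult) -> pd.DataFrame:
    """Tidy per-cycle state-occupancy trace (cycle, state, occupancy)."""
    labels = [s.label for s in result.states]
    n_cycles = result.trace.shape[0]
    return pd.DataFrame(
        {
            "cycle": np.repeat(np.arange(n_cycles), len(labels)),
            "state": np.tile(labels, n_cycles),
            "occupancy": result.trace.ravel(),
        }
    )


def _mpl():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_tornado(
    entries: Sequence[TornadoEntry],
    base_icer: float,
    path: str | Path,
    top: int = 12,
) -> None:
    plt = _mpl()
    shown = [e for e in entries if np.isfinite(e.swing)][:top][::-1]
    fig, ax = plt.subplots(figsize=(7, 0.45 * len(shown) + 1.2))
    for y, e in enumerate(shown):
        lo, hi = sorted((e.low_icer, e.high_icer))
        ax.barh(y, hi - lo, left=lo, color="#4878b0", height=0.6)
    ax.axvline(base_icer, color="k", lw=1, ls="--", label="base-case ICER")
    ax.set_yticks(range(len(shown)), [e.parameter for e in shown], fontsize=8)
    ax.set_xlabel("ICER ($/QALY)")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ceac(curve: CeacCurve, path: str | Path, wtp_line: float | None = None) -> None:
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for strategy, probs in curve.prob_accept.items():
        ax.plot(curve.wtp_grid, probs, label=strategy)
    if wtp_line is not None:
        ax.axvline(wtp_line, color="k", lw=1, ls="--")
    ax.set_xlabel("willingness to pay ($/QALY)")
    ax.set_ylabel("probability cost-effective")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_psa_scatter(
    psa: PsaResult,
    pair: tuple[str, str],
    path: str | Path,
    wtp: float | None = None,
) -> None:
    """Incremental cost vs incremental QALY cloud for one strategy pair."""
    plt = _mpl()
    i = psa.strategies.index(pair[0])
    j = psa.strategies.index(pair[1])
    dq = psa.draws[:, j, 1] - psa.draws[:, i, 1]
    dc = psa.draws[:, j, 0] - psa.draws[:, i, 0]
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(dq, dc, s=4, alpha=0.3, color="#4878b0")
    ax.axhline(0, color="k", lw=0.8)
    ax.axvline(0, color="k", lw=0.8)
    if wtp is not None:
        xs = np.linspace(*ax.get_xlim(), 10)
        ax.plot(xs, wtp * xs, "k--", lw=1, label=f"WTP {wtp:,.0f} $/QALY")
        ax.legend(fontsize=8)
    ax.set_xlabel(f"incremental QALYs ({pair[1]} vs {pair[0]})")
    ax.set_ylabel("incremental cost ($)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
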