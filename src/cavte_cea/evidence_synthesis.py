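"""Random-effects pooling of trial event rates and relative-risk application.

The no-prophylaxis event rates entering the decision model are pooled
across randomized trials with a DerSimonian–Laird random-effects model on
the logit scale (the conventional choice for proportions): per-study logits
are weighted by inverse variance inflated with the method-of-moments
between-study variance tau², and the pooled logit and its 95% interval are
back-transformed to the proportion scale.  Comparator-arm rates are derived
by multiplying the pooled baseline by a relative risk.

This module is a verification path: the packaged base-case parameter table
already holds pooled values, and this stage regenerates such values from
arm-level counts when users supply them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "TrialArm",
    "PooledRate",
    "RelativeRisk",
    "pool_proportions",
    "apply_rr",
    "read_arm_counts",
    "pool_table",
]


@dataclass(frozen=True)
class TrialArm:
    """Event count out of total for one study arm."""

    study_id: str
    events: int
    total: int

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise ValueError(f"{self.study_id}: total must be positive")
        if not 0 <= self.events <= self.total:
            raise ValueError(f"{self.study_id}: events must lie in [0, total]")


@dataclass(frozen=True)
class PooledRate:
    """Pooled proportion with 95% interval and heterogeneity on logit scale."""

    estimate: float
    ci_low: float
    ci_high: float
    tau2: float
    k: int

    def __post_init__(self) -> None:
        if not self.ci_low <= self.estimate <= self.ci_high:
            raise ValueError("interval must bracket the estimate")
        if self.tau2 < 0:
            raise ValueError("tau2 must be non-negative")


@dataclass(frozen=True)
class RelativeRisk:
    rr: float
    ci_low: float | None = None
    ci_high: float | None = None

    def __post_init__(self) -> None:
        if self.rr < 0:
            raise ValueError("relative risk must be non-negative")
        if self.ci_low is not None and self.ci_high is not None:
            if not self.ci_low <= self.rr <= self.ci_high:
                raise ValueError("interval must bracket the point estimate")


def pool_proportions(
    arms: list[TrialArm],
    continuity: float = 0.5,
    alpha: float = 0.05,
) -> PooledRate:
    """DerSimonian–Laird random-effects pooling of proportions.

    Arms with zero or all events receive a ``continuity`` correction added
    to both cells.  tau² is the DL moment estimator truncated at zero.
    """
    if not arms:
        raise ValueError("no trial arms supplied")
    events = np.array([a.events for a in arms], dtype=float)
    totals = np.array([a.total for a in arms], dtype=float)
    boundary = (events == 0) | (events == totals)
    events = events + continuity * boundary
    totals = totals + 2 * continuity * boundary

    y = logit(events / totals)
    v = 1.0 / events + 1.0 / (totals - events)

    w = 1.0 / v
    y_fe = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - y_fe) ** 2))
    k = len(arms)
    if k > 1:
        denom = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (q - (k - 1)) / denom)
    else:
        tau2 = 0.0

    w_re = 1.0 / (v + tau2)
    y_re = float(np.sum(w_re * y) / np.sum(w_re))
    se_re = float(np.sqrt(1.0 / np.sum(w_re)))
    from scipy.stats import norm

    z = norm.ppf(1.0 - alpha / 2.0)
    return PooledRate(
        estimate=float(expit(y_re)),
        ci_low=float(expit(y_re - z * se_re)),
        ci_high=float(expit(y_re + z * se_re)),
        tau2=float(tau2),
        k=k,
    )


def apply_rr(baseline: float, rr: RelativeRisk | float) -> float:
    """Comparator event rate: baseline proportion times relative risk.

    The product is capped at 1 (a probability).
    """
    if not 0.0 <= baseline <= 1.0:
        raise ValueError(f"baseline {baseline} outside [0, 1]")
    ratio = rr.rr if isinstance(rr, RelativeRisk) else float(rr)
    if ratio < 0:
        raise ValueError("relative risk must be non-negative")
    return min(1.0, baseline * ratio)


def read_arm_counts(path: str | Path) -> dict[tuple[str, str], list[TrialArm]]:
    """Read arm-level counts from CSV with columns
    study_id, strategy, outcome, events, total; grouped by (strategy, outcome)."""
    df = pd.read_csv(path)
    required = {"study_id", "strategy", "outcome", "events", "total"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"arm-count CSV missing columns {sorted(missing)}")
    groups: dict[tuple[str, str], list[TrialArm]] = {}
    for row in df.itertuples(index=False):
        key = (str(row.strategy), str(row.outcome))
        groups.setdefault(key, []).append(
            TrialArm(str(row.study_id), int(row.events), int(row.total))
        )
    return groups


def pool_table(groups: dict[tuple[str, str], list[TrialArm]]) -> pd.DataFrame:
    """Pool every (strategy, outcome) group into one tidy table."""
    records = []
    for (strategy, outcome), arms in sorted(groups.items()):
        pooled = pool_proportions(arms)
        records.append(
            {
                "strategy": strategy,
                "outcome": outcome,
                "k": pooled.k,
                "estimate": pooled.estimate,
                "ci_low": pooled.ci_low,
                "ci_high": pooled.ci_high,
                "tau2": pooled.tau2,
            }
        )
    return pd.DataFrame(records)
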