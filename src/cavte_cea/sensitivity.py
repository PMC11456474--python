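"""Deterministic and probabilistic sensitivity analysis.

One-way analysis re-runs the deterministic pipeline at the low and high
bound of each parameter (95% bounds when printed, otherwise ±20% for costs
and ±10% for probabilities) and ranks parameters by the swing of the ICER
between a strategy pair (tornado ordering).  A bisection threshold search
finds the parameter value at which the ICER crosses the willingness-to-pay
threshold.

Probabilistic analysis draws every uncertain parameter from its
distribution — beta (method of moments from mean and SD) for clinical
probabilities, proportions, utilities and disutilities; log-normal
(printed value as median, SD column as log-scale sigma) for costs — and
re-evaluates cost and QALYs per strategy per draw.  Draws are independent
across parameters; the run is seeded and bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cea import compute_icer
from .cohort import PayoffSpec, run_cohort
from .markov import MarkovOptions, TransitionModel
from .parameters import Parameter, ParameterSet, dsa_range

__all__ = [
    "TornadoEntry",
    "PsaResult",
    "beta_from_moments",
    "lognormal_from_log_scale",
    "LogNormalSpec",
    "one_way_dsa",
    "tornado",
    "threshold_search",
    "run_psa",
    "sample_parameter_set",
    "dsa_parameter_ids",
]


def beta_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Beta shape parameters matching a given mean and standard deviation."""
    if not 0.0 < mean < 1.0:
        raise ValueError(f"mean {mean} must lie strictly inside (0, 1)")
    if sd <= 0.0:
        raise ValueError("sd must be positive")
    if sd * sd >= mean * (1.0 - mean):
        raise ValueError(
            f"sd {sd} too large for mean {mean}: no beta distribution exists"
        )
    k = mean * (1.0 - mean) / (sd * sd) - 1.0
    return (mean * k, (1.0 - mean) * k)


@dataclass(frozen=True)
class LogNormalSpec:
    """Log-normal distribution given by its natural-scale median and log-sd."""

    median: float
    sigma: float

    @property
    def mu(self) -> float:
        return math.log(self.median)

    def interval95(self) -> tuple[float, float]:
        half = 1.959963984540054 * self.sigma
        return (self.median * math.exp(-half), self.median * math.exp(half))

    def sample(self, rng: np.random.Generator, size: int | None = None):
        return self.median * np.exp(self.sigma * rng.standard_normal(size))


def lognormal_from_log_scale(median: float, sigma: float) -> LogNormalSpec:
    """Log-normal cost distribution from the printed value and log-scale SD."""
    if median <= 0 or sigma <= 0:
        raise ValueError("median and sigma must be positive")
    return LogNormalSpec(median=median, sigma=sigma)


# ---------------------------------------------------------------------------
# parameter identification: "name" (shared) or "strategy:name" (override)
# ---------------------------------------------------------------------------

def _split_id(param_id: str) -> tuple[str | None, str]:
    if ":" in param_id:
        strategy, name = param_id.split(":", 1)
        return strategy, name
    return None, param_id


def dsa_parameter_ids(ps: ParameterSet, strategies: list[str]) -> list[str]:
    """Every parameter id with a resolvable one-way range that can touch the
    given strategies: shared entries plus the strategies' override chains."""
    ids: list[str] = []
    for name, p in ps.entries.items():
        if p.dist == "fixed" and not p.has_bounds:
            continue  # analysis constants carry no uncertainty
        ids.append(name)
    for strategy in strategies:
        seen: set[str] = set()
        chain: str | None = strategy
        while chain is not None:
            for name, p in ps.strategy_overrides[chain].items():
                if name in seen:
                    continue
                seen.add(name)
                if p.dist == "fixed" and not p.has_bounds:
                    continue
                ids.append(f"{strategy}:{name}")
            chain = ps.strategy_parents.get(chain)
    return ids


@dataclass(frozen=True)
class TornadoEntry:
    """One-way sensitivity result for a single parameter."""

    parameter: str
    low_value: float
    high_value: float
    low_icer: float | None
    high_icer: float | None

    @property
    def swing(self) -> float:
        if self.low_icer is None or self.high_icer is None:
            return math.inf
        return abs(self.high_icer - self.low_icer)


def _pair_icer(
    ps: ParameterSet,
    comparison: tuple[str, str],
    horizon_months: int,
    options: MarkovOptions | None = None,
) -> float | None:
    from .cohort import run_strategy

    ref, comp = comparison
    r_ref = run_strategy(ps, ref, horizon_months, options)
    r_comp = run_strategy(ps, comp, horizon_months, options)
    return compute_icer(r_ref.cost_qaly, r_comp.cost_qaly, ref, comp).icer


def one_way_dsa(
    ps: ParameterSet,
    param_id: str,
    comparison: tuple[str, str],
    horizon_months: int = 60,
    options: MarkovOptions | None = None,
) -> TornadoEntry:
    """Re-run the deterministic pipeline at both bounds of one parameter."""
    strategy, name = _split_id(param_id)
    p = ps.resolve(name, strategy)
    low, high = dsa_range(p)
    icers = []
    for value in (low, high):
        modified = ps.replace_parameter(name, value, strategy)
        icers.append(_pair_icer(modified, comparison, horizon_months, options))
    return TornadoEntry(
        parameter=param_id,
        low_value=low,
        high_value=high,
        low_icer=icers[0],
        high_icer=icers[1],
    )


def tornado(
    ps: ParameterSet,
    comparison: tuple[str, str],
    horizon_months: int = 60,
    param_ids: list[str] | None = None,
    options: MarkovOptions | None = None,
) -> list[TornadoEntry]:
    """One-way analysis over all (or the given) parameters, sorted by swing."""
    if param_ids is None:
        param_ids = dsa_parameter_ids(ps, list(comparison))
    entries = [
        one_way_dsa(ps, pid, comparison, horizon_months, options)
        for pid in param_ids
    ]
    entries.sort(key=lambda e: (-e.swing if math.isfinite(e.swing) else 0.0, e.parameter))
    return entries


def threshold_search(
    ps: ParameterSet,
    param_id: str,
    comparison: tuple[str, str],
    wtp: float,
    bracket: tuple[float, float],
    horizon_months: int = 60,
    icer_tol: float = 0.01,
    x_tol: float = 1e-6,
    options: MarkovOptions | None = None,
) -> float:
    """Bisect for the parameter value where the pairwise ICER equals WTP.

    Requires ``ICER - WTP`` to change sign over the bracket; stops when the
    ICER is within ``icer_tol`` of WTP or the bracket is narrower than
    ``x_tol``.
    """
    strategy, name = _split_id(param_id)

    def f(value: float) -> float:
        modified = ps.replace_parameter(name, value, strategy)
        icer = _pair_icer(modified, comparison, horizon_months, options)
        if icer is None:
            raise ValueError(f"ICER undefined at {param_id}={value}")
        return icer - wtp

    lo, hi = bracket
    f_lo, f_hi = f(lo), f(hi)
    if f_lo == 0.0:
        return lo
    if f_hi == 0.0:
        return hi
    if f_lo * f_hi > 0:
        raise ValueError(
            f"no sign change over bracket {bracket}: "
            f"ICER-WTP = {f_lo:.3f} at {lo}, {f_hi:.3f} at {hi}"
        )
    while True:
        mid = 0.5 * (lo + hi)
        f_mid = f(mid)
        if abs(f_mid) < icer_tol or (hi - lo) < x_tol:
            return mid
        if f_lo * f_mid <= 0:
            hi, f_hi = mid, f_mid
        else:
            lo, f_lo = mid, f_mid


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

def _sample_parameter(p: Parameter, rng: np.random.Generator, scale: float) -> float:
    if p.dist == "fixed" or p.sd == 0.0 or scale == 0.0:
        return p.mean
    if p.dist == "beta":
        a, b = beta_from_moments(p.mean, p.sd * scale)
        return float(rng.beta(a, b))
    if p.dist == "lognormal":
        return float(p.mean * math.exp(p.sd * scale * rng.standard_normal()))
    raise AssertionError(p.dist)


def sample_parameter_set(
    ps: ParameterSet,
    rng: np.random.Generator,
    scale: float = 1.0,
) -> ParameterSet:
    """One Monte Carlo draw of the full parameter set.

    Parameters are sampled independently in the deterministic order they
    are stored; ``scale`` multiplies every SD (0 returns the base set
    unchanged).
    """
    if scale < 0:
        raise ValueError("scale must be non-negative")
    if scale == 0.0:
        return ParameterSet(
            entries=dict(ps.entries),
            strategy_overrides={k: dict(v) for k, v in ps.strategy_overrides.items()},
            strategy_parents=dict(ps.strategy_parents),
            meta=dict(ps.meta),
        )
    entries = {
        name: p if p.dist == "fixed" or p.sd == 0.0 else p.with_mean(_sample_parameter(p, rng, scale))
        for name, p in ps.entries.items()
    }
    overrides = {
        strat: {
            name: p if p.dist == "fixed" or p.sd == 0.0 else p.with_mean(_sample_parameter(p, rng, scale))
            for name, p in block.items()
        }
        for strat, block in ps.strategy_overrides.items()
    }
    return ParameterSet(
        entries=entries,
        strategy_overrides=overrides,
        strategy_parents=dict(ps.strategy_parents),
        meta=dict(ps.meta),
    )


@dataclass
class PsaResult:
    """Draw-level (cost, QALY) pairs per strategy plus run provenance."""

    strategies: list[str]
    draws: np.ndarray            # (n_draws, n_strategies, 2)
    seed: int
    horizon_months: int
    clamped_draws: int = 0
    parameter_samples: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "strategy": self.strategies,
                "mean_cost": self.draws[:, :, 0].mean(axis=0),
                "mean_qaly": self.draws[:, :, 1].mean(axis=0),
            }
        )

    def to_frame(self) -> pd.DataFrame:
        n, s, _ = self.draws.shape
        return pd.DataFrame(
            {
                "draw": np.repeat(np.arange(n), s),
                "strategy": np.tile(self.strategies, n),
                "cost": self.draws[:, :, 0].ravel(),
                "qaly": self.draws[:, :, 1].ravel(),
            }
        )


def run_psa(
    ps: ParameterSet,
    n: int,
    seed: int | None,
    horizon_months: int = 60,
    strategies: list[str] | None = None,
    scale: float = 1.0,
    record_samples: bool = False,
) -> PsaResult:
    """Seeded Monte Carlo over all uncertain parameters.

    Every draw resamples the full parameter set, rebuilds the per-strategy
    transition models (branch-mass overflows are rescaled and counted, not
    silently accepted), and accrues discounted cost and QALYs.  An unseeded
    run is rejected: reproducibility is part of the contract.
    """
    if seed is None:
        raise ValueError("run_psa requires an explicit seed")
    if n < 1:
        raise ValueError("n must be at least 1")
    if strategies is None:
        strategies = ["placebo", "doacs", "lmwhs"]
    rng = np.random.default_rng(seed)
    options = MarkovOptions(on_overflow="rescale")
    draws = np.empty((n, len(strategies), 2))
    clamped = 0
    samples: dict[str, list[float]] = {} if record_samples else None  # type: ignore[assignment]
    for i in range(n):
        sampled = sample_parameter_set(ps, rng, scale)
        if record_samples:
            for name, p in sampled.entries.items():
                samples.setdefault(name, []).append(p.mean)
            for strat, block in sampled.strategy_overrides.items():
                for name, p in block.items():
                    samples.setdefault(f"{strat}:{name}", []).append(p.mean)
        discount = sampled.value("discount_rate_annual")
        for k, strategy in enumerate(strategies):
            model = TransitionModel.from_parameters(sampled, strategy, options)
            payoffs = PayoffSpec.from_parameters(sampled, strategy, model.states)
            result = run_cohort(model, payoffs, horizon_months, discount=discount)
            clamped += model.overflow_count > 0
            draws[i, k, 0] = result.total_cost
            draws[i, k, 1] = result.total_qaly
    return PsaResult(
        strategies=list(strategies),
        draws=draws,
        seed=seed,
        horizon_months=horizon_months,
        clamped_draws=clamped,
        parameter_samples=pd.DataFrame(samples) if record_samples else None,
    )
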