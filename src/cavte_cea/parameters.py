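"""Model inputs: validated parameters with provenance and uncertainty.

Every model input (event probabilities, branching proportions, utilities,
disutilities, costs, and analysis constants) is a :class:`Parameter` with a
point estimate, optional 95% bounds, a standard deviation, and a sampling
distribution family.  A :class:`ParameterSet` holds the shared entries plus
per-strategy overrides (the five prophylaxis strategies and their price
variants), with single-inheritance fallback between strategies.

The distribution conventions follow standard health-economic practice: beta
distributions for probabilities, proportions, utilities and disutilities;
log-normal distributions for costs, parameterized by the natural-scale median
(the ``mean`` field) and the log-scale standard deviation (the ``sd`` field).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping

import pandas as pd
import yaml

__all__ = [
    "Parameter",
    "ParameterSet",
    "ParameterSchemaError",
    "ParameterDomainError",
    "load_parameters",
    "dsa_range",
]

GROUPS = ("probability", "proportion", "utility", "disutility", "cost", "rate_ratio", "fixed")
DISTRIBUTIONS = ("beta", "lognormal", "fixed")

#: groups whose point estimate must lie in the unit interval
_UNIT_GROUPS = frozenset({"probability", "proportion", "utility", "disutility"})
#: distribution family each group may carry (``fixed`` is always allowed)
_GROUP_DIST = {
    "probability": "beta",
    "proportion": "beta",
    "utility": "beta",
    "disutility": "beta",
    "rate_ratio": "beta",
    "cost": "lognormal",
}


class ParameterSchemaError(ValueError):
    """A config entry is structurally invalid (missing/unknown fields)."""


class ParameterDomainError(ValueError):
    """A parameter value violates its domain invariants."""


@dataclass(frozen=True)
class Parameter:
    """One model input with provenance-grade metadata.

    Attributes
    ----------
    name : str
        Stable snake_case identifier.
    group : str
        Semantic group, one of :data:`GROUPS`.
    mean : float
        Point estimate.  For log-normal costs this is the natural-scale
        median of the sampling distribution.
    low, high : float or None
        95% uncertainty bounds when available.
    sd : float
        Standard deviation (log-scale for log-normal costs); 0 for fixed
        parameters.
    dist : str
        Sampling distribution family, one of :data:`DISTRIBUTIONS`.
    period : str or None
        Human-readable time window the value describes (e.g. ``"1 year"``).
    period_months : float or None
        The same window in months, used for per-cycle conversion; ``None``
        for one-time quantities and proportions.
    """

    name: str
    group: str
    mean: float
    low: float | None = None
    high: float | None = None
    sd: float = 0.0
    dist: str = "fixed"
    period: str | None = None
    period_months: float | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.group not in GROUPS:
            raise ParameterSchemaError(f"{self.name}: unknown group {self.group!r}")
        if self.dist not in DISTRIBUTIONS:
            raise ParameterSchemaError(f"{self.name}: unknown distribution {self.dist!r}")
        if self.dist != "fixed":
            expected = _GROUP_DIST.get(self.group)
            if expected is not None and self.dist != expected:
                raise ParameterDomainError(
                    f"{self.name}: group {self.group!r} requires {expected!r} "
                    f"distribution, got {self.dist!r}"
                )
        if self.group in _UNIT_GROUPS and not 0.0 <= self.mean <= 1.0:
            raise ParameterDomainError(
                f"{self.name}: {self.group} mean {self.mean} outside [0, 1]"
            )
        if self.group == "cost" and self.mean < 0:
            raise ParameterDomainError(f"{self.name}: negative cost {self.mean}")
        if self.group == "rate_ratio" and self.mean <= 0:
            raise ParameterDomainError(f"{self.name}: rate ratio must be positive")
        if self.sd < 0:
            raise ParameterDomainError(f"{self.name}: negative sd {self.sd}")
        if self.low is not None and self.high is not None:
            if not self.low <= self.mean <= self.high:
                raise ParameterDomainError(
                    f"{self.name}: bounds ({self.low}, {self.high}) do not bracket "
                    f"mean {self.mean}"
                )
        if self.period_months is not None and self.period_months <= 0:
            raise ParameterDomainError(f"{self.name}: period_months must be positive")

    @property
    def has_bounds(self) -> bool:
        return self.low is not None and self.high is not None

    def with_mean(self, mean: float) -> "Parameter":
        """Copy with a replaced point estimate (bounds dropped, sd kept)."""
        return replace(self, mean=float(mean), low=None, high=None)

    def to_dict(self) -> dict:
        out: dict = {"group": self.group, "mean": self.mean, "dist": self.dist}
        if self.low is not None:
            out["low"] = self.low
        if self.high is not None:
            out["high"] = self.high
        if self.sd:
            out["sd"] = self.sd
        if self.period is not None:
            out["period"] = self.period
        if self.period_months is not None:
            out["period_months"] = self.period_months
        return out

    @classmethod
    def from_dict(cls, name: str, raw: Mapping) -> "Parameter":
        if not isinstance(raw, Mapping):
            raise ParameterSchemaError(f"{name}: entry must be a mapping")
        unknown = set(raw) - {"group", "mean", "low", "high", "sd", "dist", "period", "period_months"}
        if unknown:
            raise ParameterSchemaError(f"{name}: unknown fields {sorted(unknown)}")
        for required in ("mean", "dist"):
            if required not in raw:
                raise ParameterSchemaError(f"{name}: missing required field {required!r}")
        if "group" not in raw:
            raise ParameterSchemaError(f"{name}: missing required field 'group'")
        return cls(
            name=name,
            group=str(raw["group"]),
            mean=float(raw["mean"]),
            low=None if raw.get("low") is None else float(raw["low"]),
            high=None if raw.get("high") is None else float(raw["high"]),
            sd=float(raw.get("sd", 0.0)),
            dist=str(raw["dist"]),
            period=raw.get("period"),
            period_months=None if raw.get("period_months") is None else float(raw["period_months"]),
        )


@dataclass
class ParameterSet:
    """Shared entries plus per-strategy overrides with parent fallback."""

    entries: dict[str, Parameter]
    strategy_overrides: dict[str, dict[str, Parameter]] = field(default_factory=dict)
    strategy_parents: dict[str, str | None] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def strategies(self) -> list[str]:
        return list(self.strategy_overrides)

    def resolve(self, name: str, strategy: str | None = None) -> Parameter:
        """Look up ``name``, walking strategy → parent chain → shared entries."""
        seen: set[str] = set()
        while strategy is not None:
            if strategy in seen:
                raise ParameterSchemaError(f"strategy parent cycle at {strategy!r}")
            seen.add(strategy)
            if strategy not in self.strategy_overrides:
                raise KeyError(f"unknown strategy {strategy!r}")
            override = self.strategy_overrides[strategy].get(name)
            if override is not None:
                return override
            strategy = self.strategy_parents.get(strategy)
        if name in self.entries:
            return self.entries[name]
        raise KeyError(f"unknown parameter {name!r}")

    def value(self, name: str, strategy: str | None = None) -> float:
        return self.resolve(name, strategy).mean

    def iter_parameters(self) -> Iterator[tuple[str | None, Parameter]]:
        """Yield ``(strategy_or_None, parameter)`` over every stored entry."""
        for p in self.entries.values():
            yield None, p
        for strat, overrides in self.strategy_overrides.items():
            for p in overrides.values():
                yield strat, p

    def replace_parameter(
        self, name: str, mean: float, strategy: str | None = None
    ) -> "ParameterSet":
        """Non-destructive copy with one point estimate replaced.

        When ``strategy`` is given the replacement is written into that
        strategy's override table (materializing an inherited entry if
        needed), so sibling strategies are untouched.
        """
        new = ParameterSet(
            entries=dict(self.entries),
            strategy_overrides={k: dict(v) for k, v in self.strategy_overrides.items()},
            strategy_parents=dict(self.strategy_parents),
            meta=dict(self.meta),
        )
        base = self.resolve(name, strategy)
        if strategy is None:
            new.entries[name] = base.with_mean(mean)
        else:
            new.strategy_overrides[strategy][name] = base.with_mean(mean)
        return new

    # ---- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "meta": dict(self.meta),
            "shared": {n: p.to_dict() for n, p in sorted(self.entries.items())},
            "strategies": {
                strat: {
                    "parent": self.strategy_parents.get(strat),
                    "overrides": {n: p.to_dict() for n, p in sorted(ov.items())},
                }
                for strat, ov in self.strategy_overrides.items()
            },
        }

    @classmethod
    def from_dict(cls, raw: Mapping) -> "ParameterSet":
        if "shared" not in raw:
            raise ParameterSchemaError("config missing top-level 'shared' section")
        entries = {
            name: Parameter.from_dict(name, spec)
            for name, spec in raw["shared"].items()
        }
        overrides: dict[str, dict[str, Parameter]] = {}
        parents: dict[str, str | None] = {}
        for strat, block in (raw.get("strategies") or {}).items():
            parents[strat] = block.get("parent")
            overrides[strat] = {
                name: Parameter.from_dict(f"{strat}:{name}", spec)
                for name, spec in (block.get("overrides") or {}).items()
            }
        for strat, parent in parents.items():
            if parent is not None and parent not in overrides:
                raise ParameterSchemaError(
                    f"strategy {strat!r} names unknown parent {parent!r}"
                )
        return cls(
            entries=entries,
            strategy_overrides=overrides,
            strategy_parents=parents,
            meta=dict(raw.get("meta") or {}),
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        doc = self.to_dict()
        if path.suffix == ".json":
            path.write_text(json.dumps(doc, indent=2))
        else:
            path.write_text(yaml.safe_dump(doc, sort_keys=False))

    def resolved_table(self, strategy: str) -> pd.DataFrame:
        """Fully resolved parameter table for one strategy (CSV-exportable)."""
        names = set(self.entries)
        strat: str | None = strategy
        while strat is not None:
            names |= set(self.strategy_overrides.get(strat, {}))
            strat = self.strategy_parents.get(strat)
        rows = []
        for name in sorted(names):
            p = self.resolve(name, strategy)
            rows.append(
                {
                    "name": name,
                    "strategy": strategy,
                    "group": p.group,
                    "mean": p.mean,
                    "low": p.low,
                    "high": p.high,
                    "sd": p.sd,
                    "dist": p.dist,
                    "period": p.period,
                }
            )
        return pd.DataFrame(rows)


def load_parameters(path: str | Path) -> ParameterSet:
    """Load and validate a parameter config (YAML or JSON)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise ParameterSchemaError(f"{path}: config must be a mapping")
    return ParameterSet.from_dict(raw)


def dsa_range(p: Parameter) -> tuple[float, float]:
    """Deterministic-sensitivity range for one parameter.

    The printed 95% bounds are used when present.  Otherwise costs vary by
    ±20% of the mean and probabilities/proportions by ±10% (clamped to the
    unit interval).  Utilities and disutilities without explicit bounds are
    rejected so a range must be stated in the config.
    """
    if p.has_bounds:
        return (float(p.low), float(p.high))  # type: ignore[arg-type]
    if p.group == "cost":
        return (p.mean * 0.8, p.mean * 1.2)
    if p.group in ("probability", "proportion"):
        return (max(0.0, p.mean * 0.9), min(1.0, p.mean * 1.1))
    raise ParameterDomainError(
        f"{p.name}: no bounds given and no default variation rule for "
        f"group {p.group!r}; state a range explicitly"
    )
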