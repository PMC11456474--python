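"""Packaged base-case parameters and synthetic test inputs.

The base-case parameter table ships as a data file inside the package so
it can be diffed line-by-line against its sources.  Synthetic generators
emulate the evidence base (per-study binomial event counts under a known
baseline rate, relative risk, and logit-normal between-study heterogeneity)
and produce stochastically perturbed parameter sets for stress-testing the
engine's invariants.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .evidence_synthesis import TrialArm
from .parameters import ParameterSet, load_parameters
from .sensitivity import sample_parameter_set

__all__ = [
    "base_case_parameters",
    "SyntheticTrialSpec",
    "generate_trial_arms",
    "perturb_parameters",
]


def base_case_parameters() -> ParameterSet:
    """The packaged, validated base-case parameter set."""
    with resources.as_file(
        resources.files("cavte_cea") / "data" / "parameters.yaml"
    ) as path:
        return load_parameters(path)


@dataclass(frozen=True)
class SyntheticTrialSpec:
    """Generator settings for a synthetic two-arm trial programme.

    Baseline (control) event probabilities vary between studies on the
    logit scale with variance ``tau2``; the treated arm applies ``true_rr``
    to each study's realized baseline.
    """

    true_baseline_rate: float
    true_rr: float
    k_studies: int
    arm_sizes: list[int] | int
    tau2: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.true_baseline_rate < 1.0:
            raise ValueError("baseline rate must lie in (0, 1)")
        if self.true_rr <= 0:
            raise ValueError("relative risk must be positive")
        if self.k_studies < 1:
            raise ValueError("need at least one study")
        if self.tau2 < 0:
            raise ValueError("tau2 must be non-negative")
        sizes = self.sizes()
        if len(sizes) != self.k_studies or any(n < 10 for n in sizes):
            raise ValueError("arm sizes must list one entry >= 10 per study")

    def sizes(self) -> list[int]:
        if isinstance(self.arm_sizes, int):
            return [self.arm_sizes] * self.k_studies
        return list(self.arm_sizes)


def generate_trial_arms(
    spec: SyntheticTrialSpec,
) -> list[tuple[TrialArm, TrialArm]]:
    """Simulate (control, treated) arm pairs; reproducible under the seed.

    Treated-arm probabilities ``p_i * rr`` above 1 are clamped (and can only
    arise from extreme heterogeneity draws).
    """
    rng = np.random.default_rng(spec.seed)
    logit0 = np.log(spec.true_baseline_rate / (1.0 - spec.true_baseline_rate))
    pairs = []
    for i, n in enumerate(spec.sizes()):
        shift = rng.normal(0.0, np.sqrt(spec.tau2)) if spec.tau2 > 0 else 0.0
        p_control = 1.0 / (1.0 + np.exp(-(logit0 + shift)))
        p_treated = min(1.0, p_control * spec.true_rr)
        pairs.append(
            (
                TrialArm(f"study_{i + 1}", int(rng.binomial(n, p_control)), n),
                TrialArm(f"study_{i + 1}", int(rng.binomial(n, p_treated)), n),
            )
        )
    return pairs


def perturb_parameters(
    base: ParameterSet, scale: float, seed: int
) -> ParameterSet:
    """One stochastic perturbation of the base set (scale 0 returns it)."""
    rng = np.random.default_rng(seed)
    return sample_parameter_set(base, rng, scale=scale)
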