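"""Simulated 2AFC observers with logistic psychometric sensitivity.

An observer judges which of two snakes has the larger wiggle amplitude. The
probability of a correct judgement depends only on the unsigned amplitude
difference ``delta = |target - foil|`` through

    p_correct(delta) = guess + (1 - guess - lapse) / (1 + exp(-slope * (delta - threshold)))

with guess fixed at 0.5 (2AFC chance), a small lapse rate bounding the upper
asymptote at ``1 - lapse``, and a per-condition true threshold at which
performance is 75% correct (lapse aside). The shared pedestal offset added to
both snakes cancels in ``delta``, so the statistical observer is
pedestal-invariant by default; a pedestal-sensitive variant (thresholds
scaling with the pedestal level) can be enabled for robustness experiments.

A cohort draws per-observer condition thresholds as a shared observer offset
plus independent condition noise around configurable per-condition means,
which yields the positively correlated within-observer thresholds that the
paired group analysis relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ObserverModel", "CohortSpec", "generate_cohort", "respond"]


@dataclass
class ObserverModel:
    """One simulated observer: per-condition thresholds plus slope and lapse."""

    thresholds: dict  # condition label -> true threshold delta* (> 0)
    slope: float = 25.0
    lapse: float = 0.02
    guess: float = 0.5
    seed: int | None = None
    pedestal_sensitive: bool = False
    _rng: np.random.Generator = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not (0 <= self.lapse <= 0.06):
            raise ValueError("lapse must lie in [0, 0.06]")
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if any(t <= 0 for t in self.thresholds.values()):
            raise ValueError("thresholds must be positive")
        if self._rng is None:
            self._rng = np.random.default_rng(self.seed)

    def p_correct(self, delta: float, condition: str, pedestal: float = 0.0) -> float:
        """Probability of choosing the larger-amplitude side at difference ``delta``."""
        if delta < 0:
            raise ValueError("delta must be non-negative")
        if delta == 0:
            return 0.5
        thr = self.thresholds[condition]
        if self.pedestal_sensitive:
            # Weber-like: discriminability set by delta relative to the pedestal level
            thr = thr * (1.0 + pedestal)
        return self.guess + (1.0 - self.guess - self.lapse) / (
            1.0 + np.exp(-self.slope * (delta - thr))
        )


def respond(
    obs: ObserverModel,
    target_amp: float,
    foil_amp: float,
    condition: str,
    rng: np.random.Generator | None = None,
    pedestal: float = 0.0,
) -> tuple[str, bool]:
    """Simulate one trial; returns ``(choice, correct)``.

    ``choice`` is ``"target"`` or ``"foil"``; ``correct`` means the
    larger-amplitude stimulus was chosen. At zero difference the choice is a
    fair coin and "correctness" is 50% by convention.
    """
    if target_amp <= 0 or foil_amp <= 0:
        raise ValueError("amplitudes must be positive")
    rng = obs._rng if rng is None else rng
    delta = abs(target_amp - foil_amp)
    p = obs.p_correct(delta, condition, pedestal)
    picked_larger = rng.random() < p
    larger = "target" if target_amp >= foil_amp else "foil"
    choice = larger if picked_larger else ("foil" if larger == "target" else "target")
    return choice, picked_larger


@dataclass(frozen=True)
class CohortSpec:
    """Distributional description of a simulated participant cohort.

    ``mean_thresholds`` maps condition labels to the cohort-mean true
    threshold; each observer's thresholds are those means plus a shared
    observer offset (s.d. ``observer_sd``) plus independent condition noise
    (s.d. ``condition_sd``), truncated at ``min_threshold``.
    """

    n_observers: int = 26
    mean_thresholds: dict = field(
        default_factory=lambda: {
            "uniform:leaf": 0.10,
            "flat_disruptive:leaf": 0.14,
            "edge_enhanced_disruptive:leaf": 0.20,
            "uniform:grey": 0.09,
            "flat_disruptive:grey": 0.11,
            "edge_enhanced_disruptive:grey": 0.16,
        }
    )
    observer_sd: float = 0.03
    condition_sd: float = 0.02
    slope_mean: float = 25.0
    slope_sd: float = 5.0
    lapse: float = 0.02
    min_threshold: float = 0.02

    def __post_init__(self) -> None:
        if self.n_observers < 2:
            raise ValueError("n_observers must be >= 2")
        if min(self.observer_sd, self.condition_sd, self.slope_sd) < 0:
            raise ValueError("standard deviations must be non-negative")


def generate_cohort(
    spec: CohortSpec, seed: int | np.random.Generator
) -> list[ObserverModel]:
    """Draw ``spec.n_observers`` observers from the cohort distribution."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=spec.n_observers)
    observers = []
    for i in range(spec.n_observers):
        offset = rng.normal(0.0, spec.observer_sd)
        thresholds = {
            cond: max(
                spec.min_threshold, m + offset + rng.normal(0.0, spec.condition_sd)
            )
            for cond, m in spec.mean_thresholds.items()
        }
        slope = max(5.0, rng.normal(spec.slope_mean, spec.slope_sd))
        observers.append(
            ObserverModel(
                thresholds=thresholds,
                slope=float(slope),
                lapse=spec.lapse,
                seed=int(seeds[i]),
            )
        )
    return observers
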