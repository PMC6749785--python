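"""Transformed up-down (3-down-1-up) staircases and full simulated sessions.

Each condition runs two interleaved staircases on the target's wiggle
amplitude, one starting at 1.2x baseline and one at 0.8x. The adaptive
variable is the unsigned distance ``delta = |level - 1|`` from the baseline
amplitude 1.0: after three consecutive correct responses ``delta`` shrinks by
one step, after any error it grows by one step. Balancing the step-down and
step-up probabilities (p^3 = 1/2) puts the equilibrium at p = 0.5^(1/3) =
79.37% correct. The step starts at 0.05 amplitude units and halves at each of
the first two reversals down to a minimum of 0.0125; levels are clamped so a
staircase never crosses baseline (which would invert the response mapping)
and stays within the renderable amplitude range.

A session interleaves the 12 staircases (3 colourations x 2 backgrounds x 2
starts) by uniform random selection among those not yet terminated, adds a
shared random pedestal offset (-0.20 .. +0.20 in 0.05 steps) to both target
and foil on every trial, queries the observer, and records 360 trials (30 per
staircase). Randomness is split into independent substreams (interleaving,
pedestals, side assignment, responses) derived from one session seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .observers import ObserverModel, respond

__all__ = [
    "StaircaseState",
    "TrialRecord",
    "ExperimentDesign",
    "StaircaseError",
    "update_staircase",
    "run_session",
    "simulate_convergence",
    "CONVERGENCE_PCT",
    "TRIAL_COLUMNS",
]

#: Equilibrium percent-correct of the 3-down-1-up rule: 100 * 0.5**(1/3).
CONVERGENCE_PCT = 100.0 * 0.5 ** (1.0 / 3.0)

TRIAL_COLUMNS = [
    "participant",
    "condition",
    "background",
    "colouration",
    "staircase",
    "trial",
    "target_amp",
    "foil_amp",
    "pedestal",
    "target_side",
    "response_side",
    "correct",
]


class StaircaseError(RuntimeError):
    """Raised when a terminated staircase is updated."""


@dataclass(frozen=True)
class ExperimentDesign:
    colourations: tuple[str, ...] = (
        "uniform",
        "flat_disruptive",
        "edge_enhanced_disruptive",
    )
    backgrounds: tuple[str, ...] = ("grey", "leaf")
    start_levels: tuple[float, ...] = (1.2, 0.8)
    trials_per_staircase: int = 30
    initial_step: float = 0.05
    min_step: float = 0.0125
    n_step_halvings: int = 2
    pedestal_max: float = 0.20
    pedestal_step: float = 0.05
    level_range: tuple[float, float] = (0.3, 2.5)

    @property
    def conditions(self) -> list[str]:
        return [f"{c}:{b}" for c in self.colourations for b in self.backgrounds]

    @property
    def pedestals(self) -> np.ndarray:
        n = int(round(2 * self.pedestal_max / self.pedestal_step)) + 1
        return np.round(np.linspace(-self.pedestal_max, self.pedestal_max, n), 10)


@dataclass
class StaircaseState:
    """Mutable state of one 3-down-1-up track on ``delta = |level - 1|``."""

    start_level: float
    step: float
    min_step: float
    min_delta: float
    max_delta: float
    n_halvings_left: int = 2
    delta: float = field(init=False)
    direction: int = field(init=False)  # +1: track above baseline, -1: below
    consecutive_correct: int = 0
    reversals: int = 0
    trial_index: int = 0
    max_trials: int = 30
    last_move: int = 0  # -1 shrink, +1 grow, 0 none yet
    history: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.direction = 1 if self.start_level >= 1.0 else -1
        self.delta = abs(self.start_level - 1.0)

    @property
    def level(self) -> float:
        return 1.0 + self.direction * self.delta

    @property
    def terminated(self) -> bool:
        return self.trial_index >= self.max_trials


def update_staircase(state: StaircaseState, correct: bool) -> StaircaseState:
    """Record one response and apply the 3-down-1-up rule in place.

    Returns the same state object (mutated) for convenience.
    """
    if state.terminated:
        raise StaircaseError("staircase already terminated")
    state.history.append((state.level, bool(correct)))
    state.trial_index += 1
    move = 0
    if correct:
        state.consecutive_correct += 1
        if state.consecutive_correct >= 3:
            state.consecutive_correct = 0
            move = -1
    else:
        state.consecutive_correct = 0
        move = +1
    if move != 0:
        if state.last_move != 0 and move != state.last_move:
            state.reversals += 1
            if state.n_halvings_left > 0:
                state.step = max(state.min_step, state.step / 2.0)
                state.n_halvings_left -= 1
        state.delta = float(
            np.clip(state.delta + move * state.step, state.min_delta, state.max_delta)
        )
        state.last_move = move
    return state


def _make_staircase(
    start_level: float, design: ExperimentDesign
) -> StaircaseState:
    lo, hi = design.level_range
    max_delta = (hi - 1.0) if start_level >= 1.0 else (1.0 - lo)
    return StaircaseState(
        start_level=start_level,
        step=design.initial_step,
        min_step=design.min_step,
        min_delta=design.min_step,
        max_delta=max_delta,
        n_halvings_left=design.n_step_halvings,
        max_trials=design.trials_per_staircase,
    )


@dataclass(frozen=True)
class TrialRecord:
    participant: str
    condition: str
    background: str
    colouration: str
    staircase: int
    trial: int
    target_amp: float
    foil_amp: float
    pedestal: float
    target_side: str
    response_side: str
    correct: bool


def run_session(
    observer: ObserverModel,
    design: ExperimentDesign,
    seed: int | np.random.SeedSequence,
    participant: str = "sim",
) -> list[TrialRecord]:
    """Run one complete simulated session (all conditions in one block).

    Returns ``len(conditions) * len(start_levels) * trials_per_staircase``
    trial records (360 under the default design).
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng_pick, rng_ped, rng_side, rng_resp = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    staircases: dict[tuple[str, int], StaircaseState] = {}
    for cond in design.conditions:
        for k, start in enumerate(design.start_levels):
            staircases[(cond, k)] = _make_staircase(start, design)
    pedestals = design.pedestals
    records: list[TrialRecord] = []
    keys = list(staircases)
    while True:
        live = [k for k in keys if not staircases[k].terminated]
        if not live:
            break
        cond, k = live[int(rng_pick.integers(len(live)))]
        st = staircases[(cond, k)]
        pedestal = float(pedestals[int(rng_ped.integers(pedestals.size))])
        target_amp = st.level + pedestal
        foil_amp = 1.0 + pedestal
        target_side = "left" if rng_side.random() < 0.5 else "right"
        choice, correct = respond(
            observer, target_amp, foil_amp, cond, rng=rng_resp, pedestal=pedestal
        )
        response_side = (
            target_side
            if choice == "target"
            else ("right" if target_side == "left" else "left")
        )
        colouration, background = cond.split(":")
        records.append(
            TrialRecord(
                participant=participant,
                condition=cond,
                background=background,
                colouration=colouration,
                staircase=k,
                trial=st.trial_index,
                target_amp=round(target_amp, 10),
                foil_amp=round(foil_amp, 10),
                pedestal=pedestal,
                target_side=target_side,
                response_side=response_side,
                correct=correct,
            )
        )
        update_staircase(st, correct)
    return records


def simulate_convergence(
    p_correct,
    n_trials: int = 100_000,
    step: float = 0.005,
    start_delta: float = 0.2,
    burn_in: int = 2_000,
    seed: int = 0,
    max_delta: float = 0.7,
) -> dict:
    """Long-run equilibrium of the 3-down-1-up rule against a known observer.

    Runs a single untruncated track with a constant step against a response
    model ``p_correct(delta) -> probability`` and returns the mean post
    burn-in level together with the model's true percent-correct at that mean
    level — the empirical counterpart of the analytic 79.37% equilibrium. A
    finite step biases the mean level slightly upward (the track dwells
    asymmetrically around the balance point), so the asymptote is measured
    with a constant step finer than the session schedule's minimum.
    """
    rng = np.random.default_rng(seed)
    delta = start_delta
    run = 0
    total = 0.0
    count = 0
    u = rng.random(n_trials)
    for i in range(n_trials):
        if i >= burn_in:
            total += delta
            count += 1
        if u[i] < p_correct(delta):
            run += 1
            if run >= 3:
                run = 0
                delta = max(step, delta - step)
        else:
            run = 0
            delta = min(max_delta, delta + step)
    mean_delta = total / count
    return {
        "mean_delta": mean_delta,
        "percent_correct_at_mean": 100.0 * float(p_correct(mean_delta)),
        "analytic_percent": CONVERGENCE_PCT,
        "n_trials": n_trials,
    }
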