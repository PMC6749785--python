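"""Logistic psychometric fits and 75%-correct wiggle thresholds.

Each condition's 60 trials (two interleaved staircases) are folded onto the
unsigned amplitude difference ``delta = |target - foil|``, proportions correct
are computed per distinct level, and a logistic

    psi(delta) = gamma + (1 - gamma - lambda) / (1 + exp(-beta * (delta - alpha)))

with guess rate gamma fixed at 0.5 and lapse lambda fixed at 0 is fitted by
weighted least squares on the per-level proportions (weights = trials per
level). With these fixed asymptotes, psi(alpha) = 0.75 exactly, so alpha is
the 75%-correct point on the folded axis and the reported wiggle threshold is
the corresponding target amplitude ``1 + alpha``.

The optimiser is a coarse grid search over (alpha, beta) followed by bounded
local minimisation from the best grid point; fits whose alpha sticks to a
bound (e.g. all-correct data) are returned flagged rather than raised.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize

from .staircase import TrialRecord

__all__ = [
    "PsychometricFit",
    "FitError",
    "psychometric",
    "fit_levels",
    "fit_condition",
    "threshold_from_fit",
    "plot_fit",
]

ALPHA_BOUNDS = (0.005, 0.6)
BETA_BOUNDS = (1.0, 200.0)


class FitError(ValueError):
    """Data insufficient for a psychometric fit."""


@dataclass(frozen=True)
class PsychometricFit:
    """Fitted logistic with fixed asymptotes and its derived threshold."""

    alpha: float
    beta: float
    gamma: float  # 0.5, fixed
    lambda_: float  # 0.0, fixed
    threshold: float  # 1 + alpha
    residual_sse: float
    n_trials: int
    n_levels: int
    flagged: bool = False
    message: str = ""


def psychometric(
    delta: np.ndarray, alpha: float, beta: float, gamma: float = 0.5, lambda_: float = 0.0
) -> np.ndarray:
    """Logistic probability-correct at folded difference ``delta``."""
    return gamma + (1.0 - gamma - lambda_) / (
        1.0 + np.exp(-beta * (np.asarray(delta, dtype=np.float64) - alpha))
    )


def _fold(trials: Iterable[TrialRecord]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    deltas = []
    corrects = []
    for t in trials:
        deltas.append(abs(t.target_amp - t.foil_amp))
        corrects.append(bool(t.correct))
    d = np.round(np.asarray(deltas, dtype=np.float64), 9)
    c = np.asarray(corrects, dtype=np.float64)
    levels, inverse = np.unique(d, return_inverse=True)
    counts = np.bincount(inverse).astype(np.float64)
    props = np.bincount(inverse, weights=c) / counts
    return levels, props, counts


def fit_levels(
    levels: Sequence[float], props: Sequence[float], counts: Sequence[float]
) -> PsychometricFit:
    """Weighted least-squares logistic fit on per-level proportions correct."""
    x = np.asarray(levels, dtype=np.float64)
    y = np.asarray(props, dtype=np.float64)
    w = np.asarray(counts, dtype=np.float64)
    n_trials = int(w.sum())
    if x.size < 3:
        raise FitError("need at least 3 distinct folded levels")

    def sse(params: np.ndarray) -> float:
        a, b = params
        r = y - psychometric(x, a, b)
        return float(np.sum(w * r * r))

    a_grid = np.linspace(ALPHA_BOUNDS[0], ALPHA_BOUNDS[1], 30)
    b_grid = np.geomspace(BETA_BOUNDS[0], BETA_BOUNDS[1], 20)
    pred = 0.5 + 0.5 / (
        1.0
        + np.exp(
            -b_grid[None, :, None] * (x[None, None, :] - a_grid[:, None, None])
        )
    )
    grid_sse = np.sum(w * (y - pred) ** 2, axis=-1)
    ia, ib = np.unravel_index(np.argmin(grid_sse), grid_sse.shape)

    best = None
    for x0 in ((a_grid[ia], b_grid[ib]), (0.1, 25.0)):
        res = optimize.minimize(
            sse,
            x0=np.asarray(x0),
            method="L-BFGS-B",
            bounds=[ALPHA_BOUNDS, BETA_BOUNDS],
            options={"ftol": 1e-12, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    alpha, beta = float(best.x[0]), float(best.x[1])
    flagged = False
    message = ""
    tol = 1e-6
    if alpha <= ALPHA_BOUNDS[0] + tol or alpha >= ALPHA_BOUNDS[1] - tol:
        flagged = True
        message = f"alpha at bound ({alpha:.4g}); data may be degenerate"
    elif not best.success and best.fun > 1e-10:
        # an "abnormal termination" on an essentially perfect fit is benign
        flagged = True
        message = f"optimiser did not converge: {best.message}"
    return PsychometricFit(
        alpha=alpha,
        beta=beta,
        gamma=0.5,
        lambda_=0.0,
        threshold=1.0 + alpha,
        residual_sse=float(best.fun),
        n_trials=n_trials,
        n_levels=int(x.size),
        flagged=flagged,
        message=message,
    )


def fit_condition(trials: Sequence[TrialRecord]) -> PsychometricFit:
    """Fold one condition's trials and fit the fixed-asymptote logistic.

    Requires at least 20 trials spanning at least 3 distinct folded levels.
    """
    trials = list(trials)
    if len(trials) < 20:
        raise FitError("need at least 20 trials")
    levels, props, counts = _fold(trials)
    return fit_levels(levels, props, counts)


def threshold_from_fit(fit: PsychometricFit) -> float:
    """75%-correct wiggle threshold as a target amplitude multiplier (1 + alpha)."""
    if fit.flagged:
        raise FitError(f"flagged fit: {fit.message}")
    return fit.threshold


def plot_fit(
    levels: np.ndarray,
    props: np.ndarray,
    counts: np.ndarray,
    fit: PsychometricFit,
    path,
    title: str = "",
) -> None:
    """Diagnostic plot: per-level proportions (sized by count) and fitted curve."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(levels, props, s=10 * np.asarray(counts), alpha=0.7, label="data")
    grid = np.linspace(0, max(float(np.max(levels)) * 1.2, fit.alpha * 2), 200)
    ax.plot(grid, psychometric(grid, fit.alpha, fit.beta), "k-", label="fit")
    ax.axhline(0.75, ls=":", c="grey")
    ax.axvline(fit.alpha, ls=":", c="grey")
    ax.set_xlabel("amplitude difference |target − foil|")
    ax.set_ylabel("proportion correct")
    ax.set_ylim(0.4, 1.02)
    ax.set_title(title or f"threshold = {fit.threshold:.3f}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
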