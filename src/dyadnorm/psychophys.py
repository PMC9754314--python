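"""Maximum-likelihood psychophysical weight fitting and session rules.

The perceptual response model is a no-intercept regression of the integer
estimate on the presented dot count (or its natural log for the log-linear
variant) with Gaussian noise. Model comparison uses AIC with k = 2 free
parameters per model (slope and noise SD).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np

from .synthetic_data import TrialRecord

MIN_VALID_ESTIMATE = 10
_K_PARAMS = 2


@dataclass(frozen=True)
class WeightFit:
    w: float
    noise_sd: float
    loglik: float
    aic: float
    n_trials: int
    model_tag: str  # "linear" | "loglinear"


@dataclass(frozen=True)
class DroppedTrial:
    record: TrialRecord
    reason: str


def clean_trials(
    records: Iterable[TrialRecord],
) -> Tuple[List[TrialRecord], List[DroppedTrial]]:
    """Apply the outlier rule: drop trials whose estimate is missing
    (incomplete) or below 10. Order is preserved."""
    kept: List[TrialRecord] = []
    dropped: List[DroppedTrial] = []
    for r in records:
        if r.estimate is None:
            dropped.append(DroppedTrial(r, "missing estimate"))
        elif r.estimate < MIN_VALID_ESTIMATE:
            dropped.append(DroppedTrial(r, f"estimate {r.estimate} < {MIN_VALID_ESTIMATE}"))
        else:
            kept.append(r)
    return kept, dropped


def _fit_no_intercept(
    x: np.ndarray, y: np.ndarray, model_tag: str
) -> WeightFit:
    n = len(y)
    if n < 2:
        raise ValueError("need at least 2 records to fit a weight")
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise ValueError("all regressor values are zero")
    w = float(np.sum(x * y) / sxx)
    resid = y - w * x
    # ML (1/n) noise variance, as required for a likelihood-based AIC
    var = float(np.mean(resid**2))
    if var <= 0:
        loglik = math.inf
        noise_sd = 0.0
    else:
        noise_sd = math.sqrt(var)
        loglik = -0.5 * n * (math.log(2 * math.pi * var) + 1.0)
    aic = 2 * _K_PARAMS - 2 * loglik
    return WeightFit(w, noise_sd, loglik, aic, n, model_tag)


def _extract(records: Sequence[TrialRecord]) -> Tuple[np.ndarray, np.ndarray]:
    dots = np.array([r.dot_count for r in records], dtype=float)
    ests = np.array(
        [r.estimate for r in records], dtype=float
    )
    if any(r.estimate is None for r in records):
        raise ValueError("records with missing estimates; run clean_trials first")
    return dots, ests


def fit_linear_weight(records: Sequence[TrialRecord]) -> WeightFit:
    """ML fit of ``Est = w * DotNum + eps``; the slope has the closed form
    ``sum(Est*Dot) / sum(Dot^2)``."""
    dots, ests = _extract(records)
    return _fit_no_intercept(dots, ests, "linear")


def fit_loglinear_weight(records: Sequence[TrialRecord]) -> WeightFit:
    """ML fit of ``Est = w * log(DotNum) + eps`` (natural log)."""
    dots, ests = _extract(records)
    return _fit_no_intercept(np.log(dots), ests, "loglinear")


def compare_models(linear: WeightFit, loglinear: WeightFit) -> Tuple[str, float]:
    """Return (preferred model tag, delta AIC = loglinear - linear).

    Lower AIC wins; exact ties go to the linear model by convention.
    """
    if linear.n_trials != loglinear.n_trials:
        raise ValueError("fits come from different numbers of trials")
    if linear.aic == loglinear.aic:
        return "linear", 0.0
    delta = loglinear.aic - linear.aic
    return ("linear" if linear.aic < loglinear.aic else "loglinear"), delta


_REWARD_STEPS = ((5.0, 1000), (10.0, 800), (15.0, 600), (20.0, 400), (25.0, 200))


def compute_reward(mean_abs_error: float, boundary_inclusive: bool = True) -> int:
    """Stepwise additional reward (JPY) from the mean absolute error.

    The printed rule leaves exactly 25.0 undefined ("< 25, or > 25"); by
    default a boundary value maps to the lower-reward side of each strict
    threshold, so 25.0 -> 200. Pass ``boundary_inclusive=False`` to map
    exact boundaries to 0-side/open behavior (25.0 -> 0).
    """
    if mean_abs_error < 0:
        raise ValueError("mean_abs_error must be non-negative")
    for bound, reward in _REWARD_STEPS:
        if mean_abs_error < bound:
            return reward
    if boundary_inclusive and mean_abs_error == _REWARD_STEPS[-1][0]:
        return _REWARD_STEPS[-1][1]
    return 0
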