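"""Random-walk Metropolis building blocks used by the Bayesian modules.

No external PPL is available at run time, so the samplers are written
directly: scalar random-walk proposals (on the log scale for positive
parameters) with Robbins-Monro scale adaptation during burn-in only, which
keeps chains Markovian afterwards and runs reproducible under a seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict

import numpy as np
from scipy.special import log_ndtr as _scipy_log_ndtr

TARGET_ACCEPT = 0.44  # optimal-ish for one-dimensional random walks


@dataclass
class AdaptiveScale:
    log_scale: float = math.log(0.5)
    adapting: bool = True
    _step: int = 0

    @property
    def scale(self) -> float:
        return math.exp(self.log_scale)

    def update(self, accept_prob: float) -> None:
        if not self.adapting:
            return
        self._step += 1
        gamma = self._step ** -0.6
        self.log_scale += gamma * (accept_prob - TARGET_ACCEPT)
        self.log_scale = min(max(self.log_scale, -12.0), 4.0)

    def freeze(self) -> None:
        self.adapting = False


def mh_step(
    value: float,
    logpost: Callable[[float], float],
    current_lp: float,
    scale: AdaptiveScale,
    rng: np.random.Generator,
    log_space: bool = False,
) -> tuple:
    """One scalar random-walk Metropolis step.

    When ``log_space`` is set the proposal is multiplicative
    (random walk on log(value)) and the Jacobian correction is included, so
    the target density stays the one over the original parameter.

    Returns ``(new_value, new_lp, accepted)``; ``logpost`` must return
    ``-inf`` outside the support.
    """
    eps = float(rng.normal(0.0, scale.scale))
    if log_space:
        prop = value * math.exp(eps)
        log_ratio_jac = math.log(prop) - math.log(value)
    else:
        prop = value + eps
        log_ratio_jac = 0.0
    prop_lp = logpost(prop)
    log_alpha = prop_lp - current_lp + log_ratio_jac
    accept_prob = min(1.0, math.exp(min(log_alpha, 0.0))) if math.isfinite(prop_lp) else 0.0
    accepted = math.log(max(rng.uniform(), 1e-300)) < log_alpha
    scale.update(accept_prob)
    if accepted:
        return prop, prop_lp, True
    return value, current_lp, False


@dataclass
class ScaleBank:
    """Named collection of adaptive proposal scales."""

    scales: Dict[str, AdaptiveScale] = field(default_factory=dict)

    def __getitem__(self, name: str) -> AdaptiveScale:
        if name not in self.scales:
            self.scales[name] = AdaptiveScale()
        return self.scales[name]

    def freeze(self) -> None:
        for s in self.scales.values():
            s.freeze()


def log_truncnorm0(x: float, mu: float, sd: float) -> float:
    """Log-density of N(mu, sd) truncated to x >= 0 (normalised)."""
    if x < 0 or sd <= 0:
        return -math.inf
    z = (x - mu) / sd
    # P(X >= 0) = Phi(mu / sd)
    log_norm = _log_ndtr(mu / sd)
    return -0.5 * z * z - math.log(sd) - 0.5 * math.log(2 * math.pi) - log_norm


def _log_ndtr(z: float) -> float:
    return float(_scipy_log_ndtr(z))
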