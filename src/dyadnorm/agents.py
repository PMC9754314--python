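"""Programmed computer partners for the interaction phases.

Two partner types are provided:

* **Asch-type** — unresponsive: keeps a fixed built-in estimation weight and
  answers ``round(w * dots) + eta`` on every trial, with ``eta`` drawn
  uniformly from a small integer support.
* **Sherif-type** — reciprocating: its estimation weight on each trial is an
  affine function of its own and the participant's implied weights over the
  previous five trials, so it gradually concedes toward the participant.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._util import clip_estimate, round_half_away

#: lag coefficients on the partner's own weight history (most recent first)
DEFAULT_A = (0.091, 0.044, 0.037, 0.032, 0.025)
#: lag coefficients on the participant's implied-weight history
DEFAULT_B = (0.066, 0.014, 0.001, -0.015, -0.011)

UNDER_WEIGHT = 0.61
OVER_WEIGHT = 1.21
DEFAULT_PARTICIPANT_REF = 0.91

N_LAGS = 5


@dataclass
class AgentConfig:
    """Configuration of a computer partner.

    Parameters
    ----------
    partner_type:
        ``"asch"`` or ``"sherif"``.
    initial_weight:
        Built-in estimation bias (0.61 for the underestimator, 1.21 for the
        overestimator).
    eta_support:
        Integer support of the additive noise term; a value is drawn
        uniformly on every trial.
    intercept:
        Constant of the Sherif weight recurrence.
    a, b:
        Five lag coefficients on the partner's own past weights (``a``) and
        on the participant's past implied weights (``b``).
    participant_ref_weight:
        Value used to pre-fill the participant-weight history before any
        participant estimate has been observed.
    intercept_mode:
        How a non-default ``initial_weight`` is realised for the Sherif
        partner. ``"history"`` (default) keeps the printed intercept and only
        warm-starts the weight histories at ``initial_weight``;
        ``"rescaled"`` recomputes the intercept so that ``initial_weight`` is
        reproduced exactly from the warm start.
    """

    partner_type: str
    initial_weight: float = UNDER_WEIGHT
    eta_support: Sequence[int] = (-2, -1, 0, 1, 2)
    intercept: float = 0.61
    a: Sequence[float] = DEFAULT_A
    b: Sequence[float] = DEFAULT_B
    participant_ref_weight: float = DEFAULT_PARTICIPANT_REF
    intercept_mode: str = "history"

    def __post_init__(self) -> None:
        if self.partner_type not in ("asch", "sherif"):
            raise ValueError(f"unknown partner_type: {self.partner_type!r}")
        if len(self.a) != N_LAGS or len(self.b) != N_LAGS:
            raise ValueError("a and b must each hold exactly 5 lag coefficients")
        if len(self.eta_support) == 0:
            raise ValueError("eta_support must be non-empty")
        if any(int(e) != e for e in self.eta_support):
            raise ValueError("eta_support must contain integers")
        if self.intercept_mode not in ("history", "rescaled"):
            raise ValueError(f"unknown intercept_mode: {self.intercept_mode!r}")

    @property
    def effective_intercept(self) -> float:
        if self.intercept_mode == "rescaled":
            return (
                self.initial_weight * (1.0 - sum(self.a))
                - sum(self.b) * self.participant_ref_weight
            )
        return self.intercept


@dataclass
class SherifState:
    """Lag buffers of the Sherif recurrence (most recent entry first)."""

    w_history: list = field(default_factory=list)
    partner_w_history: list = field(default_factory=list)


def init_sherif_state(
    config: AgentConfig, participant_pre_weight: Optional[float] = None
) -> SherifState:
    """Warm-started state: own lags at the built-in weight, participant lags
    at the (assumed) pre-interaction participant weight."""
    ref = (
        participant_pre_weight
        if participant_pre_weight is not None
        else config.participant_ref_weight
    )
    return SherifState(
        w_history=[config.initial_weight] * N_LAGS,
        partner_w_history=[ref] * N_LAGS,
    )


def _draw_eta(config: AgentConfig, rng: np.random.Generator) -> int:
    return int(rng.choice(np.asarray(config.eta_support, dtype=int)))


def asch_estimate(
    config: AgentConfig,
    dot_count: int,
    rng: np.random.Generator,
    eta: Optional[int] = None,
) -> int:
    """Estimate of the unresponsive partner: ``round(w*dots) + eta``, >= 1.

    ``eta`` may be forced for testing; otherwise it is drawn uniformly from
    ``config.eta_support``.
    """
    if eta is None:
        eta = _draw_eta(config, rng)
    return clip_estimate(round_half_away(config.initial_weight * dot_count) + eta)


def sherif_update_weight(config: AgentConfig, state: SherifState) -> float:
    """Advance the reciprocating partner's weight by one trial.

    Returns the new weight and shifts it into the own-weight lag buffer.
    """
    if len(state.w_history) != N_LAGS or len(state.partner_w_history) != N_LAGS:
        raise ValueError("histories must hold exactly 5 lags (warm up first)")
    for w in (*state.w_history, *state.partner_w_history):
        if not math.isfinite(w):
            raise ValueError("non-finite weight in history")
    w_new = (
        config.effective_intercept
        + sum(aj * wj for aj, wj in zip(config.a, state.w_history))
        + sum(bj * wj for bj, wj in zip(config.b, state.partner_w_history))
    )
    state.w_history.insert(0, w_new)
    state.w_history.pop()
    return w_new


def sherif_estimate(
    config: AgentConfig,
    state: SherifState,
    dot_count: int,
    rng: np.random.Generator,
    eta: Optional[int] = None,
) -> int:
    """One estimate of the reciprocating partner (weight update included)."""
    w = sherif_update_weight(config, state)
    if eta is None:
        eta = _draw_eta(config, rng)
    return clip_estimate(round_half_away(w * dot_count) + eta)


def observe_participant(
    state: SherifState, participant_estimate: int, dot_count: int
) -> SherifState:
    """Push the participant's implied weight (estimate / dots) into the
    partner-side lag buffer."""
    if dot_count <= 0:
        raise ValueError("dot_count must be positive")
    state.partner_w_history.insert(0, participant_estimate / dot_count)
    state.partner_w_history.pop()
    return state


def sherif_fixed_point(config: AgentConfig, participant_weight: float) -> float:
    """Closed-form limit of the weight recurrence for a constant participant
    weight: ``(c + sum(b)*w_i) / (1 - sum(a))``."""
    return (config.effective_intercept + sum(config.b) * participant_weight) / (
        1.0 - sum(config.a)
    )
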