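"""Synthetic dyadic dot-estimation experiments.

Generates trial schedules for the three experimental designs (laboratory
pair/individual, fMRI-behavioral, online 2x2), virtual participants whose
latent estimation weight follows a Gaussian random walk, interaction phases
against programmed partners or other virtual participants, and CSV
readers/writers for the long-format trial table.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from . import agents as _agents
from ._util import clip_estimate, round_half_away

LAB_DOTS: Tuple[int, ...] = tuple(range(25, 56, 2))  # 25..55 step 2 -> 16 values
FMRI_DOTS: Tuple[int, ...] = tuple(range(25, 59, 3))  # 25..58 step 3 -> 12 values

LAB_SOLO_TRIALS = 16
LAB_INTERACTION_TRIALS = 144
SHORT_PHASE_TRIALS = 24
INTERACTION_PHASE_TRIALS = 48

POPULATION_MEAN_WEIGHT = 0.915
#: the built-in partner bias 0.61 sits 1.5 population SDs below the mean
POPULATION_SD_WEIGHT = (0.915 - 0.61) / 1.5

CSV_COLUMNS = (
    "participant_id",
    "condition",
    "phase",
    "trial",
    "dot_count",
    "estimate",
    "partner_estimate",
)


@dataclass(frozen=True)
class SchedulePhase:
    label: str
    dot_counts: Tuple[int, ...]
    interactive: bool = False

    @property
    def trial_count(self) -> int:
        return len(self.dot_counts)


@dataclass(frozen=True)
class Schedule:
    design_name: str
    phases: Tuple[SchedulePhase, ...]

    def phase(self, label: str) -> SchedulePhase:
        for ph in self.phases:
            if ph.label == label:
                return ph
        raise KeyError(f"no phase labelled {label!r}")


@dataclass
class ReciprocityCoeffs:
    """Lag-5 linear adjustment of a participant's latent weight.

    The next latent weight is ``intercept + sum(a_j * w_self(t-j)) +
    sum(b_j * w_partner(t-j))`` plus the random-walk noise, where the lagged
    weights are implied weights (estimate / dot count). When ``intercept`` is
    ``None`` it is derived as ``base * (1 - sum(a) - sum(b))`` so that the
    participant's own base weight is the fixed point in the absence of a
    deviating partner; the recurrence then pulls the weight toward the
    partner with mixing rate ``sum(b) / (1 - sum(a))``.
    """

    a: Sequence[float] = _agents.DEFAULT_A
    b: Sequence[float] = _agents.DEFAULT_B
    intercept: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.a) != 5 or len(self.b) != 5:
            raise ValueError("a and b must each hold exactly 5 lag coefficients")

    def effective_intercept(self, base_weight: float) -> float:
        if self.intercept is not None:
            return self.intercept
        return base_weight * (1.0 - sum(self.a) - sum(self.b))

    def is_null(self) -> bool:
        return all(c == 0 for c in self.a) and all(c == 0 for c in self.b)


@dataclass
class VirtualParticipant:
    id: str
    base_weight: float
    sigma_mu_true: float = 0.0
    sigma_obs_true: float = 0.0
    estimate_noise_sd: float = 0.0
    reciprocity_coeffs: Optional[ReciprocityCoeffs] = None

    def __post_init__(self) -> None:
        if self.base_weight <= 0:
            raise ValueError("base_weight must be positive")
        for name in ("sigma_mu_true", "sigma_obs_true", "estimate_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class TrialRecord:
    participant_id: str
    phase: str
    trial: int  # 1-based within phase
    dot_count: int
    estimate: Optional[int] = None
    partner_estimate: Optional[int] = None
    condition: str = ""


def default_population_params() -> Tuple[float, float]:
    """Mean and SD of the base estimation-weight distribution."""
    return POPULATION_MEAN_WEIGHT, POPULATION_SD_WEIGHT


def make_schedule(design_name: str, seed: int, balanced: bool = False) -> Schedule:
    """Build the trial schedule of one participant for a named design.

    ``lab`` solo phases present each magnitude 25..55 (step 2) exactly once;
    the 144-trial interaction phase repeats that set nine times. ``fmri`` and
    ``online`` phases draw from 25..58 (step 3), uniformly unless
    ``balanced`` is set, in which case each magnitude appears equally often.
    Presentation order is a seeded permutation in every phase.
    """
    rng = np.random.default_rng(seed)

    def perm(values: Sequence[int]) -> Tuple[int, ...]:
        return tuple(int(v) for v in rng.permutation(np.asarray(values, dtype=int)))

    def draw(n: int) -> Tuple[int, ...]:
        if balanced:
            if n % len(FMRI_DOTS):
                raise ValueError(
                    f"balanced phase length {n} not divisible by {len(FMRI_DOTS)}"
                )
            return perm(list(FMRI_DOTS) * (n // len(FMRI_DOTS)))
        return tuple(int(v) for v in rng.choice(FMRI_DOTS, size=n, replace=True))

    if design_name == "lab":
        phases = (
            SchedulePhase("phase1", perm(LAB_DOTS)),
            SchedulePhase(
                "phase2", perm(list(LAB_DOTS) * 9), interactive=True
            ),
            SchedulePhase("phase3", perm(LAB_DOTS)),
        )
    elif design_name == "fmri":
        phases = (
            SchedulePhase("pre", draw(SHORT_PHASE_TRIALS)),
            SchedulePhase("interaction1", draw(INTERACTION_PHASE_TRIALS), True),
            SchedulePhase("post1", draw(SHORT_PHASE_TRIALS)),
            SchedulePhase("interaction2", draw(INTERACTION_PHASE_TRIALS), True),
            SchedulePhase("post2", draw(SHORT_PHASE_TRIALS)),
        )
    elif design_name == "online":
        phases = (
            SchedulePhase("pre", draw(SHORT_PHASE_TRIALS)),
            SchedulePhase("interaction", draw(INTERACTION_PHASE_TRIALS), True),
            SchedulePhase("post", draw(SHORT_PHASE_TRIALS)),
        )
    else:
        raise ValueError(f"unknown design_name: {design_name!r}")
    return Schedule(design_name, phases)


def _emit_estimate(
    weight: float, dot_count: int, noise_sd: float, rng: np.random.Generator
) -> int:
    est = round_half_away(weight * dot_count)
    est += round_half_away(float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0)
    return clip_estimate(est)


def _draw_obs_weight(
    mu: float, participant: VirtualParticipant, rng: np.random.Generator
) -> float:
    if participant.sigma_obs_true > 0:
        return mu + float(rng.normal(0.0, participant.sigma_obs_true))
    return mu


def _walk(mu: float, participant: VirtualParticipant, rng: np.random.Generator) -> float:
    if participant.sigma_mu_true > 0:
        return mu + float(rng.normal(0.0, participant.sigma_mu_true))
    return mu


def _simulate_solo(
    participant: VirtualParticipant,
    phase: SchedulePhase,
    rng: np.random.Generator,
    mu0: Optional[float] = None,
    condition: str = "",
) -> Tuple[List[TrialRecord], float]:
    mu = participant.base_weight if mu0 is None else mu0
    records: List[TrialRecord] = []
    for t, dot in enumerate(phase.dot_counts, start=1):
        if t > 1:
            mu = _walk(mu, participant, rng)
        w = _draw_obs_weight(mu, participant, rng)
        est = _emit_estimate(w, dot, participant.estimate_noise_sd, rng)
        records.append(
            TrialRecord(participant.id, phase.label, t, dot, est, None, condition)
        )
    return records, mu


def simulate_solo_phase(
    participant: VirtualParticipant,
    phase: SchedulePhase,
    seed: int,
    condition: str = "",
) -> List[TrialRecord]:
    """Simulate a non-interactive phase.

    The latent weight starts at ``base_weight`` and follows a Gaussian random
    walk with SD ``sigma_mu_true``; each trial's observed weight adds
    ``sigma_obs_true`` noise, and the integer estimate is
    ``round(weight * dots)`` plus rounded Gaussian estimate noise, floored
    at 1.
    """
    if phase.interactive:
        raise ValueError("phase is interactive; use simulate_interaction_phase")
    records, _ = _simulate_solo(
        participant, phase, np.random.default_rng(seed), condition=condition
    )
    return records


class _ReciprocalUpdater:
    """Shared latent-weight update used for participant-vs-agent and
    participant-vs-participant interaction."""

    def __init__(self, participant: VirtualParticipant):
        self.p = participant
        self.coeffs = participant.reciprocity_coeffs
        self.mu = participant.base_weight
        self.self_hist = [participant.base_weight] * 5
        # neutral warm start: no partner influence before any observation
        self.partner_hist = [participant.base_weight] * 5

    def observe(self, own_estimate: int, partner_estimate: int, dot: int) -> None:
        self.self_hist.insert(0, own_estimate / dot)
        self.self_hist.pop()
        self.partner_hist.insert(0, partner_estimate / dot)
        self.partner_hist.pop()

    def advance(self, rng: np.random.Generator) -> None:
        if self.coeffs is None or self.coeffs.is_null():
            self.mu = _walk(self.mu, self.p, rng)
            return
        target = (
            self.coeffs.effective_intercept(self.p.base_weight)
            + sum(a * w for a, w in zip(self.coeffs.a, self.self_hist))
            + sum(b * w for b, w in zip(self.coeffs.b, self.partner_hist))
        )
        if self.p.sigma_mu_true > 0:
            target += float(rng.normal(0.0, self.p.sigma_mu_true))
        self.mu = target


def _simulate_interaction(
    participant: VirtualParticipant,
    agent: _agents.AgentConfig,
    phase: SchedulePhase,
    rng: np.random.Generator,
    mu0: Optional[float] = None,
    condition: str = "",
) -> Tuple[List[TrialRecord], float]:
    upd = _ReciprocalUpdater(participant)
    if mu0 is not None:
        upd.mu = mu0
    state = (
        _agents.init_sherif_state(agent, participant_pre_weight=participant.base_weight)
        if agent.partner_type == "sherif"
        else None
    )
    records: List[TrialRecord] = []
    for t, dot in enumerate(phase.dot_counts, start=1):
        if t > 1:
            upd.advance(rng)
        w = _draw_obs_weight(upd.mu, participant, rng)
        est_i = _emit_estimate(w, dot, participant.estimate_noise_sd, rng)
        if agent.partner_type == "asch":
            est_p = _agents.asch_estimate(agent, dot, rng)
        else:
            est_p = _agents.sherif_estimate(agent, state, dot, rng)
            _agents.observe_participant(state, est_i, dot)
        upd.observe(est_i, est_p, dot)
        records.append(
            TrialRecord(participant.id, phase.label, t, dot, est_i, est_p, condition)
        )
    return records, upd.mu


def simulate_interaction_phase(
    participant: VirtualParticipant,
    agent: _agents.AgentConfig,
    phase: SchedulePhase,
    seed: int,
    condition: str = "",
) -> List[TrialRecord]:
    """Simulate an interaction phase against a programmed partner.

    Both sides estimate the same dot count on every trial; after each trial
    the participant's lag buffers are updated with both implied weights and
    the latent weight for the next trial is advanced by the reciprocity
    recurrence (or by the plain random walk when no coefficients are set).
    """
    records, _ = _simulate_interaction(
        participant, agent, phase, np.random.default_rng(seed), condition=condition
    )
    return records


def _simulate_pair(
    p1: VirtualParticipant,
    p2: VirtualParticipant,
    phase: SchedulePhase,
    rng: np.random.Generator,
    mu0: Tuple[Optional[float], Optional[float]] = (None, None),
    condition: str = "pair",
) -> Tuple[List[TrialRecord], List[TrialRecord], float, float]:
    u1, u2 = _ReciprocalUpdater(p1), _ReciprocalUpdater(p2)
    if mu0[0] is not None:
        u1.mu = mu0[0]
    if mu0[1] is not None:
        u2.mu = mu0[1]
    rec1: List[TrialRecord] = []
    rec2: List[TrialRecord] = []
    for t, dot in enumerate(phase.dot_counts, start=1):
        if t > 1:
            u1.advance(rng)
            u2.advance(rng)
        e1 = _emit_estimate(_draw_obs_weight(u1.mu, p1, rng), dot, p1.estimate_noise_sd, rng)
        e2 = _emit_estimate(_draw_obs_weight(u2.mu, p2, rng), dot, p2.estimate_noise_sd, rng)
        u1.observe(e1, e2, dot)
        u2.observe(e2, e1, dot)
        rec1.append(TrialRecord(p1.id, phase.label, t, dot, e1, e2, condition))
        rec2.append(TrialRecord(p2.id, phase.label, t, dot, e2, e1, condition))
    return rec1, rec2, u1.mu, u2.mu


def simulate_pair_phase(
    p1: VirtualParticipant,
    p2: VirtualParticipant,
    phase: SchedulePhase,
    seed: int,
) -> Tuple[List[TrialRecord], List[TrialRecord]]:
    """Simulate two virtual participants interacting with each other."""
    r1, r2, _, _ = _simulate_pair(p1, p2, phase, np.random.default_rng(seed))
    return r1, r2


def sample_population(
    n: int,
    seed: int,
    mean_weight: Optional[float] = None,
    sd_weight: Optional[float] = None,
    sigma_mu: float = 0.05,
    sigma_obs: float = 0.08,
    estimate_noise_sd: float = 1.0,
    reciprocity: Optional[ReciprocityCoeffs] = None,
    id_prefix: str = "P",
) -> List[VirtualParticipant]:
    """Draw ``n`` virtual participants with Normal base weights (floored at
    0.05 to respect the positivity invariant)."""
    m, s = default_population_params()
    mean_weight = m if mean_weight is None else mean_weight
    sd_weight = s if sd_weight is None else sd_weight
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        w = max(0.05, float(rng.normal(mean_weight, sd_weight)))
        out.append(
            VirtualParticipant(
                id=f"{id_prefix}{i + 1:03d}",
                base_weight=w,
                sigma_mu_true=sigma_mu,
                sigma_obs_true=sigma_obs,
                estimate_noise_sd=estimate_noise_sd,
                reciprocity_coeffs=reciprocity,
            )
        )
    return out


def simulate_lab_pair_experiment(
    p1: VirtualParticipant,
    p2: VirtualParticipant,
    seed: int,
) -> List[TrialRecord]:
    """Full three-phase laboratory pair session for one real pair.

    The latent weight carries over between phases, so post-interaction solo
    behavior reflects the influence accumulated during the interaction.
    """
    rng = np.random.default_rng(seed)
    sched = make_schedule("lab", int(rng.integers(2**31)))
    records: List[TrialRecord] = []
    r1, m1 = _simulate_solo(p1, sched.phase("phase1"), rng, condition="pair")
    r2, m2 = _simulate_solo(p2, sched.phase("phase1"), rng, condition="pair")
    records += r1 + r2
    r1, r2, m1, m2 = _simulate_pair(
        p1, p2, sched.phase("phase2"), rng, mu0=(m1, m2)
    )
    records += r1 + r2
    r1, _ = _simulate_solo(p1, sched.phase("phase3"), rng, mu0=m1, condition="pair")
    r2, _ = _simulate_solo(p2, sched.phase("phase3"), rng, mu0=m2, condition="pair")
    records += r1 + r2
    return records


def simulate_online_session(
    participant: VirtualParticipant,
    agent: _agents.AgentConfig,
    seed: int,
    balanced: bool = False,
) -> List[TrialRecord]:
    """Full pre/interaction/post online session against a computer partner."""
    rng = np.random.default_rng(seed)
    sched = make_schedule("online", int(rng.integers(2**31)), balanced=balanced)
    condition = f"{agent.partner_type}-{agent.initial_weight:g}"
    records, mu = _simulate_solo(
        participant, sched.phase("pre"), rng, condition=condition
    )
    r, mu = _simulate_interaction(
        participant, agent, sched.phase("interaction"), rng, mu0=mu, condition=condition
    )
    records += r
    r, _ = _simulate_solo(
        participant, sched.phase("post"), rng, mu0=mu, condition=condition
    )
    return records + r


# ---------------------------------------------------------------------------
# trial-table CSV I/O


def write_trials(path, records: Iterable[TrialRecord]) -> None:
    """Write records to the fixed-header trial-table CSV (UTF-8). Missing
    estimates are encoded as empty fields."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.participant_id,
                    r.condition,
                    r.phase,
                    r.trial,
                    r.dot_count,
                    "" if r.estimate is None else r.estimate,
                    "" if r.partner_estimate is None else r.partner_estimate,
                ]
            )


class TrialTableError(ValueError):
    pass


def _parse_int(value: str, column: str, row: int, required: bool = True) -> Optional[int]:
    value = value.strip()
    if value == "":
        if required:
            raise TrialTableError(f"row {row}: missing value in column {column!r}")
        return None
    try:
        return int(value)
    except ValueError:
        raise TrialTableError(
            f"row {row}: non-integer value {value!r} in column {column!r}"
        ) from None


def read_trials(path) -> List[TrialRecord]:
    """Read a trial-table CSV, validating the header and integer columns.

    Raises :class:`TrialTableError` naming the offending row on malformed
    input; empty estimate fields are read as missing.
    """
    records: List[TrialRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise TrialTableError("empty file: missing header") from None
        if tuple(h.strip() for h in header) != CSV_COLUMNS:
            raise TrialTableError(
                f"malformed header {header!r}; expected {list(CSV_COLUMNS)}"
            )
        for i, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(CSV_COLUMNS):
                raise TrialTableError(
                    f"row {i}: expected {len(CSV_COLUMNS)} fields, got {len(row)}"
                )
            pid, condition, phase, trial, dot, est, pest = row
            records.append(
                TrialRecord(
                    participant_id=pid,
                    condition=condition,
                    phase=phase,
                    trial=_parse_int(trial, "trial", i),
                    dot_count=_parse_int(dot, "dot_count", i),
                    estimate=_parse_int(est, "estimate", i, required=False),
                    partner_estimate=_parse_int(
                        pest, "partner_estimate", i, required=False
                    ),
                )
            )
    return records
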