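"""Time-varying decomposition of estimation during interaction.

The participant's per-trial estimation weight is decomposed into a constant
Baseline plus time-varying coefficients on two lagged regressors: the
partner's atypicality (distance from a reference observer, a nuisance term)
and the pair's estimate similarity (the quantity of interest). The
coefficients follow local-linear-trend dynamics, giving a linear-Gaussian
state-space model whose states are marginalised by a Kalman filter during
MCMC over the innovation/noise scales. Model comparison uses WAIC over the
full model and seven reduced variants; a posterior predictive check
correlates observed and model-predicted estimates.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _mcmc, _ssm
from ._util import clip_estimate, round_half_away
from .synthetic_data import TrialRecord

REFERENCE_WEIGHT = 0.91
RHAT_THRESHOLD = 1.05

MODEL_TAGS = (
    "full",
    "null",
    "baseline",
    "atyp",
    "sim",
    "baseline+atyp",
    "baseline+sim",
    "atyp+sim",
)

_COMPONENTS = {
    "full": frozenset({"baseline", "atyp", "sim"}),
    "null": frozenset(),
    "baseline": frozenset({"baseline"}),
    "atyp": frozenset({"atyp"}),
    "sim": frozenset({"sim"}),
    "baseline+atyp": frozenset({"baseline", "atyp"}),
    "baseline+sim": frozenset({"baseline", "sim"}),
    "atyp+sim": frozenset({"atyp", "sim"}),
}


def compute_atyp(
    partner_estimate: float, dot_count: float, reference_weight: float = REFERENCE_WEIGHT
) -> float:
    """Atypicality of the partner's estimate relative to a reference
    observer: ``1 - est_p / (ref * dots)``."""
    if dot_count <= 0:
        raise ValueError("dot_count must be positive")
    return 1.0 - partner_estimate / (reference_weight * dot_count)


def compute_sim(
    est_i: float,
    est_p: float,
    dot_count: float,
    w_i_pre: float,
    w_p_pre: float,
) -> float:
    """Similarity of the two estimates relative to the pair's
    pre-interaction weight gap: ``pi/2 - atan(|est_i - est_p| /
    |(w_i_pre - w_p_pre) * dots|)``; range (0, pi/2].

    A degenerate denominator (equal pre weights) returns the continuous
    limits: 0 for any non-zero numerator, pi/2 when both are zero.
    """
    if dot_count <= 0:
        raise ValueError("dot_count must be positive")
    num = abs(est_i - est_p)
    den = abs((w_i_pre - w_p_pre) * dot_count)
    if den == 0.0:
        return math.pi / 2 if num == 0.0 else 0.0
    return math.pi / 2 - math.atan(num / den)


@dataclass
class RegressorSet:
    """Aligned arrays for trials t = 2..T of one interaction session."""

    y: np.ndarray  # est_i(t)
    dot: np.ndarray  # DotNum(t)
    atyp: np.ndarray  # Atyp(t-1)
    sim: np.ndarray  # Sim(t-1)
    w_i_pre: float
    w_p_pre: float
    reference_weight: float = REFERENCE_WEIGHT

    @property
    def n_trials(self) -> int:
        return len(self.y)


def build_regressors(
    records: Sequence[TrialRecord],
    w_i_pre: float,
    w_p_pre: float,
    reference_weight: float = REFERENCE_WEIGHT,
) -> RegressorSet:
    """Lagged regressors from an interaction trace (both estimates needed)."""
    rows = sorted(records, key=lambda r: r.trial)
    for r in rows:
        if r.estimate is None or r.partner_estimate is None:
            raise ValueError(
                f"trial {r.trial}: interaction records need both estimates"
            )
    y, dot, atyp, sim = [], [], [], []
    for prev, cur in zip(rows[:-1], rows[1:]):
        y.append(float(cur.estimate))
        dot.append(float(cur.dot_count))
        atyp.append(
            compute_atyp(prev.partner_estimate, prev.dot_count, reference_weight)
        )
        sim.append(
            compute_sim(
                prev.estimate, prev.partner_estimate, prev.dot_count, w_i_pre, w_p_pre
            )
        )
    return RegressorSet(
        np.asarray(y),
        np.asarray(dot),
        np.asarray(atyp),
        np.asarray(sim),
        w_i_pre,
        w_p_pre,
        reference_weight,
    )


@dataclass
class DecompConfig:
    """Sampler settings. Defaults mirror the published run (four chains of
    20,000 iterations, half discarded, thinned by 50 -> 200 kept per
    chain); tests and quick analyses should pass something smaller."""

    chains: int = 4
    draws: int = 200
    burnin: int = 10_000
    thin: int = 50
    # tight by design: Baseline is anchored at the pre-phase weight so the
    # time-varying coefficients, not the intercept, absorb social influence
    sigma_baseline: float = 0.02
    init_state_sd: float = 0.2
    scale_upper: float = 2.0
    sigma_eps_upper: float = 10.0


@dataclass
class DecompositionPosterior:
    model_tag: str
    participant_id: str
    regressors: RegressorSet
    params: Dict[str, np.ndarray]  # name -> (chains, draws)
    pointwise_loglik: np.ndarray  # (chains*draws, n_trials)
    state_draws: Dict[str, np.ndarray]  # component path -> (chains*draws, n)
    diagnostics: pd.DataFrame
    reliable: bool
    config: DecompConfig

    @property
    def mean_coef_sim(self) -> float:
        """Across-trial mean of the posterior-mean Sim-coefficient path."""
        if "coef_sim" not in self.state_draws:
            raise ValueError(f"model {self.model_tag!r} has no Sim component")
        return float(np.mean(self.state_draws["coef_sim"]))

    def posterior_mean_params(self) -> Dict[str, float]:
        return {k: float(np.mean(v)) for k, v in self.params.items()}


def _build_ssm(
    reg: RegressorSet, components: frozenset, cfg: DecompConfig
) -> Tuple[Optional[_ssm.TimeVaryingSSM], List[str], Dict[str, slice]]:
    """Assemble the time-varying SSM for a model variant.

    Returns (ssm or None for the null model, ordered scale-parameter names
    excluding sigma_eps, mapping of component -> state index)."""
    n = reg.n_trials
    blocks: List[Tuple[str, int]] = []
    if "baseline" in components:
        blocks.append(("baseline", 1))
    if "sim" in components:
        blocks.append(("sim", 2))
    if "atyp" in components:
        blocks.append(("atyp", 2))
    if not blocks:
        return None, [], {}
    m = sum(sz for _, sz in blocks)
    Z = np.zeros((n, m))
    T = np.zeros((m, m))
    a1 = np.zeros(m)
    P1 = np.zeros(m)
    idx: Dict[str, slice] = {}
    pos = 0
    for name, sz in blocks:
        sl = slice(pos, pos + sz)
        idx[name] = sl
        if name == "baseline":
            Z[:, pos] = reg.dot
            T[pos, pos] = 1.0
            a1[pos] = reg.w_i_pre
            P1[pos] = cfg.sigma_baseline**2
        else:
            x = reg.sim if name == "sim" else reg.atyp
            Z[:, pos] = x * reg.dot
            # local linear trend: coef += gamma, gamma random walk
            T[pos, pos] = 1.0
            T[pos, pos + 1] = 1.0
            T[pos + 1, pos + 1] = 1.0
            P1[pos] = cfg.init_state_sd**2
            P1[pos + 1] = cfg.init_state_sd**2
        pos += sz
    names = []
    for name, _ in blocks:
        if name != "baseline":
            names += [f"sigma_coef_{name}", f"sigma_gamma_{name}"]
    return _ssm.TimeVaryingSSM(Z, T, a1, P1), names, idx


def _q_diag(
    theta: Dict[str, float], idx: Dict[str, slice], m: int
) -> np.ndarray:
    q = np.zeros(m)
    for name in ("sim", "atyp"):
        if name in idx:
            sl = idx[name]
            q[sl.start] = theta[f"sigma_coef_{name}"] ** 2
            q[sl.start + 1] = theta[f"sigma_gamma_{name}"] ** 2
    return q


def fit_decomposition(
    regressors: RegressorSet,
    mcmc_config: Optional[DecompConfig] = None,
    seed: int = 0,
    model: str = "full",
    participant_id: str = "",
    min_trials: int = 20,
) -> DecompositionPosterior:
    """Posterior of one model variant for one interaction session.

    Scale parameters carry uniform priors truncated above; the states are
    marginalised during sampling and re-drawn by FFBS for each kept draw.
    The pointwise one-step predictive log-densities are stored for WAIC.
    """
    if model not in _COMPONENTS:
        raise ValueError(f"unknown model tag {model!r}")
    if regressors.n_trials < min_trials - 1:
        raise ValueError(
            f"session has {regressors.n_trials + 1} usable interaction trials; "
            f"need at least {min_trials}"
        )
    cfg = mcmc_config or DecompConfig()
    reg = regressors
    components = _COMPONENTS[model]
    ssm, scale_names, idx = _build_ssm(reg, components, cfg)
    all_names = scale_names + ["sigma_eps"]
    n = reg.n_trials
    n_keep = cfg.draws
    seeds = np.random.SeedSequence(seed).spawn(cfg.chains)

    params_out = {name: np.empty((cfg.chains, n_keep)) for name in all_names}
    pointwise = np.empty((cfg.chains, n_keep, n))
    state_names = []
    if "baseline" in components:
        state_names.append("baseline")
    if "sim" in components:
        state_names += ["coef_sim", "gamma_sim"]
    if "atyp" in components:
        state_names += ["coef_atyp", "gamma_atyp"]
    states_out = {name: np.empty((cfg.chains, n_keep, n)) for name in state_names}

    null_resid = reg.y - reg.w_i_pre * reg.dot  # used only by the null model

    for c, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        theta: Dict[str, float] = {}
        for name in scale_names:
            theta[name] = 0.05 * math.exp(float(rng.normal(0.0, 0.3)))
        theta["sigma_eps"] = max(
            0.5, 0.5 * float(np.std(null_resid)) * math.exp(float(rng.normal(0.0, 0.2)))
        )
        bank = _mcmc.ScaleBank()

        def upper(name: str) -> float:
            return cfg.sigma_eps_upper if name == "sigma_eps" else cfg.scale_upper

        def loglik(th: Dict[str, float]) -> Tuple[float, np.ndarray]:
            se = th["sigma_eps"]
            if ssm is None:
                pw = (
                    -0.5 * (math.log(2 * math.pi) + 2 * math.log(se))
                    - 0.5 * (null_resid / se) ** 2
                )
                return float(np.sum(pw)), pw
            ll, pw, _, _ = ssm.filter(reg.y, _q_diag(th, idx, ssm.m), se**2)
            return ll, pw

        cur_ll, cur_pw = loglik(theta)
        total = cfg.burnin + n_keep * cfg.thin
        kept = 0
        for it in range(total):
            if it == cfg.burnin:
                bank.freeze()
            for name in all_names:
                def lp(x: float, name=name) -> float:
                    if not 0.0 < x <= upper(name):
                        return -math.inf
                    trial = dict(theta)
                    trial[name] = x
                    return loglik(trial)[0]

                new, new_ll, acc = _mcmc.mh_step(
                    theta[name], lp, cur_ll, bank[name], rng, log_space=True
                )
                if acc:
                    theta[name] = new
                    cur_ll = new_ll
            if it >= cfg.burnin and (it - cfg.burnin) % cfg.thin == 0:
                _, cur_pw = loglik(theta)
                for name in all_names:
                    params_out[name][c, kept] = theta[name]
                pointwise[c, kept] = cur_pw
                if ssm is not None:
                    path = ssm.ffbs(
                        reg.y, _q_diag(theta, idx, ssm.m), theta["sigma_eps"] ** 2, rng
                    )
                    if "baseline" in idx:
                        states_out["baseline"][c, kept] = path[:, idx["baseline"].start]
                    if "sim" in idx:
                        states_out["coef_sim"][c, kept] = path[:, idx["sim"].start]
                        states_out["gamma_sim"][c, kept] = path[:, idx["sim"].start + 1]
                    if "atyp" in idx:
                        states_out["coef_atyp"][c, kept] = path[:, idx["atyp"].start]
                        states_out["gamma_atyp"][c, kept] = path[
                            :, idx["atyp"].start + 1
                        ]
                kept += 1

    import arviz as az

    diag_rows = []
    reliable = True
    for name in all_names:
        draws = params_out[name]
        rhat = _safe_rhat(az, draws)
        diag_rows.append({"parameter": name, "rhat": rhat, "ess": _safe_ess(az, draws)})
        reliable &= not (rhat > RHAT_THRESHOLD)
    if not reliable:
        warnings.warn(
            f"decomposition fit ({model}): R-hat > {RHAT_THRESHOLD}; "
            "result marked unreliable",
            stacklevel=2,
        )
    return DecompositionPosterior(
        model_tag=model,
        participant_id=participant_id,
        regressors=reg,
        params=params_out,
        pointwise_loglik=pointwise.reshape(cfg.chains * n_keep, n),
        state_draws={k: v.reshape(cfg.chains * n_keep, n) for k, v in states_out.items()},
        diagnostics=pd.DataFrame(diag_rows),
        reliable=reliable,
        config=cfg,
    )


def _safe_rhat(az, draws: np.ndarray) -> float:
    if draws.shape[0] < 2 or draws.shape[1] < 4:
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.rhat(draws))


def _safe_ess(az, draws: np.ndarray) -> float:
    if draws.shape[1] < 4:
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.ess(draws))


@dataclass(frozen=True)
class WaicResult:
    model_tag: str
    lppd: float
    p_waic: float
    waic: float
    n_trials: int


def compute_waic(
    pointwise_loglik: np.ndarray, model_tag: str = ""
) -> WaicResult:
    """WAIC from a (draws x trials) pointwise log-likelihood matrix:
    ``lppd = sum_t log mean_s exp(ll)``, ``p_waic = sum_t var_s(ll)``
    (sample variance), ``waic = -2 (lppd - p_waic)``."""
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2 or ll.shape[0] < 2 or ll.shape[1] < 1:
        raise ValueError("need a (draws >= 2) x (trials >= 1) matrix")
    if not np.all(np.isfinite(ll)):
        raise ValueError("non-finite pointwise log-likelihood")
    from scipy.special import logsumexp

    s = ll.shape[0]
    lppd = float(np.sum(logsumexp(ll, axis=0) - math.log(s)))
    p_waic = float(np.sum(np.var(ll, axis=0, ddof=1)))
    return WaicResult(model_tag, lppd, p_waic, -2.0 * (lppd - p_waic), ll.shape[1])


def model_ladder_fit(
    regressors: RegressorSet,
    mcmc_config: Optional[DecompConfig] = None,
    seed: int = 0,
    participant_id: str = "",
) -> List[WaicResult]:
    """Fit the full model and the seven reduced variants, returning their
    WAIC results ranked best (lowest) first."""
    results = []
    for i, tag in enumerate(MODEL_TAGS):
        post = fit_decomposition(
            regressors,
            mcmc_config=mcmc_config,
            seed=seed + i,
            model=tag,
            participant_id=participant_id,
        )
        results.append(compute_waic(post.pointwise_loglik, model_tag=tag))
    return sorted(results, key=lambda r: r.waic)


def posterior_predictive_check(posterior: DecompositionPosterior) -> float:
    """Pearson correlation between observed estimates and predictions from
    the posterior-mean parameters (smoothed states). Returns NaN when the
    predictions have zero variance."""
    reg = posterior.regressors
    cfg = posterior.config
    theta = posterior.posterior_mean_params()
    components = _COMPONENTS[posterior.model_tag]
    ssm, _, idx = _build_ssm(reg, components, cfg)
    if ssm is None:
        pred = reg.w_i_pre * reg.dot
    else:
        sm = ssm.smoother(reg.y, _q_diag(theta, idx, ssm.m), theta["sigma_eps"] ** 2)
        pred = np.sum(ssm.Z * sm, axis=1)
    if np.std(pred) == 0 or np.std(reg.y) == 0:
        return float("nan")
    return float(np.corrcoef(reg.y, pred)[0, 1])


def simulate_session_records(
    dots: Sequence[int],
    partner_estimates: Sequence[int],
    w_i_pre: float,
    w_p_pre: float,
    coef_sim: Sequence[float],
    coef_atyp: Sequence[float],
    baseline: float,
    sigma_eps: float,
    seed: int,
    participant_id: str = "SIM",
    phase: str = "interaction",
    reference_weight: float = REFERENCE_WEIGHT,
) -> List[TrialRecord]:
    """Generate an interaction trace whose participant estimates follow the
    decomposition model exactly (given a fixed partner-estimate stream).

    ``coef_sim``/``coef_atyp`` give the coefficient trajectory for trials
    2..T (length ``len(dots) - 1``). The first trial uses the pre weight.
    Estimates are rounded and floored at 1 as in the experiments.
    """
    rng = np.random.default_rng(seed)
    dots = [int(d) for d in dots]
    est_p = [int(e) for e in partner_estimates]
    if len(est_p) != len(dots):
        raise ValueError("partner_estimates must match dots in length")
    if len(coef_sim) != len(dots) - 1 or len(coef_atyp) != len(dots) - 1:
        raise ValueError("coefficient paths must have length len(dots) - 1")
    records: List[TrialRecord] = []
    est_prev = clip_estimate(round_half_away(w_i_pre * dots[0]))
    records.append(TrialRecord(participant_id, phase, 1, dots[0], est_prev, est_p[0]))
    for t in range(1, len(dots)):
        at = compute_atyp(est_p[t - 1], dots[t - 1], reference_weight)
        st = compute_sim(est_prev, est_p[t - 1], dots[t - 1], w_i_pre, w_p_pre)
        w_t = baseline + coef_atyp[t - 1] * at + coef_sim[t - 1] * st
        val = w_t * dots[t] + float(rng.normal(0.0, sigma_eps)) if sigma_eps > 0 else w_t * dots[t]
        est = clip_estimate(round_half_away(val))
        records.append(
            TrialRecord(participant_id, phase, t + 1, dots[t], est, est_p[t])
        )
        est_prev = est
    return records
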