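"""Hierarchical Bayesian local-level model of estimation-weight stability.

Each participant's per-trial implied weight (estimate / dot count) is
modelled as a latent Gaussian random walk observed with noise; the
system-noise SD ``sigma_mu`` is the per-participant stability index (smaller
= more stable). Both SDs are tied across participants by truncated-normal
group distributions. Inference is Metropolis-within-Gibbs with the latent
path marginalised by a Kalman filter, which makes the sampler a
low-dimensional random walk over the SD parameters.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _mcmc, _ssm
from .synthetic_data import TrialRecord

MIN_SERIES_LENGTH = 8
RHAT_THRESHOLD = 1.05


@dataclass(frozen=True)
class WeightSeries:
    participant_id: str
    phase_label: str
    w_obs: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.w_obs, dtype=float)
        if not np.all(np.isfinite(w)) or np.any(w <= 0):
            raise ValueError("w_obs must be finite and positive")


@dataclass
class MCMCConfig:
    """Sampler settings; defaults follow the published analysis (four
    chains, 1000 kept draws each after a 500-iteration burn-in)."""

    chains: int = 4
    draws: int = 1000
    burnin: int = 500
    thin: int = 1
    path_draws: int = 100  # latent-path draws stored per chain


@dataclass
class StabilityPriors:
    sd_upper: float = 5.0
    mean_lower: float = -5.0
    mean_upper: float = 5.0
    mu1_prior_sd: float = 0.5


@dataclass
class StabilityPosterior:
    participant_ids: List[str]
    phase_label: str
    sigma_mu: np.ndarray  # (chains, draws, n_participants)
    sigma_obs: np.ndarray  # (chains, draws, n_participants)
    group: Dict[str, np.ndarray]  # name -> (chains, draws)
    latent_paths: Dict[str, np.ndarray]  # id -> (n_path_draws, T)
    summary: pd.DataFrame
    diagnostics: pd.DataFrame
    reliable: bool

    def sigma_mean(self, participant_id: str) -> float:
        row = self.summary.loc[self.summary.participant_id == participant_id]
        if row.empty:
            raise KeyError(participant_id)
        return float(row.sigma_mean.iloc[0])


def build_weight_series(
    records: Sequence[TrialRecord],
    min_trials: int = MIN_SERIES_LENGTH,
) -> List[WeightSeries]:
    """Per-(participant, phase) observed weight series, in trial order.

    Trials with a missing estimate are removed before indexing; series
    shorter than ``min_trials`` usable trials are excluded with a warning.
    """
    groups: Dict[Tuple[str, str], List[TrialRecord]] = {}
    order: List[Tuple[str, str]] = []
    for r in records:
        key = (r.participant_id, r.phase)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(r)
    out: List[WeightSeries] = []
    for key in order:
        rows = sorted(groups[key], key=lambda r: r.trial)
        w = [r.estimate / r.dot_count for r in rows if r.estimate is not None]
        if len(w) < min_trials:
            warnings.warn(
                f"participant {key[0]} phase {key[1]}: only {len(w)} usable "
                f"trials (< {min_trials}); series excluded",
                stacklevel=2,
            )
            continue
        out.append(WeightSeries(key[0], key[1], np.asarray(w)))
    return out


def _init_values(y: np.ndarray, jitter: np.random.Generator) -> Tuple[float, float]:
    s_obs = max(0.3 * float(np.std(y)), 0.02)
    s_mu = max(0.3 * float(np.std(np.diff(y))), 0.02) if len(y) > 1 else 0.05
    f = math.exp(float(jitter.normal(0.0, 0.2)))
    return s_obs * f, s_mu / f


def fit_stability(
    series: Sequence[WeightSeries],
    mcmc_config: Optional[MCMCConfig] = None,
    seed: int = 0,
    priors: Optional[StabilityPriors] = None,
    hierarchical: Optional[bool] = None,
) -> StabilityPosterior:
    """Sample the joint posterior of the stability model for one phase.

    With two or more participants the group-level tie is used; a single
    series falls back to independent uniform priors on the SDs. Results are
    reproducible given ``seed``. If any scalar parameter has R-hat above
    1.05 the posterior is marked ``reliable=False``.
    """
    if len(series) == 0:
        raise ValueError("no weight series supplied")
    phase = series[0].phase_label
    cfg = mcmc_config or MCMCConfig()
    pri = priors or StabilityPriors()
    if hierarchical is None:
        hierarchical = len(series) >= 2

    ids = [s.participant_id for s in series]
    ys = [np.asarray(s.w_obs, dtype=float) for s in series]
    n_part = len(series)
    n_keep = cfg.draws
    seeds = np.random.SeedSequence(seed).spawn(cfg.chains)

    sig_mu_out = np.empty((cfg.chains, n_keep, n_part))
    sig_obs_out = np.empty((cfg.chains, n_keep, n_part))
    group_out = {
        name: np.empty((cfg.chains, n_keep))
        for name in ("gmu_obs", "gsig_obs", "gmu_mu", "gsig_mu")
    }
    path_keep = min(cfg.path_draws, n_keep)
    path_stride = max(1, n_keep // path_keep)
    paths: Dict[str, List[np.ndarray]] = {pid: [] for pid in ids}

    for c, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        s_obs = np.empty(n_part)
        s_mu = np.empty(n_part)
        for i, y in enumerate(ys):
            s_obs[i], s_mu[i] = _init_values(y, rng)
        gmu_obs, gsig_obs = float(np.mean(s_obs)), max(float(np.std(s_obs)), 0.05)
        gmu_mu, gsig_mu = float(np.mean(s_mu)), max(float(np.std(s_mu)), 0.05)
        bank = _mcmc.ScaleBank()

        ll = np.array(
            [
                _ssm.local_level_loglik(y, s_obs[i], s_mu[i], y[0], pri.mu1_prior_sd)
                for i, y in enumerate(ys)
            ]
        )

        def sd_prior(x: float, gmu: float, gsig: float) -> float:
            if not 0.0 < x <= pri.sd_upper:
                return -math.inf
            if hierarchical:
                return _mcmc.log_truncnorm0(x, gmu, gsig)
            return 0.0

        total_iters = cfg.burnin + n_keep * cfg.thin
        kept = 0
        for it in range(total_iters):
            if it == cfg.burnin:
                bank.freeze()
            for i, y in enumerate(ys):
                # observation-noise SD
                def lp_obs(x: float, i=i, y=y) -> float:
                    pr = sd_prior(x, gmu_obs, gsig_obs)
                    if not math.isfinite(pr):
                        return -math.inf
                    return (
                        _ssm.local_level_loglik(y, x, s_mu[i], y[0], pri.mu1_prior_sd)
                        + pr
                    )

                cur_lp = ll[i] + sd_prior(s_obs[i], gmu_obs, gsig_obs)
                new, new_lp, acc = _mcmc.mh_step(
                    s_obs[i], lp_obs, cur_lp, bank[f"s_obs_{i}"], rng, log_space=True
                )
                if acc:
                    s_obs[i] = new
                    ll[i] = new_lp - sd_prior(new, gmu_obs, gsig_obs)

                # system-noise SD (the stability index)
                def lp_mu(x: float, i=i, y=y) -> float:
                    pr = sd_prior(x, gmu_mu, gsig_mu)
                    if not math.isfinite(pr):
                        return -math.inf
                    return (
                        _ssm.local_level_loglik(y, s_obs[i], x, y[0], pri.mu1_prior_sd)
                        + pr
                    )

                cur_lp = ll[i] + sd_prior(s_mu[i], gmu_mu, gsig_mu)
                new, new_lp, acc = _mcmc.mh_step(
                    s_mu[i], lp_mu, cur_lp, bank[f"s_mu_{i}"], rng, log_space=True
                )
                if acc:
                    s_mu[i] = new
                    ll[i] = new_lp - sd_prior(new, gmu_mu, gsig_mu)

            if hierarchical:
                gmu_obs, gsig_obs = _update_group(
                    s_obs, gmu_obs, gsig_obs, bank, "obs", pri, rng
                )
                gmu_mu, gsig_mu = _update_group(
                    s_mu, gmu_mu, gsig_mu, bank, "mu", pri, rng
                )

            if it >= cfg.burnin and (it - cfg.burnin) % cfg.thin == 0:
                sig_obs_out[c, kept] = s_obs
                sig_mu_out[c, kept] = s_mu
                group_out["gmu_obs"][c, kept] = gmu_obs
                group_out["gsig_obs"][c, kept] = gsig_obs
                group_out["gmu_mu"][c, kept] = gmu_mu
                group_out["gsig_mu"][c, kept] = gsig_mu
                if kept % path_stride == 0:
                    for i, y in enumerate(ys):
                        paths[ids[i]].append(
                            _ssm.local_level_ffbs(
                                y, s_obs[i], s_mu[i], y[0], pri.mu1_prior_sd, rng
                            )
                        )
                kept += 1

    latent_paths = {pid: np.asarray(p) for pid, p in paths.items()}
    summary, diagnostics, reliable = _summarise(
        ids, phase, sig_mu_out, sig_obs_out, group_out if hierarchical else {}
    )
    if not reliable:
        warnings.warn(
            f"stability fit for phase {phase!r}: R-hat > {RHAT_THRESHOLD} for "
            "some parameters; result marked unreliable",
            stacklevel=2,
        )
    return StabilityPosterior(
        ids,
        phase,
        sig_mu_out,
        sig_obs_out,
        group_out if hierarchical else {},
        latent_paths,
        summary,
        diagnostics,
        reliable,
    )


def _update_group(
    values: np.ndarray,
    gmu: float,
    gsig: float,
    bank: _mcmc.ScaleBank,
    tag: str,
    pri: StabilityPriors,
    rng: np.random.Generator,
) -> Tuple[float, float]:
    def loglik_group(mu: float, sig: float) -> float:
        if not (pri.mean_lower <= mu <= pri.mean_upper and 0.0 < sig <= pri.sd_upper):
            return -math.inf
        return sum(_mcmc.log_truncnorm0(v, mu, sig) for v in values)

    cur = loglik_group(gmu, gsig)
    gmu, cur, _ = _mcmc.mh_step(
        gmu, lambda m: loglik_group(m, gsig), cur, bank[f"gmu_{tag}"], rng
    )
    gsig, _, _ = _mcmc.mh_step(
        gsig,
        lambda s: loglik_group(gmu, s),
        cur,
        bank[f"gsig_{tag}"],
        rng,
        log_space=True,
    )
    return gmu, gsig


def _summarise(
    ids: List[str],
    phase: str,
    sig_mu: np.ndarray,
    sig_obs: np.ndarray,
    group: Dict[str, np.ndarray],
) -> Tuple[pd.DataFrame, pd.DataFrame, bool]:
    import arviz as az

    rows = []
    diag_rows = []
    reliable = True
    for i, pid in enumerate(ids):
        draws = sig_mu[:, :, i]
        rhat = _safe_rhat(az, draws)
        ess = _safe_ess(az, draws)
        flat = draws.reshape(-1)
        rows.append(
            {
                "participant_id": pid,
                "phase": phase,
                "sigma_mean": float(np.mean(flat)),
                "sigma_l95": float(np.quantile(flat, 0.025)),
                "sigma_u95": float(np.quantile(flat, 0.975)),
                "sigma_obs_mean": float(np.mean(sig_obs[:, :, i])),
                "rhat": rhat,
            }
        )
        diag_rows.append({"parameter": f"sigma_mu[{pid}]", "rhat": rhat, "ess": ess})
        obs_rhat = _safe_rhat(az, sig_obs[:, :, i])
        diag_rows.append(
            {
                "parameter": f"sigma_obs[{pid}]",
                "rhat": obs_rhat,
                "ess": _safe_ess(az, sig_obs[:, :, i]),
            }
        )
        # NaN R-hat (too few chains/draws to assess) does not trip the flag
        reliable &= not (rhat > RHAT_THRESHOLD) and not (obs_rhat > RHAT_THRESHOLD)
    for name, draws in group.items():
        rhat = _safe_rhat(az, draws)
        diag_rows.append({"parameter": name, "rhat": rhat, "ess": _safe_ess(az, draws)})
        reliable &= not (rhat > RHAT_THRESHOLD)
    return pd.DataFrame(rows), pd.DataFrame(diag_rows), bool(reliable)


def _safe_rhat(az, draws: np.ndarray) -> float:
    if draws.shape[0] < 2 or draws.shape[1] < 4:
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        val = float(az.rhat(draws[None] if draws.ndim == 1 else draws))
    return val


def _safe_ess(az, draws: np.ndarray) -> float:
    if draws.shape[0] < 1 or draws.shape[1] < 4:
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.ess(draws))


def delta_sigma(pre: StabilityPosterior, post: StabilityPosterior) -> pd.Series:
    """Per-participant change in the stability index (post minus pre);
    negative values indicate stabilization."""
    if set(pre.participant_ids) != set(post.participant_ids):
        raise ValueError("pre and post posteriors cover different participants")
    deltas = {
        pid: post.sigma_mean(pid) - pre.sigma_mean(pid)
        for pid in pre.participant_ids
    }
    return pd.Series(deltas, name="delta_sigma")
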