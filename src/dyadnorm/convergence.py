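"""Pair-level convergence analyses and routine effect-size statistics.

Covers the absolute weight-difference comparison for real versus shuffled
(non-partner) pairs, the ordering-accuracy score, paired/Welch/one-sample
t-tests with Cohen's d, the 2x2 between-participants ANOVA with partial
eta squared, and Holm-Bonferroni correction.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

Pair = Tuple[str, str]


@dataclass(frozen=True)
class PairAssignment:
    participant_ids: Tuple[str, ...]
    real_pairs: Tuple[Pair, ...]

    def __post_init__(self) -> None:
        ids = self.participant_ids
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate participant ids")
        seen = set()
        for a, b in self.real_pairs:
            if a == b:
                raise ValueError(f"self-pair {a!r}")
            for x in (a, b):
                if x in seen:
                    raise ValueError(f"participant {x!r} appears in multiple pairs")
                seen.add(x)


def abs_weight_diff(
    pair: Pair, weights_by_phase: Dict[str, Dict[str, float]]
) -> Dict[str, float]:
    """Per-phase absolute difference in fitted weights for one pair.

    ``weights_by_phase`` maps phase label -> {participant_id: weight}.
    """
    a, b = pair
    out = {}
    for phase, weights in weights_by_phase.items():
        if a not in weights or b not in weights:
            missing = a if a not in weights else b
            raise KeyError(f"no weight for participant {missing!r} in phase {phase!r}")
        out[phase] = abs(weights[a] - weights[b])
    return out


def make_shuffled_pairs(
    ids: Sequence[str], real_pairs: Iterable[Pair]
) -> List[Pair]:
    """All unordered pairs of ids excluding the real pairings."""
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate participant ids")
    real = {frozenset(p) for p in real_pairs}
    return [p for p in combinations(ids, 2) if frozenset(p) not in real]


def ordering_accuracy(records) -> float:
    """Spearman rank correlation between estimates and true dot counts
    (average-rank ties). Returns NaN for constant estimates; needs >= 5
    trials with estimates."""
    rows = [(r.dot_count, r.estimate) for r in records if r.estimate is not None]
    if len(rows) < 5:
        raise ValueError("need at least 5 trials with estimates")
    dots = np.array([d for d, _ in rows], dtype=float)
    ests = np.array([e for _, e in rows], dtype=float)
    if np.std(ests) == 0 or np.std(dots) == 0:
        return float("nan")
    rho = stats.spearmanr(ests, dots).statistic
    return float(rho)


@dataclass(frozen=True)
class TestResult:
    t: float
    df: float
    p: float
    cohens_d: float
    design: str


def paired_t(x: Sequence[float], y: Sequence[float]) -> TestResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("paired test needs two equal-length samples, n >= 2")
    diff = x - y
    sd = float(np.std(diff, ddof=1))
    d = float(np.mean(diff)) / sd if sd > 0 else 0.0
    if sd == 0:
        return TestResult(0.0, len(x) - 1, 1.0, 0.0, "paired")
    res = stats.ttest_rel(x, y)
    return TestResult(float(res.statistic), float(res.df), float(res.pvalue), d, "paired")


def welch_t(x: Sequence[float], y: Sequence[float]) -> TestResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("Welch test needs n >= 2 per group")
    res = stats.ttest_ind(x, y, equal_var=False)
    # Cohen's d with the pooled SD convention
    nx, ny = len(x), len(y)
    pooled = math.sqrt(
        ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / (nx + ny - 2)
    )
    d = (float(np.mean(x)) - float(np.mean(y))) / pooled if pooled > 0 else 0.0
    return TestResult(float(res.statistic), float(res.df), float(res.pvalue), d, "welch")


def one_sample_t(x: Sequence[float], popmean: float = 0.0) -> TestResult:
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("one-sample test needs n >= 2")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        t = 0.0 if np.mean(x) == popmean else math.inf
        return TestResult(t, len(x) - 1, 1.0 if t == 0 else 0.0, 0.0, "one-sample")
    res = stats.ttest_1samp(x, popmean)
    d = (float(np.mean(x)) - popmean) / sd
    return TestResult(
        float(res.statistic), float(len(x) - 1), float(res.pvalue), d, "one-sample"
    )


def effect_stats(
    x: Sequence[float],
    y: Optional[Sequence[float]] = None,
    design: str = "paired",
    popmean: float = 0.0,
) -> TestResult:
    """Dispatch to the t-test variant named by ``design``."""
    if design == "paired":
        return paired_t(x, y)
    if design == "welch":
        return welch_t(x, y)
    if design == "one-sample":
        return one_sample_t(x, popmean)
    raise ValueError(f"unknown design {design!r}")


@dataclass(frozen=True)
class AnovaEffect:
    effect: str
    F: float
    df_num: float
    df_den: float
    p: float
    partial_eta_sq: float


def anova_2x2(groups: Dict[Tuple[str, str], Sequence[float]]) -> List[AnovaEffect]:
    """Two-way between-participants ANOVA (type II) on a 2x2 design.

    ``groups`` maps (levelA, levelB) -> observations. Returns the two main
    effects and the interaction, each with partial eta squared.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    if len(groups) != 4:
        raise ValueError("anova_2x2 expects exactly 4 cells")
    rows = []
    for (fa, fb), values in groups.items():
        values = np.asarray(values, dtype=float)
        if len(values) < 2:
            raise ValueError(f"cell ({fa}, {fb}) needs n >= 2")
        for v in values:
            rows.append({"a": fa, "b": fb, "y": float(v)})
    df = pd.DataFrame(rows)
    fit = ols("y ~ C(a) * C(b)", data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    ss_resid = float(table.loc["Residual", "sum_sq"])
    df_resid = float(table.loc["Residual", "df"])
    out = []
    for label, name in (
        ("C(a)", "a"),
        ("C(b)", "b"),
        ("C(a):C(b)", "a:b"),
    ):
        ss = float(table.loc[label, "sum_sq"])
        out.append(
            AnovaEffect(
                effect=name,
                F=float(table.loc[label, "F"]),
                df_num=float(table.loc[label, "df"]),
                df_den=df_resid,
                p=float(table.loc[label, "PR(>F)"]),
                partial_eta_sq=ss / (ss + ss_resid),
            )
        )
    return out


def holm_bonferroni(p_values: Sequence[float]) -> List[float]:
    """Holm-Bonferroni adjusted p-values (never below the raw values)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return []
    adjusted = multipletests(p, method="holm")[1]
    return [float(max(a, raw)) for a, raw in zip(adjusted, p)]
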