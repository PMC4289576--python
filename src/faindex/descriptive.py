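"""Non-survival statistics: Spearman rank correlations, exact Fisher tests
(2x2 and 2xk), Welch t-tests, per-class prevalence profiles, and the
wave-1 -> wave-2 class-transition summary.

All printed percentages use half-away-from-zero rounding to one decimal and
complete-case denominators; every cell is reported with its
numerator/denominator pair so percentages are reproducible.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._rounding import percent
from .questionnaire import FA_CLASS_ORDER

__all__ = [
    "CorrelationResult",
    "FisherResult",
    "WelchResult",
    "TransitionSummary",
    "spearman",
    "fisher_exact",
    "welch_t",
    "transition_summary",
    "class_profile_table",
    "ENUMERATION_LIMIT",
]

POOLED_ORIGINS = ("Robust", "Transient", "Frail")
TRANSITION_DESTINATIONS = (
    "Robust", "Transient", "Frail", "dead", "lost", "refused", "unscorable",
)

ENUMERATION_LIMIT = 200  # max table total for exact 2xk enumeration


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    degenerate: bool = False  # zero variance in a vector -> rho undefined


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with mid-ranks for ties.

    Complete-case: pairs with a missing value in either vector are dropped;
    at least 3 complete pairs are required. p-value via the t
    approximation. Zero variance in either vector makes rho undefined
    (NaN, ``degenerate`` flag).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired (equal length)")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(rho=float("nan"), p_value=float("nan"), n=n, degenerate=True)
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(rho=float(rho), p_value=float(p), n=n)


# ---------------------------------------------------------------------------
# Fisher exact tests
# ---------------------------------------------------------------------------


@dataclass
class FisherResult:
    p_value: float
    method: str  # "hypergeometric" | "enumeration" | "monte_carlo"
    mc_error: Optional[float] = None  # one SE of the MC p estimate
    degenerate: bool = False  # empty margin -> p = 1 by convention


def _log_factorials(n: int) -> np.ndarray:
    return np.concatenate([[0.0], np.cumsum(np.log(np.arange(1, n + 1)))])


def _table_log_prob(table: np.ndarray, lf: np.ndarray) -> float:
    """Log probability of a 2xk table under fixed margins (multivariate
    hypergeometric)."""
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = int(table.sum())
    lp = lf[rows].sum() + lf[cols].sum() - lf[n] - lf[table.ravel()].sum()
    return float(lp)


def fisher_exact(
    table,
    enumeration_limit: int = ENUMERATION_LIMIT,
    mc_draws: int = 100_000,
    random_state: int = 20140001,
) -> FisherResult:
    """Two-sided exact test of independence for a 2xk contingency table.

    The two-sided p sums the null probabilities of all tables (with the
    observed margins) no more probable than the observed one. 2x2 uses the
    hypergeometric enumeration; 2xk enumerates exactly while the grand
    total is at most ``enumeration_limit`` and otherwise samples tables
    with fixed margins (Monte-Carlo exact test with reported MC error and a
    fixed substream seed).
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[0] != 2 or t.shape[1] < 2:
        raise ValueError("expected a 2xk table with k >= 2")
    if np.any(t < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(t.sum(axis=1) == 0) or np.any(t.sum(axis=0) == 0):
        return FisherResult(p_value=1.0, method="degenerate", degenerate=True)
    if t.shape[1] == 2:
        _, p = stats.fisher_exact(t, alternative="two-sided")
        return FisherResult(p_value=float(p), method="hypergeometric")

    n = int(t.sum())
    lf = _log_factorials(n)
    lp_obs = _table_log_prob(t, lf)
    cols = t.sum(axis=0)
    r1 = int(t.sum(axis=1)[0])
    tol = 1e-9
    if n <= enumeration_limit:
        # enumerate first rows (x_1..x_k) with sum r1, 0 <= x_i <= col_i
        k = t.shape[1]
        total = 0.0
        ranges = [range(0, min(int(c), r1) + 1) for c in cols[:-1]]
        for head in itertools.product(*ranges):
            rem = r1 - sum(head)
            if rem < 0 or rem > cols[-1]:
                continue
            cand = np.vstack([np.array(list(head) + [rem]), cols - np.array(list(head) + [rem])])
            lp = _table_log_prob(cand, lf)
            if lp <= lp_obs + tol:
                total += math.exp(lp)
        return FisherResult(p_value=min(total, 1.0), method="enumeration")

    rng = np.random.default_rng(random_state)
    sampler = stats.random_table(t.sum(axis=1), cols)
    draws = sampler.rvs(mc_draws, random_state=rng).astype(int)
    # margins are fixed across draws, so only the cell term varies
    const = lf[t.sum(axis=1)].sum() + lf[cols].sum() - lf[n]
    lps = const - lf[draws].sum(axis=(1, 2))
    hits = lps <= lp_obs + tol
    p_hat = float(hits.mean())
    se = math.sqrt(max(p_hat * (1 - p_hat), 1.0 / mc_draws) / mc_draws)
    return FisherResult(p_value=p_hat, method="monte_carlo", mc_error=se)


# ---------------------------------------------------------------------------
# Welch t-test
# ---------------------------------------------------------------------------


@dataclass
class WelchResult:
    t: float
    df: float
    p_value: float


def welch_t(x, y) -> WelchResult:
    """Welch two-sample t-test with Satterthwaite degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 observations per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return WelchResult(t=0.0, df=float(len(x) + len(y) - 2), p_value=1.0)
        return WelchResult(t=float("inf"), df=float(len(x) + len(y) - 2), p_value=0.0)
    nx, ny = len(x), len(y)
    sx, sy = vx / nx, vy / ny
    t_stat = (x.mean() - y.mean()) / math.sqrt(sx + sy)
    df = (sx + sy) ** 2 / (sx**2 / (nx - 1) + sy**2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t_stat), df)
    return WelchResult(t=float(t_stat), df=float(df), p_value=float(p))


# ---------------------------------------------------------------------------
# Transition summary
# ---------------------------------------------------------------------------


@dataclass
class TransitionSummary:
    """Wave-1 pooled class x wave-2 outcome counts and row percentages."""

    counts: pd.DataFrame  # origins x destinations, integer counts
    row_percent: pd.DataFrame  # one-decimal row percentages

    def origin_n(self) -> pd.Series:
        return self.counts.sum(axis=1)


def transition_summary(w1_classes, w2_outcomes) -> TransitionSummary:
    """Cross-tabulate wave-1 pooled classes against wave-2 outcomes.

    Row percentages use each origin class's n as denominator, rounded half
    away from zero to one decimal. Unknown tokens raise ``ValueError``
    naming the offending value.
    """
    w1 = pd.Series(list(w1_classes), dtype=object)
    w2 = pd.Series(list(w2_outcomes), dtype=object)
    if len(w1) != len(w2):
        raise ValueError("wave-1 and wave-2 vectors must align")
    for v in w1.dropna().unique():
        if v not in POOLED_ORIGINS:
            raise ValueError(f"unknown wave-1 class token: {v!r}")
    for v in w2.dropna().unique():
        if v not in TRANSITION_DESTINATIONS:
            raise ValueError(f"unknown wave-2 outcome token: {v!r}")
    counts = (
        pd.crosstab(w1, w2)
        .reindex(index=list(POOLED_ORIGINS), columns=list(TRANSITION_DESTINATIONS), fill_value=0)
        .astype(int)
    )
    counts.index.name = "wave1_class"
    counts.columns.name = "wave2_outcome"
    row_n = counts.sum(axis=1)
    pct = counts.apply(
        lambda row: pd.Series(
            [percent(v, row_n[row.name]) for v in row], index=row.index
        ),
        axis=1,
    )
    return TransitionSummary(counts=counts, row_percent=pct)


# ---------------------------------------------------------------------------
# Class profile table
# ---------------------------------------------------------------------------

_PROFILE_COVARIATES = (
    "living_alone", "fair_poor_health", "chronic_pain", "depressed", "poor_vision",
)


def class_profile_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-class covariate prevalences and age summaries ("cases/n (%)" layout).

    One row per (class, characteristic); complete-case denominators are
    reported alongside counts. Age rows report mean/sd/min/max instead of a
    prevalence. An all-missing covariate yields denominator 0 and a NaN
    percentage (NA cell).
    """
    if "fa_class" not in cohort.columns:
        raise ValueError("cohort must be scored (fa_class column missing)")
    work = cohort[cohort["fa_class"].notna()]
    rows = []
    class_values = ["ALL"] + [c.value for c in FA_CLASS_ORDER]
    for cls in class_values:
        sub = work if cls == "ALL" else work[work["fa_class"] == cls]
        if "age" in sub.columns:
            age = sub["age"].dropna()
            rows.append(
                {"fa_class": cls, "characteristic": "age", "cases": None,
                 "n": int(len(age)),
                 "percent": None,
                 "mean": float(age.mean()) if len(age) else float("nan"),
                 "sd": float(age.std(ddof=1)) if len(age) > 1 else float("nan"),
                 "min": float(age.min()) if len(age) else float("nan"),
                 "max": float(age.max()) if len(age) else float("nan")}
            )
        if "sex" in sub.columns:
            known = sub["sex"].dropna()
            cases = int((known == "female").sum())
            rows.append(
                {"fa_class": cls, "characteristic": "female", "cases": cases,
                 "n": int(len(known)), "percent": percent(cases, len(known)),
                 "mean": None, "sd": None, "min": None, "max": None}
            )
        for cov in _PROFILE_COVARIATES:
            if cov not in sub.columns:
                continue
            known = sub[cov].dropna()
            cases = int(known.astype(bool).sum())
            rows.append(
                {"fa_class": cls, "characteristic": cov, "cases": cases,
                 "n": int(len(known)), "percent": percent(cases, len(known)),
                 "mean": None, "sd": None, "min": None, "max": None}
            )
    return pd.DataFrame(rows)
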