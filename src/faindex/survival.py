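"""Censored time-to-event machinery: product-limit / actuarial survival
estimates, the k-sample log-rank test, and proportional-hazards regression
with likelihood-ratio tests for the functional-class factor.

Drop-outs are treated as censored observations, never deleted; follow-up
is administratively censored at the study horizon (93 months by default in
the pipeline). The product-limit (Kaplan–Meier) estimator is the default
"life table" analysis; an actuarial (interval-based) estimator is also
exported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg

__all__ = [
    "KaplanMeierEstimate",
    "LogRankResult",
    "PHModelResult",
    "kaplan_meier",
    "actuarial_life_table",
    "log_rank_test",
    "ph_regression",
    "class_factor_lr_test",
    "ConvergenceError",
]


class ConvergenceError(RuntimeError):
    """Partial-likelihood maximization failed (e.g. monotone likelihood)."""


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


@dataclass
class KaplanMeierEstimate:
    """Right-continuous non-increasing step function S(t) with S(0) = 1."""

    times: np.ndarray  # event-time grid (0 prepended)
    survival: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    all_censored: bool = False

    def at(self, t) -> np.ndarray:
        """Evaluate S(t) (right-continuous) at arbitrary times."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t, side="right") - 1
        return self.survival[idx.clip(min=0)]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "n_at_risk": self.n_at_risk,
                "n_events": self.n_events,
            }
        )


def _check_sample(time, event) -> tuple:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.shape != event.shape:
        raise ValueError("time and event must have equal length")
    if len(time) == 0:
        raise ValueError("empty survival sample")
    if np.any(time <= 0):
        raise ValueError("follow-up times must be positive")
    return time, event


def kaplan_meier(time, event) -> KaplanMeierEstimate:
    """Product-limit estimate of the survival function.

    An all-censored sample yields S(t) = 1 everywhere with the
    ``all_censored`` flag set (and a warning).
    """
    time, event = _check_sample(time, event)
    all_censored = not bool(event.any())
    if all_censored:
        warnings.warn("all observations censored; S(t) = 1 everywhere", stacklevel=2)
        return KaplanMeierEstimate(
            times=np.array([0.0]),
            survival=np.array([1.0]),
            n_at_risk=np.array([len(time)]),
            n_events=np.array([0]),
            all_censored=True,
        )
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    event_times = np.unique(time[event == 1])
    surv = kmf.survival_function_at_times(event_times).to_numpy()
    ts = np.sort(time)
    n = len(ts)
    n_at_risk = n - np.searchsorted(ts, event_times, side="left")
    n_events = np.bincount(
        np.searchsorted(event_times, time[event == 1]), minlength=len(event_times)
    )
    return KaplanMeierEstimate(
        times=np.concatenate([[0.0], event_times]),
        survival=np.concatenate([[1.0], surv]),
        n_at_risk=np.concatenate([[n], n_at_risk]),
        n_events=np.concatenate([[0], n_events]),
    )


def actuarial_life_table(time, event, interval_width: float = 12.0) -> pd.DataFrame:
    """Actuarial (interval-based) life table.

    Within each interval, subjects censored there count as at risk for half
    the interval (the standard actuarial adjustment).
    """
    time, event = _check_sample(time, event)
    n_int = int(np.ceil(time.max() / interval_width))
    rows = []
    alive = len(time)
    surv = 1.0
    for i in range(n_int):
        lo, hi = i * interval_width, (i + 1) * interval_width
        in_int = (time > lo) & (time <= hi)
        d = int(event[in_int].sum())
        c = int((~event[in_int].astype(bool)).sum())
        eff = alive - c / 2.0
        q = d / eff if eff > 0 else 0.0
        surv *= 1.0 - q
        rows.append(
            {"interval_start": lo, "interval_end": hi, "n_enter": alive,
             "n_events": d, "n_censored": c, "effective_at_risk": eff,
             "survival": surv}
        )
        alive -= d + c
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Log-rank test
# ---------------------------------------------------------------------------


@dataclass
class LogRankResult:
    """k-sample log-rank test: (O-E)' V^{-1} (O-E) on k-1 components."""

    statistic: float
    df: int
    p_value: float
    groups: list
    observed: np.ndarray  # per-group observed events
    expected: np.ndarray  # per-group expected events
    used_generalized_inverse: bool = False


def log_rank_test(time, event, group) -> LogRankResult:
    """Mantel–Cox k-sample log-rank test for censored survival data.

    At each distinct event time the expected events per group are
    proportional to the group's at-risk count; the chi-square statistic is
    formed from the first k-1 components of O - E with the hypergeometric
    covariance. A singular covariance falls back to a generalized inverse
    (flagged).
    """
    time, event = _check_sample(time, event)
    group = np.asarray(group)
    if group.shape != time.shape:
        raise ValueError("group must align with time")
    labels, gidx = np.unique(group, return_inverse=True)
    k = len(labels)
    if k < 2:
        raise ValueError("log-rank test needs at least two groups")
    if event.sum() == 0:
        raise ValueError("log-rank test needs at least one event")
    counts = np.bincount(gidx, minlength=k)
    if np.any(counts == 0):
        raise ValueError("every group must contain at least one subject")

    event_times = np.unique(time[event == 1])
    # at-risk counts per group at each event time (subjects with time >= t)
    sort_per_group = [np.sort(time[gidx == j]) for j in range(k)]
    n_at_risk = np.column_stack(
        [len(tj) - np.searchsorted(tj, event_times, side="left") for tj in sort_per_group]
    )  # (m, k)
    # observed events per group at each event time
    d_obs = np.zeros((len(event_times), k))
    t_pos = np.searchsorted(event_times, time)
    for j in range(k):
        mask = (gidx == j) & (event == 1)
        np.add.at(d_obs[:, j], t_pos[mask], 1)

    n_tot = n_at_risk.sum(axis=1)
    d_tot = d_obs.sum(axis=1)
    frac = n_at_risk / n_tot[:, None]
    expected = frac * d_tot[:, None]
    # hypergeometric covariance, summed over event times
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(n_tot > 1, d_tot * (n_tot - d_tot) / (n_tot - 1), 0.0)
    V = np.zeros((k, k))
    for t in range(len(event_times)):
        f = frac[t]
        V += scale[t] * (np.diag(f) - np.outer(f, f))

    O = d_obs.sum(axis=0)
    E = expected.sum(axis=0)
    diff = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    used_pinv = False
    try:
        sol = np.linalg.solve(Vsub, diff)
        if not np.all(np.isfinite(sol)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        sol = np.linalg.pinv(Vsub) @ diff
        used_pinv = True
    statistic = float(diff @ sol)
    df = k - 1
    p = float(stats.chi2.sf(statistic, df))
    return LogRankResult(
        statistic=statistic,
        df=df,
        p_value=p,
        groups=list(labels),
        observed=O,
        expected=E,
        used_generalized_inverse=used_pinv,
    )


# ---------------------------------------------------------------------------
# Proportional hazards regression
# ---------------------------------------------------------------------------


@dataclass
class PHModelResult:
    """Cox proportional-hazards fit by partial likelihood.

    ``lr_statistic``/``lr_df``/``lr_p`` are filled by nested-model
    comparisons (see :func:`class_factor_lr_test`).
    """

    params: pd.Series  # log hazard ratios
    standard_errors: pd.Series
    log_likelihood: float
    ties_method: str
    n: int
    n_events: int
    lr_statistic: Optional[float] = None
    lr_df: Optional[int] = None
    lr_p: Optional[float] = None

    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.params)


_MONOTONE_BOUND = 15.0  # |log HR| beyond this signals monotone likelihood


def ph_regression(
    data: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariate_cols: Sequence[str],
    ties: str = "efron",
) -> PHModelResult:
    """Fit a Cox model by maximizing the partial likelihood.

    Efron tie correction by default (``ties='breslow'`` available).
    Raises :class:`ConvergenceError` on monotone likelihood (complete
    separation) and ``ValueError`` on collinear covariates or an event-free
    sample.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    cols = list(covariate_cols)
    X = data[cols].to_numpy(dtype=float)
    time, event = _check_sample(data[duration_col], data[event_col])
    if event.sum() == 0:
        raise ValueError("no events in sample; PH model is not estimable")
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < X.shape[1]:
        raise ValueError("collinear (rank-deficient) covariate matrix")
    model = PHReg(time, X, status=event, ties=ties)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(disp=False)
    params = np.asarray(res.params, dtype=float)
    if not np.all(np.isfinite(params)) or np.any(np.abs(params) > _MONOTONE_BOUND):
        raise ConvergenceError(
            "partial likelihood appears monotone (complete separation); "
            f"estimates: {dict(zip(cols, params))}"
        )
    se = np.sqrt(np.diag(res.cov_params()))
    return PHModelResult(
        params=pd.Series(params, index=cols),
        standard_errors=pd.Series(se, index=cols),
        log_likelihood=float(model.loglike(params)),
        ties_method=ties,
        n=len(time),
        n_events=int(event.sum()),
    )


def class_factor_lr_test(
    data: pd.DataFrame,
    duration_col: str,
    event_col: str,
    class_col: str,
    adjust_cols: Sequence[str] = (),
    reference: str = "Robust",
    ties: str = "efron",
) -> PHModelResult:
    """LR test of the functional-class factor added to an adjusted model.

    Fits the Cox model with the class factor (dummies vs ``reference``)
    plus adjustment covariates, and the nested model without the class
    dummies; reports 2*(loglik_full - loglik_reduced) on (levels - 1) df.
    """
    levels = [reference] + sorted(set(data[class_col]) - {reference})
    if len(levels) < 2:
        raise ValueError("class factor needs at least two observed levels")
    work = data.copy()
    dummy_cols = []
    for lv in levels[1:]:
        col = f"{class_col}[{lv}]"
        work[col] = (work[class_col] == lv).astype(float)
        dummy_cols.append(col)
    full = ph_regression(
        work, duration_col, event_col, dummy_cols + list(adjust_cols), ties=ties
    )
    if adjust_cols:
        reduced = ph_regression(work, duration_col, event_col, list(adjust_cols), ties=ties)
        ll_reduced = reduced.log_likelihood
    else:
        # null model: partial likelihood with beta = 0
        X = work[dummy_cols].to_numpy(dtype=float)
        time, event = _check_sample(work[duration_col], work[event_col])
        null_model = PHReg(time, X, status=event, ties=ties)
        ll_reduced = float(null_model.loglike(np.zeros(X.shape[1])))
    lr = 2.0 * (full.log_likelihood - ll_reduced)
    lr = max(lr, 0.0)
    df = len(dummy_cols)
    full.lr_statistic = lr
    full.lr_df = df
    full.lr_p = float(stats.chi2.sf(lr, df))
    return full
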