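"""Synthetic cohort generator for FA-index validation studies.

Generates cohorts with the joint structure the downstream analyses assume:

* item responses driven by a latent frailty trait ``z ~ N(0, 1)`` — each
  indicative-risk answer fires with probability ``logistic(a_r + b z)`` and
  each indicative-resource answer with ``logistic(a_s - b z)``, so risks
  load positively and resources negatively on frailty. Class membership is
  *emergent*: generated raw answers are scored through the real scoring
  path, never assigned directly.
* class-dependent demographics and health covariates (age from truncated
  normals, sex and five binary covariates from per-class prevalences),
* class-dependent constant (exponential) hazards for death and nursing-care
  onset over a 93-month follow-up window, with lost-to-follow-up censoring,
* a second questionnaire wave six years on: a row-stochastic transition
  model over the pooled classes {Robust, Transient, Frail} with terminal
  destinations dead / lost / refused (plus a small unscorable remainder),
  reconciled with the hazard model by giving the hazard priority for death.

Default parameters reproduce the published cohort structure: four-class
mixture 60.9 / 13.1 / 10.2 / 15.8 %, class-specific 93-month death
fractions 9.5 / 22.3 / 27.3 / 35.8 %, and the published transition-row
fractions. The item model is calibrated at construction time (quadrature +
root finding) so the population class-cell probabilities equal the target
mixture exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator
from scipy import optimize, stats

from .questionnaire import (
    FREQ_1_2,
    FREQ_3_4,
    FREQ_5_7,
    FREQ_NEVER,
    NO,
    QUESTION_COLUMNS,
    WALK500_LIMITED,
    WALK500_NO,
    WALK500_YES,
    YES,
    FAClass,
    PooledClass,
    score_cohort,
)

__all__ = [
    "ItemModel",
    "AgeModel",
    "HazardModel",
    "CensoringModel",
    "TransitionModel",
    "SimulationConfig",
    "CohortTable",
    "CalibrationError",
    "calibrate_item_model",
    "class_cell_probabilities",
    "calibrate_hazards",
    "sample_wave2_outcome",
    "generate_cohort",
    "events_table",
]

CLASS_ORDER = ("Robust", "postRobust", "preFrail", "Frail")
POOLED = ("Robust", "Transient", "Frail")
WAVE2_OUTCOMES = ("Robust", "Transient", "Frail", "dead", "lost", "refused", "unscorable")


class CalibrationError(RuntimeError):
    """Item model cannot reach the target class mixture."""


# ---------------------------------------------------------------------------
# Config sub-models
# ---------------------------------------------------------------------------


class ItemModel(BaseModel):
    """Latent-trait item response model.

    ``risk_intercepts`` are the logits of an indicative-risk answer at
    z = 0 for the six risk items; ``resource_intercepts`` likewise for the
    five resource items other than resource 2 (which is the complement of
    risk 5 by construction). ``loading`` is the shared |slope| on z; risks
    use ``+loading``, resources ``-loading``. The remaining fields split
    each binary indicator side into concrete answer categories; they are
    cosmetic (they never change a score).
    """

    model_config = ConfigDict(extra="forbid")

    loading: float = Field(gt=0)
    risk_intercepts: Tuple[float, float, float, float, float, float]
    resource_intercepts: Tuple[float, float, float, float, float]
    walk_never_share: float = Field(default=0.35, ge=0, le=1)
    walk_5_7_share: float = Field(default=0.5, ge=0, le=1)
    activity_freq_shares: Tuple[float, float, float] = (0.45, 0.35, 0.20)
    walk500_limited_share: float = Field(default=0.7, ge=0, le=1)

    @field_validator("activity_freq_shares")
    @classmethod
    def _shares_sum(cls, v):
        if abs(sum(v) - 1.0) > 1e-9:
            raise ValueError("activity_freq_shares must sum to 1")
        return v


class AgeModel(BaseModel):
    """Per-class truncated-normal age distributions (years)."""

    model_config = ConfigDict(extra="forbid")

    mean: Dict[str, float] = {
        "Robust": 70.0, "postRobust": 74.4, "preFrail": 75.2, "Frail": 77.7,
    }
    sd: Dict[str, float] = {
        "Robust": 6.2, "postRobust": 7.5, "preFrail": 7.8, "Frail": 7.8,
    }
    lower: Dict[str, float] = {
        "Robust": 61.2, "postRobust": 61.7, "preFrail": 61.5, "Frail": 61.4,
    }
    upper: Dict[str, float] = {
        "Robust": 91.9, "postRobust": 93.7, "preFrail": 94.0, "Frail": 96.8,
    }


class HazardModel(BaseModel):
    """Per-class cumulative event fractions at the horizon.

    Constant (exponential) hazards are derived as
    ``lambda = -ln(1 - fraction) / horizon``. Death fractions follow the
    published 93-month class-specific mortality; nursing-care fractions are
    a loose, order-preserving calibration to the wave-2 survivor
    percentages (no direct class-specific incidence is published). A
    ``weibull_shape`` hook (shape 1 = exponential) is left for non-constant
    hazards.
    """

    model_config = ConfigDict(extra="forbid")

    death_fraction: Dict[str, float] = {
        "Robust": 0.095, "postRobust": 0.223, "preFrail": 0.273, "Frail": 0.358,
    }
    nursing_fraction: Dict[str, float] = {
        "Robust": 0.025, "postRobust": 0.036, "preFrail": 0.107, "Frail": 0.225,
    }
    weibull_shape: float = Field(default=1.0, gt=0)

    @field_validator("death_fraction", "nursing_fraction")
    @classmethod
    def _valid_fraction(cls, v):
        for k, f in v.items():
            if not (0.0 <= f < 1.0):
                raise ValueError(f"event fraction for {k} must lie in [0, 1)")
        return v


class CensoringModel(BaseModel):
    """Per-class unconditional probabilities of drop-out before wave 2."""

    model_config = ConfigDict(extra="forbid")

    lost: Dict[str, float] = {
        "Robust": 33 / 1022, "postRobust": 10 / 220,
        "preFrail": 10 / 172, "Frail": 14 / 265,
    }
    refused: Dict[str, float] = {
        "Robust": 106 / 1022, "postRobust": 21 / 220,
        "preFrail": 31 / 172, "Frail": 45 / 265,
    }


def _default_transition_rows() -> Dict[str, Dict[str, float]]:
    # published counts per pooled origin row; remainders are stay-in-class
    # (Transient, Frail) and a small unscorable fraction (Robust).
    robust = {"Robust": 519, "Transient": 152, "Frail": 106, "dead": 97,
              "lost": 33, "refused": 106, "unscorable": 9}
    transient = {"Robust": 48, "Transient": 71, "Frail": 105, "dead": 96,
                 "lost": 20, "refused": 52, "unscorable": 0}
    frail = {"Robust": 9, "Transient": 15, "Frail": 87, "dead": 95,
             "lost": 14, "refused": 45, "unscorable": 0}
    rows = {}
    for name, counts in (("Robust", robust), ("Transient", transient), ("Frail", frail)):
        n = sum(counts.values())
        rows[name] = {k: v / n for k, v in counts.items()}
    return rows


class TransitionModel(BaseModel):
    """Row-stochastic wave-1 pooled class -> wave-2 outcome matrix."""

    model_config = ConfigDict(extra="forbid")

    rows: Dict[str, Dict[str, float]] = Field(default_factory=_default_transition_rows)

    @model_validator(mode="after")
    def _stochastic(self):
        for origin, row in self.rows.items():
            if origin not in POOLED:
                raise ValueError(f"unknown origin class: {origin}")
            unknown = set(row) - set(WAVE2_OUTCOMES)
            if unknown:
                raise ValueError(f"unknown wave-2 outcome(s) in row {origin}: {sorted(unknown)}")
            if any(p < 0 for p in row.values()):
                raise ValueError(f"negative probability in row {origin}")
            if abs(sum(row.values()) - 1.0) > 1e-8:
                raise ValueError(f"transition row {origin} does not sum to 1")
        return self

    def row_vector(self, origin: str) -> np.ndarray:
        if origin not in self.rows:
            raise KeyError(f"unknown origin class: {origin}")
        row = self.rows[origin]
        return np.array([row.get(o, 0.0) for o in WAVE2_OUTCOMES])


class SimulationConfig(BaseModel):
    """Full generator configuration; ``seed`` is required (no default randomness)."""

    model_config = ConfigDict(extra="forbid")

    n: int = Field(default=1679, ge=0)
    seed: int
    class_mixture: Tuple[float, float, float, float] = (0.609, 0.131, 0.102, 0.158)
    item_model: Optional[ItemModel] = None  # calibrated from class_mixture if None
    age_model: AgeModel = Field(default_factory=AgeModel)
    sex_model: Dict[str, float] = {
        "Robust": 579 / 1022, "postRobust": 153 / 220,
        "preFrail": 123 / 172, "Frail": 188 / 265,
    }
    covariate_model: Dict[str, Dict[str, float]] = {
        "living_alone": {"Robust": 287 / 1005, "postRobust": 91 / 212,
                         "preFrail": 69 / 165, "Frail": 141 / 256},
        "fair_poor_health": {"Robust": 167 / 1006, "postRobust": 95 / 217,
                             "preFrail": 74 / 168, "Frail": 174 / 260},
        "chronic_pain": {"Robust": 199 / 986, "postRobust": 96 / 210,
                         "preFrail": 39 / 156, "Frail": 119 / 243},
        "depressed": {"Robust": 91 / 971, "postRobust": 34 / 212,
                      "preFrail": 25 / 156, "Frail": 61 / 243},
        "poor_vision": {"Robust": 182 / 1014, "postRobust": 70 / 216,
                        "preFrail": 57 / 170, "Frail": 113 / 258},
    }
    hazard_model: HazardModel = Field(default_factory=HazardModel)
    censoring_model: CensoringModel = Field(default_factory=CensoringModel)
    transition_model: TransitionModel = Field(default_factory=TransitionModel)
    horizon_months: float = Field(default=93.0, gt=0)

    @field_validator("class_mixture")
    @classmethod
    def _mixture_sums(cls, v):
        if any(p < 0 for p in v):
            raise ValueError("class mixture probabilities must be nonnegative")
        if abs(sum(v) - 1.0) > 1e-6:
            raise ValueError("class_mixture must sum to 1")
        return v

    @classmethod
    def defaults(cls, seed: int, n: int = 1679, **overrides) -> "SimulationConfig":
        """The calibrated default profile reproducing the published cohort structure."""
        cfg = cls(seed=seed, n=n, **overrides)
        if cfg.item_model is None:
            cfg = cfg.model_copy(
                update={"item_model": calibrate_item_model(cfg.class_mixture)}
            )
        return cfg

    def resolved_item_model(self) -> ItemModel:
        if self.item_model is not None:
            return self.item_model
        return calibrate_item_model(self.class_mixture)


# ---------------------------------------------------------------------------
# Item-model calibration
# ---------------------------------------------------------------------------

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(80)
_Z_NODES = math.sqrt(2.0) * _GH_NODES
_Z_WEIGHTS = _GH_WEIGHTS / math.sqrt(math.pi)


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def class_cell_probabilities(
    risk_intercept: float, resource_intercept: float, loading: float
) -> np.ndarray:
    """Population probabilities of (Robust, postRobust, preFrail, Frail).

    Computed by Gauss–Hermite quadrature over the latent trait, with the
    six risk items sharing indicative probability ``logistic(a_r + b z)``,
    the five free resource items sharing ``logistic(a_s - b z)``, and
    resource 2 equal to the complement of risk 5.
    """
    z = _Z_NODES
    pr = _logistic(risk_intercept + loading * z)
    ps = _logistic(resource_intercept - loading * z)
    # risk score = Bern(pr) [walk item] + Binom(5, pr); resource score =
    # (1 - walk item) + Binom(5, ps). Conditional on z and the walk item the
    # two binomials are independent.
    hi_risk = {x: stats.binom.sf(2 - x, 5, pr) for x in (0, 1)}  # P(B5r >= 3 - x)
    lo_res = {x: stats.binom.cdf(1 + x, 5, ps) for x in (0, 1)}  # P(B5s <= 2-(1-x))
    p_hi_risk = np.zeros_like(z)
    p_lo_res = np.zeros_like(z)
    p_joint = np.zeros_like(z)
    for x, px in ((1, pr), (0, 1.0 - pr)):
        p_hi_risk += px * hi_risk[x]
        p_lo_res += px * lo_res[x]
        p_joint += px * hi_risk[x] * lo_res[x]
    hi_risk_m = float(np.sum(_Z_WEIGHTS * p_hi_risk))
    lo_res_m = float(np.sum(_Z_WEIGHTS * p_lo_res))
    frail = float(np.sum(_Z_WEIGHTS * p_joint))
    post_robust = hi_risk_m - frail
    pre_frail = lo_res_m - frail
    robust = 1.0 - hi_risk_m - pre_frail
    return np.array([robust, post_robust, pre_frail, frail])


def calibrate_item_model(
    class_mixture: Sequence[float],
    x0: Tuple[float, float, float] = (-1.5, 1.5, 1.2),
    tol: float = 1e-10,
) -> ItemModel:
    """Solve for (risk intercept, resource intercept, loading) hitting the mixture.

    Three free parameters against the three independent cells of the 2x2
    class table; the fourth cell follows. Raises :class:`CalibrationError`
    when no solution exists (infeasible mixture for this item family).
    """
    target = np.asarray(class_mixture, dtype=float)

    def residual(theta):
        a_r, a_s, log_b = theta
        cells = class_cell_probabilities(a_r, a_s, math.exp(log_b))
        # match P(high risk), P(low resource) and the Frail joint cell
        return [
            (cells[1] + cells[3]) - (target[1] + target[3]),
            (cells[2] + cells[3]) - (target[2] + target[3]),
            cells[3] - target[3],
        ]

    sol = optimize.root(residual, [x0[0], x0[1], math.log(x0[2])], tol=tol)
    a_r, a_s, log_b = sol.x
    cells = class_cell_probabilities(a_r, a_s, math.exp(log_b))
    err = float(np.max(np.abs(cells - target)))
    if not sol.success or err > 1e-6:
        raise CalibrationError(
            "item model cannot reach the target class mixture: "
            f"best cells {np.round(cells, 4).tolist()} vs target {target.tolist()} "
            f"(max abs error {err:.2e}; solver: {sol.message})"
        )
    b = math.exp(log_b)
    return ItemModel(
        loading=b,
        risk_intercepts=(a_r,) * 6,
        resource_intercepts=(a_s,) * 5,
    )


# ---------------------------------------------------------------------------
# Hazard calibration
# ---------------------------------------------------------------------------


def calibrate_hazards(target_fraction: float, horizon: float) -> float:
    """Constant hazard lambda with ``1 - exp(-lambda * horizon) == target_fraction``."""
    if not (0.0 <= target_fraction < 1.0):
        raise ValueError("target_fraction must lie in [0, 1); 1 implies infinite hazard")
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    return -math.log1p(-target_fraction) / horizon


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


@dataclass
class CohortTable:
    """Generated cohort: one row per respondent plus the generating config."""

    table: pd.DataFrame
    config: SimulationConfig
    item_model: ItemModel

    def __len__(self) -> int:
        return len(self.table)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _draw_questionnaire(
    im: ItemModel, z: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw raw answer tokens for n respondents given latent frailty z."""
    n = len(z)
    b = im.loading
    risk_p = np.column_stack([_logistic(a + b * z) for a in im.risk_intercepts])
    risk_ind = rng.random((n, 6)) < risk_p  # indicative-risk answers
    res_p = np.column_stack([_logistic(a - b * z) for a in im.resource_intercepts])
    res_ind = rng.random((n, 5)) < res_p  # indicative-resource answers
    u = rng.random((n, 6))  # category refinement within a binary side

    def yesno(flags):
        return np.where(flags, YES, NO)

    cols: Dict[str, np.ndarray] = {}
    cols["weight_loss_5kg"] = yesno(risk_ind[:, 0])
    cols["changed_walk_1km"] = yesno(risk_ind[:, 1])
    cols["changed_climb_10steps"] = yesno(risk_ind[:, 2])
    cols["changed_car_bus"] = yesno(risk_ind[:, 3])
    low_walk = risk_ind[:, 4]
    cols["walk_outside_freq"] = np.where(
        low_walk,
        np.where(u[:, 0] < im.walk_never_share, FREQ_NEVER, FREQ_1_2),
        np.where(u[:, 1] < im.walk_5_7_share, FREQ_5_7, FREQ_3_4),
    )
    cols["falls_12mo"] = yesno(risk_ind[:, 5])
    cols["walk_500m"] = np.where(
        res_ind[:, 0],
        WALK500_YES,
        np.where(u[:, 2] < im.walk500_limited_share, WALK500_LIMITED, WALK500_NO),
    )
    s1, s2, _ = im.activity_freq_shares
    for j, name in ((1, "moderate_activity_freq"), (2, "strenuous_activity_freq")):
        uu = u[:, 2 + j]
        active_cat = np.where(uu < s1, FREQ_1_2, np.where(uu < s1 + s2, FREQ_3_4, FREQ_5_7))
        cols[name] = np.where(res_ind[:, j], active_cat, FREQ_NEVER)
    cols["work_or_volunteer_7d"] = yesno(res_ind[:, 3])
    cols["fear_falling_limits"] = np.where(res_ind[:, 4], NO, YES)  # resource = no fear
    return pd.DataFrame(cols, columns=list(QUESTION_COLUMNS))


def _truncnorm_rejection(
    mean: float, sd: float, lo: float, hi: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    out = np.empty(size)
    remaining = np.arange(size)
    while remaining.size:
        draw = rng.normal(mean, sd, remaining.size)
        ok = (draw >= lo) & (draw <= hi)
        out[remaining[ok]] = draw[ok]
        remaining = remaining[~ok]
    return out


def sample_wave2_outcome(
    class_w1: str | PooledClass,
    transition_model: TransitionModel,
    rng: np.random.Generator,
    size: int = 1,
) -> np.ndarray:
    """Draw wave-2 outcome categories from the full transition row.

    Outcomes dead / lost / refused terminate the trajectory. Raises
    ``KeyError`` for an unknown origin class.
    """
    origin = class_w1.value if isinstance(class_w1, PooledClass) else str(class_w1)
    p = transition_model.row_vector(origin)
    idx = rng.choice(len(WAVE2_OUTCOMES), size=size, p=p)
    return np.asarray(WAVE2_OUTCOMES, dtype=object)[idx]


def _conditional_exponential(
    rate: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Exponential draws; rate 0 yields +inf (event never happens)."""
    t = np.full(rate.shape, np.inf)
    pos = rate > 0
    t[pos] = rng.exponential(1.0 / rate[pos])
    return t


def generate_cohort(config: SimulationConfig) -> CohortTable:
    """Generate a full cohort (wave-1 answers, demographics, events, wave 2).

    Reproducible given (config, seed): a single global seed spawns
    per-stage substreams so stages can be re-run independently. With n=0 an
    empty cohort is returned.
    """
    im = config.resolved_item_model()
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng_latent, rng_items, rng_demo, rng_events, rng_trans, rng_w2 = (
        np.random.default_rng(s) for s in streams
    )
    n = config.n
    horizon = config.horizon_months

    if n == 0:
        empty = pd.DataFrame()
        return CohortTable(table=empty, config=config, item_model=im)

    z = rng_latent.standard_normal(n)
    answers = _draw_questionnaire(im, z, rng_items)
    scored = score_cohort(answers).table
    scored.insert(0, "id", np.arange(1, n + 1))
    scored.insert(1, "z", z)
    fa = scored["fa_class"].to_numpy()
    pooled = scored["pooled_class"].to_numpy()

    # demographics & covariates conditional on the emergent class
    age = np.empty(n)
    female = np.zeros(n, dtype=bool)
    cov_draws = {name: np.zeros(n, dtype=bool) for name in config.covariate_model}
    am = config.age_model
    for cls in CLASS_ORDER:
        mask = fa == cls
        k = int(mask.sum())
        if k == 0:
            continue
        age[mask] = _truncnorm_rejection(
            am.mean[cls], am.sd[cls], am.lower[cls], am.upper[cls], k, rng_demo
        )
        female[mask] = rng_demo.random(k) < config.sex_model[cls]
        for name, prev in config.covariate_model.items():
            cov_draws[name][mask] = rng_demo.random(k) < prev[cls]
    scored["age"] = age
    scored["sex"] = np.where(female, "female", "male")
    for name, vals in cov_draws.items():
        scored[name] = vals

    # event times: constant hazards calibrated to horizon fractions
    death_rate = np.array(
        [calibrate_hazards(config.hazard_model.death_fraction[c], horizon) for c in fa]
    )
    nursing_rate = np.array(
        [calibrate_hazards(config.hazard_model.nursing_fraction[c], horizon) for c in fa]
    )
    t_death = _conditional_exponential(death_rate, rng_events)
    t_nursing = _conditional_exponential(nursing_rate, rng_events)
    dead = t_death <= horizon
    scored["time_death_raw"] = t_death
    scored["time_nursing_raw"] = t_nursing

    # wave-2 outcome: hazard model has priority for death; among survivors,
    # lost/refusal at 4-class granularity, then a class destination from the
    # pooled transition row renormalised over non-terminal outcomes.
    raw_outcome = np.empty(n, dtype=object)
    for origin in POOLED:
        mask = pooled == origin
        if mask.any():
            raw_outcome[mask] = sample_wave2_outcome(
                origin, config.transition_model, rng_trans, int(mask.sum())
            )
    outcome = np.empty(n, dtype=object)
    outcome[dead] = "dead"
    alive = ~dead
    u_drop = rng_trans.random(n)
    lost = np.zeros(n, dtype=bool)
    refused = np.zeros(n, dtype=bool)
    cm = config.censoring_model
    hm = config.hazard_model
    for cls in CLASS_ORDER:
        mask = alive & (fa == cls)
        if not mask.any():
            continue
        surv = 1.0 - hm.death_fraction[cls]
        q_lost = min(cm.lost[cls] / surv, 1.0)
        rem = surv - cm.lost[cls]
        q_ref = min(cm.refused[cls] / rem, 1.0) if rem > 0 else 1.0
        lost[mask] = u_drop[mask] < q_lost
        refused[mask] = (~lost[mask]) & (
            rng_trans.random(int(mask.sum())) < q_ref
        )
    outcome[alive & lost] = "lost"
    outcome[alive & refused] = "refused"
    remaining = alive & ~lost & ~refused
    u_dest = rng_trans.random(n)
    for origin in POOLED:
        mask = remaining & (pooled == origin)
        if not mask.any():
            continue
        row = config.transition_model.row_vector(origin)
        dest = np.array([row[WAVE2_OUTCOMES.index(o)] for o in ("Robust", "Transient", "Frail", "unscorable")])
        if dest.sum() <= 0:
            raise CalibrationError(
                f"transition row {origin} leaves no mass on class destinations"
            )
        dest = dest / dest.sum()
        cdf = np.cumsum(dest)
        idx = np.searchsorted(cdf, u_dest[mask], side="right").clip(max=3)
        outcome[mask] = np.asarray(["Robust", "Transient", "Frail", "unscorable"], dtype=object)[idx]
    scored["wave2_outcome_raw"] = raw_outcome  # audit: unreconciled row draw
    scored["wave2_outcome"] = outcome

    # censoring: lost-to-follow-up censors both endpoints at Uniform(0, horizon);
    # refusal does not censor registry-ascertained endpoints.
    censor_time = np.full(n, horizon)
    censor_reason = np.full(n, "administrative", dtype=object)
    is_lost = outcome == "lost"
    censor_time[is_lost] = rng_events.uniform(0.0, horizon, int(is_lost.sum()))
    censor_reason[is_lost] = "lost"
    scored["censor_time"] = censor_time
    scored["censor_reason"] = censor_reason

    obs_death = np.minimum(t_death, censor_time)
    scored["observed_death_time"] = obs_death
    scored["death_event"] = (t_death <= censor_time).astype(int)
    # death before nursing-care onset censors the nursing endpoint at death
    nursing_censor = np.minimum(censor_time, t_death)
    scored["observed_nursing_time"] = np.minimum(t_nursing, nursing_censor)
    scored["nursing_event"] = (t_nursing <= nursing_censor).astype(int)
    # nobody needs nursing care at wave 1: onset times are strictly positive
    assert (scored["observed_nursing_time"] > 0).all()

    # wave-2 questionnaires for respondents whose outcome is a class:
    # resample z by accept-reject until the scored pooled class matches.
    w2_cols = {f"w2_{c}": np.full(n, None, dtype=object) for c in QUESTION_COLUMNS}
    w2_class = np.full(n, None, dtype=object)
    need = np.flatnonzero(np.isin(outcome, ("Robust", "Transient", "Frail")))
    target = outcome[need]
    pending = need.copy()
    pending_target = target.copy()
    for _ in range(200):
        if pending.size == 0:
            break
        z2 = rng_w2.standard_normal(pending.size)
        ans2 = _draw_questionnaire(im, z2, rng_w2)
        sc2 = score_cohort(ans2).table
        got = sc2["pooled_class"].to_numpy()
        ok = got == pending_target
        hit = pending[ok]
        for c in QUESTION_COLUMNS:
            w2_cols[f"w2_{c}"][hit] = ans2.loc[ok, c].to_numpy()
        w2_class[hit] = got[ok]
        pending = pending[~ok]
        pending_target = pending_target[~ok]
    if pending.size:
        raise CalibrationError(
            "accept-reject for wave-2 questionnaires failed to converge; "
            "the item model places (almost) no mass on a required class"
        )
    for name, vals in w2_cols.items():
        scored[name] = vals
    scored["w2_pooled_class"] = w2_class

    return CohortTable(table=scored, config=config, item_model=im)


def events_table(cohort: CohortTable) -> pd.DataFrame:
    """Long-format events CSV: one row per respondent per endpoint.

    Columns: id, endpoint (death | nursing_care), time_months, event
    (1 = event, 0 = censored), fa_class, pooled_class, age, sex,
    fair_poor_health — the layout survival tooling consumes.
    """
    t = cohort.table
    if t.empty:
        return pd.DataFrame(
            columns=["id", "endpoint", "time_months", "event", "fa_class",
                     "pooled_class", "age", "sex", "fair_poor_health"]
        )
    base = t[["id", "fa_class", "pooled_class", "age", "sex", "fair_poor_health"]]
    death = base.copy()
    death.insert(1, "endpoint", "death")
    death.insert(2, "time_months", t["observed_death_time"].to_numpy())
    death.insert(3, "event", t["death_event"].to_numpy())
    nursing = base.copy()
    nursing.insert(1, "endpoint", "nursing_care")
    nursing.insert(2, "time_months", t["observed_nursing_time"].to_numpy())
    nursing.insert(3, "event", t["nursing_event"].to_numpy())
    return pd.concat([death, nursing], ignore_index=True)
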