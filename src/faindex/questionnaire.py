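"""Functional Ability (FA) index: questionnaire encoding, scoring and classification.

The FA index is a self-report screening instrument for community-dwelling
seniors. Eleven questions are mapped onto six frailty-*risk* indicators
(weight loss, changed way of walking 1 km, of climbing 10 steps, of getting
in/out of a car or bus, infrequent outdoor walking, falls) and six
robustness-*resource* indicators (walking 500 m without help, frequent
outdoor walking, moderate activity, strenuous activity, paid or volunteer
work, no fear-of-falling limitation). One question — outdoor walking
frequency — has double weight: it feeds risk indicator 5 and resource
indicator 2 with opposite coding, so exactly one of the two always fires.

The risk score (0–6) and resource score (0–6) cross-classify respondents
into four functional classes on a 2x2 grid:

    ==============  =================  =================
                     resources 3–6      resources 0–2
    risks 0–2        Robust             preFrail
    risks 3–6        postRobust         Frail
    ==============  =================  =================

For transition analyses postRobust and preFrail are pooled into a single
``Transient`` class.

Missing answers make a record *unscorable*: complete-case exclusion, never
partial scoring or imputation.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from ._rounding import percent

__all__ = [
    "YES",
    "NO",
    "FREQ_NEVER",
    "FREQ_1_2",
    "FREQ_3_4",
    "FREQ_5_7",
    "FREQ_CATEGORIES",
    "WALK500_YES",
    "WALK500_LIMITED",
    "WALK500_NO",
    "WALK500_CATEGORIES",
    "QUESTION_COLUMNS",
    "RISK_NAMES",
    "RESOURCE_NAMES",
    "FAClass",
    "PooledClass",
    "QuestionnaireRecord",
    "FAScores",
    "UnscorableRecordError",
    "derive_indicators",
    "classify",
    "classify_scores",
    "score_cohort",
    "CohortScores",
    "read_questionnaire_csv",
]

# ---------------------------------------------------------------------------
# Controlled answer tokens (the CSV data dictionary)
# ---------------------------------------------------------------------------

YES = "yes"
NO = "no"

FREQ_NEVER = "never"
FREQ_1_2 = "1-2"
FREQ_3_4 = "3-4"
FREQ_5_7 = "5-7"
FREQ_CATEGORIES = (FREQ_NEVER, FREQ_1_2, FREQ_3_4, FREQ_5_7)

WALK500_YES = "yes"
WALK500_LIMITED = "yes_with_difficulty"  # with difficulty / device / help
WALK500_NO = "no"
WALK500_CATEGORIES = (WALK500_YES, WALK500_LIMITED, WALK500_NO)

#: Column names of the 11 raw questions, in instrument order.
QUESTION_COLUMNS = (
    "weight_loss_5kg",
    "changed_walk_1km",
    "changed_climb_10steps",
    "changed_car_bus",
    "walk_outside_freq",
    "falls_12mo",
    "walk_500m",
    "moderate_activity_freq",
    "strenuous_activity_freq",
    "work_or_volunteer_7d",
    "fear_falling_limits",
)

RISK_NAMES = tuple(f"risk_{i}" for i in range(1, 7))
RESOURCE_NAMES = tuple(f"resource_{i}" for i in range(1, 7))

_YESNO = {YES, NO}
_VALID = {
    "weight_loss_5kg": _YESNO,
    "changed_walk_1km": _YESNO,
    "changed_climb_10steps": _YESNO,
    "changed_car_bus": _YESNO,
    "walk_outside_freq": set(FREQ_CATEGORIES),
    "falls_12mo": _YESNO,
    "walk_500m": set(WALK500_CATEGORIES),
    "moderate_activity_freq": set(FREQ_CATEGORIES),
    "strenuous_activity_freq": set(FREQ_CATEGORIES),
    "work_or_volunteer_7d": _YESNO,
    "fear_falling_limits": _YESNO,
}


class FAClass(str, Enum):
    """Four-level functional class."""

    ROBUST = "Robust"
    POST_ROBUST = "postRobust"
    PRE_FRAIL = "preFrail"
    FRAIL = "Frail"

    @property
    def pooled(self) -> "PooledClass":
        if self in (FAClass.POST_ROBUST, FAClass.PRE_FRAIL):
            return PooledClass.TRANSIENT
        return PooledClass(self.value)

    @property
    def ordinal(self) -> int:
        """Severity encoding for rank correlations: Robust=0 … Frail=3."""
        return _ORDINAL[self]


class PooledClass(str, Enum):
    """Three-level class with postRobust + preFrail pooled as Transient."""

    ROBUST = "Robust"
    TRANSIENT = "Transient"
    FRAIL = "Frail"


_ORDINAL = {
    FAClass.ROBUST: 0,
    FAClass.POST_ROBUST: 1,
    FAClass.PRE_FRAIL: 2,
    FAClass.FRAIL: 3,
}

FA_CLASS_ORDER = (FAClass.ROBUST, FAClass.POST_ROBUST, FAClass.PRE_FRAIL, FAClass.FRAIL)
POOLED_ORDER = (PooledClass.ROBUST, PooledClass.TRANSIENT, PooledClass.FRAIL)


class UnscorableRecordError(ValueError):
    """Raised when a questionnaire record has missing or invalid answers."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__(
            "record is unscorable (complete-case exclusion): " + "; ".join(self.problems)
        )


@dataclass(frozen=True)
class QuestionnaireRecord:
    """One respondent's raw answers to the 11 FA questions at one wave.

    Every field admits ``None`` as the distinguished missing value; any
    missing answer makes the record unscorable.
    """

    weight_loss_5kg: Optional[str] = None
    changed_walk_1km: Optional[str] = None
    changed_climb_10steps: Optional[str] = None
    changed_car_bus: Optional[str] = None
    walk_outside_freq: Optional[str] = None
    falls_12mo: Optional[str] = None
    walk_500m: Optional[str] = None
    moderate_activity_freq: Optional[str] = None
    strenuous_activity_freq: Optional[str] = None
    work_or_volunteer_7d: Optional[str] = None
    fear_falling_limits: Optional[str] = None

    def missing_fields(self) -> list:
        out = []
        for f in fields(self):
            v = getattr(self, f.name)
            if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
                out.append(f.name)
        return out


@dataclass(frozen=True)
class FAScores:
    """Derived indicator flags and the two sum scores.

    Invariants: ``risk_score = sum(risk_indicators)``,
    ``resource_score = sum(resource_indicators)`` and
    ``risk_indicators[4] + resource_indicators[1] == 1`` (the doubly
    weighted outdoor-walking question), hence
    ``risk_score + resource_score <= 11``.
    """

    risk_indicators: tuple
    resource_indicators: tuple

    def __post_init__(self):
        if len(self.risk_indicators) != 6 or len(self.resource_indicators) != 6:
            raise ValueError("expected 6 risk and 6 resource indicators")
        if self.risk_indicators[4] + self.resource_indicators[1] != 1:
            raise ValueError(
                "risk_5 and resource_2 code the same question with opposite "
                "polarity; exactly one must fire"
            )

    @property
    def risk_score(self) -> int:
        return int(sum(self.risk_indicators))

    @property
    def resource_score(self) -> int:
        return int(sum(self.resource_indicators))


def derive_indicators(record: QuestionnaireRecord) -> FAScores:
    """Map raw answers to the 6+6 binary indicators and sum scores.

    Raises :class:`UnscorableRecordError` when any answer is missing or not
    a controlled token — the record is then excluded from all denominators
    (complete-case rule), never partially scored.
    """
    problems = [f"missing answer: {name}" for name in record.missing_fields()]
    if not problems:
        for name in QUESTION_COLUMNS:
            v = getattr(record, name)
            if v not in _VALID[name]:
                problems.append(f"invalid answer for {name}: {v!r}")
    if problems:
        raise UnscorableRecordError(problems)

    low_walk = record.walk_outside_freq in (FREQ_NEVER, FREQ_1_2)
    risks = (
        int(record.weight_loss_5kg == YES),
        int(record.changed_walk_1km == YES),
        int(record.changed_climb_10steps == YES),
        int(record.changed_car_bus == YES),
        int(low_walk),
        int(record.falls_12mo == YES),
    )
    resources = (
        int(record.walk_500m == WALK500_YES),  # unqualified yes only
        int(not low_walk),
        int(record.moderate_activity_freq != FREQ_NEVER),
        int(record.strenuous_activity_freq != FREQ_NEVER),
        int(record.work_or_volunteer_7d == YES),
        int(record.fear_falling_limits == NO),
    )
    return FAScores(risk_indicators=risks, resource_indicators=resources)


def classify(risk_score: int, resource_score: int) -> FAClass:
    """Classify a (risk, resource) score pair on the 2x2 grid.

    Few risks (0–2) with ample resources (3–6) is Robust; many risks (3–6)
    with ample resources is postRobust; few of both is preFrail; many risks
    with few resources is Frail.
    """
    if not (0 <= risk_score <= 6 and 0 <= resource_score <= 6):
        raise ValueError("scores must lie in 0..6")
    low_risk = risk_score <= 2
    high_resource = resource_score >= 3
    if low_risk and high_resource:
        return FAClass.ROBUST
    if not low_risk and high_resource:
        return FAClass.POST_ROBUST
    if low_risk and not high_resource:
        return FAClass.PRE_FRAIL
    return FAClass.FRAIL


def classify_scores(scores: FAScores) -> FAClass:
    return classify(scores.risk_score, scores.resource_score)


# ---------------------------------------------------------------------------
# Cohort-level scoring
# ---------------------------------------------------------------------------


@dataclass
class CohortScores:
    """Per-respondent scoring result plus class-count summary.

    ``table`` preserves the input order and index. Unscorable rows have
    ``scorable == False`` and carry no class label (NA).
    """

    table: pd.DataFrame

    @property
    def n_total(self) -> int:
        return len(self.table)

    @property
    def n_scorable(self) -> int:
        return int(self.table["scorable"].sum())

    def class_counts(self) -> pd.Series:
        counts = self.table.loc[self.table["scorable"], "fa_class"].value_counts()
        return counts.reindex([c.value for c in FA_CLASS_ORDER], fill_value=0).astype(int)

    def class_percentages(self) -> pd.Series:
        """Per-class share of *scorable* records, one decimal, half away from zero."""
        counts = self.class_counts()
        denom = int(counts.sum())
        return counts.map(lambda c: percent(c, denom))

    def summary(self) -> pd.DataFrame:
        counts = self.class_counts()
        return pd.DataFrame({"count": counts, "percent": self.class_percentages()})


def _record_from_row(row: pd.Series) -> QuestionnaireRecord:
    kwargs = {}
    for name in QUESTION_COLUMNS:
        v = row.get(name)
        if v is None or (isinstance(v, float) and np.isnan(v)) or v == "" or pd.isna(v):
            kwargs[name] = None
        else:
            kwargs[name] = str(v)
    return QuestionnaireRecord(**kwargs)


def score_cohort(records: Iterable[QuestionnaireRecord] | pd.DataFrame) -> CohortScores:
    """Score a collection of questionnaire records.

    Accepts either an iterable of :class:`QuestionnaireRecord` or a
    DataFrame with the 11 question columns (extra columns are carried
    through untouched). Unscorable records are flagged, excluded from the
    class denominators and left unclassified.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        recs = [_record_from_row(row) for _, row in df.iterrows()]
    else:
        recs = list(records)
        df = pd.DataFrame(
            [{name: getattr(r, name) for name in QUESTION_COLUMNS} for r in recs]
        )

    n = len(recs)
    risk_cols = {name: np.zeros(n, dtype="float64") for name in RISK_NAMES}
    res_cols = {name: np.zeros(n, dtype="float64") for name in RESOURCE_NAMES}
    scorable = np.zeros(n, dtype=bool)
    risk_score = np.full(n, np.nan)
    resource_score = np.full(n, np.nan)
    fa_class = np.full(n, None, dtype=object)
    pooled = np.full(n, None, dtype=object)

    for i, rec in enumerate(recs):
        try:
            scores = derive_indicators(rec)
        except UnscorableRecordError:
            for name in RISK_NAMES:
                risk_cols[name][i] = np.nan
            for name in RESOURCE_NAMES:
                res_cols[name][i] = np.nan
            continue
        scorable[i] = True
        for j, name in enumerate(RISK_NAMES):
            risk_cols[name][i] = scores.risk_indicators[j]
        for j, name in enumerate(RESOURCE_NAMES):
            res_cols[name][i] = scores.resource_indicators[j]
        risk_score[i] = scores.risk_score
        resource_score[i] = scores.resource_score
        label = classify_scores(scores)
        fa_class[i] = label.value
        pooled[i] = label.pooled.value

    out = df
    for name in RISK_NAMES:
        out[name] = risk_cols[name]
    for name in RESOURCE_NAMES:
        out[name] = res_cols[name]
    out["risk_score"] = risk_score
    out["resource_score"] = resource_score
    out["fa_class"] = fa_class
    out["pooled_class"] = pooled
    out["scorable"] = scorable
    return CohortScores(table=out)


def read_questionnaire_csv(path) -> pd.DataFrame:
    """Read a respondent-wave questionnaire CSV (missing = empty cell)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=True)
    missing_cols = [c for c in QUESTION_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"questionnaire CSV missing required columns: {missing_cols}")
    return df
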