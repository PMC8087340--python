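"""The four sub-scores and the composite status score.

Every score lives on 0-100, higher = better:

* **BMI score** — a five-level step function of the WHO BMI class:
  normal 100; overweight or underweight 75; obesity class 1 50;
  class 2 25; class 3 0.
* **Diet score** — food-frequency penalties (1-10 per item, higher =
  less healthy) are summed over the 51 items and affinely inverted onto
  0-100 using the minimal/maximal attainable totals, so the healthiest
  possible diet scores 100 and the unhealthiest 0.
* **Activity score** — IPAQ short-form MET-minutes/week (8.0 x vigorous,
  4.0 x moderate, 3.3 x walking, per-session minutes truncated at 180
  min/day), normalised linearly and saturated at a reference volume
  (default 3000 MET-min/week).
* **Social score** — a convex combination of a saturating degree term
  (``min(degree / D_ref, 1)``) and the mean composite score of the
  user's contacts.
* **Composite (Wakastatus)** — weighted sum of the four sub-scores
  (default weights 1/4 each).

The social score depends on the neighbours' composite scores, which in
turn contain the social score: a linear fixed point, solved by Jacobi
iteration.  With degree weight ``w`` and social weight ``c`` in the
composite, the iteration map has contraction coefficient
``(1 - w) * c`` (0.125 under defaults), so convergence is geometric and
guaranteed for any cohort.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional

import numpy as np
from pydantic import BaseModel, Field

from . import config as _config
from .domain import (
    Assessment,
    ActivityRecord,
    BMICategory,
    Cohort,
    DietRecord,
    DomainError,
    FrequencyLevel,
    bmi_category,
    compute_bmi,
)

__all__ = [
    "ScoreTable",
    "ScoringParams",
    "ScoreCard",
    "ConvergenceError",
    "score_bmi",
    "score_diet",
    "ipaq_met_minutes",
    "score_activity",
    "compute_scorecards",
]

_LEVELS = [f"L{i}" for i in range(6)]


class ConvergenceError(RuntimeError):
    """Fixed-point iteration failed to reach tolerance within max_iter."""

    def __init__(self, residual: float, iterations: int):
        self.residual = residual
        self.iterations = iterations
        super().__init__(
            f"social-score fixed point not converged after {iterations} "
            f"iterations (residual {residual:.3e})"
        )


class ScoreTable:
    """Penalty points per (food item, frequency level).

    Built from a config mapping items to groups, groups to consumption
    classes, and classes to a six-level penalty row.  ``p_min`` /
    ``p_max`` are the minimal and maximal total penalty attainable by a
    complete diet record, the normalisation constants of the diet score.
    """

    def __init__(
        self,
        penalty: Mapping[tuple[str, int], float],
        item_ids: Iterable[str],
        name: str = "custom",
    ):
        self.name = name
        self.item_ids = frozenset(item_ids)
        self.penalty = dict(penalty)
        for item in self.item_ids:
            for lv in range(6):
                p = self.penalty.get((item, lv))
                if p is None:
                    raise ValueError(f"no penalty for ({item}, L{lv})")
                if not (1 <= p <= 10):
                    raise ValueError(f"penalty {p} for ({item}, L{lv}) outside [1, 10]")
        self.p_min = sum(
            min(self.penalty[(i, lv)] for lv in range(6)) for i in self.item_ids
        )
        self.p_max = sum(
            max(self.penalty[(i, lv)] for lv in range(6)) for i in self.item_ids
        )
        if not self.p_min < self.p_max:
            raise ValueError("degenerate score table: p_min >= p_max")

    @classmethod
    def from_config(cls, source: str = "default_v1") -> "ScoreTable":
        raw = _config.load_raw_score_table(source)
        class_rows = {
            cname: [float(row[lv]) for lv in _LEVELS]
            for cname, row in raw["penalties"].items()
        }
        group_class = {gid: g["class"] for gid, g in raw["groups"].items()}
        penalty: dict[tuple[str, int], float] = {}
        for item, group in raw["items"].items():
            row = class_rows[group_class[group]]
            for lv in range(6):
                penalty[(item, lv)] = row[lv]
        return cls(penalty, raw["items"].keys(), name=raw.get("name", "custom"))


class ScoringParams(BaseModel):
    """Scoring constants; defaults are the shipped "default_v1" values."""

    met_vigorous: float = 8.0
    met_moderate: float = 4.0
    met_walk: float = 3.3
    daily_cap_minutes: float = 180.0
    activity_ref_met: float = 3000.0
    social_degree_weight: float = 0.5
    social_degree_ref: float = 10.0
    wakastatus_weights: dict[str, float] = Field(
        default_factory=lambda: {
            "diet": 0.25,
            "activity": 0.25,
            "bmi": 0.25,
            "social": 0.25,
        }
    )
    fixedpoint_tol: float = 1e-9
    fixedpoint_max_iter: int = 1000

    def model_post_init(self, __context) -> None:
        w = self.wakastatus_weights
        if set(w) != {"diet", "activity", "bmi", "social"}:
            raise ValueError("wakastatus_weights must have keys diet/activity/bmi/social")
        if any(v < 0 for v in w.values()) or abs(sum(w.values()) - 1.0) > 1e-9:
            raise ValueError("wakastatus_weights must be non-negative and sum to 1")
        if self.fixedpoint_tol <= 0 or self.daily_cap_minutes <= 0:
            raise ValueError("tolerance and caps must be positive")

    @classmethod
    def from_config(cls, source: str = "default_v1") -> "ScoringParams":
        raw = _config.load_raw_params(source)
        raw = {k: v for k, v in raw.items() if k != "name"}
        return cls(**raw)


class ScoreCard(BaseModel):
    """The five scores of one participant, plus diagnostics."""

    user_id: str
    bmi: float
    bmi_cat: BMICategory
    diet_score: float
    activity_score: float
    bmi_score: float
    social_score: float
    wakastatus: float
    met_minutes: float
    degree: int = 0
    converged: bool = True
    iterations: int = 0


_BMI_POINTS: dict[BMICategory, float] = {
    BMICategory.normal: 100.0,
    BMICategory.overweight: 75.0,
    BMICategory.underweight: 75.0,
    BMICategory.obesity1: 50.0,
    BMICategory.obesity2: 25.0,
    BMICategory.obesity3: 0.0,
}


def score_bmi(bmi: float) -> float:
    """BMI sub-score: 100 normal, 75 over/underweight, 50/25/0 obesity 1/2/3."""
    return _BMI_POINTS[bmi_category(bmi)]


def score_diet(diet: DietRecord, table: ScoreTable) -> float:
    """Diet sub-score: summed penalties inverted onto 0-100.

    ``100 * (p_max - S) / (p_max - p_min)`` where ``S`` is the total
    penalty of the record; the healthiest attainable record scores 100.
    """
    missing = table.item_ids - diet.answers.keys()
    if missing:
        raise DomainError(
            f"incomplete diet record: {len(missing)} items missing "
            f"(e.g. {sorted(missing)[:3]})"
        )
    unknown = diet.answers.keys() - table.item_ids
    if unknown:
        raise DomainError(f"items not in score table: {sorted(unknown)[:5]}")
    s = sum(table.penalty[(item, int(lv))] for item, lv in diet.answers.items())
    return 100.0 * (table.p_max - s) / (table.p_max - table.p_min)


def ipaq_met_minutes(
    activity: ActivityRecord, params: Optional[ScoringParams] = None
) -> float:
    """Weekly MET-minutes per the IPAQ short-form protocol.

    Per-session minutes in each domain are truncated at the daily cap
    (180 min) before multiplying by days and the domain MET value.
    """
    p = params or ScoringParams()
    cap = p.daily_cap_minutes
    return (
        p.met_vigorous * activity.vigorous_days * min(activity.vigorous_minutes, cap)
        + p.met_moderate * activity.moderate_days * min(activity.moderate_minutes, cap)
        + p.met_walk * activity.walk_days * min(activity.walk_minutes, cap)
    )


def score_activity(
    activity: ActivityRecord, params: Optional[ScoringParams] = None
) -> float:
    """Activity sub-score: MET-minutes, linear with saturation at the reference."""
    p = params or ScoringParams()
    return 100.0 * min(ipaq_met_minutes(activity, p) / p.activity_ref_met, 1.0)


def _social_update(
    degree: np.ndarray,
    neighbor_idx: list[np.ndarray],
    wakastatus: np.ndarray,
    params: ScoringParams,
) -> np.ndarray:
    """One Jacobi sweep of the social score given current composite scores."""
    w = params.social_degree_weight
    deg_term = np.minimum(degree / params.social_degree_ref, 1.0)
    quality = np.array(
        [wakastatus[idx].mean() if idx.size else 0.0 for idx in neighbor_idx]
    )
    return 100.0 * (w * deg_term + (1.0 - w) * quality / 100.0)


def compute_scorecards(
    cohort: Cohort,
    table: Optional[ScoreTable] = None,
    params: Optional[ScoringParams] = None,
) -> dict[str, ScoreCard]:
    """Score every completed assessment in a cohort.

    Diet, activity and BMI sub-scores are fixed per user; the social
    score and the composite are mutually dependent and solved jointly by
    Jacobi fixed-point iteration from social = 0, stopping when the
    largest social-score change falls below ``fixedpoint_tol``.
    Participants with incomplete assessments are excluded (relations
    touching them are ignored); their ids do not appear in the result.
    """
    table = table or ScoreTable.from_config()
    params = params or ScoringParams()
    item_ids = set(table.item_ids)

    users = [
        uid
        for uid in sorted(cohort.assessments)
        if cohort.assessments[uid].completed(item_ids)
    ]
    if not users:
        return {}
    index = {uid: k for k, uid in enumerate(users)}
    n = len(users)

    bmi = np.empty(n)
    base = np.empty((n, 3))  # diet, activity, bmi sub-scores
    met = np.empty(n)
    cats: list[BMICategory] = []
    for k, uid in enumerate(users):
        a: Assessment = cohort.assessments[uid]
        bmi[k] = compute_bmi(a.personal)
        cats.append(bmi_category(bmi[k]))
        base[k, 0] = score_diet(a.diet, table)
        met[k] = ipaq_met_minutes(a.activity, params)
        base[k, 1] = score_activity(a.activity, params)
        base[k, 2] = score_bmi(bmi[k])

    adj: list[set[int]] = [set() for _ in range(n)]
    for r in cohort.relations:
        ia, ib = index.get(r.user_a), index.get(r.user_b)
        if ia is None or ib is None or ia == ib:
            continue
        adj[ia].add(ib)
        adj[ib].add(ia)
    neighbor_idx = [np.fromiter(s, dtype=int) if s else np.empty(0, int) for s in adj]
    degree = np.array([len(s) for s in adj], dtype=float)

    w = params.wakastatus_weights
    base_part = (
        w["diet"] * base[:, 0] + w["activity"] * base[:, 1] + w["bmi"] * base[:, 2]
    )

    social = np.zeros(n)
    converged = False
    iterations = 0
    residual = np.inf
    for iterations in range(1, params.fixedpoint_max_iter + 1):
        wakastatus = base_part + w["social"] * social
        new_social = _social_update(degree, neighbor_idx, wakastatus, params)
        residual = float(np.max(np.abs(new_social - social)))
        social = new_social
        if residual < params.fixedpoint_tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(residual, iterations)
    wakastatus = base_part + w["social"] * social

    return {
        uid: ScoreCard(
            user_id=uid,
            bmi=float(bmi[k]),
            bmi_cat=cats[k],
            diet_score=float(base[k, 0]),
            activity_score=float(base[k, 1]),
            bmi_score=float(base[k, 2]),
            social_score=float(social[k]),
            wakastatus=float(wakastatus[k]),
            met_minutes=float(met[k]),
            degree=int(degree[k]),
            converged=converged,
            iterations=iterations,
        )
        for k, uid in enumerate(users)
    }
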