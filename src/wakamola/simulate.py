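"""Synthetic cohort generator calibrated to the pilot deployment.

The shipped profile ``pilot2019`` encodes the pilot sample: 74
completers (73% female, mean age 20.7), BMI ~ truncated normal
(21.4, 2.41) on [14, 45], per-food-group weekly consumption means,
IPAQ-item means, sleep 7.02 h/day, and a 12-block planted-partition
network with mean degree 2*178/74 and a 5/74 isolated fraction.

Generation choices worth knowing about:

* BMI is drawn directly from the truncated normal and weight derived as
  ``bmi * height**2`` (height is gender-conditional), so the published
  BMI moments are targeted exactly rather than emerging from independent
  weight/height draws.
* Food-frequency answers are ordinal levels, but the published targets
  are weekly *units* per food group.  Each item's weekly units are drawn
  from a Poisson whose rate is calibrated (by root finding) so that the
  expected value of the level representative — the value used when
  mapping levels back to units — equals the item's share of the group
  mean.  Group-level mean recovery therefore holds by construction.
* Days-per-week activity counts are Binomial(7, mean/7): supported on
  0..7 with the exact target mean.  Session minutes and sitting hours
  are gamma with the target mean.
* The relation graph is a planted partition: non-isolated users are
  split into blocks, the within-block edge probability is solved from
  the target expected edge count given the between-block probability.
"""

from __future__ import annotations

import math
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field
from scipy import optimize, stats

from . import config as _config
from .domain import (
    ActivityRecord,
    Assessment,
    Cohort,
    DietRecord,
    FrequencyLevel,
    Gender,
    MainActivity,
    PersonalRecord,
    Relation,
    RelationType,
)

__all__ = [
    "SimProfile",
    "load_profile",
    "generate_personal",
    "generate_diet",
    "generate_activity",
    "generate_network",
    "generate_cohort",
    "generate_personal_batch",
    "generate_diet_batch",
    "generate_activity_batch",
    "diet_group_units",
    "level_for_units",
]


class Dist(BaseModel):
    mean: float
    sd: float
    min: Optional[float] = None
    max: Optional[float] = None


class NetworkSpec(BaseModel):
    mean_degree: float
    n_blocks: int
    p_between: float
    isolated_fraction: float
    relation_type_probs: dict[str, float]


class SimProfile(BaseModel):
    """Parameter set for one simulated study population."""

    name: str = "custom"
    n: int
    female_fraction: float
    age: Dist
    bmi: Dist
    height: dict[str, Dist]
    sleep: Dist
    cigarettes_mean: float = 0.0
    disease_prob: float = 0.0
    zip_pool: int = 50
    food_weekly_means: dict[str, float]
    activity: dict[str, float]
    minutes_shape: float = 2.0
    network: NetworkSpec
    level_bins: list[float] = Field(default_factory=lambda: [1.0, 3.0, 7.0, 14.0])
    level_representatives: list[float] = Field(
        default_factory=lambda: [0.0, 0.5, 2.0, 4.5, 9.0, 16.0]
    )
    seed: int = 0

    def model_post_init(self, __context) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        for name, p in (
            ("female_fraction", self.female_fraction),
            ("disease_prob", self.disease_prob),
            ("isolated_fraction", self.network.isolated_fraction),
            ("p_between", self.network.p_between),
        ):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be a probability, got {p}")
        if self.age.sd < 0 or self.bmi.sd < 0 or self.sleep.sd < 0:
            raise ValueError("standard deviations must be >= 0")


def load_profile(source: str = "pilot2019") -> SimProfile:
    return SimProfile(**_config.load_raw_profile(source))


def level_for_units(units: float, bins: Sequence[float]) -> int:
    """Frequency level of a weekly unit count under the profile's bins."""
    if units <= 0:
        return 0
    cut = np.concatenate([[0.0], np.asarray(bins, dtype=float)])
    return int(min(5, np.searchsorted(cut, units, side="right")))


def _levels_for_counts(counts: np.ndarray, bins: Sequence[float]) -> np.ndarray:
    cut = np.concatenate([[0.0], np.asarray(bins, dtype=float)])
    lv = np.searchsorted(cut, counts, side="right")
    lv[counts <= 0] = 0
    return np.minimum(lv, 5)


@lru_cache(maxsize=None)
def _poisson_rate_for_mean(
    target: float, bins: tuple[float, ...], reps: tuple[float, ...]
) -> float:
    """Rate lambda with E[rep(level(Poisson(lambda)))] == target.

    The expectation is monotone increasing in lambda from rep[0] to
    rep[-1]; solved by bracketing root finding.  Targets at or above the
    top representative are unattainable and rejected.
    """
    if target <= 0:
        return 0.0
    if target >= reps[-1]:
        raise ValueError(
            f"target weekly units {target} not attainable: top representative "
            f"is {reps[-1]}"
        )
    cut = np.concatenate([[0.0], np.asarray(bins)])

    def expected_rep(lam: float) -> float:
        if lam <= 0:
            return reps[0]
        hi = int(max(30, lam + 12 * math.sqrt(lam)))
        u = np.arange(hi + 1)
        lv = np.minimum(np.searchsorted(cut, u, side="right"), 5)
        lv[0] = 0
        pmf = stats.poisson.pmf(u, lam)
        tail = max(0.0, 1.0 - pmf.sum())
        return float(np.dot(pmf, np.asarray(reps)[lv]) + tail * reps[-1])

    return optimize.brentq(lambda l: expected_rep(l) - target, 0.0, 500.0, xtol=1e-10)


def _trunc_normal(
    rng: np.random.Generator, n: int, d: Dist
) -> np.ndarray:
    lo = -np.inf if d.min is None else d.min
    hi = np.inf if d.max is None else d.max
    if d.sd == 0:
        return np.full(n, d.mean)
    a, b = (lo - d.mean) / d.sd, (hi - d.mean) / d.sd
    return stats.truncnorm.rvs(a, b, loc=d.mean, scale=d.sd, size=n, random_state=rng)


_EDUCATION = (["primary", "secondary", "university"], [0.1, 0.3, 0.6])
_MARITAL = (["single", "married", "other"], [0.9, 0.08, 0.02])
_MAIN_ACTIVITY = (
    [MainActivity.study, MainActivity.work, MainActivity.other],
    [0.85, 0.10, 0.05],
)


def generate_personal_batch(
    profile: SimProfile, n: int, rng: np.random.Generator
) -> list[PersonalRecord]:
    bmi = _trunc_normal(rng, n, profile.bmi)
    genders = np.where(
        rng.random(n) < profile.female_fraction, Gender.female.value, Gender.male.value
    )
    height = np.empty(n)
    for gname, hd in profile.height.items():
        mask = genders == gname
        if mask.any():
            height[mask] = rng.normal(hd.mean, hd.sd, mask.sum())
    height = np.clip(height, 1.4, 2.2)
    weight = bmi * height**2
    age = _trunc_normal(rng, n, profile.age)
    sleep = np.clip(rng.normal(profile.sleep.mean, profile.sleep.sd, n), 0.0, 24.0)
    cigarettes = rng.poisson(profile.cigarettes_mean, n).astype(float)
    household = 1 + rng.poisson(2.0, n)
    zips = np.array([f"46{i:03d}" for i in range(profile.zip_pool)])
    dx = rng.random((n, 4)) < profile.disease_prob
    edu = rng.choice(_EDUCATION[0], size=n, p=_EDUCATION[1])
    mar = rng.choice(_MARITAL[0], size=n, p=_MARITAL[1])
    act = rng.choice(len(_MAIN_ACTIVITY[0]), size=n, p=_MAIN_ACTIVITY[1])
    zidx = rng.integers(0, len(zips), n)
    return [
        PersonalRecord(
            weight=float(weight[i]),
            height=float(height[i]),
            gender=Gender(genders[i]),
            age=float(age[i]),
            education_level=str(edu[i]),
            marital_status=str(mar[i]),
            household_size=int(household[i]),
            main_activity=_MAIN_ACTIVITY[0][act[i]],
            zip_code=str(zips[zidx[i]]),
            sleep_hours=float(sleep[i]),
            cigarettes=float(cigarettes[i]),
            dx_hypertension=bool(dx[i, 0]),
            dx_diabetes=bool(dx[i, 1]),
            dx_cholesterol=bool(dx[i, 2]),
            dx_cardiovascular=bool(dx[i, 3]),
        )
        for i in range(n)
    ]


def _item_rates(profile: SimProfile) -> tuple[list[str], np.ndarray]:
    """Calibrated per-item Poisson rates over the canonical roster."""
    groups = _config.items_by_group()
    bins = tuple(profile.level_bins)
    reps = tuple(profile.level_representatives)
    items: list[str] = []
    rates: list[float] = []
    for group, group_items in sorted(groups.items()):
        mean = profile.food_weekly_means.get(group, 0.0)
        per_item = mean / len(group_items)
        lam = _poisson_rate_for_mean(per_item, bins, reps)
        for it in sorted(group_items):
            items.append(it)
            rates.append(lam)
    return items, np.asarray(rates)


def generate_diet_batch(
    profile: SimProfile, n: int, rng: np.random.Generator
) -> list[DietRecord]:
    items, rates = _item_rates(profile)
    counts = rng.poisson(rates, size=(n, len(items)))
    levels = _levels_for_counts(counts, profile.level_bins)
    return [
        DietRecord(
            answers={
                item: FrequencyLevel(int(levels[i, j])) for j, item in enumerate(items)
            }
        )
        for i in range(n)
    ]


def diet_group_units(record: DietRecord, profile: SimProfile) -> dict[str, float]:
    """Weekly units per food group implied by a record's levels.

    Uses the profile's level representatives — the inverse of the
    binning applied at generation time.
    """
    reps = profile.level_representatives
    groups = _config.items_by_group()
    return {
        group: sum(reps[int(record.answers[item])] for item in group_items)
        for group, group_items in groups.items()
    }


def generate_activity_batch(
    profile: SimProfile, n: int, rng: np.random.Generator
) -> list[ActivityRecord]:
    a = profile.activity
    shape = profile.minutes_shape

    def days(mean: float) -> np.ndarray:
        return rng.binomial(7, min(mean / 7.0, 1.0), n).astype(float)

    def minutes(mean: float, cap: float = 960.0) -> np.ndarray:
        if mean <= 0:
            return np.zeros(n)
        return np.clip(rng.gamma(shape, mean / shape, n), 0.0, cap)

    vig_d = days(a["vigorous_days"])
    mod_d = days(a["moderate_days"])
    walk_d = days(a["walk_days"])
    vig_m = minutes(a["vigorous_minutes"])
    mod_m = minutes(a["moderate_minutes"])
    walk_m = minutes(a["walk_minutes"])
    sit = np.clip(
        rng.gamma(shape, a["sitting_hours"] / shape, n) if a["sitting_hours"] > 0
        else np.zeros(n),
        0.0,
        168.0,
    )
    return [
        ActivityRecord(
            vigorous_days=float(vig_d[i]),
            vigorous_minutes=float(vig_m[i]),
            moderate_days=float(mod_d[i]),
            moderate_minutes=float(mod_m[i]),
            walk_days=float(walk_d[i]),
            walk_minutes=float(walk_m[i]),
            sitting_hours=float(sit[i]),
        )
        for i in range(n)
    ]


def generate_personal(profile: SimProfile, rng: np.random.Generator) -> PersonalRecord:
    return generate_personal_batch(profile, 1, rng)[0]


def generate_diet(profile: SimProfile, rng: np.random.Generator) -> DietRecord:
    return generate_diet_batch(profile, 1, rng)[0]


def generate_activity(profile: SimProfile, rng: np.random.Generator) -> ActivityRecord:
    return generate_activity_batch(profile, 1, rng)[0]


def generate_network(
    profile: SimProfile, user_ids: Sequence[str], rng: np.random.Generator
) -> list[Relation]:
    """Planted-partition relation list over the given users.

    A configured fraction of users is held out edgeless; the rest are
    split into near-equal blocks.  The within-block probability is
    solved so the expected edge count matches ``n * mean_degree / 2``
    given the between-block probability.  Each realised edge gets one
    relation type drawn from the configured type distribution.
    """
    net = profile.network
    n = len(user_ids)
    if n != profile.n:
        raise ValueError(f"expected {profile.n} users, got {n}")
    if n == 0:
        return []
    n_iso = int(round(net.isolated_fraction * n))
    order = rng.permutation(n)
    isolated = set(order[:n_iso])
    members = [i for i in range(n) if i not in isolated]
    m = len(members)
    if m < 2:
        return []

    n_blocks = min(net.n_blocks, m)
    blocks = np.array_split(rng.permutation(members), n_blocks)
    block_of = {}
    for b, blk in enumerate(blocks):
        for i in blk:
            block_of[int(i)] = b

    target_edges = n * net.mean_degree / 2.0
    within_pairs = sum(len(b) * (len(b) - 1) // 2 for b in blocks)
    total_pairs = m * (m - 1) // 2
    between_pairs = total_pairs - within_pairs
    if within_pairs == 0:
        p_in, p_out = 0.0, min(1.0, target_edges / max(between_pairs, 1))
    else:
        p_out = net.p_between
        p_in = (target_edges - p_out * between_pairs) / within_pairs
        p_in = float(np.clip(p_in, 0.0, 1.0))

    types = list(net.relation_type_probs)
    tprobs = np.array([net.relation_type_probs[t] for t in types])
    tprobs = tprobs / tprobs.sum()

    relations: list[Relation] = []
    for ai in range(m):
        for bi in range(ai + 1, m):
            i, j = members[ai], members[bi]
            p = p_in if block_of[i] == block_of[j] else p_out
            if rng.random() < p:
                t = types[rng.choice(len(types), p=tprobs)]
                relations.append(
                    Relation(
                        user_a=user_ids[i],
                        user_b=user_ids[j],
                        relation_type=RelationType(t),
                    ).canonical()
                )
    return relations


def generate_cohort(
    profile: SimProfile, n: Optional[int] = None, seed: Optional[int] = None
) -> Cohort:
    """A complete validation-clean cohort from one profile.

    The master seed spawns independent per-section streams (personal,
    diet, activity, network), so each section is reproducible on its own
    and the cohort is a pure function of (profile, seed).
    """
    if n is not None or seed is not None:
        profile = profile.model_copy(
            update={k: v for k, v in (("n", n), ("seed", seed)) if v is not None}
        )
    ss = np.random.SeedSequence(profile.seed)
    rng_p, rng_d, rng_a, rng_n = (np.random.default_rng(s) for s in ss.spawn(4))
    user_ids = [f"u{i:04d}" for i in range(profile.n)]
    personals = generate_personal_batch(profile, profile.n, rng_p)
    diets = generate_diet_batch(profile, profile.n, rng_d)
    activities = generate_activity_batch(profile, profile.n, rng_a)
    cohort = Cohort(
        assessments={
            uid: Assessment(
                user_id=uid, personal=p, diet=d, activity=a, language="es"
            )
            for uid, p, d, a in zip(user_ids, personals, diets, activities)
        },
        relations=generate_network(profile, user_ids, rng_n),
    )
    return cohort
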