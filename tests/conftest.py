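import numpy as np
import pytest

from wakamola.conversation import DialogueSpec
from wakamola.domain import (
    ActivityRecord,
    Assessment,
    Cohort,
    DietRecord,
    FrequencyLevel,
    PersonalRecord,
    Relation,
)
from wakamola.scoring import ScoreTable, ScoringParams
from wakamola.simulate import load_profile


@pytest.fixture(scope="session")
def table() -> ScoreTable:
    return ScoreTable.from_config()


@pytest.fixture(scope="session")
def params() -> ScoringParams:
    return ScoringParams()


@pytest.fixture(scope="session")
def profile():
    return load_profile("pilot2019")


@pytest.fixture(scope="session")
def dialogue_spec() -> DialogueSpec:
    return DialogueSpec.load()


def best_diet(table: ScoreTable) -> DietRecord:
    """The healthiest complete diet record under a score table."""
    answers = {
        item: FrequencyLevel(
            min(range(6), key=lambda lv: table.penalty[(item, lv)])
        )
        for item in table.item_ids
    }
    return DietRecord(answers=answers)


def worst_diet(table: ScoreTable) -> DietRecord:
    answers = {
        item: FrequencyLevel(
            max(range(6), key=lambda lv: table.penalty[(item, lv)])
        )
        for item in table.item_ids
    }
    return DietRecord(answers=answers)


def saturated_activity() -> ActivityRecord:
    # 7 days x 180 min vigorous = 10080 MET-min >> 3000 reference
    return ActivityRecord(vigorous_days=7, vigorous_minutes=180)


def normal_personal() -> PersonalRecord:
    return PersonalRecord(weight=65.0, height=1.75)  # BMI 21.2, normal


def max_assessment(user_id: str, table: ScoreTable) -> Assessment:
    """Diet, activity and BMI sub-scores all at their maxima."""
    return Assessment(
        user_id=user_id,
        personal=normal_personal(),
        diet=best_diet(table),
        activity=saturated_activity(),
    )


def clique_cohort(n: int, table: ScoreTable) -> Cohort:
    """n maximal users, fully connected by friend relations."""
    ids = [f"u{i:02d}" for i in range(n)]
    cohort = Cohort(
        assessments={uid: max_assessment(uid, table) for uid in ids}
    )
    for i in range(n):
        for j in range(i + 1, n):
            cohort.add_relation(
                Relation(user_a=ids[i], user_b=ids[j], relation_type="friend")
            )
    return cohort


def random_cohort(table: ScoreTable, seed: int, n: int = 20) -> Cohort:
    """A random valid cohort: random records, random edges."""
    rng = np.random.default_rng(seed)
    ids = [f"r{i:03d}" for i in range(n)]
    items = sorted(table.item_ids)
    cohort = Cohort()
    for uid in ids:
        diet = DietRecord(
            answers={
                it: FrequencyLevel(int(lv)) for it, lv in zip(items, rng.integers(0, 6, len(items)))
            }
        )
        personal = PersonalRecord(
            weight=float(rng.uniform(45, 160)),
            height=float(rng.uniform(1.45, 2.0)),
            sleep_hours=float(rng.uniform(4, 11)),
            age=float(rng.uniform(18, 90)),
        )
        activity = ActivityRecord(
            vigorous_days=float(rng.integers(0, 8)),
            vigorous_minutes=float(rng.uniform(0, 400)),
            moderate_days=float(rng.integers(0, 8)),
            moderate_minutes=float(rng.uniform(0, 400)),
            walk_days=float(rng.integers(0, 8)),
            walk_minutes=float(rng.uniform(0, 400)),
            sitting_hours=float(rng.uniform(0, 100)),
        )
        cohort.assessments[uid] = Assessment(
            user_id=uid, personal=personal, diet=diet, activity=activity
        )
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.15:
                cohort.add_relation(
                    Relation(
                        user_a=ids[i],
                        user_b=ids[j],
                        relation_type=["home", "family", "friend", "work"][
                            int(rng.integers(0, 4))
                        ],
                    )
                )
    return cohort
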