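"""Domain types for questionnaire-based obesity-status assessment.

The assessment is split into three interactive sections — Personal
(anthropometrics, sociodemographics, sleep, smoking, diagnosis flags),
Diet (a 51-item food-frequency questionnaire over six ordinal weekly
frequency levels) and Activity (the seven IPAQ short-form items) — plus
typed social relations (home / family / friend / work) between
participants.  A participant's assessment is *complete* when all three
questionnaire sections are present and pass validation; only completers
are scored.

Records are plain pydantic models; range invariants are enforced by the
explicit ``validate_*`` functions, which return structured violations
instead of raising, so that partially-filled or out-of-range submissions
can be inspected rather than rejected at construction time.
"""

from __future__ import annotations

from enum import Enum, IntEnum
from typing import Optional

from pydantic import BaseModel, Field

__all__ = [
    "Gender",
    "MainActivity",
    "RelationType",
    "FrequencyLevel",
    "BMICategory",
    "PersonalRecord",
    "DietRecord",
    "ActivityRecord",
    "Relation",
    "Assessment",
    "Cohort",
    "Violation",
    "DomainError",
    "FieldValidationError",
    "compute_bmi",
    "bmi_category",
    "validate_personal",
    "validate_diet",
    "validate_activity",
    "validate_assessment",
    "validate_cohort",
]


class DomainError(ValueError):
    """A value outside the domain of an operation (e.g. non-positive BMI)."""


class FieldValidationError(ValueError):
    """A record field violating its invariant; carries the field name."""

    def __init__(self, field: str, reason: str):
        self.field = field
        self.reason = reason
        super().__init__(f"{field}: {reason}")


class Gender(str, Enum):
    female = "female"
    male = "male"
    other = "other"


class MainActivity(str, Enum):
    study = "study"
    work = "work"
    other = "other"


class RelationType(str, Enum):
    home = "home"
    family = "family"
    friend = "friend"
    work = "work"


class FrequencyLevel(IntEnum):
    """Ordinal weekly consumption frequency of a food item.

    L0 never; L1 less than once a week; L2 1-2 times/week; L3 3-6
    times/week; L4 once a day; L5 twice a day or more.
    """

    L0 = 0
    L1 = 1
    L2 = 2
    L3 = 3
    L4 = 4
    L5 = 5


class BMICategory(str, Enum):
    underweight = "underweight"
    normal = "normal"
    overweight = "overweight"
    obesity1 = "obesity1"
    obesity2 = "obesity2"
    obesity3 = "obesity3"


# Half-open bands [lo, hi): gapless over (0, inf).
_BMI_BANDS: list[tuple[float, BMICategory]] = [
    (18.5, BMICategory.underweight),
    (25.0, BMICategory.normal),
    (30.0, BMICategory.overweight),
    (35.0, BMICategory.obesity1),
    (40.0, BMICategory.obesity2),
    (float("inf"), BMICategory.obesity3),
]


class PersonalRecord(BaseModel):
    """Answers to the Personal section.

    ``weight`` in kg, ``height`` in m, ``sleep_hours`` per day,
    ``cigarettes`` per day.  The four ``dx_*`` flags mean a diagnosis of
    (or medication for) the corresponding condition.
    """

    weight: float
    height: float
    gender: Gender = Gender.other
    age: float = 30.0
    education_level: str = "secondary"
    marital_status: str = "single"
    household_size: int = 1
    main_activity: MainActivity = MainActivity.other
    zip_code: str = ""
    sleep_hours: float = 8.0
    cigarettes: float = 0.0
    dx_hypertension: bool = False
    dx_diabetes: bool = False
    dx_cholesterol: bool = False
    dx_cardiovascular: bool = False


class DietRecord(BaseModel):
    """Answers to the 51-item food-frequency questionnaire.

    ``answers`` maps canonical food-item ids to frequency levels.  The
    canonical roster (each item assigned to one of 20 food groups) is
    configuration, shipped as the default score-table config.
    """

    answers: dict[str, FrequencyLevel] = Field(default_factory=dict)


class ActivityRecord(BaseModel):
    """The seven IPAQ short-form items.

    Days per week with vigorous / moderate activity and with at least 10
    continuous minutes of walking, typical minutes per session for each,
    and weekly sitting hours.
    """

    vigorous_days: float = 0.0
    vigorous_minutes: float = 0.0
    moderate_days: float = 0.0
    moderate_minutes: float = 0.0
    walk_days: float = 0.0
    walk_minutes: float = 0.0
    sitting_hours: float = 0.0


class Relation(BaseModel):
    """An undirected typed tie between two participants."""

    user_a: str
    user_b: str
    relation_type: RelationType

    def canonical(self) -> "Relation":
        """Endpoints in sorted order, the stored form of an undirected tie."""
        if self.user_a <= self.user_b:
            return self
        return Relation(
            user_a=self.user_b, user_b=self.user_a, relation_type=self.relation_type
        )

    def key(self) -> tuple[str, str, str]:
        c = self.canonical()
        return (c.user_a, c.user_b, c.relation_type.value)


class Assessment(BaseModel):
    """One participant's (possibly partial) questionnaire answers."""

    user_id: str
    personal: Optional[PersonalRecord] = None
    diet: Optional[DietRecord] = None
    activity: Optional[ActivityRecord] = None
    language: str = "es"

    def completed(self, item_ids: Optional[set[str]] = None) -> bool:
        """True iff all three sections are present and pass validation."""
        return not validate_assessment(self, item_ids=item_ids) and all(
            r is not None for r in (self.personal, self.diet, self.activity)
        )


class Cohort(BaseModel):
    """A set of assessments plus the typed relations among them."""

    assessments: dict[str, Assessment] = Field(default_factory=dict)
    relations: list[Relation] = Field(default_factory=list)

    def add_relation(self, relation: Relation) -> Relation:
        """Add a typed tie, idempotently; returns the stored canonical tie."""
        canon = relation.canonical()
        if canon.user_a == canon.user_b:
            raise DomainError(f"self-relation for user {canon.user_a!r}")
        keys = {r.key() for r in self.relations}
        if canon.key() not in keys:
            self.relations.append(canon)
        return canon

    def completed_ids(self, item_ids: Optional[set[str]] = None) -> list[str]:
        return sorted(
            uid for uid, a in self.assessments.items() if a.completed(item_ids)
        )


class Violation(BaseModel):
    """One invariant failure inside an assessment."""

    user_id: str
    section: str
    field: str
    reason: str


def compute_bmi(personal: PersonalRecord) -> float:
    """Body mass index, weight(kg) / height(m)^2.

    Raises :class:`FieldValidationError` naming the offending field when
    weight or height is outside its plausible range.
    """
    if not (20 <= personal.weight <= 400):
        raise FieldValidationError("weight", f"{personal.weight} outside [20, 400] kg")
    if not (0.9 <= personal.height <= 2.5):
        raise FieldValidationError("height", f"{personal.height} outside [0.9, 2.5] m")
    return personal.weight / personal.height**2


def bmi_category(bmi: float) -> BMICategory:
    """WHO-style BMI class over half-open bands [lo, hi).

    underweight <18.5; normal [18.5, 25); overweight [25, 30);
    obesity class 1 [30, 35); class 2 [35, 40); class 3 >=40.
    """
    if not bmi > 0:
        raise DomainError(f"BMI must be positive, got {bmi}")
    for hi, cat in _BMI_BANDS:
        if bmi < hi:
            return cat
    raise AssertionError("unreachable: bands cover (0, inf)")


_PERSONAL_RANGES: dict[str, tuple[float, float]] = {
    "weight": (20, 400),
    "height": (0.9, 2.5),
    "age": (14, 110),
    "sleep_hours": (0, 24),
}


def validate_personal(p: PersonalRecord) -> list[tuple[str, str]]:
    """(field, reason) pairs for every violated Personal invariant."""
    bad = []
    for field, (lo, hi) in _PERSONAL_RANGES.items():
        v = getattr(p, field)
        if not (lo <= v <= hi):
            bad.append((field, f"{v} outside [{lo}, {hi}]"))
    if p.household_size < 1:
        bad.append(("household_size", f"{p.household_size} < 1"))
    if p.cigarettes < 0:
        bad.append(("cigarettes", f"{p.cigarettes} < 0"))
    return bad


def validate_diet(
    d: DietRecord, item_ids: Optional[set[str]] = None
) -> list[tuple[str, str]]:
    """(field, reason) pairs; checks roster completeness when given one."""
    bad = []
    if item_ids is not None:
        missing = item_ids - d.answers.keys()
        extra = d.answers.keys() - item_ids
        if missing:
            bad.append(
                ("answers", f"missing {len(missing)} items: {sorted(missing)[:5]}...")
            )
        if extra:
            bad.append(("answers", f"unknown items: {sorted(extra)[:5]}"))
    return bad


_ACTIVITY_RANGES: dict[str, tuple[float, float]] = {
    "vigorous_days": (0, 7),
    "moderate_days": (0, 7),
    "walk_days": (0, 7),
    "vigorous_minutes": (0, 960),
    "moderate_minutes": (0, 960),
    "walk_minutes": (0, 960),
    "sitting_hours": (0, 168),
}


def validate_activity(a: ActivityRecord) -> list[tuple[str, str]]:
    bad = []
    for field, (lo, hi) in _ACTIVITY_RANGES.items():
        v = getattr(a, field)
        if not (lo <= v <= hi):
            bad.append((field, f"{v} outside [{lo}, {hi}]"))
    return bad


def validate_assessment(
    assessment: Assessment, item_ids: Optional[set[str]] = None
) -> list[Violation]:
    """All invariant violations in the present sections of an assessment.

    An absent section is not a violation by itself (assessments may be
    partial); completeness is the caller's question, via
    :meth:`Assessment.completed`.
    """
    if item_ids is None:
        from .config import default_item_ids

        item_ids = default_item_ids()
    out: list[Violation] = []
    uid = assessment.user_id
    if assessment.personal is not None:
        for field, reason in validate_personal(assessment.personal):
            out.append(
                Violation(user_id=uid, section="personal", field=field, reason=reason)
            )
    if assessment.diet is not None:
        for field, reason in validate_diet(assessment.diet, item_ids):
            out.append(
                Violation(user_id=uid, section="diet", field=field, reason=reason)
            )
    if assessment.activity is not None:
        for field, reason in validate_activity(assessment.activity):
            out.append(
                Violation(user_id=uid, section="activity", field=field, reason=reason)
            )
    return out


def validate_cohort(
    cohort: Cohort, item_ids: Optional[set[str]] = None
) -> list[Violation]:
    """Violations across all assessments plus relation integrity checks."""
    out: list[Violation] = []
    for a in cohort.assessments.values():
        out.extend(validate_assessment(a, item_ids=item_ids))
    seen: set[tuple[str, str, str]] = set()
    for r in cohort.relations:
        for endpoint in (r.user_a, r.user_b):
            if endpoint not in cohort.assessments:
                out.append(
                    Violation(
                        user_id=endpoint,
                        section="relations",
                        field="endpoint",
                        reason=f"relation {r.key()} references unknown user",
                    )
                )
        if r.user_a == r.user_b:
            out.append(
                Violation(
                    user_id=r.user_a,
                    section="relations",
                    field="endpoints",
                    reason="self-relation",
                )
            )
        k = r.key()
        if k in seen:
            out.append(
                Violation(
                    user_id=r.user_a,
                    section="relations",
                    field="duplicate",
                    reason=f"duplicate relation {k}",
                )
            )
        seen.add(k)
    return out
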