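"""Transport-agnostic dialogue engine for administering the assessment.

The engine reproduces the chatbot's structure without any messaging
platform: a main menu of six sections (personal, diet, activity, the
invitation/sharing section, the status report, and project info), typed
validated answers, typed invitations whose redemption creates relations,
and a localized status message.  A *transport* is anything that shows a
prompt string and returns an answer string; the engine itself is a pure
state machine over :class:`Session`, so console transports, scripted
test transcripts or a messaging bridge all produce identical state
trajectories for identical inputs.

Dialogue content (prompts, item names, level labels, status template) is
a per-language JSON file; Spanish, English and Catalan ship with the
package.  Question ids are language-independent, so translation
completeness is mechanically checkable with
:func:`check_translation_completeness`.
"""

from __future__ import annotations

import base64
import binascii
import json
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Optional

from pydantic import BaseModel, Field

from . import config as _config
from .domain import (
    ActivityRecord,
    Assessment,
    Cohort,
    DietRecord,
    DomainError,
    FrequencyLevel,
    Gender,
    MainActivity,
    PersonalRecord,
    Relation,
    RelationType,
)
from .scoring import ScoreCard

__all__ = [
    "Question",
    "DialogueSpec",
    "Session",
    "Invite",
    "start_session",
    "handle_answer",
    "generate_invites",
    "redeem_invite",
    "render_status",
    "check_translation_completeness",
    "build_questions",
    "UnknownLanguageError",
    "MissingTranslationError",
]

SECTIONS = ["personal", "diet", "activity", "wakanet", "wakastatus", "about"]
LANGUAGES = ["es", "en", "ca"]


class UnknownLanguageError(ValueError):
    def __init__(self, language: str):
        super().__init__(
            f"unknown language {language!r}; available: {', '.join(LANGUAGES)}"
        )
        self.available = list(LANGUAGES)


class MissingTranslationError(KeyError):
    def __init__(self, language: str, key: str):
        super().__init__(f"language {language!r} is missing translation key {key!r}")
        self.key = key


@dataclass(frozen=True)
class Question:
    """One validated question of an interactive section."""

    id: str
    section: str
    kind: str  # float | int | choice | bool | level
    field: str
    bounds: Optional[tuple[float, float]] = None
    choices: Optional[tuple[str, ...]] = None


def build_questions() -> list[Question]:
    """The canonical question list: 15 personal + 51 diet + 7 activity.

    Validation bounds mirror the domain invariants; diet questions are
    one per canonical food item, answered as a frequency level 0-5.
    """
    qs: list[Question] = []

    def personal(field: str, kind: str, **kw) -> None:
        qs.append(Question(f"personal.{field}", "personal", kind, field, **kw))

    personal("weight", "float", bounds=(20, 400))
    personal("height", "float", bounds=(0.9, 2.5))
    personal("gender", "choice", choices=tuple(g.value for g in Gender))
    personal("age", "float", bounds=(14, 110))
    personal("education_level", "choice", choices=("primary", "secondary", "university"))
    personal("marital_status", "choice", choices=("single", "married", "other"))
    personal("household_size", "int", bounds=(1, 30))
    personal("main_activity", "choice", choices=tuple(m.value for m in MainActivity))
    personal("zip_code", "text")
    personal("sleep_hours", "float", bounds=(0, 24))
    personal("cigarettes", "float", bounds=(0, 200))
    for dx in ("dx_hypertension", "dx_diabetes", "dx_cholesterol", "dx_cardiovascular"):
        personal(dx, "bool")

    for item in sorted(_config.default_item_ids()):
        qs.append(Question(f"diet.{item}", "diet", "level", item))

    for f, hi in [
        ("vigorous_days", 7),
        ("vigorous_minutes", 960),
        ("moderate_days", 7),
        ("moderate_minutes", 960),
        ("walk_days", 7),
        ("walk_minutes", 960),
        ("sitting_hours", 168),
    ]:
        qs.append(Question(f"activity.{f}", "activity", "float", f, bounds=(0, hi)))
    return qs


class DialogueSpec(BaseModel):
    """Questions plus per-language content files."""

    translations: dict[str, dict]

    @classmethod
    def load(cls, directory: Optional[str | Path] = None) -> "DialogueSpec":
        translations = {}
        if directory is None:
            root = resources.files("wakamola") / "data" / "dialogue"
            for lang in LANGUAGES:
                translations[lang] = json.loads(
                    (root / f"{lang}.json").read_text(encoding="utf-8")
                )
        else:
            for p in Path(directory).glob("*.json"):
                t = json.loads(p.read_text(encoding="utf-8"))
                translations[t["language"]] = t
        return cls(translations=translations)

    def text(self, language: str, key: str) -> str:
        if language not in self.translations:
            raise UnknownLanguageError(language)
        t = self.translations[language]
        head, _, rest = key.partition(".")
        if not rest:
            if head not in t:
                raise MissingTranslationError(language, key)
            return t[head]
        sub = t.get(head)
        if not isinstance(sub, dict) or rest not in sub:
            raise MissingTranslationError(language, key)
        return sub[rest]


def check_translation_completeness(
    spec: DialogueSpec, questions: Optional[list[Question]] = None
) -> dict[str, list[str]]:
    """Missing translation keys per language (empty dict = complete)."""
    questions = questions or build_questions()
    required = ["menu", "reprompt", "section_done", "diet_template", "status_template"]
    required += [f"section_names.{s}" for s in SECTIONS]
    required += [f"levels.{lv}" for lv in range(6)]
    required += [f"invite.{t.value}" for t in RelationType]
    required += [f"categories.{c}" for c in (
        "underweight", "normal", "overweight", "obesity1", "obesity2", "obesity3"
    )]
    for q in questions:
        if q.section == "diet":
            required.append(f"items.{q.field}")
        else:
            required.append(f"prompts.{q.id}")
    missing: dict[str, list[str]] = {}
    for lang in spec.translations:
        bad = []
        for key in required:
            try:
                spec.text(lang, key)
            except MissingTranslationError:
                bad.append(key)
        if bad:
            missing[lang] = bad
    return missing


class Session(BaseModel):
    """Dialogue state of one participant."""

    user_id: str
    language: str
    section: Optional[str] = None  # None = at main menu
    q_index: int = 0
    pending: dict[str, object] = Field(default_factory=dict)
    assessment: Assessment
    completed_sections: list[str] = Field(default_factory=list)


class Invite(BaseModel):
    """A shareable typed invitation."""

    token: str
    relation_type: RelationType
    message: str


class _EngineCtx:
    """Bundle of the static pieces handle_answer needs."""

    def __init__(self, spec: DialogueSpec):
        self.spec = spec
        self.questions = build_questions()
        self.by_section: dict[str, list[Question]] = {}
        for q in self.questions:
            self.by_section.setdefault(q.section, []).append(q)


_LEVEL_KEYS = [str(i) for i in range(6)]


def _menu_text(spec: DialogueSpec, language: str) -> str:
    names = [spec.text(language, f"section_names.{s}") for s in SECTIONS]
    lines = [spec.text(language, "menu")]
    lines += [f"{i + 1}. {name}" for i, name in enumerate(names)]
    return "\n".join(lines)


def _prompt_for(spec: DialogueSpec, language: str, q: Question) -> str:
    if q.section == "diet":
        item = spec.text(language, f"items.{q.field}")
        levels = " / ".join(
            f"{lv}={spec.text(language, f'levels.{lv}')}" for lv in range(6)
        )
        return spec.text(language, "diet_template").format(item=item, levels=levels)
    text = spec.text(language, f"prompts.{q.id}")
    if q.kind == "choice":
        text += " [" + "/".join(q.choices) + "]"
    elif q.kind == "bool":
        text += " [yes/no]"
    return text


def start_session(
    user_id: str, language: str, spec: DialogueSpec
) -> tuple[Session, str]:
    """A fresh session at the main menu, plus the menu prompt."""
    if language not in spec.translations:
        raise UnknownLanguageError(language)
    session = Session(
        user_id=user_id,
        language=language,
        assessment=Assessment(user_id=user_id, language=language),
    )
    return session, _menu_text(spec, language)


def _parse(q: Question, text: str):
    text = text.strip()
    if q.kind == "float" or q.kind == "int":
        try:
            v = float(text)
        except ValueError:
            return None
        if q.bounds and not (q.bounds[0] <= v <= q.bounds[1]):
            return None
        return int(v) if q.kind == "int" else v
    if q.kind == "choice":
        low = text.lower()
        if low in q.choices:
            return low
        if low.isdigit() and 1 <= int(low) <= len(q.choices):
            return q.choices[int(low) - 1]
        return None
    if q.kind == "bool":
        low = text.lower()
        if low in ("yes", "y", "si", "sí", "true", "1"):
            return True
        if low in ("no", "n", "false", "0"):
            return False
        return None
    if q.kind == "level":
        if text in _LEVEL_KEYS:
            return FrequencyLevel(int(text))
        return None
    return text  # free text


def _finish_section(session: Session, section: str) -> None:
    if section == "personal":
        session.assessment.personal = PersonalRecord(**session.pending)
    elif section == "diet":
        session.assessment.diet = DietRecord(answers=dict(session.pending))
    elif section == "activity":
        session.assessment.activity = ActivityRecord(**session.pending)
    if section not in session.completed_sections:
        session.completed_sections.append(section)
    session.pending = {}
    session.section = None
    session.q_index = 0


def handle_answer(
    session: Session,
    text: str,
    spec: DialogueSpec,
    status_provider: Optional[Callable[[str], Optional[ScoreCard]]] = None,
) -> tuple[Session, str]:
    """Advance the dialogue by one user utterance.

    Valid answers store the value and move to the next prompt; invalid
    answers leave the session unchanged and return the re-prompt.  At
    the menu, a section number or name enters that section; completed
    questionnaire sections are summarised rather than re-entered (the
    word ``restart`` re-enters explicitly).
    """
    ctx = _EngineCtx(spec)
    lang = session.language

    if session.section is None:
        choice = text.strip().lower()
        restart = choice.endswith("!")
        choice = choice.rstrip("!")
        section = None
        if choice.isdigit() and 1 <= int(choice) <= len(SECTIONS):
            section = SECTIONS[int(choice) - 1]
        elif choice in SECTIONS:
            section = choice
        if section is None:
            return session, _menu_text(spec, lang)
        if section == "about":
            return session, spec.text(lang, "section_names.about")
        if section == "wakanet":
            invites = generate_invites(session, spec)
            return session, "\n".join(i.message for i in invites)
        if section == "wakastatus":
            card = status_provider(session.user_id) if status_provider else None
            if card is None:
                return session, spec.text(lang, "section_done")
            return session, render_status(card, lang, spec)
        if section in session.completed_sections and not restart:
            return session, spec.text(lang, "section_done")
        session.section = section
        session.q_index = 0
        session.pending = {}
        return session, _prompt_for(spec, lang, ctx.by_section[section][0])

    questions = ctx.by_section[session.section]
    q = questions[session.q_index]
    value = _parse(q, text)
    if value is None:
        return session, spec.text(lang, "reprompt") + "\n" + _prompt_for(spec, lang, q)
    session.pending[q.field] = value
    session.q_index += 1
    if session.q_index >= len(questions):
        done = session.section
        _finish_section(session, done)
        return session, spec.text(lang, "section_done") + "\n" + _menu_text(spec, lang)
    return session, _prompt_for(spec, lang, questions[session.q_index])


def encode_token(inviter: str, relation_type: RelationType, ts: Optional[int] = None) -> str:
    payload = json.dumps(
        {"u": inviter, "t": relation_type.value, "ts": int(ts or time.time())},
        sort_keys=True,
    )
    return base64.urlsafe_b64encode(payload.encode()).decode().rstrip("=")


def decode_token(token: str) -> tuple[str, RelationType, int]:
    try:
        pad = "=" * (-len(token) % 4)
        payload = json.loads(base64.urlsafe_b64decode(token + pad))
        return payload["u"], RelationType(payload["t"]), int(payload["ts"])
    except (binascii.Error, json.JSONDecodeError, KeyError, ValueError) as e:
        raise DomainError(f"malformed invite token: {e}") from e


def generate_invites(session: Session, spec: DialogueSpec) -> list[Invite]:
    """Exactly four invites, one per relation type, in the session language."""
    out = []
    for rt in RelationType:
        token = encode_token(session.user_id, rt)
        msg = spec.text(session.language, f"invite.{rt.value}").format(token=token)
        out.append(Invite(token=token, relation_type=rt, message=msg))
    return out


def redeem_invite(token: str, new_user_id: str, cohort: Cohort) -> Relation:
    """Turn a redeemed invitation into a typed relation (idempotent)."""
    inviter, rtype, _ = decode_token(token)
    if new_user_id == inviter:
        raise DomainError("self-invitation: inviter and redeemer are the same user")
    if new_user_id not in cohort.assessments:
        cohort.assessments[new_user_id] = Assessment(user_id=new_user_id)
    if inviter not in cohort.assessments:
        cohort.assessments[inviter] = Assessment(user_id=inviter)
    return cohort.add_relation(
        Relation(user_a=inviter, user_b=new_user_id, relation_type=rtype)
    )


def render_status(scorecard: ScoreCard, language: str, spec: DialogueSpec) -> str:
    """Localized status message with the five scores and the BMI class.

    Scores print with one decimal; user-facing wording says "status",
    never "risk".
    """
    category = spec.text(language, f"categories.{scorecard.bmi_cat.value}")
    return spec.text(language, "status_template").format(
        wakastatus=f"{scorecard.wakastatus:.1f}",
        diet=f"{scorecard.diet_score:.1f}",
        activity=f"{scorecard.activity_score:.1f}",
        bmi_score=f"{scorecard.bmi_score:.1f}",
        social=f"{scorecard.social_score:.1f}",
        bmi=f"{scorecard.bmi:.1f}",
        category=category,
    )
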