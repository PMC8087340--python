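"""Cohort file formats: per-section CSVs and a single JSON bundle.

CSV layout (UTF-8, header row mandatory, one row per participant,
missing answers as empty fields):

* ``personal.csv`` — user_id, language, then the Personal fields;
* ``diet.csv`` — user_id, then one column per food item (levels 0-5);
* ``activity.csv`` — user_id, then the seven IPAQ fields;
* ``relations.csv`` — user_a, user_b, relation_type.

An entirely empty section row means the section is absent.  Floats are
written with ``repr`` so reading a cohort back and rewriting it
reproduces the files byte for byte.
"""

from __future__ import annotations

import csv
from enum import Enum
from pathlib import Path
from typing import Optional

from .domain import (
    ActivityRecord,
    Assessment,
    Cohort,
    DietRecord,
    FrequencyLevel,
    PersonalRecord,
    Relation,
)

__all__ = [
    "write_cohort_csvs",
    "read_cohort_csvs",
    "write_cohort_json",
    "read_cohort_json",
]

_PERSONAL_FIELDS = [
    "weight",
    "height",
    "gender",
    "age",
    "education_level",
    "marital_status",
    "household_size",
    "main_activity",
    "zip_code",
    "sleep_hours",
    "cigarettes",
    "dx_hypertension",
    "dx_diabetes",
    "dx_cholesterol",
    "dx_cardiovascular",
]
_ACTIVITY_FIELDS = [
    "vigorous_days",
    "vigorous_minutes",
    "moderate_days",
    "moderate_minutes",
    "walk_days",
    "walk_minutes",
    "sitting_hours",
]


def _fmt(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, Enum):
        return str(v.value)
    if isinstance(v, float):
        return repr(v)
    return str(v)


def _write_rows(path: Path, header: list[str], rows: list[list[str]]) -> None:
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        w.writerows(rows)


def write_cohort_csvs(cohort: Cohort, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    users = sorted(cohort.assessments)

    rows = []
    for uid in users:
        a = cohort.assessments[uid]
        if a.personal is None:
            rows.append([uid, a.language] + [""] * len(_PERSONAL_FIELDS))
        else:
            rows.append(
                [uid, a.language]
                + [_fmt(getattr(a.personal, f)) for f in _PERSONAL_FIELDS]
            )
    _write_rows(
        directory / "personal.csv", ["user_id", "language"] + _PERSONAL_FIELDS, rows
    )

    item_ids = sorted(
        {
            item
            for a in cohort.assessments.values()
            if a.diet is not None
            for item in a.diet.answers
        }
    )
    rows = []
    for uid in users:
        a = cohort.assessments[uid]
        if a.diet is None:
            rows.append([uid] + [""] * len(item_ids))
        else:
            rows.append(
                [uid]
                + [
                    str(int(a.diet.answers[item])) if item in a.diet.answers else ""
                    for item in item_ids
                ]
            )
    _write_rows(directory / "diet.csv", ["user_id"] + item_ids, rows)

    rows = []
    for uid in users:
        a = cohort.assessments[uid]
        if a.activity is None:
            rows.append([uid] + [""] * len(_ACTIVITY_FIELDS))
        else:
            rows.append(
                [uid] + [_fmt(getattr(a.activity, f)) for f in _ACTIVITY_FIELDS]
            )
    _write_rows(directory / "activity.csv", ["user_id"] + _ACTIVITY_FIELDS, rows)

    rows = [
        [r.user_a, r.user_b, r.relation_type.value]
        for r in sorted(cohort.relations, key=lambda r: r.key())
    ]
    _write_rows(directory / "relations.csv", ["user_a", "user_b", "relation_type"], rows)


def _parse_personal(row: dict[str, str]) -> Optional[PersonalRecord]:
    if all(row[f] == "" for f in _PERSONAL_FIELDS):
        return None
    kwargs = {}
    for f in _PERSONAL_FIELDS:
        v = row[f]
        if f.startswith("dx_"):
            kwargs[f] = v == "true"
        elif f == "household_size":
            kwargs[f] = int(v)
        elif f in ("gender", "education_level", "marital_status", "main_activity", "zip_code"):
            kwargs[f] = v
        else:
            kwargs[f] = float(v)
    return PersonalRecord(**kwargs)


def read_cohort_csvs(directory: str | Path) -> Cohort:
    directory = Path(directory)
    assessments: dict[str, Assessment] = {}

    with (directory / "personal.csv").open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            assessments[row["user_id"]] = Assessment(
                user_id=row["user_id"],
                language=row["language"],
                personal=_parse_personal(row),
            )

    with (directory / "diet.csv").open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            uid = row["user_id"]
            answers = {
                item: FrequencyLevel(int(v))
                for item, v in row.items()
                if item != "user_id" and v != ""
            }
            if answers and uid in assessments:
                assessments[uid].diet = DietRecord(answers=answers)

    with (directory / "activity.csv").open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            uid = row["user_id"]
            if all(row[f] == "" for f in _ACTIVITY_FIELDS) or uid not in assessments:
                continue
            assessments[uid].activity = ActivityRecord(
                **{f: float(row[f]) for f in _ACTIVITY_FIELDS}
            )

    relations = []
    with (directory / "relations.csv").open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            relations.append(
                Relation(
                    user_a=row["user_a"],
                    user_b=row["user_b"],
                    relation_type=row["relation_type"],
                ).canonical()
            )
    return Cohort(assessments=assessments, relations=relations)


def write_cohort_json(cohort: Cohort, path: str | Path) -> None:
    Path(path).write_text(cohort.model_dump_json(indent=1), encoding="utf-8")


def read_cohort_json(path: str | Path) -> Cohort:
    return Cohort.model_validate_json(Path(path).read_text(encoding="utf-8"))
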