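"""Cohort summary report: BMI shares, score statistics, habit tables.

Produces the descriptive tables a pilot write-up prints: BMI-category
counts with one-decimal percentages (round half-up), means and SDs of
the five scores, mean weekly consumption units per food group (sorted
ascending), mean activity/sitting/sleep values, and the network summary.
SDs are population SDs (ddof=0).
"""

from __future__ import annotations

from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import config as _config
from .domain import Cohort, bmi_category, compute_bmi
from .network import NetworkSummary, round_half_up
from .scoring import ScoreCard

__all__ = [
    "bmi_category_table",
    "score_stats",
    "food_group_table",
    "activity_table",
    "render_report",
]

_CATEGORIES = ["underweight", "normal", "overweight", "obesity1", "obesity2", "obesity3"]


def bmi_category_table(scorecards: Mapping[str, ScoreCard]) -> pd.DataFrame:
    """Count and percentage (1 dp, half-up) of each BMI category."""
    n = len(scorecards)
    counts = {c: 0 for c in _CATEGORIES}
    for sc in scorecards.values():
        counts[sc.bmi_cat.value] += 1
    rows = [
        {
            "category": c,
            "count": counts[c],
            "percent": round_half_up(100.0 * counts[c] / n) if n else 0.0,
        }
        for c in _CATEGORIES
    ]
    return pd.DataFrame(rows)


def score_stats(scorecards: Mapping[str, ScoreCard]) -> pd.DataFrame:
    """Mean and population SD of BMI and the five scores."""
    cols = [
        "bmi",
        "wakastatus",
        "diet_score",
        "activity_score",
        "bmi_score",
        "social_score",
    ]
    rows = []
    for col in cols:
        vals = np.array([getattr(sc, col) for sc in scorecards.values()], dtype=float)
        rows.append(
            {
                "measure": col,
                "mean": float(vals.mean()) if len(vals) else float("nan"),
                "sd": float(vals.std(ddof=0)) if len(vals) else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def food_group_table(
    cohort: Cohort, representatives: Optional[list[float]] = None
) -> pd.DataFrame:
    """Mean weekly units per food group, ascending by mean.

    Frequency levels map back to weekly units via the level
    representatives (default: the shipped generator's inverse mapping).
    """
    reps = representatives or [0.0, 0.5, 2.0, 4.5, 9.0, 16.0]
    groups = _config.items_by_group()
    labels = _config.default_group_labels()
    diets = [a.diet for a in cohort.assessments.values() if a.diet is not None]
    rows = []
    for gid, items in groups.items():
        per_user = [
            sum(reps[int(d.answers[i])] for i in items if i in d.answers) for d in diets
        ]
        rows.append(
            {
                "group": labels.get(gid, gid),
                "mean_units_per_week": float(np.mean(per_user)) if per_user else 0.0,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["mean_units_per_week", "group"])
        .reset_index(drop=True)
    )


def activity_table(cohort: Cohort) -> pd.DataFrame:
    """Mean weekly activity, sitting and daily sleep values."""
    acts = [a.activity for a in cohort.assessments.values() if a.activity is not None]
    pers = [a.personal for a in cohort.assessments.values() if a.personal is not None]
    rows = []
    for label, values in [
        ("Vigorous physical activities (times per week)", [a.vigorous_days for a in acts]),
        ("Vigorous physical activities (minutes)", [a.vigorous_minutes for a in acts]),
        ("Moderate physical activities (times per week)", [a.moderate_days for a in acts]),
        ("Moderate physical activities (minutes)", [a.moderate_minutes for a in acts]),
        ("Walked at least 10 continuous minutes (days per week)", [a.walk_days for a in acts]),
        ("Walking time (minutes)", [a.walk_minutes for a in acts]),
        ("Sitting (hours per week)", [a.sitting_hours for a in acts]),
        ("Sleep (hours per day)", [p.sleep_hours for p in pers]),
    ]:
        rows.append(
            {"activity": label, "mean": float(np.mean(values)) if values else 0.0}
        )
    return pd.DataFrame(rows)


def render_report(
    cohort: Cohort,
    scorecards: Mapping[str, ScoreCard],
    summary: Optional[NetworkSummary] = None,
    seed: Optional[int] = None,
    config_digest: Optional[str] = None,
) -> str:
    """Plain-text cohort report."""
    lines = ["Cohort report", "=" * 13, ""]
    lines.append(f"Participants scored (completed all sections): {len(scorecards)}")
    lines.append("")
    lines.append("BMI categories")
    lines.append(bmi_category_table(scorecards).to_string(index=False))
    lines.append("")
    lines.append("Scores (mean, population SD)")
    lines.append(score_stats(scorecards).to_string(index=False))
    lines.append("")
    lines.append("Food groups, mean units per week (ascending)")
    lines.append(food_group_table(cohort).to_string(index=False))
    lines.append("")
    lines.append("Physical activity and sleep (means)")
    lines.append(activity_table(cohort).to_string(index=False))
    if summary is not None:
        lines.append("")
        lines.append("Network")
        lines.append(
            f"nodes {summary.n_nodes}, edges {summary.n_edges}, "
            f"isolated {summary.n_isolated}, communities {summary.n_communities} "
            f"({summary.n_communities_multi} with >1 member, "
            f"largest {summary.largest_community})"
        )
        for cs in summary.communities:
            if cs.size > 1:
                comp = ", ".join(
                    f"{cat} {cnt} ({cs.bmi_percent[cat]}%)"
                    for cat, cnt in sorted(cs.bmi_counts.items())
                )
                lines.append(f"  community {cs.community} (n={cs.size}): {comp}")
    lines.append("")
    footer = ["SDs are population SDs; percentages round half-up to one decimal."]
    if seed is not None:
        footer.append(f"seed={seed}")
    if config_digest is not None:
        footer.append(f"config={config_digest}")
    lines.append(" | ".join(footer))
    return "\n".join(lines) + "\n"
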