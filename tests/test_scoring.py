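"""Sub-scores and the fixed-point composite."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wakamola.domain import (
    ActivityRecord,
    Assessment,
    Cohort,
    DietRecord,
    DomainError,
    FrequencyLevel,
    Relation,
    bmi_category,
)
from wakamola.scoring import (
    ScoreTable,
    ScoringParams,
    compute_scorecards,
    ipaq_met_minutes,
    score_activity,
    score_bmi,
    score_diet,
)

from conftest import best_diet, clique_cohort, max_assessment, random_cohort, worst_diet


@pytest.mark.parametrize(
    "bmi,points",
    [(21.2, 100), (17.0, 75), (27.0, 75), (33.0, 50), (37.0, 25), (40.0, 0), (45.0, 0)],
)
def test_score_bmi_step_function(bmi, points):
    assert score_bmi(bmi) == points


def test_score_bmi_matches_category_on_grid():
    """The step function factors exactly through the BMI category."""
    expected = {
        "normal": 100,
        "overweight": 75,
        "underweight": 75,
        "obesity1": 50,
        "obesity2": 25,
        "obesity3": 0,
    }
    for bmi in np.arange(10.0, 60.0, 0.01):
        assert score_bmi(float(bmi)) == expected[bmi_category(float(bmi)).value]


def test_score_diet_endpoints(table):
    assert score_diet(best_diet(table), table) == pytest.approx(100.0)
    assert score_diet(worst_diet(table), table) == pytest.approx(0.0)


def test_score_diet_toy_table():
    """Hand-computed value on a 3-item toy table: 100*(30-14)/(30-3)."""
    items = ["a", "b", "c"]
    penalty = {}
    for it in items:
        for lv in range(6):
            penalty[(it, lv)] = float(1 + lv + (9 - lv if lv > 4 else 0))
    # simpler explicit toy: penalties 1..10 monotone per level subset
    penalty = {(it, lv): float([1, 2, 4, 6, 8, 10][lv]) for it in items for lv in range(6)}
    toy = ScoreTable(penalty, items, name="toy")
    assert toy.p_min == 3 and toy.p_max == 30
    diet = DietRecord(
        answers={"a": FrequencyLevel.L2, "b": FrequencyLevel.L2, "c": FrequencyLevel.L3}
    )  # 4 + 4 + 6 = 14
    assert score_diet(diet, toy) == pytest.approx(100 * 16 / 27)


def test_score_diet_incomplete_raises(table):
    d = best_diet(table)
    del d.answers[sorted(d.answers)[0]]
    with pytest.raises(DomainError):
        score_diet(d, table)


def test_score_diet_unknown_item_raises(table):
    d = best_diet(table)
    d.answers["not_a_food"] = FrequencyLevel.L0
    with pytest.raises(DomainError):
        score_diet(d, table)


def test_score_diet_monotone_in_single_item_penalty(table):
    """Raising one item's frequency penalty never raises the score."""
    d = best_diet(table)
    item = sorted(d.answers)[0]
    scores = []
    for lv in sorted(range(6), key=lambda lv: table.penalty[(item, lv)]):
        d.answers[item] = FrequencyLevel(lv)
        scores.append(score_diet(d, table))
    assert all(a >= b - 1e-12 for a, b in zip(scores, scores[1:]))


@pytest.mark.parametrize(
    "activity,expected",
    [
        (ActivityRecord(), 0.0),
        (
            ActivityRecord(
                vigorous_days=3,
                vigorous_minutes=30,
                moderate_days=2,
                moderate_minutes=30,
                walk_days=5,
                walk_minutes=30,
            ),
            8 * 90 + 4 * 60 + 3.3 * 150,  # 1455
        ),
        (ActivityRecord(vigorous_days=1, vigorous_minutes=500), 8 * 180),  # cap
    ],
)
def test_ipaq_met_minutes(activity, expected):
    assert ipaq_met_minutes(activity) == pytest.approx(expected)


def test_ipaq_cap_invariant_below_cap():
    a = ActivityRecord(vigorous_days=2, vigorous_minutes=100)
    b = ActivityRecord(vigorous_days=2, vigorous_minutes=100)
    assert ipaq_met_minutes(a) == ipaq_met_minutes(b)
    # raising minutes beyond the cap changes nothing
    c = ActivityRecord(vigorous_days=2, vigorous_minutes=181)
    d = ActivityRecord(vigorous_days=2, vigorous_minutes=900)
    assert ipaq_met_minutes(c) == ipaq_met_minutes(d)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    vd=st.integers(0, 7),
    vm=st.floats(0, 960),
    md=st.integers(0, 7),
    mm=st.floats(0, 960),
    wd=st.integers(0, 7),
    wm=st.floats(0, 960),
    bump=st.floats(0, 100),
)
def test_ipaq_monotone_in_each_field(vd, vm, md, mm, wd, wm, bump):
    base = ActivityRecord(
        vigorous_days=vd, vigorous_minutes=vm, moderate_days=md,
        moderate_minutes=mm, walk_days=wd, walk_minutes=wm,
    )
    m0 = ipaq_met_minutes(base)
    for f in ("vigorous_minutes", "moderate_minutes", "walk_minutes"):
        rec = base.model_copy(update={f: min(getattr(base, f) + bump, 960)})
        assert ipaq_met_minutes(rec) >= m0 - 1e-9


def test_score_activity_endpoints_and_example(params):
    assert score_activity(ActivityRecord()) == 0.0
    sat = ActivityRecord(vigorous_days=5, vigorous_minutes=100)  # 4000 MET-min
    assert score_activity(sat) == 100.0
    a = ActivityRecord(
        vigorous_days=3, vigorous_minutes=30, moderate_days=2,
        moderate_minutes=30, walk_days=5, walk_minutes=30,
    )
    assert score_activity(a, params) == pytest.approx(48.5)


def test_isolated_maximal_user(table):
    """Closed form: quality and degree terms 0 -> social 0, composite 75."""
    cohort = Cohort(assessments={"solo": max_assessment("solo", table)})
    card = compute_scorecards(cohort, table)["solo"]
    assert card.social_score == pytest.approx(0.0, abs=1e-9)
    assert card.wakastatus == pytest.approx(75.0, abs=1e-6)


def test_two_user_fixed_point_closed_form(table):
    """Two maximal users, one edge: W = 76.25 / 0.875 = 87.142857..."""
    cohort = clique_cohort(2, table)
    cards = compute_scorecards(cohort, table)
    for card in cards.values():
        assert card.wakastatus == pytest.approx(76.25 / 0.875, abs=1e-6)
        assert card.converged


def test_full_clique_saturates_at_100(table):
    """11-clique of maximal users: degree 10 = D_ref, composite exactly 100."""
    cards = compute_scorecards(clique_cohort(11, table), table)
    for card in cards.values():
        assert card.wakastatus == pytest.approx(100.0, abs=1e-6)


def _naive_sweeps(cohort, table, params, n_sweeps=10_000, start=0.0):
    """Brute-force oracle: pure-python Jacobi sweeps of the score system."""
    from wakamola.scoring import ipaq_met_minutes  # noqa: F401 (clarity)
    from wakamola.scoring import score_activity, score_bmi, score_diet
    from wakamola.domain import compute_bmi

    users = sorted(
        u for u, a in cohort.assessments.items() if a.completed(set(table.item_ids))
    )
    base = {}
    for u in users:
        a = cohort.assessments[u]
        base[u] = (
            score_diet(a.diet, table),
            score_activity(a.activity, params),
            score_bmi(compute_bmi(a.personal)),
        )
    nbrs = {u: set() for u in users}
    for r in cohort.relations:
        if r.user_a in nbrs and r.user_b in nbrs and r.user_a != r.user_b:
            nbrs[r.user_a].add(r.user_b)
            nbrs[r.user_b].add(r.user_a)
    w = params.wakastatus_weights
    social = {u: start for u in users}
    for _ in range(n_sweeps):
        waka = {
            u: w["diet"] * base[u][0]
            + w["activity"] * base[u][1]
            + w["bmi"] * base[u][2]
            + w["social"] * social[u]
            for u in users
        }
        social = {
            u: 100.0
            * (
                params.social_degree_weight
                * min(len(nbrs[u]) / params.social_degree_ref, 1.0)
                + (1 - params.social_degree_weight)
                * (
                    (sum(waka[v] for v in nbrs[u]) / len(nbrs[u]) / 100.0)
                    if nbrs[u]
                    else 0.0
                )
            )
            for u in users
        }
    return {
        u: w["diet"] * base[u][0]
        + w["activity"] * base[u][1]
        + w["bmi"] * base[u][2]
        + w["social"] * social[u]
        for u in users
    }


@pytest.mark.parametrize("seed", [0, 1])
def test_solver_agrees_with_naive_sweeps(table, params, seed):
    """The vectorised solver matches 10,000 naive Jacobi sweeps to 1e-6."""
    cohort = random_cohort(table, seed=seed, n=15)
    cards = compute_scorecards(cohort, table, params)
    oracle = _naive_sweeps(cohort, table, params)
    assert set(cards) == set(oracle)
    for u in cards:
        assert cards[u].wakastatus == pytest.approx(oracle[u], abs=1e-6)


def test_fixed_point_independent_of_start(table, params):
    """Restarting the sweeps from social=100 reaches the same solution."""
    cohort = random_cohort(table, seed=2, n=12)
    cards = compute_scorecards(cohort, table, params)
    from_100 = _naive_sweeps(cohort, table, params, n_sweeps=2000, start=100.0)
    for u in cards:
        assert cards[u].wakastatus == pytest.approx(from_100[u], abs=1e-6)


@pytest.mark.parametrize("seed", range(6))
def test_all_scores_in_bounds_fuzz(table, params, seed):
    cards = compute_scorecards(random_cohort(table, seed=100 + seed, n=25), table, params)
    for c in cards.values():
        for v in (c.diet_score, c.activity_score, c.bmi_score, c.social_score, c.wakastatus):
            assert 0.0 <= v <= 100.0
        w = params.wakastatus_weights
        recomposed = (
            w["diet"] * c.diet_score
            + w["activity"] * c.activity_score
            + w["bmi"] * c.bmi_score
            + w["social"] * c.social_score
        )
        assert c.wakastatus == pytest.approx(recomposed, abs=1e-6)


def test_edge_to_maximal_user_never_decreases_social(table, params):
    """Adding a tie to a top-scoring user only helps the social score."""
    cohort = random_cohort(table, seed=42, n=10)
    top_id = "topuser"
    cohort.assessments[top_id] = max_assessment(top_id, table)
    before = compute_scorecards(cohort, table, params)
    target = sorted(u for u in before if u != top_id)[0]
    cohort.add_relation(Relation(user_a=target, user_b=top_id, relation_type="friend"))
    after = compute_scorecards(cohort, table, params)
    assert after[target].social_score >= before[target].social_score - 1e-9


def test_incomplete_users_excluded(table):
    cohort = clique_cohort(3, table)
    cohort.assessments["partial"] = Assessment(user_id="partial")
    cards = compute_scorecards(cohort, table)
    assert "partial" not in cards and len(cards) == 3


def test_params_reject_bad_weights():
    with pytest.raises(ValueError):
        ScoringParams(wakastatus_weights={"diet": 1.0, "activity": 0.5, "bmi": -0.25, "social": -0.25})
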