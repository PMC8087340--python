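# Methods

This note documents the models and numerical choices behind the toolkit,
what the synthetic-cohort generator does and does not emulate, and the
design decisions taken where the published description of the assessment
left the construction open.

## Scoring model

**BMI.** BMI is weight/height² (kg/m²). Categories use half-open bands
[lo, hi): underweight < 18.5, normal [18.5, 25), overweight [25, 30),
obesity classes 1–3 at [30, 35), [35, 40), ≥ 40. Published descriptions of
such bands are usually printed as "18.5–24.9 / 25–29.9", which leaves
(24.9, 25) undefined; the half-open convention closes the gaps without
moving any printed boundary. The BMI sub-score is the exact step function
normal → 100, overweight/underweight → 75, obesity 1/2/3 → 50/25/0, and
its domain error for non-positive BMI mirrors the category function.

**Diet.** Each of the 51 food items carries a penalty p(item, level) ∈
[1, 10] per frequency level (higher = less healthy at that frequency).
With S the summed penalty of a complete record and P_min/P_max the
minimal/maximal attainable totals, the score is
100·(P_max − S)/(P_max − P_min). The inversion is required because item
penalties grow with unhealthiness while every displayed score is
higher-is-better. The shipped table (`default_v1`) keys penalties on a
consumption class (daily-recommended / weekly-recommended / occasional) ×
level, because the original per-item penalty tables are not public; the
table is config-shipped and replaceable, and all scoring code treats it as
opaque (item, level) → points.

**Activity.** IPAQ short-form MET-minutes/week with the standard protocol
constants: 8.0 (vigorous), 4.0 (moderate), 3.3 (walking) MET, per-session
minutes truncated at 180 min/day before multiplying by days/week. The
score is linear with saturation: 100·min(MET-min / 3000, 1). 3000
MET-min/week is the conventional high-activity threshold; it lives in
`ScoringParams` (`activity_ref_met`), not in code.

**Social.** The social score has two published ingredients — the number of
contacts and the mean composite score of those contacts. It is implemented
as a convex combination of a saturating degree term min(d/D_ref, 1) and
the neighbour-mean term, with degree weight w = 0.5 and D_ref = 10 by
default. Isolated users get a zero quality term (and hence social score 0
under defaults), consistent with low social scores observed in sparse
pilot networks.

**Composite and fixed point.** Wakastatus is the weighted sum of the four
sub-scores (weights ¼ each by default, configurable, must sum to 1).
Because the social score depends on neighbours' composites, which contain
their social scores, the system
`S = A + B·M·S` (M the row-normalised adjacency operator) is linear with
spectral coefficient ≤ (1 − w)·weight_social = 0.125 under defaults. It is
solved by Jacobi iteration from S ≡ 0 with tolerance 1e-9 on the max
absolute change and a 1000-iteration guard; under any parameters with
(1 − w)·weight_social < 1 convergence is geometric and start-point
independent (verified by restarting from S ≡ 100 in the tests). Exceeding
the guard raises an explicit error carrying the last residual; this cannot
occur under the defaults.

Participants with incomplete assessments are excluded from scoring, and
relations touching them are ignored for degrees and neighbour means; the
CLI logs the excluded ids.

## Network analysis

Relations are undirected and typed (home/family/friend/work); duplicate
typed ties between a pair merge into a single edge carrying the set of
types, matching one-link-per-pair network drawings while preserving the
invitation labels. Communities come from the Louvain modularity heuristic
(networkx implementation) with an explicit seed (default 0) and contiguous
community ids assigned in order of each community's smallest node id, so a
given (graph, seed, resolution) always yields the same labelling. Isolated
nodes are singleton communities. Reported percentages round half-up to one
decimal, the convention of printed cohort shares (5/74 → 6.8%). Exports
are GraphML and node-link JSON with node attributes bmi, bmi_cat,
wakastatus, color, community and the edge attribute rel_types
(comma-joined); import reverses the joining, so export→import is an exact
round trip.

Node colours follow BMI: blue < 18.5, green [18.5, 25), yellow [25, 30),
red ≥ 30. A figure-legend style "overweight ≥ 25" is interpreted as
[25, 30) since red covers ≥ 30.

## Synthetic cohorts

The generator exists so every pipeline stage is testable without
participant data. The shipped profile `pilot2019` encodes a real pilot
sample of 74 university-student completers: 73% female, mean age 20.7,
BMI ~ N(21.4, 2.41²) truncated to [14, 45], published weekly consumption
means for 20 food groups, IPAQ-item means (e.g. walking on 5.80 days/week),
sitting 30.57 h/week, sleep 7.02 h/day, no obesity-related disease flags,
and a network of expected 178 relations over 12 blocks with 5/74 users
isolated.

Generation choices:

* **BMI before weight.** BMI is drawn from the truncated normal directly
  and weight derived as bmi·height² (height gender-conditional normal,
  clipped to plausible bounds), so the published BMI moments are targeted
  exactly instead of emerging from independent weight/height draws.
  Truncation at [14, 45] shifts the mean by < 0.01, far below sampling
  error at the sizes used. The absence of obesity cases in generated
  pilot-profile cohorts is emergent, not enforced.
* **Diet calibration.** Answers are ordinal levels, but the published
  targets are weekly units per food group. Units map to levels by fixed
  cut points (0 → L0; (0,1) → L1; [1,3) → L2; [3,7) → L3; [7,14) → L4;
  ≥ 14 → L5) and back by fixed representatives (0, 0.5, 2, 4.5, 9, 16).
  Naively drawing Poisson units at the group mean and binning them is
  biased once mapped back through the representatives (the dairy group
  would summarise near 6.4 instead of 4.43). Instead, each item's Poisson
  rate is calibrated by root finding so that
  E[representative(level(Poisson(rate)))] equals the item's share of the
  group mean; group-level mean recovery then holds by construction, and
  the bins/representatives remain explicit profile config.
* **Activity.** Day counts use Binomial(7, mean/7): supported exactly on
  0–7 with the exact target mean. A clipped negative binomial was
  considered and rejected because clipping at 7 biases the mean below the
  target; none of the recovered quantities needs the extra dispersion.
  Session minutes and sitting hours are gamma (shape 2) with the target
  mean, clipped at the questionnaire bounds (negligible mass).
* **Network.** A planted partition: the isolated fraction is held out
  edgeless, the rest split into near-equal blocks (12 for `pilot2019`);
  the within-block probability is solved from the target expected edge
  count n·mean_degree/2 given the between-block probability (0.01).
  Realised edges get one relation type with probabilities friend .4,
  family .3, work .2, home .1. Edge generation enumerates pairs, which is
  fine at cohort scales (10⁴ nodes and below).
* **Determinism.** A master seed spawns independent sub-streams for the
  personal, diet, activity and network sections, so cohorts are a pure
  function of (profile, seed) and each section is reproducible on its own.

What the generator does **not** emulate: self-selection bias of volunteer
samples, correlation between diet, activity, BMI and social position
(sections are generated independently), realistic degree heterogeneity
within blocks, item-level consumption correlations inside a food group,
and zip-code geography. Passing recovery tests therefore demonstrates
calibration of the marginals and of the expected edge count — not that
downstream score distributions match any real population.

## Dialogue engine

The engine is a pure state machine over `Session`; a transport only
displays prompt strings and returns answer strings, so scripted
transcripts and the console transport produce identical trajectories.
Section order is user-chosen from a six-entry menu; completion requires
Personal + Diet + Activity. Answers are validated (numeric ranges mirror
the domain invariants; choices, booleans and the 0–5 frequency levels are
enumerated); invalid input re-prompts without state change, which is a
dialogue event, not an exception. The Personal section asks 15 questions
(11 fields plus 4 diagnosis questions). Invitations are four per user, one
per relation type, with self-describing base64url tokens; redemption is
idempotent per (pair, type) and rejects self-invitation. Spanish, English
and Catalan content files ship complete; the completeness checker compares
every language against the canonical key set and is exercised in tests
against a deliberately truncated translation. User-facing wording says
"status", never "risk".

## Numerical conventions and edge cases

* Fixed-point tolerance 1e-9 (max-norm), guard 1000 iterations; scorecard
  carries `converged` and `iterations`.
* Report SDs are population SDs (ddof = 0); a single-user cohort reports
  SD 0. Percentages round half-up to one decimal via `decimal.Decimal`.
* Diet scoring requires exactly the canonical roster: missing items raise
  a completeness error, unknown items a configuration error.
* `n = 0` cohorts are valid everywhere (empty files, empty graphs, zero
  communities).
* Poisson-rate calibration rejects per-item targets at or above the top
  representative (16 units/week), which would be unattainable.

## Problem sizes

The test suite and the acceptance script use 10,000 generated records for
parameter-recovery checks (3-standard-error criteria), 60 seeds for the
expected-edge-count check, exhaustive enumeration of all 115,975
partitions of the 10-node two-clique fixture for the community-detection
oracle, and 10,000 Jacobi sweeps for the fixed-point oracle. These sizes
make the Monte-Carlo standard errors small relative to the calibration
targets while keeping a full run in seconds.

## Known limitations

The default penalty table is a provisional, class-based stand-in for the
original (unpublished) per-item tables, so absolute diet-score levels are
not comparable to the original deployment's; the social-score functional
form is one defensible reading of its two published ingredients; and the
pilot's community accounting (12 communities, 8 multi-member, 5 isolated)
is internally inconsistent under any singleton convention, so pilot
network figures are treated as structural calibration targets (edge count,
block count, isolated count), not exact reproduction targets.
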