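# Simulator profile "pilot2019" — the pilot cohort of the original
# deployment: 74 university students (54 female) who completed all
# sections, forming a network of 178 typed relations with 12 communities
# and 5 isolated users.  BMI, food-group, activity and sleep means are
# the pilot's published sample statistics; dispersions not published are
# set to values typical of young-adult cohorts.
name: pilot2019
n: 74
female_fraction: 0.7297297297297297    # 54/74
age: {mean: 20.7, sd: 2.5, min: 18.0, max: 65.0}
bmi: {mean: 21.4, sd: 2.41, min: 14.0, max: 45.0}
height:
  female: {mean: 1.63, sd: 0.06}
  male: {mean: 1.77, sd: 0.07}
  other: {mean: 1.70, sd: 0.08}
sleep: {mean: 7.02, sd: 0.9}
cigarettes_mean: 0.5
disease_prob: 0.0
zip_pool: 55
food_weekly_means:                     # units (occasions) per week per food group
  seafood: 0.54
  soft_drinks: 0.62
  butter: 0.67
  alcohol: 0.78
  french_fries: 1.18
  sweetmeats: 1.22
  blue_fish: 1.64
  rice: 2.04
  legumes: 2.04
  white_fish: 2.07
  sausage: 2.13
  meats: 2.27
  other_oils: 2.36
  cheeses: 2.43
  nuts: 2.65
  fruits: 2.83
  vegetables: 3.17
  cereals: 3.17
  milk: 4.43
  olive_oil: 12.72
activity:
  vigorous_days: 2.34
  vigorous_minutes: 33.97
  moderate_days: 5.11
  moderate_minutes: 35.76
  walk_days: 5.80
  walk_minutes: 34.26
  sitting_hours: 30.57
minutes_shape: 2.0                     # gamma shape for per-session minutes
network:
  mean_degree: 4.8108108108108105      # 2 * 178 / 74
  n_blocks: 12
  p_between: 0.01
  isolated_fraction: 0.06756756756756757   # 5/74
  relation_type_probs: {friend: 0.4, family: 0.3, work: 0.2, home: 0.1}
# Weekly-units -> frequency-level bins: 0 -> L0; (0,1) -> L1; [1,3) -> L2;
# [3,7) -> L3; [7,14) -> L4; >=14 -> L5; representative units per level
# are used when mapping levels back to weekly units in summaries.
level_bins: [1.0, 3.0, 7.0, 14.0]
level_representatives: [0.0, 0.5, 2.0, 4.5, 9.0, 16.0]
seed: 0
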