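# Default scoring parameters "default_v1".
#
# MET multipliers and the 180 min/day truncation follow the IPAQ
# short-form scoring protocol.  activity_ref_met is the weekly MET-minute
# volume that saturates the activity score at 100 (3000 MET-min/week, the
# conventional high-activity threshold).  The social score is a convex
# combination of a saturating degree term (saturation at
# social_degree_ref contacts) and the mean composite score of the
# contacts.  The composite is the weighted sum of the four sub-scores.
name: default_v1
met_vigorous: 8.0
met_moderate: 4.0
met_walk: 3.3
daily_cap_minutes: 180.0
activity_ref_met: 3000.0
social_degree_weight: 0.5
social_degree_ref: 10.0
wakastatus_weights:
  diet: 0.25
  activity: 0.25
  bmi: 0.25
  social: 0.25
fixedpoint_tol: 1.0e-9
fixedpoint_max_iter: 1000
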