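"""Simulate the synthetic study replica and its model-free statistics.

Draws an 18-agent time-optimal cohort (group risk aversion 0 under additive
and 1 under multiplicative dynamics, sd 0.3), plays both 312-trial active
sessions through the logistic choice rule, and computes the choice
proportions in favour of log utility (CP_log) on discrepant trials.
"""

from ergochoice import Dynamic, build_active_session, make_stimulus_set
from ergochoice.agents import default_study_cohort, sample_cohort, simulate_study
from ergochoice.metrics import choice_proportion_log

sessions = {d: build_active_session(make_stimulus_set(d), seed=100)
            for d in Dynamic}
cohort = sample_cohort(default_study_cohort(), seed=300)
data = simulate_study(cohort, sessions, seed=400)
print(f"dataset: {len(data)} rows "
      f"({len(cohort)} subjects x 2 conditions x 312 trials)")

cp_add = choice_proportion_log(data, sessions[Dynamic.ADDITIVE])
cp_mult = choice_proportion_log(data, sessions[Dynamic.MULTIPLICATIVE])
print(f"\nmean CP_log, additive:       {cp_add.mean():.3f}")
print(f"mean CP_log, multiplicative: {cp_mult.mean():.3f}")
print(f"mean within-subject increase: {(cp_mult - cp_add).mean():+.3f}")
print()
print("Time-optimal agents choose with linear utility under additive")
print("dynamics (CP_log << 0.5) and with log utility under multiplicative")
print("dynamics (CP_log > 0.5): the dynamic, not the subject, sets the")
print("risk preference.")
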