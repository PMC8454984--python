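"""Fit the hierarchical dynamic-specific isoelastic model.

Simulates a small time-optimal cohort and recovers the condition-specific
group risk aversions by MCMC.  The posterior of the group mean should cover
0 (additive) and 1 (multiplicative) — the time-optimal coordinates.
Run time: about half a minute.
"""

from ergochoice import Dynamic
from ergochoice.agents import default_study_cohort, sample_cohort, simulate_study
from ergochoice.estimation import McmcConfig, fit_isoelastic_hierarchical, map_estimate
from ergochoice.metrics import distance_to_diagonal, distance_to_time_optimal

cohort = sample_cohort(default_study_cohort(n_subjects=10), seed=5)
data = simulate_study(cohort, seed=6)

post = fit_isoelastic_hierarchical(
    data, cfg=McmcConfig(n_chains=4, n_draws=2000, n_burnin=500, seed=7))

eta_map = {}
for d in Dynamic:
    lo, hi = post.credible_interval("mu_eta", condition=d.value)
    mode = map_estimate(post, "mu_eta", condition=d.value)
    eta_map[d] = mode
    print(f"{d.value:>14}: MAP group eta = {mode:+.3f}, "
          f"95% CI [{lo:+.3f}, {hi:+.3f}]")

d_opt = distance_to_time_optimal(eta_map[Dynamic.ADDITIVE],
                                 eta_map[Dynamic.MULTIPLICATIVE])
d_diag = distance_to_diagonal(eta_map[Dynamic.ADDITIVE],
                              eta_map[Dynamic.MULTIPLICATIVE])
print(f"\ndistance of the group MAP to the time-optimal point (0,1): {d_opt:.3f}")
print(f"distance to the dynamic-invariant diagonal:                {d_diag:.3f}")
print("\nA small distance to (0,1) and a large distance to the diagonal is")
print("the signature of risk preferences that adapt to the wealth dynamic.")

flagged = post.flagged_parameters()
print(f"\nconvergence: {len(flagged)} parameter(s) with split-R-hat outside"
      " [1, 1.01]")
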