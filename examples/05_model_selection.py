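"""Latent-mixture model selection with protected exceedance probabilities.

Simulates three small cohorts of agents generated from the time-optimal,
prospect-theory and isoelastic utility models, fits the hierarchical
latent mixture, and summarizes which model explains each agent and which
is most frequent in the population.  Run time: one to two minutes.
"""

import numpy as np

from ergochoice.agents import model_recovery_cohorts, sample_cohort, simulate_study
from ergochoice.estimation import McmcConfig
from ergochoice.selection import (
    estimated_model_frequencies,
    fit_hlm,
    protected_exceedance_probability,
)

cohorts = model_recovery_cohorts(4)
agents = []
for i, spec in enumerate(cohorts.values()):
    agents += sample_cohort(spec, seed=21 + i)
data = simulate_study(agents, seed=24)

mp = fit_hlm(data, cfg=McmcConfig(n_chains=2, n_draws=1500, n_burnin=500,
                                  seed=25))
print("per-subject posterior model probabilities "
      "(id prefixes name the generating model):")
print(mp.model_probs.round(3).to_string())

print("\nestimated population model frequencies:")
print(estimated_model_frequencies(mp).round(3).to_string())

res = protected_exceedance_probability(mp, seed=0)
print(f"\nexceedance probabilities:           {np.round(res.exceedance, 3)}")
print(f"Bayes omnibus risk (equal-frequency null): {res.bor:.3f}")
print(f"protected exceedance probabilities: {np.round(res.pxp, 3)}")
print("\nThe cohorts are equally sized by construction, so apparent")
print("frequency differences at this small n are noise; the omnibus risk")
print("stays substantial and pulls the PXPs back toward 1/3 — the")
print("protection PXP adds over raw exceedance probabilities.")
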