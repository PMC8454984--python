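"""The coin gamble that separates expectation values from time averages.

A fair coin either multiplies wealth by 1.5 (heads) or by 0.6 (tails).
The expectation value of the growth factor is positive, yet a single player
repeating the gamble sees their wealth shrink almost surely — the two
averages disagree because multiplicative wealth changes are non-ergodic.
"""

import math

import numpy as np

from ergochoice import Dynamic, Gamble, gamble_growth_rate
from ergochoice.agents import AgentSpec, simulate_wealth_trajectory
from ergochoice.utility import UtilityModel, UtilityParams

g = Gamble((1.5, 0.6))
expectation = float(np.mean(g.outcomes))
time_avg = math.exp(gamble_growth_rate(g, Dynamic.MULTIPLICATIVE))

print(f"expected growth factor per trial:     {expectation:.4f}")
print(f"time-average growth factor per trial: {time_avg:.4f}")
print()
print("The expectation (1.05 > 1) suggests playing; the time average")
print("(~0.95 < 1) says a persistent player is ruined. Maximizing the")
print("time-average growth rate requires logarithmic utility here.")

# watch it happen: realize the gamble 1000 times
initial_wealth = 1000.0
factors = np.random.default_rng(0).choice(g.outcomes, size=1000)
final = initial_wealth * np.prod(factors)
print(f"\none realized 1000-trial wealth path ends at {final:.3g} DKK "
      f"(from {initial_wealth:.0f} DKK)")
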