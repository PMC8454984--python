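"""Construct the two-dynamics gambling paradigm.

Builds the canonical stimulus sets (additive DKK increments and
multiplicative growth factors), a bounded passive wealth sequence, and the
312-trial active session, and reports the structural counts that define
the design.
"""

import numpy as np

from ergochoice import (
    Dynamic,
    build_active_session,
    build_gamble_space,
    finite_time_growth,
    generate_passive_sequence,
    make_stimulus_set,
)

for dynamic in Dynamic:
    ss = make_stimulus_set(dynamic)
    print(f"\n=== {dynamic.value} condition ===")
    print("stimulus outcomes:", np.round(ss.values, 4).tolist())

    traj = generate_passive_sequence(ss, seed=1)
    print(f"passive sequence: {traj.n_trials} trials "
          f"(333 balanced + 1 random extra)")
    print(f"  wealth range: [{traj.wealth.min():.1f}, {traj.wealth.max():.1f}] DKK"
          " (constrained to (0, 5000))")
    print(f"  wealth after balanced block: {traj.wealth[333]:.6f} DKK"
          " (returns to the 1000 DKK endowment)")
    print(f"  finite-time growth over the whole session: "
          f"{finite_time_growth(traj):+.5f} per trial")

    mixed, pairs = build_gamble_space(ss)
    sess = build_active_session(ss, seed=1)
    print(f"active session: {len(mixed)} mixed gambles, {len(pairs)} ordered"
          f" pairs, {sess.n_trials} trials"
          f" (288 mixed presentations + 24 no-brainers)")
    print(f"  discrepant trials (linear vs log utility disagree): "
          f"{sess.n_discrepant_trials}")
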