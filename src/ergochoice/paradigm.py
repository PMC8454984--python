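"""Gambling-paradigm construction for additive vs multiplicative wealth dynamics.

A session is built from 9 stimuli whose outcome values either add a DKK
increment to in-game wealth or multiply it by a growth factor.  The module
provides the stimulus sets, bounded passive wealth trajectories, the mixed
two-outcome gamble space of the active session, growth-rate computations,
and the classifier for "discrepant" trials on which linear- and log-utility
agents disagree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
import numpy as np

__all__ = [
    "Dynamic",
    "StimulusSet",
    "WealthTrajectory",
    "Gamble",
    "TrialPair",
    "ActiveSession",
    "make_stimulus_set",
    "apply_outcome",
    "generate_passive_sequence",
    "finite_time_growth",
    "gamble_growth_rate",
    "build_gamble_space",
    "classify_discrepant",
    "build_active_session",
]

#: wealth interval (open) enforced during passive sessions, in DKK
PASSIVE_BOUNDS = (0.0, 5000.0)
#: initial endowment in DKK
INITIAL_WEALTH = 1000.0
#: approximate real time between trials, seconds; used only for real-time axes
TRIAL_INTERVAL_S = 10.0


class Dynamic(str, Enum):
    """How outcomes change wealth: additive increments or multiplicative factors."""

    ADDITIVE = "additive"
    MULTIPLICATIVE = "multiplicative"

    @property
    def neutral(self) -> float:
        """The outcome value that leaves wealth unchanged."""
        return 0.0 if self is Dynamic.ADDITIVE else 1.0

    @property
    def optimal_eta(self) -> float:
        """Relative risk aversion that maximizes the time-average growth rate."""
        return 0.0 if self is Dynamic.ADDITIVE else 1.0


@dataclass(frozen=True)
class StimulusSet:
    """Nine outcome values, strictly increasing, symmetric about the neutral outcome.

    Additive values are DKK increments equally spaced on a linear scale;
    multiplicative values are dimensionless growth factors equally spaced on a
    log scale.  Four values are losses, one is neutral, four are gains.
    """

    dynamic: Dynamic
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.size != 9:
            raise ValueError(f"expected 9 stimulus values, got {v.size}")
        if not np.all(np.diff(v) > 0):
            raise ValueError("stimulus values must be strictly increasing")
        if self.dynamic is Dynamic.MULTIPLICATIVE:
            if np.any(v <= 0):
                raise ValueError("growth factors must be positive")
            logs = np.log(v)
            if not (np.allclose(logs + logs[::-1], 0, atol=1e-9)
                    and np.allclose(np.diff(logs), np.diff(logs)[0], atol=1e-9)):
                raise ValueError("growth factors must be log-symmetric and log-equally spaced")
        else:
            if not (np.allclose(v + v[::-1], 0, atol=1e-9)
                    and np.allclose(np.diff(v), np.diff(v)[0], atol=1e-9)):
                raise ValueError("increments must be symmetric about 0 and equally spaced")

    @property
    def gains(self) -> tuple[float, ...]:
        n = self.dynamic.neutral
        return tuple(v for v in self.values if v > n)

    @property
    def losses(self) -> tuple[float, ...]:
        n = self.dynamic.neutral
        return tuple(v for v in self.values if v < n)


def make_stimulus_set(dynamic: Dynamic, extreme: float | None = None) -> StimulusSet:
    """Build the canonical 9-value stimulus set for a dynamic.

    Parameters
    ----------
    dynamic
        Additive or multiplicative.
    extreme
        Additive: the largest increment in DKK (default 428).  Multiplicative:
        the largest growth factor, > 1 (default 2.0, i.e. doubling at one
        extreme and halving at the other).
    """
    dynamic = Dynamic(dynamic)
    if extreme is None:
        extreme = 428.0 if dynamic is Dynamic.ADDITIVE else 2.0
    if dynamic is Dynamic.ADDITIVE:
        if extreme <= 0:
            raise ValueError("additive extreme must be positive")
        values = np.linspace(-extreme, extreme, 9)
    else:
        if extreme <= 1:
            raise ValueError("multiplicative extreme must exceed 1")
        values = extreme ** (np.arange(-4, 5) / 4.0)
    return StimulusSet(dynamic=dynamic, values=tuple(float(v) for v in values))


def apply_outcome(wealth: float, outcome: float, dynamic: Dynamic) -> float:
    """Update wealth by one outcome: ``wealth + s`` (additive) or ``wealth * s``."""
    if Dynamic(dynamic) is Dynamic.ADDITIVE:
        return wealth + outcome
    if wealth <= 0:
        raise ValueError("multiplicative dynamics require positive wealth")
    return wealth * outcome


@dataclass(frozen=True)
class WealthTrajectory:
    """A realized sequence of outcomes and the wealth path they induce."""

    dynamic: Dynamic
    initial_wealth: float
    outcomes: np.ndarray
    wealth: np.ndarray  # length = len(outcomes) + 1, wealth[0] == initial_wealth

    def __post_init__(self) -> None:
        if len(self.wealth) != len(self.outcomes) + 1:
            raise ValueError("wealth path must have one more entry than outcomes")

    @property
    def n_trials(self) -> int:
        return len(self.outcomes)


def _wealth_path(initial: float, outcomes: np.ndarray, dynamic: Dynamic) -> np.ndarray:
    if dynamic is Dynamic.ADDITIVE:
        return initial + np.concatenate([[0.0], np.cumsum(outcomes)])
    return initial * np.concatenate([[1.0], np.cumprod(outcomes)])


def generate_passive_sequence(
    stimuli: StimulusSet,
    reps_per_stimulus: int = 37,
    bounds: tuple[float, float] = PASSIVE_BOUNDS,
    initial_wealth: float = INITIAL_WEALTH,
    seed: int | None = None,
    max_attempts: int = 100_000,
) -> WealthTrajectory:
    """Generate a bounded passive wealth trajectory by rejection sampling.

    Each of the 9 stimuli appears exactly ``reps_per_stimulus`` times in a
    random order whose running wealth stays strictly inside the open interval
    ``bounds`` at every trial; any violating permutation is rejected and a new
    one drawn.  Because every stimulus appears equally often, wealth returns
    to ``initial_wealth`` at the end of the balanced block.  One additional
    uniformly drawn stimulus is then appended, so the session ends at a
    randomly determined wealth level.
    """
    if reps_per_stimulus < 1:
        raise ValueError("reps_per_stimulus must be >= 1")
    lo, hi = bounds
    if not lo < initial_wealth < hi:
        raise ValueError("initial wealth must lie strictly inside the bounds")
    rng = np.random.default_rng(seed)
    base = np.repeat(np.asarray(stimuli.values, float), reps_per_stimulus)
    for attempt in range(1, max_attempts + 1):
        perm = rng.permutation(base)
        path = _wealth_path(initial_wealth, perm, stimuli.dynamic)
        if np.all((path > lo) & (path < hi)):
            extra = rng.choice(np.asarray(stimuli.values, float))
            outcomes = np.concatenate([perm, [extra]])
            wealth = _wealth_path(initial_wealth, outcomes, stimuli.dynamic)
            return WealthTrajectory(
                dynamic=stimuli.dynamic,
                initial_wealth=initial_wealth,
                outcomes=outcomes,
                wealth=wealth,
            )
    raise RuntimeError(
        f"no admissible passive sequence found in {max_attempts} rejection attempts"
    )


def finite_time_growth(trajectory: WealthTrajectory) -> float:
    """Finite-time average growth rate of a trajectory, per trial.

    Additive: change in wealth per trial (DKK/trial).  Multiplicative: change
    in log-wealth per trial (log-units/trial).
    """
    if trajectory.n_trials < 1:
        raise ValueError("trajectory must contain at least one outcome")
    x0, xT = trajectory.wealth[0], trajectory.wealth[-1]
    T = trajectory.n_trials
    if trajectory.dynamic is Dynamic.ADDITIVE:
        return (xT - x0) / T
    if np.any(trajectory.wealth <= 0):
        raise ValueError("multiplicative growth requires positive wealth throughout")
    return (math.log(xT) - math.log(x0)) / T


@dataclass(frozen=True)
class Gamble:
    """Two equiprobable outcomes (a fair coin)."""

    outcomes: tuple[float, float]
    probabilities: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self) -> None:
        p1, p2 = self.probabilities
        if not (abs(p1 - 0.5) < 1e-12 and abs(p2 - 0.5) < 1e-12):
            raise ValueError("gamble outcomes must be equiprobable (fair coin)")

    def is_mixed(self, dynamic: Dynamic) -> bool:
        n = Dynamic(dynamic).neutral
        a, b = self.outcomes
        return (a > n) != (b > n) and n not in self.outcomes


def gamble_growth_rate(gamble: Gamble, dynamic: Dynamic) -> float:
    """Time-average growth rate of a gamble, per trial.

    Additive: the expected increment (DKK/trial).  Multiplicative: the
    expected log growth factor (log-units/trial) — the quantity whose
    maximization defines time optimality under that dynamic.
    """
    a, b = gamble.outcomes
    if Dynamic(dynamic) is Dynamic.ADDITIVE:
        return 0.5 * (a + b)
    if a <= 0 or b <= 0:
        raise ValueError("multiplicative outcomes must be positive")
    return 0.5 * (math.log(a) + math.log(b))


@dataclass(frozen=True)
class TrialPair:
    """A left/right pair of gambles as presented on one trial."""

    left: Gamble
    right: Gamble
    is_nobrainer: bool = False
    is_discrepant: bool = False

    @property
    def outcome_values(self) -> tuple[float, float, float, float]:
        return (*self.left.outcomes, *self.right.outcomes)


def _mean_linear_change(g: Gamble, dynamic: Dynamic, wealth: float) -> float:
    a, b = g.outcomes
    if dynamic is Dynamic.ADDITIVE:
        return 0.5 * (a + b)
    return 0.5 * (wealth * a + wealth * b) - wealth


def _mean_log_change(g: Gamble, dynamic: Dynamic, wealth: float) -> float:
    a, b = g.outcomes
    if dynamic is Dynamic.ADDITIVE:
        if wealth + min(a, b) <= 0:
            raise ValueError("log criterion undefined: outcome drives wealth non-positive")
        return 0.5 * (math.log(wealth + a) + math.log(wealth + b)) - math.log(wealth)
    return 0.5 * (math.log(a) + math.log(b))


#: relative tolerance below which an expected-change difference counts as a tie
_TIE_RTOL = 1e-9


def _sign_or_tie(d: float, scale: float) -> int:
    """Sign of a criterion difference, 0 when it is a tie at floating tolerance.

    Exact ties occur structurally (e.g. two gambles with the same mean
    increment, or factor pairs whose log-values sum identically) but emerge
    from floating arithmetic as O(1e-16) residues; those must not count as
    preferences.
    """
    if abs(d) <= _TIE_RTOL * max(scale, 1e-300):
        return 0
    return 1 if d > 0 else -1


def _criterion_scales(pair: TrialPair, dynamic: Dynamic, wealth: float
                      ) -> tuple[float, float]:
    """Magnitudes of the individual per-outcome changes (linear, log).

    Tie detection must be scaled by the terms entering the means, not by the
    means themselves, which cancel to rounding noise on structural ties.
    """
    outs = pair.outcome_values
    if dynamic is Dynamic.ADDITIVE:
        lin = max(abs(s) for s in outs)
        log = max(abs(math.log((wealth + s) / wealth)) for s in outs)
    else:
        lin = max(abs(wealth * (s - 1.0)) for s in outs)
        log = max(abs(math.log(s)) for s in outs)
    return lin, log


def classify_discrepant(pair: TrialPair, dynamic: Dynamic, reference_wealth: float) -> bool:
    """True iff a linear- and a log-utility agent prefer different gambles.

    Both expected-change criteria must be strictly nonzero and of opposite
    sign; a tie on either criterion means indifference, not disagreement.
    Under multiplicative dynamics the classification is independent of
    ``reference_wealth``.
    """
    if reference_wealth <= 0:
        raise ValueError("reference wealth must be positive")
    dynamic = Dynamic(dynamic)
    lin_scale, log_scale = _criterion_scales(pair, dynamic, reference_wealth)
    d_lin = (_mean_linear_change(pair.left, dynamic, reference_wealth)
             - _mean_linear_change(pair.right, dynamic, reference_wealth))
    d_log = (_mean_log_change(pair.left, dynamic, reference_wealth)
             - _mean_log_change(pair.right, dynamic, reference_wealth))
    return _sign_or_tie(d_lin, lin_scale) * _sign_or_tie(d_log, log_scale) == -1


def log_preferred_side(pair: TrialPair, dynamic: Dynamic, reference_wealth: float) -> str | None:
    """Which side a log-utility agent prefers ('left'/'right'), or None on a tie."""
    dynamic = Dynamic(dynamic)
    _, log_scale = _criterion_scales(pair, dynamic, reference_wealth)
    d = (_mean_log_change(pair.left, dynamic, reference_wealth)
         - _mean_log_change(pair.right, dynamic, reference_wealth))
    s = _sign_or_tie(d, log_scale)
    if s == 0:
        return None
    return "left" if s > 0 else "right"


def build_gamble_space(stimuli: StimulusSet) -> tuple[list[Gamble], list[TrialPair]]:
    """All mixed gambles and all constrained ordered left/right pairs.

    Mixed gambles combine one gain with one loss (16 for the canonical set).
    Pairs are ordered (left, right) combinations of distinct mixed gambles in
    which the four outcome values are pairwise distinct (144 for the
    canonical set: each of the 16 gambles pairs with the 9 gambles sharing
    none of its stimuli).
    """
    mixed = [Gamble(outcomes=(g, l)) for g in stimuli.gains for l in stimuli.losses]
    pairs = [
        TrialPair(left=L, right=R)
        for L in mixed
        for R in mixed
        if len({*L.outcomes, *R.outcomes}) == 4
    ]
    return mixed, pairs


def _dominated_pairs(stimuli: StimulusSet) -> list[TrialPair]:
    """All mixed-gamble pairs sharing exactly one stimulus, left dominating right."""
    out: list[TrialPair] = []
    gains, losses = stimuli.gains, stimuli.losses
    for g in gains:  # shared gain, left has the better loss
        for i, l1 in enumerate(losses):
            for l2 in losses[:i]:
                out.append(TrialPair(left=Gamble((g, l1)), right=Gamble((g, l2)),
                                     is_nobrainer=True))
    for l in losses:  # shared loss, left has the better gain
        for i, g1 in enumerate(gains):
            for g2 in gains[:i]:
                out.append(TrialPair(left=Gamble((g1, l)), right=Gamble((g2, l)),
                                     is_nobrainer=True))
    return out


@dataclass(frozen=True)
class ActiveSession:
    """The randomized list of trials presented in one active session."""

    dynamic: Dynamic
    trials: tuple[TrialPair, ...]
    seed: int | None = None
    reference_wealth: float = INITIAL_WEALTH

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_discrepant_trials(self) -> int:
        return sum(t.is_discrepant for t in self.trials)

    @property
    def n_discrepant_pairs(self) -> int:
        """Distinct discrepant ordered pairs among the session's mixed trials."""
        return len({t.outcome_values for t in self.trials if t.is_discrepant})


def build_active_session(
    stimuli: StimulusSet,
    n_nobrainers: int = 24,
    seed: int | None = None,
    reference_wealth: float = INITIAL_WEALTH,
    unordered_pairs: bool = False,
) -> ActiveSession:
    """Assemble a full active session: 2 x 144 mixed-pair trials plus no-brainers.

    Every constrained ordered pair is presented twice, no-brainers are
    sampled without replacement from the statewise-dominated pairs (with
    random orientation), and the whole list is shuffled reproducibly from
    ``seed``.  Discrepancy flags are evaluated at ``reference_wealth``.

    With ``unordered_pairs=True`` the 72 unordered pairs are used instead,
    each presented twice in both orientations (same 288 mixed trials).
    """
    if n_nobrainers < 0:
        raise ValueError("n_nobrainers must be >= 0")
    rng = np.random.default_rng(seed)
    _, pairs = build_gamble_space(stimuli)
    if unordered_pairs:
        seen: set[frozenset] = set()
        kept = []
        for p in pairs:
            key = frozenset([p.left.outcomes, p.right.outcomes])
            if key not in seen:
                seen.add(key)
                kept.append(p)
        mixed_trials = []
        for p in kept:
            swapped = TrialPair(left=p.right, right=p.left)
            mixed_trials.extend([p, swapped, p, swapped])
    else:
        mixed_trials = pairs * 2
    dominated = _dominated_pairs(stimuli)
    if n_nobrainers > len(dominated):
        raise ValueError(
            f"requested {n_nobrainers} no-brainers but only {len(dominated)} "
            "dominated pairs exist"
        )
    chosen = [dominated[i] for i in rng.choice(len(dominated), n_nobrainers, replace=False)]
    chosen = [
        TrialPair(left=p.right, right=p.left, is_nobrainer=True) if rng.random() < 0.5 else p
        for p in chosen
    ]
    trials = mixed_trials + chosen
    trials = [
        replace(t, is_discrepant=classify_discrepant(t, stimuli.dynamic, reference_wealth))
        for t in trials
    ]
    order = rng.permutation(len(trials))
    return ActiveSession(
        dynamic=stimuli.dynamic,
        trials=tuple(trials[i] for i in order),
        seed=seed,
        reference_wealth=reference_wealth,
    )
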