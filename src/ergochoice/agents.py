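"""Synthetic agents and choice-data generation.

Cohorts of utility-maximizing agents are drawn from group-level parameter
distributions mirroring the hierarchical generative model, play the active
session through the logistic choice rule, and can be simulated over long
horizons of repeated gambling to expose the growth-rate consequences of
their utility functions.

The default study replica emulates the original cohort: 18 subjects, two
conditions, 312 trials each, time-optimal agents with group risk aversion at
the dynamic's optimum (sd 0.3), wealth fixed at 1000 DKK, and choice
sensitivity calibrated so that the median |beta * delta-utility| over the
gamble space is about 2 in each condition (informative but stochastic
choices in both wealth-change scalings).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .paradigm import (
    Dynamic,
    ActiveSession,
    StimulusSet,
    WealthTrajectory,
    build_active_session,
    build_gamble_space,
    make_stimulus_set,
)
from .utility import DecisionContext, UtilityModel, UtilityParams

__all__ = [
    "AgentSpec",
    "CohortSpec",
    "sample_cohort",
    "calibrate_beta",
    "default_study_cohort",
    "model_recovery_cohorts",
    "simulate_choices",
    "simulate_study",
    "simulate_wealth_trajectory",
    "simulate_terminal_growth",
    "DATASET_COLUMNS",
]

logger = logging.getLogger(__name__)

DATASET_COLUMNS = [
    "subject_id", "dynamic", "trial_index",
    "left_out1", "left_out2", "right_out1", "right_out2",
    "choice", "wealth",
]

_BIG_NEG = -1e30  # utility assigned to outcomes that would bankrupt the agent


@dataclass(frozen=True)
class AgentSpec:
    subject_id: str
    model: UtilityModel
    params: UtilityParams


@dataclass(frozen=True)
class CohortSpec:
    """Group-level description of a synthetic cohort.

    ``mu_eta`` as a per-dynamic mapping draws a separate risk aversion per
    condition (the TIME-style generative process); a plain float draws one
    shared risk aversion per subject (the ISO-style process).  Log-scale
    means/sds govern the lognormal beta, PT curvature and loss-aversion
    distributions.  Bounded parameters (alpha in (0,1), lambda in (1,5)) are
    enforced by resampling, with the number of resamples logged.
    """

    n_subjects: int
    model: UtilityModel = UtilityModel.TIME
    mu_eta: float | Mapping[Dynamic, float] | None = None
    sigma_eta: float = 0.3
    mu_log_beta: Mapping[Dynamic, float] = field(default_factory=dict)
    sigma_log_beta: float = 0.2
    mu_log_alpha_gain: float = float(np.log(0.4))
    sigma_log_alpha_gain: float = 0.1
    mu_log_alpha_loss: float = float(np.log(0.4))
    sigma_log_alpha_loss: float = 0.1
    mu_log_lambda: float = float(np.log(2.5))
    sigma_log_lambda: float = 0.1
    seed: int | None = None
    subject_prefix: str = "sub"

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("cohort needs at least one subject")
        for s in (self.sigma_eta, self.sigma_log_beta):
            if s < 0:
                raise ValueError("group standard deviations must be non-negative")

    def to_dict(self) -> dict:
        d = {
            "n_subjects": self.n_subjects,
            "model": self.model.value,
            "mu_eta": ({k.value: v for k, v in self.mu_eta.items()}
                       if isinstance(self.mu_eta, Mapping) else self.mu_eta),
            "sigma_eta": self.sigma_eta,
            "mu_log_beta": {k.value: v for k, v in self.mu_log_beta.items()},
            "sigma_log_beta": self.sigma_log_beta,
            "mu_log_alpha_gain": self.mu_log_alpha_gain,
            "sigma_log_alpha_gain": self.sigma_log_alpha_gain,
            "mu_log_alpha_loss": self.mu_log_alpha_loss,
            "sigma_log_alpha_loss": self.sigma_log_alpha_loss,
            "mu_log_lambda": self.mu_log_lambda,
            "sigma_log_lambda": self.sigma_log_lambda,
            "seed": self.seed,
            "subject_prefix": self.subject_prefix,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        d["model"] = UtilityModel(d.get("model", "TIME"))
        if isinstance(d.get("mu_eta"), dict):
            d["mu_eta"] = {Dynamic(k): float(v) for k, v in d["mu_eta"].items()}
        d["mu_log_beta"] = {Dynamic(k): float(v)
                            for k, v in d.get("mu_log_beta", {}).items()}
        return cls(**d)


def calibrate_beta(
    dynamic: Dynamic,
    stimuli: StimulusSet | None = None,
    wealth: float = 1000.0,
    eta: float | None = None,
    target: float = 2.0,
    log_support: tuple[float, float] = (-2.3, 3.4),
) -> float:
    """Choice sensitivity giving median |beta * delta-utility| near ``target``.

    Evaluated for an isoelastic agent (default: the dynamic's time-optimal
    risk aversion) over the session's constrained gamble space, so that
    synthetic choices are informative but stochastic in both conditions even
    though additive utility differences are in DKK (order 100) and
    multiplicative ones in log-units (order 0.1).  The result is constrained
    to ``log_support`` — the support of the group-level sensitivity prior —
    so that synthetic cohorts are realizations of the hierarchical model
    they are refit with (a generating value outside the prior support cannot
    be recovered by construction).
    """
    dynamic = Dynamic(dynamic)
    stimuli = stimuli or make_stimulus_set(dynamic)
    eta = dynamic.optimal_eta if eta is None else eta
    _, pairs = build_gamble_space(stimuli)
    outs = np.array([p.outcome_values for p in pairs])
    du = _delta_u_outcomes(outs, wealth, dynamic,
                           UtilityParams(model=UtilityModel.ISO, eta=eta))
    dd = 0.5 * (du[:, 0] + du[:, 1] - du[:, 2] - du[:, 3])
    med = float(np.median(np.abs(dd)))
    if med == 0:
        raise ValueError("degenerate gamble space: zero median utility difference")
    return float(np.exp(np.clip(np.log(target / med), *log_support)))


def default_study_cohort(n_subjects: int = 18, sigma_eta: float = 0.3,
                         seed: int | None = None) -> CohortSpec:
    """The synthetic study replica: a TIME cohort matched to the paradigm."""
    return CohortSpec(
        n_subjects=n_subjects,
        model=UtilityModel.TIME,
        mu_eta={Dynamic.ADDITIVE: 0.0, Dynamic.MULTIPLICATIVE: 1.0},
        sigma_eta=sigma_eta,
        mu_log_beta={d: float(np.log(calibrate_beta(d))) for d in Dynamic},
        sigma_log_beta=0.2,
        seed=seed,
    )


def model_recovery_cohorts(n_per_cohort: int = 9, seed: int | None = None
                           ) -> dict[UtilityModel, CohortSpec]:
    """Three cohorts (TIME, PT, ISO) used for model-recovery exercises.

    The PT cohort has strong curvature (alpha about 0.4, lambda about 2.5);
    the ISO cohort holds a shared, dynamic-invariant risk aversion around
    0.5, distinguishing it from the TIME cohort's (0, 1) pattern.
    """
    beta = {d: float(np.log(calibrate_beta(d))) for d in Dynamic}
    seeds = {m: None if seed is None else seed + i
             for i, m in enumerate(UtilityModel)}
    return {
        UtilityModel.TIME: CohortSpec(
            n_subjects=n_per_cohort, model=UtilityModel.TIME,
            mu_eta={Dynamic.ADDITIVE: 0.0, Dynamic.MULTIPLICATIVE: 1.0},
            sigma_eta=0.3, mu_log_beta=beta, seed=seeds[UtilityModel.TIME],
            subject_prefix="time"),
        UtilityModel.PT: CohortSpec(
            n_subjects=n_per_cohort, model=UtilityModel.PT,
            mu_log_beta=beta, seed=seeds[UtilityModel.PT], subject_prefix="pt"),
        UtilityModel.ISO: CohortSpec(
            n_subjects=n_per_cohort, model=UtilityModel.ISO,
            mu_eta=0.5, sigma_eta=0.3, mu_log_beta=beta,
            seed=seeds[UtilityModel.ISO], subject_prefix="iso"),
    }


def _truncated_normal(rng, mu, sigma, lo, hi, size, what: str):
    """Normal draws resampled into (lo, hi); resample counts are logged."""
    out = rng.normal(mu, sigma, size)
    n_resampled = 0
    bad = (out <= lo) | (out >= hi)
    while np.any(bad):
        n_resampled += int(bad.sum())
        out[bad] = rng.normal(mu, sigma, int(bad.sum()))
        bad = (out <= lo) | (out >= hi)
    if n_resampled:
        logger.info("resampled %d out-of-bound draws for %s", n_resampled, what)
    return out


def sample_cohort(spec: CohortSpec, seed: int | None = None) -> list[AgentSpec]:
    """Draw a cohort of agents from the group-level distributions."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_subjects
    dynamics = list(Dynamic)
    log_beta = {
        d: rng.normal(spec.mu_log_beta.get(d, 0.0), spec.sigma_log_beta, n)
        for d in dynamics
    }
    agents: list[AgentSpec] = []
    if spec.model is UtilityModel.PT:
        la_g = _truncated_normal(rng, spec.mu_log_alpha_gain,
                                 spec.sigma_log_alpha_gain, -np.inf, 0.0, n,
                                 "log alpha_gain")
        la_l = _truncated_normal(rng, spec.mu_log_alpha_loss,
                                 spec.sigma_log_alpha_loss, -np.inf, 0.0, n,
                                 "log alpha_loss")
        l_lam = _truncated_normal(rng, spec.mu_log_lambda, spec.sigma_log_lambda,
                                  0.0, float(np.log(5.0)), n, "log lambda")
        for i in range(n):
            params = UtilityParams(
                model=UtilityModel.PT,
                alpha_gain=float(np.exp(la_g[i])),
                alpha_loss=float(np.exp(la_l[i])),
                lambda_=float(np.exp(l_lam[i])),
                beta={d: float(np.exp(log_beta[d][i])) for d in dynamics},
            )
            agents.append(AgentSpec(f"{spec.subject_prefix}{i:02d}",
                                    UtilityModel.PT, params))
        return agents
    mu_eta = spec.mu_eta
    if mu_eta is None:
        # TIME cohorts center on the optimum per dynamic; ISO on risk neutrality
        mu_eta = ({d: d.optimal_eta for d in dynamics}
                  if spec.model is UtilityModel.TIME else 0.0)
    if isinstance(mu_eta, Mapping):
        eta = {d: rng.normal(mu_eta[d], spec.sigma_eta, n) for d in dynamics}
    else:
        base = rng.normal(float(mu_eta), spec.sigma_eta, n)
        eta = {d: base for d in dynamics}
    for i in range(n):
        params = UtilityParams(
            model=spec.model,
            eta={d: float(eta[d][i]) for d in dynamics},
            beta={d: float(np.exp(log_beta[d][i])) for d in dynamics},
        )
        agents.append(AgentSpec(f"{spec.subject_prefix}{i:02d}", spec.model, params))
    return agents


# ---------------------------------------------------------------------------
# fast vectorized utility evaluation over trial outcome arrays


def _delta_u_outcomes(outcomes: np.ndarray, wealth, dynamic: Dynamic,
                      params: UtilityParams) -> np.ndarray:
    """Per-outcome utility change for an array of trial outcomes.

    ``outcomes`` has shape (..., 4) carrying (left1, left2, right1, right2);
    ``wealth`` is a scalar or array broadcastable against ``outcomes[..., 0]``.
    Outcomes that would drive wealth non-positive under a log-branch utility
    receive a large negative utility (the agent treats ruin as maximally bad).
    """
    s = np.asarray(outcomes, float)
    w = np.asarray(wealth, float)[..., None] if np.ndim(wealth) else float(wealth)
    if dynamic is Dynamic.ADDITIVE:
        dx = s
        x_new = w + s
    else:
        x_new = w * s
        dx = x_new - w
    if params.model is UtilityModel.PT:
        ag, al, lam = params.alpha_gain, params.alpha_loss, params.lambda_
        return np.where(dx > 0, np.abs(dx) ** ag, -lam * np.abs(dx) ** al)
    eta = params.eta_for(dynamic)
    with np.errstate(invalid="ignore", divide="ignore"):
        if eta == 1.0:
            du = np.log(x_new) - np.log(w)
        else:
            e = 1.0 - eta
            du = (np.power(x_new, e) - np.power(w, e)) / e
    return np.where(x_new > 0, du, _BIG_NEG)


def _session_outcomes(session: ActiveSession) -> np.ndarray:
    return np.array([t.outcome_values for t in session.trials], float)


def _choice_prob_left(delta_u: np.ndarray, beta: float) -> np.ndarray:
    with np.errstate(over="ignore", invalid="ignore"):
        z = beta * delta_u
        return np.where(delta_u == 0, 0.5, expit(np.where(np.isnan(z), 0.0, z)))


def simulate_choices(agent: AgentSpec, session: ActiveSession,
                     wealth: float = 1000.0, seed: int | None = None) -> pd.DataFrame:
    """Play one active session: a Bernoulli draw per trial via the logistic rule."""
    if wealth <= 0:
        raise ValueError("wealth must be positive")
    rng = np.random.default_rng(seed)
    outs = _session_outcomes(session)
    du = _delta_u_outcomes(outs, wealth, session.dynamic, agent.params)
    dd = 0.5 * (du[:, 0] + du[:, 1] - du[:, 2] - du[:, 3])
    p_left = _choice_prob_left(dd, agent.params.beta_for(session.dynamic))
    left = rng.random(len(dd)) < p_left
    return pd.DataFrame({
        "subject_id": agent.subject_id,
        "dynamic": session.dynamic.value,
        "trial_index": np.arange(len(dd)),
        "left_out1": outs[:, 0],
        "left_out2": outs[:, 1],
        "right_out1": outs[:, 2],
        "right_out2": outs[:, 3],
        "choice": np.where(left, "left", "right"),
        "wealth": wealth,
    })


def simulate_study(
    agents: Sequence[AgentSpec],
    sessions: Mapping[Dynamic, ActiveSession] | None = None,
    wealth: float = 1000.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a full two-condition study for a cohort of agents.

    All subjects face the same seeded session per condition (trial order is
    irrelevant to the fixed-wealth choice model); per-subject choice
    randomness derives from independent substreams of ``seed``.
    """
    if sessions is None:
        sessions = {d: build_active_session(make_stimulus_set(d), seed=seed)
                    for d in Dynamic}
    frames = []
    for ci, (dyn, session) in enumerate(sessions.items()):
        for si, agent in enumerate(agents):
            sub_seed = np.random.SeedSequence([int(seed), ci, si])
            frames.append(simulate_choices(agent, session, wealth,
                                           seed=sub_seed))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# long-horizon wealth simulation (growth-rate orderings)


def _simulate_paths(agent: AgentSpec, dynamic: Dynamic, n_trials: int,
                    initial_wealth: float, n_reps: int, rng,
                    stimuli: StimulusSet | None = None,
                    record_path: bool = False):
    """Vectorized repeated play: per trial a random pair from the constrained
    gamble space is offered, the agent chooses stochastically and one of the
    chosen gamble's outcomes is realized equiprobably.

    Multiplicative wealth is tracked on the log scale so that long horizons
    neither overflow nor underflow.  Additive wealth may go negative in this
    open-ended setting (the passive-session bounds do not apply here).
    """
    dynamic = Dynamic(dynamic)
    stimuli = stimuli or make_stimulus_set(dynamic)
    _, pairs = build_gamble_space(stimuli)
    P = np.array([p.outcome_values for p in pairs])  # (n_pairs, 4)
    beta = agent.params.beta_for(dynamic)
    mult = dynamic is Dynamic.MULTIPLICATIVE
    state = np.full(n_reps, np.log(initial_wealth) if mult else initial_wealth)
    path = np.empty((n_trials + 1, n_reps)) if record_path else None
    if record_path:
        path[0] = np.exp(state) if mult else state
    realized_out = np.empty((n_trials, n_reps)) if record_path else None
    for t in range(n_trials):
        s = P[rng.integers(0, len(P), n_reps)]  # (R, 4)
        w = np.exp(np.clip(state, -700, 700)) if mult else state
        du = _delta_u_outcomes(s, w, dynamic, agent.params)
        dd = 0.5 * (du[:, 0] + du[:, 1] - du[:, 2] - du[:, 3])
        left = rng.random(n_reps) < _choice_prob_left(dd, beta)
        chosen = np.where(left[:, None], s[:, 0:2], s[:, 2:4])
        realized = np.where(rng.random(n_reps) < 0.5, chosen[:, 0], chosen[:, 1])
        if mult:
            state = state + np.log(realized)
        else:
            state = state + realized
        if record_path:
            realized_out[t] = realized
            path[t + 1] = np.exp(state) if mult else state
    return state, path, realized_out


def simulate_wealth_trajectory(
    agent: AgentSpec,
    dynamic: Dynamic,
    n_trials: int,
    initial_wealth: float = 1000.0,
    seed: int | None = None,
    stimuli: StimulusSet | None = None,
) -> WealthTrajectory:
    """One realized long-run wealth trajectory of an agent playing the gamble space."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    _, path, realized = _simulate_paths(agent, dynamic, n_trials, initial_wealth,
                                        1, rng, stimuli, record_path=True)
    return WealthTrajectory(dynamic=Dynamic(dynamic), initial_wealth=initial_wealth,
                            outcomes=realized[:, 0], wealth=path[:, 0])


def simulate_terminal_growth(
    agent: AgentSpec,
    dynamic: Dynamic,
    n_trials: int,
    n_reps: int,
    initial_wealth: float = 1000.0,
    seed: int | None = None,
    stimuli: StimulusSet | None = None,
) -> np.ndarray:
    """Finite-time growth rates over ``n_reps`` independent long runs.

    Additive: (final - initial wealth)/trials, DKK per trial.  Multiplicative:
    (final - initial log-wealth)/trials, log-units per trial.  Medians across
    replicates expose the growth-rate ordering of utility functions.
    """
    rng = np.random.default_rng(seed)
    state, _, _ = _simulate_paths(agent, dynamic, n_trials, initial_wealth,
                                  n_reps, rng, stimuli)
    if Dynamic(dynamic) is Dynamic.MULTIPLICATIVE:
        return (state - np.log(initial_wealth)) / n_trials
    return (state - initial_wealth) / n_trials
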