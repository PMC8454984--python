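"""Utility models and the stochastic choice rule.

Three utility functions over changes in in-game wealth are compared
throughout the package:

* prospect theory (PT): a power value function of the wealth change, with
  separate gain/loss curvature and loss aversion, and no probability
  weighting (all outcome probabilities are 0.5 by design);
* isoelastic / CRRA (ISO): u(x) = (x**(1 - eta) - 1)/(1 - eta) over absolute
  wealth, with the logarithmic branch at eta = 1;
* time-optimal (TIME): the isoelastic utility whose risk aversion maximizes
  the time-average growth rate of wealth — linear (eta = 0) under additive
  dynamics and logarithmic (eta = 1) under multiplicative dynamics.

Choices are stochastic via a logistic rule on the expected-utility
difference between the left and right gamble, with sensitivity beta.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping

import numpy as np
from scipy.special import expit

from .paradigm import Dynamic, Gamble, TrialPair, apply_outcome

__all__ = [
    "UtilityModel",
    "UtilityParams",
    "DecisionContext",
    "pt_delta_utility",
    "iso_utility",
    "delta_utility",
    "expected_delta_utility",
    "utility_difference",
    "choice_probability",
]


class UtilityModel(str, Enum):
    PT = "PT"
    ISO = "ISO"
    TIME = "TIME"


@dataclass(frozen=True)
class DecisionContext:
    """The fixed decision context of one active session.

    Wealth is stationary over the session at the level reached at the end of
    the passive phase; gamble outcomes are hidden and only realized at the
    end of the day.
    """

    wealth: float
    dynamic: Dynamic

    def __post_init__(self) -> None:
        if self.wealth <= 0:
            raise ValueError("context wealth must be positive")


@dataclass(frozen=True)
class UtilityParams:
    """Subject-level parameters for one utility model.

    ``eta`` (ISO/TIME) may be a single float or a per-dynamic mapping; TIME
    defaults to the dynamic's optimum when ``eta`` is None.  ``beta`` is the
    choice sensitivity, one value per dynamic (a plain float is broadcast).
    """

    model: UtilityModel
    eta: float | Mapping[Dynamic, float] | None = None
    alpha_gain: float | None = None
    alpha_loss: float | None = None
    lambda_: float | None = None
    beta: float | Mapping[Dynamic, float] = 1.0

    def __post_init__(self) -> None:
        if self.model is UtilityModel.PT:
            if self.alpha_gain is None or self.alpha_loss is None or self.lambda_ is None:
                raise ValueError("PT requires alpha_gain, alpha_loss and lambda_")
            if not (0 < self.alpha_gain < 1 and 0 < self.alpha_loss < 1):
                raise ValueError("PT curvature parameters must lie in (0, 1)")
            if not (1 < self.lambda_ < 5):
                raise ValueError("loss aversion lambda must lie in (1, 5)")
        for b in (self.beta.values() if isinstance(self.beta, Mapping) else [self.beta]):
            if b <= 0:
                raise ValueError("beta must be positive")

    def eta_for(self, dynamic: Dynamic) -> float:
        if isinstance(self.eta, Mapping):
            return float(self.eta[Dynamic(dynamic)])
        if self.eta is None:
            if self.model is UtilityModel.TIME:
                return Dynamic(dynamic).optimal_eta
            raise ValueError("eta is required for the ISO model")
        return float(self.eta)

    def beta_for(self, dynamic: Dynamic) -> float:
        if isinstance(self.beta, Mapping):
            return float(self.beta[Dynamic(dynamic)])
        return float(self.beta)

    def to_dict(self) -> dict:
        enc = lambda v: ({Dynamic(k).value: float(x) for k, x in v.items()}
                         if isinstance(v, Mapping) else v)
        return {
            "model": self.model.value,
            "eta": enc(self.eta),
            "alpha_gain": self.alpha_gain,
            "alpha_loss": self.alpha_loss,
            "lambda_": self.lambda_,
            "beta": enc(self.beta),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "UtilityParams":
        dec = lambda v: ({Dynamic(k): float(x) for k, x in v.items()}
                         if isinstance(v, dict) else v)
        return cls(
            model=UtilityModel(d["model"]),
            eta=dec(d.get("eta")),
            alpha_gain=d.get("alpha_gain"),
            alpha_loss=d.get("alpha_loss"),
            lambda_=d.get("lambda_"),
            beta=dec(d.get("beta", 1.0)),
        )


def pt_delta_utility(delta_x, alpha_gain: float, alpha_loss: float, lambda_: float):
    """Prospect-theory value of a wealth change.

    Gains are raised to ``alpha_gain``; losses (including zero) are raised to
    ``alpha_loss`` and scaled by ``-lambda_``; a zero change is worth zero.
    """
    dx = np.asarray(delta_x, float)
    out = np.where(dx > 0,
                   np.power(np.abs(dx), alpha_gain),
                   -lambda_ * np.power(np.abs(dx), alpha_loss))
    return out if out.ndim else float(out)


def iso_utility(x, eta: float):
    """Isoelastic (CRRA) utility u(x) = (x**(1-eta) - 1)/(1-eta), ln x at eta = 1."""
    x = np.asarray(x, float)
    if np.any(x <= 0):
        raise ValueError("isoelastic utility requires positive wealth")
    if eta == 1.0:
        out = np.log(x)
    else:
        out = (np.power(x, 1.0 - eta) - 1.0) / (1.0 - eta)
    return out if out.ndim else float(out)


def delta_utility(context: DecisionContext, outcome: float, params: UtilityParams) -> float:
    """Change in utility produced by one outcome in the given context."""
    w = context.wealth
    x_new = apply_outcome(w, outcome, context.dynamic)
    if params.model is UtilityModel.PT:
        return float(pt_delta_utility(x_new - w, params.alpha_gain,
                                      params.alpha_loss, params.lambda_))
    eta = params.eta_for(context.dynamic)
    if x_new <= 0:
        raise ValueError("outcome drives wealth non-positive")
    return float(iso_utility(x_new, eta) - iso_utility(w, eta))


def expected_delta_utility(gamble: Gamble, context: DecisionContext,
                           params: UtilityParams) -> float:
    """Probability-weighted mean utility change of a two-outcome gamble."""
    a, b = gamble.outcomes
    return 0.5 * delta_utility(context, a, params) + 0.5 * delta_utility(context, b, params)


def utility_difference(pair: TrialPair, context: DecisionContext,
                       params: UtilityParams) -> float:
    """Expected-utility difference, left minus right."""
    return (expected_delta_utility(pair.left, context, params)
            - expected_delta_utility(pair.right, context, params))


def choice_probability(delta, beta: float):
    """Probability of choosing the left gamble: logistic(beta * delta).

    Numerically stable for arbitrarily large |beta * delta|.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    out = expit(beta * np.asarray(delta, float))
    return out if out.ndim else float(out)
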