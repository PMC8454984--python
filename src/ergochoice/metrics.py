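"""Behavioral statistics derived from choices and fitted risk preferences.

Three families of statistics summarize how gamble dynamics shape behavior:
the proportion of discrepant trials decided in favour of log utility
(CP_log), Euclidean distances of each subject's (eta_add, eta_mult) pair to
the time-optimal coordinate (0, 1) versus to the dynamic-invariant
diagonal, and the realized time-average growth rate of the gambles each
subject chose.  The per-subject table these produce is the input to
standard group-level inferential tooling, which is deliberately out of this
module's scope.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd

from .paradigm import (
    ActiveSession,
    Dynamic,
    Gamble,
    gamble_growth_rate,
    log_preferred_side,
)

__all__ = [
    "choice_proportion_log",
    "distance_to_time_optimal",
    "distance_to_diagonal",
    "realized_growth_rate",
    "subject_metrics",
]


def _aligned_session_rows(df: pd.DataFrame, session: ActiveSession) -> pd.DataFrame:
    d = df[df["dynamic"] == session.dynamic.value]
    if d.empty:
        raise ValueError(f"dataset has no rows for the {session.dynamic.value} condition")
    if d["trial_index"].max() >= session.n_trials:
        raise ValueError("dataset trial indices exceed the session length")
    return d


def choice_proportion_log(data: pd.DataFrame, session: ActiveSession) -> pd.Series:
    """Per-subject CP_log: the fraction of discrepant trials decided as a
    log-utility agent would decide them, at the session's reference wealth.

    Choosing in favour of linear utility is the complement (CP_log < 0.5
    means choices lean toward linear utility).
    """
    d = _aligned_session_rows(data, session)
    flags = np.array([t.is_discrepant for t in session.trials])
    if not flags.any():
        raise ValueError("session contains no discrepant trials")
    pref = {}
    for i, t in enumerate(session.trials):
        if flags[i]:
            pref[i] = log_preferred_side(t, session.dynamic, session.reference_wealth)
    out = {}
    for sid, g in d.groupby("subject_id"):
        g = g[g["trial_index"].isin(pref)]
        if g.empty:
            raise ValueError(f"subject {sid}: no discrepant trials in the dataset")
        agree = [row.choice == pref[row.trial_index] for row in g.itertuples()]
        out[sid] = float(np.mean(agree))
    return pd.Series(out, name=f"cp_log_{session.dynamic.value}")


def distance_to_time_optimal(eta_add: float, eta_mult: float) -> float:
    """Euclidean distance of (eta_add, eta_mult) to the time-optimal point (0, 1)."""
    return math.hypot(eta_add, eta_mult - 1.0)


def distance_to_diagonal(eta_add: float, eta_mult: float) -> float:
    """Distance of (eta_add, eta_mult) to the nearest dynamic-invariant point
    (the eta_add = eta_mult diagonal)."""
    return abs(eta_mult - eta_add) / math.sqrt(2.0)


def realized_growth_rate(data: pd.DataFrame, session: ActiveSession,
                         dynamic: Dynamic | None = None) -> pd.Series:
    """Per-subject mean time-average growth rate of the chosen gambles.

    Additive: DKK per trial; multiplicative: log-units per trial.
    """
    dynamic = Dynamic(dynamic) if dynamic is not None else session.dynamic
    d = _aligned_session_rows(data, session)
    out = {}
    for sid, g in d.groupby("subject_id"):
        rates = []
        for row in g.itertuples():
            if row.choice == "left":
                gam = Gamble((row.left_out1, row.left_out2))
            else:
                gam = Gamble((row.right_out1, row.right_out2))
            rates.append(gamble_growth_rate(gam, dynamic))
        out[sid] = float(np.mean(rates))
    return pd.Series(out, name=f"growth_{dynamic.value}")


def subject_metrics(
    data: pd.DataFrame,
    sessions: Mapping[Dynamic, ActiveSession],
    eta_map: Mapping[str, Mapping[Dynamic, float]] | None = None,
) -> pd.DataFrame:
    """Tidy per-subject table of all behavioral statistics.

    ``eta_map`` optionally supplies per-subject MAP risk aversions per
    condition (e.g. from the hierarchical fit); distances are filled only
    when it is given.
    """
    add, mult = sessions[Dynamic.ADDITIVE], sessions[Dynamic.MULTIPLICATIVE]
    cp_a = choice_proportion_log(data, add)
    cp_m = choice_proportion_log(data, mult)
    gr_a = realized_growth_rate(data, add)
    gr_m = realized_growth_rate(data, mult)
    df = pd.DataFrame({
        "cp_log_additive": cp_a,
        "cp_log_multiplicative": cp_m,
        "delta_cp_log": cp_m - cp_a,
        "growth_additive": gr_a,
        "growth_multiplicative": gr_m,
    })
    if eta_map is not None:
        rows = {}
        for sid in df.index:
            e = eta_map[sid]
            ea, em = e[Dynamic.ADDITIVE], e[Dynamic.MULTIPLICATIVE]
            rows[sid] = (ea, em, distance_to_time_optimal(ea, em),
                         distance_to_diagonal(ea, em))
        extra = pd.DataFrame.from_dict(
            rows, orient="index",
            columns=["eta_additive", "eta_multiplicative",
                     "dist_time_optimal", "dist_diagonal"])
        df = df.join(extra)
    df.index.name = "subject_id"
    return df
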