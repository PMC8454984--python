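"""Vectorized MCMC machinery shared by the hierarchical models.

The choice likelihood factorizes over subject-condition groups, and within a
group every trial's utility difference is a linear combination of the
utilities of at most nine unique post-outcome wealth levels.  Datasets are
therefore packed into dense arrays (group x unique-outcome tables plus
per-trial index arrays), so that a full-data log-likelihood evaluation for
all chains is a handful of numpy operations.  Sampling uses elementwise
adaptive random-walk Metropolis for subject-level parameters (conditionally
independent given the group level), Gibbs steps for truncated-normal group
means, and log-scale Metropolis for group standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .paradigm import Dynamic

DYNAMICS = (Dynamic.ADDITIVE, Dynamic.MULTIPLICATIVE)


@dataclass
class PackedData:
    """Choice data in likelihood-ready form.

    One "group" is a subject-condition block.  ``x_new[g, k]`` is the wealth
    after the k-th unique outcome of group g, ``dx`` the corresponding wealth
    change, ``idx[g, t, :]`` the four unique-outcome indices of trial t
    (left1, left2, right1, right2), ``sgn[g, t]`` +1/-1 for a left/right
    choice, and ``mask`` zeroes out padding trials.
    """

    x_new: np.ndarray      # (G, K)
    dx: np.ndarray         # (G, K)
    idx: np.ndarray        # (G, T, 4) int
    sgn: np.ndarray        # (G, T)
    mask: np.ndarray       # (G, T)
    wealth: np.ndarray     # (G,)
    subj: np.ndarray       # (G,) int, subject index
    cond: np.ndarray       # (G,) int, condition index (order of DYNAMICS)
    hyper: np.ndarray      # (G,) int, hyper-group index (usually == cond)
    subject_ids: list
    conditions: list       # Dynamic per condition index
    n_hyper: int
    n_replicates: int | None = None  # set when hyper-groups are (replicate, condition)

    @property
    def n_groups(self) -> int:
        return self.x_new.shape[0]

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def one_sided_groups(self) -> list[tuple]:
        """(subject, dynamic) blocks in which every choice fell on one side."""
        out = []
        for g in range(self.n_groups):
            s = self.sgn[g][self.mask[g] > 0]
            if len(s) and (np.all(s > 0) or np.all(s < 0)):
                out.append((self.subject_ids[self.subj[g]],
                            self.conditions[self.cond[g]]))
        return out


def pack_dataset(df: pd.DataFrame, replicate_col: str | None = None) -> PackedData:
    """Pack a tidy choice dataset into dense likelihood arrays.

    With ``replicate_col``, hyper-groups are (replicate, condition) pairs so
    that several independent cohorts can be fit jointly in one sampler run.
    """
    conds = [d for d in DYNAMICS if d.value in set(df["dynamic"])]
    subject_ids = sorted(df["subject_id"].unique().tolist())
    sub_index = {s: i for i, s in enumerate(subject_ids)}
    cond_index = {d.value: i for i, d in enumerate(conds)}
    if replicate_col is not None:
        reps = sorted(df[replicate_col].unique().tolist())
        rep_index = {r: i for i, r in enumerate(reps)}
        n_hyper = len(reps) * len(conds)
    else:
        reps, rep_index, n_hyper = [None], {None: 0}, len(conds)

    groups = list(df.groupby(["subject_id", "dynamic"], sort=True))
    G = len(groups)
    T = max(len(g) for _, g in groups)
    Kmax = 0
    prepared = []
    for (sid, dyn), g in groups:
        outs = g[["left_out1", "left_out2", "right_out1", "right_out2"]].to_numpy(float)
        w = float(g["wealth"].iloc[0])
        vals, idx = np.unique(outs, return_inverse=True)
        idx = idx.reshape(outs.shape)
        x_new = w + vals if dyn == Dynamic.ADDITIVE.value else w * vals
        if np.any(x_new <= 0):
            raise ValueError(
                f"subject {sid} ({dyn}): an outcome drives wealth non-positive; "
                "wealth-based utilities are undefined for this dataset"
            )
        sgn = np.where(g["choice"].to_numpy() == "left", 1.0, -1.0)
        rep = g[replicate_col].iloc[0] if replicate_col is not None else None
        prepared.append((sid, dyn, rep, x_new, vals, idx, sgn, w))
        Kmax = max(Kmax, len(vals))

    x_new = np.ones((G, Kmax))
    dx = np.zeros((G, Kmax))
    idx_arr = np.zeros((G, T, 4), dtype=np.int64)
    sgn_arr = np.zeros((G, T))
    mask = np.zeros((G, T))
    wealth = np.empty(G)
    subj = np.empty(G, dtype=np.int64)
    cond = np.empty(G, dtype=np.int64)
    hyper = np.empty(G, dtype=np.int64)
    for g, (sid, dyn, rep, xn, vals, idx, sgn, w) in enumerate(prepared):
        k, t = len(vals), len(sgn)
        x_new[g, :k] = xn
        x_new[g, k:] = xn[-1]  # padding never indexed; keep positive
        dx[g, :k] = xn - w
        idx_arr[g, :t] = idx
        sgn_arr[g, :t] = sgn
        mask[g, :t] = 1.0
        wealth[g] = w
        subj[g] = sub_index[sid]
        cond[g] = cond_index[dyn]
        hyper[g] = rep_index[rep] * len(conds) + cond_index[dyn]
    return PackedData(x_new=x_new, dx=dx, idx=idx_arr, sgn=sgn_arr, mask=mask,
                      wealth=wealth, subj=subj, cond=cond, hyper=hyper,
                      subject_ids=subject_ids, conditions=conds, n_hyper=n_hyper,
                      n_replicates=None if replicate_col is None else len(reps))


def _log_sigmoid(z: np.ndarray) -> np.ndarray:
    return -np.logaddexp(0.0, -z)


def _gather_delta_u(U: np.ndarray, pack: PackedData) -> np.ndarray:
    """Per-trial expected-utility difference from per-unique-outcome utilities.

    ``U`` has shape (..., G, K); returns (..., G, T).
    """
    g_ix = np.arange(pack.n_groups)[:, None, None]
    take = U[..., g_ix, pack.idx]  # (..., G, T, 4)
    return 0.5 * (take[..., 0] + take[..., 1] - take[..., 2] - take[..., 3])


def iso_loglik(pack: PackedData, eta: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Bernoulli log-likelihood of the isoelastic model.

    ``eta`` and ``beta`` have shape (..., G); returns (..., G).
    """
    e = (1.0 - eta)[..., None]
    x = pack.x_new
    w = pack.wealth[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        u_pow = (np.power(x, e) - np.power(w, e)) / e
    u_log = np.log(x) - np.log(w)
    U = np.where(np.abs(e) < 1e-12, u_log, u_pow)
    dd = _gather_delta_u(U, pack)
    z = pack.sgn * beta[..., None] * dd
    return (pack.mask * _log_sigmoid(z)).sum(axis=-1)


def pt_loglik(pack: PackedData, alpha_gain: np.ndarray, alpha_loss: np.ndarray,
              lambda_: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Bernoulli log-likelihood of the prospect-theory model (shapes as above)."""
    dx = pack.dx
    adx = np.abs(dx)
    U = np.where(dx > 0,
                 np.power(adx, alpha_gain[..., None]),
                 -lambda_[..., None] * np.power(adx, alpha_loss[..., None]))
    dd = _gather_delta_u(U, pack)
    z = pack.sgn * beta[..., None] * dd
    return (pack.mask * _log_sigmoid(z)).sum(axis=-1)


def norm_logpdf(x, mu, sigma):
    return -0.5 * ((x - mu) / sigma) ** 2 - np.log(sigma) - 0.5 * np.log(2 * np.pi)


def sample_truncnorm(rng, mu, sigma, lo, hi):
    """Inverse-CDF sampling from a truncated normal (vectorized)."""
    a = ndtr((lo - mu) / sigma)
    b = ndtr((hi - mu) / sigma)
    u = rng.uniform(a, b)
    u = np.clip(u, 1e-14, 1 - 1e-14)
    return mu + sigma * ndtri(u)


class AdaptiveScale:
    """Robbins-Monro adaptation of elementwise random-walk proposal scales."""

    TARGET = 0.44  # optimal acceptance for one-dimensional random walks

    def __init__(self, shape, init: float = 0.3):
        self.log_s = np.full(shape, np.log(init))

    @property
    def scale(self) -> np.ndarray:
        return np.exp(self.log_s)

    def adapt(self, acc_prob: np.ndarray, it: int) -> None:
        gamma = 1.0 / (1.0 + it) ** 0.6
        self.log_s += gamma * (acc_prob - self.TARGET)
        np.clip(self.log_s, -12.0, 4.0, out=self.log_s)


def metropolis_accept(rng, log_acc: np.ndarray):
    """Elementwise accept mask and the capped acceptance probability."""
    acc_prob = np.exp(np.minimum(log_acc, 0.0))
    accept = rng.random(log_acc.shape) < acc_prob
    return accept, acc_prob
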