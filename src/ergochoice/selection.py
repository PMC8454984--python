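"""Latent-mixture model selection over the three utility models.

A per-subject indicator z (uniform prior) selects among the time-optimal,
prospect-theory and isoelastic sub-models nested in one hierarchical model.
Two sampler variants share an interface: the default marginalizes z
analytically (responsibilities are read off the sub-model likelihoods), the
alternative samples z by Gibbs steps while parameters of unselected models
evolve under their own hierarchical priors.

Group-level inference over the population frequencies of the models uses
the random-effects Dirichlet scheme: variational estimation of the
frequency posterior, Monte-Carlo exceedance probabilities, the Bayes
omnibus risk (posterior probability that all models are equally frequent),
and the protected exceedance probability PXP = EP*(1 - BOR) + BOR/K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, logsumexp, ndtr

from . import _mcmc
from ._mcmc import PackedData, pack_dataset
from .estimation import McmcConfig, _flatten_dataset
from .io import validate_choice_dataset
from .utility import UtilityModel

__all__ = [
    "HlmSpec",
    "ModelPosterior",
    "BmsResult",
    "fit_hlm",
    "estimated_model_frequencies",
    "protected_exceedance_probability",
    "bms",
    "MODEL_ORDER",
]

#: column/reporting order of the sub-models
MODEL_ORDER = (UtilityModel.TIME, UtilityModel.PT, UtilityModel.ISO)
_LOG5 = float(np.log(5.0))


@dataclass(frozen=True)
class HlmSpec:
    """Hyperpriors of the hierarchical latent mixture.

    The time-optimal sub-model fixes the group mean risk aversion at 0
    (additive) and 1 (multiplicative), leaving only its dispersion free.
    The isoelastic sub-model has one risk aversion per subject shared across
    conditions.  Prospect theory has lognormal gain/loss curvatures
    truncated into (0, 1) and a lognormal loss aversion truncated into
    (1, 5).  Each sub-model carries its own per-condition sensitivity
    hyperpriors.
    """

    time_means: tuple[float, float] = (0.0, 1.0)  # additive, multiplicative
    sigma_eta_time_bounds: tuple[float, float] = (0.01, 1.6)
    mu_eta_iso_bounds: tuple[float, float] = (-2.5, 2.5)
    sigma_eta_iso_bounds: tuple[float, float] = (0.01, 1.6)
    mu_log_alpha_bounds: tuple[float, float] = (-2.3, 0.0)
    sigma_log_alpha_bounds: tuple[float, float] = (0.01, 1.6)
    mu_log_lambda_bounds: tuple[float, float] = (0.0, 1.6)
    sigma_log_lambda_bounds: tuple[float, float] = (0.01, 1.6)
    mu_beta_bounds: tuple[float, float] = (-2.3, 3.4)
    sigma_beta_bounds: tuple[float, float] = (0.01, 1.6)


@dataclass
class ModelPosterior:
    """Joint posterior of the latent mixture."""

    model_probs: pd.DataFrame          # subjects x (TIME, PT, ISO)
    idata: az.InferenceData
    method: str
    rhat_interval: tuple[float, float] = (1.0, 1.01)

    def rhat(self) -> pd.Series:
        return _flatten_dataset(az.rhat(self.idata))

    def flagged_parameters(self) -> pd.Series:
        r = self.rhat()
        lo, hi = self.rhat_interval
        return r[(r < lo) | (r > hi)]

    def group_probs(self) -> pd.Series:
        """Posterior model probabilities marginalized over subjects."""
        return self.model_probs.mean(axis=0)


@dataclass
class BmsResult:
    """Random-effects Bayesian model selection over the cohort."""

    alpha: np.ndarray                  # Dirichlet posterior concentrations
    frequencies: np.ndarray            # posterior mean model frequencies
    frequencies_sd: np.ndarray
    exceedance: np.ndarray
    bor: float
    pxp: np.ndarray
    models: tuple = tuple(m.value for m in MODEL_ORDER)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frequency": self.frequencies,
            "frequency_sd": self.frequencies_sd,
            "exceedance": self.exceedance,
            "pxp": self.pxp,
        }, index=list(self.models))


# ---------------------------------------------------------------------------
# sampler


def _slice_pack(pack: PackedData, sel: np.ndarray) -> PackedData:
    return PackedData(
        x_new=pack.x_new[sel], dx=pack.dx[sel], idx=pack.idx[sel],
        sgn=pack.sgn[sel], mask=pack.mask[sel], wealth=pack.wealth[sel],
        subj=pack.subj[sel], cond=pack.cond[sel], hyper=pack.hyper[sel],
        subject_ids=pack.subject_ids, conditions=pack.conditions,
        n_hyper=pack.n_hyper,
    )


def fit_hlm(
    data: pd.DataFrame,
    spec: HlmSpec | None = None,
    cfg: McmcConfig | None = None,
    method: str = "marginalized",
) -> ModelPosterior:
    """Sample the latent-mixture posterior over {TIME, PT, ISO}.

    ``method='marginalized'`` integrates the indicator analytically and
    reports per-subject mixture responsibilities; ``method='indicator'``
    samples z directly and reports its posterior frequencies.
    """
    if method not in ("marginalized", "indicator"):
        raise ValueError("method must be 'marginalized' or 'indicator'")
    spec = spec or HlmSpec()
    cfg = cfg or McmcConfig()
    validate_choice_dataset(data)
    pack = pack_dataset(data)
    if len(pack.conditions) < 2:
        raise ValueError("the latent mixture requires both conditions")
    if pack.n_groups != 2 * pack.n_subjects:
        raise ValueError("every subject must contribute both conditions")
    draws, resp = _sample_hlm(pack, spec, cfg, method)
    probs = resp.mean(axis=(0, 1))  # (N, 3)
    model_probs = pd.DataFrame(probs, index=pack.subject_ids,
                               columns=[m.value for m in MODEL_ORDER])
    idata = _hlm_to_idata(draws, resp, pack)
    mp = ModelPosterior(model_probs=model_probs, idata=idata, method=method,
                        rhat_interval=cfg.rhat_interval)
    flagged = mp.flagged_parameters()
    if len(flagged):
        warnings.warn(
            f"{len(flagged)} parameter(s) have R-hat outside "
            f"{cfg.rhat_interval}: {', '.join(flagged.index[:5])}..."
        )
    return mp


def _sample_hlm(pack: PackedData, spec: HlmSpec, cfg: McmcConfig, method: str):
    rng = np.random.default_rng(cfg.seed)
    C, G, N = cfg.n_chains, pack.n_groups, pack.n_subjects
    NC = len(pack.conditions)
    marginal = method == "marginalized"

    # groups are sorted subject-major; map (subject, cond) <-> group
    order = np.lexsort((pack.cond, pack.subj))
    assert np.array_equal(order, np.arange(G)), "pack must be subject-major"
    cond_sel = [pack.cond == c for c in range(NC)]
    packs_c = [_slice_pack(pack, s) for s in cond_sel]
    subj_of = pack.subj  # (G,)
    tm = np.array(spec.time_means)  # fixed TIME group means per condition

    # --- state initialization (overdispersed within the priors)
    sg_te = rng.uniform(0.1, 1.0, (C, NC))
    eta_t = tm[pack.cond] + sg_te[:, pack.cond] * rng.standard_normal((C, G))
    mu_ei = rng.uniform(*spec.mu_eta_iso_bounds, C)
    sg_ei = rng.uniform(0.1, 1.0, C)
    eta_i = mu_ei[:, None] + sg_ei[:, None] * rng.standard_normal((C, N))
    mu_ag = rng.uniform(*spec.mu_log_alpha_bounds, C)
    sg_ag = rng.uniform(0.1, 0.8, C)
    mu_al = rng.uniform(*spec.mu_log_alpha_bounds, C)
    sg_al = rng.uniform(0.1, 0.8, C)
    mu_lm = rng.uniform(*spec.mu_log_lambda_bounds, C)
    sg_lm = rng.uniform(0.1, 0.8, C)
    lag = np.clip(mu_ag[:, None] + sg_ag[:, None] * rng.standard_normal((C, N)),
                  None, -1e-3)
    lal = np.clip(mu_al[:, None] + sg_al[:, None] * rng.standard_normal((C, N)),
                  None, -1e-3)
    llam = np.clip(mu_lm[:, None] + sg_lm[:, None] * rng.standard_normal((C, N)),
                   1e-3, _LOG5 - 1e-3)
    mu_b = rng.uniform(*spec.mu_beta_bounds, (C, NC, 3))
    sg_b = rng.uniform(0.1, 1.0, (C, NC, 3))
    lbe = (mu_b[:, pack.cond, :]
           + sg_b[:, pack.cond, :] * rng.standard_normal((C, G, 3)))  # (C, G, 3)

    def ll_iso_full(eta_subj, beta):
        return _mcmc.iso_loglik(pack, eta_subj[:, subj_of], beta)

    def ll_pt_full(a_g, a_l, lam, beta):
        return _mcmc.pt_loglik(pack, a_g[:, subj_of], a_l[:, subj_of],
                               lam[:, subj_of], beta)

    LL = np.empty((C, G, 3))
    LL[..., 0] = _mcmc.iso_loglik(pack, eta_t, np.exp(lbe[..., 0]))
    LL[..., 1] = ll_pt_full(np.exp(lag), np.exp(lal), np.exp(llam),
                            np.exp(lbe[..., 1]))
    LL[..., 2] = ll_iso_full(eta_i, np.exp(lbe[..., 2]))

    z = rng.integers(0, 3, (C, N))

    # per-subject likelihood matrix (C, N, 3): sum of the subject's two groups
    def subj_ll(LLg):
        return LLg.reshape(C, N, NC, 3).sum(axis=2)

    def mix_delta(m, d_subj):
        """Change in the per-subject objective when model m's ll changes."""
        if marginal:
            others = [k for k in range(3) if k != m]
            lse_wo = np.logaddexp(LLs[..., others[0]], LLs[..., others[1]])
            return (np.logaddexp(lse_wo, LLs[..., m] + d_subj)
                    - np.logaddexp(lse_wo, LLs[..., m]))
        return np.where(z == m, d_subj, 0.0)

    scales = {k: _mcmc.AdaptiveScale(shape) for k, shape in {
        "eta_t": (C, G), "eta_i": (C, N), "lag": (C, N), "lal": (C, N),
        "llam": (C, N), "lbe": (C, G, 3),
    }.items()}
    hscales = {k: _mcmc.AdaptiveScale(shape, init=0.2) for k, shape in {
        "sg_te": (C, NC), "sg_ei": (C,), "mu_ag": (C,), "sg_ag": (C,),
        "mu_al": (C,), "sg_al": (C,), "mu_lm": (C,), "sg_lm": (C,),
        "sg_b": (C, NC, 3),
    }.items()}

    D = cfg.n_draws
    rec = {k: np.empty((C, D) + s) for k, s in {
        "eta_time": (G,), "eta_iso": (N,), "log_alpha_gain": (N,),
        "log_alpha_loss": (N,), "log_lambda": (N,), "log_beta": (G, 3),
        "sigma_eta_time": (NC,), "mu_eta_iso": (), "sigma_eta_iso": (),
        "mu_log_alpha_gain": (), "sigma_log_alpha_gain": (),
        "mu_log_alpha_loss": (), "sigma_log_alpha_loss": (),
        "mu_log_lambda": (), "sigma_log_lambda": (),
        "mu_log_beta": (NC, 3), "sigma_log_beta": (NC, 3),
    }.items()}
    resp = np.empty((C, D, N, 3))

    LLs = subj_ll(LL)

    # Every subject-level family is updated twice per sweep: an adaptive
    # random-walk move, and an independence move proposed from the
    # hierarchical prior (the prior cancels against the proposal, leaving
    # only the mixture-likelihood ratio).  The independence move is what
    # keeps parameters of currently-unfavoured sub-models well mixed.

    def upd_eta_t(c, independent):
        sel = cond_sel[c]
        cur = eta_t[:, sel]
        if independent:
            prop = tm[c] + sg_te[:, c:c + 1] * rng.standard_normal(cur.shape)
            dpr = 0.0
        else:
            prop = cur + scales["eta_t"].scale[:, sel] * rng.standard_normal(cur.shape)
            dpr = (_mcmc.norm_logpdf(prop, tm[c], sg_te[:, c:c + 1])
                   - _mcmc.norm_logpdf(cur, tm[c], sg_te[:, c:c + 1]))
        llp = _mcmc.iso_loglik(packs_c[c], prop, np.exp(lbe[:, sel, 0]))
        d_ll = llp - LL[:, sel, 0]
        acc, ap = _mcmc.metropolis_accept(rng, mix_delta(0, d_ll) + dpr)
        eta_t[:, sel] = np.where(acc, prop, cur)
        LL[:, sel, 0] = np.where(acc, llp, LL[:, sel, 0])
        LLs[...] = subj_ll(LL)
        if adapting and not independent:
            s = scales["eta_t"].log_s[:, sel]
            gamma = 1.0 / (1.0 + it) ** 0.6
            scales["eta_t"].log_s[:, sel] = np.clip(
                s + gamma * (ap - scales["eta_t"].TARGET), -12, 4)

    def upd_eta_i(independent):
        if independent:
            prop = mu_ei[:, None] + sg_ei[:, None] * rng.standard_normal((C, N))
            dpr = 0.0
        else:
            prop = eta_i + scales["eta_i"].scale * rng.standard_normal((C, N))
            dpr = (_mcmc.norm_logpdf(prop, mu_ei[:, None], sg_ei[:, None])
                   - _mcmc.norm_logpdf(eta_i, mu_ei[:, None], sg_ei[:, None]))
        llp = ll_iso_full(prop, np.exp(lbe[..., 2]))
        d_g = llp - LL[..., 2]
        d_subj = d_g.reshape(C, N, NC).sum(axis=2)
        acc, ap = _mcmc.metropolis_accept(rng, mix_delta(2, d_subj) + dpr)
        eta_i[...] = np.where(acc, prop, eta_i)
        accg = np.repeat(acc, NC, axis=1)
        LL[..., 2] = np.where(accg, llp, LL[..., 2])
        LLs[...] = subj_ll(LL)
        if adapting and not independent:
            scales["eta_i"].adapt(ap, it)

    _pt_blocks = (("lag", lag, -np.inf, 0.0), ("lal", lal, -np.inf, 0.0),
                  ("llam", llam, 0.0, _LOG5))

    def upd_pt(name, independent):
        arr, lo, hi = next((a, l, h) for n, a, l, h in _pt_blocks if n == name)
        mu_h, sg_h = {"lag": (mu_ag, sg_ag), "lal": (mu_al, sg_al),
                      "llam": (mu_lm, sg_lm)}[name]
        if independent:
            prop_eff = _mcmc.sample_truncnorm(
                rng, np.broadcast_to(mu_h[:, None], (C, N)),
                np.broadcast_to(sg_h[:, None], (C, N)), lo, hi)
            dpr, inb = 0.0, True
        else:
            prop = arr + scales[name].scale * rng.standard_normal((C, N))
            inb = (prop > lo) & (prop < hi)
            prop_eff = np.where(inb, prop, arr)
            dpr = (_mcmc.norm_logpdf(prop_eff, mu_h[:, None], sg_h[:, None])
                   - _mcmc.norm_logpdf(arr, mu_h[:, None], sg_h[:, None]))
        pa_g = np.exp(prop_eff if name == "lag" else lag)
        pa_l = np.exp(prop_eff if name == "lal" else lal)
        pa_m = np.exp(prop_eff if name == "llam" else llam)
        llp = ll_pt_full(pa_g, pa_l, pa_m, np.exp(lbe[..., 1]))
        d_g = llp - LL[..., 1]
        d_subj = d_g.reshape(C, N, NC).sum(axis=2)
        log_acc = np.where(inb, mix_delta(1, d_subj) + dpr, -np.inf)
        acc, ap = _mcmc.metropolis_accept(rng, log_acc)
        arr[...] = np.where(acc, prop_eff, arr)
        accg = np.repeat(acc, NC, axis=1)
        LL[..., 1] = np.where(accg, llp, LL[..., 1])
        LLs[...] = subj_ll(LL)
        if adapting and not independent:
            scales[name].adapt(ap, it)

    def upd_lbe(c, m, independent):
        sel = cond_sel[c]
        cur = lbe[:, sel, m]
        if independent:
            prop = (mu_b[:, c:c + 1, m]
                    + sg_b[:, c:c + 1, m] * rng.standard_normal(cur.shape))
            dpr = 0.0
        else:
            prop = cur + (scales["lbe"].scale[:, sel, m]
                          * rng.standard_normal(cur.shape))
            dpr = (_mcmc.norm_logpdf(prop, mu_b[:, c:c + 1, m], sg_b[:, c:c + 1, m])
                   - _mcmc.norm_logpdf(cur, mu_b[:, c:c + 1, m], sg_b[:, c:c + 1, m]))
        if m == 0:
            llp = _mcmc.iso_loglik(packs_c[c], eta_t[:, sel], np.exp(prop))
        elif m == 1:
            sub = subj_of[sel]
            llp = _mcmc.pt_loglik(packs_c[c], np.exp(lag)[:, sub],
                                  np.exp(lal)[:, sub], np.exp(llam)[:, sub],
                                  np.exp(prop))
        else:
            llp = _mcmc.iso_loglik(packs_c[c], eta_i[:, subj_of[sel]],
                                   np.exp(prop))
        d_ll = llp - LL[:, sel, m]
        acc, ap = _mcmc.metropolis_accept(rng, mix_delta(m, d_ll) + dpr)
        lbe[:, sel, m] = np.where(acc, prop, cur)
        LL[:, sel, m] = np.where(acc, llp, LL[:, sel, m])
        LLs[...] = subj_ll(LL)
        if adapting and not independent:
            s = scales["lbe"].log_s[:, sel, m]
            gamma = 1.0 / (1.0 + it) ** 0.6
            scales["lbe"].log_s[:, sel, m] = np.clip(
                s + gamma * (ap - scales["lbe"].TARGET), -12, 4)

    for it in range(cfg.n_burnin + D):
        adapting = it < cfg.n_burnin

        for independent in (False, True):
            for c in range(NC):
                upd_eta_t(c, independent)
            upd_eta_i(independent)
            for name in ("lag", "lal", "llam"):
                upd_pt(name, independent)
            for c in range(NC):
                for m in range(3):
                    upd_lbe(c, m, independent)

        # ---- indicator Gibbs step
        if not marginal:
            p = LLs - logsumexp(LLs, axis=-1, keepdims=True)
            u = rng.random((C, N, 1))
            z[...] = (np.exp(p).cumsum(axis=-1) < u).sum(axis=-1)

        # ---- hyperparameters
        sg_te = _sigma_mh_2d(rng, eta_t, tm[pack.cond], pack.cond, NC,
                             sg_te, spec.sigma_eta_time_bounds,
                             hscales["sg_te"], it, adapting)
        mu_ei = _gibbs_mean_1d(rng, eta_i, sg_ei, spec.mu_eta_iso_bounds)
        sg_ei = _sigma_mh_1d(rng, eta_i, mu_ei, sg_ei,
                             spec.sigma_eta_iso_bounds, hscales["sg_ei"],
                             it, adapting)
        mu_ag, sg_ag = _trunc_hyper_mh(rng, lag, mu_ag, sg_ag,
                                       spec.mu_log_alpha_bounds,
                                       spec.sigma_log_alpha_bounds,
                                       -np.inf, 0.0, hscales["mu_ag"],
                                       hscales["sg_ag"], it, adapting)
        mu_al, sg_al = _trunc_hyper_mh(rng, lal, mu_al, sg_al,
                                       spec.mu_log_alpha_bounds,
                                       spec.sigma_log_alpha_bounds,
                                       -np.inf, 0.0, hscales["mu_al"],
                                       hscales["sg_al"], it, adapting)
        mu_lm, sg_lm = _trunc_hyper_mh(rng, llam, mu_lm, sg_lm,
                                       spec.mu_log_lambda_bounds,
                                       spec.sigma_log_lambda_bounds,
                                       0.0, _LOG5, hscales["mu_lm"],
                                       hscales["sg_lm"], it, adapting)
        lbe_sc = lbe.reshape(C, N, NC, 3)
        m_b = lbe_sc.mean(axis=1)  # (C, NC, 3)
        mu_b = _mcmc.sample_truncnorm(rng, m_b, sg_b / np.sqrt(N),
                                      spec.mu_beta_bounds[0], spec.mu_beta_bounds[1])
        sg_b = _sigma_mh_nd(rng, lbe_sc, mu_b, sg_b, spec.sigma_beta_bounds,
                            hscales["sg_b"], it, adapting)

        if not adapting:
            k = it - cfg.n_burnin
            rec["eta_time"][:, k] = eta_t
            rec["eta_iso"][:, k] = eta_i
            rec["log_alpha_gain"][:, k] = lag
            rec["log_alpha_loss"][:, k] = lal
            rec["log_lambda"][:, k] = llam
            rec["log_beta"][:, k] = lbe
            rec["sigma_eta_time"][:, k] = sg_te
            rec["mu_eta_iso"][:, k] = mu_ei
            rec["sigma_eta_iso"][:, k] = sg_ei
            rec["mu_log_alpha_gain"][:, k] = mu_ag
            rec["sigma_log_alpha_gain"][:, k] = sg_ag
            rec["mu_log_alpha_loss"][:, k] = mu_al
            rec["sigma_log_alpha_loss"][:, k] = sg_al
            rec["mu_log_lambda"][:, k] = mu_lm
            rec["sigma_log_lambda"][:, k] = sg_lm
            rec["mu_log_beta"][:, k] = mu_b
            rec["sigma_log_beta"][:, k] = sg_b
            if marginal:
                p = LLs - logsumexp(LLs, axis=-1, keepdims=True)
                resp[:, k] = np.exp(p)
            else:
                resp[:, k] = np.eye(3)[z]

    # cache-consistency guard (cheap relative to the run)
    fresh = np.empty_like(LL)
    fresh[..., 0] = _mcmc.iso_loglik(pack, eta_t, np.exp(lbe[..., 0]))
    fresh[..., 1] = ll_pt_full(np.exp(lag), np.exp(lal), np.exp(llam),
                               np.exp(lbe[..., 1]))
    fresh[..., 2] = ll_iso_full(eta_i, np.exp(lbe[..., 2]))
    if not np.allclose(fresh, LL, rtol=1e-8, atol=1e-8):
        raise RuntimeError("internal error: likelihood cache diverged")
    return rec, resp


def _gibbs_mean_1d(rng, values, sigma, bounds):
    m = values.mean(axis=1)
    sd = sigma / np.sqrt(values.shape[1])
    return _mcmc.sample_truncnorm(rng, m, sd, bounds[0], bounds[1])


def _sigma_logp(values_sq_sum, n, sigma):
    return -n * np.log(sigma) - values_sq_sum / (2 * sigma ** 2)


def _sigma_mh_1d(rng, values, mu, sigma, bounds, scales, it, adapting):
    sq = ((values - mu[:, None]) ** 2).sum(axis=1)
    return _sigma_mh_core(rng, sq, values.shape[1], sigma, bounds, scales,
                          it, adapting)


def _sigma_mh_2d(rng, values, means, cond, NC, sigma, bounds, scales, it,
                 adapting):
    C = values.shape[0]
    sq = np.zeros((C, NC))
    np.add.at(sq, (slice(None), cond), (values - means) ** 2)
    n = np.bincount(cond, minlength=NC).astype(float)
    return _sigma_mh_core(rng, sq, n, sigma, bounds, scales, it, adapting)


def _sigma_mh_nd(rng, values_sc, mu, sigma, bounds, scales, it, adapting):
    sq = ((values_sc - mu[:, None]) ** 2).sum(axis=1)
    return _sigma_mh_core(rng, sq, values_sc.shape[1], sigma, bounds, scales,
                          it, adapting)


def _sigma_mh_core(rng, sq, n, sigma, bounds, scales, it, adapting):
    lsig = np.log(sigma)
    prop = lsig + scales.scale * rng.standard_normal(sigma.shape)
    sig_p = np.exp(prop)
    log_acc = (_sigma_logp(sq, n, sig_p) - _sigma_logp(sq, n, sigma)
               + (prop - lsig))
    log_acc = np.where((sig_p > bounds[0]) & (sig_p < bounds[1]), log_acc,
                       -np.inf)
    acc, ap = _mcmc.metropolis_accept(rng, log_acc)
    if adapting:
        scales.adapt(ap, it)
    return np.where(acc, sig_p, sigma)


def _trunc_log_norm_const(mu, sigma, lo, hi):
    """log P(lo < X < hi) for X ~ Normal(mu, sigma)."""
    hi_t = ndtr((hi - mu) / sigma) if np.isfinite(hi) else 1.0
    lo_t = ndtr((lo - mu) / sigma) if np.isfinite(lo) else 0.0
    return np.log(np.clip(hi_t - lo_t, 1e-300, None))


def _trunc_hyper_mh(rng, values, mu, sigma, mu_bounds, sigma_bounds, lo, hi,
                    mu_scales, sg_scales, it, adapting):
    """MH on the hypers of a truncated-normal subject-level prior.

    The per-subject normalization 1/P(lo < X < hi) depends on (mu, sigma),
    so plain conjugate updates do not apply.
    """
    n = values.shape[1]

    def logp(m, s):
        quad = -0.5 * ((values - m[:, None]) / s[:, None]) ** 2
        return (quad.sum(axis=1) - n * np.log(s)
                - n * _trunc_log_norm_const(m, s, lo, hi))

    prop = mu + mu_scales.scale * rng.standard_normal(mu.shape)
    log_acc = np.where((prop > mu_bounds[0]) & (prop < mu_bounds[1]),
                       logp(prop, sigma) - logp(mu, sigma), -np.inf)
    acc, ap = _mcmc.metropolis_accept(rng, log_acc)
    mu = np.where(acc, prop, mu)
    if adapting:
        mu_scales.adapt(ap, it)

    lsig = np.log(sigma)
    propl = lsig + sg_scales.scale * rng.standard_normal(sigma.shape)
    sig_p = np.exp(propl)
    log_acc = np.where((sig_p > sigma_bounds[0]) & (sig_p < sigma_bounds[1]),
                       logp(mu, sig_p) - logp(mu, sigma) + (propl - lsig),
                       -np.inf)
    acc, ap = _mcmc.metropolis_accept(rng, log_acc)
    sigma = np.where(acc, sig_p, sigma)
    if adapting:
        sg_scales.adapt(ap, it)
    return mu, sigma


def _hlm_to_idata(rec: dict, resp: np.ndarray, pack: PackedData):
    C, D, G = rec["eta_time"].shape
    N, NC = pack.n_subjects, len(pack.conditions)
    cond_names = [d.value for d in pack.conditions]
    model_names = [m.value for m in MODEL_ORDER]

    def by_subj_cond(arr):  # (C, D, G[, M]) -> (C, D, N, NC[, M])
        return arr.reshape(C, D, N, NC, *arr.shape[3:])

    posterior = {
        "eta_time": by_subj_cond(rec["eta_time"]),
        "eta_iso": rec["eta_iso"],
        "log_alpha_gain": rec["log_alpha_gain"],
        "log_alpha_loss": rec["log_alpha_loss"],
        "log_lambda": rec["log_lambda"],
        "log_beta": by_subj_cond(rec["log_beta"]),
        "sigma_eta_time": rec["sigma_eta_time"],
        "mu_eta_iso": rec["mu_eta_iso"],
        "sigma_eta_iso": rec["sigma_eta_iso"],
        "mu_log_alpha_gain": rec["mu_log_alpha_gain"],
        "sigma_log_alpha_gain": rec["sigma_log_alpha_gain"],
        "mu_log_alpha_loss": rec["mu_log_alpha_loss"],
        "sigma_log_alpha_loss": rec["sigma_log_alpha_loss"],
        "mu_log_lambda": rec["mu_log_lambda"],
        "sigma_log_lambda": rec["sigma_log_lambda"],
        "mu_log_beta": rec["mu_log_beta"],
        "sigma_log_beta": rec["sigma_log_beta"],
        "model_prob": resp,
    }
    dims = {
        "eta_time": ["subject", "condition"],
        "eta_iso": ["subject"],
        "log_alpha_gain": ["subject"],
        "log_alpha_loss": ["subject"],
        "log_lambda": ["subject"],
        "log_beta": ["subject", "condition", "model"],
        "sigma_eta_time": ["condition"],
        "mu_log_beta": ["condition", "model"],
        "sigma_log_beta": ["condition", "model"],
        "model_prob": ["subject", "model"],
    }
    coords = {"subject": pack.subject_ids, "condition": cond_names,
              "model": model_names}
    return az.from_dict(posterior=posterior, coords=coords, dims=dims)


# ---------------------------------------------------------------------------
# random-effects Bayesian model selection


def bms(log_evidence: np.ndarray, alpha0: float = 1.0, n_mc: int = 100_000,
        seed: int = 0, max_iter: int = 500, tol: float = 1e-10) -> BmsResult:
    """Random-effects model selection from subject-wise log-evidence.

    Variational estimation of the Dirichlet posterior over population model
    frequencies, Monte-Carlo exceedance probabilities, the Bayes omnibus
    risk (via the free-energy comparison against the equal-frequency null),
    and protected exceedance probabilities.
    """
    lme = np.asarray(log_evidence, float)
    if lme.ndim != 2 or lme.shape[1] < 2:
        raise ValueError("need a (subjects, models >= 2) log-evidence array")
    n, K = lme.shape
    a0 = np.full(K, float(alpha0))
    alpha = a0.copy()
    for _ in range(max_iter):
        e_log_r = digamma(alpha) - digamma(alpha.sum())
        lu = lme + e_log_r
        u = np.exp(lu - logsumexp(lu, axis=1, keepdims=True))
        alpha_new = a0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    e_log_r = digamma(alpha) - digamma(alpha.sum())
    lu = lme + e_log_r
    u = np.exp(lu - logsumexp(lu, axis=1, keepdims=True))

    a_sum = alpha.sum()
    freq = alpha / a_sum
    freq_sd = np.sqrt(alpha * (a_sum - alpha) / (a_sum ** 2 * (a_sum + 1)))

    # free energy of the random-effects model vs the equal-frequency null
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = np.where(u > 0, u * np.log(u), 0.0).sum()
    f1 = ((u * (lme + e_log_r)).sum() - ent
          + gammaln(a0.sum()) - gammaln(a0).sum()
          - gammaln(a_sum) + gammaln(alpha).sum()
          + ((a0 - alpha) * e_log_r).sum())
    f0 = logsumexp(lme - np.log(K), axis=1).sum()
    bor = float(1.0 / (1.0 + np.exp(f1 - f0)))

    rng = np.random.default_rng(seed)
    r = rng.dirichlet(alpha, size=n_mc)
    ep = np.bincount(np.argmax(r, axis=1), minlength=K) / n_mc
    pxp = ep * (1.0 - bor) + bor / K
    return BmsResult(alpha=alpha, frequencies=freq, frequencies_sd=freq_sd,
                     exceedance=ep, bor=bor, pxp=pxp,
                     models=tuple(m.value for m in MODEL_ORDER) if K == 3
                     else tuple(f"model{i}" for i in range(K)))


def _log_evidence_proxy(mp: ModelPosterior) -> np.ndarray:
    """Log of per-subject posterior model probabilities (uniform model prior)."""
    p = np.clip(mp.model_probs.to_numpy(float), 1e-12, None)
    return np.log(p)


def estimated_model_frequencies(mp: ModelPosterior) -> pd.DataFrame:
    """Posterior mean and SD of the population model frequencies."""
    if len(mp.model_probs) < 1:
        raise ValueError("need at least one subject")
    res = bms(_log_evidence_proxy(mp))
    return pd.DataFrame({"frequency": res.frequencies, "sd": res.frequencies_sd},
                        index=list(mp.model_probs.columns))


def protected_exceedance_probability(mp: ModelPosterior, n_mc: int = 100_000,
                                     seed: int = 0) -> BmsResult:
    """Protected exceedance probabilities for the cohort's model frequencies."""
    if len(mp.model_probs) < 2:
        raise ValueError("need at least two subjects")
    return bms(_log_evidence_proxy(mp), n_mc=n_mc, seed=seed)
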