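"""Hierarchical Bayesian estimation of the dynamic-specific isoelastic model.

Subject-level risk aversion eta and log choice-sensitivity log(beta) are
normally distributed around condition-specific group means, with uniform
hyperpriors on the group means and standard deviations; choices follow the
logistic rule on expected isoelastic-utility differences (a Bernoulli
likelihood per trial).  Sampling is adaptive Metropolis-within-Gibbs over
all chains simultaneously; posteriors are returned as an arviz
InferenceData with split-R-hat / ESS diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from . import _mcmc
from ._mcmc import PackedData, pack_dataset
from .io import validate_choice_dataset

__all__ = [
    "Hyperpriors",
    "McmcConfig",
    "PosteriorSamples",
    "fit_isoelastic_hierarchical",
    "map_estimate",
    "rhat",
]


@dataclass(frozen=True)
class Hyperpriors:
    """Uniform hyperprior bounds for the group-level parameters.

    Group means of log(beta) span roughly beta in (0.1, 30); group standard
    deviations are bounded away from zero to exclude degenerate groups.
    """

    mu_beta_bounds: tuple[float, float] = (-2.3, 3.4)
    sigma_beta_bounds: tuple[float, float] = (0.01, 1.6)
    mu_eta_bounds: tuple[float, float] = (-2.5, 2.5)
    sigma_eta_bounds: tuple[float, float] = (0.01, 1.6)

    def __post_init__(self) -> None:
        for lo, hi in (self.mu_beta_bounds, self.sigma_beta_bounds,
                       self.mu_eta_bounds, self.sigma_eta_bounds):
            if not lo < hi:
                raise ValueError("hyperprior bounds must satisfy lower < upper")


@dataclass(frozen=True)
class McmcConfig:
    """Sampler configuration.

    The default is a desk-scale preset (4 chains x 2000 retained draws after
    500 adaptation/burn-in sweeps).  ``paper_scale`` mirrors the original
    sampling effort (10 chains x 10^4 draws).
    """

    n_chains: int = 4
    n_draws: int = 2000
    n_burnin: int = 500
    seed: int | None = None
    rhat_interval: tuple[float, float] = (1.0, 1.01)

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("at least 2 chains are required for diagnostics")
        if self.n_burnin < 1:
            raise ValueError("burn-in must be >= 1")

    @classmethod
    def paper_scale(cls, seed: int | None = None) -> "McmcConfig":
        return cls(n_chains=10, n_draws=10_000, n_burnin=1000, seed=seed)

    @classmethod
    def desk(cls, seed: int | None = None) -> "McmcConfig":
        return cls(seed=seed)


@dataclass
class PosteriorSamples:
    """Posterior draws plus convergence diagnostics."""

    idata: az.InferenceData
    rhat_interval: tuple[float, float] = (1.0, 1.01)

    def rhat(self) -> pd.Series:
        """Split-R-hat per scalar parameter, indexed 'name[coord,...]'."""
        ds = az.rhat(self.idata)
        return _flatten_dataset(ds)

    def ess(self) -> pd.Series:
        return _flatten_dataset(az.ess(self.idata))

    def flagged_parameters(self) -> pd.Series:
        """Parameters whose R-hat falls outside the target interval."""
        r = self.rhat()
        lo, hi = self.rhat_interval
        return r[(r < lo) | (r > hi)]

    def summary(self) -> pd.DataFrame:
        return az.summary(self.idata, hdi_prob=0.95)

    def draws(self, parameter: str, **sel) -> np.ndarray:
        """Pooled draws of a parameter, chains merged, optional coord selection."""
        da = self.idata.posterior[parameter]
        if sel:
            da = da.sel(**sel)
        return da.values.reshape(-1)

    def credible_interval(self, parameter: str, prob: float = 0.95, **sel
                          ) -> tuple[float, float]:
        d = self.draws(parameter, **sel)
        a = (1 - prob) / 2
        return (float(np.quantile(d, a)), float(np.quantile(d, 1 - a)))

    def to_netcdf(self, path) -> None:
        self.idata.to_netcdf(str(path))

    def summary_csv(self, path) -> None:
        df = self.summary()
        df.index.name = "parameter"
        df.to_csv(path)


def _flatten_dataset(ds) -> pd.Series:
    out = {}
    for name, da in ds.items():
        if da.ndim == 0:
            out[name] = float(da.values)
        else:
            stacked = da.stack(_flat=da.dims)
            for coord, val in zip(stacked["_flat"].values, stacked.values):
                coord = coord if isinstance(coord, tuple) else (coord,)
                out[f"{name}[{','.join(str(c) for c in coord)}]"] = float(val)
    return pd.Series(out)


def fit_isoelastic_hierarchical(
    data: pd.DataFrame,
    hyper: Hyperpriors | None = None,
    cfg: McmcConfig | None = None,
    replicate_col: str | None = None,
) -> PosteriorSamples:
    """Sample the joint posterior of the dynamic-specific isoelastic model.

    ``data`` is a tidy choice dataset (see :mod:`ergochoice.io`).  With
    ``replicate_col`` the group level is estimated separately per
    (replicate, condition) — used to fit many independent synthetic cohorts
    in a single sampler run.
    """
    hyper = hyper or Hyperpriors()
    cfg = cfg or McmcConfig()
    validate_choice_dataset(data)
    pack = pack_dataset(data, replicate_col=replicate_col)
    if pack.n_subjects < 2:
        raise ValueError("hierarchical estimation requires at least 2 subjects")
    if len(pack.conditions) < 2:
        warnings.warn("only one condition present; fitting in single-condition mode")
    one_sided = pack.one_sided_groups()
    if one_sided:
        warnings.warn(
            f"{len(one_sided)} subject-condition block(s) have all-one-sided "
            "choices; sensitivity is weakly identified there"
        )
    draws = _sample_iso(pack, hyper, cfg)
    idata = _iso_to_idata(draws, pack)
    return PosteriorSamples(idata=idata, rhat_interval=cfg.rhat_interval)


def _sample_iso(pack: PackedData, hyper: Hyperpriors, cfg: McmcConfig) -> dict:
    rng = np.random.default_rng(cfg.seed)
    C, G, H = cfg.n_chains, pack.n_groups, pack.n_hyper
    hix = pack.hyper  # (G,)

    mu_e = rng.uniform(*hyper.mu_eta_bounds, (C, H))
    sg_e = rng.uniform(0.1, 1.0, (C, H))
    mu_b = rng.uniform(*hyper.mu_beta_bounds, (C, H))
    sg_b = rng.uniform(0.1, 1.0, (C, H))
    eta = mu_e[:, hix] + sg_e[:, hix] * rng.standard_normal((C, G))
    lbe = mu_b[:, hix] + sg_b[:, hix] * rng.standard_normal((C, G))

    ll = _mcmc.iso_loglik(pack, eta, np.exp(lbe))
    s_eta = _mcmc.AdaptiveScale((C, G))
    s_lbe = _mcmc.AdaptiveScale((C, G))
    s_sge = _mcmc.AdaptiveScale((C, H), init=0.2)
    s_sgb = _mcmc.AdaptiveScale((C, H), init=0.2)
    s_tre = _mcmc.AdaptiveScale((C, H), init=0.2)
    s_trb = _mcmc.AdaptiveScale((C, H), init=0.2)

    n_keep = cfg.n_draws
    out = {
        "eta": np.empty((C, n_keep, G)),
        "log_beta": np.empty((C, n_keep, G)),
        "mu_eta": np.empty((C, n_keep, H)),
        "sigma_eta": np.empty((C, n_keep, H)),
        "mu_log_beta": np.empty((C, n_keep, H)),
        "sigma_log_beta": np.empty((C, n_keep, H)),
    }
    counts = np.bincount(hix, minlength=H).astype(float)  # subjects per hyper-group

    for it in range(cfg.n_burnin + n_keep):
        adapting = it < cfg.n_burnin

        # subject-level eta (elementwise random walk)
        prop = eta + s_eta.scale * rng.standard_normal((C, G))
        llp = _mcmc.iso_loglik(pack, prop, np.exp(lbe))
        dpr = (_mcmc.norm_logpdf(prop, mu_e[:, hix], sg_e[:, hix])
               - _mcmc.norm_logpdf(eta, mu_e[:, hix], sg_e[:, hix]))
        acc, ap = _mcmc.metropolis_accept(rng, (llp - ll) + dpr)
        eta = np.where(acc, prop, eta)
        ll = np.where(acc, llp, ll)
        if adapting:
            s_eta.adapt(ap, it)

        # subject-level log(beta)
        prop = lbe + s_lbe.scale * rng.standard_normal((C, G))
        llp = _mcmc.iso_loglik(pack, eta, np.exp(prop))
        dpr = (_mcmc.norm_logpdf(prop, mu_b[:, hix], sg_b[:, hix])
               - _mcmc.norm_logpdf(lbe, mu_b[:, hix], sg_b[:, hix]))
        acc, ap = _mcmc.metropolis_accept(rng, (llp - ll) + dpr)
        lbe = np.where(acc, prop, lbe)
        ll = np.where(acc, llp, ll)
        if adapting:
            s_lbe.adapt(ap, it)

        # group means: truncated-normal Gibbs given subject values
        mu_e = _gibbs_group_mean(rng, eta, hix, H, counts, sg_e,
                                 hyper.mu_eta_bounds)
        mu_b = _gibbs_group_mean(rng, lbe, hix, H, counts, sg_b,
                                 hyper.mu_beta_bounds)

        # group standard deviations: log-scale Metropolis under uniform priors
        sg_e = _mh_group_sigma(rng, eta, hix, H, mu_e, sg_e,
                               hyper.sigma_eta_bounds, s_sge, it, adapting)
        sg_b = _mh_group_sigma(rng, lbe, hix, H, mu_b, sg_b,
                               hyper.sigma_beta_bounds, s_sgb, it, adapting)

        # joint translation of (group mean, all subject values): decouples
        # the funnel at small group dispersion, where componentwise moves
        # creep.  The subject-level prior and the uniform hyperprior cancel,
        # leaving only the likelihood ratio per hyper-group.
        delta = s_tre.scale * rng.standard_normal((C, H))
        prop = eta + delta[:, hix]
        llp = _mcmc.iso_loglik(pack, prop, np.exp(lbe))
        d_grp = _group_sums(llp - ll, hix, H)
        mu_p = mu_e + delta
        inb = (mu_p > hyper.mu_eta_bounds[0]) & (mu_p < hyper.mu_eta_bounds[1])
        acc, ap = _mcmc.metropolis_accept(rng, np.where(inb, d_grp, -np.inf))
        eta = np.where(acc[:, hix], prop, eta)
        ll = np.where(acc[:, hix], llp, ll)
        mu_e = np.where(acc, mu_p, mu_e)
        if adapting:
            s_tre.adapt(ap, it)

        delta = s_trb.scale * rng.standard_normal((C, H))
        prop = lbe + delta[:, hix]
        llp = _mcmc.iso_loglik(pack, eta, np.exp(prop))
        d_grp = _group_sums(llp - ll, hix, H)
        mu_p = mu_b + delta
        inb = (mu_p > hyper.mu_beta_bounds[0]) & (mu_p < hyper.mu_beta_bounds[1])
        acc, ap = _mcmc.metropolis_accept(rng, np.where(inb, d_grp, -np.inf))
        lbe = np.where(acc[:, hix], prop, lbe)
        ll = np.where(acc[:, hix], llp, ll)
        mu_b = np.where(acc, mu_p, mu_b)
        if adapting:
            s_trb.adapt(ap, it)

        if not adapting:
            k = it - cfg.n_burnin
            out["eta"][:, k] = eta
            out["log_beta"][:, k] = lbe
            out["mu_eta"][:, k] = mu_e
            out["sigma_eta"][:, k] = sg_e
            out["mu_log_beta"][:, k] = mu_b
            out["sigma_log_beta"][:, k] = sg_b
    return out


def _group_sums(values: np.ndarray, hix: np.ndarray, H: int) -> np.ndarray:
    """Sum subject-level values per hyper-group: (C, G) -> (C, H)."""
    C = values.shape[0]
    out = np.zeros((C, H))
    np.add.at(out, (slice(None), hix), values)
    return out


def _gibbs_group_mean(rng, values, hix, H, counts, sigma, bounds):
    m = _group_sums(values, hix, H) / counts
    sd = sigma / np.sqrt(counts)
    return _mcmc.sample_truncnorm(rng, m, sd, bounds[0], bounds[1])


def _mh_group_sigma(rng, values, hix, H, mu, sigma, bounds, scales, it, adapting):
    lsig = np.log(sigma)
    prop = lsig + scales.scale * rng.standard_normal(sigma.shape)
    sig_p = np.exp(prop)
    sq = _group_sums((values - mu[:, hix]) ** 2, hix, H)
    counts = np.bincount(hix, minlength=H).astype(float)
    def logp(s):
        return -counts * np.log(s) - sq / (2 * s ** 2)
    # uniform prior on sigma, sampled on the log scale (Jacobian = sigma)
    log_acc = logp(sig_p) - logp(sigma) + (prop - lsig)
    log_acc = np.where((sig_p > bounds[0]) & (sig_p < bounds[1]), log_acc, -np.inf)
    acc, ap = _mcmc.metropolis_accept(rng, log_acc)
    if adapting:
        scales.adapt(ap, it)
    return np.where(acc, sig_p, sigma)


def _iso_to_idata(draws: dict, pack: PackedData) -> az.InferenceData:
    C, D, G = draws["eta"].shape
    S, NC = pack.n_subjects, len(pack.conditions)
    cond_names = [d.value for d in pack.conditions]
    posterior, dims = {}, {}
    for name in ("eta", "log_beta"):
        arr = np.full((C, D, S, NC), np.nan)
        arr[:, :, pack.subj, pack.cond] = draws[name]
        posterior[name] = arr
        dims[name] = ["subject", "condition"]
    hyper_names = ("mu_eta", "sigma_eta", "mu_log_beta", "sigma_log_beta")
    if pack.n_replicates is None:
        coords = {"subject": pack.subject_ids, "condition": cond_names}
        for k in hyper_names:
            posterior[k] = draws[k]
            dims[k] = ["condition"]
    else:
        n_rep = pack.n_replicates
        coords = {"subject": pack.subject_ids, "condition": cond_names,
                  "replicate": list(range(n_rep))}
        for k in hyper_names:
            posterior[k] = draws[k].reshape(C, D, n_rep, NC)
            dims[k] = ["replicate", "condition"]
    return az.from_dict(posterior=posterior, coords=coords, dims=dims)


def map_estimate(samples: "PosteriorSamples | np.ndarray",
                 parameter: str | None = None, min_draws: int = 1000,
                 grid_size: int = 512, **sel) -> float:
    """Posterior mode via Gaussian KDE (Silverman bandwidth) on pooled draws.

    ``samples`` may be a :class:`PosteriorSamples` (with ``parameter`` naming
    the variable and ``sel`` selecting coords; remaining dimensions, e.g.
    subjects, are marginalized by pooling) or a raw array of draws.
    """
    if isinstance(samples, PosteriorSamples):
        if parameter is None:
            raise ValueError("parameter name required with PosteriorSamples input")
        d = samples.draws(parameter, **sel)
    else:
        d = np.asarray(samples, float).reshape(-1)
    d = d[np.isfinite(d)]
    if d.size < min_draws:
        raise ValueError(f"need at least {min_draws} draws for a MAP estimate")
    if np.ptp(d) == 0:
        return float(d[0])
    kde = gaussian_kde(d, bw_method="silverman")
    grid = np.linspace(d.min(), d.max(), grid_size)
    dens = kde(grid)
    # flatness is judged away from the support edges, where any KDE decays
    interior = kde(np.linspace(*np.quantile(d, [0.10, 0.90]), grid_size))
    if interior.min() > 0.9 * interior.max():
        warnings.warn("posterior density is nearly flat; mode is ill-defined")
    return float(grid[np.argmax(dens)])


def rhat(samples: "PosteriorSamples | np.ndarray"):
    """Split-R-hat diagnostic.

    For a :class:`PosteriorSamples`, a Series over all scalar parameters;
    for a raw (chains, draws) array, a single float.
    """
    if isinstance(samples, PosteriorSamples):
        return samples.rhat()
    arr = np.asarray(samples, float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need a (chains, draws) array with >= 2 chains")
    return float(az.rhat(az.from_dict(posterior={"x": arr})).x)
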