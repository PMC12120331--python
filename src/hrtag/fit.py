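"""MCMC fitting, model comparison and convergence diagnostics.

The posterior is sampled with componentwise Gaussian random-walk
Metropolis (Metropolis-within-Gibbs).  Coefficients get wide Normal(0,
sd 100) priors; the change-point gets a uniform prior over the central
range of the governing covariate, constrained so at least ``min_side``
observations fall on each side of any admissible threshold.  Proposals
producing any mu_t <= 0 are rejected, which truncates the prior to the
feasible region of the identity-link Poisson model.

Step sizes adapt during burn-in only (Robbins-Monro toward 0.44
acceptance per component) and are frozen before any draw is retained,
so the retained chains are draws from a fixed Markov kernel.

Model comparison uses the deviance information criterion

    DIC = Dbar + pD,   pD = Dbar - D(theta_bar)

with D(theta) = -2 log L(theta), Dbar the mean deviance over pooled
retained draws, and theta_bar the pooled posterior mean.  Convergence is
checked with the classical (non-split) Gelman-Rubin potential scale
reduction factor.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .model import (
    COLUMN_OF,
    RESPONSE_COLUMN,
    ModelError,
    ModelParams,
    ModelSpec,
    vector_to_params,
)

__all__ = [
    "MCMCConfig",
    "Priors",
    "PosteriorDraws",
    "FitSummary",
    "SamplerError",
    "DiagnosticError",
    "sample_posterior",
    "compute_dic",
    "compute_r2",
    "compute_rhat",
    "summarize_fit",
    "fit_model",
    "select_best",
]

log = logging.getLogger(__name__)


class SamplerError(RuntimeError):
    """Raised when a chain degenerates (e.g. zero acceptance after burn-in)."""


class DiagnosticError(RuntimeError):
    """Raised when a diagnostic is undefined for the given draws/data."""


@dataclass(frozen=True)
class MCMCConfig:
    """Sampling protocol: 3 parallel chains, 10,000 retained draws per
    chain after a 10,000-draw burn-in, by default."""

    n_chains: int = 3
    n_burn: int = 10_000
    n_keep: int = 10_000
    proposal_scales: Mapping[str, float] | None = None
    adapt: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.n_keep < 1 or self.n_burn < 0:
            raise ValueError("MCMC counts must be positive (n_burn may be 0)")


@dataclass(frozen=True)
class Priors:
    """Vague priors: Normal(0, coef_sd) on alpha and all slopes; uniform
    on the threshold over [q10, q90] of the governing covariate, clipped
    so >= min_side observations fall strictly above and at-or-below any
    admissible threshold."""

    coef_sd: float = 100.0
    thresh_bounds: tuple[float, float] | None = None
    min_side: int = 3


@dataclass
class PosteriorDraws:
    """Retained draws: array of shape (n_chains, n_keep, n_params)."""

    draws: np.ndarray
    param_names: list[str]
    spec: ModelSpec
    centers: dict[str, float]
    acceptance: np.ndarray  # (n_chains, n_params) post-burn-in acceptance rates
    thresh_support: tuple[float, float] | None = None

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_keep(self) -> int:
        return self.draws.shape[1]

    def pooled(self) -> np.ndarray:
        """All chains stacked: shape (n_chains * n_keep, n_params)."""
        return self.draws.reshape(-1, self.draws.shape[-1])

    def posterior_mean_params(self) -> ModelParams:
        theta_bar = self.pooled().mean(axis=0)
        return vector_to_params(theta_bar, self.spec, self.centers)

    def to_frame(self) -> pd.DataFrame:
        """Long-format draws with a chain column (for dumping as text)."""
        frames = []
        for c in range(self.n_chains):
            df = pd.DataFrame(self.draws[c], columns=self.param_names)
            df.insert(0, "chain", c)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


@dataclass
class FitSummary:
    """Posterior summary plus model-comparison statistics for one model."""

    spec: ModelSpec
    table: pd.DataFrame  # index: parameter; columns: mean, sd, q2.5, q97.5, rhat
    Dbar: float
    pD: float
    dic: float
    r2: float
    n_obs: int

    @property
    def max_rhat(self) -> float:
        return float(self.table["rhat"].max())


class _Posterior:
    """Vectorized log-posterior for one model spec on one daily table."""

    def __init__(self, spec: ModelSpec, data: pd.DataFrame, priors: Priors):
        if len(data) == 0:
            raise ModelError("cannot fit an empty daily table")
        y = data[RESPONSE_COLUMN].to_numpy(dtype=float)
        if np.any(y < 0) or np.any(y != np.round(y)):
            raise ModelError("response column 'hrm' must contain non-negative integers")
        self.spec = spec
        self.y = y
        self.n = len(y)
        self.gammaln_const = float(gammaln(y + 1.0).sum())
        self.centers = {
            cov: float(data[COLUMN_OF[cov]].mean()) for cov in spec.covariates
        }
        plain = [c for c in spec.covariates if c != spec.modulated]
        self.plain_covs = plain
        self.X_plain = np.column_stack(
            [data[COLUMN_OF[c]].to_numpy(float) - self.centers[c] for c in plain]
        ) if plain else np.empty((self.n, 0))
        self.coef_sd = float(priors.coef_sd)

        self.has_thresh = spec.threshold is not None
        if self.has_thresh:
            self.x_mod = (
                data[COLUMN_OF[spec.modulated]].to_numpy(float)
                - self.centers[spec.modulated]
            )
            self.g = data[COLUMN_OF[spec.governing]].to_numpy(float)
            self.thresh_support = self._thresh_support(priors)
        else:
            self.x_mod = None
            self.g = None
            self.thresh_support = None

        names = spec.parameter_names()
        self.param_names = names
        self.d = len(names)
        # index layout: 0 = alpha; plain betas follow covariate order with
        # the modulated pair (plus, minus) in place; thresh last.
        self.idx_plain = [names.index(f"beta_{c}") for c in plain]
        self.idx_plus = names.index(f"beta_plus_{spec.modulated}") if self.has_thresh else None
        self.idx_minus = names.index(f"beta_minus_{spec.modulated}") if self.has_thresh else None
        self.idx_thresh = names.index("thresh") if self.has_thresh else None
        self.idx_coef = [i for i in range(self.d) if i != self.idx_thresh]

    def _thresh_support(self, priors: Priors) -> tuple[float, float]:
        if priors.thresh_bounds is not None:
            return (float(priors.thresh_bounds[0]), float(priors.thresh_bounds[1]))
        g = np.sort(self.g)
        k = int(priors.min_side)
        if len(g) < 2 * k + 1 or g[k - 1] >= g[-k]:
            raise ModelError(
                "governing covariate has too few distinct values to "
                f"identify a threshold with {k} observations per side"
            )
        lo = max(float(np.quantile(g, 0.10)), float(g[k - 1]))
        hi = min(float(np.quantile(g, 0.90)), float(np.nextafter(g[-k], -np.inf)))
        if not lo < hi:
            lo, hi = float(g[k - 1]), float(np.nextafter(g[-k], -np.inf))
        return (lo, hi)

    def mu(self, theta: np.ndarray) -> np.ndarray:
        if self.idx_plain:
            mu = theta[0] + self.X_plain @ theta[self.idx_plain]
        else:
            mu = np.full(self.n, theta[0])
        if self.has_thresh:
            slope = np.where(
                self.g > theta[self.idx_thresh],
                theta[self.idx_plus],
                theta[self.idx_minus],
            )
            mu = mu + slope * self.x_mod
        return mu

    def log_post(self, theta: np.ndarray) -> float:
        if self.has_thresh:
            t = theta[self.idx_thresh]
            lo, hi = self.thresh_support
            if not (lo <= t <= hi):
                return -math.inf
        mu = self.mu(theta)
        if np.any(mu <= 0.0):
            return -math.inf
        ll = float(self.y @ np.log(mu) - mu.sum()) - self.gammaln_const
        coefs = theta[self.idx_coef]
        lp = -0.5 * float(coefs @ coefs) / (self.coef_sd ** 2)
        return ll + lp

    def log_lik_draws(self, draws: np.ndarray, chunk: int = 4000) -> np.ndarray:
        """Log-likelihood for each row of a (N, d) draw matrix."""
        out = np.empty(len(draws))
        for start in range(0, len(draws), chunk):
            th = draws[start:start + chunk]
            mu = th[:, [0]] + np.zeros((1, self.n))
            if self.idx_plain:
                mu = mu + th[:, self.idx_plain] @ self.X_plain.T
            if self.has_thresh:
                mask = self.g[None, :] > th[:, [self.idx_thresh]]
                slope = np.where(mask, th[:, [self.idx_plus]], th[:, [self.idx_minus]])
                mu = mu + slope * self.x_mod[None, :]
            bad = (mu <= 0).any(axis=1)
            mu = np.where(mu <= 0, 1.0, mu)
            ll = (self.y[None, :] * np.log(mu)).sum(axis=1) - mu.sum(axis=1)
            ll -= self.gammaln_const
            ll[bad] = -np.inf
            out[start:start + chunk] = ll
        return out

    def feasible_fallback(self) -> np.ndarray:
        """An always-feasible point: intercept at the response mean."""
        theta = np.zeros(self.d)
        theta[0] = max(float(self.y.mean()), 1.0)
        if self.has_thresh:
            lo, hi = self.thresh_support
            theta[self.idx_thresh] = 0.5 * (lo + hi)
        return theta

    def moment_init(self) -> np.ndarray:
        """Method-of-moments style start: least squares of y on the
        centered design (threshold pair initialized to a common slope)."""
        cols = [np.ones(self.n)]
        cols += [self.X_plain[:, j] for j in range(self.X_plain.shape[1])]
        if self.has_thresh:
            cols.append(self.x_mod)
        X = np.column_stack(cols)
        coef, *_ = np.linalg.lstsq(X, self.y, rcond=None)
        theta = np.zeros(self.d)
        theta[0] = coef[0]
        for j, idx in enumerate(self.idx_plain):
            theta[idx] = coef[1 + j]
        if self.has_thresh:
            b = coef[-1]
            theta[self.idx_plus] = b
            theta[self.idx_minus] = b
            lo, hi = self.thresh_support
            theta[self.idx_thresh] = float(np.clip(np.median(self.g), lo, hi))
        if not np.isfinite(self.log_post(theta)):
            theta = self.feasible_fallback()
        return theta

    def default_scales(self) -> np.ndarray:
        """Initial proposal sd per component, refined by adaptation."""
        scales = np.full(self.d, 0.1)
        scales[0] = max(0.5, 0.05 * math.sqrt(max(self.y.mean(), 1.0)))
        if self.has_thresh:
            lo, hi = self.thresh_support
            scales[self.idx_thresh] = max(0.05 * (hi - lo), 1e-3)
        return scales


def _run_chain(
    post: _Posterior,
    theta0: np.ndarray,
    scales0: np.ndarray,
    n_burn: int,
    n_keep: int,
    adapt: bool,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    d = post.d
    theta = theta0.copy()
    lp = post.log_post(theta)
    if not np.isfinite(lp):
        theta = post.feasible_fallback()
        lp = post.log_post(theta)
    scales = scales0.copy()
    kept = np.empty((n_keep, d))
    accepts = np.zeros(d)

    batch = 50
    batch_acc = np.zeros(d)
    batch_no = 0
    total = n_burn + n_keep
    noise = rng.standard_normal((total, d))
    logu = np.log(rng.random((total, d)))

    for it in range(total):
        burning = it < n_burn
        for j in range(d):
            prop = theta.copy()
            prop[j] += scales[j] * noise[it, j]
            lp_prop = post.log_post(prop)
            if logu[it, j] < lp_prop - lp:
                theta = prop
                lp = lp_prop
                if burning:
                    batch_acc[j] += 1
                else:
                    accepts[j] += 1
        if burning and adapt and (it + 1) % batch == 0:
            batch_no += 1
            rate = batch_acc / batch
            scales *= np.exp((rate - 0.44) / math.sqrt(batch_no))
            batch_acc[:] = 0
        if not burning:
            kept[it - n_burn] = theta
    return kept, accepts / n_keep


def sample_posterior(
    spec: ModelSpec,
    data: pd.DataFrame,
    mcmc: MCMCConfig | None = None,
    priors: Priors | None = None,
) -> PosteriorDraws:
    """Draw from the posterior of ``spec`` on the daily table ``data``.

    Covariates are mean-centered internally (``centers`` recorded on the
    returned draws); the threshold applies to the uncentered governing
    covariate, so its draws are in natural units.  Reproducible given
    ``mcmc.seed``.
    """
    mcmc = mcmc or MCMCConfig()
    priors = priors or Priors()
    post = _Posterior(spec, data, priors)

    base = post.moment_init()
    scales = post.default_scales()
    if mcmc.proposal_scales:
        for name, s in mcmc.proposal_scales.items():
            if name in post.param_names:
                scales[post.param_names.index(name)] = float(s)

    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.n_chains)
    chains = []
    acc = []
    for c in range(mcmc.n_chains):
        rng = np.random.default_rng(seeds[c])
        # overdispersed start around the moment estimate
        theta0 = base + rng.standard_normal(post.d) * (np.abs(base) * 0.2 + 1.0)
        if post.has_thresh:
            lo, hi = post.thresh_support
            theta0[post.idx_thresh] = rng.uniform(lo, hi)
        for _ in range(30):
            if np.isfinite(post.log_post(theta0)):
                break
            theta0 = base + 0.5 * (theta0 - base)
        else:
            theta0 = base
        kept, rates = _run_chain(
            post, theta0, scales, mcmc.n_burn, mcmc.n_keep, mcmc.adapt, rng
        )
        if np.any(rates == 0.0):
            dead = [post.param_names[j] for j in np.flatnonzero(rates == 0.0)]
            raise SamplerError(
                f"chain {c} accepted no moves for parameter(s) {dead} "
                f"after burn-in (scales={scales.tolist()})"
            )
        chains.append(kept)
        acc.append(rates)

    return PosteriorDraws(
        draws=np.stack(chains),
        param_names=post.param_names,
        spec=spec,
        centers=post.centers,
        acceptance=np.stack(acc),
        thresh_support=post.thresh_support,
    )


def compute_dic(
    draws: PosteriorDraws, spec: ModelSpec, data: pd.DataFrame
) -> tuple[float, float, float]:
    """Deviance information criterion: returns (Dbar, pD, DIC).

    Dbar averages D = -2 log L over all pooled retained draws; pD is
    Dbar minus the deviance at the pooled posterior mean.
    """
    post = _Posterior(spec, data, Priors())
    pooled = draws.pooled()
    if len(pooled) == 0:
        raise DiagnosticError("no draws")
    dev = -2.0 * post.log_lik_draws(pooled)
    if not np.all(np.isfinite(dev)):
        raise DiagnosticError("infinite deviance among retained draws")
    dbar = float(dev.mean())
    theta_bar = pooled.mean(axis=0)
    ll_bar = post.log_lik_draws(theta_bar[None, :])[0]
    if not np.isfinite(ll_bar):
        raise DiagnosticError(
            "posterior-mean parameters give mu <= 0; DIC undefined"
        )
    d_hat = -2.0 * float(ll_bar)
    pd_ = dbar - d_hat
    if pd_ < 0:
        log.warning("negative pD (%.3f) for model %s", pd_, spec.label)
    return dbar, pd_, dbar + pd_


def compute_r2(draws: PosteriorDraws, spec: ModelSpec, data: pd.DataFrame) -> float:
    """Classical R^2 = 1 - SSE/SST at posterior-mean predictions.

    May be negative when the model predicts worse than the response mean.
    """
    from .model import evaluate_mu

    y = data[RESPONSE_COLUMN].to_numpy(dtype=float)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        raise DiagnosticError("R^2 undefined: response is constant")
    mu_hat = np.asarray(evaluate_mu(draws.posterior_mean_params(), spec, data))
    sse = float(np.sum((y - mu_hat) ** 2))
    return 1.0 - sse / sst


def compute_rhat(draws: PosteriorDraws | np.ndarray) -> np.ndarray:
    """Classical Gelman-Rubin potential scale reduction per parameter.

    Accepts a PosteriorDraws or a raw (n_chains, n_iter, n_params) array;
    requires >= 2 chains of equal length.
    """
    arr = draws.draws if isinstance(draws, PosteriorDraws) else np.asarray(draws)
    if arr.ndim != 3:
        raise DiagnosticError("expected draws of shape (chains, iterations, params)")
    m, n, _ = arr.shape
    if m < 2:
        raise DiagnosticError("R-hat requires at least 2 chains")
    chain_means = arr.mean(axis=1)                      # (m, d)
    chain_vars = arr.var(axis=1, ddof=1)                # (m, d)
    w = chain_vars.mean(axis=0)
    b = n * chain_means.var(axis=0, ddof=1)
    var_hat = (n - 1) / n * w + b / n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_hat / w)
    return np.where(w == 0, 1.0, rhat)


def summarize_fit(
    draws: PosteriorDraws, spec: ModelSpec, data: pd.DataFrame
) -> FitSummary:
    """Posterior mean/sd/95% interval per parameter, R-hat, DIC, pD, R^2."""
    pooled = draws.pooled()
    table = pd.DataFrame(
        {
            "mean": pooled.mean(axis=0),
            "sd": pooled.std(axis=0, ddof=1),
            "q2.5": np.quantile(pooled, 0.025, axis=0),
            "q97.5": np.quantile(pooled, 0.975, axis=0),
            "rhat": compute_rhat(draws) if draws.n_chains >= 2 else np.nan,
        },
        index=pd.Index(draws.param_names, name="parameter"),
    )
    dbar, pd_, dic = compute_dic(draws, spec, data)
    r2 = compute_r2(draws, spec, data)
    return FitSummary(
        spec=spec, table=table, Dbar=dbar, pD=pd_, dic=dic, r2=r2, n_obs=len(data)
    )


def fit_model(
    spec: ModelSpec,
    data: pd.DataFrame,
    mcmc: MCMCConfig | None = None,
    priors: Priors | None = None,
) -> tuple[PosteriorDraws, FitSummary]:
    """Convenience: sample then summarize."""
    draws = sample_posterior(spec, data, mcmc=mcmc, priors=priors)
    return draws, summarize_fit(draws, spec, data)


def select_best(
    fits: Sequence[tuple[ModelSpec, FitSummary]],
    competitor_window: float = 5.0,
) -> pd.DataFrame:
    """Rank fitted models by DIC (smaller is better).

    Returns a table with one row per model: label, n_params, pD, DIC,
    dDIC relative to the best, R^2 and a flag for competitors within
    ``competitor_window`` DIC points of the best.  Ties are broken by
    fewer parameters, then by input order.  Models whose DIC is
    undefined (NaN) are excluded with a warning.
    """
    if len(fits) == 0:
        raise ValueError("select_best requires at least one fit")
    rows = []
    for order, (spec, summ) in enumerate(fits):
        if not math.isfinite(summ.dic):
            log.warning("excluding model %s: undefined DIC", spec.label)
            continue
        rows.append(
            {
                "model": spec.label,
                "n_params": spec.n_parameters,
                "pD": summ.pD,
                "DIC": summ.dic,
                "R2": summ.r2,
                "_order": order,
            }
        )
    if not rows:
        raise ValueError("no model has a defined DIC")
    ranking = pd.DataFrame(rows).sort_values(
        ["DIC", "n_params", "_order"], kind="mergesort"
    )
    best = ranking["DIC"].iloc[0]
    ranking["dDIC"] = ranking["DIC"] - best
    ranking["competitor"] = ranking["dDIC"] <= competitor_window
    return ranking.drop(columns="_order").reset_index(drop=True)
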