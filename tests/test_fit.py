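"""Sampler correctness (against quadrature oracles), diagnostics,
information criteria and model ranking."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

from hrtag import (
    MCMCConfig,
    ModelParams,
    ModelSpec,
    PosteriorDraws,
    ThresholdSpec,
    compute_dic,
    compute_r2,
    compute_rhat,
    fit_model,
    sample_posterior,
    select_best,
    summarize_fit,
)
from hrtag.fit import DiagnosticError, FitSummary, Priors, _Posterior
from hrtag.model import RESPONSE_COLUMN


def _daily(hrm, tf=None, tpm=None):
    n = len(hrm)
    return pd.DataFrame(
        {
            "hrm": np.asarray(hrm, int),
            "tf": np.zeros(n) if tf is None else np.asarray(tf, float),
            "tpm": np.full(n, 23.0) if tpm is None else np.asarray(tpm, float),
            "tpiq": np.full(n, 0.5),
            "acm": np.full(n, 30.0),
        }
    )


def _grid_posterior_1d(y, prior_sd=100.0):
    """Quadrature oracle for the intercept-only model's posterior."""
    alpha = np.linspace(1e-6, 120, 240_001)
    loglik = np.sum(
        y[:, None] * np.log(alpha)[None, :] - alpha[None, :], axis=0
    ) - gammaln(np.asarray(y) + 1.0).sum()
    logp = loglik - 0.5 * alpha**2 / prior_sd**2
    w = np.exp(logp - logp.max())
    w /= np.trapezoid(w, alpha)
    mean = np.trapezoid(w * alpha, alpha)
    var = np.trapezoid(w * (alpha - mean) ** 2, alpha)
    return mean, math.sqrt(var)


def _grid_posterior_2d(y, x, prior_sd=100.0):
    """Quadrature oracle for the intercept + one-slope model (centered x)."""
    xc = x - x.mean()
    alpha = np.linspace(20, 90, 701)
    beta = np.linspace(-8, 8, 801)
    A, B = np.meshgrid(alpha, beta, indexing="ij")
    mu = A[..., None] + B[..., None] * xc[None, None, :]
    bad = (mu <= 0).any(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ll = np.where(
            bad, -np.inf, (y[None, None, :] * np.log(np.abs(mu)) - mu).sum(axis=-1)
        )
    logp = ll - 0.5 * (A**2 + B**2) / prior_sd**2
    w = np.exp(logp - logp.max())
    da = alpha[1] - alpha[0]
    db = beta[1] - beta[0]
    w /= w.sum() * da * db
    mean_a = (w * A).sum() * da * db
    mean_b = (w * B).sum() * da * db
    sd_a = math.sqrt((w * (A - mean_a) ** 2).sum() * da * db)
    sd_b = math.sqrt((w * (B - mean_b) ** 2).sum() * da * db)
    return (mean_a, sd_a), (mean_b, sd_b)


class TestSamplerAgainstQuadrature:
    def test_intercept_only_matches_grid(self):
        y = np.array([46, 55, 49, 52, 50])
        grid_mean, grid_sd = _grid_posterior_1d(y)
        draws = sample_posterior(
            ModelSpec(),
            _daily(y),
            MCMCConfig(n_chains=3, n_burn=5_000, n_keep=30_000, seed=42),
        )
        pooled = draws.pooled()[:, 0]
        assert abs(pooled.mean() - grid_mean) < 0.02 * grid_sd
        assert abs(pooled.std(ddof=1) - grid_sd) < 0.02 * grid_sd

    def test_one_slope_model_matches_grid(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 20, 8)
        y = rng.poisson(45 + 1.5 * (x - x.mean()))
        (ga, sa), (gb, sb) = _grid_posterior_2d(y.astype(float), x)
        draws = sample_posterior(
            ModelSpec(("TF",)),
            _daily(y, tf=x),
            MCMCConfig(n_chains=3, n_burn=5_000, n_keep=30_000, seed=43),
        )
        pooled = draws.pooled()
        assert abs(pooled[:, 0].mean() - ga) < 0.02 * sa
        assert abs(pooled[:, 1].mean() - gb) < 0.02 * sb
        assert abs(pooled[:, 0].std(ddof=1) - sa) < 0.02 * sa
        assert abs(pooled[:, 1].std(ddof=1) - sb) < 0.02 * sb


def test_mle_agrees_with_identity_link_glm(tiny_daily):
    """Independent cross-check: with a flat enough prior the posterior
    mean approaches the identity-link Poisson GLM MLE from statsmodels,
    and the likelihood implementations agree at the MLE point."""
    import statsmodels.api as sm

    from hrtag.model import log_likelihood

    data = tiny_daily
    X = sm.add_constant(
        np.column_stack(
            [data["tf"] - data["tf"].mean(), data["tpm"] - data["tpm"].mean()]
        )
    )
    res = sm.GLM(
        data["hrm"].to_numpy(),
        X,
        family=sm.families.Poisson(link=sm.families.links.Identity()),
    ).fit()
    spec = ModelSpec(("TF", "TPm"))
    params = ModelParams(
        alpha=res.params[0],
        betas={"TF": res.params[1], "TPm": res.params[2]},
        centers={"TF": data["tf"].mean(), "TPm": data["tpm"].mean()},
    )
    assert log_likelihood(params, spec, data) == pytest.approx(res.llf, rel=1e-10)

    draws = sample_posterior(
        spec, data, MCMCConfig(n_chains=3, n_burn=4_000, n_keep=8_000, seed=3)
    )
    pooled = pooled_means = draws.pooled().mean(axis=0)
    for est, mle, se in zip(pooled_means, res.params, res.bse):
        assert abs(est - mle) < 3 * se


def test_null_slope_credible_interval_covers_zero():
    """Data generated with no feeding effect: the 95% interval for the
    feeding slope should cover zero in nearly all replicates."""
    rng = np.random.default_rng(14)
    covered = 0
    n_reps = 6
    for rep in range(n_reps):
        tf = rng.uniform(0, 20, 40)
        y = rng.poisson(50.0, 40)
        draws = sample_posterior(
            ModelSpec(("TF",)),
            _daily(y, tf=tf),
            MCMCConfig(n_chains=2, n_burn=2_000, n_keep=2_000, seed=100 + rep),
        )
        lo, hi = np.quantile(draws.pooled()[:, 1], [0.025, 0.975])
        covered += lo <= 0.0 <= hi
    assert covered >= 5


class TestDic:
    def test_degenerate_chain_has_zero_pd(self):
        data = _daily([50, 52, 48])
        theta = np.array([[[50.0]] * 4] * 2)  # 2 chains x 4 identical draws
        draws = PosteriorDraws(
            draws=theta,
            param_names=["alpha"],
            spec=ModelSpec(),
            centers={},
            acceptance=np.ones((2, 1)),
        )
        dbar, pd_, dic = compute_dic(draws, ModelSpec(), data)
        assert pd_ == pytest.approx(0.0, abs=1e-9)
        assert dic == pytest.approx(dbar)

    def test_two_draw_hand_computation(self):
        # 2-obs dataset, intercept-only, two draws: everything by hand
        y = np.array([3, 5])
        data = _daily(y)
        a1, a2 = 4.0, 5.0

        def loglik(a):
            return sum(
                yi * math.log(a) - a - math.lgamma(yi + 1) for yi in y
            )

        d1, d2 = -2 * loglik(a1), -2 * loglik(a2)
        dbar_hand = (d1 + d2) / 2
        pd_hand = dbar_hand - (-2 * loglik((a1 + a2) / 2))
        theta = np.array([[[a1], [a2]]])  # 1 chain, 2 draws
        draws = PosteriorDraws(
            draws=theta,
            param_names=["alpha"],
            spec=ModelSpec(),
            centers={},
            acceptance=np.ones((1, 1)),
        )
        dbar, pd_, dic = compute_dic(draws, ModelSpec(), data)
        assert dbar == pytest.approx(dbar_hand)
        assert pd_ == pytest.approx(pd_hand)
        assert dic == pytest.approx(dbar_hand + pd_hand)

    def test_infeasible_posterior_mean_is_error(self):
        data = _daily([3, 5])
        theta = np.array([[[10.0], [-12.0]]])  # mean is -1 -> mu <= 0
        draws = PosteriorDraws(
            draws=theta,
            param_names=["alpha"],
            spec=ModelSpec(),
            centers={},
            acceptance=np.ones((1, 1)),
        )
        with pytest.raises(DiagnosticError):
            compute_dic(draws, ModelSpec(), data)


class TestR2:
    def _draws(self, alphas):
        return PosteriorDraws(
            draws=np.asarray(alphas, float).reshape(1, -1, 1),
            param_names=["alpha"],
            spec=ModelSpec(),
            centers={},
            acceptance=np.ones((1, 1)),
        )

    def test_perfect_and_mean_predictions(self):
        # predictions exactly equal to the observations -> R^2 = 1
        data = _daily([10, 20], tf=[0.0, 10.0])
        spec = ModelSpec(("TF",))
        draws = PosteriorDraws(
            draws=np.array([[[15.0, 1.0]]]),
            param_names=["alpha", "beta_TF"],
            spec=spec,
            centers={"TF": 5.0},
            acceptance=np.ones((1, 2)),
        )
        assert compute_r2(draws, spec, data) == pytest.approx(1.0)
        # mu_hat equal to the response mean for all t -> R^2 = 0
        data = _daily([40, 60])
        assert compute_r2(self._draws([50.0]), ModelSpec(), data) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        # observations {10, 20}, predictions {12, 18}: 1 - 8/50 = 0.84
        data = _daily([10, 20], tf=[0.0, 10.0])
        spec = ModelSpec(("TF",))
        theta = np.array([[[15.0, 0.6]]])  # alpha 15, slope 0.6 on centered tf
        draws = PosteriorDraws(
            draws=theta,
            param_names=["alpha", "beta_TF"],
            spec=spec,
            centers={"TF": 5.0},
            acceptance=np.ones((1, 2)),
        )
        assert compute_r2(draws, spec, data) == pytest.approx(0.84)

    def test_constant_response_undefined(self):
        with pytest.raises(DiagnosticError):
            compute_r2(self._draws([50.0]), ModelSpec(), _daily([50, 50]))


class TestRhat:
    def test_duplicated_chains_give_unity(self):
        rng = np.random.default_rng(0)
        chain = rng.normal(size=(5_000, 2))
        draws = np.stack([chain, chain, chain])
        np.testing.assert_allclose(compute_rhat(draws), 1.0, atol=1e-3)

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        c0 = rng.normal(0.0, 1.0, size=(2_000, 1))
        c1 = rng.normal(100.0, 1.0, size=(2_000, 1))
        rhat = compute_rhat(np.stack([c0, c1]))
        # hand closed form: W ~= 1, B ~= n * (100/sqrt(2))^2 * 2 / 1
        assert rhat[0] > 10

    def test_well_mixed_sampling_converges(self):
        y = np.array([46, 55, 49, 52, 50])
        draws = sample_posterior(
            ModelSpec(), _daily(y), MCMCConfig(n_chains=3, n_burn=2_000, n_keep=4_000, seed=5)
        )
        assert np.all(compute_rhat(draws) < 1.1)

    def test_single_chain_rejected(self):
        with pytest.raises(DiagnosticError):
            compute_rhat(np.zeros((1, 100, 2)))


class TestSelectBest:
    def _fit(self, label_covs, dic, r2=0.5, thresh=False):
        spec = ModelSpec(
            label_covs,
            ThresholdSpec(label_covs[0], "TPm") if thresh else None,
        )
        table = pd.DataFrame(
            {"mean": [50.0], "sd": [1.0], "q2.5": [48.0], "q97.5": [52.0],
             "rhat": [1.0]},
            index=["alpha"],
        )
        return spec, FitSummary(
            spec=spec, table=table, Dbar=dic - 2, pD=2.0, dic=dic, r2=r2, n_obs=80
        )

    def test_best_has_zero_delta_and_competitors_flagged(self):
        fits = [
            self._fit(("TF",), 100.0),
            self._fit(("TPm",), 101.0),
            self._fit(("ACm",), 120.0),
        ]
        ranking = select_best(fits)
        assert ranking["dDIC"].iloc[0] == 0.0
        assert ranking["model"].tolist()[:2] == ["alpha + TF", "alpha + TPm"]
        assert ranking["competitor"].tolist() == [True, True, False]

    def test_ties_broken_by_parsimony(self):
        simple = self._fit(("TF",), 100.0)
        complex_ = self._fit(("TF", "TPm"), 100.0)
        ranking = select_best([complex_, simple])
        assert ranking["model"].iloc[0] == "alpha + TF"

    def test_undefined_dic_excluded(self):
        good = self._fit(("TF",), 100.0)
        bad = self._fit(("TPm",), float("nan"))
        ranking = select_best([bad, good])
        assert len(ranking) == 1
        with pytest.raises(ValueError):
            select_best([bad])


def test_model_selection_recovers_generating_structure():
    """Fitting a candidate set to data simulated from the change-point
    model: DIC ranks the generating structure first in the majority of
    seeded replicates."""
    from dataclasses import replace

    from hrtag import spec_from_label
    from hrtag.synthetic import (
        BEST_MODEL_SPEC,
        DeploymentConfig,
        generate_covariates,
        generate_hr_series,
    )

    candidates = [
        BEST_MODEL_SPEC,
        spec_from_label("alpha + TF + TPm"),
        spec_from_label("alpha + TF"),
        spec_from_label("alpha"),
    ]
    mcmc = MCMCConfig(n_chains=2, n_burn=1_500, n_keep=1_500)
    wins = 0
    n_reps = 3
    for rep in range(n_reps):
        config = DeploymentConfig(seed=500 + rep)
        cov = generate_covariates(config)
        hrm = generate_hr_series(cov, seed=500 + rep)
        data = cov.assign(hrm=hrm.to_numpy())
        fits = [
            fit_model(s, data, replace(mcmc, seed=rep * 10 + k))[1]
            for k, s in enumerate(candidates)
        ]
        ranking = select_best(list(zip(candidates, fits)))
        wins += ranking["model"].iloc[0] == BEST_MODEL_SPEC.label
    assert wins > n_reps / 2


class TestSamplerMechanics:
    def test_retained_draws_all_feasible_and_likelihood_finite(self, tiny_daily):
        from hrtag.model import log_likelihood, vector_to_params

        spec = ModelSpec(("TF", "TPm"), ThresholdSpec("TF", "TPm"))
        draws = sample_posterior(
            spec, tiny_daily, MCMCConfig(n_chains=2, n_burn=1_000, n_keep=1_000, seed=0)
        )
        pooled = draws.pooled()
        for theta in pooled[:: max(1, len(pooled) // 100)]:
            ll = log_likelihood(
                vector_to_params(theta, spec, draws.centers), spec, tiny_daily
            )
            assert math.isfinite(ll)

    def test_threshold_draws_stay_in_support(self, tiny_daily):
        spec = ModelSpec(("TF", "TPm"), ThresholdSpec("TF", "TPm"))
        draws = sample_posterior(
            spec, tiny_daily, MCMCConfig(n_chains=2, n_burn=1_000, n_keep=1_000, seed=1)
        )
        lo, hi = draws.thresh_support
        t = draws.pooled()[:, draws.param_names.index("thresh")]
        assert t.min() >= lo and t.max() <= hi
        # at least 3 observations on each side of any admissible threshold
        g = tiny_daily["tpm"].to_numpy()
        assert (g > hi).sum() >= 3 and (g <= lo).sum() >= 3

    def test_seeded_reproducibility(self, tiny_daily):
        mcmc = MCMCConfig(n_chains=2, n_burn=500, n_keep=500, seed=7)
        a = sample_posterior(ModelSpec(("TF",)), tiny_daily, mcmc)
        b = sample_posterior(ModelSpec(("TF",)), tiny_daily, mcmc)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_summary_dic_identity_and_shapes(self, tiny_daily):
        spec = ModelSpec(("TF", "TPm"))
        _, summary = fit_model(
            spec, tiny_daily, MCMCConfig(n_chains=2, n_burn=1_000, n_keep=1_000, seed=2)
        )
        assert summary.dic == pytest.approx(summary.Dbar + summary.pD)
        assert list(summary.table.index) == spec.parameter_names()
        assert summary.n_obs == len(tiny_daily)
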