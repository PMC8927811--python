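"""Sampler, log-posterior and convergence-diagnostic tests."""

import numpy as np
import pytest
from scipy import stats

from pronref import _glmm, _hmc
from pronref.data import apply_coding_filters
from pronref.diagnostics import check_convergence
from pronref.draws import GroupDraws, PosteriorDraws
from pronref.models import (JointModel, McmcConfig, NextMentionModel,
                            ProductionModel)
from pronref.simulate import DesignSpec, TrueParameters, simulate_experiment

from conftest import make_synthetic_draws


def _toy_spec(seed=0):
    """Small two-factor Bernoulli + categorical model for gradient checks."""
    rng = np.random.default_rng(seed)
    n = 25
    subj = rng.integers(0, 4, n)
    item = rng.integers(0, 3, n)
    vt = rng.choice([-1.0, 1.0], n)
    ref = rng.choice([-1.0, 1.0], n)
    pred_b = _glmm.Predictor(
        Xf=np.column_stack([np.ones(n), vt]),
        terms=[_glmm.GroupTerm(0, np.array([0, 2]),
                               np.column_stack([np.ones(n), vt]), subj),
               _glmm.GroupTerm(1, np.array([0]), np.ones((n, 1)), item)])
    pred_pp = _glmm.Predictor(
        Xf=np.column_stack([np.ones(n), ref]),
        terms=[_glmm.GroupTerm(0, np.array([1]), ref[:, None], subj),
               _glmm.GroupTerm(1, np.array([0, 1]),
                               np.column_stack([vt, ref]), item)])
    pred_ot = _glmm.Predictor(
        Xf=rng.standard_normal((n, 2)),
        terms=[_glmm.GroupTerm(0, np.array([0, 1, 2]),
                               rng.standard_normal((n, 3)), subj)])
    return _glmm.ModelSpec(
        fixed_names=("a", "b"), fixed_priors=("logistic", "normal"),
        factors=[_glmm.GroupFactor("participant", 4, ("f1", "f2", "f3")),
                 _glmm.GroupFactor("item", 3, ("g1", "g2"))],
        blocks=[_glmm.BernoulliBlock(y=rng.integers(0, 2, n).astype(float),
                                     pred=pred_b),
                _glmm.CategoricalBlock(y=rng.integers(0, 3, n),
                                       pred_pp=pred_pp, pred_other=pred_ot)])


class TestLogPosterior:
    def test_gradient_matches_finite_differences(self):
        spec = _toy_spec()
        rng = np.random.default_rng(1)
        for trial in range(3):
            q = rng.standard_normal(spec.dim) * 0.6
            lp, g = _glmm.logp_grad(spec, q)
            assert np.isfinite(lp)
            eps = 1e-6
            num = np.empty_like(q)
            for i in range(q.size):
                qp, qm = q.copy(), q.copy()
                qp[i] += eps
                qm[i] -= eps
                num[i] = (_glmm.logp_grad(spec, qp)[0]
                          - _glmm.logp_grad(spec, qm)[0]) / (2 * eps)
            assert np.abs(g - num).max() / np.abs(num).max() < 1e-6

    @pytest.mark.parametrize("k", [1, 2, 3, 5, 10])
    def test_correlation_transform_is_valid_cholesky(self, k):
        rng = np.random.default_rng(k)
        y = rng.standard_normal(k * (k - 1) // 2)
        L = _glmm.chol_from_unconstrained(y, k)
        R = L @ L.T
        assert np.allclose(np.diag(R), 1.0)
        assert np.allclose(R, R.T)
        assert np.linalg.eigvalsh(R).min() > 0
        assert np.allclose(_glmm.chol_from_unconstrained(np.zeros_like(y), k),
                           np.eye(k))

    def test_logistic_prior_is_uniform_on_probability_scale(self):
        """Sampling the Bernoulli intercept's prior and pushing the draws
        through the inverse logit must give a uniform: the Beta(1,1) prior is
        implemented as the standard-logistic density by change of variables."""
        def lg(q):
            return float(q[0] - 2 * np.logaddexp(0, q[0])), \
                np.array([1 - 2 / (1 + np.exp(-q[0]))])

        rng = np.random.default_rng(0)
        res = _hmc.sample_chain(lg, np.zeros(1), 300, 4000, rng,
                                target_accept=0.9)
        p = 1 / (1 + np.exp(-res.draws[:, 0]))
        assert stats.kstest(p, "uniform").pvalue > 0.01


class TestSampler:
    def test_gaussian_moments(self):
        sd = np.array([0.2, 1.0, 3.0])

        def lg(q):
            return float(-0.5 * np.sum((q / sd) ** 2)), -q / sd ** 2

        rng = np.random.default_rng(4)
        res = _hmc.sample_chain(lg, np.zeros(3), 400, 3000, rng)
        assert res.divergent.sum() == 0
        assert np.abs(res.draws.mean(0) / sd).max() < 0.1
        assert np.abs(res.draws.std(0) / sd - 1).max() < 0.1

    def test_same_rng_reproduces_chain(self):
        def lg(q):
            return float(-0.5 * q @ q), -q

        a = _hmc.sample_chain(lg, np.zeros(2), 50, 50,
                              np.random.default_rng(7))
        b = _hmc.sample_chain(lg, np.zeros(2), 50, 50,
                              np.random.default_rng(7))
        assert np.array_equal(a.draws, b.draws)

    def test_nonfinite_start_rejected(self):
        def lg(q):
            return float("-inf"), q

        with pytest.raises(ValueError, match="non-finite"):
            _hmc.sample_chain(lg, np.zeros(2), 10, 10,
                              np.random.default_rng(0))


class TestModelContracts:
    def test_mcmc_config_validation(self):
        with pytest.raises(ValueError, match="warmup"):
            McmcConfig(n_iterations=100, n_warmup=100)
        with pytest.raises(ValueError, match="chains"):
            McmcConfig(n_chains=1)
        assert McmcConfig().n_post_warmup == 3000

    def test_unknown_ablation_rejected(self, tiny_fit):
        with pytest.raises(ValueError, match="ablation"):
            JointModel(tiny_fit["free"], ablation="drop_everything")

    def test_ablations_change_the_parameter_roster(self, tiny_fit):
        free = tiny_fit["free"]
        full = JointModel(free)
        no_prior = JointModel(free, ablation="drop_vtype_prior")
        no_lik = JointModel(free, ablation="drop_vtype_likelihood")
        assert "beta_vtype_NP1" not in no_prior.spec.fixed_names
        assert "beta_vtype_NP1" in no_lik.spec.fixed_names
        assert "beta_vtype_PP" not in no_lik.spec.fixed_names
        assert no_prior.spec.dim < full.spec.dim
        assert "vtype" not in no_prior.spec.factors[0].family_names
        assert "PP_int" not in no_lik.spec.factors[0].family_names

    def test_single_referent_level_flagged_and_fits(self):
        tp = TrueParameters()
        df, _ = simulate_experiment(tp, DesignSpec(6, 3), rng_seed=2)
        filt, _ = apply_coding_filters(df)
        free = filt[filt["prompt"] == "free"].copy()
        free["ref"] = -1
        free["referent_raw"] = "NP2"
        m = NextMentionModel(free)
        res = m.fit(McmcConfig(n_chains=2, n_iterations=200, n_warmup=100,
                               seed=0, max_depth=6))
        assert any("separation" in f for f in res.draws.sampler_info["flags"])
        # all-NP2 outcomes push the intercept's posterior mass negative
        assert res.draws.stacked("alpha_NP1").mean() < 0

    def test_missing_form_category_flagged_and_fits(self):
        tp = TrueParameters()
        df, _ = simulate_experiment(tp, DesignSpec(6, 3), rng_seed=3)
        filt, _ = apply_coding_filters(df)
        free = filt[filt["prompt"] == "free"].copy()
        free.loc[free["form"] == "other", "form"] = "PP"
        m = ProductionModel(free)
        res = m.fit(McmcConfig(n_chains=2, n_iterations=200, n_warmup=100,
                               seed=0, max_depth=6))
        assert any("other" in f for f in res.draws.sampler_info["flags"])
        assert np.isfinite(res.draws.stacked("alpha_other")).all()

    def test_separate_and_joint_fits_agree(self, tiny_fit):
        """With zero true adjustment correlations, the joint fit's
        next-mention fixed effects match the separate fit's within posterior
        uncertainty (the generating correlations default to identity)."""
        res_sep = tiny_fit["results"]
        joint = JointModel(tiny_fit["free"]).fit(
            McmcConfig(n_chains=2, n_iterations=400, n_warmup=200, seed=2,
                       max_depth=6))
        for name in ("alpha_NP1", "beta_vtype_NP1"):
            a = res_sep.draws.stacked(name)
            b = joint.draws.stacked(name)
            tol = 0.5 * (a.std() + b.std())
            assert abs(a.mean() - b.mean()) < tol

    def test_recovery_single_replicate(self, tiny_fit):
        """Spec'd contract at small scale: the 90% credible intervals of the
        next-mention fixed effects cover the generating values."""
        res = tiny_fit["results"]
        tp = tiny_fit["truth"]["params"]
        summ = res.summary(ci=0.90)
        assert summ.loc["alpha_NP1", "q5"] <= tp.alpha_NP1 \
            <= summ.loc["alpha_NP1", "q95"]
        assert summ.loc["beta_vtype_NP1", "q5"] <= tp.beta_vtype_NP1 \
            <= summ.loc["beta_vtype_NP1", "q95"]
        assert res.convergence.n_divergent == 0


class TestConvergenceReport:
    def test_iid_chains_pass(self):
        draws = make_synthetic_draws(n_chains=4, n_draws=400, seed=1)
        report = check_convergence(draws)
        assert report.n_divergent == 0
        fixed_rows = report.table[report.table.parameter == "alpha_NP1"]
        assert abs(fixed_rows["rhat"].iloc[0] - 1.0) < 0.01
        assert report.ess_floor == pytest.approx(0.1 * 1600)
        assert report.passed

    def test_separated_chains_fail(self):
        draws = make_synthetic_draws(n_chains=2, n_draws=200, seed=2)
        bad = draws.fixed["alpha_NP1"].copy()
        bad[0] = np.random.default_rng(0).normal(0.0, 1.0, bad.shape[1])
        bad[1] = np.random.default_rng(1).normal(5.0, 1.0, bad.shape[1])
        draws.fixed["alpha_NP1"] = bad
        report = check_convergence(draws)
        row = report.table[report.table.parameter == "alpha_NP1"]
        assert row["rhat"].iloc[0] > 1.5
        assert not report.passed

    def test_ess_floor_matches_default_run_size(self):
        """Four chains of 3000 post-warmup draws: the floor is 1200."""
        cfg = McmcConfig()
        total = cfg.n_chains * cfg.n_post_warmup
        assert total == 12000
        draws = make_synthetic_draws(n_chains=4, n_draws=10)
        report = check_convergence(draws)
        assert report.ess_floor == pytest.approx(0.1 * 40)

    def test_single_chain_rejected(self):
        draws = make_synthetic_draws(n_chains=2, n_draws=50)
        for k in draws.fixed:
            draws.fixed[k] = draws.fixed[k][:1]
        for g in draws.groups.values():
            g.effects = g.effects[:1]
            g.sd = g.sd[:1]
            g.chol = g.chol[:1]
        with pytest.raises(ValueError, match="2 chains"):
            check_convergence(draws)

    def test_divergences_fail_the_verdict(self):
        draws = make_synthetic_draws(n_chains=4, n_draws=400, seed=1)
        draws.divergent[0, 0] = True
        assert not check_convergence(draws).passed
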