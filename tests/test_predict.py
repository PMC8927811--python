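import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pronref.predict import (bayes_posterior, expectancy_probability,
                             inv_logit, mirror_posterior,
                             plugin_probability_table,
                             production_conditionals, sample_predictions,
                             softmax)

from conftest import make_synthetic_draws

# posterior-mean production parameters of the form-choice model fitted to
# the accusative/dative continuation data (used as plug-in worked examples)
MIRROR_MEANS_EXP1 = {
    "alpha_PP": 2.57, "alpha_other": -1.74, "beta_ref_PP": 2.24,
    "beta_ref_other": 1.01, "beta_vtype_PP": -0.62, "beta_vtype_other": 1.05,
    "beta_int_PP": 0.24, "beta_int_other": -0.35,
}


class TestSoftmax:
    def test_symmetry(self):
        assert np.allclose(softmax([0.0, 0.0, 0.0]), 1 / 3)

    def test_worked_example_predictors(self):
        # accusative/NP1 linear predictors of the production worked example
        out = softmax([4.43, 0.0, -0.03])
        assert np.round(out, 3).tolist() == [0.977, 0.012, 0.011]

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            softmax([])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-30, 30), min_size=1, max_size=6),
           st.floats(-20, 20))
    def test_shift_invariance_and_simplex(self, scores, shift):
        a = softmax(scores)
        b = softmax([s + shift for s in scores])
        assert np.allclose(a, b, atol=1e-12)
        assert a.sum() == pytest.approx(1.0)
        assert (a > 0).all()


class TestExpectancy:
    def test_logistic_identity_at_zero(self, pron_obs):
        draws = make_synthetic_draws(zero_adjustments=True, fixed_overrides={
            "alpha_NP1": 0.0, "beta_vtype_NP1": 0.0}, seed=3)
        draws.fixed["alpha_NP1"][:] = 0.0
        draws.fixed["beta_vtype_NP1"][:] = 0.0
        pred = expectancy_probability(draws, pron_obs)
        assert np.allclose(pred.probs, 0.5)

    def test_worked_example_value(self):
        # eta = -0.68 + 0.30 = -0.38 in accusative contexts
        assert float(inv_logit(-0.38)) == pytest.approx(0.4061, abs=5e-4)

    def test_same_for_both_prompt_forms(self, synthetic_draws, pron_obs):
        p1 = expectancy_probability(synthetic_draws,
                                    pron_obs.assign(prompt="personal"))
        p2 = expectancy_probability(synthetic_draws,
                                    pron_obs.assign(prompt="demonstrative"))
        assert np.array_equal(p1.probs, p2.probs)

    def test_unseen_levels_deterministic_when_variance_zero(self, pron_obs):
        draws = make_synthetic_draws(zero_adjustments=True, seed=4)
        for g in draws.groups.values():
            g.sd[:] = 1e-12
        unseen = pron_obs.assign(participant_id="pNEW", item_id="iNEW")
        p_seen = expectancy_probability(draws, pron_obs, rng_seed=1)
        p_new = expectancy_probability(draws, unseen, rng_seed=1)
        assert np.allclose(p_seen.probs, p_new.probs, atol=1e-9)


class TestProductionConditionals:
    def test_simplex_per_draw_and_referent(self, synthetic_draws, pron_obs):
        for ref in (1, -1):
            tri = production_conditionals(synthetic_draws, pron_obs, ref)
            assert tri.shape == (synthetic_draws.n_total, len(pron_obs), 3)
            assert np.allclose(tri.sum(axis=-1), 1.0)
            assert (tri > 0).all()

    def test_all_zero_parameters_give_thirds(self, pron_obs):
        draws = make_synthetic_draws(zero_adjustments=True, seed=5)
        for name in draws.fixed:
            draws.fixed[name][:] = 0.0
        tri = production_conditionals(draws, pron_obs, 1)
        assert np.allclose(tri, 1 / 3)

    def test_invalid_referent_rejected(self, synthetic_draws, pron_obs):
        with pytest.raises(ValueError, match="referent"):
            production_conditionals(synthetic_draws, pron_obs, 0)


class TestMirrorAndBayes:
    def test_mirror_hand_value(self):
        # personal-pronoun conditionals in the accusative worked example
        l1, l2 = 0.977, 0.3186
        assert l1 / (l1 + l2) == pytest.approx(0.754, abs=5e-4)

    def test_equal_likelihoods_give_half(self, pron_obs):
        draws = make_synthetic_draws(fixed_overrides={
            "beta_ref_PP": 0.0, "beta_int_PP": 0.0,
            "beta_ref_other": 0.0, "beta_int_other": 0.0}, seed=6)
        for name in ("beta_ref_PP", "beta_int_PP", "beta_ref_other",
                     "beta_int_other"):
            draws.fixed[name][:] = 0.0
        for g in draws.groups.values():
            for fam in ("PP_ref", "PP_int", "other_ref", "other_int"):
                if fam in g.family_names:
                    g.effects[..., g.family_names.index(fam)] = 0.0
        m = mirror_posterior(draws, pron_obs)
        assert np.allclose(m.probs, 0.5, atol=1e-12)
        # ... and the Bayesian posterior then collapses onto the prior
        b = bayes_posterior(draws, pron_obs)
        e = expectancy_probability(draws, pron_obs)
        assert np.allclose(b.probs, e.probs, atol=1e-12)

    def test_bayes_with_uniform_prior_is_mirror(self, synthetic_draws, pron_obs):
        b = bayes_posterior(synthetic_draws, pron_obs, prior=0.5)
        m = mirror_posterior(synthetic_draws, pron_obs)
        assert np.allclose(b.probs, m.probs, atol=1e-12)

    def test_bayes_monotone_in_prior(self, synthetic_draws, pron_obs):
        pis = np.linspace(0.05, 0.95, 7)
        prev = None
        for pi in pis:
            p = bayes_posterior(synthetic_draws, pron_obs, prior=pi).probs
            if prev is not None:
                assert (p > prev).all()
            prev = p

    def test_direct_composition_value(self):
        pi, l1, l2 = 0.25, 0.6, 0.2
        assert l1 * pi / (l1 * pi + l2 * (1 - pi)) == pytest.approx(0.5)

    def test_prompt_form_from_observations(self, synthetic_draws, pron_obs):
        mixed = mirror_posterior(synthetic_draws, pron_obs)
        pp = mirror_posterior(synthetic_draws, pron_obs, prompt_form="PP")
        dp = mirror_posterior(synthetic_draws, pron_obs, prompt_form="DP")
        is_pp = (pron_obs["prompt"] == "personal").to_numpy()
        assert np.allclose(mixed.probs[:, is_pp], pp.probs[:, is_pp])
        assert np.allclose(mixed.probs[:, ~is_pp], dp.probs[:, ~is_pp])


class TestOracleEquivalence:
    def test_vectorized_equals_per_draw_loop(self, pron_obs):
        """Brute-force per-draw scalar arithmetic reproduces the pipeline."""
        draws = make_synthetic_draws(n_chains=2, n_draws=25, seed=8)
        obs = pron_obs.head(5).reset_index(drop=True)
        e = expectancy_probability(draws, obs).probs
        m = mirror_posterior(draws, obs).probs
        b = bayes_posterior(draws, obs).probs
        gp, gi = draws.groups["participant"], draws.groups["item"]
        uf, wf = gp.family_names, gi.family_names
        U = draws.stacked_effects("participant")
        W = draws.stacked_effects("item")
        fx = {k: draws.stacked(k) for k in draws.fixed}
        for s in range(draws.n_total):
            for n in range(len(obs)):
                si = gp.level_index(obs.participant_id[n])
                ii = gi.level_index(obs.item_id[n])
                vt = float(obs.vtype[n])
                u = U[s, si]
                w = W[s, ii]
                eta = (fx["alpha_NP1"][s] + u[uf.index("NP1")]
                       + w[wf.index("NP1")]
                       + vt * (fx["beta_vtype_NP1"][s] + u[uf.index("vtype")]))
                pi = 1 / (1 + np.exp(-eta))
                assert abs(pi - e[s, n]) < 1e-10

                def cond(ref, cat):
                    eta_c = (fx[f"alpha_{cat}"][s] + u[uf.index(cat)]
                             + w[wf.index(cat)]
                             + vt * (fx[f"beta_vtype_{cat}"][s]
                                     + u[uf.index(f"{cat}_vtype")])
                             + ref * (fx[f"beta_ref_{cat}"][s]
                                      + u[uf.index(f"{cat}_ref")]
                                      + w[wf.index(f"{cat}_ref")])
                             + vt * ref * (fx[f"beta_int_{cat}"][s]
                                           + u[uf.index(f"{cat}_int")]
                                           + w[wf.index(f"{cat}_int")]))
                    return eta_c

                form = 0 if obs.prompt[n] == "personal" else 1
                tris = {}
                for ref in (1.0, -1.0):
                    ev = np.exp([cond(ref, "PP"), 0.0, cond(ref, "other")])
                    tris[ref] = ev / ev.sum()
                l1, l2 = tris[1.0][form], tris[-1.0][form]
                assert abs(l1 / (l1 + l2) - m[s, n]) < 1e-10
                post = l1 * pi / (l1 * pi + l2 * (1 - pi))
                assert abs(post - b[s, n]) < 1e-10


class TestPluginTable:
    def test_all_zero_means_give_half(self):
        means = {k: 0.0 for k in ("alpha_NP1", "beta_vtype_NP1")}
        tab = plugin_probability_table(means, "expectancy")
        assert (tab["p_np1"] == 0.5).all()

    def test_missing_parameter_named(self):
        with pytest.raises(KeyError, match="beta_vtype_NP1"):
            plugin_probability_table({"alpha_NP1": 0.0}, "expectancy")

    def test_mirror_table_matches_hand_arithmetic(self):
        tab = plugin_probability_table(MIRROR_MEANS_EXP1, "mirror")
        cell = tab.query("vtype == 1 and prompt_form == 'PP'")
        assert cell["p_np1"].iloc[0] == pytest.approx(0.7541, abs=1e-3)
        assert cell["p_np1_2dp"].iloc[0] == 0.75

    def test_rounding_is_half_up(self):
        from pronref.predict import _round2

        assert _round2(0.005) == 0.01
        assert _round2(0.675) == 0.68


class TestSampledPredictions:
    def test_degenerate_probabilities(self, synthetic_draws, pron_obs):
        pred = expectancy_probability(synthetic_draws, pron_obs)
        pred.probs[:] = 1.0 - 1e-15
        assert sample_predictions(pred).all()

    def test_reproducible_under_seed(self, synthetic_draws, pron_obs):
        pred = mirror_posterior(synthetic_draws, pron_obs)
        assert np.array_equal(sample_predictions(pred, rng_seed=3),
                              sample_predictions(pred, rng_seed=3))

    def test_mean_matches_binomial_oracle(self, pron_obs):
        draws = make_synthetic_draws(n_chains=2, n_draws=5000, seed=9)
        pred = expectancy_probability(draws, pron_obs.head(1))
        pred.probs[:] = 0.3
        sims = sample_predictions(pred, rng_seed=11)
        k = int(sims.sum())
        lo, hi = stats.binom.interval(0.99, sims.size, 0.3)
        assert lo <= k <= hi
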