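"""Interpretation probabilities for held-out pronoun-prompt observations.

Three comprehension accounts map posterior draws to a per-draw probability
that the pronoun refers to NP1:

* expectancy: the next-mention prior alone, ``p = logit^-1(eta)``, identical
  for personal and demonstrative prompts;
* mirror: the normalized production likelihood,
  ``p = L1 / (L1 + L2)`` where ``L1, L2`` are the prompt form's softmax
  conditionals under the two hypothetical referents;
* bayesian: the posterior composition,
  ``p = L1 * pi / (L1 * pi + L2 * (1 - pi))`` with ``pi`` the prior from the
  same draw (shared adjustments, hence the joint model's draws).

Because exactly two morphologically compatible referents partition the event
space, the Expectancy account's normalization over compatible referents is
the identity and is not computed explicitly.

Participants or items never seen during fitting have their adjustments drawn
per posterior draw from that draw's population distribution (its SD and
correlation draws), so uncertainty still propagates; seen labels reuse the
fitted adjustments, which is the default path in this design where all
labels occur in every prompt condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .draws import PosteriorDraws

_PROMPT_TO_FORM = {"personal": "PP", "demonstrative": "DP"}

# probabilities are strictly positive in exact arithmetic (softmax, logistic);
# clip to the open unit interval against floating-point underflow
_P_EPS = 1e-15


def _open_unit(p: np.ndarray) -> np.ndarray:
    return np.clip(p, _P_EPS, 1.0 - _P_EPS)


def softmax(scores) -> np.ndarray:
    """Exponentiate-and-normalize along the last axis, max-stabilized."""
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("softmax of an empty vector")
    if not np.isfinite(s).all():
        raise ValueError("softmax requires finite scores")
    m = s.max(axis=-1, keepdims=True)
    e = np.exp(s - m)
    return e / e.sum(axis=-1, keepdims=True)


def inv_logit(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return np.where(x >= 0, 1.0 / (1.0 + np.exp(-x)),
                    np.exp(x) / (1.0 + np.exp(x)))


@dataclass
class PredictiveDistribution:
    """Per held-out observation, per-draw probabilities that NP1 is meant."""

    obs: pd.DataFrame
    probs: np.ndarray  # (S, N) in (0, 1)
    model: str

    def __post_init__(self):
        if self.probs.ndim != 2 or self.probs.shape[1] != len(self.obs):
            raise ValueError("probs must be draws x observations")
        if not ((self.probs > 0) & (self.probs < 1)).all():
            raise ValueError("predictive probabilities must lie in (0, 1)")

    @property
    def n_draws(self) -> int:
        return self.probs.shape[0]

    def mean_probability(self) -> np.ndarray:
        return self.probs.mean(axis=0)

    def to_long_frame(self, sampled: np.ndarray | None = None) -> pd.DataFrame:
        """One row per draw per observation, carrying the observation key."""
        S, N = self.probs.shape
        out = pd.DataFrame({
            "obs": np.tile(np.arange(N), S),
            "model": self.model,
            "draw": np.repeat(np.arange(S), N),
            "p_np1": self.probs.ravel(),
        })
        for col in ("participant_id", "item_id", "vtype", "prompt"):
            if col in self.obs.columns:
                out[col] = np.tile(self.obs[col].to_numpy(), S)
        if sampled is not None:
            out["pred_np1"] = np.asarray(sampled).ravel()
        return out


def sample_predictions(pred: PredictiveDistribution, rng_seed: int = 0) -> np.ndarray:
    """One Bernoulli draw per posterior draw per observation, (S, N) in {0,1}."""
    rng = np.random.default_rng(rng_seed)
    return (rng.uniform(size=pred.probs.shape) < pred.probs).astype(int)


def _obs_effects(draws: PosteriorDraws, factor: str, labels, rng) -> np.ndarray:
    """Adjustment vectors aligned to observations, (S, N, K).

    Seen labels reuse fitted draws; unseen labels get adjustments sampled per
    draw from the population distribution implied by that draw's SD and
    correlation Cholesky factor.
    """
    g = draws.groups[factor]
    S = draws.n_total
    eff = draws.stacked_effects(factor)          # (S, n_levels, K)
    uniq, inv = np.unique(np.asarray(labels, dtype=object), return_inverse=True)
    out = np.empty((S, len(uniq), g.k))
    known = {lab: i for i, lab in enumerate(g.labels)}
    sd = g.sd.reshape(S, g.k)
    chol = g.chol.reshape(S, g.k, g.k)
    for j, lab in enumerate(uniq):
        if lab in known:
            out[:, j, :] = eff[:, known[lab], :]
        else:
            z = rng.standard_normal((S, g.k))
            out[:, j, :] = np.einsum("skj,sj->sk", chol, z) * sd
    return out[:, inv, :]


def _fixed(draws: PosteriorDraws, name: str) -> np.ndarray:
    """Fixed-effect draws (S, 1); ablated terms contribute zero."""
    return draws.stacked_fixed(name, default=0.0)[:, None]


def _fam(eff: np.ndarray, g, name: str) -> np.ndarray:
    """One adjustment family's draws (S, N); absent families contribute zero."""
    if name in g.family_names:
        return eff[:, :, g.family_names.index(name)]
    return np.zeros(eff.shape[:2])


def _prior_eta(draws, obs, u_eff, w_eff) -> np.ndarray:
    gp = draws.groups["participant"]
    gi = draws.groups["item"]
    vt = obs["vtype"].to_numpy(float)[None, :]
    return (_fixed(draws, "alpha_NP1") + _fam(u_eff, gp, "NP1")
            + _fam(w_eff, gi, "NP1")
            + vt * (_fixed(draws, "beta_vtype_NP1") + _fam(u_eff, gp, "vtype")))


def _production_probs(draws, obs, ref: float, u_eff, w_eff) -> np.ndarray:
    """Softmax conditionals (S, N, 3) over (PP, DP, other) given a referent."""
    gp = draws.groups["participant"]
    gi = draws.groups["item"]
    vt = obs["vtype"].to_numpy(float)[None, :]
    etas = []
    for cat in ("PP", "other"):
        eta = (_fixed(draws, f"alpha_{cat}")
               + _fam(u_eff, gp, cat) + _fam(w_eff, gi, cat)
               + vt * (_fixed(draws, f"beta_vtype_{cat}")
                       + _fam(u_eff, gp, f"{cat}_vtype"))
               + ref * (_fixed(draws, f"beta_ref_{cat}")
                        + _fam(u_eff, gp, f"{cat}_ref")
                        + _fam(w_eff, gi, f"{cat}_ref"))
               + vt * ref * (_fixed(draws, f"beta_int_{cat}")
                             + _fam(u_eff, gp, f"{cat}_int")
                             + _fam(w_eff, gi, f"{cat}_int")))
        etas.append(eta)
    H = np.stack((etas[0], np.zeros_like(etas[0]), etas[1]), axis=-1)
    return softmax(H)


def _effects(draws, obs, rng_seed):
    rng = np.random.default_rng(rng_seed)
    u_eff = _obs_effects(draws, "participant", obs["participant_id"], rng)
    w_eff = _obs_effects(draws, "item", obs["item_id"], rng)
    return u_eff, w_eff


def _form_index(obs, prompt_form) -> np.ndarray:
    if prompt_form is not None:
        if prompt_form not in ("PP", "DP"):
            raise ValueError("prompt_form must be 'PP' or 'DP'")
        forms = np.full(len(obs), prompt_form, dtype=object)
    else:
        forms = obs["prompt"].map(_PROMPT_TO_FORM)
        if forms.isna().any():
            raise ValueError("observations must carry a pronoun prompt")
        forms = forms.to_numpy(dtype=object)
    return np.where(forms == "PP", 0, 1)


def expectancy_probability(draws: PosteriorDraws, obs: pd.DataFrame,
                           rng_seed: int = 0) -> PredictiveDistribution:
    """Next-mention prior per draw; the prompt's form plays no role."""
    u_eff, w_eff = _effects(draws, obs, rng_seed)
    p = _open_unit(inv_logit(_prior_eta(draws, obs, u_eff, w_eff)))
    return PredictiveDistribution(obs=obs, probs=p, model="expectancy")


def production_conditionals(draws: PosteriorDraws, obs: pd.DataFrame,
                            hypothetical_referent: int,
                            rng_seed: int = 0) -> np.ndarray:
    """P(form | referent) triples over (PP, DP, other), shape (S, N, 3)."""
    if hypothetical_referent not in (1, -1):
        raise ValueError("hypothetical_referent must be +1 (NP1) or -1 (NP2)")
    u_eff, w_eff = _effects(draws, obs, rng_seed)
    return _production_probs(draws, obs, float(hypothetical_referent),
                             u_eff, w_eff)


def mirror_posterior(draws: PosteriorDraws, obs: pd.DataFrame,
                     prompt_form: str | None = None,
                     rng_seed: int = 0) -> PredictiveDistribution:
    """Normalized production likelihood, per draw: L1 / (L1 + L2)."""
    u_eff, w_eff = _effects(draws, obs, rng_seed)
    fidx = _form_index(obs, prompt_form)
    cols = np.arange(len(obs))
    L1 = _production_probs(draws, obs, 1.0, u_eff, w_eff)[:, cols, fidx]
    L2 = _production_probs(draws, obs, -1.0, u_eff, w_eff)[:, cols, fidx]
    assert (L1 > 0).all() and (L2 > 0).all()
    return PredictiveDistribution(obs=obs, probs=_open_unit(L1 / (L1 + L2)),
                                  model="mirror")


def bayes_posterior(draws: PosteriorDraws, obs: pd.DataFrame,
                    prompt_form: str | None = None, rng_seed: int = 0,
                    prior=None) -> PredictiveDistribution:
    """Posterior composition L1*pi / (L1*pi + L2*(1-pi)), per draw.

    ``prior`` overrides the model's next-mention prior pi with a fixed value
    or array; with ``prior=0.5`` the result equals the mirror posterior.
    """
    u_eff, w_eff = _effects(draws, obs, rng_seed)
    fidx = _form_index(obs, prompt_form)
    cols = np.arange(len(obs))
    L1 = _production_probs(draws, obs, 1.0, u_eff, w_eff)[:, cols, fidx]
    L2 = _production_probs(draws, obs, -1.0, u_eff, w_eff)[:, cols, fidx]
    assert (L1 > 0).all() and (L2 > 0).all()
    if prior is None:
        pi = inv_logit(_prior_eta(draws, obs, u_eff, w_eff))
    else:
        pi = np.broadcast_to(np.asarray(prior, dtype=float), L1.shape)
    num = L1 * pi
    p = _open_unit(num / (num + L2 * (1.0 - pi)))
    return PredictiveDistribution(obs=obs, probs=p, model="bayesian")


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


_REQUIRED_MEANS = {
    "expectancy": ("alpha_NP1", "beta_vtype_NP1"),
    "mirror": ("alpha_PP", "alpha_other", "beta_vtype_PP", "beta_ref_PP",
               "beta_int_PP", "beta_vtype_other", "beta_ref_other",
               "beta_int_other"),
}
_REQUIRED_MEANS["bayesian"] = _REQUIRED_MEANS["expectancy"] + \
    _REQUIRED_MEANS["mirror"]


def plugin_probability_table(parameter_means: dict, model: str,
                             grid: list[dict] | None = None) -> pd.DataFrame:
    """Deterministic plug-in probabilities on the verb-type x pronoun grid.

    Evaluates each comprehension model at fixed parameter values (posterior
    means, say) with all group adjustments at zero. This is the worked-example
    calculator: a transform of the posterior mean, which is not the same
    estimand as the posterior mean of the per-draw transform.
    """
    if model not in _REQUIRED_MEANS:
        raise ValueError(f"unknown model {model!r}")
    missing = [k for k in _REQUIRED_MEANS[model] if k not in parameter_means]
    if missing:
        raise KeyError(f"missing parameter means: {missing}")
    m = parameter_means
    if grid is None:
        if model == "expectancy":
            grid = [{"vtype": v} for v in (1, -1)]
        else:
            grid = [{"vtype": v, "prompt_form": f}
                    for v in (1, -1) for f in ("PP", "DP")]

    def production(vt, ref):
        eta_pp = (m["alpha_PP"] + vt * m["beta_vtype_PP"]
                  + ref * m["beta_ref_PP"] + vt * ref * m["beta_int_PP"])
        eta_ot = (m["alpha_other"] + vt * m["beta_vtype_other"]
                  + ref * m["beta_ref_other"] + vt * ref * m["beta_int_other"])
        return softmax(np.array([eta_pp, 0.0, eta_ot]))

    rows = []
    for cell in grid:
        vt = float(cell["vtype"])
        pi = float(inv_logit(m["alpha_NP1"] + vt * m["beta_vtype_NP1"])) \
            if model in ("expectancy", "bayesian") else None
        if model == "expectancy":
            p = pi
            form = None
        else:
            form = cell["prompt_form"]
            j = {"PP": 0, "DP": 1}[form]
            L1 = production(vt, 1.0)[j]
            L2 = production(vt, -1.0)[j]
            if model == "mirror":
                p = L1 / (L1 + L2)
            else:
                p = L1 * pi / (L1 * pi + L2 * (1.0 - pi))
        rows.append({"vtype": int(vt), "prompt_form": form,
                     "p_np1": float(p), "p_np1_2dp": _round2(float(p))})
    return pd.DataFrame(rows)
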