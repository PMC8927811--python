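"""Hierarchical models of next-mention and referential-form choice.

Three models are fitted to free-prompt continuation data:

* :class:`NextMentionModel` — Bernoulli regression of the produced referent
  (NP1 vs NP2) on the verb-type contrast, with correlated by-participant
  adjustments (intercept, verb-type slope) and a by-item intercept. Its
  fitted probabilities are the next-mention *prior*; used alone they are the
  Expectancy account of pronoun interpretation.
* :class:`ProductionModel` — three-category softmax regression of the
  referential form (personal pronoun PP / demonstrative pronoun DP / other)
  on verb type, referent and their interaction, DP being the zero reference
  category. Its conditionals are the production *likelihoods*; normalized
  over referents they are the Mirror account.
* :class:`JointModel` — both likelihoods fitted simultaneously with one
  jointly correlated adjustment vector per grouping factor; its draws feed
  the Bayesian account (posterior ∝ likelihood × prior). Ablations remove
  the verb-type terms from either component.

Each ``fit`` runs NUTS and returns a :class:`HierarchicalResults` carrying
the posterior draws, a convergence report and prediction methods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _glmm, _hmc
from .diagnostics import ConvergenceReport, check_convergence
from .draws import GroupDraws, PosteriorDraws

U_FAMILIES_PRIOR = ("NP1", "vtype")
U_FAMILIES_PROD = ("PP", "PP_vtype", "PP_ref", "PP_int",
                   "other", "other_vtype", "other_ref", "other_int")
W_FAMILIES_PRIOR = ("NP1",)
W_FAMILIES_PROD = ("PP", "PP_ref", "PP_int", "other", "other_ref", "other_int")

PRIOR_FIXED = ("alpha_NP1", "beta_vtype_NP1")
PROD_FIXED = ("alpha_PP", "alpha_other", "beta_vtype_PP", "beta_ref_PP",
              "beta_int_PP", "beta_vtype_other", "beta_ref_other",
              "beta_int_other")

ABLATIONS = ("none", "drop_vtype_prior", "drop_vtype_likelihood")

# terms removed by each ablation (fixed effects and random-slope families)
_ABLATE_FIXED = {
    "drop_vtype_prior": {"beta_vtype_NP1"},
    "drop_vtype_likelihood": {"beta_vtype_PP", "beta_int_PP",
                              "beta_vtype_other", "beta_int_other"},
}
_ABLATE_FAMILIES = {
    "drop_vtype_prior": {"vtype"},
    "drop_vtype_likelihood": {"PP_vtype", "PP_int", "other_vtype", "other_int"},
}


@dataclass
class McmcConfig:
    """Sampler settings: 4 chains of 4000 iterations (1000 warmup) by default."""

    n_chains: int = 4
    n_iterations: int = 4000
    n_warmup: int = 1000
    seed: int = 0
    target_accept: float = 0.95
    max_depth: int = 8

    def __post_init__(self):
        if self.n_warmup >= self.n_iterations:
            raise ValueError("n_warmup must be smaller than n_iterations")
        if self.n_chains < 2:
            raise ValueError("at least 2 chains are required for diagnostics")

    @property
    def n_post_warmup(self) -> int:
        return self.n_iterations - self.n_warmup


def _check_data(data: pd.DataFrame, need_form: bool, need_ref: bool) -> None:
    req = {"participant_id", "item_id", "vtype"}
    if need_ref:
        req.add("ref")
    if need_form:
        req.add("form")
    missing = req - set(data.columns)
    if missing:
        raise ValueError(f"data lacks required columns: {sorted(missing)}")
    if len(data) == 0:
        raise ValueError("empty dataset")
    if data["participant_id"].nunique() < 2 or data["item_id"].nunique() < 2:
        raise ValueError("need at least 2 participants and 2 items")


def _prior_predictor(data, fixed_names, u_fams, w_fams, subj, item):
    n = len(data)
    vt = data["vtype"].to_numpy(float)
    Xf = np.zeros((n, len(fixed_names)))
    Xf[:, fixed_names.index("alpha_NP1")] = 1.0
    terms = []
    ucols, uX = ["NP1"], [np.ones(n)]
    if "beta_vtype_NP1" in fixed_names:
        Xf[:, fixed_names.index("beta_vtype_NP1")] = vt
        if "vtype" in u_fams:
            ucols.append("vtype")
            uX.append(vt)
    terms.append(_glmm.GroupTerm(
        factor=0, cols=np.array([u_fams.index(c) for c in ucols]),
        X=np.column_stack(uX), idx=subj))
    terms.append(_glmm.GroupTerm(
        factor=1, cols=np.array([w_fams.index("NP1")]),
        X=np.ones((n, 1)), idx=item))
    return _glmm.Predictor(Xf=Xf, terms=terms)


def _prod_predictor(cat, data, fixed_names, u_fams, w_fams, subj, item):
    """Linear predictor for the PP or other equation of the softmax."""
    n = len(data)
    vt = data["vtype"].to_numpy(float)
    ref = data["ref"].to_numpy(float)
    covs = {"": np.ones(n), "vtype": vt, "ref": ref, "int": vt * ref}
    Xf = np.zeros((n, len(fixed_names)))
    Xf[:, fixed_names.index(f"alpha_{cat}")] = 1.0
    ucols, uX = [cat], [np.ones(n)]
    wcols, wX = [cat], [np.ones(n)]
    for slope in ("vtype", "ref", "int"):
        name = f"beta_{slope}_{cat}"
        if name in fixed_names:
            Xf[:, fixed_names.index(name)] = covs[slope]
        fam = f"{cat}_{slope}"
        if fam in u_fams:
            ucols.append(fam)
            uX.append(covs[slope])
        if fam in w_fams:
            wcols.append(fam)
            wX.append(covs[slope])
    terms = [
        _glmm.GroupTerm(factor=0, cols=np.array([u_fams.index(c) for c in ucols]),
                        X=np.column_stack(uX), idx=subj),
        _glmm.GroupTerm(factor=1, cols=np.array([w_fams.index(c) for c in wcols]),
                        X=np.column_stack(wX), idx=item),
    ]
    return _glmm.Predictor(Xf=Xf, terms=terms)


class _HierarchicalModel:
    """Shared machinery: build a ModelSpec, run NUTS, package the draws."""

    model_tag = "base"

    def __init__(self, data: pd.DataFrame):
        self.data = data.reset_index(drop=True)
        self.subj, self.subj_labels = pd.factorize(self.data["participant_id"])
        self.item, self.item_labels = pd.factorize(self.data["item_id"])
        self._flags: list[str] = []
        self.spec = self._build_spec()

    def _build_spec(self) -> _glmm.ModelSpec:  # pragma: no cover - abstract
        raise NotImplementedError

    def _factors(self, u_fams, w_fams):
        return [
            _glmm.GroupFactor("participant", len(self.subj_labels), tuple(u_fams)),
            _glmm.GroupFactor("item", len(self.item_labels), tuple(w_fams)),
        ]

    def fit(self, mcmc: McmcConfig | None = None) -> "HierarchicalResults":
        mcmc = mcmc or McmcConfig()
        spec = self.spec
        seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.n_chains)
        chains = []
        for ss in seeds:
            rng = np.random.default_rng(ss)
            q0 = rng.uniform(-0.5, 0.5, spec.dim) * 0.2
            chains.append(_hmc.sample_chain(
                lambda q: _glmm.logp_grad(spec, q), q0,
                n_warmup=mcmc.n_warmup, n_draws=mcmc.n_post_warmup, rng=rng,
                target_accept=mcmc.target_accept, max_depth=mcmc.max_depth))
        draws = self._package(spec, chains, mcmc)
        report = check_convergence(draws)
        return HierarchicalResults(model=self, draws=draws, convergence=report,
                                   mcmc=mcmc)

    def _package(self, spec, chains, mcmc) -> PosteriorDraws:
        n_c, n_d = len(chains), mcmc.n_post_warmup
        fixed = {name: np.empty((n_c, n_d)) for name in spec.fixed_names}
        labels = {"participant": tuple(self.subj_labels),
                  "item": tuple(self.item_labels)}
        groups = {}
        for f in spec.factors:
            groups[f.name] = GroupDraws(
                name=f.name, family_names=f.family_names, labels=labels[f.name],
                effects=np.empty((n_c, n_d, f.n_levels, f.k)),
                sd=np.empty((n_c, n_d, f.k)),
                chol=np.empty((n_c, n_d, f.k, f.k)))
        divergent = np.zeros((n_c, n_d), dtype=bool)
        for c, ch in enumerate(chains):
            divergent[c] = ch.divergent
            for d in range(n_d):
                con = _glmm.constrain(spec, ch.draws[d])
                for name, val in con["fixed"].items():
                    fixed[name][c, d] = val
                for fac in con["factors"]:
                    g = groups[fac["name"]]
                    g.effects[c, d] = fac["B"]
                    g.sd[c, d] = fac["sd"]
                    g.chol[c, d] = fac["chol"]
        info = {"flags": list(self._flags),
                "step_size": [ch.step_size for ch in chains],
                "mean_accept": [float(ch.accept_stat.mean()) for ch in chains],
                "seed": mcmc.seed}
        return PosteriorDraws(model_tag=self.model_tag, fixed=fixed,
                              groups=groups, divergent=divergent,
                              sampler_info=info)


class NextMentionModel(_HierarchicalModel):
    """Hierarchical Bernoulli model of which referent is mentioned next."""

    model_tag = "prior_only"

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame) -> "NextMentionModel":
        return cls(data)

    def _build_spec(self):
        _check_data(self.data, need_form=False, need_ref=True)
        if self.data["ref"].nunique() < 2:
            self._flags.append("single referent level: possible separation")
        u_fams, w_fams = list(U_FAMILIES_PRIOR), list(W_FAMILIES_PRIOR)
        fixed = list(PRIOR_FIXED)
        pred = _prior_predictor(self.data, fixed, u_fams, w_fams,
                                self.subj, self.item)
        y = (self.data["ref"].to_numpy(int) == 1).astype(float)
        return _glmm.ModelSpec(
            fixed_names=tuple(fixed),
            fixed_priors=("logistic", "normal"),
            factors=self._factors(u_fams, w_fams),
            blocks=[_glmm.BernoulliBlock(y=y, pred=pred)])


class ProductionModel(_HierarchicalModel):
    """Hierarchical softmax model of referential-form choice (PP/DP/other)."""

    model_tag = "production_only"

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame) -> "ProductionModel":
        return cls(data)

    def _build_spec(self):
        _check_data(self.data, need_form=True, need_ref=True)
        present = set(self.data["form"].unique())
        for cat in ("PP", "DP", "other"):
            if cat not in present:
                self._flags.append(
                    f"form category {cat!r} absent: weakly identified intercept")
        u_fams, w_fams = list(U_FAMILIES_PROD), list(W_FAMILIES_PROD)
        fixed = list(PROD_FIXED)
        y = self.data["form"].map({"PP": 0, "DP": 1, "other": 2}).to_numpy(int)
        block = _glmm.CategoricalBlock(
            y=y,
            pred_pp=_prod_predictor("PP", self.data, fixed, u_fams, w_fams,
                                    self.subj, self.item),
            pred_other=_prod_predictor("other", self.data, fixed, u_fams,
                                       w_fams, self.subj, self.item))
        return _glmm.ModelSpec(
            fixed_names=tuple(fixed),
            fixed_priors=("normal",) * len(fixed),
            factors=self._factors(u_fams, w_fams),
            blocks=[block])


class JointModel(_HierarchicalModel):
    """Both likelihoods with shared, jointly correlated adjustments.

    ``ablation`` removes the verb-type fixed effect together with its
    interactions and random slopes from the prior ('drop_vtype_prior') or
    from the production likelihood ('drop_vtype_likelihood').
    """

    def __init__(self, data: pd.DataFrame, ablation: str = "none"):
        if ablation not in ABLATIONS:
            raise ValueError(
                f"unknown ablation {ablation!r}; expected one of {ABLATIONS}")
        self.ablation = ablation
        self.model_tag = {"none": "joint",
                          "drop_vtype_prior": "joint_no_vtype_prior",
                          "drop_vtype_likelihood": "joint_no_vtype_likelihood",
                          }[ablation]
        super().__init__(data)

    @classmethod
    def from_dataframe(cls, data, ablation="none") -> "JointModel":
        return cls(data, ablation=ablation)

    def _build_spec(self):
        _check_data(self.data, need_form=True, need_ref=True)
        drop_fixed = _ABLATE_FIXED.get(self.ablation, set())
        drop_fams = _ABLATE_FAMILIES.get(self.ablation, set())
        fixed = [f for f in PRIOR_FIXED + PROD_FIXED if f not in drop_fixed]
        priors = tuple("logistic" if f == "alpha_NP1" else "normal"
                       for f in fixed)
        u_fams = [f for f in U_FAMILIES_PRIOR + U_FAMILIES_PROD
                  if f not in drop_fams]
        w_fams = [f for f in W_FAMILIES_PRIOR + W_FAMILIES_PROD
                  if f not in drop_fams]
        y_ref = (self.data["ref"].to_numpy(int) == 1).astype(float)
        y_form = self.data["form"].map({"PP": 0, "DP": 1, "other": 2}).to_numpy(int)
        blocks = [
            _glmm.BernoulliBlock(
                y=y_ref,
                pred=_prior_predictor(self.data, fixed, u_fams, w_fams,
                                      self.subj, self.item)),
            _glmm.CategoricalBlock(
                y=y_form,
                pred_pp=_prod_predictor("PP", self.data, fixed, u_fams, w_fams,
                                        self.subj, self.item),
                pred_other=_prod_predictor("other", self.data, fixed, u_fams,
                                           w_fams, self.subj, self.item)),
        ]
        return _glmm.ModelSpec(fixed_names=tuple(fixed), fixed_priors=priors,
                               factors=self._factors(u_fams, w_fams),
                               blocks=blocks)


@dataclass
class HierarchicalResults:
    """Posterior draws plus diagnostics for one fitted hierarchical model."""

    model: _HierarchicalModel
    draws: PosteriorDraws
    convergence: ConvergenceReport
    mcmc: McmcConfig

    def summary(self, ci: float = 0.90) -> pd.DataFrame:
        return self.draws.summary(ci=ci)

    def predict(self, obs: pd.DataFrame, model: str, rng_seed: int = 0):
        """Per-draw interpretation probabilities for held-out pronoun prompts
        under the named comprehension model (expectancy/mirror/bayesian)."""
        from . import predict as _predict

        fn = {"expectancy": _predict.expectancy_probability,
              "mirror": _predict.mirror_posterior,
              "bayesian": _predict.bayes_posterior}[model]
        return fn(self.draws, obs, rng_seed=rng_seed)


def fit_prior_model(free_data: pd.DataFrame,
                    mcmc: McmcConfig | None = None) -> PosteriorDraws:
    """Fit the next-mention (Expectancy) model; returns its posterior draws."""
    return NextMentionModel(free_data).fit(mcmc).draws


def fit_production_model(free_data: pd.DataFrame,
                         mcmc: McmcConfig | None = None) -> PosteriorDraws:
    """Fit the form-choice (Mirror) model; returns its posterior draws."""
    return ProductionModel(free_data).fit(mcmc).draws


def fit_joint_model(free_data: pd.DataFrame, mcmc: McmcConfig | None = None,
                    ablation: str = "none") -> PosteriorDraws:
    """Fit the joint (Bayesian) model, optionally ablated."""
    return JointModel(free_data, ablation=ablation).fit(mcmc).draws
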