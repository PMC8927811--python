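# Methods

## The problem

In a story-continuation experiment, a participant reads a context sentence
introducing two same-gender referents — NP1 (mentioned first) and NP2 — and
completes a second sentence. Under a *free prompt* (blank line) the
completion reveals two production quantities: the **next-mention bias**
P(referent), i.e. which referent speakers talk about next, and the
**production bias** P(form | referent), i.e. which referential form
(personal pronoun, demonstrative pronoun, or something else) they choose for
a given referent. Under a *pronoun prompt* (a given personal or
demonstrative pronoun) the completion reveals the **interpretation bias**
P(referent | form).

Three accounts tie these together:

* **Expectancy**: P(referent | form) = P(referent) — the prior alone.
* **Mirror**: P(referent | form) ∝ P(form | referent) — the normalized
  production likelihood alone.
* **Bayesian**: P(referent | form) ∝ P(form | referent) · P(referent) —
  the posterior composition of both.

The package estimates the prior and the likelihood hierarchically from
free-prompt data, turns each account into a predictive distribution for
held-out pronoun-prompt data, and compares the accounts by holdout expected
log predictive density (elpd).

## Models

Coding: NP1 = +1, NP2 = −1 for the referent; the two-level verb-type
contrast is ±1 (accusative/ES = +1, dative/SE = −1); referential forms
collapse to PP (personal pronoun), DP (demonstrative pronoun, dieser- and
der-type merged) and *other*.

**Next-mention (prior) model.** Bernoulli regression on the produced
referent with predictor

    eta_i = alpha_NP1 + u_NP1[s_i] + w_NP1[j_i]
            + vtype_i * (beta_vtype_NP1 + u_vtype[s_i]),

with by-participant adjustments u (intercept and verb-type slope) and a
by-item intercept w.

**Production (likelihood) model.** Three-category softmax on the produced
form with DP as the zero-reference category. The PP and *other* equations
each carry an intercept, a verb-type slope, a referent slope and their
interaction, with by-participant adjustments on all four terms and by-item
adjustments on intercept, referent slope and interaction (verb type is a
between-item property, so it gets no by-item slope).

**Joint model.** Both likelihoods fitted simultaneously. The two adjustment
families are pooled into one correlated by-participant vector (10 families)
and one correlated by-item vector (7 families), each with a single LKJ(2)
correlation matrix. (Pooling every family that the two component models
declare is the maximal reading; a narrower pooling — e.g. six by-participant
and three by-item families — would leave the *other*-equation adjustments
uncorrelated and changes none of the predictive formulas.) The joint fit
feeds the Bayesian account, whose prior and likelihood must share
adjustments draw by draw.

**Ablations.** `drop_vtype_prior` removes the verb-type fixed effect and its
random slope from the prior component; `drop_vtype_likelihood` removes the
verb-type and interaction terms (fixed and random) from both production
equations. Comparing the ablated joint models by holdout elpd asks whether
verb-type information lives in the prior, the likelihood, or both — the
"strong" form of the Bayesian account claims the prior.

## Priors

* Bernoulli intercept: uniform Beta(1, 1) on the probability scale,
  implemented exactly as the standard-logistic density on alpha (change of
  variables), so the implied P(NP1) is uniform on (0, 1) a priori.
* Softmax intercepts and all slopes: Normal(0, 2).
* Adjustment SDs: half-Normal(0, 2).
* Correlation matrices: LKJ(2).

## Sampling

The posterior is explored with an in-package No-U-Turn sampler (recursive
tree doubling with slice sampling, dual-averaging step-size adaptation
targeting 0.95 acceptance, diagonal metric estimated in expanding warmup
windows, maximum tree depth 8 by default). The log density and its gradient
are analytic. All random effects are non-centered (B = (Z Lᵀ)·sd with
Z ~ N(0,1)), which keeps the geometry manageable at small group counts; SDs
are sampled on the log scale and correlations through the canonical
partial-correlation (tanh) parameterization of the Cholesky factor, with the
appropriate Jacobians. The gradient is verified against finite differences
in the test suite. Defaults mirror the study conditions: 4 chains × 4000
iterations with 1000 warmup.

Convergence verdict: zero divergent transitions (Hamiltonian error > 1000),
split-R̂ ≤ 1.01 for every stored parameter, and effective sample size at
least 10% of the post-warmup draw count (diagnostics via arviz). Draws are
returned even when the verdict fails.

## Prediction and evaluation

Per posterior draw and held-out observation, the Expectancy probability is
the inverse-logit of the prior predictor; the Mirror probability is
L1/(L1+L2) where L1, L2 are the prompt form's softmax conditionals under
the two hypothetical referents; the Bayesian probability is
L1·π/(L1·π + L2·(1−π)) with π the same draw's prior. Observations from
participants or items not seen during fitting receive adjustments sampled
per draw from that draw's population distribution; in the Latin-square
design every label is seen, so this path is exceptional. Probabilities are
clipped to the open unit interval at 1e−15 against floating-point
underflow.

Pointwise log predictive density is the log of the draw-averaged density
(log-mean, the standard holdout estimator — not the mean of per-draw logs).
elpd is its sum; its SE is sd(pointwise)·√N with the ddof = 1 sample sd, and
the SE of a difference is computed from pointwise differences. Stacking
weights maximize the held-out log score of the convex mixture (SLSQP on the
simplex, tolerance 1e−8); models with identical pointwise vectors split
their weight equally. The |elpd_diff| > 4 rule of thumb is reported as an
annotation, never enforced. Posterior-predictive summaries compare observed
NP1 proportions per condition with quantiles of simulated proportions.

A deterministic plug-in calculator evaluates each account at fixed parameter
values (e.g. posterior means) with adjustments at zero, rounding half-up to
two decimals for display. This is a transform of the posterior mean, which
is *not* the posterior mean of the per-draw transform (Jensen's gap): at the
published Experiment 1 means the two agree at two decimals for the
accusative prior cell and the personal-pronoun Mirror cells but can differ
elsewhere (e.g. the dative prior cell). Both estimands are available; full
per-draw propagation is the inferential path.

## Synthetic data

The generator emulates the study design: participants in three lists, each
seeing every item exactly once, prompts rotated by Latin square over
{free, personal, demonstrative}; two verb classes coded ±1. Free-prompt
referents and forms are drawn from the hierarchical prior and production
models above with correlated adjustments drawn per participant and item;
pronoun-prompt referents are Bernoulli with the probability assigned by a
selectable ground-truth comprehension model (bayesian / mirror /
expectancy) computed from the same units' true adjustments. An optional
fraction of records is corrupted into excluded categories (uniformly over
exclusion codes and non-binary referents) purely to exercise the coding
filters; these records are noise, not modelled behaviour.

Default fixed effects sit at the magnitudes typically estimated from German
continuation data of this design: next-mention intercept −0.7 and verb-type
slope 0.3 (a modest NP2 preference that verb type modulates), a strong
personal-pronoun preference for NP1 re-mention (referent slope 2.2 in the PP
equation) and demonstratives favouring NP2. Adjustment SDs default to 0.5 on
the log-odds scale — a typical by-participant/by-item spread for binary
psycholinguistic judgements — with identity correlations. What the generator
does *not* emulate: lexical content and item idiosyncrasies beyond a random
intercept/slope, annotator disagreement (it emits one adjudicated label),
more than two candidate referents, and any systematic structure in excluded
records. Passing recovery and model-selection tests therefore shows the
estimator and the decision procedure are sound under the assumed data law,
not that the behavioural claims hold for new human data.

## Test and demonstration scales

MCMC at full scale is expensive, so the simulation-based checks run at
reduced, fixed sizes chosen once: parameter recovery uses 20 replicates of
30 participants × 20 items with 2 chains × 1000 iterations (500 warmup),
checking that 90% intervals cover the generating values at a binomially
plausible rate (≥ 31/40) with zero divergences; model-selection consistency
uses 10 replicates of 18 participants × 18 items with 2 chains × 400
iterations, requiring the Bayesian account to win the holdout elpd in at
least 7; the ablation ordering check uses one 24 participants × 24 items
dataset and three joint fits. The ablation check needs the larger held-out
set because verb type is a between-item property: when it is removed from
the prior, the seen items' random intercepts absorb most of the missing
effect during fitting, and only the shrinkage residual of that absorption
is left to penalize the ablated model's predictions. The bundled smoke
pipeline runs 9 participants × 6 items with 2 × 500 iterations.

## Numerical choices and edge cases

* Tie-break in stacking for identical models: equal split (documented).
* Half-up rounding to 2 decimals in display tables.
* Degenerate inputs: a dataset with a single referent level fits but is
  flagged (possible separation); a missing form category fits with its
  intercept dominated by the prior, flagged; empty filter output raises.
* Empty condition cells are reported as NaN with a warning, never silent
  0/0; single-observation PPC groups warn about degenerate bands.
* Normalized within-participant intervals (descriptive error bars) use the
  normalize-then-interval recipe and never feed inference.

## Known limitations

* One sampler implementation (NUTS with diagonal metric); no variational or
  MAP fallback, and heavily correlated posteriors at very small group counts
  may need more iterations than the reduced-scale defaults.
* The loader accepts a single adjudicated label per record; annotator
  disagreement resolution is out of scope.
* Exactly two candidate referents; the Expectancy normalization over
  morphologically compatible referents is the identity here and is not
  computed for larger referent sets.
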