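# pronref

Bayesian models of pronoun interpretation, built for story-continuation
(sentence-completion) experiments with two same-gender referents — the
paradigm used to study German personal (*er*) vs demonstrative (*dieser*)
pronouns. The package is aimed at psycholinguists who want to estimate
next-mention and production biases hierarchically from free-prompt
continuations, and test which comprehension account best predicts held-out
pronoun-prompt interpretations.

## The models

Writing `ref ∈ {NP1, NP2}` for the referent and `form ∈ {PP, DP, other}`
for the referential form, free-prompt data identify

* the **next-mention prior** `P(ref)`, fitted as a hierarchical Bernoulli
  regression: `logit P(NP1) = α + u_NP1[s] + w_NP1[i] + vtype·(β + u_vtype[s])`,
* the **production likelihood** `P(form | ref)`, fitted as a hierarchical
  three-category softmax (demonstrative as zero reference) with verb-type,
  referent and interaction terms,

with correlated by-participant (`u`) and by-item (`w`) adjustments
(non-centered, LKJ(2) correlation priors, half-Normal(0,2) SDs, Normal(0,2)
slopes, and a uniform Beta(1,1) prior on the Bernoulli intercept's
probability scale). Three comprehension accounts then predict held-out
pronoun-prompt interpretations per posterior draw:

| account    | P(NP1 \| form) |
|------------|----------------|
| Expectancy | `π` (the prior alone) |
| Mirror     | `L1 / (L1 + L2)` (normalized likelihood) |
| Bayesian   | `L1·π / (L1·π + L2·(1−π))` |

where `L1 = P(form | NP1)` and `L2 = P(form | NP2)`. Accounts are compared
by holdout expected log predictive density (elpd) with stacking weights.
Sampling uses an in-package No-U-Turn sampler with analytic gradients;
convergence requires zero divergences, split-R̂ ≤ 1.01 and ESS ≥ 10% of the
post-warmup draws. A synthetic-data generator with a Latin-square design and
a selectable ground-truth comprehension model makes every stage testable
without any experimental data. See `docs/methods.md` for details.

## Worked example

```python
from pronref import (TrueParameters, DesignSpec, simulate_experiment,
                     apply_coding_filters, JointModel, McmcConfig,
                     pointwise_lpd, elpd_compare)

tp = TrueParameters(truth_model="bayesian")
records, truth = simulate_experiment(
    tp, DesignSpec(n_participants=18, n_items_per_class=9), rng_seed=12)
data, report = apply_coding_filters(records)
free = data[data["prompt"] == "free"]
pron = data[data["prompt"] != "free"].reset_index(drop=True)

results = JointModel(free).fit(
    McmcConfig(n_chains=2, n_iterations=600, n_warmup=300, seed=0, max_depth=7))
print(results.summary().loc[["alpha_NP1", "beta_vtype_NP1",
                             "alpha_PP", "beta_ref_PP"]].round(2))

outcomes = pron["ref"].to_numpy(int)
lpd = {name: pointwise_lpd(results.predict(pron, model=name), outcomes)
       for name in ("expectancy", "mirror", "bayesian")}
print(elpd_compare(lpd).table.round(2).to_string(index=False))
```

prints

```
                mean    q5   q95
alpha_NP1      -0.59 -1.20 -0.03
beta_vtype_NP1  0.07 -0.38  0.55
alpha_PP        3.29  2.08  4.52
beta_ref_PP     2.80  1.48  4.22
     model  elpd_diff  se_diff    elpd  se_elpd  weight  clear_difference
  bayesian       0.00     0.00  -93.15     7.07     1.0             False
    mirror     -14.93     3.75 -108.08     7.94     0.0              True
expectancy     -35.43     6.91 -128.58     4.57     0.0              True
```

The 90% credible intervals cover the generating values (intercept −0.7,
verb-type slope 0.3, PP intercept 2.6, PP referent slope 2.2), and the
Bayesian account — the ground truth here — wins the holdout comparison with
all the stacking weight; `elpd_diff` is each account's deficit relative to
the best, with its standard error from the pointwise differences. At this
deliberately short demonstration run the strict convergence verdict flags
some adjustment parameters below the ESS floor
(`results.convergence.verdict`); the default `McmcConfig()` (4 chains ×
4000 iterations) is the inferential configuration.

The deterministic plug-in calculator reproduces worked examples from
posterior means alone:

```python
from pronref import plugin_probability_table
plugin_probability_table({"alpha_NP1": -0.68, "beta_vtype_NP1": 0.30},
                         "expectancy")
#  vtype prompt_form    p_np1  p_np1_2dp
#      1        None 0.406127       0.41
#     -1        None 0.272892       0.27
```

i.e. with these posterior means the prior probability of re-mentioning the
first referent is 0.41 after accusative verbs and 0.27 after dative verbs.

A command-line interface mirrors the library
(`pronref simulate | filter | fit | predict | compare | ablate | tables | run`);
`pronref run --config cfg.yaml` executes the whole pipeline into an output
directory with a reproducibility manifest.

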