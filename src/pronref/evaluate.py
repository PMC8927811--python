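"""Holdout scoring and model comparison.

Models are scored on held-out pronoun-prompt data by their pointwise log
predictive density: per observation, the log of the draw-averaged predictive
density (log-mean over draws, the standard holdout definition — not the mean
of per-draw logs). elpd is the sum of pointwise values; standard errors use
sd(pointwise) * sqrt(N) with the sample (ddof=1) standard deviation, and the
SE of a difference is computed from the pointwise differences, never from
the marginal SEs. Stacking weights maximize the held-out log score of the
convex mixture of predictive distributions.

The usual rule of thumb — an |elpd_diff| above 4 with N > 100 makes the
normal approximation to se_diff reliable — is reported as an annotation
column, never enforced as a gate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .predict import PredictiveDistribution, sample_predictions

ELPD_RULE_OF_THUMB = 4.0


def pointwise_lpd(pred: PredictiveDistribution, outcomes) -> np.ndarray:
    """Per-observation log of the draw-averaged predictive density.

    ``outcomes`` are coded +1 (NP1) / -1 (NP2), one per observation.
    """
    y = np.asarray(outcomes)
    if y.shape != (pred.probs.shape[1],):
        raise ValueError("outcomes must align with predictions")
    if not np.isin(y, (1, -1)).all():
        raise ValueError("outcomes must be +1 or -1")
    dens = np.where(y[None, :] == 1, pred.probs, 1.0 - pred.probs)
    return logsumexp(np.log(dens), axis=0) - np.log(pred.n_draws)


@dataclass
class ComparisonResult:
    """elpd table (best model first) and optional per-group tables."""

    table: pd.DataFrame
    by_group: dict | None = None

    def __str__(self) -> str:  # pragma: no cover - display helper
        return self.table.to_string(index=False)


def _compare_table(lpd: dict[str, np.ndarray],
                   weights: dict[str, float]) -> pd.DataFrame:
    n = len(next(iter(lpd.values())))
    elpd = {m: float(v.sum()) for m, v in lpd.items()}
    se = {m: float(np.std(v, ddof=1) * np.sqrt(n)) if n > 1 else 0.0
          for m, v in lpd.items()}
    best = max(elpd, key=elpd.get)
    rows = []
    for m in sorted(lpd, key=lambda k: -elpd[k]):
        if m == best:
            diff, se_diff = 0.0, 0.0
        else:
            d = lpd[m] - lpd[best]
            diff = float(d.sum())
            se_diff = float(np.std(d, ddof=1) * np.sqrt(n)) if n > 1 else 0.0
        rows.append({"model": m, "elpd_diff": diff, "se_diff": se_diff,
                     "elpd": elpd[m], "se_elpd": se[m],
                     "weight": weights[m],
                     "clear_difference": bool(abs(diff) > ELPD_RULE_OF_THUMB
                                              and n > 100)})
    return pd.DataFrame(rows)


def elpd_compare(lpd_by_model: dict[str, np.ndarray],
                 groups=None) -> ComparisonResult:
    """Compare models by holdout elpd, overall and optionally per group.

    All pointwise vectors must score the same observations in the same
    order. Per-group tables (and per-group stacking weights) replicate the
    subset layout of condition-wise comparisons.
    """
    lpd = {m: np.asarray(v, dtype=float) for m, v in lpd_by_model.items()}
    lengths = {v.shape for v in lpd.values()}
    if len(lengths) != 1 or next(iter(lengths))[0] == 0:
        raise ValueError("models must be scored on one identical observation set")
    table = _compare_table(lpd, stacking_weights(lpd))
    by_group = None
    if groups is not None:
        groups = np.asarray(groups)
        if groups.shape[0] != len(next(iter(lpd.values()))):
            raise ValueError("groups must align with observations")
        by_group = {}
        for g in pd.unique(groups):
            sub = {m: v[groups == g] for m, v in lpd.items()}
            by_group[g] = _compare_table(sub, stacking_weights(sub))
    return ComparisonResult(table=table, by_group=by_group)


def stacking_weights(lpd_by_model: dict[str, np.ndarray],
                     tol: float = 1e-8) -> dict[str, float]:
    """Simplex weights maximizing the stacked log score.

    Maximizes ``sum_n log sum_m w_m exp(lpd_{m,n})`` over the simplex
    (a convex problem). Models with identical pointwise vectors split their
    group's weight equally (documented tie-break).
    """
    names = list(lpd_by_model)
    if not names:
        raise ValueError("need at least one model")
    L = np.asarray([lpd_by_model[m] for m in names], dtype=float)
    if not np.isfinite(L).all():
        raise ValueError("pointwise lpd values must be finite")
    if len(names) == 1:
        return {names[0]: 1.0}

    # collapse duplicate models so the optimum is unique, split weight after
    uniq: list[int] = []
    group_of = {}
    for i in range(len(names)):
        for j in uniq:
            if np.allclose(L[i], L[j], rtol=0, atol=1e-12):
                group_of[i] = j
                break
        else:
            uniq.append(i)
            group_of[i] = i
    Lu = L[uniq]
    m = len(uniq)
    if m == 1:
        w_u = np.array([1.0])
    else:
        def neg(w):
            return -float(np.sum(logsumexp(Lu + np.log(np.maximum(w, 1e-300))[:, None],
                                           axis=0)))

        def grad(w):
            z = logsumexp(Lu + np.log(np.maximum(w, 1e-300))[:, None], axis=0)
            return -np.exp(Lu - z[None, :]).sum(axis=1)

        w0 = np.full(m, 1.0 / m)
        res = minimize(neg, w0, jac=grad, method="SLSQP",
                       bounds=[(0.0, 1.0)] * m,
                       constraints=[{"type": "eq",
                                     "fun": lambda w: w.sum() - 1.0}],
                       options={"ftol": tol, "maxiter": 500})
        w_u = np.clip(res.x, 0.0, None)
        w_u /= w_u.sum()
    w_of_uniq = dict(zip(uniq, w_u))
    counts = {j: sum(1 for i in range(len(names)) if group_of[i] == j)
              for j in uniq}
    return {names[i]: float(w_of_uniq[group_of[i]] / counts[group_of[i]])
            for i in range(len(names))}


def ablation_compare(free_data: pd.DataFrame, pron_data: pd.DataFrame,
                     mcmc=None, rng_seed: int = 0) -> ComparisonResult:
    """Verb-type ablation comparison of the joint (Bayesian) model.

    Fits the full joint model and the two ablated variants (verb type removed
    from the next-mention prior / from the production likelihood), scores
    each by bayes-posterior holdout elpd on the pronoun-prompt data, and
    compares.
    """
    from .models import JointModel
    from .predict import bayes_posterior

    outcomes = pron_data["ref"].to_numpy(int)
    lpd = {}
    for label, ablation in (("full", "none"),
                            ("no_vtype_likelihood", "drop_vtype_likelihood"),
                            ("no_vtype_prior", "drop_vtype_prior")):
        res = JointModel(free_data, ablation=ablation).fit(mcmc)
        pred = bayes_posterior(res.draws, pron_data, rng_seed=rng_seed)
        lpd[label] = pointwise_lpd(pred, outcomes)
    return elpd_compare(lpd)


def ppc_summary(pred_by_model: dict[str, PredictiveDistribution],
                observed, groups, rng_seed: int = 0,
                band: float = 0.95) -> pd.DataFrame:
    """Posterior-predictive summaries of NP1 proportions per model x group.

    For each model and group, the distribution (over draws) of the simulated
    NP1 proportion is summarized by quantiles and compared with the observed
    proportion; ``outside_band`` flags observations outside the central band.
    """
    observed = np.asarray(observed)
    groups = np.asarray(groups)
    lo, hi = (1 - band) / 2, 1 - (1 - band) / 2
    rows = []
    for model, pred in pred_by_model.items():
        sims = sample_predictions(pred, rng_seed=rng_seed)  # (S, N)
        for g in pd.unique(groups):
            sel = groups == g
            if not sel.any():
                warnings.warn(f"empty group {g!r}: skipped")
                continue
            if sel.sum() == 1:
                warnings.warn(f"group {g!r} has a single observation; "
                              "its predictive band is degenerate")
            sim_prop = sims[:, sel].mean(axis=1)
            obs_prop = float((observed[sel] == 1).mean())
            qlo, qhi = np.quantile(sim_prop, [lo, hi])
            rows.append({
                "model": model, "group": g, "n": int(sel.sum()),
                "observed": obs_prop, "sim_mean": float(sim_prop.mean()),
                "sim_qlow": float(qlo), "sim_qhigh": float(qhi),
                "outside_band": bool(obs_prop < qlo or obs_prop > qhi),
            })
    return pd.DataFrame(rows)
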