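"""Synthetic story-continuation experiments with known ground truth.

The generator reproduces the statistical structure the inference assumes:
each participant sees every item exactly once, under a prompt condition
rotated by a Latin square over three lists (free, personal-pronoun,
demonstrative-pronoun). For free prompts the produced referent follows the
hierarchical Bernoulli next-mention model and the referential form follows
the hierarchical three-category softmax production model, both with
correlated by-participant and by-item adjustments. For pronoun prompts the
interpreted referent is Bernoulli with the probability a selectable
ground-truth comprehension model assigns (bayesian / mirror / expectancy),
computed from the same participant's and item's true adjustments.

Default fixed effects sit at the magnitudes typically estimated from German
continuation data of this design (NP1 next-mention intercept around -0.7,
a strong personal-pronoun preference for re-mentioning NP1, demonstratives
favouring NP2); adjustment SDs default to 0.5 on the log-odds scale with
identity correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .models import U_FAMILIES_PRIOR, U_FAMILIES_PROD, W_FAMILIES_PRIOR, \
    W_FAMILIES_PROD
from .predict import inv_logit, softmax

U_FAMILIES = U_FAMILIES_PRIOR + U_FAMILIES_PROD   # 10 by-participant families
W_FAMILIES = W_FAMILIES_PRIOR + W_FAMILIES_PROD   # 7 by-item families

TRUTH_MODELS = ("bayesian", "mirror", "expectancy")

_EXCLUSION_OPTIONS = (
    ("exclusion", "missing"), ("exclusion", "ungrammatical"),
    ("exclusion", "plural"), ("exclusion", "complex"),
    ("exclusion", "no_expression"), ("exclusion", "impersonal"),
    ("referent", "both"), ("referent", "neither"),
    ("referent", "ambiguous"), ("referent", "other"),
)


def _check_corr(corr: np.ndarray, k: int, name: str) -> np.ndarray:
    corr = np.asarray(corr, dtype=float)
    if corr.shape != (k, k):
        raise ValueError(f"{name} must be {k}x{k}")
    if not np.allclose(corr, corr.T):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(corr), 1.0):
        raise ValueError(f"{name} must have a unit diagonal")
    if np.abs(corr).max() > 1.0 + 1e-12:
        raise ValueError(f"{name} entries must lie in [-1, 1]")
    eig = np.linalg.eigvalsh(corr)
    if eig.min() < -1e-8:
        raise ValueError(f"{name} must be positive semi-definite")
    return corr


@dataclass
class TrueParameters:
    """Ground-truth generative parameters, with the truth-model tag."""

    alpha_NP1: float = -0.7
    beta_vtype_NP1: float = 0.3
    alpha_PP: float = 2.6
    alpha_other: float = -1.7
    beta_vtype_PP: float = -0.6
    beta_ref_PP: float = 2.2
    beta_int_PP: float = 0.2
    beta_vtype_other: float = 1.0
    beta_ref_other: float = 1.0
    beta_int_other: float = -0.35
    sd_u: np.ndarray = field(default_factory=lambda: np.full(len(U_FAMILIES), 0.5))
    sd_w: np.ndarray = field(default_factory=lambda: np.full(len(W_FAMILIES), 0.5))
    corr_u: np.ndarray = field(default_factory=lambda: np.eye(len(U_FAMILIES)))
    corr_w: np.ndarray = field(default_factory=lambda: np.eye(len(W_FAMILIES)))
    truth_model: str = "bayesian"

    def __post_init__(self):
        self.sd_u = np.asarray(self.sd_u, dtype=float)
        self.sd_w = np.asarray(self.sd_w, dtype=float)
        if self.sd_u.shape != (len(U_FAMILIES),):
            raise ValueError(f"sd_u must have length {len(U_FAMILIES)}")
        if self.sd_w.shape != (len(W_FAMILIES),):
            raise ValueError(f"sd_w must have length {len(W_FAMILIES)}")
        if (self.sd_u < 0).any() or (self.sd_w < 0).any():
            raise ValueError("adjustment SDs must be non-negative")
        self.corr_u = _check_corr(self.corr_u, len(U_FAMILIES), "corr_u")
        self.corr_w = _check_corr(self.corr_w, len(W_FAMILIES), "corr_w")
        if self.truth_model not in TRUTH_MODELS:
            raise ValueError(f"truth_model must be one of {TRUTH_MODELS}")
        # zero-variance families cannot carry correlation structure
        for sd, corr, nm in ((self.sd_u, self.corr_u, "corr_u"),
                             (self.sd_w, self.corr_w, "corr_w")):
            if (sd == 0).all() and not np.allclose(corr, np.eye(len(sd))):
                object.__setattr__(self, nm, np.eye(len(sd)))

    def fixed_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in (
            "alpha_NP1", "beta_vtype_NP1", "alpha_PP", "alpha_other",
            "beta_vtype_PP", "beta_ref_PP", "beta_int_PP",
            "beta_vtype_other", "beta_ref_other", "beta_int_other")}


@dataclass
class DesignSpec:
    """Latin-square design: 3 lists rotating the prompt over items."""

    n_participants: int = 48
    n_items_per_class: int = 12

    def __post_init__(self):
        if self.n_participants < 1 or self.n_items_per_class < 1:
            raise ValueError("design needs at least one participant and item")

    @property
    def n_items(self) -> int:
        return 2 * self.n_items_per_class


def sample_true_parameters(config: dict | None = None,
                           rng_seed: int = 0) -> TrueParameters:
    """Ground-truth parameters from a config of fixed values and/or ranges.

    Each entry of ``config`` either pins a field (scalar/array) or, for the
    fixed effects, gives a ``(low, high)`` pair sampled uniformly.
    Reproducible under a fixed seed.
    """
    rng = np.random.default_rng(rng_seed)
    config = dict(config or {})
    base = TrueParameters()
    values: dict = {}
    for name in list(config):
        val = config.pop(name)
        if not hasattr(base, name):
            raise ValueError(f"unknown parameter {name!r}")
        if name.startswith(("sd_", "corr_")) or name == "truth_model":
            values[name] = val
        elif np.ndim(val) == 1 and len(val) == 2:
            lo, hi = float(val[0]), float(val[1])
            values[name] = float(rng.uniform(lo, hi))
        else:
            values[name] = float(val)
    return replace(base, **values)


def _unit_effects(rng, n, sd, corr):
    L = np.linalg.cholesky(corr + 1e-12 * np.eye(len(sd)))
    return rng.standard_normal((n, len(sd))) @ L.T * sd


def _eta_ref(tp, vt, u, w):
    return (tp.alpha_NP1 + u[:, U_FAMILIES.index("NP1")]
            + w[:, W_FAMILIES.index("NP1")]
            + vt * (tp.beta_vtype_NP1 + u[:, U_FAMILIES.index("vtype")]))


def _production(tp, vt, ref, u, w):
    """Softmax probabilities (n, 3) over (PP, DP, other) given a referent."""
    ui = U_FAMILIES.index
    wi = W_FAMILIES.index
    etas = []
    for cat in ("PP", "other"):
        eta = (getattr(tp, f"alpha_{cat}") + u[:, ui(cat)] + w[:, wi(cat)]
               + vt * (getattr(tp, f"beta_vtype_{cat}") + u[:, ui(f"{cat}_vtype")])
               + ref * (getattr(tp, f"beta_ref_{cat}") + u[:, ui(f"{cat}_ref")]
                        + w[:, wi(f"{cat}_ref")])
               + vt * ref * (getattr(tp, f"beta_int_{cat}")
                             + u[:, ui(f"{cat}_int")] + w[:, wi(f"{cat}_int")]))
        etas.append(eta)
    return softmax(np.stack((etas[0], np.zeros_like(etas[0]), etas[1]), axis=-1))


def interpretation_probability(tp: TrueParameters, vt, form_idx, u, w,
                               truth_model: str | None = None) -> np.ndarray:
    """The ground-truth comprehension model's P(NP1 | pronoun) per row.

    ``form_idx`` indexes the prompt's form (0 = PP, 1 = DP) into the
    production triple; ``u`` and ``w`` are the rows' true adjustments.
    """
    model = truth_model or tp.truth_model
    pi = inv_logit(_eta_ref(tp, vt, u, w))
    if model == "expectancy":
        return pi
    rows = np.arange(len(vt))
    L1 = _production(tp, vt, 1.0, u, w)[rows, form_idx]
    L2 = _production(tp, vt, -1.0, u, w)[rows, form_idx]
    if model == "mirror":
        return L1 / (L1 + L2)
    return L1 * pi / (L1 * pi + L2 * (1.0 - pi))


def simulate_experiment(true_params: TrueParameters, design: DesignSpec,
                        rng_seed: int = 0, exclusion_fraction: float = 0.0,
                        free_only: bool = False):
    """Generate one experiment's worth of coded continuation records.

    Returns ``(records, truth)`` where ``records`` follows the loader's
    delimited-text schema and ``truth`` carries the parameters and the drawn
    adjustments. ``exclusion_fraction`` injects unmodelled uniform noise
    records (excluded codes or non-binary referents) to exercise the coding
    filters. ``free_only`` replaces the pronoun-prompt conditions with free
    prompts (every trial then exercises the production model).
    """
    tp, d = true_params, design
    root = np.random.SeedSequence(rng_seed)
    rngs = [np.random.default_rng(s) for s in root.spawn(4)]
    r_adj, r_free, r_pron, r_noise = rngs

    u_all = _unit_effects(r_adj, d.n_participants, tp.sd_u, tp.corr_u)
    w_all = _unit_effects(r_adj, d.n_items, tp.sd_w, tp.corr_w)

    part = np.repeat(np.arange(d.n_participants), d.n_items)
    item = np.tile(np.arange(d.n_items), d.n_participants)
    lists = part % 3
    prompt_idx = (item + lists) % 3
    prompts = np.array(["free", "personal", "demonstrative"])[prompt_idx]
    if free_only:
        prompts = np.full_like(prompts, "free")
    vclass = np.where(item < d.n_items_per_class, "A", "B")
    vt = np.where(item < d.n_items_per_class, 1.0, -1.0)
    u = u_all[part]
    w = w_all[item]

    n = len(part)
    ref = np.empty(n, dtype=int)
    form_raw = np.empty(n, dtype=object)

    free = prompts == "free"
    if free.any():
        pi = inv_logit(_eta_ref(tp, vt[free], u[free], w[free]))
        r1 = (r_free.uniform(size=free.sum()) < pi)
        ref_free = np.where(r1, 1, -1)
        pf = _production(tp, vt[free], ref_free.astype(float), u[free], w[free])
        cum = np.cumsum(pf, axis=-1)
        pick = (r_free.uniform(size=(free.sum(), 1)) < cum).argmax(axis=-1)
        raw = np.empty(free.sum(), dtype=object)
        raw[pick == 0] = "personal"
        dp = pick == 1
        raw[dp] = np.where(r_free.uniform(size=dp.sum()) < 0.7,
                           "demonstrative_dieser", "demonstrative_der")
        raw[pick == 2] = "other"
        ref[free] = ref_free
        form_raw[free] = raw

    pron = ~free
    if pron.any():
        fidx = np.where(prompts[pron] == "personal", 0, 1)
        pstar = interpretation_probability(tp, vt[pron], fidx, u[pron], w[pron])
        ref[pron] = np.where(r_pron.uniform(size=pron.sum()) < pstar, 1, -1)
        form_raw[pron] = np.where(prompts[pron] == "personal", "personal",
                                  "demonstrative_dieser")

    df = pd.DataFrame({
        "participant_id": [f"p{i:03d}" for i in part],
        "item_id": [f"i{i:03d}" for i in item],
        "prompt": prompts,
        "verb_class": vclass,
        "vtype": vt.astype(int),
        "referent_raw": np.where(ref == 1, "NP1", "NP2"),
        "form_raw": form_raw,
        "exclusion_code": "none",
    })

    if exclusion_fraction > 0:
        k = int(round(exclusion_fraction * n))
        rows = r_noise.choice(n, size=k, replace=False)
        kinds = r_noise.integers(0, len(_EXCLUSION_OPTIONS), size=k)
        for r, kk in zip(rows, kinds):
            what, val = _EXCLUSION_OPTIONS[kk]
            if what == "exclusion":
                df.loc[r, "exclusion_code"] = val
            else:
                df.loc[r, "referent_raw"] = val

    truth = {
        "params": tp,
        "u": u_all, "w": w_all,
        "u_labels": [f"p{i:03d}" for i in range(d.n_participants)],
        "w_labels": [f"i{i:03d}" for i in range(d.n_items)],
        "design": d, "seed": rng_seed,
    }
    return df, truth


def truth_sidecar(truth: dict) -> dict:
    """JSON/YAML-serializable ground-truth record for the sidecar file."""
    tp: TrueParameters = truth["params"]
    return {
        "truth_model": tp.truth_model,
        "fixed": tp.fixed_dict(),
        "sd_u": tp.sd_u.tolist(),
        "sd_w": tp.sd_w.tolist(),
        "corr_u": tp.corr_u.tolist(),
        "corr_w": tp.corr_w.tolist(),
        "u_families": list(U_FAMILIES),
        "w_families": list(W_FAMILIES),
        "seed": truth["seed"],
        "n_participants": truth["design"].n_participants,
        "n_items_per_class": truth["design"].n_items_per_class,
    }
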