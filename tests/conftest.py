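import numpy as np
import pandas as pd
import pytest

from pronref.draws import GroupDraws, PosteriorDraws
from pronref.models import (U_FAMILIES_PRIOR, U_FAMILIES_PROD,
                            W_FAMILIES_PRIOR, W_FAMILIES_PROD)

U_FAMS = U_FAMILIES_PRIOR + U_FAMILIES_PROD
W_FAMS = W_FAMILIES_PRIOR + W_FAMILIES_PROD


def make_synthetic_draws(n_chains=2, n_draws=25, n_subj=4, n_item=3, seed=0,
                         zero_adjustments=False, fixed_overrides=None,
                         model_tag="joint"):
    """Hand-built PosteriorDraws: valid structure without running MCMC."""
    rng = np.random.default_rng(seed)
    shape = (n_chains, n_draws)
    base = {
        "alpha_NP1": -0.7, "beta_vtype_NP1": 0.3, "alpha_PP": 2.6,
        "alpha_other": -1.7, "beta_vtype_PP": -0.6, "beta_ref_PP": 2.2,
        "beta_int_PP": 0.2, "beta_vtype_other": 1.0, "beta_ref_other": 1.0,
        "beta_int_other": -0.35,
    }
    base.update(fixed_overrides or {})
    fixed = {k: v + 0.1 * rng.standard_normal(shape) for k, v in base.items()}

    def group(name, fams, n):
        k = len(fams)
        scale = 0.0 if zero_adjustments else 0.3
        eff = scale * rng.standard_normal((*shape, n, k))
        sd = np.exp(0.2 * rng.standard_normal((*shape, k))) * 0.5
        chol = np.tile(np.eye(k), (*shape, 1, 1))
        labels = tuple(f"{name[0]}{i:03d}" for i in range(n))
        return GroupDraws(name=name, family_names=fams, labels=labels,
                          effects=eff, sd=sd, chol=chol)

    return PosteriorDraws(
        model_tag=model_tag, fixed=fixed,
        groups={"participant": group("participant", U_FAMS, n_subj),
                "item": group("item", W_FAMS, n_item)},
        divergent=np.zeros(shape, dtype=bool))


@pytest.fixture
def synthetic_draws():
    return make_synthetic_draws()


@pytest.fixture
def pron_obs():
    """Six pronoun-prompt observations over seen participants/items."""
    return pd.DataFrame({
        "participant_id": ["p000", "p001", "p002", "p003", "p000", "p001"],
        "item_id": ["i000", "i001", "i002", "i000", "i001", "i002"],
        "vtype": [1, 1, -1, -1, 1, -1],
        "prompt": ["personal", "demonstrative", "personal", "demonstrative",
                   "personal", "demonstrative"],
        "ref": [1, -1, 1, -1, -1, 1],
    })


@pytest.fixture(scope="session")
def tiny_fit():
    """One small but real next-mention fit, shared across tests."""
    from pronref.data import apply_coding_filters
    from pronref.models import McmcConfig, NextMentionModel
    from pronref.simulate import DesignSpec, TrueParameters, simulate_experiment

    tp = TrueParameters()
    df, truth = simulate_experiment(tp, DesignSpec(9, 3), rng_seed=5)
    filt, _ = apply_coding_filters(df)
    free = filt[filt["prompt"] == "free"]
    pron = filt[filt["prompt"] != "free"].reset_index(drop=True)
    res = NextMentionModel(free).fit(
        McmcConfig(n_chains=2, n_iterations=400, n_warmup=200, seed=1,
                   max_depth=7))
    return {"results": res, "free": free, "pron": pron, "truth": truth}


@pytest.fixture
def toy_records():
    """Ten coded records; 2 ambiguous + 1 missing + 1 plural flagged."""
    rows = []
    specs = [
        ("s1", "i1", "free", "acc", 1, "NP1", "personal", "none"),
        ("s1", "i2", "free", "dat", -1, "NP2", "demonstrative_dieser", "none"),
        ("s1", "i3", "personal", "acc", 1, "NP1", "personal", "none"),
        ("s2", "i1", "demonstrative", "acc", 1, "NP2", "demonstrative_der", "none"),
        ("s2", "i2", "free", "dat", -1, "ambiguous", "other", "none"),
        ("s2", "i3", "free", "acc", 1, "NP1", "demonstrative_der", "none"),
        ("s3", "i1", "free", "acc", 1, "ambiguous", "none", "none"),
        ("s3", "i2", "personal", "dat", -1, "NP2", "personal", "missing"),
        ("s3", "i3", "free", "acc", 1, "NP1", "personal", "plural"),
        ("s4", "i1", "free", "acc", 1, "NP2", "other", "none"),
    ]
    for (p, i, pr, vc, vt, ref, form, exc) in specs:
        rows.append({"participant_id": p, "item_id": i, "prompt": pr,
                     "verb_class": vc, "vtype": vt, "referent_raw": ref,
                     "form_raw": form, "exclusion_code": exc})
    return pd.DataFrame(rows)
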