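"""Container for posterior draws of the hierarchical models."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class GroupDraws:
    """Posterior draws for one grouping factor (participants or items)."""

    name: str
    family_names: tuple[str, ...]
    labels: tuple  # level labels, in index order
    effects: np.ndarray  # (chains, draws, n_levels, K) adjustments B
    sd: np.ndarray       # (chains, draws, K)
    chol: np.ndarray     # (chains, draws, K, K) correlation Cholesky factors

    @property
    def k(self) -> int:
        return len(self.family_names)

    def level_index(self, label) -> int:
        try:
            return self._index[label]
        except AttributeError:
            self._index = {lab: i for i, lab in enumerate(self.labels)}
            return self._index[label]


@dataclass
class PosteriorDraws:
    """MCMC draws over all fixed effects, variance components, correlations
    and group adjustments, with chains kept separate for diagnostics.

    ``model_tag`` is one of ``prior_only``, ``production_only``, ``joint``,
    ``joint_no_vtype_prior``, ``joint_no_vtype_likelihood``.
    """

    model_tag: str
    fixed: dict[str, np.ndarray]          # name -> (chains, draws)
    groups: dict[str, GroupDraws] = field(default_factory=dict)
    divergent: np.ndarray | None = None   # (chains, draws) bool
    sampler_info: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, arr in self.fixed.items():
            if arr.ndim != 2:
                raise ValueError(f"fixed draws for {name!r} must be chains x draws")
            if not np.isfinite(arr).all():
                raise ValueError(f"non-finite draws for {name!r}")
        for g in self.groups.values():
            if (g.sd <= 0).any():
                raise ValueError(f"non-positive SD draws for factor {g.name!r}")

    @property
    def n_chains(self) -> int:
        return next(iter(self.fixed.values())).shape[0]

    @property
    def n_draws(self) -> int:
        """Post-warmup draws per chain."""
        return next(iter(self.fixed.values())).shape[1]

    @property
    def n_total(self) -> int:
        return self.n_chains * self.n_draws

    def stacked(self, name: str) -> np.ndarray:
        """Flatten a fixed effect's draws across chains, (S,)."""
        if name not in self.fixed:
            raise KeyError(f"missing parameter: {name!r}")
        return self.fixed[name].reshape(-1)

    def stacked_fixed(self, name: str, default: float | None = None) -> np.ndarray:
        """Like :meth:`stacked` but with an optional fallback (for ablations)."""
        if name in self.fixed:
            return self.stacked(name)
        if default is None:
            raise KeyError(f"missing parameter: {name!r}")
        return np.full(self.n_total, default)

    def stacked_effects(self, factor: str) -> np.ndarray:
        g = self.groups[factor]
        return g.effects.reshape(self.n_total, len(g.labels), g.k)

    def scalar_table(self, include_groups: bool = False) -> pd.DataFrame:
        """Named-column table with one row per draw, for persistence.

        With ``include_groups`` the by-level adjustments are written too
        (columns ``B_<factor>_<family>[<label>]``), which makes the table a
        lossless round-trip via :meth:`from_table`.
        """
        cols = {}
        for name, arr in self.fixed.items():
            cols[name] = arr.reshape(-1)
        for g in self.groups.values():
            for k, fam in enumerate(g.family_names):
                cols[f"sd_{g.name}_{fam}"] = g.sd[..., k].reshape(-1)
            corr = np.einsum("cdij,cdkj->cdik", g.chol, g.chol)
            for i in range(g.k):
                for j in range(i):
                    cols[f"corr_{g.name}_{g.family_names[j]}_{g.family_names[i]}"] = \
                        corr[..., i, j].reshape(-1)
            if include_groups:
                for k, fam in enumerate(g.family_names):
                    for li, lab in enumerate(g.labels):
                        cols[f"B_{g.name}_{fam}[{lab}]"] = \
                            g.effects[..., li, k].reshape(-1)
        df = pd.DataFrame(cols)
        df.insert(0, "chain", np.repeat(np.arange(self.n_chains), self.n_draws))
        df.insert(1, "draw", np.tile(np.arange(self.n_draws), self.n_chains))
        return df

    @classmethod
    def from_table(cls, df: pd.DataFrame, model_tag: str) -> "PosteriorDraws":
        """Rebuild draws from a full table written by ``scalar_table(True)``."""
        n_chains = int(df["chain"].max()) + 1
        n_draws = int(df["draw"].max()) + 1

        def shaped(col):
            return df[col].to_numpy().reshape(n_chains, n_draws)

        fixed, factors = {}, {}
        for col in df.columns:
            if col in ("chain", "draw"):
                continue
            if col.startswith("sd_"):
                factor, fam = col[3:].split("_", 1)
                factors.setdefault(factor, {"fams": [], "labels": []})
                factors[factor]["fams"].append(fam)
            elif col.startswith("B_"):
                head, lab = col[2:-1].split("[", 1)
                factor = head.split("_", 1)[0]
                if lab not in factors[factor]["labels"]:
                    factors[factor]["labels"].append(lab)
            elif not col.startswith("corr_"):
                fixed[col] = shaped(col)
        groups = {}
        for factor, meta in factors.items():
            fams, labels = meta["fams"], meta["labels"]
            k = len(fams)
            sd = np.stack([shaped(f"sd_{factor}_{f}") for f in fams], axis=-1)
            corr = np.tile(np.eye(k), (n_chains, n_draws, 1, 1))
            for i in range(k):
                for j in range(i):
                    col = f"corr_{factor}_{fams[j]}_{fams[i]}"
                    if col in df.columns:
                        corr[..., i, j] = corr[..., j, i] = shaped(col)
            chol = np.linalg.cholesky(corr + 1e-12 * np.eye(k))
            eff = np.empty((n_chains, n_draws, len(labels), k))
            for ki, f in enumerate(fams):
                for li, lab in enumerate(labels):
                    eff[..., li, ki] = shaped(f"B_{factor}_{f}[{lab}]")
            groups[factor] = GroupDraws(name=factor, family_names=tuple(fams),
                                        labels=tuple(labels), effects=eff,
                                        sd=sd, chol=chol)
        return cls(model_tag=model_tag, fixed=fixed, groups=groups)

    def summary(self, ci: float = 0.90) -> pd.DataFrame:
        """Posterior mean and central quantile interval per scalar parameter."""
        tab = self.scalar_table().drop(columns=["chain", "draw"])
        lo, hi = (1 - ci) / 2, 1 - (1 - ci) / 2
        return pd.DataFrame({
            "mean": tab.mean(),
            f"q{round(lo * 100)}": tab.quantile(lo),
            f"q{round(hi * 100)}": tab.quantile(hi),
        })

    def to_arviz_dict(self) -> dict[str, np.ndarray]:
        """Per-parameter (chains, draws, ...) arrays for arviz diagnostics."""
        out = dict(self.fixed)
        for g in self.groups.values():
            out[f"sd_{g.name}"] = g.sd
            out[f"B_{g.name}"] = g.effects
            if g.k > 1:
                corr = np.einsum("cdij,cdkj->cdik", g.chol, g.chol)
                idx = np.tril_indices(g.k, -1)
                out[f"corr_{g.name}"] = corr[..., idx[0], idx[1]]
        return out
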