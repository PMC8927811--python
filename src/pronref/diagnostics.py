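"""MCMC convergence checks: split-R-hat, effective sample size, divergences.

Verdict policy: a fit passes when there are zero divergent transitions, every
parameter's split-R-hat is at most 1.01 and every effective sample size is at
least 10% of the total post-warmup draw count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .draws import PosteriorDraws

RHAT_THRESHOLD = 1.01
ESS_FRACTION = 0.10


@dataclass
class ConvergenceThresholds:
    rhat: float = RHAT_THRESHOLD
    ess_fraction: float = ESS_FRACTION
    max_divergences: int = 0


@dataclass
class ConvergenceReport:
    table: pd.DataFrame          # per parameter: rhat, ess
    n_divergent: int
    ess_floor: float
    passed: bool
    flags: list[str] = field(default_factory=list)

    @property
    def verdict(self) -> str:
        return "pass" if self.passed else "fail"

    @property
    def max_rhat(self) -> float:
        return float(self.table["rhat"].max())

    @property
    def min_ess(self) -> float:
        return float(self.table["ess"].min())


def check_convergence(
    draws: PosteriorDraws,
    thresholds: ConvergenceThresholds | None = None,
) -> ConvergenceReport:
    """Split-R-hat and bulk ESS per parameter with a pass/fail verdict."""
    import arviz as az

    thresholds = thresholds or ConvergenceThresholds()
    if draws.n_chains < 2:
        raise ValueError("convergence diagnostics require at least 2 chains")

    data = draws.to_arviz_dict()
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata = az.from_dict(posterior=data)
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    for name in data:
        r = np.atleast_1d(np.asarray(rhat[name])).ravel()
        e = np.atleast_1d(np.asarray(ess[name])).ravel()
        if r.size == 1:
            rows.append({"parameter": name, "rhat": float(r[0]), "ess": float(e[0])})
        else:
            for i, (ri, ei) in enumerate(zip(r, e)):
                rows.append({"parameter": f"{name}[{i}]", "rhat": float(ri),
                             "ess": float(ei)})
    table = pd.DataFrame(rows)
    # constant parameters (e.g. an SD pinned by a degenerate dataset) yield
    # NaN diagnostics; they carry no convergence information
    table = table.dropna(subset=["rhat", "ess"]).reset_index(drop=True)

    n_div = int(draws.divergent.sum()) if draws.divergent is not None else 0
    ess_floor = thresholds.ess_fraction * draws.n_total
    passed = (
        n_div <= thresholds.max_divergences
        and (table["rhat"] <= thresholds.rhat).all()
        and (table["ess"] >= ess_floor).all()
    )
    flags = list(draws.sampler_info.get("flags", []))
    return ConvergenceReport(table=table, n_divergent=n_div,
                             ess_floor=float(ess_floor), passed=bool(passed),
                             flags=flags)
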