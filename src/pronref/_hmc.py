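"""No-U-Turn sampler with dual-averaging step-size and diagonal metric.

A self-contained implementation of dynamic Hamiltonian Monte Carlo
(recursive tree doubling with slice sampling, per Hoffman & Gelman's
algorithm 6) over an arbitrary ``logp_grad(q) -> (float, ndarray)`` target.
Warmup adapts the step size towards a target acceptance statistic and
estimates a diagonal metric from an intermediate warmup window. Transitions
whose Hamiltonian error exceeds 1000 are flagged as divergent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DIVERGENCE_THRESHOLD = 1000.0


@dataclass
class ChainResult:
    draws: np.ndarray          # (n_draws, dim), post-warmup
    divergent: np.ndarray      # (n_draws,) bool
    accept_stat: np.ndarray    # (n_draws,) mean tree acceptance
    tree_depth: np.ndarray     # (n_draws,) int
    step_size: float
    inv_metric: np.ndarray     # (dim,) posterior-variance estimate


class _DualAveraging:
    """Nesterov dual averaging on log step size (Stan's defaults)."""

    def __init__(self, eps0: float, target: float, gamma: float = 0.05,
                 t0: float = 10.0, kappa: float = 0.75):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.gamma, self.t0, self.kappa = gamma, t0, kappa
        self.count = 0
        self.h_bar = 0.0
        self.log_eps_bar = 0.0
        self.log_eps = np.log(eps0)

    def update(self, accept: float) -> float:
        self.count += 1
        w = 1.0 / (self.count + self.t0)
        self.h_bar = (1.0 - w) * self.h_bar + w * (self.target - accept)
        self.log_eps = self.mu - np.sqrt(self.count) / self.gamma * self.h_bar
        eta = self.count ** -self.kappa
        self.log_eps_bar = eta * self.log_eps + (1.0 - eta) * self.log_eps_bar
        return np.exp(self.log_eps)

    @property
    def adapted(self) -> float:
        return float(np.exp(self.log_eps_bar))


class _Nuts:
    def __init__(self, logp_grad, inv_metric, rng, max_depth):
        self.f = logp_grad
        self.inv_metric = inv_metric
        self.rng = rng
        self.max_depth = max_depth
        self.divergent = False
        self.alpha_sum = 0.0
        self.n_alpha = 0

    def _leapfrog(self, q, p, grad, eps):
        p = p + 0.5 * eps * grad
        q = q + eps * self.inv_metric * p
        logp, grad = self.f(q)
        p = p + 0.5 * eps * grad
        return q, p, logp, grad

    def _hamiltonian(self, logp, p):
        return logp - 0.5 * float(p @ (self.inv_metric * p))

    def _build(self, q, p, grad, logu, v, j, eps, h0):
        if j == 0:
            q1, p1, logp1, grad1 = self._leapfrog(q, p, grad, v * eps)
            h1 = self._hamiltonian(logp1, p1)
            if not np.isfinite(h1):
                h1 = -np.inf
            n1 = int(logu <= h1)
            s1 = int(logu - DIVERGENCE_THRESHOLD < h1)
            if not s1:
                self.divergent = True
            self.alpha_sum += min(1.0, np.exp(min(0.0, h1 - h0)))
            self.n_alpha += 1
            return q1, p1, grad1, q1, p1, grad1, q1, logp1, n1, s1
        (qm, pm, gm, qp, pp_, gp, q1, logp1, n1, s1) = self._build(
            q, p, grad, logu, v, j - 1, eps, h0)
        if s1:
            if v < 0:
                (qm, pm, gm, _, _, _, q2, logp2, n2, s2) = self._build(
                    qm, pm, gm, logu, v, j - 1, eps, h0)
            else:
                (_, _, _, qp, pp_, gp, q2, logp2, n2, s2) = self._build(
                    qp, pp_, gp, logu, v, j - 1, eps, h0)
            if n1 + n2 > 0 and self.rng.uniform() < n2 / (n1 + n2):
                q1, logp1 = q2, logp2
            dq = qp - qm
            s1 = s2 * int(dq @ (self.inv_metric * pm) >= 0) * \
                int(dq @ (self.inv_metric * pp_) >= 0)
            n1 += n2
        return qm, pm, gm, qp, pp_, gp, q1, logp1, n1, s1

    def transition(self, q, logp, grad, eps):
        self.divergent = False
        self.alpha_sum = 0.0
        self.n_alpha = 0
        p0 = self.rng.standard_normal(q.size) / np.sqrt(self.inv_metric)
        h0 = self._hamiltonian(logp, p0)
        logu = h0 + np.log(self.rng.uniform())
        qm = qp = q
        pm = pp_ = p0
        gm = gp = grad
        q1, logp1 = q, logp
        n, s, depth = 1, 1, 0
        while s and depth < self.max_depth:
            v = 1 if self.rng.uniform() < 0.5 else -1
            if v < 0:
                (qm, pm, gm, _, _, _, q2, logp2, n2, s2) = self._build(
                    qm, pm, gm, logu, v, depth, eps, h0)
            else:
                (_, _, _, qp, pp_, gp, q2, logp2, n2, s2) = self._build(
                    qp, pp_, gp, logu, v, depth, eps, h0)
            if s2 and self.rng.uniform() < min(1.0, n2 / n):
                q1, logp1 = q2, logp2
            n += n2
            dq = qp - qm
            s = s2 * int(dq @ (self.inv_metric * pm) >= 0) * \
                int(dq @ (self.inv_metric * pp_) >= 0)
            depth += 1
        _, grad1 = self.f(q1) if q1 is not q else (logp1, grad)
        accept = self.alpha_sum / max(self.n_alpha, 1)
        return q1, logp1, grad1, accept, depth


def _initial_step_size(logp_grad, q, inv_metric, rng):
    """Heuristic: double/halve eps until the one-step accept prob crosses 0.5."""
    eps = 1.0
    logp, grad = logp_grad(q)
    p = rng.standard_normal(q.size) / np.sqrt(inv_metric)
    h0 = logp - 0.5 * float(p @ (inv_metric * p))

    def h_after(eps):
        p1 = p + 0.5 * eps * grad
        q1 = q + eps * inv_metric * p1
        logp1, grad1 = logp_grad(q1)
        p1 = p1 + 0.5 * eps * grad1
        return logp1 - 0.5 * float(p1 @ (inv_metric * p1))

    delta = h_after(eps) - h0
    direction = 1 if (np.isfinite(delta) and delta > np.log(0.5)) else -1
    for _ in range(50):
        eps *= 2.0 ** direction
        delta = h_after(eps) - h0
        if not np.isfinite(delta):
            delta = -np.inf
        if (direction == 1 and delta < np.log(0.5)) or \
           (direction == -1 and delta > np.log(0.5)):
            break
    return eps


def sample_chain(logp_grad, q0, n_warmup: int, n_draws: int, rng,
                 target_accept: float = 0.95, max_depth: int = 8) -> ChainResult:
    """Run one NUTS chain; returns post-warmup draws and diagnostics."""
    dim = q0.size
    inv_metric = np.ones(dim)
    q = np.asarray(q0, dtype=float).copy()
    logp, grad = logp_grad(q)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log density")

    eps = _initial_step_size(logp_grad, q, inv_metric, rng)
    da = _DualAveraging(eps, target_accept)
    nuts = _Nuts(logp_grad, inv_metric, rng, max_depth)

    # warmup: initial step-size phase, then expanding metric windows, then
    # a final step-size-only phase (Stan-like schedule)
    w1 = max(1, int(0.15 * n_warmup))
    w_end = max(w1 + 1, int(0.9 * n_warmup))
    boundaries = {max(w1 + 1, int(0.5 * n_warmup)), w_end}
    window: list[np.ndarray] = []
    for i in range(n_warmup):
        q, logp, grad, accept, _ = nuts.transition(q, logp, grad, eps)
        eps = da.update(accept)
        if w1 <= i < w_end:
            window.append(q.copy())
        if (i + 1) in boundaries and len(window) >= 10:
            var = np.var(np.asarray(window), axis=0, ddof=1)
            inv_metric = np.clip(var, 1e-6, 1e6)
            nuts.inv_metric = inv_metric
            eps = _initial_step_size(logp_grad, q, inv_metric, rng)
            da = _DualAveraging(eps, target_accept)
            window = []
    eps = da.adapted if n_warmup > 0 else eps

    draws = np.empty((n_draws, dim))
    divergent = np.zeros(n_draws, dtype=bool)
    accept_stat = np.empty(n_draws)
    tree_depth = np.empty(n_draws, dtype=int)
    for i in range(n_draws):
        q, logp, grad, accept, depth = nuts.transition(q, logp, grad, eps)
        draws[i] = q
        divergent[i] = nuts.divergent
        accept_stat[i] = accept
        tree_depth[i] = depth
    return ChainResult(draws=draws, divergent=divergent, accept_stat=accept_stat,
                       tree_depth=tree_depth, step_size=eps, inv_metric=inv_metric)
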