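"""Log-posterior and analytic gradient for the hierarchical regressions.

The models are Bernoulli and/or three-category softmax regressions with
crossed, correlated by-participant and by-item adjustments. All sampling is
done on an unconstrained parameter vector:

* fixed effects: identity;
* adjustment SDs: log transform (half-Normal(0, 2) prior plus Jacobian);
* correlation matrices: Cholesky parameterization through canonical partial
  correlations ``x = tanh(y)`` (LKJ(2) prior plus the transform's
  log-Jacobian);
* adjustments themselves: non-centered, ``B = (Z @ L.T) * sd`` with
  ``Z ~ N(0, 1)`` i.i.d.

The Bernoulli intercept carries a uniform Beta(1, 1) prior on its
inverse-logit, implemented as the standard-logistic density on the log-odds
scale (exact change of variables). All other fixed effects are Normal(0, 2).

Gradients are closed-form. For the correlation transform, with
``s_j = prod_{c<j}(1 - x_c^2)`` one has ``L[i,j] = x_j sqrt(s_j)`` and
``dL[i,j]/dx_m = -L[i,j] x_m / (1 - x_m^2)`` for ``m < j`` (``sqrt(s_m)`` at
``m = j``), so the backward pass is a reversed cumulative sum — everything
is vectorized over whole rows. Group gather/scatter goes through
precompiled sparse designs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.special import expit

PRIOR_SD = 2.0  # Normal(0, 2) slopes/intercepts, half-Normal(0, 2) SDs
LKJ_ETA = 2.0


@dataclass
class GroupFactor:
    name: str
    n_levels: int
    family_names: tuple[str, ...]

    @property
    def k(self) -> int:
        return len(self.family_names)

    @property
    def n_corr(self) -> int:
        return self.k * (self.k - 1) // 2


@dataclass
class GroupTerm:
    """One grouping factor's contribution to a linear predictor."""

    factor: int          # index into ModelSpec.factors
    cols: np.ndarray     # (k,) family columns used by this predictor
    X: np.ndarray        # (N, k) covariate per family (1, vtype, ref, ...)
    idx: np.ndarray      # (N,) level index per observation


@dataclass
class Predictor:
    Xf: np.ndarray       # (N, F) fixed-effect design
    terms: list[GroupTerm] = field(default_factory=list)


@dataclass
class BernoulliBlock:
    y: np.ndarray        # (N,) in {0, 1}
    pred: Predictor


@dataclass
class CategoricalBlock:
    """Three-category softmax with the middle category as zero reference."""

    y: np.ndarray        # (N,) in {0: PP, 1: DP, 2: other}
    pred_pp: Predictor
    pred_other: Predictor


@dataclass
class ModelSpec:
    fixed_names: tuple[str, ...]
    fixed_priors: tuple[str, ...]      # 'logistic' | 'normal'
    factors: list[GroupFactor]
    blocks: list

    @property
    def n_fixed(self) -> int:
        return len(self.fixed_names)

    @property
    def dim(self) -> int:
        d = self.n_fixed
        for f in self.factors:
            d += f.n_levels * f.k + f.k + f.n_corr
        return d


class _CompiledPredictor:
    """Sparse N x (n_levels * K) design per factor, plus its transpose."""

    def __init__(self, pred: Predictor, factors: list[GroupFactor]):
        self.Xf = np.ascontiguousarray(pred.Xf)
        self.mats = []  # (factor_index, S, S_T)
        for t in pred.terms:
            f = factors[t.factor]
            n_obs, k = t.X.shape
            rows = np.repeat(np.arange(n_obs), k)
            cols = (t.idx[:, None] * f.k + t.cols[None, :]).ravel()
            S = sparse.csr_matrix(
                (t.X.ravel(), (rows, cols)), shape=(n_obs, f.n_levels * f.k))
            self.mats.append((t.factor, S, S.T.tocsr()))

    def eta(self, theta, B_flat):
        eta = self.Xf @ theta
        for fi, S, _ in self.mats:
            eta += S @ B_flat[fi]
        return eta

    def accumulate(self, r, gf, C_flat):
        gf += r @ self.Xf
        for fi, _, ST in self.mats:
            C_flat[fi] += ST @ r


def compile_spec(spec: ModelSpec):
    """Precompute sparse designs, slices and prior masks; cached on the spec."""
    cache = getattr(spec, "_compiled", None)
    if cache is None:
        blocks = []
        for block in spec.blocks:
            if isinstance(block, BernoulliBlock):
                blocks.append(("bern", block.y,
                               _CompiledPredictor(block.pred, spec.factors)))
            elif isinstance(block, CategoricalBlock):
                blocks.append(("cat", block.y,
                               _CompiledPredictor(block.pred_pp, spec.factors),
                               _CompiledPredictor(block.pred_other, spec.factors)))
            else:  # pragma: no cover - spec construction guards this
                raise TypeError(f"unknown block type {type(block)!r}")
        layout = []
        pos = spec.n_fixed
        for f in spec.factors:
            nz = f.n_levels * f.k
            layout.append((f.n_levels, f.k,
                           slice(pos, pos + nz),
                           slice(pos + nz, pos + nz + f.k),
                           slice(pos + nz + f.k, pos + nz + f.k + f.n_corr)))
            pos += nz + f.k + f.n_corr
        priors = np.asarray(spec.fixed_priors)
        logistic_idx = np.flatnonzero(priors == "logistic")
        normal_idx = np.flatnonzero(priors == "normal")
        cache = (blocks, layout, logistic_idx, normal_idx)
        spec._compiled = cache
    return cache


def unpack(spec: ModelSpec, q: np.ndarray):
    """Split the flat unconstrained vector into (theta, [(Z, t, y), ...])."""
    pos = spec.n_fixed
    theta = q[:pos]
    parts = []
    for f in spec.factors:
        nz = f.n_levels * f.k
        Z = q[pos:pos + nz].reshape(f.n_levels, f.k)
        pos += nz
        t = q[pos:pos + f.k]
        pos += f.k
        y = q[pos:pos + f.n_corr]
        pos += f.n_corr
        parts.append((Z, t, y))
    return theta, parts


_LKJ_CONST: dict[int, tuple] = {}


def _lkj_const(k: int):
    """Per-dimension constants: lower-triangle indices, Jacobian exponents
    ``jc[i, j] = 1 + (i - 1 - j)/2`` and LKJ diagonal coefficients
    ``ci[i] = k - i + 2*eta - 3`` (zero on the first row)."""
    cached = _LKJ_CONST.get(k)
    if cached is None:
        lower = np.tril_indices(k, -1)
        rows = np.arange(k)[:, None]
        cols = np.arange(k)[None, :]
        jc = np.where(cols < rows, 1.0 + (rows - 1 - cols) / 2.0, 0.0)
        ci = np.where(np.arange(k) >= 1,
                      k - np.arange(k) + 2.0 * LKJ_ETA - 3.0, 0.0)
        cached = (lower, jc, ci)
        _LKJ_CONST[k] = cached
    return cached


def _lkj_rows(y: np.ndarray, k: int):
    """Row-matrix form of the partial-correlation transform.

    Returns (X, omx, s, L): X holds tanh(y) on the strict lower triangle,
    ``omx = 1 - X**2``, ``s[i, j] = prod_{c<j} omx[i, c]`` and L is the
    Cholesky factor (unit first row, ``L[i, j] = X[i, j] * sqrt(s[i, j])``,
    diagonal ``sqrt(s[i, i])``).
    """
    X = np.zeros((k, k))
    X[_lkj_const(k)[0]] = np.tanh(y)
    omx = np.maximum(1.0 - X ** 2, 1e-300)
    s = np.empty((k, k))
    s[:, 0] = 1.0
    np.cumprod(omx[:, :-1], axis=1, out=s[:, 1:])
    L = X * np.sqrt(s)
    np.fill_diagonal(L, np.sqrt(np.diagonal(s)))
    return X, omx, s, L


def chol_from_unconstrained(y: np.ndarray, k: int) -> np.ndarray:
    """Cholesky factor of a correlation matrix from canonical partial corrs."""
    if k == 1:
        return np.eye(1)
    if k == 2:
        x = np.tanh(y[0])
        return np.array([[1.0, 0.0], [x, np.sqrt(1.0 - x * x)]])
    return _lkj_rows(y, k)[3]


def _corr_logp_grad(y: np.ndarray, k: int, GL: np.ndarray):
    """LKJ(2) + transform-Jacobian log density and gradient wrt y.

    GL carries d(data logp)/dL on entry (lower triangle including the
    diagonal); the LKJ density's diagonal term is added here.
    """
    if k == 1 or y.size == 0:
        return 0.0, np.zeros(0)
    if k == 2:
        x = np.tanh(y[0])
        # tanh saturates at +/-1 for extreme warmup proposals; floor the
        # complement so the log stays finite (the proposal is then rejected)
        omx = max(1.0 - x * x, 1e-300)
        l11 = np.sqrt(omx)
        logp = 2.0 * np.log(omx)
        gy = omx * GL[1, 0] - x * (GL[1, 1] * l11 + 2.0) - 2.0 * x
        return float(logp), np.array([gy])
    X, omx, s, L = _lkj_rows(y, k)
    lower, jc, ci = _lkj_const(k)
    diag_L = np.diagonal(L)
    logp = float(np.sum(jc[lower] * np.log(omx[lower]))
                 + np.sum(ci[1:] * np.log(diag_L[1:])))
    GLd = np.tril(GL)
    GLd[np.arange(k), np.arange(k)] += ci / diag_L
    A = GLd * L
    revcum = np.cumsum(A[:, ::-1], axis=1)[:, ::-1]
    tail = np.hstack((revcum[:, 1:], np.zeros((k, 1))))
    GY = omx * GLd * np.sqrt(s) - X * tail - 2.0 * X * jc
    return logp, GY[lower]


def logp_grad(spec: ModelSpec, q: np.ndarray):
    """Joint log posterior density (up to a constant) and its gradient."""
    blocks, layout, logistic_idx, normal_idx = compile_spec(spec)
    theta = q[: spec.n_fixed]
    grad = np.zeros_like(q)
    gf = grad[: spec.n_fixed]

    parts, Ls, sigmas, B_flat = [], [], [], []
    for n, k, zsl, tsl, ysl in layout:
        Z = q[zsl].reshape(n, k)
        t = q[tsl]
        y = q[ysl]
        L = chol_from_unconstrained(y, k)
        sig = np.exp(t)
        parts.append((Z, t, y))
        Ls.append(L)
        sigmas.append(sig)
        B_flat.append(((Z @ L.T) * sig).ravel())

    logp = 0.0
    C_flat = [np.zeros_like(b) for b in B_flat]

    for block in blocks:
        if block[0] == "bern":
            _, yv, cp = block
            eta = cp.eta(theta, B_flat)
            logp += float(np.sum(yv * eta - np.logaddexp(0.0, eta)))
            cp.accumulate(yv - expit(eta), gf, C_flat)
        else:
            _, yv, cp_pp, cp_ot = block
            eta_pp = cp_pp.eta(theta, B_flat)
            eta_ot = cp_ot.eta(theta, B_flat)
            H = np.column_stack((eta_pp, np.zeros_like(eta_pp), eta_ot))
            m = H.max(axis=1, keepdims=True)
            E = np.exp(H - m)
            denom = E.sum(axis=1)
            logp += float(np.sum(H[np.arange(H.shape[0]), yv]
                                 - m[:, 0] - np.log(denom)))
            P = E / denom[:, None]
            cp_pp.accumulate((yv == 0) - P[:, 0], gf, C_flat)
            cp_ot.accumulate((yv == 2) - P[:, 2], gf, C_flat)

    # fixed-effect priors (logistic = Beta(1,1) on the probability scale)
    if logistic_idx.size:
        th = theta[logistic_idx]
        logp += float(np.sum(th - 2.0 * np.logaddexp(0.0, th)))
        gf[logistic_idx] += 1.0 - 2.0 * expit(th)
    if normal_idx.size:
        th = theta[normal_idx]
        logp += float(np.sum(-0.5 * th ** 2 / PRIOR_SD ** 2))
        gf[normal_idx] += -th / PRIOR_SD ** 2

    # group parts: chain rule through B = (Z L^T) * sigma plus priors
    for (n, k, zsl, tsl, ysl), (Z, t, y), L, sig, cf in zip(
            layout, parts, Ls, sigmas, C_flat):
        C = cf.reshape(n, k)
        Csig = C * sig
        gZ = Csig @ L
        gsig = np.einsum("nk,nk->k", C, Z @ L.T)
        GL = Csig.T @ Z

        # priors: Z ~ N(0,1); sigma ~ half-N(0,2) with log-Jacobian
        logp += float(-0.5 * np.sum(Z * Z))
        gZ -= Z
        logp += float(np.sum(-0.5 * sig ** 2 / PRIOR_SD ** 2 + t))
        grad[tsl] = sig * gsig - sig ** 2 / PRIOR_SD ** 2 + 1.0

        lp_corr, gy = _corr_logp_grad(y, k, GL)
        logp += lp_corr
        grad[zsl] = gZ.ravel()
        grad[ysl] = gy

    return logp, grad


def constrain(spec: ModelSpec, q: np.ndarray):
    """Constrained view of one draw: fixed effects, SDs, correlations, B."""
    theta, parts = unpack(spec, q)
    out = {"fixed": dict(zip(spec.fixed_names, theta))}
    out["factors"] = []
    for f, (Z, t, y) in zip(spec.factors, parts):
        L = chol_from_unconstrained(y, f.k)
        sig = np.exp(t)
        out["factors"].append(
            {"name": f.name, "sd": sig, "chol": L, "corr": L @ L.T,
             "B": (Z @ L.T) * sig}
        )
    return out
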