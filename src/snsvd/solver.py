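"""Rank-one sparse network-regularized SVD solver.

The model for a data matrix X (p x n) is

    minimize_{u,v,d}  ||X - d u v^T||_F^2
    subject to        ||u||_2 <= 1,  lambda ||u||_1 + sigma u^T L u <= c1,
                      ||v||_2 <= 1,  ||v||_0 <= k_v,

worked in its Lagrangian form

    F(u, v) = -u^T X v + lambda ||u||_1 + sigma u^T L u,

where L is the normalized Laplacian of a prior gene network.  The
solver alternates:

* a u-step: cyclic (Gauss-Seidel) coordinate descent with the
  network-smoothed soft-thresholding update
  ``u_j <- S(z_j + sigma * W_j u, lambda)`` where ``z = X v`` and
  ``W = D^{-1/2} A D^{-1/2}``, followed by L2 normalization;
* a v-step: keep the k_v entries of ``z_v = X^T u`` with largest
  magnitude, zero the rest, normalize (the exact L0-constrained
  minimizer).

The coordinate fixed-point map is contractive only for sigma < 1
(||W||_2 <= 1); to keep F monotone at any sigma the outer loop applies
a safeguard: whenever the coordinate-descent candidate fails to lower
the u-subproblem objective, the same convex subproblem is re-solved by
projected proximal gradient, which decreases it by construction.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .graph import LaplacianPair
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

_SCALE_CAP = 1e100  # bail out of diverging inner sweeps before overflow


@dataclass
class SolverConfig:
    """Tunable knobs of the rank-one solver.

    lambda_ : L1 weight on the gene loading u (>= 0).
    sigma   : network-Laplacian weight (>= 0).
    k_v     : sample-side cardinality bound, ``||v||_0 <= k_v``
              (``None`` means no truncation, k_v = n).
    max_outer_iters / outer_tol : alternating-loop budget and stopping
              threshold on ``max(||u_t - u_{t-1}||, ||v_t - v_{t-1}||)``.
    max_inner_sweeps / inner_tol : coordinate-descent budget per u-step;
              a sweep stops when the largest coordinate change, relative
              to the sup-norm of the iterate, falls below ``inner_tol``.
    """

    lambda_: float = 0.0
    sigma: float = 0.0
    k_v: int | None = None
    max_outer_iters: int = 200
    outer_tol: float = 1e-6
    max_inner_sweeps: int = 50
    inner_tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_ < 0 or self.sigma < 0:
            raise ValueError("lambda_ and sigma must be nonnegative")
        if self.k_v is not None and self.k_v < 1:
            raise ValueError("k_v must be a positive integer")


@dataclass
class FactorPair:
    """One sparse singular triplet (u, v, d) with solver diagnostics."""

    u: np.ndarray
    v: np.ndarray
    d: float
    n_iters: int = 0
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = False
    degenerate: bool = False

    @property
    def nnz_u(self) -> int:
        return int(np.count_nonzero(self.u))

    @property
    def nnz_v(self) -> int:
        return int(np.count_nonzero(self.v))


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, ExpressionMatrix):
        return X.values
    return np.asarray(X, dtype=float)


def soft_threshold(a, lambda_: float):
    """S(a, lambda) = sign(a) (|a| - lambda)_+ (elementwise on arrays)."""
    if lambda_ < 0:
        raise ValueError("threshold must be nonnegative")
    a = np.asarray(a, dtype=float)
    out = np.sign(a) * np.maximum(np.abs(a) - lambda_, 0.0)
    return float(out) if out.ndim == 0 else out


# -- inner coordinate-descent sweeps -----------------------------------------

def _gs_sweeps_python(indptr, indices, data, z, lam, sigma, u, max_sweeps, tol):
    """Pure-NumPy Gauss-Seidel sweeps; same update order as the JIT kernel."""
    p = z.shape[0]
    for sweep in range(max_sweeps):
        scale = max(np.max(np.abs(u)), 1e-300)
        max_change = 0.0
        for j in range(p):
            lo, hi = indptr[j], indptr[j + 1]
            acc = np.dot(data[lo:hi], u[indices[lo:hi]]) if hi > lo else 0.0
            a = z[j] + sigma * acc
            if a > lam:
                new = a - lam
            elif a < -lam:
                new = a + lam
            else:
                new = 0.0
            change = abs(new - u[j])
            if change > max_change:
                max_change = change
            u[j] = new
        if max_change / scale < tol:
            return sweep + 1
        if np.max(np.abs(u)) > _SCALE_CAP:
            return sweep + 1
    return max_sweeps


_gs_sweeps_jit = None


def _get_gs_kernel():
    """Compile the sweep kernel with numba when available."""
    global _gs_sweeps_jit
    if _gs_sweeps_jit is not None:
        return _gs_sweeps_jit
    try:
        from numba import njit
    except ImportError:  # pragma: no cover - numba is an optional extra
        _gs_sweeps_jit = _gs_sweeps_python
        return _gs_sweeps_jit

    @njit(cache=True)
    def kernel(indptr, indices, data, z, lam, sigma, u, max_sweeps, tol):
        p = z.shape[0]
        for sweep in range(max_sweeps):
            scale = 1e-300
            for j in range(p):
                if abs(u[j]) > scale:
                    scale = abs(u[j])
            max_change = 0.0
            biggest = 0.0
            for j in range(p):
                acc = 0.0
                for idx in range(indptr[j], indptr[j + 1]):
                    acc += data[idx] * u[indices[idx]]
                a = z[j] + sigma * acc
                if a > lam:
                    new = a - lam
                elif a < -lam:
                    new = a + lam
                else:
                    new = 0.0
                change = abs(new - u[j])
                if change > max_change:
                    max_change = change
                u[j] = new
                if abs(new) > biggest:
                    biggest = abs(new)
            if max_change / scale < tol:
                return sweep + 1
            if biggest > 1e100:
                return sweep + 1
        return max_sweeps

    _gs_sweeps_jit = kernel
    return _gs_sweeps_jit


def update_u(
    X,
    v: np.ndarray,
    lap: LaplacianPair | None,
    lambda_: float,
    sigma: float,
    u_init: np.ndarray,
    max_sweeps: int = 50,
    tol: float = 1e-6,
    return_info: bool = False,
):
    """One u-step: Gauss-Seidel coordinate descent on the u-subproblem.

    Computes ``z = X v`` then sweeps ``u_j <- S(z_j + sigma W_j u,
    lambda)`` in fixed index order, each update seeing the newest
    coordinates, and returns the L2-normalized result.  If every
    coordinate thresholds to zero the zero vector is returned and
    flagged degenerate (``info["degenerate"]``) rather than raising.

    With ``return_info=True`` also returns a dict with the unnormalized
    fixed-point iterate (``u_raw``), sweep count and degeneracy flag.
    """
    Xm = _as_matrix(X)
    z = Xm @ np.asarray(v, dtype=float)
    u = np.array(u_init, dtype=float).ravel().copy()
    if u.shape[0] != Xm.shape[0]:
        raise ValueError("u_init length does not match the number of rows")
    if sigma > 0 and lap is not None:
        w = lap.W.tocsr()
        kernel = _get_gs_kernel()
        sweeps = kernel(
            w.indptr, w.indices, w.data, z, float(lambda_), float(sigma),
            u, int(max_sweeps), float(tol),
        )
        u_raw = u
    else:
        # sigma = 0 (or no network): the sweep decouples and converges in one pass
        u_raw = soft_threshold(z, lambda_)
        sweeps = 1
    nrm = float(np.linalg.norm(u_raw))
    degenerate = not (nrm > 0 and np.isfinite(nrm))
    u_unit = np.zeros_like(u_raw) if degenerate else u_raw / nrm
    if return_info:
        return u_unit, {"u_raw": u_raw, "sweeps": sweeps, "degenerate": degenerate}
    return u_unit


def update_v(X, u: np.ndarray, k_v: int, return_info: bool = False):
    """One v-step: L0 projection of ``z_v = X^T u`` onto the top k_v entries.

    Ties at the k_v-th order statistic are broken toward the smallest
    index (stable sort), making the result deterministic.
    """
    Xm = _as_matrix(X)
    n = Xm.shape[1]
    if not 1 <= k_v <= n:
        raise ValueError(f"k_v must be in [1, {n}], got {k_v}")
    z_v = Xm.T @ np.asarray(u, dtype=float)
    order = np.argsort(-np.abs(z_v), kind="stable")
    keep = order[:k_v]
    v = np.zeros(n)
    v[keep] = z_v[keep]
    nrm = float(np.linalg.norm(v))
    degenerate = nrm == 0.0
    if not degenerate:
        v /= nrm
    if return_info:
        return v, {"degenerate": degenerate}
    return v


# -- objective and the monotone safeguard ------------------------------------

def lagrangian_objective(X, u, v, lambda_, sigma, lap: LaplacianPair | None) -> float:
    """F(u, v) = -u^T X v + lambda ||u||_1 + sigma u^T L u."""
    Xm = _as_matrix(X)
    val = -float(u @ (Xm @ v)) + lambda_ * float(np.abs(u).sum())
    if sigma > 0 and lap is not None:
        val += sigma * float(u @ (lap.L @ u))
    return val


def _u_subobjective(z, u, lambda_, sigma, lap) -> float:
    val = -float(u @ z) + lambda_ * float(np.abs(u).sum())
    if sigma > 0 and lap is not None:
        val += sigma * float(u @ (lap.L @ u))
    return val


def _prox_l1_ball(x: np.ndarray, lam: float) -> np.ndarray:
    """prox of lam||.||_1 + indicator(||.||_2 <= 1): soft-threshold, then
    radially project onto the unit ball."""
    s = np.sign(x) * np.maximum(np.abs(x) - lam, 0.0)
    nrm = float(np.linalg.norm(s))
    return s / nrm if nrm > 1.0 else s


def _ista_u(z, lap, lambda_, sigma, u0, max_iter=500, tol=1e-12) -> np.ndarray:
    """Projected proximal gradient on the convex u-subproblem.

    Minimizes ``-u.z + sigma u^T L u + lambda ||u||_1`` over the unit
    ball; with step 1/Lip (Lip <= 4 sigma since eig(L) <= 2) each step
    is guaranteed not to increase the objective.
    """
    u = np.array(u0, dtype=float)
    nrm = float(np.linalg.norm(u))
    if nrm > 1.0:
        u /= nrm
    step = 1.0 / (4.0 * sigma + 1e-12)
    for _ in range(max_iter):
        grad = -z + 2.0 * sigma * (lap.L @ u)
        u_new = _prox_l1_ball(u - step * grad, step * lambda_)
        if float(np.max(np.abs(u_new - u))) < tol:
            u = u_new
            break
        u = u_new
    return u


def _zero_factor(p: int, n: int, trace) -> FactorPair:
    return FactorPair(
        u=np.zeros(p),
        v=np.zeros(n),
        d=0.0,
        n_iters=len(trace),
        objective_trace=np.asarray(trace, dtype=float),
        converged=False,
        degenerate=True,
    )


def solve_rank_one(
    X,
    lap: LaplacianPair | None,
    cfg: SolverConfig,
    u0: np.ndarray,
    v0: np.ndarray,
) -> FactorPair:
    """Alternating minimization for one sparse network-regularized triplet.

    Starting from normalized ``u0, v0``, alternates :func:`update_u`
    and :func:`update_v` until the larger of the two iterate changes
    drops below ``cfg.outer_tol`` or ``cfg.max_outer_iters`` is reached.
    ``F(u, v)`` is recorded at the start and after every outer
    iteration; a safeguarded u-step keeps the trace non-increasing.
    Returns a flagged zero :class:`FactorPair` if either loading
    collapses to zero (e.g. lambda_ beyond the thresholding bound).
    """
    Xm = _as_matrix(X)
    p, n = Xm.shape
    k_v = n if cfg.k_v is None else int(cfg.k_v)
    if not 1 <= k_v <= n:
        raise ValueError(f"k_v must be in [1, {n}]")
    u = np.asarray(u0, dtype=float).ravel().copy()
    v = np.asarray(v0, dtype=float).ravel().copy()
    if u.shape[0] != p or v.shape[0] != n:
        raise ValueError("initial vectors do not match the matrix shape")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("initial vectors must be nonzero")
    u /= nu
    v /= nv

    trace = [lagrangian_objective(Xm, u, v, cfg.lambda_, cfg.sigma, lap)]
    converged = False
    it = 0
    for it in range(1, cfg.max_outer_iters + 1):
        u_prev, v_prev = u, v
        z = Xm @ v
        u_cand, info = update_u(
            Xm, v, lap, cfg.lambda_, cfg.sigma, u,
            max_sweeps=cfg.max_inner_sweeps, tol=cfg.inner_tol,
            return_info=True,
        )
        if info["degenerate"]:
            return _zero_factor(p, n, trace)
        if cfg.sigma > 0 and lap is not None:
            # Monotone safeguard: accept the coordinate-descent candidate
            # only if it lowers the u-subproblem objective; otherwise fall
            # back to the provably descending proximal-gradient solve.
            f_prev = _u_subobjective(z, u, cfg.lambda_, cfg.sigma, lap)
            f_cand = _u_subobjective(z, u_cand, cfg.lambda_, cfg.sigma, lap)
            if not f_cand <= f_prev + 1e-12 * max(1.0, abs(f_prev)):
                u_ista = _ista_u(z, lap, cfg.lambda_, cfg.sigma, u)
                f_ista = _u_subobjective(z, u_ista, cfg.lambda_, cfg.sigma, lap)
                u_cand = u_ista if f_ista < f_cand else u_cand
                if _u_subobjective(z, u_cand, cfg.lambda_, cfg.sigma, lap) > f_prev:
                    u_cand = u_prev  # keep the previous iterate; v-step may still improve
                if float(np.linalg.norm(u_cand)) == 0.0:
                    return _zero_factor(p, n, trace)
        u = u_cand
        v, vinfo = update_v(Xm, u, k_v, return_info=True)
        if vinfo["degenerate"]:
            return _zero_factor(p, n, trace)
        trace.append(lagrangian_objective(Xm, u, v, cfg.lambda_, cfg.sigma, lap))
        delta = max(
            float(np.linalg.norm(u - u_prev)), float(np.linalg.norm(v - v_prev))
        )
        if delta < cfg.outer_tol:
            converged = True
            break

    nrm_u = float(np.linalg.norm(u))
    if nrm_u == 0.0:
        return _zero_factor(p, n, trace)
    u_out = u / nrm_u  # report the direction when the safeguard left ||u|| < 1
    d = float(u_out @ (Xm @ v))
    if d < 0:  # sign convention: flip v so the singular value is nonnegative
        v = -v
        d = -d
    return FactorPair(
        u=u_out,
        v=v,
        d=d,
        n_iters=it,
        objective_trace=np.asarray(trace, dtype=float),
        converged=converged,
        degenerate=False,
    )


def l0svd_rank_one(
    X,
    k_u: int,
    k_v: int,
    u0: np.ndarray,
    v0: np.ndarray,
    max_outer_iters: int = 200,
    outer_tol: float = 1e-6,
) -> FactorPair:
    """Plain L0-constrained sparse SVD (no network term).

    Alternates hard-thresholded power steps: keep the k_u largest-|.|
    entries of ``X v`` and the k_v largest of ``X^T u``, normalizing
    each time.  This is the network-free baseline the full model
    reduces to, with the same cardinality projection applied to both
    sides.
    """
    Xm = _as_matrix(X)
    p, n = Xm.shape
    if not (1 <= k_u <= p and 1 <= k_v <= n):
        raise ValueError("cardinalities out of range")
    u = np.asarray(u0, dtype=float).ravel() / np.linalg.norm(u0)
    v = np.asarray(v0, dtype=float).ravel() / np.linalg.norm(v0)
    trace = [-float(u @ (Xm @ v))]
    converged = False
    it = 0

    def top_k(zv: np.ndarray, k: int) -> np.ndarray:
        order = np.argsort(-np.abs(zv), kind="stable")
        out = np.zeros_like(zv)
        out[order[:k]] = zv[order[:k]]
        return out

    for it in range(1, max_outer_iters + 1):
        u_prev, v_prev = u, v
        zu = top_k(Xm @ v, k_u)
        nrm = float(np.linalg.norm(zu))
        if nrm == 0.0:
            return _zero_factor(p, n, trace)
        u = zu / nrm
        zv = top_k(Xm.T @ u, k_v)
        nrm = float(np.linalg.norm(zv))
        if nrm == 0.0:
            return _zero_factor(p, n, trace)
        v = zv / nrm
        trace.append(-float(u @ (Xm @ v)))
        if max(np.linalg.norm(u - u_prev), np.linalg.norm(v - v_prev)) < outer_tol:
            converged = True
            break
    d = float(u @ (Xm @ v))
    if d < 0:
        v, d = -v, -d
    return FactorPair(
        u=u, v=v, d=d, n_iters=it,
        objective_trace=np.asarray(trace, dtype=float),
        converged=converged, degenerate=False,
    )
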