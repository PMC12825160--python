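"""Pathwise coordinate descent on the Gram system, for Lasso and MCP.

All solvers work on the sufficient statistics ``G = X'X/n`` and
``c = X'y/n`` rather than the raw design, which makes cross-validated and
node-wise fits cheap: fold Grams are computed once and sliced, and
held-out error is a quadratic form in the coefficients.  Kernels are
numba-compiled; the ``gamma`` argument selects the penalty (``gamma <= 0``
is the Lasso, ``gamma > 1`` the minimax concave penalty, whose univariate
solution is flat beyond ``gamma * lambda``).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["cd_path_gram", "cv_error_path", "nodewise_coefficients", "make_folds"]


@njit(cache=True)
def _univariate(z: float, v: float, lam: float, gamma: float) -> float:
    """Minimiser of 0.5*v*b**2 - z*b + rho(b; lam, gamma).

    For the MCP (gamma > 1) the solution is the firm-thresholding rule:
    soft(z, lam)/(v - 1/gamma) inside ``|z| <= gamma*lam*v``, the
    unpenalised z/v beyond.  gamma <= 0 selects the Lasso.
    """
    if v <= 0.0:
        return 0.0
    if lam <= 0.0:
        return z / v
    az = abs(z)
    if gamma > 0.0:
        if az <= gamma * lam * v:
            t = az - lam
            if t <= 0.0:
                return 0.0
            denom = v - 1.0 / gamma
            return (t / denom) if z > 0 else (-t / denom)
        return z / v
    t = az - lam
    if t <= 0.0:
        return 0.0
    return (t / v) if z > 0 else (-t / v)


@njit(cache=True)
def _cd_path(G, c, alphas, gamma, penalty, tol, max_iter, B, iters):
    d = c.shape[0]
    b = np.zeros(d)
    r = c.copy()  # r = c - G @ b, maintained incrementally
    for k in range(alphas.shape[0]):
        lam = alphas[k]
        it = 0
        converged = False
        while it < max_iter:
            it += 1
            max_delta = 0.0
            for j in range(d):
                v = G[j, j]
                z = r[j] + v * b[j]
                bj = _univariate(z, v, lam * penalty[j], gamma)
                db = bj - b[j]
                if db != 0.0:
                    b[j] = bj
                    for i in range(d):
                        r[i] -= G[i, j] * db
                    if abs(db) > max_delta:
                        max_delta = abs(db)
            if max_delta < tol:
                converged = True
                break
        iters[k] = it if converged else -1
        for j in range(d):
            B[k, j] = b[j]


def cd_path_gram(
    G: np.ndarray,
    c: np.ndarray,
    alphas: np.ndarray,
    gamma: float = -1.0,
    penalty: np.ndarray | None = None,
    tol: float = 1e-7,
    max_iter: int = 10_000,
) -> np.ndarray:
    """Coefficient path along ``alphas`` (decreasing), warm-started.

    Raises on non-convergence, reporting the offending penalty level.
    """
    G = np.ascontiguousarray(G, dtype=np.float64)
    c = np.ascontiguousarray(c, dtype=np.float64)
    alphas = np.ascontiguousarray(alphas, dtype=np.float64)
    d = c.shape[0]
    if penalty is None:
        penalty = np.ones(d)
    penalty = np.ascontiguousarray(penalty, dtype=np.float64)
    B = np.empty((alphas.shape[0], d))
    iters = np.empty(alphas.shape[0], dtype=np.int64)
    _cd_path(G, c, alphas, gamma, penalty, tol, max_iter, B, iters)
    if np.any(iters < 0):
        k = int(np.argmax(iters < 0))
        raise RuntimeError(
            f"coordinate descent did not converge at penalty level "
            f"alpha={alphas[k]:.3e} (index {k}) within {max_iter} sweeps"
        )
    return B


@njit(cache=True)
def _cv_errors(G_tr, c_tr, G_te, c_te, yy_te, alphas, gamma, penalty,
               tol, max_iter, errs):
    """Held-out squared error along the path for one fold (Gram form)."""
    d = c_tr.shape[0]
    K = alphas.shape[0]
    B = np.empty((K, d))
    iters = np.empty(K, dtype=np.int64)
    _cd_path(G_tr, c_tr, alphas, gamma, penalty, tol, max_iter, B, iters)
    nz = np.empty(d, dtype=np.int64)
    for k in range(K):
        # ||y - Xb||^2/n_te = yy - 2 b'c + b'G b, using only active coords
        m = 0
        for j in range(d):
            if B[k, j] != 0.0:
                nz[m] = j
                m += 1
        quad = 0.0
        lin = 0.0
        for a in range(m):
            j = nz[a]
            bj = B[k, j]
            lin += bj * c_te[j]
            gb = 0.0
            for b_ in range(m):
                i = nz[b_]
                gb += G_te[j, i] * B[k, i]
            quad += bj * gb
        errs[k] = yy_te - 2.0 * lin + quad


def make_folds(n: int, n_folds: int, seed: int) -> np.ndarray:
    """Deterministic fold labels in 0..n_folds-1 (seeded permutation)."""
    rng = np.random.default_rng(seed)
    labels = np.tile(np.arange(n_folds), n // n_folds + 1)[:n]
    return labels[rng.permutation(n)]


def cv_error_path(
    X: np.ndarray,
    y: np.ndarray,
    alphas: np.ndarray,
    folds: np.ndarray,
    gamma: float = -1.0,
    penalty: np.ndarray | None = None,
    tol: float = 1e-7,
    max_iter: int = 10_000,
) -> np.ndarray:
    """Mean held-out squared error along ``alphas`` over the given folds."""
    n, d = X.shape
    if penalty is None:
        penalty = np.ones(d)
    n_folds = int(folds.max()) + 1
    errs = np.zeros((n_folds, alphas.shape[0]))
    buf = np.empty(alphas.shape[0])
    for f in range(n_folds):
        te = folds == f
        tr = ~te
        Xtr, Xte = X[tr], X[te]
        ytr, yte = y[tr], y[te]
        G_tr = Xtr.T @ Xtr / len(ytr)
        c_tr = Xtr.T @ ytr / len(ytr)
        G_te = Xte.T @ Xte / len(yte)
        c_te = Xte.T @ yte / len(yte)
        _cv_errors(
            np.ascontiguousarray(G_tr), c_tr,
            np.ascontiguousarray(G_te), c_te,
            float(yte @ yte / len(yte)),
            np.ascontiguousarray(alphas, dtype=np.float64), gamma,
            np.ascontiguousarray(penalty, dtype=np.float64),
            tol, max_iter, buf,
        )
        errs[f] = buf
    return errs.mean(axis=0)


@njit(cache=True)
def _cd_one(G, c, b, r, lam, penalty, tol, max_iter):
    """Lasso coordinate descent at one lambda, warm-started in place.

    ``r = c - G b`` is maintained by the caller across lambdas.
    Returns the sweep count, or -1 on non-convergence.
    """
    d = c.shape[0]
    it = 0
    while it < max_iter:
        it += 1
        max_delta = 0.0
        for j in range(d):
            v = G[j, j]
            z = r[j] + v * b[j]
            bj = _univariate(z, v, lam * penalty[j], -1.0)
            db = bj - b[j]
            if db != 0.0:
                b[j] = bj
                for i in range(d):
                    r[i] -= G[i, j] * db
                if abs(db) > max_delta:
                    max_delta = abs(db)
        if max_delta < tol:
            return it
    return -1


@njit(cache=True)
def _nodewise(G, G_folds, fold_sizes, n_alphas, alpha_ratio,
              tol, max_iter, Gamma, tau2, lam_sel):
    """Node-wise Lasso of each column on the rest, CV-tuned, Gram form.

    G is the full-sample Gram (d x d); G_folds stacks per-fold Grams.
    Folds advance in lockstep along the lambda path and the path stops
    early once the CV error has not improved for several steps, so the
    dense small-lambda tail is never solved.  Writes the coefficient
    matrix Gamma (row j = gamma_j, zero at j), tau2[j] =
    ||X_j - X_{-j}g||^2/n + lam*||g||_1, and the selected lambda.
    """
    d = G.shape[0]
    F = G_folds.shape[0]
    m = d - 1
    stall_limit = 5
    n_total = 0.0
    for f in range(F):
        n_total += fold_sizes[f]

    subs_tr = np.empty((F, m, m))
    cs_tr = np.empty((F, m))
    subs_te = np.empty((F, m, m))
    cs_te = np.empty((F, m))
    b_f = np.empty((F, m))
    r_f = np.empty((F, m))
    sub_tr = np.empty((m, m))
    c_tr = np.empty(m)
    alphas = np.empty(n_alphas)
    errs = np.empty(n_alphas)
    B = np.empty((n_alphas, m))
    iters = np.empty(n_alphas, dtype=np.int64)
    penalty = np.ones(m)
    idx = np.empty(m, dtype=np.int64)
    nz = np.empty(m, dtype=np.int64)

    for j in range(d):
        k = 0
        for i in range(d):
            if i != j:
                idx[k] = i
                k += 1
        cmax = 0.0
        for a in range(m):
            ca = G[idx[a], j]
            c_tr[a] = ca
            if abs(ca) > cmax:
                cmax = abs(ca)
        if cmax <= 0.0:
            for a in range(m):
                Gamma[j, idx[a]] = 0.0
            tau2[j] = G[j, j]
            lam_sel[j] = 0.0
            continue
        lmax = cmax
        lmin = lmax * alpha_ratio
        step = (np.log(lmax) - np.log(lmin)) / (n_alphas - 1)
        for k in range(n_alphas):
            alphas[k] = np.exp(np.log(lmax) - step * k)

        for f in range(F):
            w_te = fold_sizes[f] / n_total
            w_tr = 1.0 - w_te
            for a in range(m):
                ia = idx[a]
                cs_te[f, a] = G_folds[f, ia, j]
                cs_tr[f, a] = (G[ia, j] - w_te * cs_te[f, a]) / w_tr
                for b_ in range(m):
                    ib = idx[b_]
                    subs_te[f, a, b_] = G_folds[f, ia, ib]
                    subs_tr[f, a, b_] = (G[ia, ib] - w_te * subs_te[f, a, b_]) / w_tr
                b_f[f, a] = 0.0
                r_f[f, a] = cs_tr[f, a]

        best = 0
        stall = 0
        n_done = 0
        for k in range(n_alphas):
            err_k = 0.0
            for f in range(F):
                w_te = fold_sizes[f] / n_total
                _cd_one(subs_tr[f], cs_tr[f], b_f[f], r_f[f], alphas[k],
                        penalty, tol, max_iter)
                mz = 0
                for a in range(m):
                    if b_f[f, a] != 0.0:
                        nz[mz] = a
                        mz += 1
                quad = 0.0
                lin = 0.0
                for a_ in range(mz):
                    a = nz[a_]
                    ba = b_f[f, a]
                    lin += ba * cs_te[f, a]
                    gb = 0.0
                    for b__ in range(mz):
                        b_ = nz[b__]
                        gb += subs_te[f, a, b_] * b_f[f, b_]
                    quad += ba * gb
                err_k += (G_folds[f, j, j] - 2.0 * lin + quad) * w_te
            errs[k] = err_k
            n_done = k + 1
            if k == 0 or err_k < errs[best] - 1e-12:
                best = k
                stall = 0
            else:
                stall += 1
                if stall >= stall_limit:
                    break
        lam = alphas[best]
        # final fit on the full sample at the selected lambda
        for a in range(m):
            c_tr[a] = G[idx[a], j]
            for b_ in range(m):
                sub_tr[a, b_] = G[idx[a], idx[b_]]
        _cd_path(sub_tr, c_tr, alphas[: best + 1], -1.0, penalty,
                 tol, max_iter, B, iters)
        l1 = 0.0
        fit_lin = 0.0
        fit_quad = 0.0
        for a in range(m):
            g = B[best, a]
            Gamma[j, idx[a]] = g
            if g != 0.0:
                l1 += abs(g)
                fit_lin += g * c_tr[a]
                gb = 0.0
                for b_ in range(m):
                    if B[best, b_] != 0.0:
                        gb += sub_tr[a, b_] * B[best, b_]
                fit_quad += g * gb
        tau2[j] = G[j, j] - 2.0 * fit_lin + fit_quad + lam * l1
        lam_sel[j] = lam


def nodewise_coefficients(
    X: np.ndarray,
    folds: np.ndarray,
    n_alphas: int = 50,
    alpha_ratio: float = 0.01,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """CV-tuned node-wise Lasso for every column of X.

    Returns ``(Gamma, tau2, lambdas)`` where row j of Gamma holds the
    coefficients of column j regressed on the others (zero at j), and
    ``tau2`` the corresponding regularised residual scales used to form
    the relaxed inverse of the sample covariance.
    """
    n, d = X.shape
    if d < 2:
        raise ValueError("node-wise regression needs at least two columns")
    n_folds = int(folds.max()) + 1
    G = X.T @ X / n
    G_folds = np.empty((n_folds, d, d))
    fold_sizes = np.empty(n_folds)
    for f in range(n_folds):
        Xf = X[folds == f]
        fold_sizes[f] = len(Xf)
        G_folds[f] = Xf.T @ Xf / len(Xf)
    Gamma = np.zeros((d, d))
    tau2 = np.empty(d)
    lam_sel = np.empty(d)
    _nodewise(
        np.ascontiguousarray(G), np.ascontiguousarray(G_folds),
        fold_sizes, n_alphas, alpha_ratio,
        tol, max_iter, Gamma, tau2, lam_sel,
    )
    if np.any(tau2 <= 0):
        k = int(np.argmax(tau2 <= 0))
        raise RuntimeError(f"node-wise regression failed on column {k}")
    return Gamma, tau2, lam_sel
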