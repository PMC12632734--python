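"""Batched L1-regularized logistic regression.

Leave-one-trial-out decoding with label-shuffle nulls solves tens of
thousands of tiny lasso-logistic problems that differ only in one dropped
trial or a permuted label vector.  Fitting them one at a time through a
generic estimator wastes almost all its time on per-call overhead, so this
module runs a compiled second-order coordinate descent (the GLMNET-style
update liblinear itself uses) over the whole batch, warm-starting every
leave-one-out fold from the all-trial solution of the same problem — which
cuts the fold solves to a couple of epochs since dropping one of n trials
barely moves the optimum.

The objective per problem matches the liblinear primal used by
``LogisticRegression(penalty="l1", solver="liblinear")``:

    min_w  ||w||_1 + C * sum_i log(1 + exp(-y_i x_i . w))

with the intercept as an appended constant column (and therefore penalized,
exactly as liblinear treats it with ``intercept_scaling=1``).  A unit test
cross-checks held-out margins against liblinear.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy.special import expit


@njit(cache=True)
def _objective(y, m, w, C):
    obj = 0.0
    for i in range(len(m)):
        ym = -y[i] * m[i]
        # log(1 + exp(ym)) computed stably
        if ym > 30.0:
            obj += ym
        else:
            obj += np.log(1.0 + np.exp(ym))
    obj *= C
    for j in range(len(w)):
        obj += abs(w[j])
    return obj


@njit(cache=True)
def _glmnet_one(Xt, y, C, w, m, max_outer, max_inner, tol):
    """One lasso-logistic problem by outer Newton steps with inner
    coordinate descent on the quadratic model (newGLMNET), updating the
    weight vector ``w`` and margins ``m`` in place.

    ``Xt`` is the transposed design (f, n) so every inner scan over
    observations is contiguous."""
    f, n = Xt.shape
    qC = np.empty(n)
    d = np.empty(n)
    r = np.empty(n)
    H = np.empty(f)
    delta = np.empty(f)
    for _ in range(max_outer):
        obj0 = _objective(y, m, w, C)
        for i in range(n):
            p = 1.0 / (1.0 + np.exp(y[i] * m[i]))  # sigma(-y m)
            qC[i] = -C * y[i] * p
            d[i] = C * p * (1.0 - p) + 1e-10
        for j in range(f):
            h = 1e-12
            for i in range(n):
                h += d[i] * Xt[j, i] * Xt[j, i]
            H[j] = h
        for j in range(f):
            delta[j] = 0.0
        for i in range(n):
            r[i] = 0.0
        active = np.ones(f, dtype=np.bool_)
        for ep in range(max_inner):
            maxd = 0.0
            for j in range(f):
                if not active[j]:
                    continue
                g = 0.0
                for i in range(n):
                    g += Xt[j, i] * (qC[i] + d[i] * r[i])
                wj = w[j] + delta[j]
                u = H[j] * wj - g
                if u > 1.0:
                    wn = (u - 1.0) / H[j]
                elif u < -1.0:
                    wn = (u + 1.0) / H[j]
                else:
                    wn = 0.0
                dd = wn - wj
                if dd != 0.0:
                    delta[j] += dd
                    for i in range(n):
                        r[i] += Xt[j, i] * dd
                    ad = abs(dd)
                    if ad > maxd:
                        maxd = ad
                elif ep == 0 and wn == 0.0 and wj == 0.0:
                    # zero coordinate satisfying the KKT condition: skip it
                    # in later epochs of this quadratic subproblem
                    active[j] = False
            if maxd < 0.5 * tol:
                break
        step_max = 0.0
        for j in range(f):
            if abs(delta[j]) > step_max:
                step_max = abs(delta[j])
        if step_max == 0.0:
            break
        # backtracking line search on the true objective (r holds X @ delta)
        step = 1.0
        accepted = False
        while step > 1e-6:
            obj1 = 0.0
            for i in range(n):
                ym = -y[i] * (m[i] + step * r[i])
                if ym > 30.0:
                    obj1 += ym
                else:
                    obj1 += np.log(1.0 + np.exp(ym))
            obj1 *= C
            for j in range(f):
                obj1 += abs(w[j] + step * delta[j])
            if obj1 <= obj0 + 1e-12:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        for j in range(f):
            if delta[j] != 0.0:
                w[j] += step * delta[j]
        for i in range(n):
            m[i] += step * r[i]
        if step * step_max < tol:
            break
    return w


@njit(cache=True)
def _cd_many(Xt, Y, C, W, max_outer, tol):
    """Xt: (B, f, n); Y: (B, n, S); W: (B, f, S) solved in place."""
    B, f, n = Xt.shape
    S = Y.shape[2]
    m = np.empty(n)
    for b in range(B):
        for s in range(S):
            w = W[b, :, s].copy()
            for i in range(n):
                acc = 0.0
                for j in range(f):
                    if w[j] != 0.0:
                        acc += Xt[b, j, i] * w[j]
                m[i] = acc
            _glmnet_one(Xt[b], Y[b, :, s], C, w, m, max_outer, 8, tol)
            W[b, :, s] = w


def lasso_logistic_batch(
    X: np.ndarray,
    Y: np.ndarray,
    C: float,
    max_outer: int = 100,
    tol: float = 1e-6,
    W0: np.ndarray | None = None,
) -> np.ndarray:
    """Solve B x S lasso-logistic problems.

    ``X`` (B, n, f) holds B designs (intercept column already appended by the
    caller); ``Y`` (B, n, S) holds S label vectors in {-1, +1} per design.
    ``tol`` bounds the largest accepted Newton-step coordinate change.
    Returns weights (B, f, S).
    """
    Xt = np.ascontiguousarray(np.transpose(X, (0, 2, 1)), dtype=np.float64)
    Y = np.ascontiguousarray(Y, dtype=np.float64)
    W = np.zeros((Xt.shape[0], Xt.shape[1], Y.shape[2])) if W0 is None else W0.copy()
    _cd_many(Xt, Y, float(C), W, max_outer, float(tol))
    return W


def append_intercept(X: np.ndarray) -> np.ndarray:
    """Add the constant column liblinear uses for its (penalized) intercept."""
    ones = np.ones(X.shape[:-1] + (1,))
    return np.concatenate([X, ones], axis=-1)


def loo_margins(
    X: np.ndarray,
    Y: np.ndarray,
    C: float,
    tol: float = 1e-6,
    cross_temporal: bool = False,
) -> np.ndarray:
    """Leave-one-out decision margins for every (label set, trial, bin).

    ``X``: (n_trials, f, n_bins) features (no intercept column);
    ``Y``: (S, n_trials) labels in {-1, +1}.  For each training bin and
    held-out trial a model is fitted on the remaining n-1 trials for every
    label set.  Returns margins of the held-out trial under its fold's model:
    (S, n_trials, n_bins) evaluated at the training bin, or
    (S, n_trials, n_train_bins, n_test_bins) when ``cross_temporal``.
    """
    n, f, nb = X.shape
    S = Y.shape[0]
    Xb = append_intercept(np.ascontiguousarray(X.transpose(2, 0, 1)))  # (nb, n, f+1)
    Yb = np.ascontiguousarray(np.broadcast_to(Y.T[None], (nb, n, S)))

    W_full = lasso_logistic_batch(Xb, Yb, C, tol=tol)

    keep = ~np.eye(n, dtype=bool)
    Xf = np.empty((nb, n, n - 1, f + 1))
    Yf = np.empty((nb, n, n - 1, S))
    for i in range(n):
        Xf[:, i] = Xb[:, keep[i], :]
        Yf[:, i] = Yb[:, keep[i], :]
    Xf = Xf.reshape(nb * n, n - 1, f + 1)
    Yf = Yf.reshape(nb * n, n - 1, S)
    W0 = np.repeat(W_full, n, axis=0)
    W = lasso_logistic_batch(Xf, Yf, C, tol=tol, W0=W0)  # (nb*n, f+1, S)

    if not cross_temporal:
        held = Xb.reshape(nb * n, f + 1)  # row (b*n + i) is trial i at bin b
        m = np.einsum("bf,bfs->bs", held, W)
        return m.reshape(nb, n, S).transpose(2, 1, 0)
    Wr = W.reshape(nb, n, f + 1, S)
    # margin of trial i (features at test bin t) under the model of train bin b
    return np.einsum("bifs,ift->sibt", Wr, append_intercept(X.transpose(0, 2, 1)).transpose(0, 2, 1))
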