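"""Independent reference implementations used only to check the package.

These are deliberately naive (dense linear algebra, brute force, Monte
Carlo) and share no code with the implementations they verify.
"""

import numpy as np


def cca_eigen_oracle(X, Y, n_dims):
    """Classical CCA via the generalized eigenproblem on raw covariances."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    n = X.shape[0]
    Xc, Yc = X - X.mean(0), Y - Y.mean(0)
    Sxx = Xc.T @ Xc / (n - 1)
    Syy = Yc.T @ Yc / (n - 1)
    Sxy = Xc.T @ Yc / (n - 1)
    M = np.linalg.solve(Sxx, Sxy) @ np.linalg.solve(Syy, Sxy.T)
    vals = np.sort(np.linalg.eigvals(M).real)[::-1]
    return np.sqrt(np.clip(vals[:n_dims], 0.0, 1.0))


def nipals_pls2(X, Y, n_comp, tol=1e-12, max_iter=1000):
    """Textbook NIPALS PLS2 (regression mode); returns per-component X weights."""
    X = np.asarray(X, float).copy()
    Y = np.asarray(Y, float).copy()
    X -= X.mean(0)
    Y -= Y.mean(0)
    weights = []
    for _ in range(n_comp):
        u = Y[:, int(np.argmax(Y.var(axis=0)))].copy()
        for _ in range(max_iter):
            w = X.T @ u
            w /= np.linalg.norm(w)
            t = X @ w
            c = Y.T @ t
            c /= np.linalg.norm(c)
            u_new = Y @ c
            if np.linalg.norm(u_new - u) < tol:
                u = u_new
                break
            u = u_new
        t = X @ w
        p = X.T @ t / (t @ t)
        q = Y.T @ t / (t @ t)
        X = X - np.outer(t, p)
        Y = Y - np.outer(t, q)
        weights.append(w)
    return np.column_stack(weights)


def permutation_pvalue(a, b, n_perm=4000, seed=0):
    """Two-sided permutation p-value for the difference of group means."""
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    n_a = len(a)
    observed = abs(np.mean(a) - np.mean(b))
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(perm[:n_a].mean() - perm[n_a:].mean()) >= observed:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def brute_force_best_feature(X, y):
    """Index of the feature with the largest |covariance| with y."""
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    Xc = X - X.mean(0)
    yc = y - y.mean()
    return int(np.argmax(np.abs(Xc.T @ yc)))


def titer_grid_oracle(dilutions, od_values, cutoff=0.2, n_grid=2_000_001):
    """Cutoff crossing found by brute force on a fine log-dilution grid."""
    logd = np.log10(np.asarray(dilutions, float))
    od = np.asarray(od_values, float)
    g = np.linspace(logd[0], logd[-1], n_grid)
    curve = np.interp(g, logd, od)
    below = np.flatnonzero(curve <= cutoff)
    if len(below) == 0:
        return None
    return 10.0 ** g[below[0]]
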