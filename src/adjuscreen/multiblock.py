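"""Latent-variable integration: PCA, (regularized) CCA, sparse multiblock
PLS and its discriminant variant, with cross-validated tuning.

All solvers are written directly on numpy/scipy linear algebra.

* ``pca`` -- SVD of the centered (optionally standardized) matrix with a
  deterministic sign convention.
* ``cca`` / ``rcca`` -- canonical correlation by whitening the
  cross-covariance with the (ridge-regularized) block covariances; the
  classical solution at :math:`\\lambda = 0`, well-posed for :math:`n < p`
  with positive penalties, and converging to the cross-covariance SVD
  (the PLS limit) as :math:`\\lambda \\to \\infty`.
* ``block_spls`` -- sparse generalized-CCA-style power iteration: each
  block's weight vector is the soft-thresholded top-``keepX`` projection of
  the design-weighted covariance with the other blocks' scores, iterated to
  convergence, with regression-mode deflation.
* ``block_splsda`` -- the discriminant wrapper: the class indicator matrix,
  column-centered, joins as the outcome block, and each selected feature is
  tagged with the class in which its within-class mean is larger.

Deterministic sign conventions (largest-magnitude weight entry positive)
make repeated runs bit-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from sklearn.model_selection import KFold, StratifiedKFold

__all__ = [
    "PCAModel",
    "CCAModel",
    "LatentModel",
    "ConvergenceError",
    "pca",
    "cca",
    "rcca",
    "tune_rcc",
    "similarity_matrix",
    "soft_select",
    "block_spls",
    "dichotomize",
    "block_splsda",
    "tune_block_splsda",
]


class ConvergenceError(RuntimeError):
    """Raised when the power iteration does not converge; carries the last iterate."""

    def __init__(self, message: str, last_model: "LatentModel | None" = None):
        super().__init__(message)
        self.last_model = last_model


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAModel:
    loadings: np.ndarray  # features x components, orthonormal columns
    scores: np.ndarray  # substances x components, column means 0
    explained_variance_ratio: np.ndarray
    center: np.ndarray
    scale: np.ndarray | None
    feature_names: list[str] | None = None


def _fix_loading_signs(loadings: np.ndarray, scores: np.ndarray) -> None:
    """In-place: make the largest-magnitude entry of each loading positive."""
    for k in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1.0
            scores[:, k] *= -1.0


def pca(X, scale: bool = False, n_components: int | None = None) -> PCAModel:
    """Principal components of a centered (optionally standardized) matrix."""
    df = pd.DataFrame(X)
    names = [str(c) for c in df.columns]
    M = df.to_numpy(dtype=float)
    n, p = M.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 rows")
    k = min(n - 1, p) if n_components is None else int(n_components)
    if k < 1 or k > min(n, p):
        raise ValueError(f"n_components must lie in 1..{min(n, p)}, got {k}")
    center = M.mean(axis=0)
    Z = M - center
    sd = None
    if scale:
        sd = M.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = [names[j] for j in np.flatnonzero(sd == 0)]
            raise ValueError(f"zero-variance columns (drop them first): {bad}")
        Z = Z / sd
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    total = float((s**2).sum())
    ratio = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    loadings = Vt[:k].T.copy()
    scores = U[:, :k] * s[:k]
    _fix_loading_signs(loadings, scores)
    return PCAModel(
        loadings=loadings,
        scores=scores,
        explained_variance_ratio=ratio,
        center=center,
        scale=sd,
        feature_names=names,
    )


# ---------------------------------------------------------------------------
# CCA / rCCA
# ---------------------------------------------------------------------------


@dataclass
class CCAModel:
    canonical_correlations: np.ndarray  # non-increasing, in [0, 1]
    x_weights: np.ndarray  # p x d
    y_weights: np.ndarray  # q x d
    x_scores: np.ndarray  # n x d
    y_scores: np.ndarray  # n x d
    lambda1: float
    lambda2: float
    x_center: np.ndarray = field(repr=False, default=None)
    y_center: np.ndarray = field(repr=False, default=None)
    _Xc: np.ndarray = field(repr=False, default=None)
    _Yc: np.ndarray = field(repr=False, default=None)
    x_names: list[str] | None = None
    y_names: list[str] | None = None


def _inv_sqrt(S: np.ndarray) -> np.ndarray:
    vals, vecs = scipy.linalg.eigh(S)
    if vals.min() <= 0:
        raise np.linalg.LinAlgError("covariance not positive definite")
    return (vecs / np.sqrt(vals)) @ vecs.T


def rcca(X, Y, lambda1: float = 0.0, lambda2: float = 0.0, n_dims: int | None = None) -> CCAModel:
    """Ridge-regularized CCA.

    Weights come from the SVD of the whitened cross-covariance
    ``(Sxx + l1 I)^{-1/2} Sxy (Syy + l2 I)^{-1/2}``.  Reported canonical
    correlations are the sample correlations of the fitted score pairs
    (oriented non-negative), which coincide with the classical generalized
    eigenvalues at ``lambda = 0``.
    """
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("penalties must be non-negative")
    Xdf, Ydf = pd.DataFrame(X), pd.DataFrame(Y)
    Xm, Ym = Xdf.to_numpy(dtype=float), Ydf.to_numpy(dtype=float)
    n, p = Xm.shape
    q = Ym.shape[1]
    if Ym.shape[0] != n:
        raise ValueError("X and Y must have the same number of rows")
    d = min(p, q) if n_dims is None else int(n_dims)
    if d < 1 or d > min(p, q):
        raise ValueError(f"n_dims must lie in 1..{min(p, q)}")
    x_center, y_center = Xm.mean(axis=0), Ym.mean(axis=0)
    Xc, Yc = Xm - x_center, Ym - y_center
    Sxx = Xc.T @ Xc / (n - 1) + lambda1 * np.eye(p)
    Syy = Yc.T @ Yc / (n - 1) + lambda2 * np.eye(q)
    Sxy = Xc.T @ Yc / (n - 1)
    try:
        Kx, Ky = _inv_sqrt(Sxx), _inv_sqrt(Syy)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular block covariance; use rcca with positive penalties"
        ) from err
    U, _, Vt = np.linalg.svd(Kx @ Sxy @ Ky)
    A = Kx @ U[:, :d]
    B = Ky @ Vt[:d].T
    x_scores = Xc @ A
    y_scores = Yc @ B
    # deterministic orientation: x-weight convention, then align y by corr sign
    _fix_loading_signs(A, x_scores)
    rho = np.empty(d)
    for k in range(d):
        sx, sy = x_scores[:, k], y_scores[:, k]
        denom = np.linalg.norm(sx - sx.mean()) * np.linalg.norm(sy - sy.mean())
        r = 0.0 if denom == 0 else float((sx - sx.mean()) @ (sy - sy.mean()) / denom)
        if r < 0:
            B[:, k] *= -1.0
            y_scores[:, k] *= -1.0
            r = -r
        rho[k] = min(r, 1.0)
    return CCAModel(
        canonical_correlations=rho,
        x_weights=A,
        y_weights=B,
        x_scores=x_scores,
        y_scores=y_scores,
        lambda1=lambda1,
        lambda2=lambda2,
        x_center=x_center,
        y_center=y_center,
        _Xc=Xc,
        _Yc=Yc,
        x_names=[str(c) for c in Xdf.columns],
        y_names=[str(c) for c in Ydf.columns],
    )


def cca(X, Y, n_dims: int | None = None) -> CCAModel:
    """Classical CCA; requires n > p + q and nonsingular block covariances."""
    Xm, Ym = np.asarray(X, dtype=float), np.asarray(Y, dtype=float)
    n, p = Xm.shape
    q = Ym.shape[1]
    if n <= p + q:
        raise ValueError(
            f"classical CCA needs n > p + q (got n={n}, p={p}, q={q}); use rcca"
        )
    return rcca(X, Y, 0.0, 0.0, n_dims=n_dims)


def tune_rcc(
    X,
    Y,
    lambda_grid=None,
    folds: int = 5,
    seed: int = 0,
) -> tuple[float, float, pd.DataFrame]:
    """Grid-search ridge penalties by cross-validated first canonical correlation.

    For every (l1, l2) pair the model is fitted on the training folds and
    scored by the correlation of the held-out first score pair, averaged
    over folds.  Ties go to the smallest ``l1 + l2``.
    """
    if lambda_grid is None:
        lambda_grid = np.logspace(-4, 0, 5)
    grid = [float(v) for v in np.atleast_1d(lambda_grid)]
    if not grid:
        raise ValueError("lambda_grid must be non-empty")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    Xm, Ym = np.asarray(X, dtype=float), np.asarray(Y, dtype=float)
    n = Xm.shape[0]
    splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
    split_list = list(splitter.split(Xm))
    for _, test in split_list:
        if len(test) < 3:
            raise ValueError("each fold needs at least 3 held-out samples")
    rows = []
    for l1 in grid:
        for l2 in grid:
            fold_scores = []
            for train, test in split_list:
                model = rcca(Xm[train], Ym[train], l1, l2, n_dims=1)
                tx = (Xm[test] - model.x_center) @ model.x_weights[:, 0]
                ty = (Ym[test] - model.y_center) @ model.y_weights[:, 0]
                sx, sy = tx - tx.mean(), ty - ty.mean()
                denom = np.linalg.norm(sx) * np.linalg.norm(sy)
                fold_scores.append(0.0 if denom == 0 else float(sx @ sy / denom))
            rows.append({"lambda1": l1, "lambda2": l2, "cv_score": float(np.mean(fold_scores))})
    surface = pd.DataFrame(rows)
    top = surface[np.isclose(surface["cv_score"], surface["cv_score"].max())]
    top = top.assign(total=top["lambda1"] + top["lambda2"]).sort_values(
        ["total", "lambda1"]
    )
    best_row = top.iloc[0]
    return float(best_row["lambda1"]), float(best_row["lambda2"]), surface


def similarity_matrix(model: CCAModel, n_dims: int | None = None) -> pd.DataFrame:
    """Feature-feature similarity behind the cross-correlation heatmaps.

    Entry (j, k) sums, over dimensions, the product of the correlations of
    X-feature j and Y-feature k with the per-dimension average score.
    """
    avail = model.x_scores.shape[1]
    d = avail if n_dims is None else int(n_dims)
    if d < 1 or d > avail:
        raise ValueError(f"n_dims must lie in 1..{avail}")
    Xc, Yc = model._Xc, model._Yc

    def corr_with(scores: np.ndarray, Z: np.ndarray) -> np.ndarray:
        s = scores - scores.mean()
        zn = Z / np.maximum(np.linalg.norm(Z, axis=0), 1e-300)
        sn = s / max(np.linalg.norm(s), 1e-300)
        return zn.T @ sn

    sim = np.zeros((Xc.shape[1], Yc.shape[1]))
    for k in range(d):
        m = 0.5 * (model.x_scores[:, k] + model.y_scores[:, k])
        sim += np.outer(corr_with(m, Xc), corr_with(m, Yc))
    return pd.DataFrame(sim, index=model.x_names, columns=model.y_names)


# ---------------------------------------------------------------------------
# Sparse multiblock PLS / PLS-DA
# ---------------------------------------------------------------------------


def soft_select(v: np.ndarray, keep: int) -> np.ndarray:
    """Sparse unit vector: top-``keep`` magnitudes, soft-thresholded.

    Entries outside the ``keep`` largest absolute values are zeroed; the
    survivors are shrunk toward zero by the largest excluded magnitude and
    the result is L2-normalized.  Boundary ties break toward the lowest
    feature index.  If shrinkage annihilates every survivor (an exact tie at
    the boundary), the survivors keep their unshrunk values so the selection
    itself is preserved.
    """
    v = np.asarray(v, dtype=float)
    p = len(v)
    if keep < 1:
        raise ValueError("keep must be >= 1")
    if keep > p:
        warnings.warn(f"keep={keep} exceeds vector length {p}; keeping all", stacklevel=2)
        keep = p
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("cannot select from an all-zero vector")
    order = np.lexsort((np.arange(p), -np.abs(v)))  # magnitude desc, index asc
    survivors = order[:keep]
    tau = np.abs(v[order[keep]]) if keep < p else 0.0
    out = np.zeros(p)
    shrunk = np.sign(v[survivors]) * np.maximum(np.abs(v[survivors]) - tau, 0.0)
    if np.all(shrunk == 0.0):
        shrunk = v[survivors]
    out[survivors] = shrunk
    return out / np.linalg.norm(out)


@dataclass
class LatentModel:
    """Fitted sparse multiblock decomposition."""

    mode: str  # "regression" | "discriminant"
    block_names: list[str]
    weights: dict[str, np.ndarray]  # block -> features x n_comp
    scores: dict[str, np.ndarray]  # block -> substances x n_comp
    y_weights: np.ndarray
    y_scores: np.ndarray
    selected_features: dict[str, list[list[str]]]  # block -> per-component names
    feature_names: dict[str, list[str]]
    y_names: list[str]
    design: np.ndarray
    keepX: dict[str, int]
    n_iter: list[int]
    class_labels: np.ndarray | None = None
    classes: list[str] | None = None
    dominant_class: dict[str, list[dict[str, str]]] | None = None

    def averaged_scores(self) -> np.ndarray:
        """Mean of the block score matrices (the consensus sample projection)."""
        return np.mean([self.scores[b] for b in self.block_names], axis=0)


def _default_design(n_blocks: int, block_block: float = 0.1) -> np.ndarray:
    """Y connected to every block with weight 1; block-block weight 0.1."""
    d = np.full((n_blocks + 1, n_blocks + 1), block_block)
    d[-1, :] = 1.0
    d[:, -1] = 1.0
    np.fill_diagonal(d, 0.0)
    return d


def block_spls(
    blocks: dict[str, object],
    Y,
    keepX: dict[str, int] | int,
    n_comp: int = 1,
    design: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    mode: str = "regression",
) -> LatentModel:
    """Sparse multiblock PLS on pre-scaled blocks.

    ``blocks`` maps names to substances x features matrices (already
    standardized); ``Y`` is the outcome matrix, treated as an additional
    connected block with dense weights.  ``design`` is the symmetric
    (n_blocks+1) x (n_blocks+1) connection matrix with Y last.
    """
    names = list(blocks)
    Xs = {}
    feat_names = {}
    for b in names:
        df = pd.DataFrame(blocks[b])
        feat_names[b] = [str(c) for c in df.columns]
        M = df.to_numpy(dtype=float)
        Xs[b] = M - M.mean(axis=0)
    Ydf = pd.DataFrame(Y)
    y_names = [str(c) for c in Ydf.columns]
    Ym = Ydf.to_numpy(dtype=float)
    Ym = Ym - Ym.mean(axis=0)
    n = Ym.shape[0]
    if any(Xs[b].shape[0] != n for b in names):
        raise ValueError("all blocks and Y must have the same number of rows")
    if isinstance(keepX, int):
        keepX = {b: keepX for b in names}
    for b in names:
        if keepX[b] > Xs[b].shape[1]:
            raise ValueError(
                f"keepX[{b!r}]={keepX[b]} exceeds {Xs[b].shape[1]} features"
            )
    B = len(names)
    if design is None:
        design = _default_design(B)
    design = np.asarray(design, dtype=float)
    if design.shape != (B + 1, B + 1):
        raise ValueError(f"design must be {(B + 1, B + 1)}, got {design.shape}")
    if np.any(design < 0) or not np.allclose(design, design.T):
        raise ValueError("design must be symmetric and non-negative")

    weights = {b: np.zeros((Xs[b].shape[1], n_comp)) for b in names}
    scores = {b: np.zeros((n, n_comp)) for b in names}
    y_weights = np.zeros((Ym.shape[1], n_comp))
    y_scores = np.zeros((n, n_comp))
    selected = {b: [] for b in names}
    n_iter: list[int] = []

    def first_right_sv(M: np.ndarray) -> np.ndarray:
        _, _, Vt = np.linalg.svd(M, full_matrices=False)
        return Vt[0]

    Xdef = {b: Xs[b].copy() for b in names}
    Ydef = Ym.copy()
    for h in range(n_comp):
        w = {b: first_right_sv(Xdef[b]) for b in names}
        wy = first_right_sv(Ydef)
        t = {b: Xdef[b] @ w[b] for b in names}
        ty = Ydef @ wy
        converged = False
        for it in range(1, max_iter + 1):
            t_old = {b: t[b].copy() for b in names}
            ty_old = ty.copy()
            for bi, b in enumerate(names):
                inner = design[bi, B] * (Xdef[b].T @ ty)
                for bj, other in enumerate(names):
                    if other != b:
                        inner = inner + design[bi, bj] * (Xdef[b].T @ t[other])
                w[b] = soft_select(inner, keepX[b])
                t[b] = Xdef[b] @ w[b]
            inner_y = np.zeros(Ydef.shape[1])
            for bj, other in enumerate(names):
                inner_y = inner_y + design[B, bj] * (Ydef.T @ t[other])
            ny = np.linalg.norm(inner_y)
            if ny == 0:
                raise ConvergenceError(f"degenerate outcome weight at component {h + 1}")
            wy = inner_y / ny
            ty = Ydef @ wy
            crit = max(
                max(np.linalg.norm(t[b] - t_old[b]) for b in names),
                np.linalg.norm(ty - ty_old),
            )
            if crit < tol:
                converged = True
                break
        if not converged:
            partial = LatentModel(
                mode=mode,
                block_names=names,
                weights=weights,
                scores=scores,
                y_weights=y_weights,
                y_scores=y_scores,
                selected_features=selected,
                feature_names=feat_names,
                y_names=y_names,
                design=design,
                keepX=dict(keepX),
                n_iter=n_iter + [max_iter],
            )
            raise ConvergenceError(
                f"component {h + 1} did not converge in {max_iter} iterations", partial
            )
        n_iter.append(it)
        # deterministic orientation per block, then record
        for b in names:
            j = int(np.argmax(np.abs(w[b])))
            if w[b][j] < 0:
                w[b] = -w[b]
                t[b] = -t[b]
        j = int(np.argmax(np.abs(wy)))
        if wy[j] < 0:
            wy, ty = -wy, -ty
        for b in names:
            weights[b][:, h] = w[b]
            scores[b][:, h] = t[b]
            selected[b].append([feat_names[b][j] for j in np.flatnonzero(w[b])])
        y_weights[:, h] = wy
        y_scores[:, h] = ty
        # regression-mode deflation: each block on its own score, Y on the
        # consensus (average) block score
        for b in names:
            tb = t[b]
            denom = tb @ tb
            if denom > 0:
                Xdef[b] = Xdef[b] - np.outer(tb, (tb @ Xdef[b]) / denom)
        tbar = np.mean([t[b] for b in names], axis=0)
        denom = tbar @ tbar
        if denom > 0:
            Ydef = Ydef - np.outer(tbar, (tbar @ Ydef) / denom)
    return LatentModel(
        mode=mode,
        block_names=names,
        weights=weights,
        scores=scores,
        y_weights=y_weights,
        y_scores=y_scores,
        selected_features=selected,
        feature_names=feat_names,
        y_names=y_names,
        design=design,
        keepX=dict(keepX),
        n_iter=n_iter,
    )


def dichotomize(outcome_values) -> np.ndarray:
    """Split substances at the cohort mean: above -> "high", at or below -> "low"."""
    v = np.asarray(outcome_values, dtype=float)
    if len(np.unique(v)) < 2:
        raise ValueError("cannot dichotomize a constant outcome")
    mean = v.mean()
    return np.where(v > mean, "high", "low")


def _dummy_matrix(labels: np.ndarray, classes: list[str]) -> np.ndarray:
    ind = np.column_stack([(labels == c).astype(float) for c in classes])
    return ind - ind.mean(axis=0)


def block_splsda(
    blocks: dict[str, object],
    class_labels,
    keepX: dict[str, int] | int,
    n_comp: int = 1,
    design: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> LatentModel:
    """Sparse multiblock PLS-DA: discriminate high vs low adjuvanticity.

    The centered two-class indicator matrix joins as the outcome block.
    Every selected feature is tagged with its *dominant class*: the class
    whose within-class mean of that feature is larger (the loading-plot
    coloring).
    """
    labels = np.asarray(class_labels).astype(str)
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {classes}")
    if min((labels == c).sum() for c in classes) < 2:
        raise ValueError("each class needs at least 2 members")
    Ydummy = _dummy_matrix(labels, classes)
    model = block_spls(
        blocks, Ydummy, keepX, n_comp=n_comp, design=design, tol=tol, max_iter=max_iter,
        mode="discriminant",
    )
    model.y_names = classes
    model.class_labels = labels
    model.classes = classes
    dominant: dict[str, list[dict[str, str]]] = {}
    for b in model.block_names:
        df = pd.DataFrame(blocks[b])
        df.columns = model.feature_names[b]
        per_comp = []
        for h in range(n_comp):
            tags = {}
            for feat in model.selected_features[b][h]:
                means = {c: float(df.loc[labels == c, feat].mean()) for c in classes}
                tags[feat] = max(classes, key=lambda c: (means[c], c))
            per_comp.append(tags)
        dominant[b] = per_comp
    model.dominant_class = dominant
    return model


def tune_block_splsda(
    blocks: dict[str, object],
    class_labels,
    keepX_grid,
    folds: int = 5,
    repeats: int = 3,
    seed: int = 0,
    n_comp: int = 1,
    design: np.ndarray | None = None,
) -> tuple[dict[str, int], pd.DataFrame]:
    """Choose keepX by repeated stratified CV balanced error rate.

    Held-out samples are classified by the nearest class centroid in the
    averaged block-score space.  Blocks are standardized inside each
    training fold and the training scaling applied to the held-out samples.
    Ties go to the smallest total keepX.
    """
    labels = np.asarray(class_labels).astype(str)
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {classes}")
    names = list(blocks)
    raw = {b: pd.DataFrame(blocks[b]).to_numpy(dtype=float) for b in names}
    candidates = []
    for cand in keepX_grid:
        if isinstance(cand, dict):
            candidates.append({b: int(cand[b]) for b in names})
        else:
            candidates.append({b: min(int(cand), raw[b].shape[1]) for b in names})
    if not candidates:
        raise ValueError("keepX_grid must be non-empty")
    min_class = min((labels == c).sum() for c in classes)
    if min_class < folds:
        raise ValueError(
            f"smallest class has {min_class} members; cannot stratify {folds} folds"
        )

    def fold_ber(cand: dict[str, int], train: np.ndarray, test: np.ndarray) -> float:
        train_blocks, test_blocks = {}, {}
        for b in names:
            tr = raw[b][train]
            mu, sd = tr.mean(axis=0), tr.std(axis=0, ddof=1)
            keepcols = sd > 0
            sd = np.where(keepcols, sd, 1.0)
            train_blocks[b] = ((tr - mu) / sd)[:, keepcols]
            test_blocks[b] = ((raw[b][test] - mu) / sd)[:, keepcols]
        adj = {b: min(cand[b], train_blocks[b].shape[1]) for b in names}
        model = block_splsda(
            train_blocks, labels[train], adj, n_comp=n_comp, design=design
        )
        train_avg = model.averaged_scores()
        centroids = {
            c: train_avg[labels[train] == c].mean(axis=0) for c in classes
        }
        test_avg = np.mean(
            [test_blocks[b] @ model.weights[b] for b in names], axis=0
        )
        pred = []
        for row in test_avg:
            pred.append(min(classes, key=lambda c: np.linalg.norm(row - centroids[c])))
        pred = np.asarray(pred)
        errs = []
        for c in classes:
            in_c = labels[test] == c
            if in_c.any():
                errs.append(float((pred[in_c] != c).mean()))
        return float(np.mean(errs))

    rows = []
    for ci, cand in enumerate(candidates):
        bers = []
        for rep in range(repeats):
            splitter = StratifiedKFold(
                n_splits=folds, shuffle=True, random_state=seed + rep
            )
            for train, test in splitter.split(np.zeros(len(labels)), labels):
                bers.append(fold_ber(cand, train, test))
        rows.append(
            {
                "candidate": ci,
                **{f"keepX_{b}": cand[b] for b in names},
                "mean_ber": float(np.mean(bers)),
                "sd_ber": float(np.std(bers, ddof=1)) if len(bers) > 1 else 0.0,
            }
        )
    table = pd.DataFrame(rows)
    best_err = table["mean_ber"].min()
    top = table[np.isclose(table["mean_ber"], best_err)]
    totals = top[[f"keepX_{b}" for b in names]].sum(axis=1)
    best_idx = int(top.loc[totals.idxmin(), "candidate"])
    return candidates[best_idx], table
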