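"""Multivariate statistics: Ward clustering, presence filtering and OPLS-DA.

The OPLS-DA implementation follows the orthogonal-signal-correction
scheme: class-orthogonal components are extracted and removed from X
before plain PLS2 predictive components are fitted, so that with zero
orthogonal components the model coincides with ordinary PLS-DA.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .datatypes import FeatureTable, ValidationError, as_matrix

logger = logging.getLogger(__name__)

DISTANCES = {
    "euclidean": "euclidean",
    "squared_euclidean": "sqeuclidean",
    "manhattan": "cityblock",
}


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------


@dataclass
class Dendrogram:
    """Merge sequence of an agglomerative clustering run.

    ``merges`` holds one row per merge: (cluster_i, cluster_j, height,
    size) with original observations labelled 0..n-1 and merged clusters
    n, n+1, ... in creation order (the scipy linkage convention).
    """

    merges: np.ndarray
    labels: list
    linkage: str
    distance: str

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def cophenetic_matrix(self) -> np.ndarray:
        """Leaf x leaf matrix of merge heights."""
        n = self.n_leaves
        members = {i: [i] for i in range(n)}
        coph = np.zeros((n, n))
        for k, (i, j, h, _size) in enumerate(self.merges):
            i, j = int(i), int(j)
            for a in members[i]:
                for b in members[j]:
                    coph[a, b] = coph[b, a] = h
            members[n + k] = members.pop(i) + members.pop(j)
        return coph

    def to_newick(self) -> str:
        n = self.n_leaves
        node = {i: str(self.labels[i]) for i in range(n)}
        height = {i: 0.0 for i in range(n)}
        for k, (i, j, h, _size) in enumerate(self.merges):
            i, j = int(i), int(j)
            bi = max(h - height[i], 0.0)
            bj = max(h - height[j], 0.0)
            node[n + k] = f"({node[i]}:{bi:g},{node[j]}:{bj:g})"
            height[n + k] = h
        return node[n + len(self.merges) - 1] + ";" if len(self.merges) else ";"


def ward_hca(data, distance: str = "euclidean", labels=None) -> Dendrogram:
    """Agglomerative Ward clustering via the Lance-Williams update.

    The initial dissimilarity matrix is computed with the requested
    metric and the Ward recurrence is applied to it directly (for the
    Manhattan metric this is heuristic but mirrors common practice).
    Ties are broken deterministically by the lowest cluster-index pair.
    """
    X = as_matrix(data)
    if np.isnan(X).any():
        raise ValidationError("input matrix contains NaN")
    n = X.shape[0]
    if n < 2:
        raise ValidationError("need at least 2 rows to cluster")
    if distance not in DISTANCES:
        raise ValidationError(f"unknown distance {distance!r}; choose from {sorted(DISTANCES)}")
    if labels is None:
        labels = list(range(n))

    D = squareform(pdist(X, metric=DISTANCES[distance]))
    # active cluster id -> (row index into D, size); D grows logically by
    # reusing rows: keep a dict of current dissimilarities instead
    dmat: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dmat[(i, j)] = float(D[i, j])
    size = {i: 1 for i in range(n)}
    active = list(range(n))
    merges = []
    next_id = n
    for _step in range(n - 1):
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                key = (i, j) if i < j else (j, i)
                d = dmat[key]
                cand = (d, key[0], key[1])
                if best is None or cand < best:
                    best = cand
        d, i, j = best
        merges.append((i, j, d, size[i] + size[j]))
        ni, nj = size[i], size[j]
        for k in active:
            if k in (i, j):
                continue
            nk = size[k]
            dik = dmat[(min(i, k), max(i, k))]
            djk = dmat[(min(j, k), max(j, k))]
            dnew = ((ni + nk) * dik + (nj + nk) * djk - nk * d) / (ni + nj + nk)
            dmat[(min(next_id, k), max(next_id, k))] = dnew
        active = [a for a in active if a not in (i, j)] + [next_id]
        size[next_id] = ni + nj
        next_id += 1
    return Dendrogram(np.array(merges, dtype=float), list(labels), "ward", distance)


# ---------------------------------------------------------------------------
# presence filter
# ---------------------------------------------------------------------------


def presence_filter(table: FeatureTable, fraction: float = 0.75) -> FeatureTable:
    """Keep compounds detected in >= ``fraction`` of the replicates of at
    least one treatment group.  Abundances are never altered."""
    if not 0.0 < fraction <= 1.0:
        raise ValidationError("fraction must be in (0, 1]")
    groups = table.treatment()
    if groups.isna().any() or len(groups.unique()) == 0:
        raise ValidationError("feature table lacks treatment group metadata")
    present = table.abundance.notna()
    frac = present.groupby(groups.to_numpy()).mean()
    keep = table.compounds[(frac >= fraction).any(axis=0).to_numpy()]
    logger.info(
        "presence filter (>=%.0f%%): %d/%d compounds retained",
        100 * fraction,
        len(keep),
        table.n_compounds,
    )
    return table.subset_compounds(keep)


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------


def _one_hot(classes) -> tuple[np.ndarray, np.ndarray]:
    classes = np.asarray(classes)
    levels = np.unique(classes)
    if levels.size < 2:
        raise ValidationError("need at least two classes")
    Y = (classes[:, None] == levels[None, :]).astype(float)
    if (Y.sum(axis=0) < 2).any():
        raise ValidationError("every class needs at least two samples")
    return Y, levels


def _scale(X: np.ndarray, scaling: str):
    mean = X.mean(axis=0)
    if scaling == "none":
        scale = np.ones(X.shape[1])
    else:
        sd = X.std(axis=0, ddof=1)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            raise ValidationError(
                f"constant column(s) under {scaling} scaling: {bad.tolist()}"
            )
        scale = sd if scaling == "uv" else np.sqrt(sd)
        if scaling not in ("uv", "pareto"):
            raise ValidationError(f"unknown scaling {scaling!r}")
    return (X - mean) / scale, mean, scale


def _dominant_weight(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    S = X.T @ Y
    u, s, _ = np.linalg.svd(S, full_matrices=False)
    return u[:, 0]


@dataclass
class OplsModel:
    """Fitted OPLS-DA state."""

    weights: np.ndarray          # p x A_pred, normalised predictive weights
    scores: np.ndarray           # n x A_pred predictive scores
    loadings: np.ndarray         # p x A_pred predictive loadings
    y_loadings: np.ndarray       # k x A_pred
    ortho_weights: np.ndarray    # p x A_ortho
    ortho_scores: np.ndarray     # n x A_ortho
    ortho_loadings: np.ndarray   # p x A_ortho
    classes_: np.ndarray
    y_mean: np.ndarray
    x_mean: np.ndarray
    x_scale: np.ndarray
    r2y: float
    n_ortho: int
    n_pred: int
    scaling: str
    q2y: float | None = None
    vip: np.ndarray | None = None

    @property
    def coef_(self) -> np.ndarray:
        W, P, C = self.weights, self.loadings, self.y_loadings
        return W @ np.linalg.solve(P.T @ W, C.T)

    def _filter(self, Xc: np.ndarray) -> np.ndarray:
        for a in range(self.n_ortho):
            t_o = Xc @ self.ortho_weights[:, a]
            Xc = Xc - np.outer(t_o, self.ortho_loadings[:, a])
        return Xc

    def predict_scores(self, X) -> np.ndarray:
        Xc = (as_matrix(X) - self.x_mean) / self.x_scale
        Xc = self._filter(Xc)
        return Xc @ self.weights @ np.linalg.inv(self.loadings.T @ self.weights)

    def predict_y(self, X) -> np.ndarray:
        Xc = (as_matrix(X) - self.x_mean) / self.x_scale
        Xc = self._filter(Xc)
        return Xc @ self.coef_ + self.y_mean

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_y(X), axis=1)]


def opls_da_fit(
    X,
    classes,
    n_ortho: int = 0,
    scaling: str = "uv",
    n_pred: int | None = None,
) -> OplsModel:
    """Fit an OPLS-DA model.

    Orthogonal components are extracted first (Trygg-Wold style, with the
    loading projected off the orthonormal basis of the Y-covariance
    space) and removed from X, then ``n_pred`` plain PLS2 components are
    fitted.  With ``n_ortho=0`` the model is an ordinary PLS-DA.
    """
    X = as_matrix(X)
    if n_ortho < 0:
        raise ValidationError("n_ortho must be >= 0")
    Y, levels = _one_hot(classes)
    if n_pred is None:
        n_pred = max(1, levels.size - 1)
    Xc, x_mean, x_scale = _scale(X, scaling)
    y_mean = Y.mean(axis=0)
    Yc = Y - y_mean
    ssy_total = float((Yc**2).sum())

    n, p = Xc.shape
    # --- orthogonal components -------------------------------------------
    W_o = np.zeros((p, 0))
    T_o = np.zeros((n, 0))
    P_o = np.zeros((p, 0))
    Xres = Xc
    # orthonormal basis of the Y-covariance space of the *scaled* X
    B = np.linalg.qr(Xc.T @ Yc)[0]
    actual_ortho = 0
    for _a in range(n_ortho):
        w = _dominant_weight(Xres, Yc)
        t = Xres @ w
        pl = Xres.T @ t / (t @ t)
        w_o = pl - B @ (B.T @ pl)
        nrm = np.linalg.norm(w_o)
        if nrm < 1e-12:
            warnings.warn(
                f"no orthogonal variation left after {actual_ortho} component(s)",
                stacklevel=2,
            )
            break
        w_o = w_o / nrm
        t_o = Xres @ w_o
        p_o = Xres.T @ t_o / (t_o @ t_o)
        Xres = Xres - np.outer(t_o, p_o)
        W_o = np.column_stack([W_o, w_o])
        T_o = np.column_stack([T_o, t_o])
        P_o = np.column_stack([P_o, p_o])
        actual_ortho += 1

    # --- predictive PLS2 components --------------------------------------
    W = np.zeros((p, 0))
    T = np.zeros((n, 0))
    P = np.zeros((p, 0))
    C = np.zeros((Y.shape[1], 0))
    Xd, Yd = Xres.copy(), Yc.copy()
    for _a in range(n_pred):
        if np.linalg.norm(Xd.T @ Yd) < 1e-12:
            break
        w = _dominant_weight(Xd, Yd)
        t = Xd @ w
        tt = t @ t
        if tt < 1e-12:
            break
        c = Yd.T @ t / tt
        pl = Xd.T @ t / tt
        Xd = Xd - np.outer(t, pl)
        Yd = Yd - np.outer(t, c)
        W = np.column_stack([W, w])
        T = np.column_stack([T, t])
        P = np.column_stack([P, pl])
        C = np.column_stack([C, c])

    Yhat = T @ C.T
    r2y = 1.0 - float(((Yc - Yhat) ** 2).sum()) / ssy_total
    model = OplsModel(
        weights=W,
        scores=T,
        loadings=P,
        y_loadings=C,
        ortho_weights=W_o,
        ortho_scores=T_o,
        ortho_loadings=P_o,
        classes_=levels,
        y_mean=y_mean,
        x_mean=x_mean,
        x_scale=x_scale,
        r2y=r2y,
        n_ortho=actual_ortho,
        n_pred=W.shape[1],
        scaling=scaling,
    )
    model.vip = vip_scores(model)
    return model


def vip_scores(model: OplsModel) -> np.ndarray:
    """Variable importance in projection over the predictive components.

    VIP_j = sqrt(p * sum_a SSY_a * (w_aj/||w_a||)^2 / sum_a SSY_a); the
    mean of the squared scores is 1 by construction.
    """
    W, T, C = model.weights, model.scores, model.y_loadings
    if W.shape[1] == 0:
        raise ValidationError("model has no fitted predictive components")
    p = W.shape[0]
    ssy = np.einsum("ia,ia->a", T, T) * np.einsum("ka,ka->a", C, C)
    wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    vip = np.sqrt(p * (wn**2 @ ssy) / ssy.sum())
    return vip


def select_discriminant(vip, threshold: float, ids=None):
    """Variables with VIP strictly above ``threshold``, best first."""
    if threshold <= 0:
        pass  # threshold 0 admits everything with positive VIP
    vip = np.asarray(vip, dtype=float)
    if ids is None:
        ids = np.arange(vip.size)
    ids = np.asarray(ids)
    mask = vip > threshold
    order = np.argsort(-vip[mask], kind="stable")
    return list(ids[mask][order])


def _stratified_folds(classes: np.ndarray, folds: int, seed: int):
    """Deterministic stratified fold assignment (list of test-index arrays)."""
    rng = np.random.default_rng(seed)
    assign = np.empty(classes.shape[0], dtype=int)
    for level in np.unique(classes):
        idx = np.flatnonzero(classes == level)
        idx = rng.permutation(idx)
        assign[idx] = np.arange(idx.size) % folds
    return [np.flatnonzero(assign == f) for f in range(folds)]


def _cv_predictions(X, classes, n_ortho, folds, scaling, seed, n_pred):
    X = as_matrix(X)
    classes = np.asarray(classes)
    _, levels = _one_hot(classes)
    min_count = min((classes == lv).sum() for lv in levels)
    if folds > min_count:
        warnings.warn(
            f"reducing folds from {folds} to {min_count} (smallest class)",
            stacklevel=2,
        )
        folds = int(min_count)
    if folds < 2:
        raise ValidationError("need at least 2 folds")
    Yhat = np.zeros((X.shape[0], levels.size))
    tss = 0.0
    Y_full = (classes[:, None] == levels[None, :]).astype(float)
    for test in _stratified_folds(classes, folds, seed):
        train = np.setdiff1d(np.arange(X.shape[0]), test)
        model = opls_da_fit(
            X[train], classes[train], n_ortho=n_ortho, scaling=scaling, n_pred=n_pred
        )
        Yhat[test] = model.predict_y(X[test])
        tss += float(((Y_full[test] - Y_full[train].mean(axis=0)) ** 2).sum())
    press = float(((Y_full - Yhat) ** 2).sum())
    return Yhat, press, tss, Y_full, folds


def q2y(
    X,
    classes,
    n_ortho: int = 0,
    folds: int = 7,
    scaling: str = "uv",
    seed: int = 0,
    n_pred: int | None = None,
) -> float:
    """Cross-validated predictive ability: 1 - PRESS/TSS over held-out folds."""
    _, press, tss, _, _ = _cv_predictions(X, classes, n_ortho, folds, scaling, seed, n_pred)
    return 1.0 - press / tss


@dataclass
class CvAnovaResult:
    p: float
    F: float
    df1: int
    df2: int
    press: float
    ss_total: float
    degenerate: bool = False


def cv_anova(
    X,
    classes,
    n_ortho: int = 0,
    folds: int = 7,
    scaling: str = "uv",
    seed: int = 0,
    n_pred: int | None = None,
) -> CvAnovaResult:
    """F-test of cross-validated predictive residuals (Eriksson-style).

    The total Y variation about its mean is decomposed into the part
    explained by cross-validated predictions and the PRESS; the ratio of
    their mean squares is referred to an F distribution with the model
    component count and the remaining sample degrees of freedom.
    """
    X = as_matrix(X)
    classes = np.asarray(classes)
    _, press, _, Y_full, _ = _cv_predictions(
        X, classes, n_ortho, folds, scaling, seed, n_pred
    )
    ss_total = float(((Y_full - Y_full.mean(axis=0)) ** 2).sum())
    k = np.unique(classes).size
    n_pred_eff = max(1, k - 1) if n_pred is None else n_pred
    df1 = n_pred_eff + n_ortho
    df2 = max(X.shape[0] - df1 - 1, 1)
    if press <= np.finfo(float).eps * ss_total:
        logger.warning("cv_anova: zero cross-validated residual variance")
        return CvAnovaResult(float(np.finfo(float).eps), np.inf, df1, df2, press, ss_total, True)
    F = ((ss_total - press) / df1) / (press / df2)
    p = float(stats.f.sf(F, df1, df2)) if F > 0 else 1.0
    return CvAnovaResult(p, float(F), df1, df2, press, ss_total)


@dataclass
class ValidationReport:
    cv_anova_p: float
    permutation_p: float
    n_permutations: int
    observed_q2: float
    observed_r2: float
    perm_q2: np.ndarray = field(default_factory=lambda: np.array([]))
    perm_r2: np.ndarray = field(default_factory=lambda: np.array([]))


def permutation_test(
    X,
    classes,
    n_perm: int = 200,
    seed: int = 0,
    n_ortho: int = 0,
    folds: int = 7,
    scaling: str = "uv",
    n_pred: int | None = None,
) -> ValidationReport:
    """Label-permutation overfitting check.

    p = (1 + #{permuted Q2Y >= observed Q2Y}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    X = as_matrix(X)
    classes = np.asarray(classes)
    obs_q2 = q2y(X, classes, n_ortho=n_ortho, folds=folds, scaling=scaling, seed=seed, n_pred=n_pred)
    obs_model = opls_da_fit(X, classes, n_ortho=n_ortho, scaling=scaling, n_pred=n_pred)
    rng = np.random.default_rng(seed)
    perm_q2 = np.empty(n_perm)
    perm_r2 = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(classes)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            perm_q2[b] = q2y(
                X, perm, n_ortho=n_ortho, folds=folds, scaling=scaling, seed=seed, n_pred=n_pred
            )
            perm_r2[b] = opls_da_fit(
                X, perm, n_ortho=n_ortho, scaling=scaling, n_pred=n_pred
            ).r2y
    p = (1 + int((perm_q2 >= obs_q2).sum())) / (1 + n_perm)
    cv = cv_anova(X, classes, n_ortho=n_ortho, folds=folds, scaling=scaling, seed=seed, n_pred=n_pred)
    return ValidationReport(
        cv_anova_p=cv.p,
        permutation_p=p,
        n_permutations=n_perm,
        observed_q2=obs_q2,
        observed_r2=obs_model.r2y,
        perm_q2=perm_q2,
        perm_r2=perm_r2,
    )


def choose_n_ortho(
    X, classes, max_ortho: int = 5, min_gain: float = 0.01, **kwargs
) -> int:
    """Pick the orthogonal component count at the Q2Y plateau."""
    best = q2y(X, classes, n_ortho=0, **kwargs)
    chosen = 0
    for a in range(1, max_ortho + 1):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            q = q2y(X, classes, n_ortho=a, **kwargs)
        if q - best < min_gain:
            break
        best, chosen = q, a
    return chosen
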