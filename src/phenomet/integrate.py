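"""Phenome-metabolome linkage.

Random-forest trait selection, trait-metabolite Pearson correlation, and
co-inertia analysis with Escoufier's RV coefficient as the global
concordance measure between the two blocks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import train_test_split

from .datatypes import ValidationError, as_matrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# random forest trait importance
# ---------------------------------------------------------------------------


@dataclass
class RFImportance:
    importances: pd.Series   # per-trait mean decrease in held-out accuracy
    ranks: pd.Series         # 1 = most important
    accuracy: float          # held-out classification accuracy
    n_trees: int
    seed: int


def rf_trait_importance(
    traits: pd.DataFrame,
    labels,
    n_trees: int = 500,
    seed: int = 0,
    test_size: float = 0.4,
    n_repeats: int = 10,
) -> RFImportance:
    """Permutation importance of traits for treatment classification.

    The forest is fitted on a stratified training split; importance is
    the mean decrease in accuracy when a trait is permuted on the
    held-out split, which also supplies the reported accuracy.
    """
    X = as_matrix(traits)
    if np.isnan(X).any():
        raise ValidationError("trait matrix contains missing values")
    y = np.asarray(labels)
    levels, counts = np.unique(y, return_counts=True)
    if levels.size < 2:
        raise ValidationError("need at least two classes")
    if counts.min() < 2:
        bad = levels[counts < 2]
        raise ValidationError(f"class(es) with a single sample: {bad.tolist()}")
    Xtr, Xte, ytr, yte = train_test_split(
        X, y, test_size=test_size, stratify=y, random_state=seed
    )
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    rf.fit(Xtr, ytr)
    accuracy = float(rf.score(Xte, yte))
    imp = permutation_importance(
        rf, Xte, yte, n_repeats=n_repeats, random_state=seed, n_jobs=1
    )
    names = (
        list(traits.columns)
        if isinstance(traits, pd.DataFrame)
        else [f"trait_{i}" for i in range(X.shape[1])]
    )
    importances = pd.Series(imp.importances_mean, index=names)
    order = importances.sort_values(ascending=False, kind="stable")
    ranks = pd.Series(np.arange(1, len(order) + 1), index=order.index).loc[names]
    return RFImportance(importances, ranks, accuracy, n_trees, seed)


# ---------------------------------------------------------------------------
# trait-metabolite correlation
# ---------------------------------------------------------------------------


@dataclass
class CorrelationMatrix:
    r: pd.DataFrame            # traits x compounds
    p: pd.DataFrame
    significant: pd.DataFrame  # boolean
    invalid: pd.DataFrame      # boolean; degenerate pairs (zero variance / n<4)
    alpha: float


def trait_metabolite_correlation(
    traits: pd.DataFrame,
    features: pd.DataFrame,
    alpha: float = 0.05,
    correction: str | None = None,
) -> CorrelationMatrix:
    """Pearson correlation of every trait against every compound.

    Samples are aligned on the index; mismatches are an error.  P-values
    are two-sided and, by default, uncorrected (``correction="bh"`` turns
    on Benjamini-Hochberg across all pairs).
    """
    only_t = traits.index.difference(features.index)
    only_f = features.index.difference(traits.index)
    if len(only_t) or len(only_f):
        raise ValidationError(
            f"sample ids misaligned; traits-only={sorted(only_t.tolist())[:5]} "
            f"features-only={sorted(only_f.tolist())[:5]}"
        )
    features = features.loc[traits.index]
    n = len(traits)
    if n < 4:
        raise ValidationError("need at least 4 aligned samples")
    T = as_matrix(traits)
    F = as_matrix(features)
    r = np.full((T.shape[1], F.shape[1]), np.nan)
    p = np.full_like(r, np.nan)
    invalid = np.zeros_like(r, dtype=bool)

    t_sd = T.std(axis=0, ddof=1)
    f_ok = ~np.isnan(F).any(axis=0)
    f_sd = np.nanstd(F, axis=0, ddof=1)
    # vectorised path for complete, non-degenerate columns
    good_t = t_sd > 0
    good_f = f_ok & (f_sd > 0)
    if good_t.any() and good_f.any():
        Tz = (T[:, good_t] - T[:, good_t].mean(axis=0)) / t_sd[good_t]
        Fz = (F[:, good_f] - F[:, good_f].mean(axis=0)) / f_sd[good_f]
        rr = (Tz.T @ Fz) / (n - 1)
        rr = np.clip(rr, -1.0, 1.0)
        df = n - 2
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = rr * np.sqrt(df / np.maximum(1.0 - rr**2, np.finfo(float).tiny))
        pp = 2 * stats.t.sf(np.abs(tstat), df)
        r[np.ix_(good_t, good_f)] = rr
        p[np.ix_(good_t, good_f)] = pp
    # per-pair path for columns with missing values
    for j in np.flatnonzero(~f_ok):
        col = F[:, j]
        mask = np.isfinite(col)
        if mask.sum() < 4:
            invalid[:, j] = True
            continue
        for i in range(T.shape[1]):
            x, y = T[mask, i], col[mask]
            if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
                invalid[i, j] = True
                continue
            res = stats.pearsonr(x, y)
            r[i, j], p[i, j] = res.statistic, res.pvalue
    invalid[~good_t, :] = True
    invalid[:, np.flatnonzero(f_ok & ~(f_sd > 0))] = True

    if correction == "bh":
        flat = p.ravel()
        ok = np.isfinite(flat)
        adj = np.full_like(flat, np.nan)
        m = ok.sum()
        order = np.argsort(flat[ok])
        ranked = flat[ok][order] * m / (np.arange(m) + 1)
        adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
        tmp = np.empty(m)
        tmp[order] = np.minimum(adj_sorted, 1.0)
        adj[ok] = tmp
        p_used = adj.reshape(p.shape)
    elif correction is None:
        p_used = p
    else:
        raise ValidationError(f"unknown correction {correction!r}")

    sig = (p_used < alpha) & ~invalid & np.isfinite(p_used)
    tix, fix = list(traits.columns), list(features.columns)
    return CorrelationMatrix(
        r=pd.DataFrame(r, index=tix, columns=fix),
        p=pd.DataFrame(p_used, index=tix, columns=fix),
        significant=pd.DataFrame(sig, index=tix, columns=fix),
        invalid=pd.DataFrame(invalid, index=tix, columns=fix),
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# RV coefficient and co-inertia
# ---------------------------------------------------------------------------


def rv_coefficient(X, Y) -> float:
    """Escoufier's RV between two column-centered blocks on the same samples.

    RV = trace(XX'YY') / sqrt(trace((XX')^2) trace((YY')^2)), computed
    via the equivalent cross-product form for efficiency.
    """
    X = as_matrix(X)
    Y = as_matrix(Y)
    if X.shape[0] != Y.shape[0]:
        raise ValidationError(
            f"row mismatch: {X.shape[0]} vs {Y.shape[0]} samples"
        )
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    sxx = float((np.linalg.norm(Xc.T @ Xc, "fro")))
    syy = float((np.linalg.norm(Yc.T @ Yc, "fro")))
    if sxx == 0 or syy == 0:
        raise ValidationError("a block has zero total variance")
    sxy = float(np.linalg.norm(Xc.T @ Yc, "fro")) ** 2
    return sxy / (sxx * syy)


@dataclass
class CoinertiaResult:
    x_loadings: np.ndarray    # p x n_axes
    y_loadings: np.ndarray    # q x n_axes
    singular_values: np.ndarray
    rv: float
    n_axes: int
    permutation_p: float | None = None


def _block_scale(M: np.ndarray, scaling: str) -> np.ndarray:
    Mc = M - M.mean(axis=0)
    if scaling == "none":
        return Mc
    sd = M.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    if scaling == "uv":
        return Mc / sd
    if scaling == "pareto":
        return Mc / np.sqrt(sd)
    raise ValidationError(f"unknown scaling {scaling!r}")


def coinertia(
    X,
    Y,
    n_axes: int = 2,
    x_scaling: str = "uv",
    y_scaling: str = "pareto",
) -> CoinertiaResult:
    """Co-inertia analysis: SVD of the cross-covariance of two blocks.

    Blocks are column-centered and scaled (unit variance for the trait
    block, Pareto for the metabolite block by default); the paired axes
    maximise the covariance between block projections.  The RV
    coefficient of the preprocessed blocks is attached.
    """
    X = as_matrix(X)
    Y = as_matrix(Y)
    if X.shape[0] != Y.shape[0]:
        raise ValidationError("blocks must share samples (same row count)")
    Xs = _block_scale(X, x_scaling)
    Ys = _block_scale(Y, y_scaling)
    max_axes = min(Xs.shape[1], Ys.shape[1])
    if n_axes > max_axes:
        warnings.warn(f"n_axes clipped from {n_axes} to {max_axes}", stacklevel=2)
        n_axes = max_axes
    cross = Ys.T @ Xs / (X.shape[0] - 1)
    U, s, Vt = np.linalg.svd(cross, full_matrices=False)
    rv = rv_coefficient(Xs, Ys)
    return CoinertiaResult(
        x_loadings=Vt[:n_axes].T,
        y_loadings=U[:, :n_axes],
        singular_values=s[:n_axes],
        rv=rv,
        n_axes=n_axes,
    )


def rv_permutation_test(X, Y, n_perm: int = 199, seed: int = 0) -> float:
    """Add-one permutation p-value for the observed RV (rows of Y shuffled)."""
    X = as_matrix(X)
    Y = as_matrix(Y)
    observed = rv_coefficient(X, Y)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(Y.shape[0])
        if rv_coefficient(X, Y[perm]) >= observed:
            count += 1
    return (1 + count) / (1 + n_perm)
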