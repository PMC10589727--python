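"""Highly-variable-region selection, Horn's parallel analysis, CV contract.

For an intercept NB model the sum of squared Pearson residuals of a region
is asymptotically chi-square with n - 1 degrees of freedom under the null of
trend-level variance, so an upper-tail test with BH correction selects
regions whose variance exceeds the mean-variance trend ("highly variable").
The retained principal-component count comes from Horn's permutation
parallel analysis: eigenvalues of the real matrix are kept while they exceed
the mean eigenvalues of feature-wise permuted matrices.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

from .annotate import bh_fdr


def select_hvr(residuals: pd.DataFrame, fdr: float = 0.05, df_params: int = 1):
    """Chi-square selection of highly variable regions.

    Parameters
    ----------
    residuals : regions x samples clipped Pearson residuals from an intercept
        (p = ``df_params``) model.
    fdr : BH false-discovery-rate cutoff.

    Returns a DataFrame (statistic, p_value, q_value, selected) indexed like
    ``residuals``.
    """
    R = residuals.to_numpy()
    n = R.shape[1]
    T = (R ** 2).sum(axis=1)
    p = stats.chi2.sf(T, df=n - df_params)
    q = bh_fdr(p)
    return pd.DataFrame({"statistic": T, "p_value": p, "q_value": q,
                         "selected": q <= fdr}, index=residuals.index)


def horn_pca(X: np.ndarray, n_perm: int = 3, max_components: int | None = None,
             seed: int = 0):
    """PCA with the component count chosen by Horn's parallel analysis.

    Each feature's values are permuted independently across samples
    (destroying correlation, preserving marginals). Real eigenvalues are
    compared against the noise ceiling — the largest permuted eigenvalue,
    averaged over permutations — and retention stops at the first eigenvalue
    that fails to exceed it (contiguous rule). Comparing against the ceiling
    rather than rank-matched permuted eigenvalues keeps the count stable at
    the bulk edge, where rank-matched comparisons are coin flips. At least
    one component's scores are returned even if none is retained, with
    ``n_components = 0`` reported.

    Returns ``(n_components, scores, loadings)``.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 2 or p < 2:
        raise ValueError("need at least 2 samples and 2 features")
    rng = np.random.default_rng(seed)
    k = min(n, p) - 1
    if max_components is not None:
        k = min(k, max_components)
    pca = PCA(n_components=k, svd_solver="randomized", random_state=seed)
    pca.fit(X)
    real_ev = pca.explained_variance_

    perm_ev = np.zeros(k)
    for _ in range(n_perm):
        Xp = X.copy()
        for j in range(p):
            Xp[:, j] = Xp[rng.permutation(n), j]
        ppca = PCA(n_components=k, svd_solver="randomized",
                   random_state=seed)
        ppca.fit(Xp)
        perm_ev += ppca.explained_variance_
    perm_ev /= n_perm

    exceeds = real_ev > perm_ev[0]
    n_components = int(np.argmin(exceeds)) if not exceeds.all() else k
    n_keep = max(n_components, 1)
    scores = pca.transform(X)[:, :n_keep]
    loadings = pca.components_[:n_keep]
    return n_components, scores, loadings


class HVRSelector(TransformerMixin, BaseEstimator):
    """sklearn selector keeping highly variable regions (chi-square + BH).

    X is samples x regions of Pearson residuals. Fitted attributes:
    ``support_`` (boolean mask), ``stats_`` (the selection table).
    """

    def __init__(self, fdr=0.05, df_params=1):
        self.fdr = fdr
        self.df_params = df_params

    def fit(self, X, y=None):
        residuals = X.T if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X).T)
        self.stats_ = select_hvr(residuals, fdr=self.fdr, df_params=self.df_params)
        self.support_ = self.stats_["selected"].to_numpy()
        return self

    def transform(self, X):
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.support_]
        return np.asarray(X)[:, self.support_]


class HornPCA(TransformerMixin, BaseEstimator):
    """PCA whose dimensionality is set by Horn's parallel analysis.

    Fitted attributes: ``n_components_`` (parallel-analysis count),
    ``components_``, ``scores_``.
    """

    def __init__(self, n_perm=3, max_components=None, random_state=0):
        self.n_perm = n_perm
        self.max_components = max_components
        self.random_state = random_state

    def fit(self, X, y=None):
        X = X.to_numpy() if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        self.mean_ = X.mean(axis=0)
        n_components, scores, loadings = horn_pca(
            X, n_perm=self.n_perm, max_components=self.max_components,
            seed=self.random_state)
        self.n_components_ = n_components
        self.components_ = loadings
        self.scores_ = scores
        return self

    def transform(self, X):
        X = X.to_numpy() if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        return (X - self.mean_) @ self.components_.T


def classify_balanced(scores, labels, model: str = "knn", folds: int = 10,
                      seed: int = 0, n_neighbors: int = 10) -> float:
    """Stratified k-fold CV balanced accuracy (mean per-class recall).

    ``model`` is "knn" (k-nearest neighbors) or "gbt" (histogram gradient
    boosted trees with balanced sample weights). When the smallest class has
    fewer members than ``folds``, the fold count is reduced with a warning.
    Out-of-fold predictions are pooled before scoring.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes, y = np.unique(labels, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    min_class = np.bincount(y).min()
    if min_class < folds:
        warnings.warn(f"smallest class has {min_class} members; reducing "
                      f"folds from {folds} to {max(min_class, 2)}")
        folds = max(min_class, 2)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    preds = np.empty_like(y)
    for train, test in skf.split(scores, y):
        if model == "knn":
            clf = KNeighborsClassifier(n_neighbors=min(n_neighbors, len(train)))
            clf.fit(scores[train], y[train])
        elif model == "gbt":
            clf = HistGradientBoostingClassifier(random_state=seed)
            w = _balanced_weights(y[train])
            clf.fit(scores[train], y[train], sample_weight=w)
        else:
            raise ValueError(f"unknown model {model!r}")
        preds[test] = clf.predict(scores[test])
    return float(balanced_accuracy_score(y, preds))


def _balanced_weights(y: np.ndarray) -> np.ndarray:
    counts = np.bincount(y)
    return (len(y) / (len(counts) * counts))[y]
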