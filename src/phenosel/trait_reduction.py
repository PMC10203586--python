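"""Trait-redundancy characterisation and dimensionality reduction.

The phenomic panel is heavily redundant: many vegetation indices re-express
the same underlying canopy state. ``unique_trait_count`` quantifies that
redundancy (number of traits surviving greedy correlation pruning at a given
threshold), ``pca_cumvar``/``select_pco`` summarise the panel by principal
components, and ``pls_components`` extracts yield-supervised partial least
squares components (NIPALS PLS1) for use as co-responses in multivariate
prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ComponentSet",
    "unique_trait_count",
    "pca_cumvar",
    "select_pco",
    "pls_components",
]


@dataclass
class ComponentSet:
    """Scores/loadings of a PCO or PLS decomposition, with per-component
    yield correlation and dominant trait categories for reporting."""

    kind: str  # "PCO" or "PLS"
    scores: pd.DataFrame  # observations x components
    loadings: pd.DataFrame  # traits x components
    yield_corr: pd.Series
    dominant_categories: pd.DataFrame | None = None  # components x categories (bool)

    @property
    def k(self) -> int:
        return self.scores.shape[1]


def _as_matrix(trait_matrix) -> tuple[np.ndarray, list]:
    if isinstance(trait_matrix, pd.DataFrame):
        return trait_matrix.to_numpy(dtype=float), list(trait_matrix.columns)
    X = np.asarray(trait_matrix, dtype=float)
    return X, [f"T{i + 1}" for i in range(X.shape[1])]


def unique_trait_count(trait_matrix, threshold: float) -> int:
    """Number of traits surviving greedy redundancy pruning.

    Walking columns in panel order, a trait is retained only if its maximum
    absolute Pearson correlation with all previously retained traits is
    strictly below ``threshold``. Counts are non-decreasing in the
    threshold (retention constraints are nested).
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    X, _ = _as_matrix(trait_matrix)
    if X.shape[1] == 1:
        return 1
    if np.isnan(X).any():
        # pairwise-complete fallback
        R = pd.DataFrame(X).corr().to_numpy()
        keep: list = []
        for j in range(X.shape[1]):
            if not keep or np.nanmax(np.abs(R[j, keep])) < threshold:
                keep.append(j)
        return len(keep)
    n = X.shape[0]
    sd = X.std(axis=0, ddof=0)
    Xs = (X - X.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    kept = np.empty((n, 0))
    count = 0
    for j in range(X.shape[1]):
        if kept.shape[1]:
            r = np.abs(kept.T @ Xs[:, j]) / n
            if r.max() >= threshold:
                continue
        count += 1
        kept = np.hstack([kept, Xs[:, [j]]])
    return count


def pca_cumvar(trait_matrix) -> np.ndarray:
    """Cumulative explained-variance curve of the trait correlation matrix.

    Constant columns are dropped with a warning. The returned fractions are
    non-decreasing and end at 1.
    """
    X, _ = _as_matrix(trait_matrix)
    if X.shape[1] < 2:
        raise ValueError("need at least two traits")
    sd = X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        warnings.warn(f"dropping {int((sd == 0).sum())} constant trait column(s)",
                      stacklevel=2)
        X = X[:, sd > 0]
    R = np.corrcoef(X, rowvar=False)
    eig = np.sort(np.clip(np.linalg.eigvalsh(R), 0.0, None))[::-1]
    return np.cumsum(eig) / eig.sum()


def _dominant_categories(
    loadings: pd.DataFrame, panel: pd.DataFrame, mass_threshold: float = 0.25
) -> pd.DataFrame:
    """Flag, per component, categories contributing more than
    ``mass_threshold`` of its squared loading mass (reporting convention)."""
    cat = panel.set_index("trait_id")["category"].reindex(loadings.index)
    sq = loadings**2
    mass = sq.groupby(cat).sum()
    frac = mass / mass.sum(axis=0)
    return (frac > mass_threshold).T


def select_pco(
    trait_matrix,
    yield_vector=None,
    k: int = 3,
    panel: pd.DataFrame | None = None,
) -> ComponentSet:
    """Scores of the first ``k`` principal components of the standardised
    trait matrix, with their correlation to yield attached for reporting."""
    X, names = _as_matrix(trait_matrix)
    index = (
        trait_matrix.index if isinstance(trait_matrix, pd.DataFrame)
        else pd.RangeIndex(X.shape[0])
    )
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    names = [nm for nm, k_ in zip(names, keep) if k_]
    rank = min(X.shape)
    if k > rank:
        warnings.warn(f"k={k} exceeds rank {rank}; truncating", stacklevel=2)
        k = rank
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    comp_names = [f"PCO{i + 1}" for i in range(k)]
    scores = pd.DataFrame((U[:, :k] * s[:k]), index=index, columns=comp_names)
    loadings = pd.DataFrame(Vt[:k].T, index=names, columns=comp_names)
    if yield_vector is not None:
        y = np.asarray(yield_vector, dtype=float)
        corr = pd.Series(
            [np.corrcoef(scores[c], y)[0, 1] for c in comp_names], index=comp_names
        )
    else:
        corr = pd.Series(np.nan, index=comp_names)
    dom = _dominant_categories(loadings, panel) if panel is not None else None
    return ComponentSet("PCO", scores, loadings, corr, dom)


def pls_components(
    trait_matrix,
    yield_vector,
    k: int,
    panel: pd.DataFrame | None = None,
) -> ComponentSet:
    """PLS1 components of the trait matrix with yield as the response.

    Components are extracted by NIPALS (deflating X after each component)
    and returned ranked by their contribution to the fitted yield variance,
    each with its correlation to yield and, when a trait panel is supplied,
    the categories dominating its loadings.
    """
    X, names = _as_matrix(trait_matrix)
    index = (
        trait_matrix.index if isinstance(trait_matrix, pd.DataFrame)
        else pd.RangeIndex(X.shape[0])
    )
    y = np.asarray(yield_vector, dtype=float)
    if len(y) != X.shape[0]:
        raise ValueError("trait matrix and yield vector must have matching rows")
    if k < 1:
        raise ValueError("k must be >= 1")
    if y.std(ddof=0) == 0:
        raise ValueError("yield has zero variance")
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    Xc = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    names = [nm for nm, k_ in zip(names, keep) if k_]
    yc = y - y.mean()
    n = len(y)
    k = min(k, min(Xc.shape))
    T = np.zeros((n, k))
    P = np.zeros((Xc.shape[1], k))
    W = np.zeros((Xc.shape[1], k))
    q = np.zeros(k)
    Xd, yd = Xc.copy(), yc.copy()
    for a in range(k):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            k = a
            break
        w /= nw
        t = Xd @ w
        tt = t @ t
        p_load = Xd.T @ t / tt
        q[a] = yd @ t / tt
        T[:, a], P[:, a], W[:, a] = t, p_load, w
        Xd = Xd - np.outer(t, p_load)
        yd = yd - q[a] * t
    T, P, W, q = T[:, :k], P[:, :k], W[:, :k], q[:k]
    # contribution of each component to the fitted yield variance
    contrib = q**2 * (T**2).sum(axis=0) / n
    order = np.argsort(-contrib, kind="stable")
    comp_names = [f"PLS{i + 1}" for i in range(k)]
    scores = pd.DataFrame(T[:, order], index=index, columns=comp_names)
    loadings = pd.DataFrame(W[:, order], index=names, columns=comp_names)
    corr = pd.Series(
        [
            np.corrcoef(scores[c], y)[0, 1] if scores[c].std() > 0 else 0.0
            for c in comp_names
        ],
        index=comp_names,
    )
    dom = _dominant_categories(loadings, panel) if panel is not None else None
    cs = ComponentSet("PLS", scores, loadings, corr, dom)
    cs.fitted = y.mean() + T[:, order] @ q[order]  # for rank-equivalence checks
    return cs
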