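"""Frozen-PCA projection for visual classification of held-out samples.

Principal components are fitted on the training samples restricted to the
signature genes (per-gene centering and, by default, unit-variance scaling
with training statistics).  The model is then frozen: test samples are
projected with the stored rotation and scaling and can never influence the
components, so training coordinates are identical whether or not test
samples are present.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin


class FrozenPCA(BaseEstimator, TransformerMixin):
    """PCA with immutable training-derived centering/scaling and rotation.

    Parameters
    ----------
    n_components : int
    scale : bool
        Divide each gene by its training sd (correlation PCA) when True.

    Attributes (after ``fit``)
    --------------------------
    mean_, scale_ : per-gene training statistics
    components_ : (n_components, n_genes) orthonormal loadings; sign fixed
        so each component's largest-magnitude loading is positive
    explained_variance_ratio_ : non-increasing, sums to <= 1
    genes_ : gene identifiers retained (zero-variance genes are dropped
        with a warning before the fit)
    """

    def __init__(self, n_components: int = 3, scale: bool = True):
        self.n_components = n_components
        self.scale = scale

    def fit(self, X, y=None, feature_names=None):
        if isinstance(X, pd.DataFrame):
            feature_names = list(X.columns)
            X = X.to_numpy(float)
        X = np.asarray(X, float)
        n_samples, n_genes = X.shape
        names = (
            list(feature_names)
            if feature_names is not None
            else [str(i) for i in range(n_genes)]
        )
        sd = X.std(axis=0)
        keep = sd > 1e-10 * np.maximum(1.0, np.abs(X.mean(axis=0)))
        if not keep.all():
            dropped = [names[i] for i in np.flatnonzero(~keep)]
            warnings.warn(
                f"dropping zero-variance gene(s) before PCA: {dropped}",
                stacklevel=2,
            )
        X = X[:, keep]
        names = [n for n, k in zip(names, keep) if k]
        if self.n_components > min(len(names), n_samples - 1):
            raise ValueError(
                f"n_components={self.n_components} exceeds min(n_genes={len(names)}, "
                f"n_samples-1={n_samples - 1})"
            )
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0) if self.scale else np.ones(len(names))
        Z = (X - self.mean_) / self.scale_
        _, s, vt = np.linalg.svd(Z, full_matrices=False)
        comps = vt[: self.n_components]
        # deterministic sign: largest-magnitude loading positive
        for row in comps:
            j = int(np.argmax(np.abs(row)))
            if row[j] < 0:
                row *= -1
        self.components_ = comps
        var = s**2
        self.explained_variance_ratio_ = (var / var.sum())[: self.n_components]
        self.genes_ = names
        return self

    def transform(self, X):
        if isinstance(X, pd.DataFrame):
            missing = [g for g in self.genes_ if g not in X.columns]
            if missing:
                raise KeyError(f"signature gene(s) missing from matrix: {missing}")
            X = X[self.genes_].to_numpy(float)
        X = np.asarray(X, float)
        Z = (X - self.mean_) / self.scale_
        return Z @ self.components_.T


def fit_pca(
    x: pd.DataFrame,
    sheet: pd.DataFrame,
    genes: list[str],
    n_components: int = 3,
    scale: bool = True,
) -> FrozenPCA:
    """Fit frozen PCA on the training samples restricted to ``genes``."""
    missing = [g for g in genes if g not in x.index]
    if missing:
        raise KeyError(f"signature gene(s) missing from matrix: {missing}")
    return FrozenPCA(n_components=n_components, scale=scale).fit(
        x.loc[list(genes)].to_numpy().T, feature_names=list(genes)
    )


def project(model: FrozenPCA, x: pd.DataFrame) -> pd.DataFrame:
    """Project samples of a gene x sample matrix into the frozen space."""
    missing = [g for g in model.genes_ if g not in x.index]
    if missing:
        raise KeyError(f"signature gene(s) missing from matrix: {missing}")
    scores = model.transform(x.loc[model.genes_].to_numpy().T)
    return pd.DataFrame(
        scores,
        index=pd.Index(x.columns, name="sample_id"),
        columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
    )


def scores_table(
    model: FrozenPCA, x: pd.DataFrame, sheet: pd.DataFrame
) -> pd.DataFrame:
    """Plotting-ready score table: sample_id, PC columns, class, role."""
    scores = project(model, x).reset_index()
    info = sheet.set_index("sample_id").loc[list(x.columns)]
    scores["class_label"] = info["class_label"].to_numpy()
    scores["role"] = info["role"].to_numpy()
    return scores
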