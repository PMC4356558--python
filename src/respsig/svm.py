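"""Linear soft-margin SVM on standardized features, with decision values.

The classifier of the assay: a linear-kernel support vector machine trained
on per-gene standardized expression, used with an unbiased maximum-margin
hyperplane — the classification threshold is the raw decision value
d(x) = w . x_std + b compared against exactly 0, with no post-hoc bias
tuning or class weighting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC

from .io import labels_from_sheet


class SignatureSVM(BaseEstimator, ClassifierMixin):
    """Linear SVM over a gene signature with frozen training scaling.

    Features are standardized by the *training* mean and (population) sd;
    those statistics are stored and reused verbatim when scoring new
    samples.  Labels are +1 (respiratory sensitizer) / -1.

    Parameters
    ----------
    C : float
        Soft-margin cost of the SVM.

    Attributes
    ----------
    mean_, scale_ : ndarray of shape (n_features,)
        Training standardization statistics; zero-sd features get scale 1
        (they are constant, hence uninformative).
    coef_ : ndarray of shape (n_features,)
        Hyperplane weights in standardized feature space.
    intercept_ : float
        Hyperplane bias b.
    feature_names_ : list of str or None
        Signature gene identifiers when fitted from a DataFrame or given
        explicitly.
    """

    def __init__(self, C: float = 1.0):
        self.C = C

    def fit(self, X, y, feature_names=None):
        X, names = _as_array(X, feature_names)
        y = np.asarray(y)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValueError("X must be n_samples x n_features matching y")
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training data contains a single class")
        if set(classes) != {-1, 1}:
            raise ValueError("labels must be +1/-1")
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        constant = sd <= 1e-10 * np.maximum(1.0, np.abs(self.mean_))
        self.scale_ = np.where(constant, 1.0, sd)
        Xs = (X - self.mean_) / self.scale_
        # tight solver tolerance: keeps the hyperplane invariant to sample
        # order at the precision the elimination trace relies on
        svc = SVC(kernel="linear", C=self.C, tol=1e-7)
        svc.fit(Xs, y)
        self.coef_ = svc.coef_.ravel().copy()
        self.intercept_ = float(svc.intercept_[0])
        self.classes_ = classes
        self.feature_names_ = names
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        X, _ = _as_array(X, None, expect_names=self.feature_names_)
        Xs = (X - self.mean_) / self.scale_
        return Xs @ self.coef_ + self.intercept_

    def predict(self, X) -> np.ndarray:
        return np.where(self.decision_function(X) > 0, 1, -1)


def _as_array(X, feature_names, expect_names=None):
    if isinstance(X, pd.DataFrame):
        if expect_names is not None:
            missing = [g for g in expect_names if g not in X.columns]
            if missing:
                raise KeyError(f"signature gene(s) missing from matrix: {missing}")
            X = X[list(expect_names)]
        names = list(X.columns)
        return X.to_numpy(float), names
    arr = np.asarray(X, float)
    if feature_names is not None:
        feature_names = list(feature_names)
        if len(feature_names) != arr.shape[1]:
            raise ValueError("feature_names length mismatch")
    return arr, feature_names


def train_linear_svm(
    x: pd.DataFrame, sheet: pd.DataFrame, genes: list[str], C: float = 1.0
) -> SignatureSVM:
    """Fit the signature SVM from a gene x sample matrix and sample sheet."""
    missing = [g for g in genes if g not in x.index]
    if missing:
        raise KeyError(f"signature gene(s) missing from matrix: {missing}")
    ordered = sheet.set_index("sample_id").loc[list(x.columns)]
    y = labels_from_sheet(ordered)
    X = x.loc[list(genes)].to_numpy().T  # samples x genes
    return SignatureSVM(C=C).fit(X, y, feature_names=list(genes))


def save_model(model: SignatureSVM, path) -> None:
    """Persist a fitted signature SVM as JSON (weights, bias, scaling)."""
    import json

    payload = {
        "C": model.C,
        "genes": model.feature_names_,
        "coef": model.coef_.tolist(),
        "intercept": model.intercept_,
        "mean": model.mean_.tolist(),
        "scale": model.scale_.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path) -> SignatureSVM:
    import json

    with open(path) as fh:
        payload = json.load(fh)
    model = SignatureSVM(C=payload["C"])
    model.feature_names_ = payload["genes"]
    model.coef_ = np.asarray(payload["coef"], float)
    model.intercept_ = float(payload["intercept"])
    model.mean_ = np.asarray(payload["mean"], float)
    model.scale_ = np.asarray(payload["scale"], float)
    model.classes_ = np.array([-1, 1])
    model.n_features_in_ = len(model.coef_)
    return model


def loocv_decision_values(X, y, C: float = 1.0) -> np.ndarray:
    """Leave-one-out cross-validated decision values.

    Each sample's decision value comes from an SVM trained on all other
    samples, with standardization statistics recomputed inside every fold so
    the held-out array never leaks into the scaling.  Deterministic.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    n = len(y)
    if n < 2:
        raise ValueError("LOOCV needs at least 2 samples")
    d = np.empty(n)
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        if len(np.unique(y[mask])) < 2:
            raise ValueError(
                f"leaving out sample {i} leaves a single-class training fold"
            )
        model = SignatureSVM(C=C).fit(X[mask], y[mask])
        d[i] = model.decision_function(X[i : i + 1])[0]
    return d
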