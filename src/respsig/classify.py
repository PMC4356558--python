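"""Scoring of independent samples and compound-level calls.

A trained signature SVM assigns each array a decision value
d = w . x_std + b using the *training* standardization statistics.  A
compound is called a sensitizer when any of its replicate stimulations has
d strictly greater than 0 (the any-replicate rule); vehicle controls are
scored but excluded from calls and metrics.  Assay performance is
summarized per replicate by ROC AUC and per compound by cooper statistics
(sensitivity, specificity, accuracy of the confusion matrix).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .io import RESPIRATORY
from .svm import SignatureSVM


def roc_auc(d, y) -> float:
    """Area under the ROC curve of decision values ``d`` against labels.

    Mann-Whitney formulation: the probability that a random positive
    outranks a random negative, ties credited 1/2.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC AUC undefined for single-class labels")
    return float(roc_auc_score(y, np.asarray(d, float)))


def predict_decision_values(
    model: SignatureSVM, x: pd.DataFrame, sheet: pd.DataFrame
) -> pd.DataFrame:
    """Decision table for every sample in ``x``.

    Columns: sample_id, compound, d, class_label, is_vehicle.  Vehicles are
    scored but flagged so downstream calls/metrics can exclude them.
    """
    genes = model.feature_names_
    if genes is None:
        raise ValueError("model lacks feature names; fit with a gene list")
    missing = [g for g in genes if g not in x.index]
    if missing:
        raise KeyError(f"signature gene(s) missing from matrix: {missing}")
    info = sheet.set_index("sample_id").loc[list(x.columns)]
    d = model.decision_function(x.loc[list(genes)].to_numpy().T)
    return pd.DataFrame(
        {
            "sample_id": list(x.columns),
            "compound": info["compound"].to_numpy(),
            "d": d,
            "class_label": info["class_label"].to_numpy(),
            "is_vehicle": info["is_vehicle"].to_numpy(bool),
        }
    )


@dataclass
class CompoundCall:
    """Any-replicate compound call: sensitizer iff max replicate d > 0."""

    compound: str
    decision_values: list[float]
    call: str  # "sensitizer" | "non_sensitizer"
    truth: str  # class_label


@dataclass
class CooperStats:
    """Confusion counts and rates of a predictive toxicology assay."""

    TP: int
    FP: int
    TN: int
    FN: int
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None

    def rounded_percent(self) -> dict:
        return {
            k: (None if v is None else round(100 * v))
            for k, v in {
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "accuracy": self.accuracy,
            }.items()
        }


def call_compounds(table: pd.DataFrame) -> list[CompoundCall]:
    """Per-compound calls from a decision table (vehicles excluded).

    Strict inequality: a maximum decision value of exactly 0 is a
    non-sensitizer call.
    """
    rows = table[~table["is_vehicle"].astype(bool)]
    calls = []
    for compound, grp in rows.groupby("compound", sort=True):
        d = grp["d"].astype(float).tolist()
        truths = set(grp["class_label"])
        if len(truths) != 1:
            raise ValueError(f"conflicting class labels for compound {compound!r}")
        calls.append(
            CompoundCall(
                compound=compound,
                decision_values=d,
                call="sensitizer" if max(d) > 0 else "non_sensitizer",
                truth=truths.pop(),
            )
        )
    return calls


def cooper_statistics(calls: list[CompoundCall]) -> CooperStats:
    """Compound-level sensitivity, specificity and accuracy.

    Rates with a zero denominator are reported as None (undefined), never
    as 0.
    """
    if not calls:
        raise ValueError("no compound calls")
    tp = sum(c.truth == RESPIRATORY and c.call == "sensitizer" for c in calls)
    fn = sum(c.truth == RESPIRATORY and c.call == "non_sensitizer" for c in calls)
    tn = sum(c.truth != RESPIRATORY and c.call == "non_sensitizer" for c in calls)
    fp = sum(c.truth != RESPIRATORY and c.call == "sensitizer" for c in calls)
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("need at least one positive and one negative compound")

    def rate(num, den):
        return num / den if den else None

    return CooperStats(
        TP=tp,
        FP=fp,
        TN=tn,
        FN=fn,
        sensitivity=rate(tp, tp + fn),
        specificity=rate(tn, tn + fp),
        accuracy=rate(tp + tn, tp + fp + tn + fn),
    )


def calls_frame(calls: list[CompoundCall]) -> pd.DataFrame:
    """Flatten compound calls to a decision-table-style frame."""
    return pd.DataFrame(
        {
            "compound": [c.compound for c in calls],
            "decision_values": [
                ";".join(f"{v:g}" for v in c.decision_values) for c in calls
            ],
            "call": [c.call for c in calls],
            "truth": [c.truth for c in calls],
        }
    )
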