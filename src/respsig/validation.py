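"""Signature robustness via repeated stratified resampling.

The biomarker-identification procedure is rerun on repeated stratified
70/30 splits of the training cohort; the percentage of iterations in which
each transcript enters the signature is its Validation Call Frequency
(VCF), a stability measure for the selection process.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import labels_from_sheet, validate_sample_sheet
from .selection import AnovaGeneFilter, KLDBackwardEliminator
from .svm import SignatureSVM


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def stratified_split(
    sheet: pd.DataFrame, train_frac: float = 0.7, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Class-stratified sample split; seed-deterministic.

    Per class, round(train_frac * n_class) samples (round half up) go to the
    training part; the split is disjoint and exhaustive.
    """
    validate_sample_sheet(sheet)
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train_ids: list[str] = []
    test_ids: list[str] = []
    for _, grp in sheet.groupby("class_label", sort=True):
        ids = grp["sample_id"].tolist()
        n_train = _round_half_up(train_frac * len(ids))
        if n_train < 1 or n_train >= len(ids):
            raise ValueError(
                f"class with {len(ids)} samples cannot appear in both parts "
                f"at train_frac={train_frac}"
            )
        perm = rng.permutation(len(ids))
        train_ids += [ids[i] for i in perm[:n_train]]
        test_ids += [ids[i] for i in perm[n_train:]]
    return sorted(train_ids), sorted(test_ids)


def vcf_crossvalidation(
    x: pd.DataFrame,
    sheet: pd.DataFrame,
    iterations: int = 20,
    K: int = 100,
    seed: int = 0,
    train_frac: float = 0.7,
    C: float = 1.0,
    backward_elimination: bool = False,
    elimination_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Validation Call Frequencies over repeated stratified splits.

    Per iteration: split the cohort, derive a signature on the training
    part (ANOVA filter at the same K; optionally followed by backward
    elimination), train the signature SVM and score the test part.  The VCF
    of a gene is the percentage of iterations whose signature contains it.
    Per-iteration seeds derive deterministically from ``seed``.

    Returns a frame with columns gene_id, count, vcf_percent (descending),
    carrying the per-iteration test AUCs in ``frame.attrs["test_aucs"]``.
    """
    from .classify import predict_decision_values, roc_auc

    counts = pd.Series(0, index=x.index, dtype=int)
    aucs: list[float] = []
    child_seeds = np.random.SeedSequence(seed).generate_state(iterations) % (2**31)
    for it in range(iterations):
        train_ids, test_ids = stratified_split(
            sheet, train_frac=train_frac, seed=int(child_seeds[it])
        )
        x_tr = x[train_ids]
        sheet_idx = sheet.set_index("sample_id")
        y_tr = labels_from_sheet(sheet_idx.loc[train_ids])
        flt = AnovaGeneFilter(K=K).fit(
            x_tr.to_numpy().T, y_tr, feature_names=list(x.index)
        )
        signature = flt.selected_genes_
        if backward_elimination:
            elim = KLDBackwardEliminator(C=C, **(elimination_kwargs or {})).fit(
                x_tr.loc[signature].to_numpy().T, y_tr, feature_names=signature
            )
            signature = elim.signature_
        counts[signature] += 1

        model = SignatureSVM(C=C).fit(
            x_tr.loc[signature].to_numpy().T, y_tr, feature_names=signature
        )
        table = predict_decision_values(model, x[test_ids], sheet)
        scored = table[~table["is_vehicle"]]
        y_te = np.where(scored["class_label"] == "respiratory", 1, -1)
        if len(np.unique(y_te)) == 2:
            aucs.append(roc_auc(scored["d"].to_numpy(), y_te))

    out = pd.DataFrame(
        {
            "gene_id": counts.index,
            "count": counts.to_numpy(),
            "vcf_percent": 100.0 * counts.to_numpy() / iterations,
        }
    ).sort_values(["vcf_percent", "gene_id"], ascending=[False, True], ignore_index=True)
    out.attrs["test_aucs"] = aucs
    return out
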