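"""Reading, writing and validation of the pipeline's tabular formats.

The canonical in-memory containers are plain pandas objects:

* expression matrix — ``DataFrame`` of log-scale normalized intensities,
  index = gene identifiers, columns = sample identifiers;
* sample sheet — ``DataFrame`` with one row per sample and the columns
  ``sample_id, compound, class_label, replicate, batch, is_vehicle, role``.

Both are validated on read and on demand; missing values are rejected
(arrays are complete after normalization).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

RESPIRATORY = "respiratory"
NON_RESPIRATORY = "non_respiratory"
CLASS_LABELS = (RESPIRATORY, NON_RESPIRATORY)
ROLES = ("train", "test")

SHEET_COLUMNS = [
    "sample_id",
    "compound",
    "class_label",
    "replicate",
    "batch",
    "is_vehicle",
    "role",
]


class FormatError(ValueError):
    """A file or table violates the pipeline's format contract."""


def validate_expression_matrix(x: pd.DataFrame) -> pd.DataFrame:
    """Check matrix invariants; return the validated frame.

    Raises :class:`FormatError` on duplicate gene/sample identifiers or
    non-finite values.
    """
    dup_genes = x.index[x.index.duplicated()].unique()
    if len(dup_genes):
        raise FormatError(f"duplicate gene identifier(s): {list(map(str, dup_genes))}")
    dup_samples = x.columns[x.columns.duplicated()].unique()
    if len(dup_samples):
        raise FormatError(
            f"duplicate sample identifier(s): {list(map(str, dup_samples))}"
        )
    values = x.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        # locate the first offending cell for the error message
        for j, col in enumerate(x.columns):
            coerced = pd.to_numeric(x[col], errors="coerce")
            bad = coerced.index[coerced.isna() & x[col].notna()]
            if len(bad):
                raise FormatError(
                    f"non-numeric value at gene {bad[0]!r}, sample {col!r}"
                )
        raise FormatError("matrix contains non-numeric values")
    if not np.all(np.isfinite(values)):
        gi, sj = np.argwhere(~np.isfinite(values))[0]
        raise FormatError(
            f"non-finite value at gene {x.index[gi]!r}, sample {x.columns[sj]!r}"
        )
    return x


def read_expression_matrix(path) -> pd.DataFrame:
    """Read a tab-delimited gene x sample matrix.

    First column holds gene identifiers, header row holds sample identifiers.
    """
    x = pd.read_csv(path, sep="\t", index_col=0)
    x.index = x.index.astype(str)
    x.columns = x.columns.astype(str)
    if x.isna().any().any():
        gi = x.index[x.isna().any(axis=1)][0]
        raise FormatError(f"missing value in row for gene {gi!r}")
    for col in x.columns:
        if not np.issubdtype(x[col].dtype, np.number):
            coerced = pd.to_numeric(x[col], errors="coerce")
            bad = coerced.index[coerced.isna()][0]
            raise FormatError(f"non-numeric value at gene {bad!r}, sample {col!r}")
    return validate_expression_matrix(x)


def write_expression_matrix(x: pd.DataFrame, path) -> None:
    validate_expression_matrix(x)
    x.to_csv(path, sep="\t", index_label="gene_id")


def validate_sample_sheet(
    sheet: pd.DataFrame, x: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Check sample-sheet invariants; return the validated frame.

    Vehicle samples must carry the non-respiratory label (solvent controls
    are grouped with the negative class); replicate indices must be unique
    within (compound, role); if a matrix is given, its samples and the sheet's
    must agree one-to-one.
    """
    missing = [c for c in SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise FormatError(f"sample sheet missing column(s): {missing}")
    dup = sheet["sample_id"][sheet["sample_id"].duplicated()]
    if len(dup):
        raise FormatError(f"duplicate sample_id(s): {sorted(set(dup))}")
    bad_class = set(sheet["class_label"]) - set(CLASS_LABELS)
    if bad_class:
        raise FormatError(f"unknown class label(s): {sorted(bad_class)}")
    bad_role = set(sheet["role"]) - set(ROLES)
    if bad_role:
        raise FormatError(f"unknown role(s): {sorted(bad_role)}")
    if (sheet["replicate"] < 1).any():
        raise FormatError("replicate indices must be positive")
    veh = sheet[sheet["is_vehicle"].astype(bool)]
    if (veh["class_label"] != NON_RESPIRATORY).any():
        bad = veh.loc[veh["class_label"] != NON_RESPIRATORY, "sample_id"].tolist()
        raise FormatError(f"vehicle sample(s) not labelled non_respiratory: {bad}")
    dup_rep = sheet.duplicated(subset=["compound", "role", "replicate"])
    if dup_rep.any():
        rows = sheet.loc[dup_rep, ["compound", "role", "replicate"]]
        raise FormatError(
            f"replicate index reused within (compound, role): {rows.to_dict('records')}"
        )
    if x is not None:
        sheet_ids = set(sheet["sample_id"])
        mat_ids = set(map(str, x.columns))
        if sheet_ids != mat_ids:
            raise FormatError(
                f"sheet/matrix sample mismatch: only in sheet {sorted(sheet_ids - mat_ids)}, "
                f"only in matrix {sorted(mat_ids - sheet_ids)}"
            )
    return sheet


def read_sample_sheet(path, x: pd.DataFrame | None = None) -> pd.DataFrame:
    sheet = pd.read_csv(path)
    sheet["sample_id"] = sheet["sample_id"].astype(str)
    sheet["compound"] = sheet["compound"].astype(str)
    sheet["batch"] = sheet["batch"].astype(str)
    if sheet["is_vehicle"].dtype == object:
        sheet["is_vehicle"] = (
            sheet["is_vehicle"].astype(str).str.lower().isin(("true", "1", "yes"))
        )
    sheet["is_vehicle"] = sheet["is_vehicle"].astype(bool)
    sheet["replicate"] = sheet["replicate"].astype(int)
    return validate_sample_sheet(sheet, x)


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    validate_sample_sheet(sheet)
    sheet.to_csv(path, columns=SHEET_COLUMNS, index=False)


def labels_from_sheet(sheet: pd.DataFrame) -> np.ndarray:
    """Class labels as +/-1 (+1 = respiratory sensitizer)."""
    return np.where(sheet["class_label"].to_numpy() == RESPIRATORY, 1, -1)
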