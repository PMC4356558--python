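"""Batch adjustment and array-level quality control.

The batch adjuster is a location-only stand-in for empirical-Bayes batch
correction: per gene, each batch is mean-centred and shifted back to the
pooled per-gene grand mean, which removes additive batch offsets exactly and
leaves within-batch variation untouched.  The outlier detector flags arrays
far from their compound-group centroid in top-3 principal-component space,
a reproducible surrogate for the visual exclusion of aberrant replicate
stimulations.  The marker QC applies the Welch t-test of a maturation marker
(e.g. CD86 surface expression) per compound against its vehicle control, a
bioavailability check for poorly soluble chemicals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import validate_expression_matrix, validate_sample_sheet


@dataclass
class QCReport:
    """Outcome of an array-level QC step."""

    flagged_samples: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["sample_id", "reason"])
    )
    marker_pvalues: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["compound", "p_value", "significant"]
        )
    )

    def write_flags(self, path) -> None:
        self.flagged_samples.to_csv(path, sep="\t", index=False)

    def write_marker(self, path) -> None:
        self.marker_pvalues.to_csv(path, sep="\t", index=False)


def adjust_batches(x: pd.DataFrame, sheet: pd.DataFrame) -> pd.DataFrame:
    """Mean-centre batches per gene and restore the pooled grand mean.

    Batches with a single sample are left unadjusted with a warning. Output
    dimensions and ordering are unchanged; per-gene grand means are preserved
    to numerical precision.
    """
    validate_expression_matrix(x)
    validate_sample_sheet(sheet, x)
    batches = sheet.set_index("sample_id").loc[list(x.columns), "batch"]
    out = x.copy()
    grand_mean = x.mean(axis=1)
    for batch, ids in batches.groupby(batches).groups.items():
        cols = list(ids)
        if len(cols) < 2:
            warnings.warn(
                f"batch {batch!r} has a single sample; left unadjusted",
                stacklevel=2,
            )
            continue
        batch_mean = x[cols].mean(axis=1)
        out[cols] = x[cols].sub(batch_mean, axis=0).add(grand_mean, axis=0)
    return out


def detect_outliers(
    x: pd.DataFrame, sheet: pd.DataFrame, k: float = 4.0
) -> QCReport:
    """Flag arrays far from their compound-group centre in PC space.

    All samples are projected onto the top three principal components of the
    gene-centred matrix; a sample is flagged when its Euclidean distance to
    its (compound, role) group centre exceeds ``median + k * MAD`` of all
    within-group distances.  The group centre is the coordinate-wise median,
    which an aberrant replicate cannot drag toward itself (a mean centroid
    would make the outlier's clean siblings look deviant too).  Deterministic
    and invariant to sample order.
    """
    validate_expression_matrix(x)
    validate_sample_sheet(sheet, x)
    if x.shape[1] < 3:
        raise ValueError("outlier detection needs at least 3 samples")
    info = sheet.set_index("sample_id").loc[list(x.columns)]
    groups = list(zip(info["compound"], info["role"]))
    if len(set(groups)) < 3:
        warnings.warn(
            "fewer than 3 replicate groups; outlier detection skipped",
            stacklevel=2,
        )
        return QCReport()

    centred = x.to_numpy().T - x.to_numpy().mean(axis=1)  # samples x genes
    n_comp = min(3, centred.shape[0] - 1, centred.shape[1])
    # deterministic full SVD; scores in top-PC space
    u, s, _ = np.linalg.svd(centred, full_matrices=False)
    scores = u[:, :n_comp] * s[:n_comp]

    dist = np.empty(len(x.columns))
    group_index = pd.Series(range(len(groups)), index=pd.MultiIndex.from_tuples(groups))
    for _, idx in group_index.groupby(level=[0, 1]).groups.items():
        rows = group_index.loc[idx].to_numpy()
        centre = np.median(scores[rows], axis=0)
        dist[rows] = np.linalg.norm(scores[rows] - centre, axis=1)

    med = np.median(dist)
    mad = np.median(np.abs(dist - med))
    threshold = med + k * mad
    flagged = [
        {
            "sample_id": sid,
            "reason": f"PC-space distance {dist[i]:.3g} exceeds median+{k:g}*MAD ({threshold:.3g})",
        }
        for i, sid in enumerate(x.columns)
        if dist[i] > threshold
    ]
    return QCReport(
        flagged_samples=pd.DataFrame(flagged, columns=["sample_id", "reason"])
    )


def marker_qc_ttest(
    marker_values: pd.Series,
    sheet: pd.DataFrame,
    vehicle_map: dict[str, str] | None = None,
    alpha: float = 0.05,
) -> QCReport:
    """Welch t-test of a per-sample marker per compound against its vehicle.

    ``marker_values`` is indexed by sample_id.  ``vehicle_map`` maps each
    compound to its vehicle-control compound name; when omitted and exactly
    one vehicle compound exists in the sheet it is used for every compound.
    Two-sided p-values; groups with zero variance and equal means give p=1.
    """
    validate_sample_sheet(sheet)
    info = sheet.set_index("sample_id")
    vehicles = sorted(set(info.loc[info["is_vehicle"], "compound"]))
    if vehicle_map is None:
        if len(vehicles) != 1:
            raise ValueError(
                "vehicle_map required when the sheet has != 1 vehicle compound"
            )
        vehicle_map = {}
    default_vehicle = vehicles[0] if len(vehicles) == 1 else None

    rows = []
    compounds = sorted(set(info.loc[~info["is_vehicle"], "compound"]))
    for compound in compounds:
        vehicle = vehicle_map.get(compound, default_vehicle)
        if vehicle is None:
            raise ValueError(f"no vehicle mapped for compound {compound!r}")
        grp = marker_values[info.index[info["compound"] == compound]].to_numpy(float)
        veh = marker_values[info.index[info["compound"] == vehicle]].to_numpy(float)
        if len(grp) < 2 or len(veh) < 2:
            raise ValueError(
                f"compound {compound!r} or its vehicle has <2 replicates"
            )
        if np.ptp(grp) == 0 and np.ptp(veh) == 0:
            p = 1.0 if grp[0] == veh[0] else 0.0
        else:
            p = float(stats.ttest_ind(grp, veh, equal_var=False).pvalue)
            if np.isnan(p):
                p = 1.0
        rows.append(
            {"compound": compound, "p_value": p, "significant": bool(p < alpha)}
        )
    return QCReport(marker_pvalues=pd.DataFrame(rows))
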