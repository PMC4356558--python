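"""Packaged reference tables of the published assay validation.

Three small fixtures ship with the package:

* the independent-test-set SVM decision values per replicate stimulation,
  with the published compound-level calls;
* the maturation-marker (CD86) significance calls of the training-panel
  stimulations against their vehicle controls;
* the replication scheme of the training and independent test cohorts
  (arrays per compound, vehicles included).

They let the compound-calling and metrics stages be exercised against the
published validation without the original arrays, which are not shipped.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

# geometry of the published feature selection: candidate transcripts that
# survived the ANOVA p-value filter, and eliminations at the KL-error minimum
CANDIDATE_COUNT = 999
N_REMOVED_AT_KLD_MIN = 610


def _load(name: str) -> pd.DataFrame:
    with resources.files("respsig.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_test_set_decisions() -> pd.DataFrame:
    """Per-replicate decision values of the independent test set.

    Columns: compound, class_label, replicate, d, published_call.  As a
    decision table it carries no vehicle rows (vehicle controls were
    excluded from the published calls).
    """
    df = _load("test_set_decision_values.tsv")
    df["is_vehicle"] = False
    df["sample_id"] = df["compound"] + "_r" + df["replicate"].astype(str)
    return df


def load_marker_significance() -> pd.DataFrame:
    """CD86 marker QC significance call per training-panel compound."""
    df = _load("marker_significance.tsv")
    df["significant"] = df["significant"].astype(bool)
    return df


def load_study_design() -> pd.DataFrame:
    """Replication scheme of both cohorts (arrays per compound)."""
    df = _load("study_design.tsv")
    df["is_vehicle"] = df["is_vehicle"].astype(bool)
    return df
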