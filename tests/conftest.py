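import numpy as np
import pandas as pd
import pytest

from respsig import SimConfig, generate


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale cohort with clear signal: 200 genes, 10 signal."""
    cfg = SimConfig(
        n_genes=200,
        n_signal_genes=10,
        effect_size_mean=1.5,
        noise_sd=0.3,
        n_resp_compounds=4,
        n_nonresp_compounds=8,
        replicates_per_compound=3,
        n_vehicle_replicates=3,
        seed=42,
    )
    return generate(cfg)


@pytest.fixture
def toy_matrix():
    """3-gene x 4-sample matrix with matching sheet."""
    x = pd.DataFrame(
        np.arange(12, dtype=float).reshape(3, 4),
        index=["G1", "G2", "G3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    sheet = pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3", "s4"],
            "compound": ["a", "a", "b", "b"],
            "class_label": [
                "respiratory",
                "respiratory",
                "non_respiratory",
                "non_respiratory",
            ],
            "replicate": [1, 2, 1, 2],
            "batch": ["B1", "B1", "B1", "B1"],
            "is_vehicle": [False, False, False, False],
            "role": ["train", "train", "train", "train"],
        }
    )
    return x, sheet


def make_sheet(n_resp, n_nonresp, batch="B1", role="train"):
    """Minimal valid sheet with one compound per sample."""
    rows = []
    for i in range(n_resp):
        rows.append(
            dict(sample_id=f"r{i}", compound=f"rc{i}", class_label="respiratory",
                 replicate=1, batch=batch, is_vehicle=False, role=role)
        )
    for i in range(n_nonresp):
        rows.append(
            dict(sample_id=f"n{i}", compound=f"nc{i}", class_label="non_respiratory",
                 replicate=1, batch=batch, is_vehicle=False, role=role)
        )
    return pd.DataFrame(rows)
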