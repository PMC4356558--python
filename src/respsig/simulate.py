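"""Synthetic expression cohorts with known ground truth.

The generator emulates the statistical structure of a chemically stimulated
dendritic-cell-surrogate microarray study: a gene x sample log-scale matrix
in which a designated subset of signal genes carries a class mean-shift
between respiratory and non-respiratory sensitizers, replicate stimulations
of the same compound share a compound-level random effect, arrays carry
additive batch offsets, solvent-only vehicle controls are drawn from the
negative-class background, and an aberrant outlier array can be injected.

Model per gene g and sample j:

    x_gj = mu_g + delta_g * 1[class_j = respiratory]
                + c_{g, compound_j} + b_{batch_j} + eps_gj

with eps ~ N(0, noise_sd^2), c ~ N(0, compound_sd^2) shared across a
compound's replicates, b a fixed per-batch scalar shift, and
delta_g ~ sign_g * N(effect_size_mean, effect_size_sd^2) for signal genes
(half up-, half down-regulated), zero otherwise.  Vehicles have delta = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import NON_RESPIRATORY, RESPIRATORY, SHEET_COLUMNS

BASELINE_MEAN = 7.0  # log2-scale array intensity baseline
BASELINE_SD = 1.0


@dataclass
class SimConfig:
    """Design of one synthetic cohort.

    Defaults mirror the study design at reduced gene count: 10 respiratory
    and 20 non-respiratory compounds in biological triplicate plus two
    vehicle-control groups of 6 replicates, 2000 transcripts of which 50
    carry a class effect of mean 1.5 log-units against replicate noise of
    sd 0.3.
    """

    n_genes: int = 2000
    n_signal_genes: int = 50
    effect_size_mean: float = 1.5
    effect_size_sd: float = 0.2
    compound_sd: float = 0.15
    noise_sd: float = 0.3
    n_resp_compounds: int = 10
    n_nonresp_compounds: int = 20
    replicates_per_compound: int = 3
    n_vehicle_replicates: int = 6
    batch_shifts: list[float] = field(default_factory=lambda: [0.0])
    outlier_magnitude: float | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_signal_genes > self.n_genes:
            raise ValueError(
                f"n_signal_genes ({self.n_signal_genes}) > n_genes ({self.n_genes})"
            )
        for name in ("effect_size_sd", "compound_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in (
            "n_genes",
            "n_resp_compounds",
            "n_nonresp_compounds",
            "replicates_per_compound",
            "n_vehicle_replicates",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not self.batch_shifts:
            raise ValueError("batch_shifts must list at least one batch")


@dataclass
class SimTruth:
    """Ground truth of a generated cohort, for recovery tests."""

    signal_gene_ids: list[str]
    effects: pd.Series  # per-gene true class effect delta_g (0 for noise genes)
    outlier_sample_ids: list[str]

    def write(self, path) -> None:
        df = pd.DataFrame(
            {
                "gene_id": self.effects.index,
                "true_effect": self.effects.to_numpy(),
                "is_signal": [g in set(self.signal_gene_ids) for g in self.effects.index],
            }
        )
        df.to_csv(path, sep="\t", index=False)


VEHICLE_COMPOUNDS = ("vehicle_dmso", "vehicle_water")


def generate(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Draw one cohort; identical config + seed gives bit-identical output.

    Returns (expression matrix, sample sheet, truth).  Samples are laid out
    compound by compound (respiratory, then non-respiratory, then the two
    vehicle groups), batches assigned cyclically so every batch holds
    multiple samples; all samples carry role ``train``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    signal_idx = rng.choice(config.n_genes, size=config.n_signal_genes, replace=False)
    signal_idx.sort()

    effects = np.zeros(config.n_genes)
    if config.n_signal_genes:
        magnitudes = rng.normal(
            config.effect_size_mean, config.effect_size_sd, config.n_signal_genes
        )
        signs = np.ones(config.n_signal_genes)
        signs[config.n_signal_genes // 2 :] = -1.0  # half up-, half down-regulated
        effects[signal_idx] = signs * magnitudes

    mu = rng.normal(BASELINE_MEAN, BASELINE_SD, config.n_genes)

    # sample layout
    compounds: list[tuple[str, str, bool, int]] = []  # (compound, class, vehicle, reps)
    for i in range(config.n_resp_compounds):
        compounds.append((f"resp_{i + 1:02d}", RESPIRATORY, False,
                          config.replicates_per_compound))
    for i in range(config.n_nonresp_compounds):
        compounds.append((f"nonresp_{i + 1:02d}", NON_RESPIRATORY, False,
                          config.replicates_per_compound))
    for veh in VEHICLE_COMPOUNDS:
        compounds.append((veh, NON_RESPIRATORY, True, config.n_vehicle_replicates))

    rows = []
    columns = []
    sample_class = []
    n_batches = len(config.batch_shifts)
    sample_counter = 0
    compound_effect = {}
    for compound, klass, is_vehicle, reps in compounds:
        compound_effect[compound] = rng.normal(0.0, config.compound_sd, config.n_genes)
        for rep in range(1, reps + 1):
            sid = f"S{sample_counter + 1:03d}_{compound}_r{rep}"
            batch = f"B{sample_counter % n_batches + 1}"
            rows.append(
                {
                    "sample_id": sid,
                    "compound": compound,
                    "class_label": klass,
                    "replicate": rep,
                    "batch": batch,
                    "is_vehicle": is_vehicle,
                    "role": "train",
                }
            )
            columns.append(sid)
            sample_class.append(klass)
            sample_counter += 1

    sheet = pd.DataFrame(rows, columns=SHEET_COLUMNS)
    n_samples = len(columns)

    values = np.empty((config.n_genes, n_samples))
    batch_shift = np.array(
        [config.batch_shifts[i % n_batches] for i in range(n_samples)]
    )
    is_resp = np.array([c == RESPIRATORY for c in sample_class])
    for j in range(n_samples):
        comp = sheet.at[j, "compound"]
        values[:, j] = (
            mu
            + (effects if is_resp[j] else 0.0)
            + compound_effect[comp]
            + batch_shift[j]
            + rng.normal(0.0, config.noise_sd, config.n_genes)
        )

    outlier_ids: list[str] = []
    if config.outlier_magnitude is not None:
        non_vehicle = sheet.index[~sheet["is_vehicle"]].to_numpy()
        pick = int(rng.choice(non_vehicle))
        extra_sd = config.outlier_magnitude * config.noise_sd
        values[:, pick] += rng.normal(0.0, extra_sd, config.n_genes)
        outlier_ids.append(sheet.at[pick, "sample_id"])

    x = pd.DataFrame(values, index=genes, columns=columns)
    truth = SimTruth(
        signal_gene_ids=[genes[i] for i in signal_idx],
        effects=pd.Series(effects, index=genes, name="true_effect"),
        outlier_sample_ids=outlier_ids,
    )
    return x, sheet, truth


def config_from_dict(d: dict) -> SimConfig:
    known = {f for f in SimConfig.__dataclass_fields__}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown simulation config key(s): {sorted(unknown)}")
    return SimConfig(**d)


def config_to_dict(config: SimConfig) -> dict:
    return asdict(config)
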