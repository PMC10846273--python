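"""Synthetic coevolution experiments observed through colony plating.

Emulates the statistical structure of a yeast cooperator/cheater
serial-transfer study: replicate lines propagated by daily 1:100 dilution,
with the cooperator frequency assayed every ~50 generations by plating
~200 colonies and scoring the hygromycin-resistant ones.  The resistance
cassette replaces the invertase gene, so resistant colonies count
*cheaters* and the cooperator frequency is one minus the resistant
fraction.

The latent dynamics (``privgood.dynamics``) are deterministic and shared
by all replicate lines of a design; lines differ only through the binomial
colony-sampling noise.  Every random draw is made from a per-line,
per-assay child seed derived from the design's master seed, so any single
record can be regenerated in isolation and a whole table is byte-stable
under re-runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .dynamics import (
    TransferRegime,
    assay_transfer_indices,
    simulate_serial_transfers,
    step_frequency,
)
from .model import ModelParams

__all__ = [
    "TrajectoryRecord",
    "ExperimentDesign",
    "neutral_params",
    "child_seed",
    "sample_assay",
    "generate_coevolution_dataset",
    "generate_competition_assay",
    "write_records_tsv",
    "read_records_tsv",
    "write_design_config",
]

RECORD_COLUMNS = ["line_id", "generation", "x_true", "n_colonies", "n_resistant", "seed"]


def neutral_params(fmax: float = 1.0, Km: float = 1.0, r: float = 1.0) -> ModelParams:
    """Parameters for a non-public-good sugar: no privatization, no cost.

    With alpha = 0 both types draw the identical shared pool and C = 0
    removes the producer's burden, so cooperator and cheater fitness are
    equal and the latent frequency never moves — the glucose/fructose
    control condition.
    """
    return ModelParams(fmax=fmax, Km=Km, C=0.0, r=r, alpha=0.0)


@dataclass(frozen=True)
class TrajectoryRecord:
    """One plating assay: latent frequency plus observed colony counts."""

    line_id: str
    generation: float
    x_true: float
    n_colonies: int
    n_resistant: int
    seed: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.x_true <= 1.0):
            raise ValueError(f"x_true must be in [0, 1], got {self.x_true}")
        if not (0 <= self.n_resistant <= self.n_colonies):
            raise ValueError("need 0 <= n_resistant <= n_colonies")


@dataclass(frozen=True)
class ExperimentDesign:
    """A complete synthetic coevolution experiment.

    Defaults mirror the sucrose arm of the study: six replicate lines
    started at 1:1 cooperator:cheater, 1:100 daily transfers for ~200
    generations, assays of ~200 colonies every 50 generations.  Control
    arms use three lines and ``neutral_params()``.
    """

    truth: ModelParams
    regime: TransferRegime = TransferRegime()
    n_lines: int = 6
    x0: float = 0.5
    n_colonies_nominal: int = 200
    colony_count_model: str = "fixed"  # or "poisson"
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 1:
            raise ValueError(f"n_lines must be >= 1, got {self.n_lines}")
        if not (0.0 <= self.x0 <= 1.0):
            raise ValueError(f"x0 must be in [0, 1], got {self.x0}")
        if self.n_colonies_nominal < 1:
            raise ValueError("n_colonies_nominal must be >= 1")
        if self.colony_count_model not in ("fixed", "poisson"):
            raise ValueError("colony_count_model must be 'fixed' or 'poisson'")


def child_seed(master_seed: int, line_index: int, assay_index: int) -> int:
    """Deterministic per-(line, assay) seed below 2**31.

    Splits the master seed through numpy's SeedSequence entropy pipeline,
    keyed on the line and assay indices, so records are independently
    regenerable and well decorrelated across the table.
    """
    ss = np.random.SeedSequence([int(master_seed), int(line_index), int(assay_index)])
    return int(ss.generate_state(1, np.uint64)[0] % (2**31))


def sample_assay(x_true: float, n_colonies: int, seed: int) -> int:
    """Colony-plating observation: resistant (cheater) colony count.

    n_resistant ~ Binomial(n_colonies, 1 - x_true), deterministic given
    the seed.
    """
    if not (0.0 <= x_true <= 1.0):
        raise ValueError(f"x_true must be in [0, 1], got {x_true}")
    if n_colonies < 1:
        raise ValueError(f"n_colonies must be >= 1, got {n_colonies}")
    rng = np.random.default_rng(seed)
    return int(rng.binomial(n_colonies, 1.0 - x_true))


def _draw_record(
    line_id: str,
    line_index: int,
    assay_index: int,
    generation: float,
    x_true: float,
    design: ExperimentDesign,
) -> TrajectoryRecord:
    seed = child_seed(design.master_seed, line_index, assay_index)
    rng = np.random.default_rng(seed)
    if design.colony_count_model == "poisson":
        n = max(1, int(rng.poisson(design.n_colonies_nominal)))
    else:
        n = design.n_colonies_nominal
    k = int(rng.binomial(n, 1.0 - x_true))
    return TrajectoryRecord(line_id, generation, x_true, n, k, seed)


def generate_coevolution_dataset(design: ExperimentDesign) -> pd.DataFrame:
    """Long-format table of plating assays for every line of a design.

    The latent trajectory is simulated once under ``design.truth`` and
    shared by all lines; assays are taken at generation 0 and at the
    transfers nearest each multiple of the assay interval.  Columns are
    line_id, generation, x_true, n_colonies, n_resistant, seed.
    """
    traj = simulate_serial_transfers(design.truth, design.regime, design.x0)
    idx = assay_transfer_indices(design.regime)
    records = []
    for i in range(design.n_lines):
        line_id = f"L{i + 1}"
        for j, t in enumerate(idx):
            records.append(
                _draw_record(line_id, i, j, float(traj.generations[t]), float(traj.x[t]), design)
            )
    return pd.DataFrame([r.__dict__ for r in records], columns=RECORD_COLUMNS)


def generate_competition_assay(
    params: ModelParams,
    x0: float = 0.5,
    duration_generations: float = math.log2(100),
    n_colonies: int = 200,
    seed: int = 0,
    line_id: str = "competition",
) -> TrajectoryRecord:
    """One competition assay: a single batch of growth, then one plating.

    Two strains are mixed at frequency ``x0``, grown for one batch
    (default one transfer's worth of generations, ~6.6), and the final
    composition is observed by plating ``n_colonies`` colonies.
    """
    x_end = step_frequency(params, x0, duration_generations)
    k = sample_assay(x_end, n_colonies, seed)
    return TrajectoryRecord(line_id, duration_generations, x_end, n_colonies, k, seed)


def write_records_tsv(df: pd.DataFrame, path) -> None:
    """Write a record table in the long-format TSV dialect."""
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_records_tsv(path) -> pd.DataFrame:
    """Read a record table written by :func:`write_records_tsv`."""
    df = pd.read_csv(path, sep="\t")
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"record table missing columns: {sorted(missing)}")
    return df


def write_design_config(design: ExperimentDesign, path) -> None:
    """Serialize a design as flat key=value lines for provenance."""
    t, rg = design.truth, design.regime
    lines = {
        "fmax": t.fmax, "Km": t.Km, "C": t.C, "r": t.r, "alpha": t.alpha,
        "dilution_factor": rg.dilution_factor,
        "n_transfers": rg.n_transfers,
        "assay_interval_generations": rg.assay_interval_generations,
        "n_lines": design.n_lines,
        "x0": design.x0,
        "n_colonies_nominal": design.n_colonies_nominal,
        "colony_count_model": design.colony_count_model,
        "master_seed": design.master_seed,
    }
    with open(path, "w") as fh:
        for k, v in lines.items():
            fh.write(f"{k}={v}\n")
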