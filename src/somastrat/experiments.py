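"""Self-contained benchmark experiments exercising the pipeline's guarantees.

Each function builds its inputs with the synthetic generator (or directly
from the stated sampling scheme), runs the relevant part of the package,
and returns the measured quantity:

* familywise error of the Bonferroni-thresholded univariate Fine-Gray
  screen under a global null with block-correlated proteins;
* the silhouette-selected number of groups on two-group data;
* normalization QC on a clean plate set (QC-ratio band coverage and the
  largest plate scale factor).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import OutcomeData
from .normalize import normalize_pipeline
from .screening import univariate_screen
from .simulate import SimConfig, simulate_cohort
from .stratify import select_k

__all__ = ["null_screen_fwer", "two_group_k_selection", "clean_plate_qc"]


def null_screen_fwer(seed: int, n_replicates: int = 500, n_patients: int = 150,
                     n_proteins: int = 200, block_size: int = 10,
                     rho: float = 0.5, alpha: float = 0.05) -> float:
    """Empirical FWER of the Bonferroni-thresholded univariate screen.

    Per replicate: *n_patients* subjects with *n_proteins* standardized
    proteins in equicorrelated blocks (within-block correlation *rho*);
    event times independent of every protein, with ~30% cause-1 events,
    ~25% competing deaths and the rest censored.  A replicate counts as a
    familywise error when any protein is rejected at alpha/n_proteins.
    """
    rng = np.random.default_rng(seed)
    n_blocks = n_proteins // block_size
    cols = [f"P{j}" for j in range(n_proteins)]
    errors = 0
    for _ in range(n_replicates):
        shared = rng.normal(size=(n_patients, n_blocks))
        noise = rng.normal(size=(n_patients, n_proteins))
        X = (np.sqrt(rho) * np.repeat(shared, block_size, axis=1)
             + np.sqrt(1 - rho) * noise)
        df = pd.DataFrame(X, columns=cols)
        df = (df - df.mean()) / df.std(ddof=1)
        u = rng.uniform(size=n_patients)
        cause = np.where(u < 0.30, 1, np.where(u < 0.55, 2, 0))
        time = rng.exponential(5.0, size=n_patients)
        oc = OutcomeData(pd.Series(time, index=df.index),
                         pd.Series(cause, index=df.index))
        res = univariate_screen(df, oc, alpha=alpha)
        errors += res.n_selected > 0
    return errors / n_replicates


def two_group_k_selection(seed: int, n_patients: int = 250, n_proteins: int = 50,
                          group2_fraction: float = 0.38, delta: float = 1.5,
                          n_restarts: int = 25) -> int:
    """Silhouette-selected k on data with two planted patient groups."""
    rng = np.random.default_rng(seed)
    g = rng.uniform(size=n_patients) < group2_fraction
    X = rng.normal(size=(n_patients, n_proteins))
    X[g] += delta
    model = select_k(X, seed=seed, n_restarts=n_restarts)
    return model.k


def clean_plate_qc(seed: int, n_somamers: int = 500, n_plates: int = 3,
                   calibrators_per_plate: int = 5, qc_per_plate: int = 2,
                   noise_sd: float = 0.05,
                   sample_bias_range=(0.7, 1.4)) -> tuple:
    """Full normalization of a clean control-only plate set.

    Returns (percent of QC-sample per-SOMAmer ratios inside [0.84, 1.19],
    maximum plate scale factor).
    """
    cfg = SimConfig(
        n_patients=0, n_somamers=n_somamers, removal_count=0, dup2_count=0,
        dup3_count=0, n_plates=n_plates,
        calibrators_per_plate=calibrators_per_plate, qc_per_plate=qc_per_plate,
        buffer_per_plate=0, n_informative=0, noise_sd=noise_sd,
        sample_bias_range=tuple(sample_bias_range), seed=seed,
    )
    cohort = simulate_cohort(cfg)
    _, factors, report = normalize_pipeline(cohort.somamer_table)
    return 100.0 * report.qc_fraction_in_band, float(factors.plate_scale.max())
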