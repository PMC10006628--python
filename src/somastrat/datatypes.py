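"""In-memory containers for aptamer-array and clinical cohort data.

The containers are light dataclasses around pandas objects; construction
validates the invariants each downstream stage relies on (non-negative RFU,
unique reagent ids, legal cause codes, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SAMPLE_TYPES = ("calibrator", "qc", "buffer", "study")
DILUTION_SETS = (1, 2, 3)

#: cause codes for competing-risk follow-up
CENSORED, EVENT_HF, EVENT_DEATH = 0, 1, 2


@dataclass
class SomamerTable:
    """Plate-structured samples x SOMAmer RFU matrix with metadata.

    Parameters
    ----------
    rfu : pandas.DataFrame
        Samples (rows, indexed by sample id) by SOMAmer reagents (columns,
        indexed by SOMAmer id) of relative fluorescence units.
    somamer_meta : pandas.DataFrame
        Indexed by SOMAmer id with columns ``protein_symbol``,
        ``dilution_set`` (1, 2 or 3), ``is_hyb_control`` and
        ``flagged_removed`` (booleans).
    sample_meta : pandas.DataFrame
        Indexed by sample id with columns ``sample_type`` (one of
        ``calibrator``, ``qc``, ``buffer``, ``study``) and ``plate_id``.
    """

    rfu: pd.DataFrame
    somamer_meta: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.rfu.columns.equals(self.somamer_meta.index):
            raise ValueError("rfu columns must match somamer_meta index")
        if not self.rfu.index.equals(self.sample_meta.index):
            raise ValueError("rfu index must match sample_meta index")
        if self.somamer_meta.index.has_duplicates:
            dup = self.somamer_meta.index[self.somamer_meta.index.duplicated()]
            raise ValueError(f"duplicate somamer_id: {list(dup.unique())}")
        if self.sample_meta.index.has_duplicates:
            dup = self.sample_meta.index[self.sample_meta.index.duplicated()]
            raise ValueError(f"duplicate sample_id: {list(dup.unique())}")
        vals = self.rfu.to_numpy()
        if vals.size and not np.issubdtype(vals.dtype, np.number):
            raise ValueError("RFU matrix must be numeric")
        if vals.size and (~np.isfinite(vals)).any():
            r, c = np.argwhere(~np.isfinite(vals))[0]
            raise ValueError(
                f"non-finite RFU at sample {self.rfu.index[r]!r}, "
                f"somamer {self.rfu.columns[c]!r}"
            )
        if vals.size and (vals < 0).any():
            r, c = np.argwhere(vals < 0)[0]
            raise ValueError(
                f"negative RFU at sample {self.rfu.index[r]!r}, "
                f"somamer {self.rfu.columns[c]!r}"
            )
        for col in ("protein_symbol", "dilution_set", "is_hyb_control", "flagged_removed"):
            if col not in self.somamer_meta.columns:
                raise ValueError(f"somamer_meta missing column {col!r}")
        for col in ("sample_type", "plate_id"):
            if col not in self.sample_meta.columns:
                raise ValueError(f"sample_meta missing column {col!r}")
        bad = set(self.somamer_meta["dilution_set"]) - set(DILUTION_SETS)
        if bad:
            raise ValueError(f"dilution_set values outside {DILUTION_SETS}: {bad}")
        bad = set(self.sample_meta["sample_type"]) - set(SAMPLE_TYPES)
        if bad:
            raise ValueError(f"sample_type values outside {SAMPLE_TYPES}: {bad}")

    # -- convenience selectors used throughout the normalization chain -----
    @property
    def n_samples(self) -> int:
        return self.rfu.shape[0]

    @property
    def n_somamers(self) -> int:
        return self.rfu.shape[1]

    @property
    def plates(self) -> list:
        return list(pd.unique(self.sample_meta["plate_id"]))

    def hyb_control_ids(self) -> pd.Index:
        return self.somamer_meta.index[self.somamer_meta["is_hyb_control"].astype(bool)]

    def analyte_ids(self) -> pd.Index:
        """SOMAmer ids that are not hybridization controls."""
        return self.somamer_meta.index[~self.somamer_meta["is_hyb_control"].astype(bool)]

    def samples_of_type(self, *types: str) -> pd.Index:
        return self.sample_meta.index[self.sample_meta["sample_type"].isin(types)]

    def plate_samples(self, plate_id) -> pd.Index:
        return self.sample_meta.index[self.sample_meta["plate_id"] == plate_id]

    def copy(self) -> "SomamerTable":
        return SomamerTable(
            self.rfu.copy(), self.somamer_meta.copy(), self.sample_meta.copy()
        )


@dataclass
class ClinicalTable:
    """Per-patient clinical covariates with an explicit missingness mask."""

    values: pd.DataFrame
    binary_vars: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.binary_vars = tuple(self.binary_vars)
        unknown = set(self.binary_vars) - set(self.values.columns)
        if unknown:
            raise ValueError(f"binary_vars not in table: {sorted(unknown)}")

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean frame, True where the value is missing."""
        return self.values.isna()

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    @property
    def continuous_vars(self) -> tuple:
        return tuple(c for c in self.values.columns if c not in self.binary_vars)

    def copy(self) -> "ClinicalTable":
        return ClinicalTable(self.values.copy(), self.binary_vars)


@dataclass
class OutcomeData:
    """Follow-up time (years) and cause code per patient.

    Cause codes: 0 censored, 1 hospitalization for heart failure (the event
    of interest), 2 all-cause death (the competing event).
    """

    time: pd.Series
    cause: pd.Series

    def __post_init__(self) -> None:
        if not self.time.index.equals(self.cause.index):
            raise ValueError("time and cause must share a patient index")
        t = np.asarray(self.time, dtype=float)
        if (~np.isfinite(t)).any() or (t <= 0).any():
            bad = self.time.index[~(np.isfinite(t) & (t > 0))]
            raise ValueError(f"times must be finite and positive; offending: {list(bad[:5])}")
        c = np.asarray(self.cause)
        legal = {CENSORED, EVENT_HF, EVENT_DEATH}
        if not set(np.unique(c)).issubset(legal):
            raise ValueError(f"cause codes must be in {sorted(legal)}")
        self.cause = self.cause.astype(int)

    def __len__(self) -> int:
        return len(self.time)

    @property
    def patients(self) -> pd.Index:
        return self.time.index

    def subset(self, idx) -> "OutcomeData":
        return OutcomeData(self.time.loc[idx].copy(), self.cause.loc[idx].copy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.time, "cause": self.cause})
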