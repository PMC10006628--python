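"""Normalization and calibration of plate-structured aptamer RFU data.

Five multiplicative corrections remove systematic assay biases, each built
on the same median-of-ratios primitive:

1. **Hybridization control normalization** — per-sample scale factor from
   the spiked hybridization control sequences, reference = per-control
   median within the plate.
2. **Intraplate median signal normalization** — per-(calibrator x dilution
   set) factors against the within-plate calibrator medians; applied to
   calibrator samples only.
3. **Plate scaling** — one factor per plate: median over SOMAmers of
   (global calibrator reference / local calibrator median).
4. **Calibration** — per-(plate x SOMAmer) factor aligning local calibrator
   medians to the global calibrator reference.
5. **Median normalization to a reference** — per-(sample x dilution)
   factors for study/QC/buffer samples against a normalization reference.

Acceptance bands: hybridization, intraplate and plate factors are expected
in [0.4, 2.5]; at least 85% of QC-sample per-SOMAmer ratios to the
reference are expected inside [0.84, 1.19].

Even-count medians are the midpoint of the two central order statistics
(numpy convention); hybridization controls are excluded from all
analyte-level medians.  Every step works on a copy of its input.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import SomamerTable

__all__ = [
    "GlobalReference",
    "NormFactors",
    "QcReport",
    "hybridization_normalize",
    "intraplate_median_normalize",
    "build_global_reference",
    "plate_scale",
    "calibrate",
    "median_normalize_to_reference",
    "qc_report",
    "normalize_pipeline",
]

FACTOR_BAND = (0.4, 2.5)
QC_RATIO_BAND = (0.84, 1.19)
QC_PASS_FRACTION = 0.85


@dataclass
class GlobalReference:
    """Per-SOMAmer reference RFU levels.

    ``calibrator_ref`` anchors plate scaling and calibration (median over
    all calibrator samples); ``normalization_ref`` anchors the final median
    normalization of study/QC/buffer samples.
    """

    calibrator_ref: pd.Series
    normalization_ref: pd.Series = None

    def __post_init__(self):
        if self.normalization_ref is None:
            self.normalization_ref = self.calibrator_ref.copy()
        for name, ref in (("calibrator_ref", self.calibrator_ref),
                          ("normalization_ref", self.normalization_ref)):
            vals = np.asarray(ref, dtype=float)
            if (vals <= 0).any() or (~np.isfinite(vals)).any():
                raise ValueError(f"{name} must be strictly positive and finite")


@dataclass
class NormFactors:
    """Scale factors accumulated along the normalization chain."""

    hyb: pd.Series = None                 # per sample
    intraplate: pd.DataFrame = None       # (calibrator sample, dilution) -> factor
    plate_scale: pd.Series = None         # per plate
    calibration: pd.DataFrame = None      # plates x somamers
    ref_median: pd.DataFrame = None       # (sample, dilution) -> factor
    qc_ratios: pd.DataFrame = None        # QC samples x somamers

    def merged_with(self, other: "NormFactors") -> "NormFactors":
        out = NormFactors()
        for f in ("hyb", "intraplate", "plate_scale", "calibration",
                  "ref_median", "qc_ratios"):
            mine, theirs = getattr(self, f), getattr(other, f)
            setattr(out, f, theirs if theirs is not None else mine)
        return out


def _check_positive(values, what: str) -> None:
    vals = np.asarray(values, dtype=float)
    if (~np.isfinite(vals)).any() or (vals <= 0).any():
        raise ValueError(f"{what} must be strictly positive and finite")


def hybridization_normalize(table: SomamerTable):
    """Per-sample scale from the hybridization controls (within-plate reference).

    For each control the reference is its median RFU within the plate; the
    ratio reference/measured is formed per control and the sample factor is
    the median of those ratios.  Every RFU in the sample, controls
    included, is multiplied by the factor.
    """
    out = table.copy()
    hyb = table.hyb_control_ids()
    if len(hyb) == 0:
        raise ValueError("no hybridization-control SOMAmers present")
    factors = pd.Series(np.nan, index=out.rfu.index, name="hyb_factor")
    for plate in out.plates:
        rows = out.plate_samples(plate)
        ctrl = out.rfu.loc[rows, hyb]
        _check_positive(ctrl, f"hybridization control RFU on plate {plate!r}")
        ref = ctrl.median(axis=0)  # per-control plate median
        ratios = ref.to_numpy()[None, :] / ctrl.to_numpy()
        factors.loc[rows] = np.median(ratios, axis=1)
    out.rfu = out.rfu.mul(factors, axis=0)
    return out, NormFactors(hyb=factors)


def intraplate_median_normalize(table: SomamerTable, sample_group=("calibrator",)):
    """Per-dilution median signal normalization within each plate.

    Applied to calibrator samples (the default group): for each sample and
    dilution set, the factor is the median over analyte SOMAmers of
    (local reference / measured), where the local reference is the
    per-SOMAmer median over the group within the plate.
    """
    out = table.copy()
    analytes = out.analyte_ids()
    dil = out.somamer_meta.loc[analytes, "dilution_set"]
    records = []
    for plate in out.plates:
        rows = out.sample_meta.index[
            (out.sample_meta["plate_id"] == plate)
            & out.sample_meta["sample_type"].isin(sample_group)
        ]
        if len(rows) == 0:
            continue
        block = out.rfu.loc[rows, analytes]
        _check_positive(block, f"calibrator RFU on plate {plate!r}")
        local_ref = block.median(axis=0)
        for d in sorted(dil.unique()):
            cols = analytes[dil == d]
            if len(cols) == 0:
                raise ValueError(f"empty dilution set {d} on plate {plate!r}")
            ratios = local_ref[cols].to_numpy()[None, :] / block[cols].to_numpy()
            f = np.median(ratios, axis=1)
            out.rfu.loc[rows, cols] = out.rfu.loc[rows, cols].to_numpy() * f[:, None]
            for s, fv in zip(rows, f):
                records.append((s, d, fv))
    fac = pd.DataFrame(records, columns=["sample_id", "dilution_set", "factor"])
    return out, NormFactors(intraplate=fac)


def build_global_reference(table: SomamerTable) -> GlobalReference:
    """Per-SOMAmer median over all calibrator samples across plates."""
    cal = table.samples_of_type("calibrator")
    if len(cal) == 0:
        raise ValueError("no calibrator samples; cannot build a global reference")
    analytes = table.analyte_ids()
    ref = table.rfu.loc[cal, analytes].median(axis=0)
    return GlobalReference(calibrator_ref=ref)


def plate_scale(table: SomamerTable, ref: GlobalReference):
    """One multiplicative factor per plate from the calibrator medians.

    factor(plate) = median over SOMAmers of (reference / local calibrator
    median); applied to every measurement on the plate.
    """
    out = table.copy()
    analytes = out.analyte_ids()
    factors = {}
    for plate in out.plates:
        cal = out.sample_meta.index[
            (out.sample_meta["plate_id"] == plate)
            & (out.sample_meta["sample_type"] == "calibrator")
        ]
        if len(cal) == 0:
            raise ValueError(f"plate {plate!r} has no calibrator samples")
        local = out.rfu.loc[cal, analytes].median(axis=0)
        _check_positive(local, f"local calibrator medians on plate {plate!r}")
        factors[plate] = float(np.median(ref.calibrator_ref[analytes] / local))
        rows = out.plate_samples(plate)
        out.rfu.loc[rows] = out.rfu.loc[rows].to_numpy() * factors[plate]
    return out, NormFactors(plate_scale=pd.Series(factors, name="plate_scale"))


def calibrate(table: SomamerTable, ref: GlobalReference):
    """Per-(plate x SOMAmer) calibration to the global calibrator reference.

    After application the plate's calibrator median equals the global
    reference for every SOMAmer.
    """
    out = table.copy()
    analytes = out.analyte_ids()
    rows_factors = {}
    for plate in out.plates:
        cal = out.sample_meta.index[
            (out.sample_meta["plate_id"] == plate)
            & (out.sample_meta["sample_type"] == "calibrator")
        ]
        if len(cal) == 0:
            raise ValueError(f"plate {plate!r} has no calibrator samples")
        local = out.rfu.loc[cal, analytes].median(axis=0)
        _check_positive(local, f"local calibrator medians on plate {plate!r}")
        f = ref.calibrator_ref[analytes] / local
        rows = out.plate_samples(plate)
        out.rfu.loc[rows, analytes] = out.rfu.loc[rows, analytes].to_numpy() * f.to_numpy()[None, :]
        rows_factors[plate] = f
    calib = pd.DataFrame(rows_factors).T
    calib.index.name = "plate_id"
    return out, NormFactors(calibration=calib)


def median_normalize_to_reference(table: SomamerTable, ref: GlobalReference,
                                  sample_group=("study", "qc", "buffer")):
    """Per-(sample x dilution) median normalization to the reference.

    For each sample in the group, the factor per dilution set is the median
    over that dilution's analyte SOMAmers of (reference / measured).
    """
    out = table.copy()
    analytes = out.analyte_ids()
    dil = out.somamer_meta.loc[analytes, "dilution_set"]
    rows = out.samples_of_type(*sample_group)
    if len(rows) == 0:
        warnings.warn("no samples in the requested group; median normalization skipped")
        return out, NormFactors(ref_median=pd.DataFrame(
            columns=["sample_id", "dilution_set", "factor"]))
    records = []
    for d in sorted(dil.unique()):
        cols = analytes[dil == d]
        block = out.rfu.loc[rows, cols]
        _check_positive(block, f"sample RFU in dilution set {d}")
        ratios = ref.normalization_ref[cols].to_numpy()[None, :] / block.to_numpy()
        f = np.median(ratios, axis=1)
        out.rfu.loc[rows, cols] = block.to_numpy() * f[:, None]
        for s, fv in zip(rows, f):
            records.append((s, d, fv))
    fac = pd.DataFrame(records, columns=["sample_id", "dilution_set", "factor"])
    return out, NormFactors(ref_median=fac)


# ---------------------------------------------------------------------------
# QC report
# ---------------------------------------------------------------------------

@dataclass
class QcReport:
    """Pass/fail of every factor class against the acceptance bands."""

    factor_checks: dict = field(default_factory=dict)  # class -> (frac_in_band, pass)
    qc_fraction_in_band: float = float("nan")
    qc_pass: bool = True
    overall_pass: bool = True

    def to_dict(self) -> dict:
        return {
            "factor_checks": {
                k: {"fraction_in_band": v[0], "pass": v[1], "n": v[2]}
                for k, v in self.factor_checks.items()
            },
            "qc_fraction_in_band": self.qc_fraction_in_band,
            "qc_pass": self.qc_pass,
            "overall_pass": self.overall_pass,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def qc_report(factors: NormFactors) -> QcReport:
    """Check scale factors against [0.4, 2.5] and QC ratios against [0.84, 1.19].

    Only the hybridization, intraplate and plate scale factors carry the
    [0.4, 2.5] acceptance band; median-normalization factors are recorded
    in the factor set but not gated (buffer samples are background-only
    and their factors are uninformative).
    """
    rep = QcReport()
    lo, hi = FACTOR_BAND

    def check(name, values):
        vals = np.asarray(values, dtype=float)
        if vals.size == 0:
            return
        frac = float(((vals >= lo) & (vals <= hi)).mean())
        rep.factor_checks[name] = (frac, frac == 1.0, int(vals.size))

    if factors.hyb is not None:
        check("hybridization", factors.hyb)
    if factors.intraplate is not None and len(factors.intraplate):
        check("intraplate", factors.intraplate["factor"])
    if factors.plate_scale is not None:
        check("plate_scale", factors.plate_scale)

    if factors.qc_ratios is not None and factors.qc_ratios.size:
        r = factors.qc_ratios.to_numpy(dtype=float).ravel()
        qlo, qhi = QC_RATIO_BAND
        rep.qc_fraction_in_band = float(((r >= qlo) & (r <= qhi)).mean())
        rep.qc_pass = rep.qc_fraction_in_band >= QC_PASS_FRACTION
    rep.overall_pass = rep.qc_pass and all(ok for _, ok, _ in rep.factor_checks.values())
    return rep


def normalize_pipeline(table: SomamerTable):
    """Full chain: hybridization -> intraplate (calibrators) -> plate scale
    -> calibration -> median normalization to a reference; returns the
    normalized table, the merged factor set, and the QC report.

    The normalization reference stands in for the external population
    reference of the assay: the per-SOMAmer calibrator reference, which in
    a pooled-plasma design carries the population-average profile with far
    less sampling noise than any within-cohort median.  QC ratios
    (measured / normalization reference, per SOMAmer) are computed on the
    QC samples after the full chain.
    """
    t1, f_hyb = hybridization_normalize(table)
    t2, f_intra = intraplate_median_normalize(t1)
    ref = build_global_reference(t2)
    t3, f_plate = plate_scale(t2, ref)
    t4, f_cal = calibrate(t3, ref)

    analytes = t4.analyte_ids()
    ref.normalization_ref = ref.calibrator_ref.copy()
    t5, f_ref = median_normalize_to_reference(t4, ref)

    factors = NormFactors(
        hyb=f_hyb.hyb, intraplate=f_intra.intraplate,
        plate_scale=f_plate.plate_scale, calibration=f_cal.calibration,
        ref_median=f_ref.ref_median,
    )
    qc = t5.samples_of_type("qc")
    if len(qc):
        factors.qc_ratios = t5.rfu.loc[qc, analytes] / ref.normalization_ref[analytes]
    report = qc_report(factors)
    return t5, factors, report
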