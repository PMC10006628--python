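"""Synthetic cohort generator for end-to-end testing of the pipeline.

Emulates the statistical structure of a two-cohort aptamer-proteomics study
of heart-failure risk after myocardial infarction:

* plate-structured RFU measurements with per-sample multiplicative readout
  biases, per-plate biases, lognormal measurement noise, hybridization
  control sequences spanning the signal range, and calibrator/QC/buffer
  control samples sharing a pooled profile;
* a patient population with two latent groups, the second group shifted by
  ``delta`` (log2 scale) on ``n_informative`` proteins;
* competing event times (heart-failure hospitalization vs all-cause death)
  drawn from a *direct* subdistribution-hazard model, so that the true
  subdistribution hazard ratio of the latent group is exactly
  ``exp(beta1)``;
* clinical covariates correlated with the latent group, plus sparse
  missingness.

One master seed drives everything; independent substreams are derived per
component so that each piece regenerates reproducibly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .datatypes import ClinicalTable, OutcomeData, SomamerTable

__all__ = [
    "SimConfig",
    "SyntheticCohort",
    "simulate_competing_events",
    "simulate_cohort",
    "simulate_two_cohorts",
    "inject_missing",
]

#: clinical variables used by the adjusted group-risk models
NAMED_CLINICAL = (
    "age", "gender", "ejection_fraction", "diabetes",
    "killip2", "creatinine", "bnp", "ntprobnp",
)
_BINARY_NAMED = ("gender", "diabetes", "killip2")


@dataclass
class SimConfig:
    """Study conditions of the synthetic cohort.

    Defaults mirror the derivation cohort's shape: 254 patients, 5284
    SOMAmer reagents of which 414 are flagged for removal and 197 proteins
    are measured by two (192) or three (5) reagents, leaving 4668 analyzable
    proteins; ~37% of patients in the high-risk latent group; follow-up
    censored administratively between 6 and 13 years.
    """

    n_patients: int = 254
    n_somamers: int = 5284
    removal_count: int = 414
    dup2_count: int = 192
    dup3_count: int = 5
    n_plates: int = 3
    calibrators_per_plate: int = 5
    qc_per_plate: int = 2
    buffer_per_plate: int = 1
    n_hyb_controls: int = 12
    group2_fraction: float = 94 / 254
    n_informative: int = 50
    delta: float = 1.5
    beta1: float = math.log(2.0)
    p_asym: float = 0.25
    lambda1: float = 0.15
    lambda2: float = 0.04
    censor_lo: float = 6.0
    censor_hi: float = 13.0
    clinical_missing_rate: float = 53 / 6858
    noise_sd: float = 0.05          # lognormal measurement noise (log-e sd)
    sample_bias_range: tuple = (0.7, 1.4)
    plate_bias_range: tuple = (0.9, 1.1)
    patient_sd: float = 1.0         # biological spread per protein, log2
    seed: int = 0

    @property
    def n_proteins(self) -> int:
        return (self.n_somamers - self.removal_count
                - self.dup2_count - 2 * self.dup3_count)

    def validate(self) -> None:
        counts = dict(
            n_patients=self.n_patients, n_somamers=self.n_somamers,
            removal_count=self.removal_count, dup2_count=self.dup2_count,
            dup3_count=self.dup3_count, n_plates=self.n_plates,
            calibrators_per_plate=self.calibrators_per_plate,
            qc_per_plate=self.qc_per_plate, buffer_per_plate=self.buffer_per_plate,
            n_hyb_controls=self.n_hyb_controls, n_informative=self.n_informative,
        )
        for k, v in counts.items():
            if v < 0:
                raise ValueError(f"{k} must be >= 0, got {v}")
        if self.n_proteins <= 0:
            raise ValueError("derived n_proteins must be positive")
        if not 0 < self.group2_fraction < 1:
            raise ValueError("group2_fraction must be in (0, 1)")
        if not 0 < self.p_asym < 1:
            raise ValueError("p_asym must be in (0, 1)")
        if not self.censor_lo < self.censor_hi:
            raise ValueError("censor_lo must be < censor_hi")
        if not 0 <= self.clinical_missing_rate < 1:
            raise ValueError("clinical_missing_rate must be in [0, 1)")
        if self.n_informative > self.n_proteins:
            raise ValueError("n_informative exceeds n_proteins")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticCohort:
    """A generated cohort plus the latent truth behind it."""

    somamer_table: SomamerTable
    clinical: ClinicalTable
    outcomes: OutcomeData
    truth: dict


# ---------------------------------------------------------------------------
# competing event times: direct subdistribution parameterization
# ---------------------------------------------------------------------------

def simulate_competing_events(linpred, cfg: SimConfig, rng=None,
                              censoring: bool = True,
                              index=None) -> OutcomeData:
    """Draw competing event times from the direct subdistribution model.

    The cause-1 (heart failure) subdistribution is

        F1(t | x) = 1 - [1 - p (1 - exp(-lambda1 t))]^{exp(lp)},

    with asymptote F1(inf | x) = 1 - (1 - p)^{exp(lp)}; ``linpred`` is the
    linear predictor lp = x * beta1.  Under this mixture construction the
    subdistribution hazard of cause 1 is exactly proportional to exp(lp),
    so a unit covariate carries a true SHR of exp(beta1).  Cause-2 times are
    exponential(lambda2) conditional on not failing from cause 1;
    administrative censoring is uniform on (censor_lo, censor_hi).
    """
    cfg.validate()
    lp = np.asarray(linpred, dtype=float)
    if (~np.isfinite(lp)).any():
        bad = np.flatnonzero(~np.isfinite(lp))
        raise ValueError(f"non-finite linear predictor for patient(s) {list(bad[:5])}")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = len(lp)
    eta = np.exp(lp)
    p = cfg.p_asym
    p1 = 1.0 - (1.0 - p) ** eta

    is1 = rng.uniform(size=n) < p1
    # inverse-CDF draw restricted to the cause-1 branch
    u = rng.uniform(size=n) * p1
    inner = 1.0 - (1.0 - (1.0 - u) ** (1.0 / eta)) / p
    t1 = -np.log(np.clip(inner, 1e-300, None)) / cfg.lambda1
    t2 = rng.exponential(1.0 / cfg.lambda2, size=n)
    event_time = np.where(is1, t1, t2)
    cause = np.where(is1, 1, 2)
    if censoring:
        c = rng.uniform(cfg.censor_lo, cfg.censor_hi, size=n)
        time = np.minimum(event_time, c)
        cause = np.where(event_time <= c, cause, 0)
    else:
        time = event_time
    time = np.clip(time, 1e-12, None)
    if index is None:
        index = pd.RangeIndex(n)
    return OutcomeData(pd.Series(time, index=index, name="time"),
                       pd.Series(cause, index=index, name="cause"))


# ---------------------------------------------------------------------------
# full cohort
# ---------------------------------------------------------------------------

def _protein_params(cfg: SimConfig, rng) -> dict:
    """Assay-level parameters shared by paired cohorts."""
    n_prot = cfg.n_proteins
    proteins = [f"P{i:05d}" for i in range(n_prot)]
    mu = rng.normal(8.0, 1.5, size=n_prot)  # baseline log2 abundance
    informative = sorted(rng.choice(n_prot, size=cfg.n_informative, replace=False))

    # reagent multiplicity: dup3 proteins first, then dup2, rest single
    order = rng.permutation(n_prot)
    dup3 = order[: cfg.dup3_count]
    dup2 = order[cfg.dup3_count: cfg.dup3_count + cfg.dup2_count]
    mult = np.ones(n_prot, dtype=int)
    mult[dup3] = 3
    mult[dup2] = 2

    som_ids, som_protein, som_pidx, som_offset = [], [], [], []
    k = 0
    for p_idx in range(n_prot):
        for r in range(mult[p_idx]):
            som_ids.append(f"SM{k:05d}")
            som_protein.append(proteins[p_idx])
            som_pidx.append(p_idx)
            som_offset.append(0.0 if r == 0 else rng.normal(0.0, 0.3))
            k += 1
    flagged = [False] * k
    # flagged-for-removal reagents carry their own symbols so that removal
    # does not disturb the multiplicity bookkeeping
    for j in range(cfg.removal_count):
        som_ids.append(f"SM{k:05d}")
        som_protein.append(f"FLAGGED{j:04d}")
        som_pidx.append(-1)
        som_offset.append(0.0)
        flagged.append(True)
        k += 1
    assert k == cfg.n_somamers

    # dilution sets follow abundance tertiles (high-abundance analytes are
    # measured at higher dilution), flagged reagents uniform
    base = np.where(np.array(som_pidx) >= 0, mu[np.array(som_pidx)], rng.normal(8, 1.5, k))
    q1, q2 = np.quantile(base, [1 / 3, 2 / 3])
    dilution = np.where(base < q1, 1, np.where(base < q2, 2, 3))

    hyb_ids = [f"HYB{j:02d}" for j in range(cfg.n_hyb_controls)]
    hyb_levels = np.geomspace(2.0 ** 5, 2.0 ** 15, max(cfg.n_hyb_controls, 1))

    return dict(
        proteins=proteins, mu=mu, informative=informative,
        som_ids=som_ids, som_protein=som_protein,
        som_pidx=np.array(som_pidx), som_offset=np.array(som_offset),
        flagged=np.array(flagged), dilution=dilution,
        hyb_ids=hyb_ids, hyb_levels=hyb_levels,
    )


def _gen_cohort(cfg: SimConfig, params: dict, n_patients: int, rng,
                prefix: str) -> SyntheticCohort:
    r_pat, r_rfu, r_out, r_clin = rng.spawn(4)

    n_prot = cfg.n_proteins
    mu = params["mu"]
    informative = params["informative"]

    group = (r_pat.uniform(size=n_patients) < cfg.group2_fraction).astype(int)
    X = mu[None, :] + r_pat.normal(0.0, cfg.patient_sd, size=(n_patients, n_prot))
    X[:, informative] += cfg.delta * group[:, None]

    patient_ids = [f"{prefix}{i:04d}" for i in range(n_patients)]

    # ---- plate layout ----------------------------------------------------
    plates = [f"{prefix}PL{j}" for j in range(cfg.n_plates)]
    sample_ids, sample_type, plate_of = [], [], []
    for i, pid in enumerate(patient_ids):
        sample_ids.append(pid)
        sample_type.append("study")
        plate_of.append(plates[i % cfg.n_plates])
    for j, pl in enumerate(plates):
        for c in range(cfg.calibrators_per_plate):
            sample_ids.append(f"{pl}_CAL{c}")
            sample_type.append("calibrator")
            plate_of.append(pl)
        for c in range(cfg.qc_per_plate):
            sample_ids.append(f"{pl}_QC{c}")
            sample_type.append("qc")
            plate_of.append(pl)
        for c in range(cfg.buffer_per_plate):
            sample_ids.append(f"{pl}_BUF{c}")
            sample_type.append("buffer")
            plate_of.append(pl)
    n_samples = len(sample_ids)

    # ---- RFU matrix ------------------------------------------------------
    som_pidx = params["som_pidx"]
    som_offset = params["som_offset"]
    n_som = len(params["som_ids"])
    # pooled control samples carry the population-average profile, including
    # the group mixture's mean shift on the informative proteins
    mu_pop = mu.copy()
    mu_pop[informative] += cfg.delta * cfg.group2_fraction
    pooled_log2 = np.where(som_pidx >= 0, mu_pop[np.clip(som_pidx, 0, None)], 8.0) + som_offset

    log2_true = np.empty((n_samples, n_som))
    stypes = np.array(sample_type)
    study_rows = np.flatnonzero(stypes == "study")
    analyte_true_study = np.where(
        som_pidx[None, :] >= 0,
        X[:, np.clip(som_pidx, 0, None)] + som_offset[None, :],
        8.0,
    )
    log2_true[study_rows] = analyte_true_study
    ctrl_rows = np.flatnonzero(stypes != "study")
    log2_true[ctrl_rows] = pooled_log2[None, :]
    buf_rows = np.flatnonzero(stypes == "buffer")
    log2_true[buf_rows] = np.log2(100.0)  # buffer: background only

    lo, hi = cfg.sample_bias_range
    sample_bias = r_rfu.uniform(lo, hi, size=n_samples)
    plo, phi = cfg.plate_bias_range
    plate_bias_map = {pl: b for pl, b in zip(plates, r_rfu.uniform(plo, phi, size=len(plates)))}
    plate_bias = np.array([plate_bias_map[pl] for pl in plate_of])

    noise = r_rfu.normal(0.0, cfg.noise_sd, size=(n_samples, n_som + cfg.n_hyb_controls))
    rfu_analytes = (2.0 ** log2_true
                    * sample_bias[:, None] * plate_bias[:, None]
                    * np.exp(noise[:, :n_som]))
    rfu_hyb = (params["hyb_levels"][None, :]
               * sample_bias[:, None] * plate_bias[:, None]
               * np.exp(noise[:, n_som:]))

    som_ids = list(params["som_ids"]) + list(params["hyb_ids"])
    rfu = pd.DataFrame(
        np.hstack([rfu_analytes, rfu_hyb]),
        index=pd.Index(sample_ids, name="sample_id"),
        columns=som_ids,
    )
    somamer_meta = pd.DataFrame(
        {
            "protein_symbol": list(params["som_protein"]) + list(params["hyb_ids"]),
            "dilution_set": np.concatenate([params["dilution"],
                                            np.ones(cfg.n_hyb_controls, dtype=int)]),
            "is_hyb_control": [False] * n_som + [True] * cfg.n_hyb_controls,
            "flagged_removed": list(params["flagged"]) + [False] * cfg.n_hyb_controls,
        },
        index=pd.Index(som_ids, name="somamer_id"),
    )
    sample_meta = pd.DataFrame(
        {"sample_type": sample_type, "plate_id": plate_of},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    table = SomamerTable(rfu, somamer_meta, sample_meta)

    # ---- outcomes --------------------------------------------------------
    linpred = cfg.beta1 * group
    outcomes = simulate_competing_events(
        linpred, cfg, rng=r_out, index=pd.Index(patient_ids, name="patient_id")
    )

    # ---- clinical covariates --------------------------------------------
    clinical_full = _gen_clinical(group, r_clin, patient_ids)
    binary_vars = tuple(c for c in clinical_full.columns
                        if c in _BINARY_NAMED or c.startswith("noise_b"))
    clinical = ClinicalTable(clinical_full, binary_vars)
    if cfg.clinical_missing_rate > 0:
        clinical = inject_missing(clinical, cfg.clinical_missing_rate,
                                  seed=int(r_clin.integers(2 ** 31)))

    truth = dict(
        group=pd.Series(group + 1, index=pd.Index(patient_ids, name="patient_id"),
                        name="group"),
        informative_proteins=[params["proteins"][i] for i in informative],
        beta1=cfg.beta1,
        complete_clinical=clinical_full,
    )
    return SyntheticCohort(table, clinical, outcomes, truth)


def _gen_clinical(group: np.ndarray, rng, patient_ids) -> pd.DataFrame:
    n = len(group)
    g = group.astype(float)
    df = pd.DataFrame(index=pd.Index(patient_ids, name="patient_id"))
    df["age"] = np.round(54 + 11 * g + rng.normal(0, 13, n), 1)
    df["gender"] = (rng.uniform(size=n) < 0.26).astype(float)  # 1 = woman
    df["ejection_fraction"] = np.round(51 - 6 * g + rng.normal(0, 9, n), 1)
    df["diabetes"] = (rng.uniform(size=n) < 0.18 + 0.13 * g).astype(float)
    df["killip2"] = (rng.uniform(size=n) < 0.18 + 0.27 * g).astype(float)
    df["creatinine"] = np.round(np.exp(np.log(90) + 0.1 * g + rng.normal(0, 0.25, n)), 1)
    df["bnp"] = np.round(np.exp(np.log(150) + 0.6 * g + rng.normal(0, 0.8, n)), 1)
    df["ntprobnp"] = np.round(np.exp(np.log(900) + 0.6 * g + rng.normal(0, 0.9, n)), 1)
    # noise variables (independent of group) complete the 27-variable table
    n_named = len(df.columns)
    n_noise = 27 - n_named
    n_noise_bin = n_noise // 2
    for j in range(n_noise - n_noise_bin):
        df[f"noise_c{j:02d}"] = np.round(rng.normal(0, 1, n), 3)
    for j in range(n_noise_bin):
        df[f"noise_b{j:02d}"] = (rng.uniform(size=n) < 0.3).astype(float)
    assert df.shape[1] == 27
    return df


def simulate_cohort(cfg: SimConfig, rng=None, prefix: str = "PT") -> SyntheticCohort:
    """Generate one full synthetic cohort (assay + clinical + outcomes)."""
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    r_params, r_cohort = rng.spawn(2)
    params = _protein_params(cfg, r_params)
    return _gen_cohort(cfg, params, cfg.n_patients, r_cohort, prefix)


def simulate_two_cohorts(cfg: SimConfig, n_validation: int = 238):
    """Generate paired derivation and validation cohorts.

    Both cohorts share the assay-level parameters (protein abundances,
    reagent multiplicities, informative set) and differ in patients, plates
    and follow-up, mirroring a derivation/validation design.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    r_params, r_deriv, r_valid = rng.spawn(3)
    params = _protein_params(cfg, r_params)
    deriv = _gen_cohort(cfg, params, cfg.n_patients, r_deriv, "D")
    valid = _gen_cohort(cfg, params, n_validation, r_valid, "V")
    return deriv, valid


def inject_missing(clinical: ClinicalTable, rate: float, seed: int) -> ClinicalTable:
    """Mask each clinical cell independently with probability *rate*."""
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1); a fully missing table is unusable")
    if rate == 0:
        return clinical.copy()
    rng = np.random.default_rng(seed)
    vals = clinical.values.copy()
    mask = rng.uniform(size=vals.shape) < rate
    arr = vals.to_numpy(dtype=float)
    arr[mask] = np.nan
    out = pd.DataFrame(arr, index=vals.index, columns=vals.columns)
    return ClinicalTable(out, clinical.binary_vars)
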