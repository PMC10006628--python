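"""End-to-end orchestration of the three-step analysis.

Step 1 selects proteins on the derivation cohort (normalization ->
protein aggregation -> log2 -> derivation-anchored standardization ->
univariate Fine-Gray screening at the Bonferroni threshold); step 2 builds
patient groups on the selected proteins by silhouette-selected k-means and
transfers them to the validation cohort by nearest centroid; step 3
quantifies the groups' effect on heart-failure occurrence with
competing-risk models (unadjusted and adjusted), cumulative incidence
curves, and a sensitivity re-clustering without chosen marker proteins.

Everything lands in a machine-readable JSON report plus TSV artifacts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import adat
from .competing import cif_aalen_johansen
from .datatypes import OutcomeData
from .enrichment import fisher_overrepresentation
from .normalize import normalize_pipeline
from .preprocess import (
    CohortStandardizer,
    aggregate_to_proteins,
    impute_clinical,
    log2_transform,
    remove_flagged,
)
from .screening import correlation_summary, direction_concordance, univariate_screen
from .simulate import SimConfig, simulate_two_cohorts
from .stratify import assign, compare_groups, group_risk_model, select_k, sensitivity_drop

logger = logging.getLogger("somastrat")

__all__ = ["PipelineConfig", "run_pipeline", "score_patient"]

DEFAULT_ADJUSTMENTS = ("age", "gender", "ejection_fraction", "diabetes",
                       "killip2", "creatinine", "bnp", "ntprobnp")


@dataclass
class PipelineConfig:
    """Inputs and knobs of a full pipeline run.

    Exactly one of ``sim`` (a SimConfig for a synthetic study) or
    ``derivation_adat``/``validation_adat`` paths must be provided.
    """

    sim: SimConfig = None
    derivation_adat: str = None
    validation_adat: str = None
    derivation_clinical: str = None
    validation_clinical: str = None
    derivation_outcomes: str = None
    validation_outcomes: str = None
    term_sets: str = None
    alpha: float = 0.05
    k_range: tuple = (2, 3, 4, 5, 6)
    adjustments: tuple = DEFAULT_ADJUSTMENTS
    sensitivity_drop: tuple = ()
    n_validation: int = 238
    seed: int = 0
    out_dir: str = "somastrat_out"

    def validate(self):
        has_sim = self.sim is not None
        has_paths = self.derivation_adat is not None
        if has_sim == has_paths:
            raise ValueError("provide exactly one of sim config or input paths")
        if has_paths and (self.validation_adat is None
                          or self.derivation_outcomes is None
                          or self.validation_outcomes is None):
            raise ValueError("file inputs need ADAT and outcome paths for both cohorts")


def _prepare_cohort(table, name, out_dir):
    normalized, factors, qc = normalize_pipeline(table)
    logger.info("%s: normalization %s", name, "PASS" if qc.overall_pass else "FAIL")
    cleaned = remove_flagged(normalized)
    matrix = log2_transform(aggregate_to_proteins(cleaned))
    return normalized, matrix, qc


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full workflow and return (and write) the JSON report."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = {"seed": config.seed, "alpha": config.alpha,
              "k_range": list(config.k_range)}

    # ---- inputs ----------------------------------------------------------
    if config.sim is not None:
        logger.info("simulating paired cohorts (seed=%d)", config.sim.seed)
        deriv, valid = simulate_two_cohorts(config.sim, config.n_validation)
        table_d, clinical_d, outcomes_d = deriv.somamer_table, deriv.clinical, deriv.outcomes
        table_v, clinical_v, outcomes_v = valid.somamer_table, valid.clinical, valid.outcomes
        report["simulated"] = True
        report["sim_config"] = {k: (list(v) if isinstance(v, tuple) else v)
                                for k, v in config.sim.to_dict().items()}
    else:
        table_d = adat.read_adat(config.derivation_adat)
        table_v = adat.read_adat(config.validation_adat)
        outcomes_d = adat.read_outcomes(config.derivation_outcomes)
        outcomes_v = adat.read_outcomes(config.validation_outcomes)
        clinical_d = (adat.read_clinical(config.derivation_clinical)
                      if config.derivation_clinical else None)
        clinical_v = (adat.read_clinical(config.validation_clinical)
                      if config.validation_clinical else None)
        report["simulated"] = False

    # ---- step 0: normalization & preprocessing ---------------------------
    _, matrix_d, qc_d = _prepare_cohort(table_d, "derivation", out)
    _, matrix_v, qc_v = _prepare_cohort(table_v, "validation", out)
    report["qc"] = {"derivation": qc_d.to_dict(), "validation": qc_v.to_dict()}

    if clinical_d is not None and clinical_d.n_missing:
        logger.info("imputing %d missing derivation clinical cells", clinical_d.n_missing)
        clinical_d = impute_clinical(clinical_d)
    if clinical_v is not None and clinical_v.n_missing:
        clinical_v = impute_clinical(clinical_v)

    std = CohortStandardizer().fit(matrix_d)
    std.to_frame().to_csv(out / "standardization.tsv", sep="\t")
    z_d = std.transform(matrix_d)
    z_v = std.transform(matrix_v)

    # ---- step 1: protein selection --------------------------------------
    outcomes_d = outcomes_d.subset(z_d.patients)
    outcomes_v = outcomes_v.subset(z_v.patients)
    screen_d = univariate_screen(z_d, outcomes_d, alpha=config.alpha)
    selected = list(screen_d.selected)
    screen_d.table.to_csv(out / "screen_derivation.tsv", sep="\t")
    report["screening"] = {
        "m": screen_d.m,
        "threshold": screen_d.threshold,
        "n_selected": screen_d.n_selected,
        "selected": selected,
    }
    logger.info("selected %d/%d proteins at p < %.3g",
                screen_d.n_selected, screen_d.m, screen_d.threshold)
    if not selected:
        report["warning"] = "no proteins selected"
        (out / "report.json").write_text(json.dumps(report, indent=2))
        return report

    sel_d = z_d.values[selected]
    sel_v = z_v.values[selected]
    screen_v = univariate_screen(sel_v, outcomes_v, alpha=config.alpha)
    n_same, n_opp, opp = direction_concordance(screen_d, screen_v, selected)
    corr, pair, max_r = correlation_summary(sel_d)
    report["validation_concordance"] = {"same_sign": n_same, "opposite_sign": n_opp,
                                        "opposite_proteins": opp}
    report["max_correlation"] = {"pair": list(pair), "r": max_r}

    # ---- step 2: stratification ------------------------------------------
    model = select_k(sel_d, k_range=config.k_range, seed=config.seed,
                     outcomes=outcomes_d)
    labels_d = model.labels
    labels_v = assign(sel_v, model.centroids)
    (out / "cluster_model.json").write_text(json.dumps(model.to_dict(), indent=2))
    pd.concat([labels_d, labels_v]).rename("group").to_frame().to_csv(
        out / "groups.tsv", sep="\t")
    report["stratification"] = {
        "k": model.k,
        "silhouette_by_k": {str(k): v for k, v in model.silhouette_by_k.items()},
        "group_sizes_derivation": labels_d.value_counts().sort_index().to_dict(),
        "group_sizes_validation": labels_v.value_counts().sort_index().to_dict(),
    }

    comparisons = {}
    for name, clin, labels in (("derivation", clinical_d, labels_d),
                               ("validation", clinical_v, labels_v)):
        if clin is not None and model.k == 2:
            comp = compare_groups(clin.values, labels, binary_vars=clin.binary_vars)
            comp.table.to_csv(out / f"group_comparison_{name}.tsv", sep="\t")
            comparisons[name] = list(comp.significant)
    report["group_differences"] = comparisons

    # heatmap export: patients ordered by group, selected proteins
    for name, z, labels in (("derivation", sel_d, labels_d), ("validation", sel_v, labels_v)):
        ordered = z.loc[labels.sort_values(kind="stable").index]
        ordered.to_csv(out / f"heatmap_{name}.tsv", sep="\t")

    # ---- step 3: groups' effect on heart failure -------------------------
    risk = {}
    for name, labels, oc, clin in (("derivation", labels_d, outcomes_d, clinical_d),
                                   ("validation", labels_v, outcomes_v, clinical_v)):
        entry = {}
        if model.k == 2 and labels.nunique() == 2:
            fit = group_risk_model(labels, oc)
            entry["unadjusted"] = _fit_record(fit)
            if clin is not None:
                adj = {}
                for var in config.adjustments:
                    if var in clin.values.columns:
                        try:
                            f = group_risk_model(labels, oc, adjust=clin.values[[var]])
                            adj[var] = _fit_record(f)
                        except ValueError as exc:
                            adj[var] = {"error": str(exc)}
                entry["adjusted"] = adj
        for g in sorted(labels.unique()):
            cif = cif_aalen_johansen(oc.subset(labels.index[labels == g]), cause=1)
            cif.to_frame().to_csv(out / f"cif_{name}_group{g}.tsv", sep="\t", index=False)
        risk[name] = entry
    report["group_risk"] = risk

    # ---- sensitivity: drop chosen markers --------------------------------
    drop = [p for p in config.sensitivity_drop if p in selected]
    if drop:
        sens_model, n_ch_d, n_ch_v = sensitivity_drop(
            sel_d, drop, model, matrix_valid=sel_v, seed=config.seed,
            outcomes=outcomes_d)
        report["sensitivity"] = {
            "dropped": drop,
            "n_changed_derivation": n_ch_d,
            "n_changed_validation": n_ch_v,
        }

    # ---- enrichment ------------------------------------------------------
    if config.term_sets:
        from .enrichment import read_term_sets
        terms = read_term_sets(config.term_sets)
        enr = fisher_overrepresentation(set(selected), set(z_d.proteins), terms)
        enr.table.to_csv(out / "enrichment.tsv", sep="\t")
        report["enrichment"] = {
            "n_terms": len(enr.table),
            "significant": list(enr.significant()),
        }

    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def _fit_record(fit):
    ci = fit.ci95[0]
    return {
        "beta": float(fit.beta[0]),
        "shr": float(fit.shr[0]),
        "ci95": [float(ci[0]), float(ci[1])],
        "p": float(fit.p[0]),
    }


def score_patient(params: CohortStandardizer, model, protein_vector) -> int:
    """Assign a single patient to a group from raw log2 protein levels.

    *protein_vector* is a mapping or Series of log2 protein level per
    protein symbol; it must cover every protein of the cluster panel.  The
    vector is standardized with the frozen derivation parameters and
    assigned to the nearest centroid.
    """
    vec = pd.Series(protein_vector, dtype=float)
    missing = [p for p in model.proteins if p not in vec.index]
    if missing:
        raise ValueError(f"patient vector missing proteins: {missing[:10]}")
    df = vec[list(model.proteins)].to_frame().T
    z = params.transform(df)
    return int(assign(z, model.centroids).iloc[0])
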