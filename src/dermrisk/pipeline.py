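"""End-to-end orchestration: generate or load a cohort, split, build the
PRS, select factors, fit the per-cancer 32-factor GLMs, score both
splits, evaluate on the validation set, and derive lifetime risk
trajectories with prospective validation.

All randomness flows from a single seed through named substreams, and the
training / validation split isolates every fitted quantity (GWAS, PRS
weights, factor selection, model coefficients, standardization constants)
from validation rows.  Principal components are the one exception, by
design: ancestry axes are computed once on the full genotype matrix, as
is conventional.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import evaluation, io, model_build, risk_scores, trajectories
from .genetics import ClumpThresholdPRS, compute_pcs, genomic_control_lambda
from .model_build import FactorSpec, build_design, choose_poly_degree, fit_glm
from .synthetic import (CANCERS, GROUP_DEMOGRAPHIC, GROUP_FAMILY, GROUP_PRS,
                        GeneratorConfig, generate_cohort, generate_followup)


@dataclass
class RunConfig:
    """Pipeline configuration: exactly one data source plus thresholds."""

    generator: Optional[GeneratorConfig] = None
    cohort_path: Optional[str] = None
    genotype_path: Optional[str] = None
    variants_path: Optional[str] = None
    survival_path: Optional[str] = None
    split_fraction: float = 0.537        # temporal-split proportion
    split_by_enrollment: bool = True
    stage1_alpha: float = 0.05
    scan_alpha: float = 1e-8
    prs_p_threshold: float = 1e-6
    clump_window_bp: int = 250_000
    clump_r2_max: float = 0.1
    n_bins: int = 100
    middle_band: tuple = (48, 53)
    strata: list = field(default_factory=lambda: trajectories.DEFAULT_STRATA)
    n_pcs: int = 5
    extra_phenotypes: Optional[pd.DataFrame] = None
    seed: int = 0
    out_dir: Optional[str] = None

    def __post_init__(self):
        has_paths = self.cohort_path is not None
        if has_paths and self.generator is not None:
            raise ValueError("give either input paths or a generator "
                             "config, not both")
        if not has_paths and self.generator is None:
            self.generator = GeneratorConfig(seed=self.seed)
        if not (0 < self.split_fraction < 1):
            raise ValueError("split_fraction must lie in (0, 1)")


def _split(table: pd.DataFrame, config: RunConfig):
    n = len(table)
    n_train = int(round(n * config.split_fraction))
    if config.split_by_enrollment and "enroll_order" in table.columns:
        order = np.argsort(table["enroll_order"].to_numpy(), kind="stable")
    else:
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 31]))
        order = rng.permutation(n)
    return order[:n_train], order[n_train:]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the run report dict.

    Stages: generate (or load) -> split -> GWAS + PRS (training only) ->
    stage-1 selection -> optional phenotype scan -> final per-cancer GLM
    -> scores (both splits, standardized on training) -> validation-set
    evaluation -> lifetime-risk trajectories and follow-up concordance.
    Intermediate tables are written under ``out_dir`` when given.
    """
    t0 = time.time()
    out = Path(config.out_dir) if config.out_dir else None
    report: dict = {"seed": config.seed, "stages": {}}

    # ------------------------------------------------------------- data
    if config.generator is not None:
        gen = config.generator
        cohort, genotypes = generate_cohort(gen)
        if gen.followup_years >= 1:
            cohort = generate_followup(cohort, gen)
        factors = list(gen.factor_specs)
        followup_years = gen.followup_years
    else:
        from .synthetic import default_factor_catalog
        factors = default_factor_catalog()
        cohort = io.read_cohort(config.cohort_path, factors=factors)
        if config.genotype_path is None or config.variants_path is None:
            raise ValueError("genotype and variant paths are required "
                             "with a cohort path")
        genotypes = io.read_genotypes(config.genotype_path,
                                      config.variants_path)
        followup_years = max(
            [int(c.split("_")[0][2:]) for c in cohort.table.columns
             if c.startswith("fu") and "_diag_" in c] or [0])
    report["stages"]["generate"] = {"n": cohort.n,
                                    "m_variants": genotypes.m}

    table = cohort.table.copy()
    table["age"] = table["current_age"].astype(float)
    table["family_history"] = risk_scores.family_history_score(
        table["fh_father"], table["fh_mother"], table["fh_sibling"],
        table["fh_child"])

    itrain, ivalid = _split(table, config)
    train = table.iloc[itrain].reset_index(drop=True)
    valid = table.iloc[ivalid].reset_index(drop=True)

    # per-split phenotype imputation of factor columns
    fac_names = [f.name for f in factors]
    train_imp, _ = model_build.impute_phenotypes(train, columns=fac_names)
    valid_imp, _ = model_build.impute_phenotypes(valid, columns=fac_names)

    # --------------------------------------------------------- genetics
    pcs = compute_pcs(genotypes, k=config.n_pcs) if genotypes.m > config.n_pcs \
        else np.zeros((cohort.n, 0))
    gtrain = _subset_genotypes(genotypes, itrain)
    gvalid = _subset_genotypes(genotypes, ivalid)
    prs_models, prs_train, prs_valid, lambdas = {}, {}, {}, {}
    for c in CANCERS:
        est = ClumpThresholdPRS(p_threshold=config.prs_p_threshold,
                                window_bp=config.clump_window_bp,
                                r2_max=config.clump_r2_max)
        cov = pd.DataFrame(np.column_stack(
            [train_imp["age"], train_imp["sex_male"], pcs[itrain]]))
        est.fit(gtrain, train[f"case_{c}"].to_numpy(), covariates=cov)
        prs_models[c] = est
        prs_train[c] = est.transform(gtrain)
        prs_valid[c] = est.transform(gvalid)
        pvals = est.assoc_["p_value"].dropna()
        lambdas[c] = (genomic_control_lambda(pvals)
                      if len(pvals) >= 100 else None)
        if out is not None:
            io.write_table(est.assoc_, out / f"assoc_{c}.tsv")
            io.write_prs_model(est.model_, est.assoc_, out / f"prs_{c}.tsv")
    report["stages"]["prs"] = {
        c: {"n_variants": prs_models[c].n_variants_,
            "lambda_gc": lambdas[c]} for c in CANCERS}

    # --------------------------------------------- stage 1 factor screen
    survey_specs = [f for f in factors]
    age_spec = FactorSpec("age", "continuous", GROUP_DEMOGRAPHIC,
                          {"mean": 0.0, "sd": 1.0})
    fh_spec = FactorSpec("family_history", "ordinal", GROUP_FAMILY,
                         {"probs": [0.55, 0.25, 0.15, 0.05]})
    outcomes_train = {c: train[f"case_{c}"].to_numpy() for c in CANCERS}
    age_degree = max(choose_poly_degree(train_imp["age"].to_numpy(),
                                        outcomes_train[c])
                     for c in CANCERS)
    extra = {("ancestry", GROUP_DEMOGRAPHIC): pcs[itrain]} \
        if pcs.shape[1] else {}
    fm_all = build_design(train_imp, survey_specs + [age_spec, fh_spec],
                          poly_degrees={"age": age_degree},
                          extra_numeric=extra)
    trace = model_build.stage1_select(fm_all, outcomes_train,
                                      alpha=config.stage1_alpha)
    report["stages"]["stage1"] = {
        "kept": trace.kept, "age_degree": age_degree,
        "n_kept": len(trace.kept)}

    # ------------------------------------- optional extra-phenotype scan
    scan_candidates: list = []
    if config.extra_phenotypes is not None:
        fm_kept = fm_all.subset([f for f in trace.kept
                                 if f in fm_all.factor_columns])
        scan_tab, scan_candidates = model_build.scan_additional(
            fm_kept, outcomes_train,
            config.extra_phenotypes.iloc[itrain].reset_index(drop=True),
            alpha=config.scan_alpha)
        if out is not None:
            io.write_table(scan_tab, out / "scan_additional.tsv")
    report["stages"]["scan"] = {"candidates": scan_candidates}

    # ------------------------------------------------- final 32-factor fit
    kept_specs = [f for f in survey_specs if f.name in trace.kept]
    final_specs = kept_specs + [age_spec, fh_spec]
    models, fm_train, fm_valid = {}, {}, {}
    for c in CANCERS:
        extra_tr = dict(extra)
        extra_va = {("ancestry", GROUP_DEMOGRAPHIC): pcs[ivalid]} \
            if pcs.shape[1] else {}
        if prs_models[c].n_variants_ > 0 and np.std(prs_train[c]) > 0:
            extra_tr[("prs", GROUP_PRS)] = prs_train[c]
            extra_va[("prs", GROUP_PRS)] = prs_valid[c]
        fm_tr = build_design(train_imp, final_specs,
                             poly_degrees={"age": age_degree},
                             extra_numeric=extra_tr)
        fm_va = build_design(valid_imp, final_specs,
                             extra_numeric=extra_va, reference_fm=fm_tr)
        models[c] = fit_glm(fm_tr, outcomes_train[c], cancer=c)
        fm_train[c], fm_valid[c] = fm_tr, fm_va
        if out is not None:
            io.write_table(_coef_table(models[c]), out / f"model_{c}.tsv")
    report["stages"]["fit"] = {
        c: {"deviance_explained": models[c].deviance_explained,
            "n_factors": len(models[c].factor_columns)} for c in CANCERS}

    # ------------------------------------------------------------ scores
    score_train = {c: risk_scores.compute_score_set(fm_train[c], models[c])
                   for c in CANCERS}
    score_valid = {c: risk_scores.compute_score_set(fm_valid[c], models[c])
                   for c in CANCERS}
    if out is not None:
        for c in CANCERS:
            io.write_table(score_valid[c].scores.assign(
                participant_id=valid["participant_id"].to_numpy()),
                out / f"scores_valid_{c}.tsv")

    # -------------------------------------------------------- evaluation
    eval_report = {}
    n_bins = min(config.n_bins, max(2, len(valid) // 20))
    for c in CANCERS:
        y = valid[f"case_{c}"].to_numpy()
        entry = {}
        for name in ("DRS", "DRSA"):
            s = score_valid[c].scores[name].to_numpy()
            ref = score_train[c].scores[name].to_numpy()
            auc, _, _ = evaluation.roc_auc(s, y)
            orsd, lo, hi = evaluation.or_per_sd(s, y, reference=ref)
            bins = evaluation.percentile_bins(s, n_bins=n_bins)
            middle = (max(1, int(config.middle_band[0] * n_bins / 100)),
                      max(1, int(config.middle_band[1] * n_bins / 100)))
            summ = evaluation.summarize_bins(
                bins, y, valid[f"age_dx_{c}"].to_numpy(), middle=middle)
            top = summ.iloc[-1]
            entry[name] = {
                "auc": auc, "pr_auc": evaluation.precision_recall_auc(s, y),
                "or_per_sd": orsd, "or_ci": [lo, hi],
                "top_bin_prevalence": float(top["prevalence"]),
                "top_bin_fold": float(top["fold_vs_middle"])}
            if out is not None:
                io.write_table(summ, out / f"bins_{name}_{c}.tsv")
        eval_report[c] = entry
    report["stages"]["evaluate"] = eval_report

    # ------------------------------------------------------ trajectories
    surv = (io.read_survival_table(config.survival_path)
            if config.survival_path else
            trajectories.synthetic_survival_schedule())
    traj_report = {}
    for c in CANCERS:
        drsa = score_valid[c].scores["DRSA"].to_numpy()
        traj = trajectories.lifetime_risk_curves(
            valid["current_age"].to_numpy(),
            valid[f"age_dx_{c}"].to_numpy(), drsa,
            strata=config.strata)
        onset = {}
        for gi, (label, _) in enumerate(traj.strata):
            I = trajectories.incidence_from_prevalence(traj.prevalence[gi])
            try:
                s = trajectories.expected_age_of_diagnosis(I, surv)
                onset[label] = {"mean": s.mean, "sd": s.sd}
            except ValueError:
                onset[label] = None
        entry = {"expected_onset": onset,
                 "lifetime_risk_90": {
                     label: float(traj.prevalence[gi][-1])
                     for gi, (label, _) in enumerate(traj.strata)}}
        if followup_years >= 1:
            status = trajectories.classify_followup(valid, c,
                                                    followup_years)
            conc = trajectories.expected_vs_observed_incidence(
                traj, valid, c, drsa, window=min(2, followup_years))
            entry["followup"] = {
                "n_incident": int((status == "incident").sum()),
                "n_cancer_free": int((status == "cancer_free").sum()),
                "concordant_strata": (int(conc["concordant"].sum())
                                      if len(conc) else 0),
                "n_strata": int(len(conc))}
            if out is not None:
                io.write_table(conc, out / f"concordance_{c}.tsv")
        if out is not None:
            curves = pd.DataFrame(traj.prevalence.T, index=traj.ages,
                                  columns=[s[0] for s in traj.strata])
            curves.index.name = "age"
            io.write_table(curves.reset_index(),
                           out / f"trajectories_{c}.tsv")
        traj_report[c] = entry
    report["stages"]["trajectories"] = traj_report

    report["runtime_s"] = round(time.time() - t0, 2)
    if out is not None:
        io.write_cohort(cohort, out / "cohort.tsv")
        io.write_genotypes(genotypes, out / "genotypes.tsv",
                           out / "variants.tsv")
        io.write_report(report, out / "report.json")
    return report


def _subset_genotypes(genotypes, idx):
    from .genetics import GenotypeMatrix
    return GenotypeMatrix(
        dosages=genotypes.dosages[idx],
        participant_ids=[genotypes.participant_ids[i] for i in idx],
        variants=genotypes.variants)


def _coef_table(model) -> pd.DataFrame:
    rows = []
    for f, cols in model.factor_columns.items():
        for col in cols:
            rows.append({"factor": f, "column": col,
                         "beta": model.coef[col], "se": model.se[col],
                         "p_value": model.pvalues[col],
                         "group": model.groups.get(f, "")})
    return pd.DataFrame(rows)
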