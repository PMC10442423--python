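"""End-to-end synthetic experiment: phantoms -> mJSW -> three GWAS -> PRS.

One configuration drives the whole comparison between a quantitative
joint-space endophenotype, its threshold-ascertained binary version,
and an under-reported health-record label: cohort and genotypes are
simulated, traits drawn under a liability-threshold model, the phantom
measurement pipeline is validated on a subset, and the three
association analyses are compared on genomic inflation, locus counts,
heritability, genetic correlation and hold-out polygenic-score
performance.

Randomness: one global seed expands to per-stage seeds through a
counter scheme (``stage_seed``), so stages are independently
re-runnable and every generator is a pure function of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from oa_phenopower import assoc, genarch, measure, phenotyping
from oa_phenopower.simulate.cohort import CohortConfig, generate_cohort
from oa_phenopower.simulate.genotypes import PanelConfig, simulate_genotypes
from oa_phenopower.simulate.phantoms import RESOLUTION_SET, PhantomSpec, generate_knee_phantom
from oa_phenopower.simulate.traits import TraitArchitecture, simulate_traits

#: reference counts printed for the UK Biobank knee-OA cohort this
#: pipeline emulates: cohort size, health-record (ICD-10 M17) cases,
#: model-ascertained cases, and single-gene locus annotation counts.
REFERENCE_COUNTS = {
    "n_cohort": 29257,
    "n_ehr_cases": 1085,
    "n_model_cases": 3016,
    "n_total_loci": 18,
    "n_single_gene_loci": 7,
    "n_skeletal_single_gene_loci": 4,
}


def stage_seed(seed: int, stage: int) -> int:
    """Deterministic per-stage child seed (< 2**31)."""
    return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class ExperimentConfig:
    n_gwas: int = 4000
    n_holdout: int = 2000
    n_snps: int = 2000
    block_size: int = 10
    rho: float = 0.8
    arch: TraitArchitecture = field(
        default_factory=lambda: TraitArchitecture(m_causal=20, h2=0.25,
                                                  prevalence_K=0.10,
                                                  ehr_sensitivity=0.36)
    )
    model_prevalence_target: float = 0.10
    clump: assoc.ClumpParams = field(default_factory=assoc.ClumpParams)
    ld_window_kb: float = genarch.DEFAULT_LD_WINDOW_KB
    prs_thresholds: tuple = genarch.PRS_THRESHOLDS
    rater_sensitivity: float = 0.77
    rater_specificity: float = 0.97
    n_rater_images: int = 182
    n_phantom_subjects: int = 100
    resolution_set: tuple = tuple(RESOLUTION_SET)
    seed: int = 0


def _covariate_block(cov: pd.DataFrame) -> np.ndarray:
    return np.column_stack(
        [
            (cov["sex"].to_numpy() == "M").astype(float),
            cov["age"].to_numpy(dtype=float),
            cov["bmi"].to_numpy(dtype=float),
            cov["height"].to_numpy(dtype=float),
        ]
    )


def phantom_validation(traits: pd.DataFrame, resolutions: tuple, seed: int,
                       n_subjects: int, noise_sd: float = 0.0) -> pd.DataFrame:
    """Render both legs of a subject subset and re-measure them.

    Per-leg gap anchors are derived from the subject's true mJSW (the
    narrower leg equals it; the other leg is 0.15 mm wider), with a
    medial-narrower asymmetry of +/-0.4 mm, so the generator truth for
    the nine-point average equals the per-leg center gap.
    """
    sub = traits.iloc[:n_subjects]
    scans, heights = {}, {}
    for i, row in enumerate(sub.itertuples()):
        spacing = resolutions[i % len(resolutions)]
        width, height_px = RESOLUTION_SET[spacing]
        wider = 0.15 if i % 2 == 0 else 0.0
        legs = {}
        for j, side in enumerate(("left", "right")):
            center = max(row.true_mjsw + (wider if j == 0 else 0.15 - wider), 0.8)
            spec = PhantomSpec(
                image_width=width,
                image_height=height_px,
                pixel_spacing=spacing,
                side=side,
                gap_mm={"lateral": center + 0.4, "center": center, "medial": center - 0.4},
                noise_sd=noise_sd,
                seed=stage_seed(seed, 1000 + 2 * i + j),
            )
            legs[side] = generate_knee_phantom(spec)
        scans[row.subject_id] = legs
        heights[row.subject_id] = row.height
    measured = measure.measure_subjects(scans, heights, reference_group=resolutions[0])
    truth = sub.set_index("subject_id")["true_mjsw"]
    measured["true_mjsw"] = measured["subject_id"].map(truth)
    measured["abs_error_mm"] = (measured["mjsw_norm"] - measured["true_mjsw"]).abs()
    measured["within_2px"] = measured["abs_error_mm"] <= 2.0 * measured["pixel_spacing"]
    return measured


def geometry_cohort(n: int, seed: int) -> pd.DataFrame:
    """Cohort whose joint width is exactly its height-linear component.

    Used by the geometry suite: with no subject-level scatter around the
    height regression, normalization-factor estimation error is
    negligible and any residual disagreement between measured and true
    mJSW is pure measurement/discretization error.
    """
    cohort = generate_cohort(n, CohortConfig(), seed=seed)
    mm = TraitArchitecture().mjsw_map
    cohort["true_mjsw"] = (
        mm.mean_mm + mm.height_slope_mm_per_cm * (cohort["height"] - mm.height_ref_cm)
    )
    return cohort


def simulate_rater_panel(true_case: np.ndarray, sensitivity: float, specificity: float,
                         n_images: int, seed: int):
    """Three noisy raters on shared image sets; averaged pairwise tables."""
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(true_case), size=min(3 * n_images, len(true_case)), replace=False)
    tables = []
    for pair in range(3):
        sel = idx[pair * n_images:(pair + 1) * n_images]
        truth = true_case[sel]
        labels = []
        for _rater in range(2):
            noisy = np.where(
                truth,
                rng.random(len(sel)) < sensitivity,
                rng.random(len(sel)) < 1.0 - specificity,
            )
            labels.append(noisy.astype(int))
        tables.append(phenotyping.pairwise_confusion(labels[0], labels[1]))
    return phenotyping.average_tables(tables), tables


def run_gwas_suite(panel, traits: pd.DataFrame, model_case: np.ndarray,
                   clump_params: assoc.ClumpParams, covars: np.ndarray) -> dict:
    """The three-way association comparison on one sample."""
    out = {}
    y = traits["true_mjsw"].to_numpy()
    out["mjsw"] = assoc.linear_assoc(panel, y, covariates=covars, phenotype="mjsw")
    out["model_binary"] = assoc.logistic_assoc(
        panel, model_case, covariates=covars, phenotype="model_binary")
    out["ehr_binary"] = assoc.logistic_assoc(
        panel, traits["ehr_case"].to_numpy(), covariates=covars, phenotype="ehr_binary")
    return out


def run_experiment(config: ExperimentConfig, outdir=None) -> dict:
    """Execute every stage; returns the report dict (also written as JSON).

    All intermediate tables are written under ``outdir`` with a
    manifest; the report only re-states numbers from those artifacts.
    """
    seed = config.seed
    n_total = config.n_gwas + config.n_holdout
    report: dict = {"config_seed": seed}

    cohort = generate_cohort(n_total, CohortConfig(), seed=stage_seed(seed, 1))
    panel_all = simulate_genotypes(
        PanelConfig(n_subjects=n_total, n_snps=config.n_snps,
                    block_size=config.block_size, rho=config.rho),
        seed=stage_seed(seed, 2),
    )
    traits_all = simulate_traits(panel_all, config.arch, cohort, seed=stage_seed(seed, 3))

    gwas_idx = np.arange(config.n_gwas)
    hold_idx = np.arange(config.n_gwas, n_total)
    traits = traits_all.iloc[gwas_idx].reset_index(drop=True)
    panel = panel_all.subset_subjects(gwas_idx)
    panel_hold = panel_all.subset_subjects(hold_idx)
    traits_hold = traits_all.iloc[hold_idx].reset_index(drop=True)

    # -- geometry validation: measurement pipeline on a noiseless,
    #    height-determined phantom cohort (a pure measurement QC stage)
    geometry = phantom_validation(
        geometry_cohort(config.n_phantom_subjects, stage_seed(seed, 9)),
        config.resolution_set, seed, config.n_phantom_subjects)
    report["geometry"] = {
        "n_subjects": int(len(geometry)),
        "max_abs_error_mm": float(geometry["abs_error_mm"].max()),
        "frac_within_2px": float(geometry["within_2px"].mean()),
    }

    # -- case ascertainment
    dich = phenotyping.dichotomize(traits["true_mjsw"].to_numpy(),
                                   config.model_prevalence_target)
    model_case = dich.case_flags
    true_case = traits["true_case"].to_numpy()
    ehr_case = traits["ehr_case"].to_numpy()
    sens, spec = phenotyping.sens_spec(true_case, model_case)
    comparison = phenotyping.compare_cases(ehr_case, model_case)
    avg_table, _ = simulate_rater_panel(
        true_case, config.rater_sensitivity, config.rater_specificity,
        min(config.n_rater_images, config.n_gwas // 3), stage_seed(seed, 4))
    report["ascertainment"] = {
        "cutoff_mm": dich.cutoff,
        "n_model_cases": comparison.n_model_cases,
        "n_ehr_cases": comparison.n_ehr_cases,
        "n_new_cases": comparison.n_new_cases,
        "pct_increase": comparison.pct_increase,
        "model_sensitivity_vs_truth": sens,
        "model_specificity_vs_truth": spec,
        "rater_table_proportions": avg_table.table.tolist(),
    }

    # -- epidemiological associations
    controls = ~model_case & ~ehr_case
    keep = model_case | controls
    pain = phenotyping.pain_association(
        model_case[keep],
        traits["pain_month_flag"].to_numpy()[keep],
        traits["pain_3mo_flag"].to_numpy()[keep],
        traits["pain_rating"].to_numpy()[keep],
    )
    frac = phenotyping.fracture_model(
        traits["fracture_5yr_flag"].to_numpy(), traits["true_mjsw"].to_numpy(), traits)
    report["epidemiology"] = {
        "pain": pain,
        "fracture_mjsw_estimate": frac.estimate,
        "fracture_mjsw_se": frac.se,
        "fracture_mjsw_p": frac.p,
    }

    # -- three GWAS, inflation, clumping
    covars = _covariate_block(traits)
    gwas = run_gwas_suite(panel, traits, model_case, config.clump, covars)
    loci = {}
    report["gwas"] = {}
    for name, res in gwas.items():
        ls = assoc.greedy_clump(res, panel, config.clump)
        loci[name] = ls
        report["gwas"][name] = {
            "lambda": assoc.lambda_gc(res),
            "n_loci": ls.count,
            "n_snps_tested": int(len(res.usable())),
        }

    # -- LD score regression
    l = genarch.ld_scores(panel, config.ld_window_kb)
    report["ldsc"] = {}
    h2_by_name = {}
    for name, res in gwas.items():
        tab = res.usable()
        mask = np.isin(panel.variant_map["SNP"].to_numpy(), tab["SNP"].to_numpy())
        est = genarch.ldsc_h2(tab["CHI2"].to_numpy(), l[mask],
                              N=res.n_used, M=int(mask.sum()))
        h2_by_name[name] = est
        report["ldsc"][name] = {"h2_hat": est.h2_hat, "se": est.se,
                                "intercept": est.intercept}
    rg_report = None
    if h2_by_name["mjsw"].h2_hat > 0 and h2_by_name["model_binary"].h2_hat > 0:
        t1 = gwas["mjsw"].table.set_index("SNP")
        t2 = gwas["model_binary"].usable().set_index("SNP")
        shared = t1.index.intersection(t2.index)
        z1 = np.sign(t1.loc[shared, "BETA"]) * np.sqrt(t1.loc[shared, "CHI2"])
        z2 = np.sign(t2.loc[shared, "BETA"]) * np.sqrt(t2.loc[shared, "CHI2"])
        mask = np.isin(panel.variant_map["SNP"].to_numpy(), shared.to_numpy())
        rg = genarch.ldsc_rg(z1.to_numpy(), z2.to_numpy(), l[mask],
                             gwas["mjsw"].n_used, gwas["model_binary"].n_used,
                             h2_by_name["mjsw"].h2_hat,
                             h2_by_name["model_binary"].h2_hat,
                             M=int(mask.sum()))
        rg_report = {"rg_hat": rg.rg_hat, "se": rg.se, "clipped": rg.clipped}
    report["ldsc"]["rg_mjsw_vs_model_binary"] = rg_report

    # -- PRS on hold-out (predicting the health-record label, as a
    #    record-based diagnosis is all that exists outside the imaged set)
    hold_covars = _covariate_block(traits_hold)
    hold_outcome = traits_hold["ehr_case"].to_numpy()
    report["prs"] = {}
    if hold_outcome.sum() >= 5:
        for name, res in gwas.items():
            model = genarch.build_prs(res, panel, thresholds=config.prs_thresholds,
                                      clump_params=config.clump)
            ev = genarch.score_and_evaluate(model, panel_hold, hold_outcome,
                                            covariates=hold_covars)
            report["prs"][name] = {
                "n_significant_thresholds": ev.n_significant(),
                "per_threshold": ev.table.to_dict(orient="records"),
            }

    report["power_ordering"] = {
        "loci_quantitative": loci["mjsw"].count,
        "loci_model_binary": loci["model_binary"].count,
        "loci_ehr_binary": loci["ehr_binary"].count,
    }

    if outdir is not None:
        _write_artifacts(outdir, config, cohort, traits_all, gwas, geometry, report)
    return report


def _write_artifacts(outdir, config, cohort, traits_all, gwas, geometry, report):
    from oa_phenopower.io import sumstats_frame, write_tsv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {}
    write_tsv(cohort, outdir / "cohort.tsv")
    manifest["cohort"] = "cohort.tsv"
    write_tsv(traits_all.drop(columns=["subject_id"]).assign(
        subject_id=traits_all["subject_id"]), outdir / "traits.tsv")
    manifest["traits"] = "traits.tsv"
    write_tsv(geometry, outdir / "geometry_validation.tsv")
    manifest["geometry"] = "geometry_validation.tsv"
    for name, res in gwas.items():
        write_tsv(sumstats_frame(res), outdir / f"sumstats_{name}.tsv")
        manifest[f"sumstats_{name}"] = f"sumstats_{name}.tsv"
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    manifest["report"] = "report.json"
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def worked_example_report() -> pd.DataFrame:
    """Arithmetic checks recomputed from the reference cohort's counts.

    Each row recomputes a derived quantity from the printed input counts
    through the package's own accounting code and states the value the
    source reports.
    """
    c = REFERENCE_COUNTS
    n, n_ehr, n_model = c["n_cohort"], c["n_ehr_cases"], c["n_model_cases"]
    ehr = np.zeros(n, dtype=bool)
    ehr[:n_ehr] = True
    model = np.zeros(n, dtype=bool)
    model[:n_model] = True
    cmp = phenotyping.compare_cases(ehr, model)
    rows = [
        {"quantity": "new_model_cases", "computed": cmp.n_new_cases, "reported": 1931},
        {"quantity": "pct_case_increase", "computed": cmp.pct_increase, "reported": 178},
        {"quantity": "ehr_controls", "computed": cmp.n_total - cmp.n_ehr_cases,
         "reported": 28172},
        {"quantity": "implied_ehr_sensitivity",
         "computed": round(n_ehr / n_model, 3), "reported": 0.360},
        {"quantity": "model_case_prevalence",
         "computed": round(n_model / n, 4), "reported": 0.1031},
        {"quantity": "skeletal_single_gene_pct",
         "computed": int(round(100 * c["n_skeletal_single_gene_loci"]
                               / c["n_single_gene_loci"])), "reported": 57},
    ]
    df = pd.DataFrame(rows)
    df["match"] = df["computed"] == df["reported"]
    return df
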