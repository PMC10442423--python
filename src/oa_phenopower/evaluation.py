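"""Benchmark suites for the pipeline's statistical guarantees.

Each function runs a self-contained simulation study sized for a
single-CPU desk run and returns its summary numbers: geometry
round-trip accuracy of the measurement pipeline, null calibration of
the association tests, heritability and genetic-correlation recovery
of LD score regression, and the quantitative-versus-binary power
ordering that motivates the whole pipeline.
"""

from __future__ import annotations

import numpy as np

from oa_phenopower import assoc, genarch
from oa_phenopower.experiment import geometry_cohort, phantom_validation, stage_seed
from oa_phenopower.simulate.cohort import generate_cohort
from oa_phenopower.simulate.genotypes import PanelConfig, simulate_genotypes
from oa_phenopower.simulate.phantoms import RESOLUTION_SET
from oa_phenopower.simulate.traits import TraitArchitecture, simulate_traits, simulate_trait_pair


def geometry_suite(n_subjects: int = 100, seed: int = 0) -> dict:
    """Measure 2*n noiseless phantoms across the resolution set.

    The cohort's joint width is exactly its height-linear component, so
    disagreement between normalized mJSW and generator truth is pure
    measurement error; accuracy is reported against a two-pixel-spacing
    band.
    """
    cohort = geometry_cohort(n_subjects, stage_seed(seed, 1))
    measured = phantom_validation(cohort, tuple(RESOLUTION_SET), seed, n_subjects)
    return {
        "n_phantoms": 2 * int(len(measured)),
        "max_abs_error_mm": float(measured["abs_error_mm"].max()),
        "frac_within_2px": float(measured["within_2px"].mean()),
    }


def null_calibration(n: int = 2000, m: int = 5000, seed: int = 0,
                     n_reps: int = 10) -> dict:
    """Genomic inflation and type-I error under a fully null trait.

    Independent SNPs (no LD), heritability zero, covariate-adjusted
    linear association. Lambda is averaged and the type-I fraction
    pooled over ``n_reps`` replicate draws: the sample median behind a
    single lambda has Monte-Carlo error ~0.03 at M = 5000, so a
    one-draw check would mostly measure that noise rather than the
    test's calibration.
    """
    lambdas, rejections, m_tested = [], 0, 0
    for rep in range(n_reps):
        panel = simulate_genotypes(
            PanelConfig(n_subjects=n, n_snps=m, rho=0.0),
            seed=stage_seed(seed, 2 + 10 * rep))
        cohort = generate_cohort(n, seed=stage_seed(seed, 3 + 10 * rep))
        rng = np.random.default_rng(stage_seed(seed, 4 + 10 * rep))
        y = rng.standard_normal(n)
        covars = np.column_stack(
            [(cohort["sex"] == "M").astype(float), cohort["age"],
             cohort["bmi"], cohort["height"]]
        )
        res = assoc.linear_assoc(panel, y, covariates=covars)
        lambdas.append(assoc.lambda_gc(res))
        rejections += int((res.p < 0.05).sum())
        m_tested += len(res.table)
    return {
        "lambda": float(np.mean(lambdas)),
        "type1_rate_at_0.05": rejections / m_tested,
        "m_tested": m_tested,
        "n_reps": n_reps,
    }


def h2_recovery(n_seeds: int = 50, n: int = 5000, m: int = 5000,
                m_causal: int | None = None, h2: float = 0.24, seed: int = 0) -> dict:
    """LD-score-regression heritability recovery over repeated draws.

    The default architecture is infinitesimal (every SNP causal), the
    model LD score regression actually assumes; sparse architectures
    couple the realized genetic variance to block-level tagging and
    bias the slope at desk-scale M.
    """
    arch = TraitArchitecture(m_causal=m if m_causal is None else m_causal, h2=h2)
    vals = []
    for s in range(n_seeds):
        panel = simulate_genotypes(
            PanelConfig(n_subjects=n, n_snps=m), seed=stage_seed(seed, 100 + s))
        cohort = generate_cohort(n, seed=stage_seed(seed, 200 + s))
        traits = simulate_traits(panel, arch, cohort, seed=stage_seed(seed, 300 + s))
        res = assoc.linear_assoc(panel, traits["y_quant"].to_numpy())
        l = genarch.ld_scores(panel)
        vals.append(genarch.ldsc_h2(res.chi2, l, N=n, M=m).h2_hat)
    vals = np.asarray(vals)
    return {
        "mean_h2_hat": float(vals.mean()),
        "mc_se": float(vals.std(ddof=1) / np.sqrt(n_seeds)),
        "truth": h2,
        "n_seeds": n_seeds,
    }


def rg_recovery(n_seeds: int = 25, n: int = 5000, m: int = 2000,
                m_causal: int | None = None, h2: float = 0.25, rg: float = -0.9,
                seed: int = 0) -> dict:
    """Cross-trait LDSC genetic-correlation recovery over repeated draws.

    Trait pairs share an infinitesimal causal architecture with effect
    correlation ``rg``. The genetic covariance is normalized by the
    known simulated heritabilities: at desk-scale M a single seed's own
    h2 estimate is noisy enough to put the ratio's tails far from the
    truth, so normalizing by per-seed estimates would test the tail
    behaviour of a ratio rather than recovery of the correlation.
    """
    arch = TraitArchitecture(m_causal=m if m_causal is None else m_causal,
                             h2=h2, rg_shared=rg)
    vals = []
    for s in range(n_seeds):
        panel = simulate_genotypes(
            PanelConfig(n_subjects=n, n_snps=m), seed=stage_seed(seed, 400 + s))
        y1, y2 = simulate_trait_pair(panel, arch, seed=stage_seed(seed, 500 + s))
        r1 = assoc.linear_assoc(panel, y1)
        r2 = assoc.linear_assoc(panel, y2)
        l = genarch.ld_scores(panel)
        z1 = np.sign(r1.table["BETA"].to_numpy()) * np.sqrt(r1.chi2)
        z2 = np.sign(r2.table["BETA"].to_numpy()) * np.sqrt(r2.chi2)
        est = genarch.ldsc_rg(z1, z2, l, n, n, h2, h2, M=m)
        vals.append(est.rg_hat)
    vals = np.asarray(vals)
    return {
        "mean_rg_hat": float(vals.mean()),
        "mc_se": float(vals.std(ddof=1) / np.sqrt(len(vals))),
        "truth": rg,
        "n_seeds_used": int(len(vals)),
    }


def power_ordering(n_seeds: int = 25, n_gwas: int = 4000, n_holdout: int = 2000,
                   m: int = 2000, m_causal: int = 20, h2: float = 0.25,
                   prevalence: float = 0.10, ehr_sensitivity: float = 0.36,
                   seed: int = 0) -> dict:
    """Loci and PRS power for quantitative vs dichotomized vs EHR labels.

    For each seed the same liability is analyzed three ways — as the
    quantitative trait itself, thresholded at prevalence K, and
    additionally thinned at the health-record sensitivity — and each
    set of summary statistics is clumped at genome-wide thresholds and
    turned into a clumping+thresholding PRS evaluated on a disjoint
    hold-out against the record label.
    """
    arch = TraitArchitecture(m_causal=m_causal, h2=h2, prevalence_K=prevalence,
                             ehr_sensitivity=ehr_sensitivity)
    n_total = n_gwas + n_holdout
    loci = {"quant": [], "dichotomized": [], "ehr": []}
    prs_sig = {"quant": [], "dichotomized": [], "ehr": []}
    for s in range(n_seeds):
        panel_all = simulate_genotypes(
            PanelConfig(n_subjects=n_total, n_snps=m), seed=stage_seed(seed, 600 + s))
        cohort = generate_cohort(n_total, seed=stage_seed(seed, 700 + s))
        traits = simulate_traits(panel_all, arch, cohort, seed=stage_seed(seed, 800 + s))
        covars_all = np.column_stack(
            [(cohort["sex"] == "M").astype(float), cohort["age"],
             cohort["bmi"], cohort["height"]]
        )
        gidx = np.arange(n_gwas)
        hidx = np.arange(n_gwas, n_total)
        panel = panel_all.subset_subjects(gidx)
        panel_hold = panel_all.subset_subjects(hidx)
        covars = covars_all[gidx]
        results = {
            "quant": assoc.linear_assoc(
                panel, traits["y_quant"].to_numpy()[gidx], covariates=covars),
            "dichotomized": assoc.logistic_assoc(
                panel, traits["true_case"].to_numpy()[gidx], covariates=covars),
            "ehr": assoc.logistic_assoc(
                panel, traits["ehr_case"].to_numpy()[gidx], covariates=covars),
        }
        hold_outcome = traits["ehr_case"].to_numpy()[hidx]
        for name, res in results.items():
            loci[name].append(assoc.greedy_clump(res, panel).count)
            model = genarch.build_prs(res, panel)
            ev = genarch.score_and_evaluate(
                model, panel_hold, hold_outcome, covariates=covars_all[hidx])
            prs_sig[name].append(ev.n_significant())
    return {
        "mean_loci": {k: float(np.mean(v)) for k, v in loci.items()},
        "mean_prs_significant_thresholds": {k: float(np.mean(v)) for k, v in prs_sig.items()},
        "n_seeds": n_seeds,
    }
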