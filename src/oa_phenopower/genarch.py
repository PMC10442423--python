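"""Genetic-architecture estimation: LD score regression and C+T scores.

LD scores sum squared dosage correlations over a physical window
(including the self term, so l_j >= 1 up to sampling noise); the window
is in kb because the simulated map has no genetic-map distances.

Heritability comes from unweighted OLS of per-SNP chi-square on LD
score with a free intercept: E[chi2_j] = 1 + N h2 l_j / M under a
polygenic model, so h2_hat = slope * M / N. Standard errors are
leave-one-block-out jackknife over contiguous SNP blocks. Cross-trait
genetic correlation regresses z1*z2 on l the same way:
E[z1 z2] = sqrt(N1 N2) * gencov * l / M (+ an overlap intercept), and
rg = gencov / sqrt(h2_1 h2_2).

Polygenic scores use clumping + thresholding: one greedy clump at the
loosest threshold, then per-threshold retention of index SNPs, weights
equal to the GWAS betas. Evaluation z-scores each score in the hold-out
sample and tests it in a covariate-adjusted logistic model with
Bonferroni correction over all (phenotype, threshold) tests performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from oa_phenopower.assoc import AssocResult, ClumpParams, greedy_clump

DEFAULT_LD_WINDOW_KB = 1000.0
PRS_THRESHOLDS = (1.0, 0.1, 1e-2, 1e-3, 1e-4, 1e-5, 1e-6)
#: Bonferroni denominator: 3 phenotypes x 7 thresholds
DEFAULT_TOTAL_TESTS = 21


def ld_scores(panel, window_kb: float = DEFAULT_LD_WINDOW_KB) -> np.ndarray:
    """Per-SNP sum of r^2 with all SNPs in a same-chromosome kb window.

    Includes the self term (r^2 = 1). A zero window degenerates to
    l_j = 1 for every SNP.
    """
    if panel.n_snps == 0:
        raise ValueError("empty panel")
    gs = panel.standardized()
    n = panel.n_subjects
    chrom = panel.variant_map["CHR"].to_numpy()
    pos = panel.variant_map["BP"].to_numpy()
    m = panel.n_snps
    l = np.ones(m)
    window_bp = window_kb * 1000.0
    for d in range(1, m):
        pair_ok = (chrom[:-d] == chrom[d:]) & (np.abs(pos[d:] - pos[:-d]) <= window_bp)
        if not pair_ok.any():
            # positions increase within a chromosome, so larger offsets
            # can only qualify across chromosome boundaries; scan on
            # until no same-chromosome pair remains at this offset
            if not (chrom[:-d] == chrom[d:]).any():
                break
            continue
        r = np.einsum("ij,ij->j", gs[:, :-d], gs[:, d:]) / n
        r2 = np.where(pair_ok, r**2, 0.0)
        l[:-d] += r2
        l[d:] += r2
    return l


@dataclass
class HeritabilityEstimate:
    h2_hat: float
    se: float
    intercept: float
    n: int
    m: int
    out_of_bounds: bool = False


def _block_jackknife(values_fn, m: int, n_blocks: int) -> tuple:
    """Full estimate and delete-one-block jackknife SE.

    ``values_fn(mask)`` computes the estimate on the SNPs where mask is
    True.
    """
    full = values_fn(np.ones(m, dtype=bool))
    edges = np.linspace(0, m, n_blocks + 1).astype(int)
    reps = []
    for b in range(n_blocks):
        mask = np.ones(m, dtype=bool)
        mask[edges[b]:edges[b + 1]] = False
        reps.append(values_fn(mask))
    reps = np.asarray(reps)
    b = len(reps)
    se = float(np.sqrt((b - 1) / b * np.sum((reps - reps.mean()) ** 2)))
    return full, se


def _ols_slope_intercept(x: np.ndarray, y: np.ndarray) -> tuple:
    if np.ptp(x) == 0:
        raise ValueError("constant LD scores: slope unidentifiable")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def ldsc_h2(chi2: np.ndarray, l: np.ndarray, N: int, M: int,
            n_blocks: int = 20) -> HeritabilityEstimate:
    """LD score regression heritability with block-jackknife SE."""
    chi2 = np.asarray(chi2, dtype=float)
    l = np.asarray(l, dtype=float)
    if chi2.shape != l.shape:
        raise ValueError("chi2 and LD score vectors differ in length")
    if N <= 0 or M <= 0:
        raise ValueError("N and M must be positive")
    ok = np.isfinite(chi2)
    chi2, l = chi2[ok], l[ok]
    m = len(chi2)

    def est(mask):
        slope, _ = _ols_slope_intercept(l[mask], chi2[mask])
        return slope * M / N

    h2_hat, se = _block_jackknife(est, m, min(n_blocks, m))
    _, intercept = _ols_slope_intercept(l, chi2)
    return HeritabilityEstimate(
        h2_hat=float(h2_hat),
        se=se,
        intercept=intercept,
        n=N,
        m=M,
        out_of_bounds=not 0.0 <= h2_hat <= 1.0,
    )


@dataclass
class GeneticCorrelation:
    rg_hat: float
    se: float
    gencov: float
    clipped: bool = False


def ldsc_rg(z1: np.ndarray, z2: np.ndarray, l: np.ndarray, N1: int, N2: int,
            h2_1: float, h2_2: float, M: int | None = None,
            n_blocks: int = 20) -> GeneticCorrelation:
    """Cross-trait LD score regression genetic correlation.

    ``h2_1``/``h2_2`` are the per-trait (estimated or true) SNP
    heritabilities used to normalize the genetic covariance; they must
    be positive. Sample overlap only shifts the free intercept.
    """
    z1 = np.asarray(z1, float)
    z2 = np.asarray(z2, float)
    l = np.asarray(l, float)
    if h2_1 <= 0 or h2_2 <= 0:
        raise ValueError("per-trait h2 must be positive to normalize rg")
    if not (z1.shape == z2.shape == l.shape):
        raise ValueError("input vectors differ in length")
    if M is None:
        M = len(l)
    m = len(l)
    prod = z1 * z2
    denom = np.sqrt(h2_1 * h2_2)

    def est(mask):
        slope, _ = _ols_slope_intercept(l[mask], prod[mask])
        gencov = slope * M / np.sqrt(N1 * N2)
        return gencov / denom

    rg_hat, se = _block_jackknife(est, m, min(n_blocks, m))
    gencov = rg_hat * denom
    return GeneticCorrelation(
        rg_hat=float(rg_hat), se=se, gencov=float(gencov),
        clipped=abs(rg_hat) > 1.0,
    )


@dataclass
class PRSModel:
    """Clumping + thresholding score: nested SNP sets by p threshold."""

    thresholds: tuple
    snps: dict          # threshold -> list of SNP ids
    weights: dict       # threshold -> np.ndarray of betas
    clump_params: ClumpParams
    empty_thresholds: list = field(default_factory=list)


def build_prs(sumstats: AssocResult, panel, thresholds: tuple = PRS_THRESHOLDS,
              clump_params: ClumpParams | None = None) -> PRSModel:
    """Clump once at the loosest threshold, then threshold the indices."""
    if clump_params is None:
        clump_params = ClumpParams()
    loosest = max(thresholds)
    base = ClumpParams(p1=loosest, p2=max(loosest, clump_params.p2),
                       r2_max=clump_params.r2_max, window_kb=clump_params.window_kb)
    loci = greedy_clump(sumstats, panel, base)
    tab = sumstats.usable().set_index("SNP")
    idx_p = {l.index_snp: l.p for l in loci.loci}
    model = PRSModel(thresholds=tuple(sorted(thresholds, reverse=True)), snps={},
                     weights={}, clump_params=clump_params)
    for t in model.thresholds:
        sel = [s for s, p in idx_p.items() if p <= t]
        model.snps[t] = sel
        model.weights[t] = tab.loc[sel, "BETA"].to_numpy() if sel else np.array([])
        if not sel:
            model.empty_thresholds.append(t)
    return model


@dataclass
class PRSEvaluation:
    table: pd.DataFrame   # per threshold: ESTIMATE, SE, P, SIGNIFICANT, N_SNPS
    alpha: float
    total_tests: int

    def n_significant(self) -> int:
        return int(self.table["SIGNIFICANT"].sum())


def score_prs(model: PRSModel, panel, threshold: float) -> np.ndarray:
    """Raw (un-normalized) score: sum of beta-weighted dosages."""
    snps = model.snps[threshold]
    if not snps:
        return np.zeros(panel.n_subjects)
    col_of = {s: j for j, s in enumerate(panel.variant_map["SNP"])}
    cols = [col_of[s] for s in snps]
    return panel.dosage_float()[:, cols] @ model.weights[threshold]


def score_and_evaluate(model: PRSModel, holdout_panel, outcome_flags: np.ndarray,
                       covariates=None, alpha: float = 0.05,
                       total_tests: int = DEFAULT_TOTAL_TESTS) -> PRSEvaluation:
    """Logistic evaluation of z-scored PRS against a binary outcome.

    One covariate-adjusted logistic fit per threshold; the significance
    flag applies Bonferroni at alpha / total_tests (21 by default:
    3 phenotypes x 7 thresholds). Zero-variance scores are skipped and
    flagged with NaN estimates.
    """
    y = np.asarray(outcome_flags).astype(float)
    n = holdout_panel.n_subjects
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    else:
        C = np.empty((n, 0))
    rows = []
    for t in model.thresholds:
        raw = score_prs(model, holdout_panel, t)
        sd = raw.std()
        if sd == 0:
            rows.append({"THRESHOLD": t, "N_SNPS": len(model.snps[t]),
                         "ESTIMATE": np.nan, "SE": np.nan, "P": np.nan,
                         "SIGNIFICANT": False, "SKIPPED": True})
            continue
        z = (raw - raw.mean()) / sd
        X = sm.add_constant(np.column_stack([z, C]))
        fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
        est, se, p = fit.params[1], fit.bse[1], fit.pvalues[1]
        rows.append({"THRESHOLD": t, "N_SNPS": len(model.snps[t]),
                     "ESTIMATE": float(est), "SE": float(se), "P": float(p),
                     "SIGNIFICANT": bool(p < alpha / total_tests), "SKIPPED": False})
    return PRSEvaluation(table=pd.DataFrame(rows), alpha=alpha, total_tests=total_tests)
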