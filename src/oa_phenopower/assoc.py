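"""Per-SNP association testing, genomic inflation, and LD clumping.

Quantitative traits get covariate-adjusted OLS (equivalent to
regressing covariate-residualized phenotype on covariate-residualized
dosage) with two-sided t-based p-values; binary traits get a full
per-SNP logistic fit by Newton/IRLS with Wald p-values, batched across
SNPs for speed. Underflowing p-values are reported at the smallest
positive representable double, never 0.

Clumping is the greedy index-SNP algorithm used by standard GWAS
tooling: candidates below the primary threshold are visited in
ascending p (ties by position then id); each unassigned candidate
becomes an index and absorbs the unassigned SNPs below the secondary
threshold that lie within the physical window and are in LD (r-squared
at or above the threshold) with it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

P_FLOOR = float(np.nextafter(0, 1))


@dataclass
class AssocResult:
    """Per-SNP summary statistics (beta, se, p, chi2) plus bookkeeping."""

    table: pd.DataFrame          # SNP, CHR, BP, BETA, SE, P, CHI2, (CONVERGED)
    phenotype: str = ""
    n_used: int = 0

    @property
    def p(self) -> np.ndarray:
        return self.table["P"].to_numpy()

    @property
    def chi2(self) -> np.ndarray:
        return self.table["CHI2"].to_numpy()

    def usable(self) -> pd.DataFrame:
        """Rows that converged (all rows for linear fits)."""
        if "CONVERGED" in self.table.columns:
            return self.table[self.table["CONVERGED"]]
        return self.table


def _covariate_matrix(n: int, covariates: np.ndarray | pd.DataFrame | None) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    C = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    return C


def _result_frame(variant_map: pd.DataFrame, keep: np.ndarray, beta, se, p, chi2,
                  converged=None) -> pd.DataFrame:
    out = pd.DataFrame(
        {
            "SNP": variant_map["SNP"].to_numpy()[keep],
            "CHR": variant_map["CHR"].to_numpy()[keep],
            "BP": variant_map["BP"].to_numpy()[keep],
            "BETA": beta,
            "SE": se,
            "P": np.maximum(p, P_FLOOR),
            "CHI2": chi2,
        }
    )
    if converged is not None:
        out["CONVERGED"] = converged
    return out


def linear_assoc(panel, y: np.ndarray, covariates=None, maf_min: float = 0.0,
                 phenotype: str = "quant") -> AssocResult:
    """Covariate-adjusted OLS of a quantitative trait on each SNP dosage.

    Monomorphic SNPs (and SNPs below ``maf_min``) are excluded before
    testing. SEs use the residual variance with n - p - 1 degrees of
    freedom, p counting covariates, intercept and the SNP.
    """
    y = np.asarray(y, dtype=float)
    n = panel.n_subjects
    if y.shape[0] != n:
        raise ValueError("phenotype length does not match panel")
    C = _covariate_matrix(n, covariates)
    G = panel.dosage_float()
    freq = G.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    keep = maf > max(maf_min, 0.0)
    G = G[:, keep]

    Q, _ = np.linalg.qr(C)
    y_r = y - Q @ (Q.T @ y)
    G_r = G - Q @ (Q.T @ G)

    gg = np.einsum("ij,ij->j", G_r, G_r)
    gy = G_r.T @ y_r
    yy = float(y_r @ y_r)
    dof = n - C.shape[1] - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = gy / gg
        rss = np.maximum(yy - beta * gy, 0.0)
        sigma2 = rss / dof
        se = np.sqrt(sigma2 / gg)
        tstat = beta / se
        p = 2.0 * stats.t.sf(np.abs(tstat), dof)
        chi2 = tstat**2
    # perfect fits: zero residual variance -> p at the underflow floor
    exact = (se == 0) | ~np.isfinite(p)
    p[exact & np.isfinite(beta)] = 0.0
    chi2[exact] = np.inf
    return AssocResult(
        table=_result_frame(panel.variant_map, keep, beta, se, p, chi2),
        phenotype=phenotype,
        n_used=n,
    )


def logistic_assoc(panel, case_flags: np.ndarray, covariates=None,
                   maf_min: float = 0.0, phenotype: str = "binary",
                   max_iter: int = 25, tol: float = 1e-6) -> AssocResult:
    """Per-SNP logistic regression, Newton/IRLS batched over SNPs.

    Every SNP gets its own full fit of [intercept, covariates, dosage];
    fits that fail to converge or drift toward separation (|beta| > 12
    on the dosage) are flagged CONVERGED=False and excluded from
    downstream locus counts. Wald z-tests give SE and p.
    """
    yb = np.asarray(case_flags).astype(float)
    n = panel.n_subjects
    if yb.shape[0] != n:
        raise ValueError("phenotype length does not match panel")
    if yb.min() == yb.max():
        raise ValueError("both classes must be present")
    C = _covariate_matrix(n, covariates)
    p0 = C.shape[1]
    G = panel.dosage_float()
    freq = G.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    keep = maf > max(maf_min, 0.0)
    G = G[:, keep]
    m = G.shape[1]

    # warm start at the covariate-only fit shared by all SNPs
    b_null = np.zeros(p0)
    for _ in range(50):
        eta0 = C @ b_null
        mu0 = 1.0 / (1.0 + np.exp(-eta0))
        w0 = np.maximum(mu0 * (1.0 - mu0), 1e-12)
        H0 = C.T @ (C * w0[:, None])
        g0 = C.T @ (yb - mu0)
        step0 = np.linalg.solve(H0, g0)
        b_null += step0
        if np.max(np.abs(step0)) < tol:
            break

    Bc = np.tile(b_null[:, None], (1, m))      # (p0, m) covariate coefs
    bg = np.zeros(m)                           # dosage coefs
    # n x p0(p0+1)/2 products for batched C' W C
    iu = np.triu_indices(p0)
    P = (C[:, iu[0]] * C[:, iu[1]])            # (n, k)
    def batched_hessian(Gs, Bcs, bgs):
        eta = C @ Bcs + Gs * bgs
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        k = Gs.shape[1]
        Hs = np.zeros((k, p0 + 1, p0 + 1))
        Hcc_flat = w.T @ P
        Hs[:, iu[0], iu[1]] = Hcc_flat
        Hs[:, iu[1], iu[0]] = Hcc_flat
        wG = w * Gs
        Hs[:, :p0, p0] = (C.T @ wG).T
        Hs[:, p0, :p0] = Hs[:, :p0, p0]
        Hs[:, p0, p0] = np.einsum("ij,ij->j", wG, Gs)
        r = yb[:, None] - mu
        grad = np.empty((k, p0 + 1))
        grad[:, :p0] = (C.T @ r).T
        grad[:, p0] = np.einsum("ij,ij->j", Gs, r)
        return Hs, grad

    active = np.ones(m, dtype=bool)
    converged = np.zeros(m, dtype=bool)
    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        Ha, grad = batched_hessian(G[:, idx], Bc[:, idx], bg[idx])
        try:
            step = np.linalg.solve(Ha, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.stack(
                [np.linalg.lstsq(Ha[j], grad[j], rcond=None)[0] for j in range(len(idx))]
            )
        step = np.clip(step, -5.0, 5.0)        # dampen early overshoot
        Bc[:, idx] += step[:, :p0].T
        bg[idx] += step[:, p0]
        done = np.max(np.abs(step), axis=1) < tol
        converged[idx[done]] = True
        active[idx[done]] = False

    H, _ = batched_hessian(G, Bc, bg)          # curvature at the final coefs
    with np.errstate(invalid="ignore", divide="ignore"):
        Hinv = np.linalg.inv(H)
        se = np.sqrt(Hinv[:, p0, p0])
        z = bg / se
        p = 2.0 * stats.norm.sf(np.abs(z))
        chi2 = z**2
    ok = converged & np.isfinite(se) & (np.abs(bg) <= 12.0)
    return AssocResult(
        table=_result_frame(panel.variant_map, keep, bg, se, p, chi2, converged=ok),
        phenotype=phenotype,
        n_used=n,
    )


#: median of the 1-df chi-square distribution
CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, df=1))


def lambda_gc(results: AssocResult | np.ndarray) -> float:
    """Genomic inflation: median test chi-square over its null median."""
    chi2 = results.chi2 if isinstance(results, AssocResult) else np.asarray(results, float)
    chi2 = chi2[np.isfinite(chi2)]
    if chi2.size == 0:
        raise ValueError("no finite chi-square statistics")
    return float(np.median(chi2) / CHI2_1DF_MEDIAN)


@dataclass(frozen=True)
class ClumpParams:
    p1: float = 5e-8
    p2: float = 1e-4
    r2_max: float = 0.1          # LD floor for clump membership
    window_kb: float = 250.0

    def validate(self) -> None:
        if self.p1 > self.p2:
            raise ValueError("p1 must be <= p2")
        if not 0.0 < self.r2_max < 1.0:
            raise ValueError("r2_max must be in (0, 1)")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be positive")


@dataclass
class Locus:
    index_snp: str
    chrom: int
    pos: int
    p: float
    members: list = field(default_factory=list)


@dataclass
class LocusSet:
    loci: list

    @property
    def count(self) -> int:
        return len(self.loci)

    def index_snps(self) -> list:
        return [l.index_snp for l in self.loci]


def greedy_clump(results: AssocResult, panel, params: ClumpParams | None = None) -> LocusSet:
    """Greedy LD clumping of summary statistics into independent loci."""
    if params is None:
        params = ClumpParams()
    params.validate()
    tab = results.usable()
    if tab["BP"].isna().any():
        raise ValueError("missing positions in summary statistics")
    vm = panel.variant_map
    col_of = {s: j for j, s in enumerate(vm["SNP"])}
    snp = tab["SNP"].to_numpy()
    chrom = tab["CHR"].to_numpy()
    pos = tab["BP"].to_numpy()
    pval = tab["P"].to_numpy()

    cand_mask = pval <= params.p1
    member_mask = pval <= params.p2
    order = np.lexsort((snp[cand_mask], pos[cand_mask], pval[cand_mask]))
    cand_rows = np.flatnonzero(cand_mask)[order]

    G = panel.dosage_float()
    Gc = G - G.mean(axis=0)
    norms = np.sqrt(np.einsum("ij,ij->j", Gc, Gc))
    assigned = np.zeros(len(tab), dtype=bool)
    window_bp = params.window_kb * 1000.0
    loci = []
    for row in cand_rows:
        if assigned[row]:
            continue
        assigned[row] = True
        near = (
            member_mask
            & ~assigned
            & (chrom == chrom[row])
            & (np.abs(pos - pos[row]) <= window_bp)
        )
        near_rows = np.flatnonzero(near)
        members = []
        if near_rows.size:
            jx = col_of[snp[row]]
            jks = [col_of[s] for s in snp[near_rows]]
            with np.errstate(invalid="ignore", divide="ignore"):
                r = (Gc[:, jks].T @ Gc[:, jx]) / (norms[jks] * norms[jx])
            r2 = np.nan_to_num(r**2)
            for nr, rr in zip(near_rows, r2):
                if rr >= params.r2_max:
                    assigned[nr] = True
                    members.append(snp[nr])
        loci.append(
            Locus(
                index_snp=snp[row],
                chrom=int(chrom[row]),
                pos=int(pos[row]),
                p=float(pval[row]),
                members=members,
            )
        )
    return LocusSet(loci=loci)
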