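"""Trait simulator: polygenic liability, threshold cases, EHR thinning.

The quantitative trait is y = g + e with g a standardized polygenic
score over ``m_causal`` randomly placed causal SNPs (sample variance
exactly h2) and e standardized environmental noise (variance 1 - h2).
Disease liability equals y; a subject is a true case when liability
exceeds the upper-K standard-normal quantile, so the expected prevalence
is K.  The health-record label thins true cases at ``ehr_sensitivity``
(under-diagnosis) and flips controls at 1 - ``ehr_specificity`` (default
specificity 1: no false positives in the record).

mJSW in millimetres is an affine map of liability with a height
component: narrower joints mean higher liability, and taller subjects
have wider joints (which is what the height-regression normalization of
the measurement pipeline exploits).

Pain items are drawn conditionally independent given case status; the
default case/control rates mirror the reference study (past-month pain
49.4%/27.2%, 3-month pain 80.4%/70.6%, mean 0-10 rating 3.33/2.58).
Fracture-in-5-years is drawn from a logistic model in mJSW, height,
sex, age and body fat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: default EHR sensitivity: ICD-10-recorded cases / model-ascertained cases
#: in the reference cohort (1085 / 3016).
DEFAULT_EHR_SENSITIVITY = 1085 / 3016

#: default prevalence: model-ascertained cases over the full cohort
#: (3016 / 29,257).
DEFAULT_PREVALENCE = 3016 / 29257


@dataclass(frozen=True)
class PainParams:
    month_rate_case: float = 0.494
    month_rate_control: float = 0.272
    chronic_rate_case: float = 0.804
    chronic_rate_control: float = 0.706
    rating_mean_case: float = 3.33
    rating_mean_control: float = 2.58


@dataclass(frozen=True)
class FractureParams:
    """Log-odds coefficients of the fracture generator (per unit shown)."""

    intercept: float = -3.2
    mjsw: float = -0.30          # per mm of joint space
    height: float = -0.005       # per cm
    sex_male: float = -0.20
    age: float = 0.015           # per year
    body_fat: float = 0.005      # per percentage point


@dataclass(frozen=True)
class MJSWMap:
    """Affine map from standardized liability to joint space in mm."""

    mean_mm: float = 4.0
    sd_mm: float = 0.55
    height_slope_mm_per_cm: float = 0.06
    height_ref_cm: float = 169.5


@dataclass(frozen=True)
class TraitArchitecture:
    m_causal: int = 200
    h2: float = 0.25
    prevalence_K: float = DEFAULT_PREVALENCE
    ehr_sensitivity: float = DEFAULT_EHR_SENSITIVITY
    ehr_specificity: float = 1.0
    rg_shared: float = -0.9       # effect correlation for paired traits
    pain: PainParams = field(default_factory=PainParams)
    fracture: FractureParams = field(default_factory=FractureParams)
    mjsw_map: MJSWMap = field(default_factory=MJSWMap)

    def validate(self, n_snps: int | None = None) -> None:
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError(f"h2 must be in [0, 1], got {self.h2}")
        if not 0.0 < self.prevalence_K < 1.0:
            raise ValueError("prevalence_K must be in (0, 1)")
        if not 0.0 < self.ehr_sensitivity <= 1.0:
            raise ValueError("ehr_sensitivity must be in (0, 1]")
        if not 0.0 < self.ehr_specificity <= 1.0:
            raise ValueError("ehr_specificity must be in (0, 1]")
        if n_snps is not None and self.m_causal > n_snps:
            raise ValueError("m_causal exceeds panel size")
        if not -1.0 <= self.rg_shared <= 1.0:
            raise ValueError("rg_shared must be in [-1, 1]")


def liability_threshold(prevalence_K: float) -> float:
    """Upper-K quantile of the standard normal (0 at K = 0.5)."""
    return float(stats.norm.isf(prevalence_K))


def _standardize_columns(g: np.ndarray) -> np.ndarray:
    g = g - g.mean(axis=0)
    sd = g.std(axis=0)
    sd[sd == 0] = np.inf
    return g / sd


def _standardize(x: np.ndarray, target_var: float) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd * np.sqrt(target_var)


def polygenic_component(panel, m_causal: int, h2: float, rng: np.random.Generator,
                        effects: np.ndarray | None = None,
                        causal_idx: np.ndarray | None = None):
    """Standardized genetic value (sample variance exactly h2).

    Returns (g, causal_idx, effects): raw per-SNP effects are N(0,1) on
    standardized dosages; the aggregate is rescaled to variance h2.
    """
    if causal_idx is None:
        causal_idx = np.sort(rng.choice(panel.n_snps, size=m_causal, replace=False))
    if effects is None:
        effects = rng.standard_normal(len(causal_idx))
    gs = _standardize_columns(panel.dosages[:, causal_idx].astype(np.float64))
    g = _standardize(gs @ effects, h2)
    return g, causal_idx, effects


def simulate_traits(panel, arch: TraitArchitecture, covariates: pd.DataFrame,
                    seed: int = 0) -> pd.DataFrame:
    """Per-subject phenotypes for one trait architecture.

    ``covariates`` must have height, sex, age, body_fat columns aligned
    with the panel's subjects. Returns a copy of ``covariates`` with
    y_quant, liability, true_case, ehr_case, true_mjsw, pain and
    fracture columns appended; causal-SNP metadata in ``df.attrs``.
    """
    arch.validate(panel.n_snps)
    if len(covariates) != panel.n_subjects:
        raise ValueError("covariate table and panel disagree on subject count")
    rng = np.random.default_rng(seed)
    n = panel.n_subjects

    g, causal_idx, effects = polygenic_component(panel, arch.m_causal, arch.h2, rng)
    e = _standardize(rng.standard_normal(n), 1.0 - arch.h2)
    y = g + e
    thresh = liability_threshold(arch.prevalence_K)
    true_case = y > thresh

    ehr_case = true_case & (rng.random(n) < arch.ehr_sensitivity)
    if arch.ehr_specificity < 1.0:
        ehr_case |= ~true_case & (rng.random(n) < 1.0 - arch.ehr_specificity)

    mm = arch.mjsw_map
    true_mjsw = (
        mm.mean_mm
        + mm.height_slope_mm_per_cm * (covariates["height"].to_numpy() - mm.height_ref_cm)
        - mm.sd_mm * y
    )

    p = arch.pain
    pain_month = rng.random(n) < np.where(true_case, p.month_rate_case, p.month_rate_control)
    pain_3mo = rng.random(n) < np.where(true_case, p.chronic_rate_case, p.chronic_rate_control)
    rating_mean = np.where(true_case, p.rating_mean_case, p.rating_mean_control)
    pain_rating = rng.binomial(10, rating_mean / 10.0)

    f = arch.fracture
    logit = (
        f.intercept
        + f.mjsw * true_mjsw
        + f.height * covariates["height"].to_numpy()
        + f.sex_male * (covariates["sex"].to_numpy() == "M")
        + f.age * covariates["age"].to_numpy()
        + f.body_fat * covariates["body_fat"].to_numpy()
    )
    fracture = rng.random(n) < 1.0 / (1.0 + np.exp(-logit))

    out = covariates.copy()
    out["y_quant"] = y
    out["liability"] = y
    out["true_case"] = true_case
    out["ehr_case"] = ehr_case
    out["true_mjsw"] = true_mjsw
    out["pain_month_flag"] = pain_month
    out["pain_3mo_flag"] = pain_3mo
    out["pain_rating"] = pain_rating
    out["fracture_5yr_flag"] = fracture
    out.attrs["liability_threshold"] = thresh
    out.attrs["causal_idx"] = causal_idx
    out.attrs["causal_effects"] = effects
    out.attrs["genetic_value"] = g
    return out


def simulate_trait_pair(panel, arch: TraitArchitecture, seed: int = 0):
    """Two traits sharing causal SNPs with effect correlation rg_shared.

    Both traits have heritability ``arch.h2`` and independent
    environments; used for genetic-correlation recovery. Returns
    (y1, y2) arrays.
    """
    arch.validate(panel.n_snps)
    rng = np.random.default_rng(seed)
    n = panel.n_subjects
    causal_idx = np.sort(rng.choice(panel.n_snps, size=arch.m_causal, replace=False))
    r = arch.rg_shared
    cov = np.array([[1.0, r], [r, 1.0]])
    betas = rng.multivariate_normal(np.zeros(2), cov, size=arch.m_causal)
    ys = []
    gs = _standardize_columns(panel.dosages[:, causal_idx].astype(np.float64))
    for k in range(2):
        g = _standardize(gs @ betas[:, k], arch.h2)
        e = _standardize(rng.standard_normal(n), 1.0 - arch.h2)
        ys.append(g + e)
    return ys[0], ys[1]
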