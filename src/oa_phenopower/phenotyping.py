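"""Binary case ascertainment and its epidemiological read-outs.

``dichotomize`` stands in for an image classifier: it labels the
lowest-mJSW fraction of the cohort as cases at a target prevalence
(severe radiographic knee OA is marked by joint-space narrowing, so a
rank cut on the same latent quantity captures exactly the
quantitative-versus-binary power construct under study).  The default
target prevalence, 3016/29,257, matches the reference cohort's
model-ascertained case fraction.

The rest of the module is ascertainment analytics: pairwise inter-rater
confusion tables expressed as proportions of 100, sensitivity and
specificity, health-record-versus-model case comparison, and the pain
and fracture association statistics (plain Pearson chi-square without
continuity correction, Welch two-sided t, covariate-adjusted logistic
regression).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

DEFAULT_PREVALENCE_TARGET = 3016 / 29257


@dataclass
class DichotomyResult:
    case_flags: np.ndarray
    cutoff: float
    realized_fraction: float


def dichotomize(mjsw: np.ndarray, prevalence_target: float = DEFAULT_PREVALENCE_TARGET) -> DichotomyResult:
    """Flag the lowest-``prevalence_target`` fraction of values as cases.

    The cutoff is the k-th smallest value with k = floor(target * n);
    all values <= cutoff are cases, so ties are included and the
    realized fraction is reported (it can exceed the target only
    through ties).
    """
    mjsw = np.asarray(mjsw, dtype=float)
    if mjsw.size == 0:
        raise ValueError("empty mJSW list")
    if not 0.0 < prevalence_target < 1.0:
        raise ValueError(f"prevalence target must be in (0, 1), got {prevalence_target}")
    n = mjsw.size
    k = int(np.floor(prevalence_target * n))
    if k == 0:
        return DichotomyResult(np.zeros(n, dtype=bool), -np.inf, 0.0)
    cutoff = float(np.sort(mjsw)[k - 1])
    flags = mjsw <= cutoff
    return DichotomyResult(flags, cutoff, float(flags.mean()))


@dataclass
class RaterTable:
    """2x2 agreement table as proportions of 100.

    Rows: first rater (or truth) control|case; columns: second rater
    (or prediction) control|case.
    """

    table: np.ndarray
    n_images: int


def pairwise_confusion(rater_a: np.ndarray, rater_b: np.ndarray) -> RaterTable:
    a = np.asarray(rater_a).astype(int)
    b = np.asarray(rater_b).astype(int)
    if a.shape != b.shape:
        raise ValueError("label vectors differ in length")
    counts = np.zeros((2, 2), dtype=float)
    for i in (0, 1):
        for j in (0, 1):
            counts[i, j] = np.sum((a == i) & (b == j))
    return RaterTable(table=counts * 100.0 / a.size, n_images=a.size)


def average_tables(tables: list) -> RaterTable:
    """Elementwise mean of pairwise tables (still proportions of 100)."""
    stacked = np.stack([t.table for t in tables])
    return RaterTable(table=stacked.mean(axis=0), n_images=int(np.mean([t.n_images for t in tables])))


def sens_spec(truth: np.ndarray, pred: np.ndarray) -> tuple:
    truth = np.asarray(truth).astype(bool)
    pred = np.asarray(pred).astype(bool)
    if truth.shape != pred.shape:
        raise ValueError("label vectors differ in length")
    if not truth.any():
        raise ValueError("no cases in truth labels")
    if truth.all():
        raise ValueError("no controls in truth labels")
    tp = np.sum(truth & pred)
    fn = np.sum(truth & ~pred)
    tn = np.sum(~truth & ~pred)
    fp = np.sum(~truth & pred)
    return float(tp / (tp + fn)), float(tn / (tn + fp))


@dataclass
class CaseComparison:
    n_total: int
    n_ehr_cases: int
    n_model_cases: int
    n_overlap: int
    n_new_cases: int            # model cases absent from the record
    pct_increase: int | None    # rounded to integer; None if no EHR cases


def compare_cases(ehr_flags: np.ndarray, model_flags: np.ndarray) -> CaseComparison:
    ehr = np.asarray(ehr_flags).astype(bool)
    model = np.asarray(model_flags).astype(bool)
    if ehr.shape != model.shape:
        raise ValueError("flag vectors differ in length")
    n_new = int(np.sum(model & ~ehr))
    n_ehr = int(ehr.sum())
    pct = int(round(100.0 * n_new / n_ehr)) if n_ehr > 0 else None
    return CaseComparison(
        n_total=ehr.size,
        n_ehr_cases=n_ehr,
        n_model_cases=int(model.sum()),
        n_overlap=int(np.sum(model & ehr)),
        n_new_cases=n_new,
        pct_increase=pct,
    )


def pain_association(case_flags: np.ndarray, pain_month: np.ndarray,
                     pain_3mo: np.ndarray, pain_rating: np.ndarray) -> dict:
    """Case/control contrasts for the three self-reported pain items.

    Binary items get a plain Pearson chi-square (no continuity
    correction) on the 2x2 table; the 0-10 rating gets a two-sided
    Welch t-test.
    """
    case = np.asarray(case_flags).astype(bool)
    if case.sum() < 2 or (~case).sum() < 2:
        raise ValueError("need at least two cases and two controls")
    out = {}
    for name, flags in (("pain_month", pain_month), ("pain_3mo", pain_3mo)):
        flags = np.asarray(flags).astype(bool)
        table = np.array(
            [
                [np.sum(case & flags), np.sum(case & ~flags)],
                [np.sum(~case & flags), np.sum(~case & ~flags)],
            ]
        )
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        out[name] = {
            "chi2": float(chi2),
            "p": float(p),
            "rate_case": float(flags[case].mean()),
            "rate_control": float(flags[~case].mean()),
        }
    rating = np.asarray(pain_rating, dtype=float)
    t, p = stats.ttest_ind(rating[case], rating[~case], equal_var=False)
    out["pain_rating"] = {
        "t": float(t),
        "p": float(p),
        "mean_case": float(rating[case].mean()),
        "mean_control": float(rating[~case].mean()),
    }
    return out


def chi2_2x2(table: np.ndarray) -> float:
    """Pearson chi-square of a 2x2 table, no continuity correction."""
    chi2, _, _, _ = stats.chi2_contingency(np.asarray(table, dtype=float), correction=False)
    return float(chi2)


@dataclass
class LogisticEffect:
    estimate: float | None
    se: float | None
    p: float | None
    separation_flagged: bool = False


def fracture_model(fracture_flags: np.ndarray, mjsw: np.ndarray,
                   covariates: pd.DataFrame) -> LogisticEffect:
    """Wald test of the mJSW effect on 5-year fracture risk.

    Logistic regression (IRLS maximum likelihood) of fracture on mJSW
    controlling for height, sex, age and body-fat percentage; perfect
    separation is flagged rather than estimated.
    """
    y = np.asarray(fracture_flags).astype(float)
    X = pd.DataFrame(
        {
            "mjsw": np.asarray(mjsw, dtype=float),
            "height": covariates["height"].to_numpy(dtype=float),
            "sex_male": (covariates["sex"].to_numpy() == "M").astype(float),
            "age": covariates["age"].to_numpy(dtype=float),
            "body_fat": covariates["body_fat"].to_numpy(dtype=float),
        }
    )
    X = sm.add_constant(X)
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
        return LogisticEffect(None, None, None, separation_flagged=True)
    se = float(fit.bse["mjsw"])
    if not fit.mle_retvals.get("converged", True) or not np.isfinite(se) or se > 1e3:
        return LogisticEffect(None, None, None, separation_flagged=True)
    return LogisticEffect(float(fit.params["mjsw"]), se, float(fit.pvalues["mjsw"]))
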