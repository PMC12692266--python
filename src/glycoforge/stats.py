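"""Cohort statistics: enzyme-age association, LOSO prediction, peak tests.

Three analyses connect the fitted enzyme concentrations back to subject-level
covariates:

* ordinary-least-squares regression of each fitted enzyme total against age,
  with Bonferroni and Benjamini-Hochberg multiplicity correction across the
  family of six enzymes;
* leave-one-subject-out (LOSO) cross-validated age prediction from a single
  predictor, reporting MSE, RMSE and MAE in years (the squared and root
  scales are both reported explicitly because they are easy to conflate);
* per-peak two-sided Mann-Whitney comparison of experimental and simulated
  cohort peak distributions, BH-adjusted across peaks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AssociationResult",
    "regress_vs_age",
    "associate_enzymes_with_age",
    "CvEntry",
    "loso_age_prediction",
    "loso_report",
    "compare_peak_distributions",
]

EXACT_MW_MAX_N = 20  # exact Mann-Whitney null up to this group size


@dataclass(frozen=True)
class AssociationResult:
    """OLS fit of one predictor against age, with adjusted p-values."""

    predictor: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    p_bonferroni: float = np.nan
    p_bh: float = np.nan
    n: int = 0


def regress_vs_age(values: np.ndarray, ages: np.ndarray,
                   name: str = "") -> AssociationResult:
    """Simple OLS of *values* on age (slope per year, R^2, two-sided p)."""
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if values.shape != ages.shape or values.ndim != 1:
        raise ValueError("values and ages must be equal-length 1-D arrays")
    if len(values) < 3:
        raise ValueError("regression needs at least 3 subjects")
    if np.ptp(values) == 0:
        raise ValueError(f"predictor {name or 'values'} is constant; "
                         "R^2 undefined")
    res = sps.linregress(ages, values)
    return AssociationResult(
        predictor=name, slope=float(res.slope), intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2), p_value=float(res.pvalue),
        n=len(values),
    )


def associate_enzymes_with_age(
    fits: pd.DataFrame,
    predictors: Optional[Sequence[str]] = None,
    age_column: str = "age",
) -> pd.DataFrame:
    """Regress each fitted enzyme total against age and adjust p-values.

    The multiplicity family is the set of predictors tested together
    (default: every non-age numeric column — the six fitted enzymes).
    Returns a DataFrame sorted as given, one row per predictor.
    """
    if predictors is None:
        predictors = [c for c in fits.columns
                      if c != age_column and c != "subject_id"
                      and pd.api.types.is_numeric_dtype(fits[c])]
    ages = fits[age_column].to_numpy(dtype=float)
    rows = [regress_vs_age(fits[p].to_numpy(dtype=float), ages, name=p)
            for p in predictors]
    raw = np.array([r.p_value for r in rows])
    p_bonf = multipletests(raw, method="bonferroni")[1]
    p_bh = multipletests(raw, method="fdr_bh")[1]
    return pd.DataFrame([
        {"predictor": r.predictor, "slope": r.slope, "intercept": r.intercept,
         "r_squared": r.r_squared, "p_value": r.p_value,
         "p_bonferroni": float(pb), "p_bh": float(ph), "n": r.n}
        for r, pb, ph in zip(rows, p_bonf, p_bh)
    ])


@dataclass(frozen=True)
class CvEntry:
    """LOSO age-prediction errors of one predictor (years / years^2)."""

    predictor: str
    mse: float
    rmse: float
    mae: float
    n: int


def loso_age_prediction(values: np.ndarray, ages: np.ndarray,
                        name: str = "") -> CvEntry:
    """Leave-one-subject-out age prediction from a single predictor.

    For each held-out subject, age ~ predictor is fit by OLS on the others
    and the held-out age predicted; errors accumulate over all folds.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(ages, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("values and ages must be equal-length 1-D arrays")
    n = len(x)
    if n < 3:
        raise ValueError("LOSO needs at least 3 subjects")
    errors = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        m = idx != i
        xm, ym = x[m], y[m]
        sxx = np.sum((xm - xm.mean()) ** 2)
        if sxx == 0:
            errors[i] = ym.mean() - y[i]  # constant predictor: intercept-only
            continue
        slope = np.sum((xm - xm.mean()) * (ym - ym.mean())) / sxx
        intercept = ym.mean() - slope * xm.mean()
        errors[i] = intercept + slope * x[i] - y[i]
    mse = float(np.mean(errors ** 2))
    return CvEntry(predictor=name, mse=mse, rmse=float(np.sqrt(mse)),
                   mae=float(np.mean(np.abs(errors))), n=n)


def loso_report(fits: pd.DataFrame,
                predictors: Optional[Sequence[str]] = None,
                age_column: str = "age") -> pd.DataFrame:
    """LOSO errors for every predictor, one row each."""
    if predictors is None:
        predictors = [c for c in fits.columns
                      if c != age_column and c != "subject_id"
                      and pd.api.types.is_numeric_dtype(fits[c])]
    ages = fits[age_column].to_numpy(dtype=float)
    rows = [loso_age_prediction(fits[p].to_numpy(dtype=float), ages, name=p)
            for p in predictors]
    return pd.DataFrame([
        {"predictor": r.predictor, "mse": r.mse, "rmse": r.rmse,
         "mae": r.mae, "n": r.n} for r in rows
    ])


def compare_peak_distributions(
    exp_peaks: pd.DataFrame, sim_peaks: pd.DataFrame,
) -> pd.DataFrame:
    """Two-sided Mann-Whitney test per peak, BH-adjusted across peaks.

    Uses the exact null distribution when both groups have at most 20
    subjects (and no ties), the tie-corrected normal approximation
    otherwise.  An all-tied peak yields p = 1 with a warning.
    """
    import warnings

    common = [c for c in exp_peaks.columns if c in sim_peaks.columns
              and c.startswith("GP")]
    if not common:
        raise ValueError("no shared peak columns between the two cohorts")
    if len(exp_peaks) < 2 or len(sim_peaks) < 2:
        raise ValueError("each cohort needs at least 2 subjects")

    rows = []
    for peak in common:
        a = exp_peaks[peak].to_numpy(dtype=float)
        b = sim_peaks[peak].to_numpy(dtype=float)
        if np.ptp(np.concatenate([a, b])) == 0:
            warnings.warn(f"peak {peak}: all values tied; p set to 1")
            rows.append({"peak": peak, "u_statistic": len(a) * len(b) / 2,
                         "p_value": 1.0})
            continue
        method = ("exact" if len(a) <= EXACT_MW_MAX_N and len(b) <= EXACT_MW_MAX_N
                  and len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
                  else "asymptotic")
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        rows.append({"peak": peak, "u_statistic": float(res.statistic),
                     "p_value": float(res.pvalue)})
    out = pd.DataFrame(rows)
    out["p_bh"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
    return out
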