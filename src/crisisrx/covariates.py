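"""Derivation of the model's explanatory variables from raw monthly records.

Covers the NCEP ATP III metabolic-syndrome rule, the six study age groups,
country-of-birth grouping, cancer coding, visit counts, and the
unemployment-probability score with its quintile assignment (the study's
socio-economic proxy).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "AGE_GROUPS",
    "COUNTRY_GROUPS",
    "CANCER_LEVELS",
    "age_group",
    "derive_metabolic_syndrome",
    "hypercholesterolemia",
    "estimate_unemployment_probability",
    "assign_quintiles",
    "DegenerateQuintileError",
]

#: study age groups; reference category first
AGE_GROUPS = ("15-34", "35-44", "45-54", "55-64", "65-74", "75+")
_AGE_EDGES = np.array([15, 35, 45, 55, 65, 75, np.inf])

#: country-of-birth groups; reference (Spain) first.  "EU" excludes the
#: former Eastern Bloc; "east_europe" includes Romania.
COUNTRY_GROUPS = (
    "spain",
    "eu",
    "east_europe",
    "maghreb",
    "latin_america",
    "subsaharan_africa",
    "india_pakistan",
    "other_asia",
    "other_oecd",
)

#: cancer coding: 0 none (reference), 1 any neoplasm, 2 fear of having cancer
CANCER_LEVELS = ("none", "neoplasm", "fear_of_cancer")


class DegenerateQuintileError(ValueError):
    """All scores identical; quintile cut points are undefined."""


def age_group(age_years) -> np.ndarray:
    """Map age in whole or fractional years to the six study categories.

    Ages are evaluated at the first day of the month.  Ages below 15 (the
    cohort restriction is adults 15+) return the sentinel ``'<15'`` so the
    caller can flag exclusions rather than silently dropping rows.
    """
    age = np.atleast_1d(np.asarray(age_years, dtype=float))
    idx = np.searchsorted(_AGE_EDGES, age, side="right") - 1
    out = np.where(idx < 0, "<15", np.array(AGE_GROUPS + ("75+",), dtype=object)[np.clip(idx, 0, 5)])
    return out if np.ndim(age_years) else out[0]


def derive_metabolic_syndrome(clinical: pd.DataFrame, sex: pd.Series | None = None) -> pd.Series:
    """NCEP ATP III metabolic syndrome: >=3 of five components.

    Components, each a monthly clinical fact (missing counts as absent):

    1. physician-diagnosed hypertension;
    2. physician-diagnosed type-II diabetes OR fasting glucose in the
       elevated band (101, 126] mg/dL;
    3. obesity: BMI > 30 kg/m^2;
    4. hypertriglyceridemia: triglycerides >= 150 mg/dL;
    5. low HDL: < 40 mg/dL (men) / < 50 mg/dL (women).

    ``sex`` (values 'male'/'female') may be a column of ``clinical`` or passed
    separately; it is required whenever an HDL value is present.
    """
    if sex is None:
        if "sex" not in clinical.columns:
            raise ValueError("sex required for the HDL criterion: pass sex= or a 'sex' column")
        sex = clinical["sex"]
    sex = pd.Series(sex, index=clinical.index)

    def col(name):
        if name in clinical.columns:
            return clinical[name]
        return pd.Series(np.nan, index=clinical.index)

    def flag(series):
        return series.astype("boolean").fillna(False).astype(bool)

    htn = flag(col("hypertension_dx"))
    glucose = col("fasting_glucose")
    dm = flag(col("diabetes_dx")) | flag((glucose > 101) & (glucose <= 126))
    obese = flag(col("bmi") > 30)
    tg = flag(col("triglycerides") >= 150)
    hdl = col("hdl")
    if hdl.notna().any() and sex.isna().any():
        bad = clinical.index[hdl.notna() & sex.isna()]
        if len(bad):
            raise ValueError(f"sex missing where HDL present (rows {list(bad[:5])})")
    low_hdl = flag(((hdl < 40) & (sex == "male")) | ((hdl < 50) & (sex == "female")))

    n_missing = int(clinical.reindex(
        columns=["hypertension_dx", "diabetes_dx", "bmi", "fasting_glucose", "triglycerides", "hdl"]
    ).isna().any(axis=1).sum())
    if n_missing:
        logger.debug("metabolic syndrome: %d rows with missing components treated as absent", n_missing)

    count = (
        htn.astype(int) + dm.astype(int) + obese.astype(int) + tg.astype(int) + low_hdl.astype(int)
    )
    return count >= 3


def hypercholesterolemia(total_cholesterol) -> np.ndarray:
    """Total cholesterol >= 200 mg/dL (derived and stored, but *not* a
    metabolic-syndrome component — the five components are exhaustive)."""
    tc = np.asarray(total_cholesterol, dtype=float)
    return np.where(np.isnan(tc), False, tc >= 200)


def estimate_unemployment_probability(
    data: pd.DataFrame,
    labels,
    covariate_cols: list[str],
    coefficients: dict[str, float] | None = None,
) -> pd.Series:
    """Fit (or apply) a logistic model of unemployment and score every row.

    ``labels`` are binary employment outcomes for the training rows (NaN rows
    are scored but not fitted on).  ``coefficients`` lets a fully specified
    external model (intercept + per-column slopes) be injected instead of
    fitting, so a transcription of the study's exact specification can drop in
    without code change.  Deterministic given data.
    """
    X = sm.add_constant(data[covariate_cols].astype(float), has_constant="add")
    if coefficients is not None:
        beta = np.array([coefficients.get("const", 0.0)] + [coefficients[c] for c in covariate_cols])
        eta = X.to_numpy() @ beta
        return pd.Series(1.0 / (1.0 + np.exp(-eta)), index=data.index, name="p_unemployed")
    y = pd.Series(labels, index=data.index).astype(float)
    train = y.notna()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y[train], X[train]).fit(disp=0, maxiter=200)
        if not np.all(np.isfinite(res.bse)):
            raise np.linalg.LinAlgError("non-finite standard errors")
        beta = res.params.to_numpy()
    except Exception:  # separation / non-convergence -> ridge-penalized fit
        logger.warning("unemployment logistic fit unstable; using L2-penalized fallback")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y[train], X[train]).fit_regularized(
                disp=0, alpha=1.0, L1_wt=0.0, maxiter=500
            )
        beta = np.asarray(res.params)
    eta = X.to_numpy() @ beta
    return pd.Series(1.0 / (1.0 + np.exp(-eta)), index=data.index, name="p_unemployed")


def assign_quintiles(scores) -> np.ndarray:
    """Assign pooled empirical quintiles (1..5) to a score vector.

    Cut points are the 20/40/60/80 linear-interpolation percentiles of the
    pooled distribution; a score equal to a cut point goes to the lower
    quintile.
    """
    s = np.asarray(scores, dtype=float)
    if s.size < 5 or np.unique(s[~np.isnan(s)]).size < 5:
        raise DegenerateQuintileError("need >=5 distinct scores to form quintiles")
    cuts = np.nanquantile(s, [0.2, 0.4, 0.6, 0.8])
    if np.unique(cuts).size < 4:
        raise DegenerateQuintileError("degenerate quantile cut points (mass points in scores)")
    return (np.searchsorted(cuts, s, side="left") + 1).astype(int)
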