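"""Multiple imputation of pre-pregnancy BMI category.

BMI enters the analysis as four clinical categories (<18.5, 18.5–<25,
25–<30, >=30) and is missing for a large share of records (~42% in the
motivating cohort).  Missing categories are multiply imputed (default
m = 10) from a multinomial logistic model on maternal age, parity,
insurance and marital status.  Each imputation refits the model on a
bootstrap resample of the complete cases before drawing categories from the
predicted probabilities, so that parameter uncertainty propagates into the
between-imputation variance pooled by Rubin's rules.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from patsy import dmatrix

__all__ = ["BMI_CATEGORIES", "bmi_category", "impute_bmi"]

BMI_CATEGORIES = ("<18.5", "18.5-24.9", "25-29.9", ">=30")

_PREDICTORS = "age_years + C(parity) + C(insurance) + C(marital_status)"


def bmi_category(bmi: float | None) -> str | float:
    """Clinical BMI category; NaN stays missing."""
    if bmi is None or (isinstance(bmi, float) and np.isnan(bmi)):
        return np.nan
    if bmi < 18.5:
        return BMI_CATEGORIES[0]
    if bmi < 25.0:
        return BMI_CATEGORIES[1]
    if bmi < 30.0:
        return BMI_CATEGORIES[2]
    return BMI_CATEGORIES[3]


def impute_bmi(
    records: pd.DataFrame,
    m: int = 10,
    seed: int | np.random.Generator = 0,
) -> list[pd.DataFrame]:
    """Return ``m`` copies of ``records`` with ``bmi_cat`` fully observed.

    Observed categories are never altered.  With no missing values all
    ``m`` datasets equal the input.
    """
    if m < 2:
        raise ValueError("need at least m=2 imputations")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    df = records.copy()
    if "bmi_cat" not in df.columns:
        df["bmi_cat"] = df["bmi"].map(bmi_category)
    missing = df["bmi_cat"].isna().to_numpy()
    if missing.all():
        raise ValueError("all BMI values missing; nothing to fit the imputation model on")
    if not missing.any():
        return [df.copy() for _ in range(m)]

    X_all = np.asarray(dmatrix(_PREDICTORS, df, return_type="dataframe"))
    obs_idx = np.flatnonzero(~missing)
    mis_idx = np.flatnonzero(missing)
    y_obs = pd.Categorical(
        df["bmi_cat"].iloc[obs_idx], categories=list(BMI_CATEGORIES)
    ).codes
    out = []
    for _ in range(m):
        boot = rng.integers(0, len(obs_idx), len(obs_idx))
        rows = obs_idx[boot]
        classes, codes = np.unique(y_obs[boot], return_inverse=True)
        marg = np.bincount(codes, minlength=len(classes)) / len(codes)
        prob = None
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for method in ("newton", "bfgs"):
                try:
                    model = sm.MNLogit(codes, X_all[rows]).fit(
                        disp=0, method=method, maxiter=200
                    )
                    prob = np.asarray(model.predict(X_all[mis_idx]))
                    break
                except np.linalg.LinAlgError:
                    continue
        if prob is None:
            prob = np.tile(marg, (len(mis_idx), 1))
        # quasi-separation in a small bootstrap can overflow the link; fall
        # back to the bootstrap marginal frequencies for affected rows
        bad = ~np.isfinite(prob).all(axis=1)
        if bad.any():
            prob[bad] = marg
        cum = np.cumsum(prob, axis=1)
        cum[:, -1] = 1.0  # guard against rounding
        picks = (rng.random(len(mis_idx))[:, None] > cum).sum(axis=1)
        draws = classes[picks]
        filled = df.copy()
        col = filled["bmi_cat"].copy()
        col.iloc[mis_idx] = np.array(BMI_CATEGORIES, dtype=object)[draws]
        filled["bmi_cat"] = col
        out.append(filled)
    return out
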