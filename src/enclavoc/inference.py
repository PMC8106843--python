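"""Hierarchical inference for GDM risk by joint VOC/enclave exposure.

One model is fitted per VOC per exposure window: a random-intercept
(region-level) logistic regression of GDM on the four joint exposure
categories, adjusted for maternal age, marital status, insurance, BMI
category, parity, season of conception, hospital type and area-level
poverty.  Fits are repeated over the multiply-imputed BMI datasets and
pooled with Rubin's rules; standard errors are cluster-robust on the mother
to account for repeat births.  Benjamini–Hochberg step-up control at
q = 0.10 is applied to the per-window families of contrast p-values.

Two sensitivity analyses mirror the primary model: (1) component models
relating the binary enclave flag and each segregation-measure tertile to
GDM, and (2) a "high multiple VOC" analysis in which PCA on the
window-averaged VOC matrix picks a correlated pollutant block and exposure
is "high on every selected VOC".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from patsy import dmatrix
from scipy import stats

from .joint import JOINT_CATEGORIES, REFERENCE_CATEGORY, joint_category_column
from .mixedlogit import MixedLogitFit, fit_random_intercept_logit

__all__ = [
    "ADJUSTMENT_RHS",
    "ModelResult",
    "FdrDecision",
    "fit_hier_logit",
    "fit_mi_model",
    "pool_rubin",
    "bh_adjust",
    "fit_component_models",
    "high_multiple_voc",
]

#: Covariate adjustment set shared by all models.
ADJUSTMENT_RHS = (
    "age_years + C(marital_status) + C(insurance) + C(bmi_cat) "
    "+ C(parity) + C(season_of_conception) + C(hospital_type) + area_poverty"
)


@dataclass
class ModelResult:
    """Pooled (or single-fit) model summary for one exposure definition."""

    voc_name: str
    window: str
    label: str  # "joint", "enclave", "density", "dissimilarity", "isolation", ...
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame  # columns lo, hi on the log-odds scale
    odds_ratios: pd.DataFrame  # term, n, OR, ci_low, ci_high, p for exposure contrasts
    n_used: int
    n_imputations: int
    converged: bool
    sigma: float


@dataclass(frozen=True)
class FdrDecision:
    label: str
    p: float
    rank: int
    threshold: float
    significant: bool


def _design(
    df: pd.DataFrame, exposure_term: str, rhs: str = ADJUSTMENT_RHS
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    X = dmatrix(f"{exposure_term} + {rhs}", df, return_type="dataframe")
    y = df["gdm"].to_numpy(dtype=float)
    if len(X) != len(df):
        raise ValueError("design dropped rows; missing covariate values present")
    return y, np.asarray(X), list(X.columns)


def _check_exposure(df: pd.DataFrame, column: str, levels: Sequence) -> None:
    counts = df[column].value_counts()
    empty = [lv for lv in levels if counts.get(lv, 0) == 0]
    if empty:
        raise ValueError(f"empty exposure categor{'y' if len(empty)==1 else 'ies'}: {empty}")


def fit_hier_logit(
    df: pd.DataFrame,
    exposure_term: str,
    *,
    rhs: str = ADJUSTMENT_RHS,
    group_col: str = "region_id",
    cluster_col: str = "mother_id",
    n_quad: int = 9,
    start: np.ndarray | None = None,
    start_logsigma: float | None = None,
) -> MixedLogitFit:
    """Single-dataset random-intercept logit with mother-clustered sandwich."""
    if df[group_col].nunique() < 2:
        raise ValueError("need at least 2 regions")
    y, X, names = _design(df, exposure_term, rhs)
    kw = {} if start_logsigma is None else {"start_logsigma": start_logsigma}
    return fit_random_intercept_logit(
        y,
        X,
        df[group_col].to_numpy(),
        df[cluster_col].to_numpy(),
        param_names=names,
        n_quad=n_quad,
        start=start,
        **kw,
    )


def pool_rubin(
    fits: Sequence[MixedLogitFit],
) -> tuple[pd.Series, pd.Series, pd.Series, pd.DataFrame, float]:
    """Rubin's-rules pooling of per-imputation fits.

    Returns pooled coefficients, total SEs, two-sided p-values, 95% CIs on
    the log-odds scale (t reference with the classic Rubin degrees of
    freedom), and the mean random-intercept SD.
    """
    m = len(fits)
    if m < 2:
        raise ValueError("need at least 2 imputation fits to pool")
    names = fits[0].param_names
    for f in fits[1:]:
        if f.param_names != names:
            raise ValueError("imputation fits have mismatched model terms")
    Q = np.stack([f.params for f in fits])  # (m, p)
    U = np.stack([np.diag(f.cov_robust) for f in fits])  # (m, p)
    qbar = Q.mean(axis=0)
    ubar = U.mean(axis=0)
    B = Q.var(axis=0, ddof=1)
    T = ubar + (1.0 + 1.0 / m) * B
    se = np.sqrt(T)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (1.0 + 1.0 / m) * B / ubar
        df_rubin = np.where(B > 0, (m - 1) * (1.0 + 1.0 / np.where(r > 0, r, np.inf)) ** 2, np.inf)
    tstat = qbar / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df_rubin)
    tcrit = stats.t.ppf(0.975, df_rubin)
    ci = pd.DataFrame(
        {"lo": qbar - tcrit * se, "hi": qbar + tcrit * se}, index=names
    )
    sigma = float(np.mean([f.sigma for f in fits]))
    return (
        pd.Series(qbar, index=names),
        pd.Series(se, index=names),
        pd.Series(pvals, index=names),
        ci,
        sigma,
    )


def _single_fit_summary(fit: MixedLogitFit):
    se = fit.bse_robust
    z = fit.params / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    names = fit.param_names
    ci = pd.DataFrame(
        {"lo": fit.params - 1.96 * se, "hi": fit.params + 1.96 * se}, index=names
    )
    return (
        pd.Series(fit.params, index=names),
        pd.Series(se, index=names),
        pd.Series(p, index=names),
        ci,
        fit.sigma,
    )


def _or_table(
    params: pd.Series,
    pvalues: pd.Series,
    ci: pd.DataFrame,
    exposure_terms: Mapping[str, str],
    n_by_level: Mapping[str, int],
) -> pd.DataFrame:
    rows = []
    for term, level in exposure_terms.items():
        rows.append(
            {
                "term": level,
                "n": int(n_by_level.get(level, 0)),
                "OR": float(np.exp(params[term])),
                "ci_low": float(np.exp(ci.loc[term, "lo"])),
                "ci_high": float(np.exp(ci.loc[term, "hi"])),
                "p": float(pvalues[term]),
            }
        )
    return pd.DataFrame(rows)


def fit_mi_model(
    datasets: Sequence[pd.DataFrame],
    exposure_term: str,
    exposure_column: str,
    levels: Sequence,
    reference,
    *,
    voc_name: str = "",
    window: str = "",
    label: str = "joint",
    rhs: str = ADJUSTMENT_RHS,
    group_col: str = "region_id",
    cluster_col: str = "mother_id",
    n_quad: int = 9,
) -> ModelResult:
    """Fit one exposure model across imputed datasets and pool.

    ``exposure_term`` is the patsy term (e.g. a ``C(...)`` treatment
    contrast); ``exposure_column``/``levels``/``reference`` identify the
    underlying categorical so contrast rows can be labelled and counted.
    """
    _check_exposure(datasets[0], exposure_column, levels)
    d0 = datasets[0]
    if d0[group_col].nunique() < 2:
        raise ValueError("need at least 2 regions")
    y, X0, names = _design(d0, exposure_term, rhs)
    groups = d0[group_col].to_numpy()
    clusters = d0[cluster_col].to_numpy()
    # imputed datasets differ only in the BMI fill: swap those dummy columns
    # instead of rebuilding the whole design matrix
    bmi_cols = {
        j: nm.split("[T.", 1)[1][:-1]
        for j, nm in enumerate(names)
        if "bmi_cat" in nm and "[T." in nm
    }
    ref = d0.drop(columns=["bmi_cat"], errors="ignore")
    fits: list[MixedLogitFit] = []
    start, start_ls = None, None
    for d in datasets:
        if d is d0:
            X = X0
        elif bmi_cols and d.drop(columns=["bmi_cat"], errors="ignore").equals(ref):
            X = X0.copy()
            for j, level in bmi_cols.items():
                X[:, j] = (d["bmi_cat"].to_numpy() == level).astype(float)
        else:
            _, X, _ = _design(d, exposure_term, rhs)
        kw = {} if start_ls is None else {"start_logsigma": start_ls}
        fit = fit_random_intercept_logit(
            y,
            X,
            groups,
            clusters,
            param_names=names,
            n_quad=n_quad,
            start=start,
            **kw,
        )
        start, start_ls = fit.params, float(np.log(max(fit.sigma, 1e-8)))
        fits.append(fit)
    if len(fits) == 1:
        params, se, pvals, ci, sigma = _single_fit_summary(fits[0])
    else:
        params, se, pvals, ci, sigma = pool_rubin(fits)

    names = fits[0].param_names
    exposure_terms = {}
    for lv in levels:
        if lv == reference:
            continue
        matches = [t for t in names if exposure_column in t and t.endswith(f"[T.{lv}]")]
        if len(matches) != 1:
            raise ValueError(f"cannot locate contrast column for level {lv!r}")
        exposure_terms[matches[0]] = lv
    n_by_level = datasets[0][exposure_column].value_counts().to_dict()
    return ModelResult(
        voc_name=voc_name,
        window=window,
        label=label,
        params=params,
        bse=se,
        pvalues=pvals,
        conf_int=ci,
        odds_ratios=_or_table(params, pvals, ci, exposure_terms, n_by_level),
        n_used=len(datasets[0]),
        n_imputations=len(fits),
        converged=all(f.converged for f in fits),
        sigma=sigma,
    )


def fit_joint_model(
    datasets: Sequence[pd.DataFrame],
    voc_name: str,
    window: str,
    high_low: Mapping[str, str],
    **kwargs,
) -> ModelResult:
    """Primary per-VOC per-window joint-category model over MI datasets.

    ``high_low`` maps pregnancy_id to 'low'/'high' for this VOC and window;
    the enclave flag must already be present as a boolean ``is_enclave``
    column.
    """
    prepared = []
    for d in datasets:
        d = d.copy()
        lv = d["pregnancy_id"].map(high_low)
        if lv.isna().any():
            raise ValueError("high/low labels missing for some pregnancies")
        d["joint_category"] = joint_category_column(lv, d["is_enclave"])
        prepared.append(d)
    term = f"C(joint_category, Treatment('{REFERENCE_CATEGORY}'))"
    return fit_mi_model(
        prepared,
        term,
        "joint_category",
        JOINT_CATEGORIES,
        REFERENCE_CATEGORY,
        voc_name=voc_name,
        window=window,
        label="joint",
        **kwargs,
    )


def bh_adjust(
    p_values: Mapping[str, float] | pd.Series, q: float = 0.10
) -> list[FdrDecision]:
    """Benjamini–Hochberg step-up decisions at false discovery rate ``q``.

    Rejects every hypothesis whose p-value ranks at or below
    ``max{k : p_(k) <= k q / m}`` on the sorted p-values.
    """
    items = list(p_values.items())
    labels = [k for k, _ in items]
    p = np.array([v for _, v in items], dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    mtot = len(p)
    order = np.argsort(p, kind="stable")
    thresholds = q * (np.arange(1, mtot + 1)) / mtot
    passing = np.flatnonzero(p[order] <= thresholds)
    k_max = passing.max() + 1 if passing.size else 0
    decisions = []
    ranks = np.empty(mtot, dtype=int)
    ranks[order] = np.arange(1, mtot + 1)
    for i, label in enumerate(labels):
        rk = int(ranks[i])
        decisions.append(
            FdrDecision(
                label=label,
                p=float(p[i]),
                rank=rk,
                threshold=float(q * rk / mtot),
                significant=bool(rk <= k_max),
            )
        )
    return decisions


def fit_component_models(
    datasets: Sequence[pd.DataFrame], **kwargs
) -> dict[str, ModelResult]:
    """Enclave and single-component sensitivity models.

    Fits four models — binary enclave residence (non-enclave reference) and
    one per segregation-measure tertile (low reference) — each adjusted for
    the shared covariates plus dichotomised preconception and
    first-trimester benzene.  Requires columns ``is_enclave``,
    ``density_tertile``, ``dissimilarity_tertile``, ``isolation_tertile``,
    ``benzene_preconception`` and ``benzene_first_trimester``.
    """
    rhs = (
        ADJUSTMENT_RHS
        + " + C(benzene_preconception) + C(benzene_first_trimester)"
    )
    results: dict[str, ModelResult] = {}
    results["enclave"] = fit_mi_model(
        datasets,
        "C(is_enclave, Treatment(False))",
        "is_enclave",
        [False, True],
        False,
        label="enclave",
        rhs=rhs,
        **kwargs,
    )
    for label, col in (
        ("density", "density_tertile"),
        ("dissimilarity", "dissimilarity_tertile"),
        ("isolation", "isolation_tertile"),
    ):
        results[label] = fit_mi_model(
            datasets,
            f"C({col}, Treatment('low'))",
            col,
            ["low", "medium", "high"],
            "low",
            label=label,
            rhs=rhs,
            **kwargs,
        )
    return results


def select_voc_block(
    averages_wide: pd.DataFrame, loading_threshold: float = 0.4
) -> tuple[list[str], pd.Series]:
    """VOCs loading heavily on the first principal component.

    ``averages_wide`` is pregnancies × VOCs of window-averaged
    concentrations; columns are standardised before the PCA.  Loadings are
    on the correlation scale (eigenvector scaled by the component's singular
    value), i.e. each VOC's correlation with the first component, so the
    threshold is comparable across block sizes.  The component sign is
    fixed so its mean loading is positive; VOCs at or above the threshold
    form the candidate block.
    """
    Z = averages_wide.to_numpy(dtype=float)
    sd = Z.std(axis=0, ddof=1)
    if np.any(sd == 0):
        const = [c for c, s in zip(averages_wide.columns, sd) if s == 0]
        raise ValueError(f"constant VOC column(s) {const}: cannot standardise for PCA")
    Z = (Z - Z.mean(axis=0)) / sd
    _, svals, vt = np.linalg.svd(Z, full_matrices=False)
    loading = vt[0] * svals[0] / np.sqrt(Z.shape[0] - 1)
    if loading.mean() < 0:
        loading = -loading
    loadings = pd.Series(loading, index=averages_wide.columns)
    selected = list(loadings.index[loadings >= loading_threshold])
    if len(selected) < 2:
        raise ValueError(
            "PCA selected fewer than 2 VOCs; first-component loadings: "
            + ", ".join(f"{k}={v:.3f}" for k, v in loadings.items())
        )
    return selected, loadings


def high_multiple_voc(
    datasets: Sequence[pd.DataFrame],
    averages_wide: pd.DataFrame,
    high_flags: pd.DataFrame,
    window: str,
    *,
    loading_threshold: float = 0.4,
    fit: bool = True,
    **kwargs,
) -> dict:
    """"High multiple VOC" sensitivity analysis for one exposure window.

    ``averages_wide`` and ``high_flags`` are pregnancies × VOCs (means and
    'high'/'low' labels).  A pregnancy is flagged iff it is high on *every*
    PCA-selected VOC; joint categories are rebuilt with
    Not-High/Enclave as reference and the primary model is refitted.
    """
    selected, loadings = select_voc_block(averages_wide, loading_threshold)
    flag = (high_flags[selected] == "high").all(axis=1)
    out = {
        "selected_vocs": selected,
        "loadings": loadings,
        "high_multiple": flag,
        "window": window,
    }
    if not fit:
        return out
    levels = (
        "NotHigh_Enclave",
        "NotHigh_NoEnclave",
        "HighMulti_Enclave",
        "HighMulti_NoEnclave",
    )
    prepared = []
    for d in datasets:
        d = d.copy()
        hm = d["pregnancy_id"].map(flag).to_numpy(dtype=bool)
        enc = d["is_enclave"].to_numpy(dtype=bool)
        part = np.where(hm, "HighMulti", "NotHigh")
        tail = np.where(enc, "_Enclave", "_NoEnclave")
        d["multi_category"] = pd.Categorical(
            np.char.add(part.astype(str), tail.astype(str)), categories=levels
        )
        prepared.append(d)
    out["model"] = fit_mi_model(
        prepared,
        "C(multi_category, Treatment('NotHigh_Enclave'))",
        "multi_category",
        levels,
        "NotHigh_Enclave",
        voc_name="multiple",
        window=window,
        label="high_multiple_voc",
        **kwargs,
    )
    return out
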