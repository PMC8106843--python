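"""Rubin pooling, BH-FDR, sensitivity models and the PCA block selector."""

import itertools

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from enclavoc.inference import (
    bh_adjust,
    fit_component_models,
    fit_joint_model,
    fit_mi_model,
    high_multiple_voc,
    pool_rubin,
    select_voc_block,
)
from enclavoc.mixedlogit import MixedLogitFit


def _fake_fit(params, var, names=None):
    p = len(params)
    names = names or [f"b{i}" for i in range(p)]
    cov = np.diag(np.asarray(var, dtype=float))
    return MixedLogitFit(
        params=np.asarray(params, dtype=float),
        sigma=0.1,
        cov_robust=cov,
        cov_model=cov,
        param_names=names,
        llf=0.0,
        converged=True,
        n_obs=100,
        n_groups=5,
        n_clusters=100,
        eb_modes=np.zeros(5),
    )


# -------------------------------------------------------------- Rubin pooling
def test_pooling_identical_fits_is_identity():
    fits = [_fake_fit([1.0, -0.5], [0.04, 0.09])] * 5
    params, se, pvals, ci, sigma = pool_rubin(fits)
    assert params.to_numpy() == pytest.approx([1.0, -0.5])
    assert se.to_numpy() == pytest.approx([0.2, 0.3])  # between-variance zero


def test_pooling_hand_worked_example():
    # coefs {1, 2}, within-variances {0.1, 0.1}:
    # pooled = 1.5, T = 0.1 + 1.5 * var([1,2]) = 0.1 + 1.5*0.5 = 0.85
    fits = [_fake_fit([1.0], [0.1]), _fake_fit([2.0], [0.1])]
    params, se, *_ = pool_rubin(fits)
    assert params.iloc[0] == pytest.approx(1.5)
    assert se.iloc[0] ** 2 == pytest.approx(0.85)


def test_pooled_se_at_least_mean_within_se():
    rng = np.random.default_rng(0)
    fits = [_fake_fit([rng.normal()], [0.04]) for _ in range(8)]
    _, se, *_ = pool_rubin(fits)
    assert se.iloc[0] >= 0.2


def test_pooling_rejects_mismatched_terms():
    with pytest.raises(ValueError, match="mismatched"):
        pool_rubin([_fake_fit([1.0], [0.1], ["a"]), _fake_fit([1.0], [0.1], ["b"])])


# ------------------------------------------------------------------- BH-FDR
def test_bh_step_up_hand_example():
    decisions = {d.label: d.significant for d in bh_adjust({"a": 0.01, "b": 0.02, "c": 0.2})}
    assert decisions == {"a": True, "b": True, "c": False}


def test_bh_all_ones_none_rejected_all_zeros_all_rejected():
    assert not any(d.significant for d in bh_adjust({f"t{i}": 1.0 for i in range(6)}))
    assert all(d.significant for d in bh_adjust({f"t{i}": 0.0 for i in range(6)}))


def test_bh_invalid_p_rejected():
    with pytest.raises(ValueError):
        bh_adjust({"a": 1.5})


def _bh_bruteforce(p, q):
    """Largest valid rejection set: every p in S is <= |S| q / m."""
    m = len(p)
    best = frozenset()
    for r in range(1, m + 1):
        for S in itertools.combinations(range(m), r):
            if max(p[i] for i in S) <= r * q / m and r > len(best):
                best = frozenset(S)
    return best


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_bh_matches_bruteforce_and_statsmodels(seed):
    rng = np.random.default_rng(seed)
    for _ in range(20):
        m = int(rng.integers(1, 11))
        p = np.round(rng.random(m) ** 2, 3)
        labels = [f"t{i}" for i in range(m)]
        got = {
            int(d.label[1:])
            for d in bh_adjust(dict(zip(labels, p)), q=0.10)
            if d.significant
        }
        assert got == set(_bh_bruteforce(p, 0.10))
        sm_reject = multipletests(p, alpha=0.10, method="fdr_bh")[0]
        assert got == {i for i in range(m) if sm_reject[i]}


# ------------------------------------------------------------ PCA block pick
def _voc_matrix(rng, n, block_rho=0.9, n_block=7, n_free=7):
    L = np.linalg.cholesky(
        block_rho * np.ones((n_block, n_block)) + (1 - block_rho) * np.eye(n_block)
    )
    block = rng.normal(size=(n, n_block)) @ L.T
    free = rng.normal(size=(n, n_free))
    cols = [f"block{i}" for i in range(n_block)] + [f"free{i}" for i in range(n_free)]
    return pd.DataFrame(np.c_[block, free], columns=cols)


def test_perfectly_correlated_vocs_all_selected():
    rng = np.random.default_rng(0)
    base = rng.normal(size=200)
    wide = pd.DataFrame({f"v{i}": base * (i + 1) + i for i in range(5)})
    selected, _ = select_voc_block(wide)
    assert set(selected) == set(wide.columns)


def test_correlated_block_identified(rng):
    wide = _voc_matrix(rng, 400)
    selected, loadings = select_voc_block(wide)
    assert set(selected) == {f"block{i}" for i in range(7)}


def test_too_few_selected_raises_with_diagnostics():
    rng = np.random.default_rng(2)
    wide = pd.DataFrame(rng.normal(size=(300, 8)), columns=[f"v{i}" for i in range(8)])
    with pytest.raises(ValueError, match="loadings"):
        select_voc_block(wide, loading_threshold=0.9)


def test_all_selected_rule_requires_every_voc_high(rng, small_study):
    """A pregnancy high on all but one selected VOC is not flagged."""
    wide = _voc_matrix(rng, 300)
    flags = wide.apply(lambda c: np.where(c >= c.quantile(0.75), "high", "low"))
    out = high_multiple_voc([], wide, flags, "preconception", fit=False)
    sel = out["selected_vocs"]
    flag = out["high_multiple"]
    brute = (flags[sel] == "high").all(axis=1)
    assert (flag == brute).all()
    # specifically: rows high on all but one selected VOC are excluded
    near_miss = (flags[sel] == "high").sum(axis=1) == len(sel) - 1
    assert not flag[near_miss].any()


# -------------------------------------------------- structure of sensitivity
@pytest.fixture(scope="module")
def component_inputs(small_study):
    from enclavoc.exposure import dichotomize_high, window_average_table

    study = small_study
    df = study.cohort.copy()
    # tertiles and benzene flags as the pipeline would attach them
    from enclavoc.enclaves import classify_enclaves
    from enclavoc.segregation import aggregate_to_region, region_profile

    tert = {}
    for period, units in study.regions.units_by_period.items():
        counts = aggregate_to_region(units, study.regions.crosswalk)
        profiles = [
            region_profile(rc, period, study.regions.poverty[rc.region_id])
            for rc in counts
        ]
        for lab in classify_enclaves(profiles):
            tert[(lab.region_id, period)] = lab
    df["is_enclave"] = [
        tert[(r, p)].is_enclave for r, p in zip(df["region_id"], df["period"])
    ]
    df["density_tertile"] = [
        tert[(r, p)].density_tertile for r, p in zip(df["region_id"], df["period"])
    ]
    df["dissimilarity_tertile"] = [
        tert[(r, p)].dissimilarity_tertile
        for r, p in zip(df["region_id"], df["period"])
    ]
    df["isolation_tertile"] = [
        tert[(r, p)].isolation_tertile for r, p in zip(df["region_id"], df["period"])
    ]
    for w in ("preconception", "first_trimester"):
        avg = window_average_table(study.exposure, df, w, vocs=["benzene"])
        lv = dichotomize_high(avg, "benzene", w)
        df[f"benzene_{w}"] = df["pregnancy_id"].map(lv)
    df["bmi_cat"] = df["bmi_cat"].fillna("18.5-24.9")  # complete-case shortcut
    return df


def test_component_models_structure(component_inputs):
    results = fit_component_models([component_inputs])
    assert set(results) == {"enclave", "density", "dissimilarity", "isolation"}
    assert len(results["enclave"].odds_ratios) == 1
    for key in ("density", "dissimilarity", "isolation"):
        assert len(results[key].odds_ratios) == 2
        assert list(results[key].odds_ratios["term"]) == ["medium", "high"]
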