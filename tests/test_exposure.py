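"""Exposure-window bounds, averaging, dichotomisation, rank correlations."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

from enclavoc.exposure import (
    ExposureSeries,
    conception_from_delivery,
    dichotomize_high,
    spearman_voc_matrix,
    window_average,
    window_average_table,
    window_bounds,
)


def daily_series(start, values, region="R1", voc="benzene"):
    ts = np.arange(
        np.datetime64(start, "D"), np.datetime64(start, "D") + len(values)
    ).astype("datetime64[ns]")
    return ExposureSeries(region, voc, ts, np.asarray(values, dtype=float))


# ------------------------------------------------------------------- windows
def test_preconception_window_is_91_days_before_conception():
    assert window_bounds(date(2005, 7, 1), "preconception") == (
        date(2005, 4, 1),
        date(2005, 6, 30),
    )


def test_first_trimester_window_spans_13_weeks():
    assert window_bounds(date(2005, 7, 1), "first_trimester") == (
        date(2005, 7, 1),
        date(2005, 9, 29),
    )


def test_windows_are_adjacent_and_disjoint():
    c = date(2006, 3, 15)
    pre = window_bounds(c, "preconception")
    tri = window_bounds(c, "first_trimester")
    assert pre[1] < tri[0]
    assert (tri[0] - pre[1]).days == 1


def test_unknown_window_rejected():
    with pytest.raises(ValueError, match="unknown exposure window"):
        window_bounds(date(2005, 7, 1), "second_trimester")


def test_conception_backed_out_of_delivery_and_gestation():
    # LMP-based gestation: conception = delivery - gestation + 14 days
    assert conception_from_delivery(date(2005, 10, 1), 280) == date(2005, 1, 8)


# ----------------------------------------------------------------- averaging
def test_constant_series_averages_to_the_constant():
    s = daily_series(date(2005, 1, 1), [2.5] * 120)
    wa = window_average(s, date(2005, 2, 1), date(2005, 3, 1))
    assert wa.mean_ppb == pytest.approx(2.5)
    assert wa.n_points == 29


def test_two_point_mean():
    s = daily_series(date(2005, 1, 1), [1.0, 3.0])
    wa = window_average(s, date(2005, 1, 1), date(2005, 1, 2))
    assert wa.mean_ppb == pytest.approx(2.0)


def test_91_day_ramp_average_closed_form():
    s = daily_series(date(2005, 1, 1), np.arange(1.0, 92.0))
    wa = window_average(s, date(2005, 1, 1), date(2005, 4, 1))
    assert wa.n_points == 91
    assert wa.mean_ppb == pytest.approx(46.0)


def test_no_coverage_errors():
    s = daily_series(date(2005, 1, 1), [1.0] * 10)
    with pytest.raises(ValueError, match="no exposure coverage"):
        window_average(s, date(2006, 1, 1), date(2006, 2, 1))


def test_resolution_invariance_daily_vs_hourly():
    """Equal window means when the underlying step function is unchanged."""
    days = 30
    values = np.linspace(1.0, 3.0, days)
    daily = daily_series(date(2005, 3, 1), values)
    hourly_ts = np.arange(
        np.datetime64("2005-03-01T00", "h"),
        np.datetime64("2005-03-01T00", "h") + 24 * days,
    ).astype("datetime64[ns]")
    hourly = ExposureSeries("R1", "benzene", hourly_ts, np.repeat(values, 24))
    lo, hi = date(2005, 3, 5), date(2005, 3, 20)
    assert window_average(daily, lo, hi).mean_ppb == pytest.approx(
        window_average(hourly, lo, hi).mean_ppb
    )


def test_window_average_table_matches_scalar_path():
    values = np.abs(np.sin(np.arange(400))) + 0.1
    series = {("R1", "benzene"): daily_series(date(2004, 6, 1), values)}
    cohort = pd.DataFrame(
        {
            "pregnancy_id": ["p1", "p2"],
            "region_id": ["R1", "R1"],
            "conception_date": [date(2005, 1, 10), date(2005, 3, 2)],
        }
    )
    table = window_average_table(series, cohort, "preconception", vocs=["benzene"])
    for _, row in table.iterrows():
        c = cohort.set_index("pregnancy_id").loc[row["pregnancy_id"], "conception_date"]
        lo, hi = window_bounds(c, "preconception")
        wa = window_average(series[("R1", "benzene")], lo, hi)
        assert row["mean_ppb"] == pytest.approx(wa.mean_ppb)
        assert row["n_points"] == wa.n_points


# ------------------------------------------------------------ dichotomisation
def frame(values, voc="benzene", window="preconception"):
    return pd.DataFrame(
        {
            "pregnancy_id": [f"p{i}" for i in range(len(values))],
            "voc_name": voc,
            "window": window,
            "mean_ppb": values,
            "n_points": 91,
        }
    )


def test_dichotomize_1_to_100_matches_quantile_oracle():
    values = np.arange(1.0, 101.0)
    labels = dichotomize_high(frame(values), "benzene", "preconception")
    cutoff = np.quantile(values, 0.75)
    highs = {f"p{i}" for i, v in enumerate(values) if v >= cutoff}
    assert {k for k, v in labels.items() if v == "high"} == highs
    assert len(highs) in (25, 26)


def test_identical_averages_are_all_high():
    labels = dichotomize_high(frame([3.0] * 8), "benzene", "preconception")
    assert set(labels.values()) == {"high"}


def test_single_top_value_is_high_at_n4():
    labels = dichotomize_high(frame([1.0, 1.1, 0.9, 7.0]), "benzene", "preconception")
    assert labels["p3"] == "high"


def test_scaling_one_voc_preserves_labels():
    values = np.exp(np.random.default_rng(3).normal(size=60))
    base = dichotomize_high(frame(values), "benzene", "preconception")
    scaled = dichotomize_high(frame(values * 17.3), "benzene", "preconception")
    assert base == scaled


def test_high_group_mean_exceeds_low_group_mean():
    values = np.random.default_rng(4).gamma(2.0, 1.0, 200)
    labels = dichotomize_high(frame(values), "benzene", "preconception")
    high = [values[int(k[1:])] for k, v in labels.items() if v == "high"]
    low = [values[int(k[1:])] for k, v in labels.items() if v == "low"]
    assert np.mean(high) >= np.mean(low)


def test_small_or_empty_stratum_errors():
    with pytest.raises(ValueError):
        dichotomize_high(frame([1.0, 2.0, 3.0]), "benzene", "preconception")
    with pytest.raises(ValueError, match="empty stratum"):
        dichotomize_high(frame([1.0] * 5), "toluene", "preconception")


# ------------------------------------------------------------------ spearman
def test_spearman_self_reversed_and_bruteforce():
    rng = np.random.default_rng(5)
    a = rng.normal(size=40)
    wide = pd.DataFrame({"a": a, "b": -a, "c": rng.normal(size=40)})
    m = spearman_voc_matrix(wide)
    assert m.loc["a", "a"] == pytest.approx(1.0)
    assert m.loc["a", "b"] == pytest.approx(-1.0)
    # 5-observation brute force: rank then Pearson
    x = np.array([3.0, 1.0, 4.0, 1.5, 9.0])
    y = np.array([2.0, 7.0, 1.0, 8.0, 2.5])
    small = spearman_voc_matrix(pd.DataFrame({"x": x, "y": y}))
    rx = pd.Series(x).rank().to_numpy()
    ry = pd.Series(y).rank().to_numpy()
    oracle = np.corrcoef(rx, ry)[0, 1]
    assert small.loc["x", "y"] == pytest.approx(oracle)


def test_constant_voc_flagged_not_zeroed():
    wide = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [5.0] * 4})
    with pytest.warns(UserWarning, match="constant VOC"):
        m = spearman_voc_matrix(wide)
    assert np.isnan(m.loc["a", "b"])
    assert np.isnan(m.loc["b", "b"])
    assert m.loc["a", "a"] == pytest.approx(1.0)
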