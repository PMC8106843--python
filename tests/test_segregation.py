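"""Area-level segregation measures: closed-form examples and invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enclavoc.segregation import (
    AreaUnit,
    RegionCounts,
    aggregate_to_region,
    api_density,
    dissimilarity_index,
    isolation_index,
)

from conftest import make_region


# ---------------------------------------------------------------- aggregation
def test_aggregation_sums_counts_within_region():
    units = [AreaUnit("a", 10, 5, 100), AreaUnit("b", 40, 10, 100)]
    (region,) = aggregate_to_region(units, {"a": "R1", "b": "R1"})
    assert region.api_total == 50
    assert region.white_total == 15
    assert region.pop_total == 200
    assert region.n_units == 2


def test_aggregation_of_nothing_is_empty():
    assert aggregate_to_region([], {"a": "R1"}) == []


def test_aggregation_matches_groupby_oracle(rng):
    units = [
        AreaUnit(f"u{i}", int(a), int(w), int(a + w + extra))
        for i, (a, w, extra) in enumerate(
            zip(
                rng.integers(0, 50, 30),
                rng.integers(0, 50, 30),
                rng.integers(0, 100, 30),
            )
        )
    ]
    crosswalk = {u.unit_id: f"R{i % 3}" for i, u in enumerate(units)}
    regions = {r.region_id: r for r in aggregate_to_region(units, crosswalk)}
    oracle = (
        pd.DataFrame(
            {
                "region": [crosswalk[u.unit_id] for u in units],
                "api": [u.api_count for u in units],
                "white": [u.white_count for u in units],
                "pop": [u.total_pop for u in units],
            }
        )
        .groupby("region")
        .sum()
    )
    for rid, row in oracle.iterrows():
        assert regions[rid].api_total == row["api"]
        assert regions[rid].white_total == row["white"]
        assert regions[rid].pop_total == row["pop"]


def test_aggregation_rejects_unknown_and_duplicate_units():
    with pytest.raises(ValueError, match="missing from crosswalk"):
        aggregate_to_region([AreaUnit("zz", 1, 1, 10)], {"a": "R1"})
    units = [AreaUnit("a", 1, 1, 10), AreaUnit("a", 2, 2, 10)]
    with pytest.raises(ValueError, match="duplicate"):
        aggregate_to_region(units, {"a": "R1"})


def test_unit_count_invariants_enforced():
    with pytest.raises(ValueError, match="exceeds total_pop"):
        AreaUnit("u", 11, 0, 10)
    with pytest.raises(ValueError, match="negative"):
        AreaUnit("u", -1, 0, 10)


# ------------------------------------------------------------------- density
@pytest.mark.parametrize(
    "counts, expected",
    [
        ([(25, 10, 100)], 25.0),
        ([(100, 0, 100), (50, 0, 50)], 100.0),  # all-API region hits the maximum
        ([(10, 5, 100), (40, 5, 100)], 25.0),
    ],
)
def test_api_density_examples(counts, expected):
    assert api_density(make_region(counts)) == pytest.approx(expected)


def test_api_density_empty_region_errors():
    with pytest.raises(ValueError, match="empty region"):
        api_density(make_region([(0, 0, 0)]))


# ------------------------------------------------------------- dissimilarity
@pytest.mark.parametrize(
    "counts, expected",
    [
        ([(0, 100, 100), (100, 0, 100)], 1.0),  # complete separation
        ([(50, 50, 100), (50, 50, 100)], 0.0),  # identical distributions
        ([(20, 80, 100), (80, 20, 100)], 0.6),  # hand: 0.5*(|.8-.2|+|.2-.8|)
    ],
)
def test_dissimilarity_examples(counts, expected):
    assert dissimilarity_index(make_region(counts)) == pytest.approx(expected)


def test_dissimilarity_undefined_for_empty_group():
    with pytest.raises(ValueError, match="empty group"):
        dissimilarity_index(make_region([(0, 10, 100), (0, 20, 100)]))


# ----------------------------------------------------------------- isolation
@pytest.mark.parametrize(
    "counts, expected",
    [
        ([(20, 10, 100)], 0.20),  # (20/20)*(20/100)
        ([(100, 0, 100), (30, 0, 30)], 1.0),  # entirely API units
        ([(20, 10, 100), (80, 10, 100)], 0.68),  # 0.2*0.2 + 0.8*0.8
    ],
)
def test_isolation_examples(counts, expected):
    assert isolation_index(make_region(counts)) == pytest.approx(expected)


def test_isolation_strict_printed_variant_uses_region_total():
    region = make_region([(20, 10, 100), (80, 10, 100)])
    # (20/100)*(20/200) + (80/100)*(80/200)
    assert isolation_index(region, region_denominator=True) == pytest.approx(0.34)


def test_isolation_errors():
    with pytest.raises(ValueError, match="empty group"):
        isolation_index(make_region([(0, 10, 100)]))
    # API residents in a zero-population unit are rejected at construction
    with pytest.raises(ValueError):
        AreaUnit("a", 5, 0, 0)


# ---------------------------------------------------------------- properties
counts_strategy = st.lists(
    st.tuples(
        st.integers(1, 500),  # api
        st.integers(1, 500),  # white
        st.integers(0, 500),  # extra (non-API non-White)
    ),
    min_size=1,
    max_size=12,
)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(counts_strategy)
def test_indices_bounded(triples):
    region = make_region([(a, w, a + w + e) for a, w, e in triples])
    assert 0.0 <= dissimilarity_index(region) <= 1.0 + 1e-12
    assert 0.0 <= isolation_index(region) <= 1.0 + 1e-12
    assert 0.0 <= api_density(region) <= 100.0 + 1e-12


@settings(max_examples=100, deadline=None, derandomize=True)
@given(counts_strategy, st.integers(2, 7))
def test_scale_invariance(triples, k):
    base = make_region([(a, w, a + w + e) for a, w, e in triples])
    scaled = make_region([(k * a, k * w, k * (a + w + e)) for a, w, e in triples])
    assert api_density(scaled) == pytest.approx(api_density(base))
    assert dissimilarity_index(scaled) == pytest.approx(dissimilarity_index(base))
    assert isolation_index(scaled) == pytest.approx(isolation_index(base))


@settings(max_examples=200, deadline=None, derandomize=True)
@given(counts_strategy)
def test_isolation_at_least_overall_share(triples):
    """Cauchy–Schwarz: isolation >= A_T/P_T, equality at even API spread."""
    region = make_region([(a, w, a + w + e) for a, w, e in triples])
    assert isolation_index(region) >= region.api_total / region.pop_total - 1e-12


def test_isolation_equality_under_proportional_spread():
    # a_i/A_T = P_i/P_T for all units -> isolation equals the overall share
    region = make_region([(10, 20, 100), (20, 40, 200), (40, 10, 400)])
    assert isolation_index(region) == pytest.approx(
        region.api_total / region.pop_total
    )


@settings(max_examples=100, deadline=None, derandomize=True)
@given(counts_strategy)
def test_dissimilarity_order_and_split_invariance(triples):
    counts = [(a, w, a + w + e) for a, w, e in triples]
    base = make_region(counts)
    shuffled = make_region(counts[::-1])
    assert dissimilarity_index(shuffled) == pytest.approx(dissimilarity_index(base))
    # splitting the first unit into two proportional halves changes nothing
    a, w, p = counts[0]
    if a % 2 == 0 and w % 2 == 0 and p % 2 == 0:
        split = [(a // 2, w // 2, p // 2)] * 2 + counts[1:]
        assert dissimilarity_index(make_region(split)) == pytest.approx(
            dissimilarity_index(base)
        )
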