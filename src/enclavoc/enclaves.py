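"""Ethnic-enclave classification from region segregation profiles.

A region is an ethnic enclave when it sits in the top tertile of all three
region-level measures simultaneously: API population density, API–White
dissimilarity, and API isolation.  Tertile cutpoints are the 33.333rd and
66.667th percentiles of the region-level distribution within one census
period (linear-interpolation sample quantiles); a value equal to a cutpoint
falls in the upper of the two adjacent tertiles (the ">= 66th percentile"
rule).

Cutpoints may optionally be population-weighted (each region weighted by
its residents rather than counting once); the default weights regions
equally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .segregation import RegionProfile

__all__ = ["EnclaveLabel", "tertile_cutpoints", "assign_tertile", "classify_enclaves"]

MEASURES = ("api_density", "dissimilarity", "isolation")


@dataclass(frozen=True)
class EnclaveLabel:
    region_id: str
    period: str
    density_tertile: str
    dissimilarity_tertile: str
    isolation_tertile: str
    is_enclave: bool


def tertile_cutpoints(
    values: Sequence[float], weights: Sequence[float] | None = None
) -> tuple[float, float]:
    """Return the (33.333rd, 66.667th) percentile cutpoints.

    Unweighted cutpoints use the linear-interpolation sample quantile.  With
    ``weights`` the cutpoints are weighted quantiles (inverse of the
    normalised cumulative weight, linearly interpolated between order
    statistics).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError(f"need at least 3 values to form tertiles, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite value in tertile input")
    probs = np.array([1.0, 2.0]) / 3.0
    if weights is None:
        lo, hi = np.quantile(x, probs, method="linear")
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != x.shape or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be nonnegative, same length, not all zero")
        order = np.argsort(x, kind="stable")
        xs, ws = x[order], w[order]
        # interpolation positions as in the weighted analogue of the
        # linear-interpolation quantile: midpoint-free cumulative shares
        cw = np.cumsum(ws) - 0.5 * ws
        cw /= ws.sum()
        lo, hi = np.interp(probs, cw, xs)
    return float(lo), float(hi)


def assign_tertile(value: float, cutpoints: tuple[float, float]) -> str:
    """Place a value into low / medium / high, ties going upward."""
    lower, upper = cutpoints
    if value >= upper:
        return "high"
    if value >= lower:
        return "medium"
    return "low"


def classify_enclaves(
    profiles: Sequence[RegionProfile], weights: Sequence[float] | None = None
) -> list[EnclaveLabel]:
    """Label each region's tertiles and enclave status within one period.

    All profiles must share a single census period: cutpoints are only
    meaningful within one period's distribution.
    """
    if not profiles:
        return []
    periods = {p.period for p in profiles}
    if len(periods) > 1:
        raise ValueError(f"profiles span multiple periods: {sorted(periods)}")
    cuts = {
        m: tertile_cutpoints([getattr(p, m) for p in profiles], weights)
        for m in MEASURES
    }
    labels = []
    for p in profiles:
        terts = {m: assign_tertile(getattr(p, m), cuts[m]) for m in MEASURES}
        labels.append(
            EnclaveLabel(
                region_id=p.region_id,
                period=p.period,
                density_tertile=terts["api_density"],
                dissimilarity_tertile=terts["dissimilarity"],
                isolation_tertile=terts["isolation"],
                is_enclave=all(t == "high" for t in terts.values()),
            )
        )
    return labels
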