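"""Area-level residential segregation measures.

Small-area (ZCTA-like) race/ethnicity counts are aggregated to regions
(HRR-like catchment areas) and summarised by three measures used to
characterise ethnic enclaves:

* **API population density** — percent of the region's residents who are
  Asian/Pacific Islander, ``(A_T / P_T) * 100``.
* **Dissimilarity index** — ``0.5 * sum_i |w_i/W_T - a_i/A_T|``, the share
  of either group that would have to relocate for the two groups to be
  evenly distributed across the region's area units.  Range 0–1.
* **Isolation index** — ``sum_i (a_i/A_T) * (a_i/P_i)``, the probability
  that a randomly chosen within-unit contact of an API resident is also
  API.  Range ``A_T/P_T``–1.

Only the API and White groups enter the two-group indices; residents of
other groups count toward unit populations but toward neither group total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "AreaUnit",
    "RegionCounts",
    "RegionProfile",
    "aggregate_to_region",
    "api_density",
    "dissimilarity_index",
    "isolation_index",
    "region_profile",
]


@dataclass(frozen=True)
class AreaUnit:
    """One small-area record of API / White / total person counts."""

    unit_id: str
    api_count: int
    white_count: int
    total_pop: int

    def __post_init__(self) -> None:
        if self.total_pop < 0:
            raise ValueError(f"unit {self.unit_id!r}: negative total_pop")
        for name in ("api_count", "white_count"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"unit {self.unit_id!r}: negative {name}")
            if v > self.total_pop:
                raise ValueError(
                    f"unit {self.unit_id!r}: {name}={v} exceeds total_pop={self.total_pop}"
                )


@dataclass(frozen=True)
class RegionCounts:
    """A region's area units together with their exact integer totals."""

    region_id: str
    units: tuple[AreaUnit, ...]
    api_total: int = field(init=False)
    white_total: int = field(init=False)
    pop_total: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.units:
            raise ValueError(f"region {self.region_id!r} has no units")
        object.__setattr__(self, "api_total", sum(u.api_count for u in self.units))
        object.__setattr__(self, "white_total", sum(u.white_count for u in self.units))
        object.__setattr__(self, "pop_total", sum(u.total_pop for u in self.units))

    @property
    def n_units(self) -> int:
        return len(self.units)


@dataclass(frozen=True)
class RegionProfile:
    """Per-region segregation measures for one census period."""

    region_id: str
    period: str
    api_density: float  # percent, [0, 100]
    dissimilarity: float  # fraction, [0, 1]
    isolation: float  # fraction, [0, 1]
    poverty_rate: float  # fraction, [0, 1]


def aggregate_to_region(
    units: Iterable[AreaUnit], crosswalk: Mapping[str, str]
) -> list[RegionCounts]:
    """Group area units into regions via a unit→region crosswalk.

    Regions appear in order of first appearance among ``units``; unit order
    is preserved within each region.  A unit missing from the crosswalk, or
    appearing twice, raises ``ValueError`` naming the unit.
    """
    seen: set[str] = set()
    grouped: dict[str, list[AreaUnit]] = {}
    for u in units:
        if u.unit_id in seen:
            raise ValueError(f"duplicate unit_id {u.unit_id!r}")
        seen.add(u.unit_id)
        try:
            region = crosswalk[u.unit_id]
        except KeyError:
            raise ValueError(f"unit_id {u.unit_id!r} missing from crosswalk") from None
        grouped.setdefault(region, []).append(u)
    return [RegionCounts(region_id=r, units=tuple(us)) for r, us in grouped.items()]


def api_density(region: RegionCounts) -> float:
    """Percent API residents, ``(A_T / P_T) * 100``."""
    if region.pop_total <= 0:
        raise ValueError(f"empty region {region.region_id!r}")
    return 100.0 * region.api_total / region.pop_total


def dissimilarity_index(region: RegionCounts) -> float:
    """API–White dissimilarity, ``0.5 * sum_i |w_i/W_T - a_i/A_T|``."""
    if region.api_total == 0 or region.white_total == 0:
        raise ValueError(
            f"region {region.region_id!r}: index undefined for empty group"
        )
    a_t, w_t = region.api_total, region.white_total
    return 0.5 * sum(
        abs(u.white_count / w_t - u.api_count / a_t) for u in region.units
    )


def isolation_index(region: RegionCounts, *, region_denominator: bool = False) -> float:
    """API isolation, ``sum_i (a_i/A_T) * (a_i/P_i)``.

    The second factor uses the unit population ``P_i`` (the standard
    interaction-probability form, bounded by 1).  ``region_denominator=True``
    substitutes the region total ``P_T``, a variant occasionally printed in
    summary tables; for multi-unit regions that variant cannot reach 1.
    """
    a_t = region.api_total
    if a_t == 0:
        raise ValueError(f"region {region.region_id!r}: index undefined for empty group")
    if region_denominator:
        return sum((u.api_count / a_t) * (u.api_count / region.pop_total) for u in region.units)
    total = 0.0
    for u in region.units:
        if u.api_count == 0:
            continue
        if u.total_pop == 0:
            raise ValueError(
                f"region {region.region_id!r}: unit {u.unit_id!r} has API residents "
                "but zero population"
            )
        total += (u.api_count / a_t) * (u.api_count / u.total_pop)
    return total


def region_profile(
    region: RegionCounts,
    period: str,
    poverty_rate: float,
    *,
    region_denominator: bool = False,
) -> RegionProfile:
    """Bundle the three measures for one region and census period."""
    return RegionProfile(
        region_id=region.region_id,
        period=period,
        api_density=api_density(region),
        dissimilarity=dissimilarity_index(region),
        isolation=isolation_index(region, region_denominator=region_denominator),
        poverty_rate=poverty_rate,
    )
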