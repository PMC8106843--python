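"""Joint VOC × enclave exposure categories and descriptive tabulations."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from math import exp, log, sqrt

import numpy as np
import pandas as pd

__all__ = [
    "JOINT_CATEGORIES",
    "REFERENCE_CATEGORY",
    "assign_joint_category",
    "joint_category_column",
    "tabulate_outcome",
    "crude_or",
    "percent_1dp",
]

#: Category order; the anticipated lowest-risk category is the reference.
JOINT_CATEGORIES = (
    "LowVOC_Enclave",
    "LowVOC_NoEnclave",
    "HighVOC_Enclave",
    "HighVOC_NoEnclave",
)
REFERENCE_CATEGORY = "LowVOC_Enclave"


def assign_joint_category(level: str, is_enclave: bool) -> str:
    """Map a (high/low VOC level, enclave flag) pair to its joint category."""
    if level not in ("low", "high"):
        raise ValueError(f"VOC level must be 'low' or 'high', got {level!r}")
    part = "LowVOC" if level == "low" else "HighVOC"
    return f"{part}_Enclave" if is_enclave else f"{part}_NoEnclave"


def joint_category_column(levels: pd.Series, enclave: pd.Series) -> pd.Series:
    """Vectorised :func:`assign_joint_category` over aligned Series."""
    bad = ~levels.isin(["low", "high"])
    if bad.any():
        raise ValueError(f"invalid VOC level(s): {sorted(levels[bad].unique())}")
    part = np.where(levels.to_numpy() == "low", "LowVOC", "HighVOC")
    tail = np.where(enclave.to_numpy(dtype=bool), "_Enclave", "_NoEnclave")
    out = pd.Series(
        pd.Categorical(
            np.char.add(part.astype(str), tail.astype(str)),
            categories=JOINT_CATEGORIES,
        ),
        index=levels.index,
        name="joint_category",
    )
    return out


def percent_1dp(numerator: int, denominator: int) -> float:
    """Percent to one decimal, half-up rounding (table convention)."""
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def tabulate_outcome(
    records: pd.DataFrame, grouping: list[str] | str, outcome: str = "gdm"
) -> pd.DataFrame:
    """Per-stratum n, outcome count and percent (one decimal, half-up).

    Empty strata (possible with categorical groupers) are reported with
    ``n=0`` and a missing percent.
    """
    if isinstance(grouping, str):
        grouping = [grouping]
    y = records[outcome]
    if not set(pd.unique(y.dropna())) <= {0, 1, True, False}:
        raise ValueError(f"outcome {outcome!r} must be binary")
    g = records.groupby(grouping, observed=False, dropna=False)
    out = g[outcome].agg(n="size", n_outcome="sum").reset_index()
    out["n_outcome"] = out["n_outcome"].astype(int)
    out["percent_outcome"] = [
        percent_1dp(k, n) if n > 0 else np.nan
        for k, n in zip(out["n_outcome"], out["n"])
    ]
    return out


def crude_or(a: int, b: int, c: int, d: int) -> tuple[float, tuple[float, float]]:
    """Unadjusted odds ratio and 95% Wald CI from a 2×2 table.

    Cells are (a = exposed cases, b = exposed non-cases, c = unexposed
    cases, d = unexposed non-cases).  Zero cells raise rather than applying
    a silent continuity correction.
    """
    cells = (a, b, c, d)
    if any(x <= 0 for x in cells):
        raise ValueError(f"2x2 table has an empty cell: {cells}")
    or_ = (a * d) / (b * c)
    se = sqrt(sum(1.0 / x for x in cells))
    lo, hi = exp(log(or_) - 1.96 * se), exp(log(or_) + 1.96 * se)
    return or_, (lo, hi)
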