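"""Pregnancy exposure windows over ambient VOC concentration series.

Each region carries a time-resolved concentration series (ppb) for each of
14 volatile organic compounds.  For every pregnancy the series is averaged
over two clinically defined windows anchored at the conception date:

* **preconception** — the 91 days ending the day before conception;
* **first_trimester** — conception through 13 gestational weeks (91 days).

Window averages are dichotomised at the 75th percentile of the analytic
sample, separately for each (VOC, window) stratum: values at or above the
cutoff are "high", the rest "low".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VOC_NAMES",
    "BLOCK_VOCS",
    "WINDOWS",
    "ExposureSeries",
    "WindowAverage",
    "window_bounds",
    "conception_from_delivery",
    "window_average",
    "window_average_table",
    "dichotomize_high",
    "spearman_voc_matrix",
]

#: The 14 modelled VOC species.
VOC_NAMES = (
    "benzene",
    "1,3-butadiene",
    "ethylbenzene",
    "cyclohexane",
    "methyl-tertiary-butyl ether",
    "n-hexane",
    "ethyl-methyl ketone",
    "m-xylene",
    "o-xylene",
    "p-xylene",
    "propene",
    "sesquiterpene",
    "styrene",
    "toluene",
)

#: Traffic/fuel-related VOCs that co-vary strongly in ambient air.
BLOCK_VOCS = (
    "benzene",
    "ethylbenzene",
    "toluene",
    "m-xylene",
    "o-xylene",
    "p-xylene",
    "n-hexane",
)

WINDOWS = ("preconception", "first_trimester")

PRECONCEPTION_DAYS = 91
TRIMESTER_DAYS = 91


@dataclass(frozen=True)
class ExposureSeries:
    """One region's concentration series for one VOC.

    ``timestamps`` must be strictly increasing; daily or hourly resolution
    both work (points are equally weighted within a window).
    """

    region_id: str
    voc_name: str
    timestamps: np.ndarray  # datetime64[ns], strictly increasing
    concentrations: np.ndarray  # ppb, nonnegative finite

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype="datetime64[ns]")
        c = np.asarray(self.concentrations, dtype=float)
        if ts.shape != c.shape or ts.ndim != 1:
            raise ValueError("timestamps and concentrations must be equal-length 1-d")
        if ts.size == 0:
            raise ValueError("empty exposure series")
        if np.any(np.diff(ts).astype("int64") <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(c)) or np.any(c < 0):
            raise ValueError("concentrations must be nonnegative and finite")
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "concentrations", c)


@dataclass(frozen=True)
class WindowAverage:
    pregnancy_id: str
    voc_name: str
    window: str
    mean_ppb: float
    n_points: int


def window_bounds(
    conception_date: date,
    window: str,
    *,
    preconception_days: int = PRECONCEPTION_DAYS,
    trimester_days: int = TRIMESTER_DAYS,
) -> tuple[date, date]:
    """Closed [start, end] date bounds of an exposure window."""
    if window == "preconception":
        return (
            conception_date - timedelta(days=preconception_days),
            conception_date - timedelta(days=1),
        )
    if window == "first_trimester":
        return conception_date, conception_date + timedelta(days=trimester_days - 1)
    raise ValueError(f"unknown exposure window {window!r}")


def conception_from_delivery(delivery_date: date, gestation_days: int) -> date:
    """Conception date from delivery date and LMP-based gestational length.

    Conception is taken as two weeks after the last menstrual period, i.e.
    ``delivery - gestation_days + 14``.
    """
    return delivery_date - timedelta(days=gestation_days - 14)


def _window_mask(ts: np.ndarray, start: date, end: date) -> np.ndarray:
    lo = np.datetime64(start, "ns")
    hi = np.datetime64(end + timedelta(days=1), "ns")  # whole end day included
    return (ts >= lo) & (ts < hi)


def window_average(
    series: ExposureSeries,
    start: date,
    end: date,
    *,
    pregnancy_id: str = "",
    window: str = "",
) -> WindowAverage:
    """Arithmetic mean of concentrations with timestamps in [start, end]."""
    mask = _window_mask(series.timestamps, start, end)
    n = int(mask.sum())
    if n == 0:
        raise ValueError(
            f"no exposure coverage for {series.voc_name!r} in region "
            f"{series.region_id!r} over [{start}, {end}]"
        )
    return WindowAverage(
        pregnancy_id=pregnancy_id,
        voc_name=series.voc_name,
        window=window,
        mean_ppb=float(series.concentrations[mask].mean()),
        n_points=n,
    )


def window_average_table(
    series_map: Mapping[tuple[str, str], ExposureSeries],
    cohort: pd.DataFrame,
    window: str,
    vocs: Sequence[str] = VOC_NAMES,
) -> pd.DataFrame:
    """Window averages for every pregnancy × VOC, vectorised via prefix sums.

    ``cohort`` needs columns ``pregnancy_id``, ``region_id`` and
    ``conception_date``.  Returns a long DataFrame with columns
    ``pregnancy_id, voc_name, window, mean_ppb, n_points``.
    """
    conception = pd.to_datetime(cohort["conception_date"])
    if window == "preconception":
        start = conception - pd.Timedelta(days=PRECONCEPTION_DAYS)
        end = conception - pd.Timedelta(days=1)
    elif window == "first_trimester":
        start = conception
        end = conception + pd.Timedelta(days=TRIMESTER_DAYS - 1)
    else:
        raise ValueError(f"unknown exposure window {window!r}")
    end_excl = (end + pd.Timedelta(days=1)).to_numpy()
    start = start.to_numpy()

    frames = []
    for region_id, idx in cohort.groupby("region_id", sort=False).indices.items():
        for voc in vocs:
            try:
                series = series_map[(region_id, voc)]
            except KeyError:
                raise ValueError(
                    f"no exposure series for region {region_id!r}, VOC {voc!r}"
                ) from None
            ts = series.timestamps
            csum = np.concatenate([[0.0], np.cumsum(series.concentrations)])
            i0 = np.searchsorted(ts, start[idx], side="left")
            i1 = np.searchsorted(ts, end_excl[idx], side="left")
            n = i1 - i0
            if np.any(n <= 0):
                bad = cohort.iloc[idx[np.argmax(n <= 0)]]
                raise ValueError(
                    f"no exposure coverage for pregnancy {bad['pregnancy_id']!r} "
                    f"({voc}, {window})"
                )
            frames.append(
                pd.DataFrame(
                    {
                        "pregnancy_id": cohort["pregnancy_id"].to_numpy()[idx],
                        "voc_name": voc,
                        "window": window,
                        "mean_ppb": (csum[i1] - csum[i0]) / n,
                        "n_points": n,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def dichotomize_high(
    averages: Iterable[WindowAverage] | pd.DataFrame,
    voc_name: str,
    window: str,
    *,
    percentile: float = 75.0,
) -> dict[str, str]:
    """High/low labels at the stratum's 75th percentile (>= cutoff is high).

    The cutoff is the linear-interpolation percentile of ``mean_ppb`` over
    the analytic sample within the (VOC, window) stratum.
    """
    if isinstance(averages, pd.DataFrame):
        df = averages
    else:
        df = pd.DataFrame([a.__dict__ for a in averages])
    sub = df[(df["voc_name"] == voc_name) & (df["window"] == window)]
    if len(sub) == 0:
        raise ValueError(f"empty stratum ({voc_name!r}, {window!r})")
    if len(sub) < 4:
        raise ValueError(
            f"need at least 4 window averages to dichotomize ({voc_name!r}, {window!r})"
        )
    vals = sub["mean_ppb"].to_numpy(dtype=float)
    cutoff = float(np.quantile(vals, percentile / 100.0, method="linear"))
    labels = np.where(vals >= cutoff, "high", "low")
    return dict(zip(sub["pregnancy_id"], labels))


def spearman_voc_matrix(wide: pd.DataFrame) -> pd.DataFrame:
    """Spearman rank correlations among VOC window averages.

    ``wide`` is pregnancies × VOCs.  Entries involving a constant VOC are
    NaN (undefined) and trigger a warning rather than a silent zero.
    """
    cols = list(wide.columns)
    constant = [c for c in cols if wide[c].nunique() <= 1]
    if constant:
        warnings.warn(
            f"constant VOC column(s) {constant}: Spearman undefined, entries set NaN",
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns on constant input
        rho = stats.spearmanr(wide.to_numpy(), axis=0).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-column case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    out = pd.DataFrame(rho, index=cols, columns=cols)
    for c in cols:
        out.loc[c, c] = np.nan if c in constant else 1.0
        if c in constant:
            out.loc[c, :] = np.nan
            out.loc[:, c] = np.nan
    return out
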