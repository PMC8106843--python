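"""CSV readers and writers for the pipeline's typed inputs and reports.

Conventions: header row required; dates ISO-8601; missing values written as
empty fields; floats at 10 significant digits so a rewritten file is
byte-identical for identical values.  Readers validate invariants at load
and report the offending row number (1-based, excluding the header).
"""

from __future__ import annotations

import csv
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .enclaves import EnclaveLabel
from .exposure import ExposureSeries
from .segregation import AreaUnit, RegionProfile

__all__ = [
    "read_units",
    "read_crosswalk",
    "read_cohort",
    "read_exposure",
    "write_units",
    "write_crosswalk",
    "write_cohort",
    "write_exposure",
    "write_profiles",
    "write_labels",
    "write_frame",
]

FLOAT_FMT = "%.10g"

UNITS_HEADER = ["period", "unit_id", "api_count", "white_count", "total_pop"]
COHORT_COLUMNS = [
    "mother_id",
    "pregnancy_id",
    "region_id",
    "conception_date",
    "delivery_date",
    "gestation_days",
    "gdm",
    "age_years",
    "marital_status",
    "insurance",
    "bmi",
    "parity",
    "season_of_conception",
    "hospital_type",
    "area_poverty",
]
EXPOSURE_HEADER = ["region_id", "voc_name", "timestamp", "ppb"]


def _check_header(path: Path, got: Sequence[str], want: Sequence[str]) -> None:
    if list(got) != list(want):
        raise ValueError(f"{path}: expected header {want}, got {list(got)}")


def read_units(path: str | Path) -> dict[str, list[AreaUnit]]:
    """Per-period area-unit count tables."""
    path = Path(path)
    out: dict[str, list[AreaUnit]] = {}
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        _check_header(path, next(reader), UNITS_HEADER)
        for i, row in enumerate(reader, start=1):
            try:
                period, uid = row[0], row[1]
                unit = AreaUnit(uid, int(row[2]), int(row[3]), int(row[4]))
            except (ValueError, IndexError) as e:
                raise ValueError(f"{path}, row {i}: {e}") from None
            out.setdefault(period, []).append(unit)
    return out


def read_crosswalk(path: str | Path) -> dict[str, str]:
    path = Path(path)
    out: dict[str, str] = {}
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        _check_header(path, next(reader), ["unit_id", "region_id"])
        for i, row in enumerate(reader, start=1):
            if row[0] in out:
                raise ValueError(f"{path}, row {i}: duplicate unit_id {row[0]!r}")
            out[row[0]] = row[1]
    return out


def read_cohort(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, dtype={"mother_id": str, "pregnancy_id": str, "region_id": str})
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    for col in ("conception_date", "delivery_date"):
        parsed = pd.to_datetime(df[col], format="%Y-%m-%d", errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            raise ValueError(
                f"{path}, row {int(np.flatnonzero(bad)[0]) + 1}: unparseable {col}"
            )
        df[col] = parsed.dt.date
    if df["pregnancy_id"].duplicated().any():
        dup = df["pregnancy_id"][df["pregnancy_id"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate pregnancy_id {dup!r}")
    bad_age = ~(df["age_years"] > 0)
    if bad_age.any():
        raise ValueError(
            f"{path}, row {int(np.flatnonzero(bad_age)[0]) + 1}: nonpositive age"
        )
    if not df["gdm"].isin([0, 1]).all():
        raise ValueError(f"{path}: gdm must be 0/1")
    return df


def read_exposure(path: str | Path) -> dict[tuple[str, str], ExposureSeries]:
    path = Path(path)
    df = pd.read_csv(path)
    _check_header(path, df.columns, EXPOSURE_HEADER)
    if (df["ppb"] < 0).any():
        row = int(np.flatnonzero(df["ppb"].to_numpy() < 0)[0]) + 1
        raise ValueError(f"{path}, row {row}: negative concentration")
    out: dict[tuple[str, str], ExposureSeries] = {}
    ts_all = pd.to_datetime(df["timestamp"]).to_numpy()
    for (rid, voc), idx in df.groupby(["region_id", "voc_name"], sort=False).indices.items():
        out[(rid, voc)] = ExposureSeries(
            region_id=rid,
            voc_name=voc,
            timestamps=ts_all[idx],
            concentrations=df["ppb"].to_numpy()[idx],
        )
    return out


def write_units(path: str | Path, units_by_period: Mapping[str, Iterable[AreaUnit]]) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(UNITS_HEADER)
        for period in sorted(units_by_period):
            for u in units_by_period[period]:
                w.writerow([period, u.unit_id, u.api_count, u.white_count, u.total_pop])


def write_crosswalk(path: str | Path, crosswalk: Mapping[str, str]) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["unit_id", "region_id"])
        for uid, rid in crosswalk.items():
            w.writerow([uid, rid])


def write_cohort(path: str | Path, cohort: pd.DataFrame) -> None:
    df = cohort[COHORT_COLUMNS].copy()
    df.to_csv(Path(path), index=False, float_format=FLOAT_FMT)


def write_exposure(
    path: str | Path, series: Mapping[tuple[str, str], ExposureSeries]
) -> None:
    frames = []
    for (rid, voc), s in series.items():
        frames.append(
            pd.DataFrame(
                {
                    "region_id": rid,
                    "voc_name": voc,
                    "timestamp": pd.to_datetime(s.timestamps).strftime("%Y-%m-%d"),
                    "ppb": s.concentrations,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        Path(path), index=False, float_format=FLOAT_FMT
    )


def write_profiles(path: str | Path, profiles: Iterable[RegionProfile]) -> None:
    pd.DataFrame(
        [
            {
                "region_id": p.region_id,
                "period": p.period,
                "api_density": p.api_density,
                "dissimilarity": p.dissimilarity,
                "isolation": p.isolation,
                "poverty_rate": p.poverty_rate,
            }
            for p in profiles
        ]
    ).to_csv(Path(path), index=False, float_format=FLOAT_FMT)


def write_labels(path: str | Path, labels: Iterable[EnclaveLabel]) -> None:
    pd.DataFrame(
        [
            {
                "region_id": l.region_id,
                "period": l.period,
                "density_tertile": l.density_tertile,
                "dissimilarity_tertile": l.dissimilarity_tertile,
                "isolation_tertile": l.isolation_tertile,
                "is_enclave": l.is_enclave,
            }
            for l in labels
        ]
    ).to_csv(Path(path), index=False)


def write_frame(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(Path(path), index=False, float_format=FLOAT_FMT)
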