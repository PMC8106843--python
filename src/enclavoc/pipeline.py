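"""End-to-end analysis pipeline: segregation → enclaves → exposure → models.

``run_pipeline`` takes a :class:`RunConfig` pointing at the three input CSVs
(area-unit counts with a period column, unit→region crosswalk, pregnancy
cohort, per-region VOC series), executes the stages in order and writes all
report CSVs plus a machine-readable run log.  Every stage failure aborts
with an error naming the stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .enclaves import classify_enclaves
from .exposure import VOC_NAMES, WINDOWS, dichotomize_high, spearman_voc_matrix, window_average_table
from .imputation import impute_bmi
from .inference import bh_adjust, fit_component_models, fit_joint_model, high_multiple_voc
from .io import (
    read_cohort,
    read_crosswalk,
    read_exposure,
    read_units,
    write_frame,
    write_labels,
    write_profiles,
)
from .joint import joint_category_column, tabulate_outcome
from .mixedlogit import SeparationError
from .segregation import aggregate_to_region, region_profile

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    units_path: str
    crosswalk_path: str
    cohort_path: str
    exposure_path: str
    out_dir: str
    seed: int = 0
    vocs: Sequence[str] = VOC_NAMES
    windows: Sequence[str] = WINDOWS
    n_imputations: int = 10
    fdr_q: float = 0.10
    quadrature_nodes: int = 9
    pca_loading_threshold: float = 0.4
    run_sensitivity: bool = True
    poverty_by_region: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["vocs"] = list(self.vocs)
        d["windows"] = list(self.windows)
        return d


def _poverty_lookup(config: RunConfig, cohort: pd.DataFrame) -> dict[str, float]:
    if config.poverty_by_region:
        return dict(config.poverty_by_region)
    # fall back to the cohort's own area_poverty column (constant per region)
    return cohort.groupby("region_id")["area_poverty"].first().to_dict()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the in-memory result bundle."""
    for p in (
        config.units_path,
        config.crosswalk_path,
        config.cohort_path,
        config.exposure_path,
    ):
        if not Path(p).exists():
            raise FileNotFoundError(f"input file not found before run: {p}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as e:
                raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
        return deco

    # ---- segregation ----------------------------------------------------
    @stage("segregation")
    def seg():
        units_by_period = read_units(config.units_path)
        crosswalk = read_crosswalk(config.crosswalk_path)
        cohort = read_cohort(config.cohort_path)
        poverty = _poverty_lookup(config, cohort)
        profiles = {}
        for period, units in units_by_period.items():
            counts = aggregate_to_region(units, crosswalk)
            profiles[period] = [
                region_profile(rc, period, poverty.get(rc.region_id, float("nan")))
                for rc in counts
            ]
        return units_by_period, cohort, profiles

    units_by_period, cohort, profiles = seg
    write_profiles(out / "region_profiles.csv", [p for ps in profiles.values() for p in ps])

    # ---- enclave classification -----------------------------------------
    @stage("classify")
    def labels_by_period():
        return {period: classify_enclaves(ps) for period, ps in profiles.items()}

    all_labels = [l for ls in labels_by_period.values() for l in ls]
    write_labels(out / "enclave_labels.csv", all_labels)
    flag = {(l.region_id, l.period): l.is_enclave for l in all_labels}
    tert = {
        (l.region_id, l.period): (
            l.density_tertile,
            l.dissimilarity_tertile,
            l.isolation_tertile,
        )
        for l in all_labels
    }

    @stage("link")
    def cohort2():
        df = cohort.copy()
        df["period"] = np.where(
            pd.to_datetime(df["delivery_date"]).dt.year <= 2004,
            "census2000",
            "acs2007_2011",
        )
        try:
            df["is_enclave"] = [
                flag[(r, p)] for r, p in zip(df["region_id"], df["period"])
            ]
            trip = [tert[(r, p)] for r, p in zip(df["region_id"], df["period"])]
        except KeyError as e:
            raise ValueError(f"no enclave label for region/period {e}") from None
        df["density_tertile"] = [t[0] for t in trip]
        df["dissimilarity_tertile"] = [t[1] for t in trip]
        df["isolation_tertile"] = [t[2] for t in trip]
        return df

    cohort = cohort2

    # ---- exposure windows ------------------------------------------------
    @stage("expose")
    def exposures():
        series = read_exposure(config.exposure_path)
        averages = pd.concat(
            [
                window_average_table(series, cohort, w, vocs=config.vocs)
                for w in config.windows
            ],
            ignore_index=True,
        )
        levels = {
            (voc, w): dichotomize_high(averages, voc, w)
            for voc in config.vocs
            for w in config.windows
        }
        return averages, levels

    averages, levels = exposures
    write_frame(out / "window_averages.csv", averages)
    lv_frame = pd.concat(
        [
            pd.DataFrame(
                {
                    "pregnancy_id": list(m),
                    "voc_name": voc,
                    "window": w,
                    "level": list(m.values()),
                }
            )
            for (voc, w), m in levels.items()
        ],
        ignore_index=True,
    )
    write_frame(out / "exposure_levels.csv", lv_frame)

    # Spearman correlations among window averages, per window
    spearman = {}
    for w in config.windows:
        wide = averages[averages["window"] == w].pivot(
            index="pregnancy_id", columns="voc_name", values="mean_ppb"
        )[list(config.vocs)]
        spearman[w] = spearman_voc_matrix(wide)
        spearman[w].round(10).to_csv(out / f"spearman_{w}.csv")

    # ---- tabulations -----------------------------------------------------
    @stage("report")
    def tables():
        t2 = tabulate_outcome(cohort, "is_enclave")
        rows = []
        for (voc, w), m in levels.items():
            d = cohort[["pregnancy_id", "gdm", "is_enclave"]].copy()
            d["joint_category"] = joint_category_column(
                d["pregnancy_id"].map(m), d["is_enclave"]
            )
            tab = tabulate_outcome(d, "joint_category")
            tab.insert(0, "voc_name", voc)
            tab.insert(1, "window", w)
            rows.append(tab)
        return t2, pd.concat(rows, ignore_index=True)

    table_enclave, table_joint = tables
    write_frame(out / "table_enclave.csv", table_enclave)
    write_frame(out / "table_joint.csv", table_joint)

    # ---- inference -------------------------------------------------------
    @stage("fit")
    def fits():
        datasets = impute_bmi(cohort, m=config.n_imputations, seed=config.seed)
        results = {}
        skipped = []
        for w in config.windows:
            for voc in config.vocs:
                try:
                    results[(voc, w)] = fit_joint_model(
                        datasets,
                        voc,
                        w,
                        levels[(voc, w)],
                        n_quad=config.quadrature_nodes,
                    )
                except (ValueError, SeparationError) as e:
                    # e.g. an empty joint category or a separated nuisance
                    # stratum for this VOC at small n
                    skipped.append((voc, w, str(e)))
                    logging.getLogger("enclavoc").warning(
                        "skipping model %s/%s: %s", voc, w, e
                    )
        decisions = {}
        for w in config.windows:
            fam = {}
            for voc in config.vocs:
                if (voc, w) not in results:
                    continue
                for _, row in results[(voc, w)].odds_ratios.iterrows():
                    fam[f"{voc}|{w}|{row['term']}"] = row["p"]
            decisions[w] = bh_adjust(fam, q=config.fdr_q) if fam else []
        sens = {}
        if config.run_sensitivity:
            ref_voc = "benzene" if "benzene" in config.vocs else config.vocs[0]
            benz_pre = levels.get((ref_voc, "preconception"))
            benz_tri = levels.get((ref_voc, "first_trimester"))
            if benz_pre is not None and benz_tri is not None:
                prepared = []
                for d in datasets:
                    d = d.copy()
                    d["benzene_preconception"] = d["pregnancy_id"].map(benz_pre)
                    d["benzene_first_trimester"] = d["pregnancy_id"].map(benz_tri)
                    prepared.append(d)
                try:
                    sens["components"] = fit_component_models(
                        prepared, n_quad=config.quadrature_nodes
                    )
                except (ValueError, SeparationError) as e:
                    logging.getLogger("enclavoc").warning(
                        "skipping component models: %s", e
                    )
            for w in config.windows:
                wide_avg = averages[averages["window"] == w].pivot(
                    index="pregnancy_id", columns="voc_name", values="mean_ppb"
                )[list(config.vocs)]
                wide_flag = lv_frame[lv_frame["window"] == w].pivot(
                    index="pregnancy_id", columns="voc_name", values="level"
                )[list(config.vocs)]
                try:
                    sens[f"high_multiple_{w}"] = high_multiple_voc(
                        datasets,
                        wide_avg,
                        wide_flag,
                        w,
                        loading_threshold=config.pca_loading_threshold,
                        n_quad=config.quadrature_nodes,
                    )
                except (ValueError, SeparationError):
                    sens[f"high_multiple_{w}"] = None
        return results, decisions, sens

    results, decisions, sens = fits

    rows = []
    sig = {
        w: {d.label: d.significant for d in ds} for w, ds in decisions.items()
    }
    for (voc, w), res in results.items():
        for _, r in res.odds_ratios.iterrows():
            rows.append(
                {
                    "voc_name": voc,
                    "window": w,
                    "category": r["term"],
                    "n": r["n"],
                    "OR": r["OR"],
                    "ci_low": r["ci_low"],
                    "ci_high": r["ci_high"],
                    "p": r["p"],
                    "bh_significant": sig[w][f"{voc}|{w}|{r['term']}"],
                    "sigma": res.sigma,
                    "converged": res.converged,
                }
            )
    model_frame = pd.DataFrame(rows)
    write_frame(out / "model_results.csv", model_frame)
    fdr_frame = pd.DataFrame(
        [
            {
                "window": w,
                "label": d.label,
                "p": d.p,
                "rank": d.rank,
                "threshold": d.threshold,
                "significant": d.significant,
            }
            for w, ds in decisions.items()
            for d in ds
        ]
    )
    write_frame(out / "fdr_decisions.csv", fdr_frame)

    if sens.get("components"):
        comp_rows = []
        for label, res in sens["components"].items():
            for _, r in res.odds_ratios.iterrows():
                comp_rows.append(
                    {
                        "model": label,
                        "level": r["term"],
                        "n": r["n"],
                        "OR": r["OR"],
                        "ci_low": r["ci_low"],
                        "ci_high": r["ci_high"],
                        "p": r["p"],
                    }
                )
        write_frame(out / "component_models.csv", pd.DataFrame(comp_rows))
    for w in config.windows:
        hm = sens.get(f"high_multiple_{w}")
        if hm and "model" in hm:
            write_frame(out / f"high_multiple_{w}.csv", hm["model"].odds_ratios)

    log = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "versions": {
            "enclavoc": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "n_pregnancies": int(len(cohort)),
        "n_models": len(results),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))

    return {
        "profiles": profiles,
        "labels": labels_by_period,
        "cohort": cohort,
        "averages": averages,
        "levels": levels,
        "spearman": spearman,
        "table_enclave": table_enclave,
        "table_joint": table_joint,
        "models": results,
        "model_frame": model_frame,
        "fdr": decisions,
        "sensitivity": sens,
    }
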