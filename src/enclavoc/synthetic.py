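"""Synthetic nested-cohort generator with known ground truth.

Emulates the structure of a national hospital-based birth cohort: small
area units (ZCTA-like) nested in regions (HRR-like), mothers nested in
regions with a small fraction of repeat births, 14 correlated ambient VOC
series per region, categorical maternal covariates, and a GDM outcome drawn
from a logistic model with region random intercepts and known
joint-exposure-category odds ratios.

Everything is deterministic under the top-level seed.  A designated subset
of regions is generated "enclave-like" (high API share, strong within-region
clustering of API residents) so that the enclave classifier recovers them;
the outcome is generated from the *classifier's* enclave labels and the
*pipeline's* dichotomised VOC level, so the generating joint category is
exactly the category the analysis reconstructs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Mapping

import numpy as np
import pandas as pd

from .enclaves import classify_enclaves
from .exposure import (
    BLOCK_VOCS,
    VOC_NAMES,
    ExposureSeries,
    dichotomize_high,
    window_average_table,
)
from .joint import joint_category_column
from .segregation import AreaUnit, aggregate_to_region, region_profile

__all__ = [
    "GeneratorConfig",
    "SyntheticRegions",
    "SyntheticTruth",
    "SimulatedStudy",
    "gen_regions",
    "gen_exposure",
    "gen_cohort",
    "simulate",
    "period_for_delivery",
]

PERIODS = ("census2000", "acs2007_2011")

#: Typical urban ambient levels (ppb, log scale) for the 14 species.
_DEFAULT_LOG_MEANS = {
    "benzene": np.log(0.35),
    "1,3-butadiene": np.log(0.05),
    "ethylbenzene": np.log(0.15),
    "cyclohexane": np.log(0.08),
    "methyl-tertiary-butyl ether": np.log(0.20),
    "n-hexane": np.log(0.25),
    "ethyl-methyl ketone": np.log(0.30),
    "m-xylene": np.log(0.25),
    "o-xylene": np.log(0.12),
    "p-xylene": np.log(0.12),
    "propene": np.log(0.60),
    "sesquiterpene": np.log(0.02),
    "styrene": np.log(0.04),
    "toluene": np.log(0.90),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-shaped defaults: ~9 069 births to ~8 350 mothers in 15 regions."""

    n_regions: int = 15
    units_per_region: int = 40
    n_enclave_regions: int = 5  # designated enclave-like subset (top tertile)
    enclave_population_share: float = 0.208  # share of mothers in those regions
    api_share_range: tuple[float, float] = (0.02, 0.12)
    api_share_range_enclave: tuple[float, float] = (0.25, 0.40)
    #: Beta concentration of unit-level API shares; low = clustered (enclave-like)
    segregation_strength: float = 0.8
    mixing_strength: float = 50.0
    n_mothers: int = 8350
    repeat_birth_fraction: float = 0.079  # of births, i.e. ~731 of 9069
    vocs: tuple[str, ...] = VOC_NAMES
    voc_log_means: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_LOG_MEANS)
    )
    voc_log_sd: float = 0.5  # day-to-day, log scale
    region_log_sd: float = 0.3  # between-region, log scale
    seasonal_amplitude: float = 0.2  # log scale
    voc_block_correlation: float = 0.9
    voc_weak_correlation: float = 0.1
    true_log_ors: Mapping[str, float] = field(
        default_factory=lambda: {
            "LowVOC_NoEnclave": np.log(1.5),
            "HighVOC_Enclave": np.log(1.2),
            "HighVOC_NoEnclave": np.log(2.0),
        }
    )
    random_intercept_sd: float = 0.3
    #: log-OR per covariate level (centered design; see docs/methods.md)
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: {
            "age_per_year": 0.06,
            "bmi_<18.5": -0.5,
            "bmi_25-29.9": 0.65,
            "bmi_>=30": 0.9,
            "parity_multiparous": 0.2,
            "insurance_public": -0.1,
            "insurance_self_pay": -0.05,
            "insurance_other": -0.45,
            "marital_single": -0.5,
            "marital_other": 0.1,
            "season_summer": -0.15,
            "season_fall": 0.05,
            "season_winter": 0.15,
            "hospital_community_teaching": 0.2,
            "hospital_community_nonteaching": -0.2,
            "poverty_per_unit": 0.3,
        }
    )
    baseline_gdm_logit: float = -3.01  # calibrated to ~9.9% prevalence at defaults
    bmi_missing_fraction: float = 0.42
    outcome_voc: str = "benzene"
    outcome_window: str = "preconception"
    series_start: date = date(2001, 1, 1)
    series_end: date = date(2008, 12, 31)

    def __post_init__(self) -> None:
        if not 0 <= self.enclave_population_share <= 1:
            raise ValueError("enclave_population_share must be in [0, 1]")
        if not 0 <= self.repeat_birth_fraction < 1:
            raise ValueError("repeat_birth_fraction must be in [0, 1)")
        if not 0 <= self.bmi_missing_fraction <= 1:
            raise ValueError("bmi_missing_fraction must be in [0, 1]")
        if self.n_enclave_regions >= self.n_regions:
            raise ValueError("n_enclave_regions must be < n_regions")
        if self.outcome_voc not in self.vocs:
            raise ValueError(f"outcome_voc {self.outcome_voc!r} not in vocs")
        bad = set(self.vocs) - set(self.voc_log_means)
        if bad:
            raise ValueError(f"no log-mean configured for VOC(s) {sorted(bad)}")


@dataclass
class SyntheticRegions:
    units_by_period: dict[str, list[AreaUnit]]
    crosswalk: dict[str, str]
    poverty: dict[str, float]
    designated_enclaves: list[str]
    region_ids: list[str]


@dataclass
class SyntheticTruth:
    designated_enclaves: list[str]
    classified_enclaves: dict[tuple[str, str], bool]  # (region, period) -> flag
    true_log_ors: dict[str, float]
    random_intercepts: dict[str, float]
    joint_category: pd.Series  # per pregnancy, the generating category
    baseline_gdm_logit: float


@dataclass
class SimulatedStudy:
    config: GeneratorConfig
    regions: SyntheticRegions
    exposure: dict[tuple[str, str], ExposureSeries]
    cohort: pd.DataFrame
    truth: SyntheticTruth


def _child_seeds(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def period_for_delivery(delivery: date) -> str:
    """Births through 2004 link to the 2000 census; later births to the ACS."""
    return PERIODS[0] if delivery.year <= 2004 else PERIODS[1]


def gen_regions(config: GeneratorConfig, seed: int) -> SyntheticRegions:
    """Small-area composition, the unit→region crosswalk, and poverty rates."""
    rng = np.random.default_rng(seed)
    region_ids = [f"R{i+1:02d}" for i in range(config.n_regions)]
    designated = region_ids[: config.n_enclave_regions]
    units_census: list[AreaUnit] = []
    crosswalk: dict[str, str] = {}
    poverty: dict[str, float] = {}
    unit_no = 0
    for rid in region_ids:
        enclaveish = rid in designated
        lo, hi = (
            config.api_share_range_enclave if enclaveish else config.api_share_range
        )
        p_r = rng.uniform(lo, hi)
        kappa = config.segregation_strength if enclaveish else config.mixing_strength
        pops = np.maximum(
            200, np.round(np.exp(rng.normal(9.3, 0.8, config.units_per_region)))
        ).astype(int)
        shares = rng.beta(kappa * p_r, kappa * (1.0 - p_r), config.units_per_region)
        white_frac = rng.uniform(0.5, 0.7, config.units_per_region) * (1.0 - shares)
        api = np.round(shares * pops).astype(int)
        white = np.minimum(np.round(white_frac * pops).astype(int), pops - api)
        for k in range(config.units_per_region):
            unit_no += 1
            uid = f"Z{unit_no:05d}"
            units_census.append(
                AreaUnit(uid, int(api[k]), int(white[k]), int(pops[k]))
            )
            crosswalk[uid] = rid
        poverty[rid] = float(rng.uniform(0.08, 0.25))
    # guarantee both group totals are positive in every region
    by_region: dict[str, list[AreaUnit]] = {}
    for u in units_census:
        by_region.setdefault(crosswalk[u.unit_id], []).append(u)
    fixed: list[AreaUnit] = []
    for rid, us in by_region.items():
        if sum(u.api_count for u in us) == 0:
            us[0] = replace_counts(us[0], api_count=1)
        if sum(u.white_count for u in us) == 0:
            us[0] = replace_counts(us[0], white_count=1)
        fixed.extend(us)
    units_census = fixed
    # ACS counts: small multiplicative drift on the census composition
    units_acs = []
    for u in units_census:
        factor = np.exp(rng.normal(0.0, 0.05, 3))
        pop = max(1, int(round(u.total_pop * factor[2])))
        api = min(int(round(u.api_count * factor[0])), pop)
        white = min(int(round(u.white_count * factor[1])), pop - api)
        units_acs.append(AreaUnit(u.unit_id, api, white, pop))
    return SyntheticRegions(
        units_by_period={PERIODS[0]: units_census, PERIODS[1]: units_acs},
        crosswalk=crosswalk,
        poverty=poverty,
        designated_enclaves=designated,
        region_ids=region_ids,
    )


def replace_counts(u: AreaUnit, **kw) -> AreaUnit:
    base = dict(
        unit_id=u.unit_id,
        api_count=u.api_count,
        white_count=u.white_count,
        total_pop=u.total_pop,
    )
    base.update(kw)
    base["total_pop"] = max(base["total_pop"], base["api_count"] + 0, base["white_count"])
    return AreaUnit(**base)


def _voc_correlation(config: GeneratorConfig) -> np.ndarray:
    vocs = list(config.vocs)
    V = len(vocs)
    in_block = np.array([v in BLOCK_VOCS for v in vocs])
    R = np.full((V, V), config.voc_weak_correlation)
    for i in range(V):
        for j in range(V):
            if in_block[i] and in_block[j]:
                R[i, j] = config.voc_block_correlation
    np.fill_diagonal(R, 1.0)
    # nudge to PSD if the block/weak mix is not (it is, for defaults)
    w, Q = np.linalg.eigh(R)
    if w.min() < 1e-10:
        R = (Q * np.clip(w, 1e-10, None)) @ Q.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
    return R


def gen_exposure(
    config: GeneratorConfig,
    regions: SyntheticRegions,
    seed: int,
    cohort: pd.DataFrame | None = None,
) -> dict[tuple[str, str], ExposureSeries]:
    """Daily log-normal VOC series per region with a correlated block.

    The fuel/traffic block shares one winter-peaking seasonal cycle and a
    high cross-VOC correlation in both its day-to-day noise and its
    between-region offsets; the remaining species get spread-out seasonal
    phases and weak correlation.
    """
    rng = np.random.default_rng(seed)
    vocs = list(config.vocs)
    V = len(vocs)
    n_days = (config.series_end - config.series_start).days + 1
    ts = np.arange(
        np.datetime64(config.series_start, "D"),
        np.datetime64(config.series_end, "D") + 1,
    ).astype("datetime64[ns]")
    doy = np.arange(n_days) % 365.25
    L = np.linalg.cholesky(_voc_correlation(config))
    mu = np.array([config.voc_log_means[v] for v in vocs])
    # seasonal phases: one shared winter peak for the block, spread otherwise
    phases = np.empty(V)
    k = 0
    for i, v in enumerate(vocs):
        if v in BLOCK_VOCS:
            phases[i] = 15.0  # mid-January peak
        else:
            phases[i] = 365.25 * (k + 0.5) / max(1, V - sum(1 for x in vocs if x in BLOCK_VOCS))
            k += 1
    seasonal = config.seasonal_amplitude * np.cos(
        2.0 * np.pi * (doy[:, None] - phases[None, :]) / 365.25
    )  # (n_days, V)
    out: dict[tuple[str, str], ExposureSeries] = {}
    for rid in regions.region_ids:
        offset = config.region_log_sd * (L @ rng.normal(size=V))  # (V,)
        noise = rng.normal(size=(n_days, V)) @ L.T * config.voc_log_sd
        logc = mu[None, :] + offset[None, :] + seasonal + noise
        conc = np.exp(logc)
        for i, v in enumerate(vocs):
            out[(rid, v)] = ExposureSeries(
                region_id=rid, voc_name=v, timestamps=ts, concentrations=conc[:, i]
            )
    return out


def classify_generated_regions(
    regions: SyntheticRegions,
) -> dict[tuple[str, str], bool]:
    """Run the segregation + enclave pipeline on the generated area tables."""
    flags: dict[tuple[str, str], bool] = {}
    for period, units in regions.units_by_period.items():
        counts = aggregate_to_region(units, regions.crosswalk)
        profiles = [
            region_profile(rc, period, regions.poverty[rc.region_id]) for rc in counts
        ]
        for lab in classify_enclaves(profiles):
            flags[(lab.region_id, period)] = lab.is_enclave
    return flags


def _draw_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    marital = rng.choice(
        ["married", "single", "other"], size=n, p=[0.843, 0.137, 0.020]
    )
    insurance = rng.choice(
        ["private", "public", "self_pay", "other"],
        size=n,
        p=[0.703, 0.141, 0.021, 0.135],
    )
    age = np.clip(rng.normal(29.5, 5.5, n), 15.0, 48.0)
    bmi_cat = rng.choice(
        ["<18.5", "18.5-24.9", "25-29.9", ">=30"],
        size=n,
        p=[0.118, 0.659, 0.142, 0.081],
    )
    low = {"<18.5": 16.0, "18.5-24.9": 18.5, "25-29.9": 25.0, ">=30": 30.0}
    high = {"<18.5": 18.5, "18.5-24.9": 25.0, "25-29.9": 30.0, ">=30": 42.0}
    bmi = np.array(
        [rng.uniform(low[c], high[c]) for c in bmi_cat]
    )
    return pd.DataFrame(
        {
            "age_years": age,
            "marital_status": marital,
            "insurance": insurance,
            "bmi": bmi,
        }
    )


_SEASONS = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "fall", 10: "fall", 11: "fall",
}


def gen_cohort(
    config: GeneratorConfig,
    regions: SyntheticRegions,
    seed: int,
    exposure: dict[tuple[str, str], ExposureSeries] | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Pregnancy records with covariates, exposure category and GDM outcome.

    The outcome model is
    ``logit p = baseline + covariate effects + joint-category log-OR + b_region``
    with the joint category built from the classifier's enclave label and
    the pooled 75th-percentile dichotomisation of the outcome VOC's window
    average — exactly what the analysis pipeline reconstructs.
    """
    rng_cohort, rng_exp, rng_out = _child_seeds(seed, 3)
    if exposure is None:
        exposure = gen_exposure(config, regions, rng_exp.integers(2**31 - 1))

    n_mothers = config.n_mothers
    f = config.repeat_birth_fraction
    n_repeat = int(round(n_mothers * f / (1.0 - f)))
    n_births = n_mothers + n_repeat

    # mothers to regions: designated enclave-like regions absorb the
    # configured population share, split by region size within each stratum
    pops = {
        rid: sum(
            u.total_pop
            for u in regions.units_by_period[PERIODS[0]]
            if regions.crosswalk[u.unit_id] == rid
        )
        for rid in regions.region_ids
    }
    enc = regions.designated_enclaves
    non = [r for r in regions.region_ids if r not in enc]
    w = np.empty(len(regions.region_ids))
    for i, rid in enumerate(regions.region_ids):
        stratum, share = (enc, config.enclave_population_share) if rid in enc else (
            non,
            1.0 - config.enclave_population_share,
        )
        w[i] = share * pops[rid] / sum(pops[r] for r in stratum)
    mother_region = rng_cohort.choice(regions.region_ids, size=n_mothers, p=w / w.sum())

    repeat_mothers = (
        rng_cohort.choice(n_mothers, size=n_repeat, replace=False)
        if n_repeat
        else np.array([], dtype=int)
    )
    mother_idx = np.r_[np.arange(n_mothers), repeat_mothers]
    is_second = np.r_[np.zeros(n_mothers, bool), np.ones(n_repeat, bool)]

    # conception dates: first births anywhere in the study span; repeat
    # births 400-800 days after the mother's first conception
    span_start = date(2001, 7, 1)
    first_days = rng_cohort.integers(0, (date(2008, 2, 28) - span_start).days, n_mothers)
    gap = rng_cohort.integers(400, 800, n_repeat)
    # keep repeat conceptions inside the span by shifting the pair back if needed
    first_for_repeat = first_days[repeat_mothers]
    limit = (date(2008, 2, 28) - span_start).days
    overflow = np.maximum(0, first_for_repeat + gap - limit)
    first_days[repeat_mothers] = first_for_repeat - overflow
    conc_days = np.r_[first_days, first_days[repeat_mothers] + gap]
    conception = np.array([span_start + timedelta(days=int(d)) for d in conc_days])
    gestation = np.clip(np.round(rng_cohort.normal(273, 14, n_births)), 182, 300).astype(int)
    delivery = np.array(
        [c + timedelta(days=int(g) - 14) for c, g in zip(conception, gestation)]
    )

    # hospital of delivery: multiple hospitals can share a region (the
    # emulated study had 19 hospitals across 15 regions), so type varies
    # within region; drawing per mother keeps every stratum populated
    hosp = rng_cohort.choice(
        ["university", "community_teaching", "community_nonteaching"],
        size=n_births,
        p=[0.41, 0.545, 0.045],
    )
    cov = _draw_covariates(rng_cohort, n_births)
    miss = rng_cohort.random(n_births) < config.bmi_missing_fraction
    bmi_obs = cov["bmi"].to_numpy().copy()
    bmi_obs[miss] = np.nan
    parity_first = np.where(
        rng_cohort.random(n_mothers) < 0.511, "multiparous", "nulliparous"
    )
    parity = np.where(is_second, "multiparous", parity_first[mother_idx])

    region = mother_region[mother_idx]
    df = pd.DataFrame(
        {
            "mother_id": [f"M{m+1:06d}" for m in mother_idx],
            "pregnancy_id": [f"P{i+1:06d}" for i in range(n_births)],
            "region_id": region,
            "conception_date": conception,
            "delivery_date": delivery,
            "gestation_days": gestation,
            "age_years": cov["age_years"],
            "marital_status": cov["marital_status"],
            "insurance": cov["insurance"],
            "bmi": bmi_obs,
            "parity": parity,
            "hospital_type": hosp,
            "area_poverty": [regions.poverty[r] for r in region],
        }
    )
    df["season_of_conception"] = [
        _SEASONS[c.month] for c in conception
    ]
    df["period"] = [period_for_delivery(d) for d in delivery]
    from .imputation import bmi_category  # local import avoids a cycle

    df["bmi_cat"] = df["bmi"].map(bmi_category)

    # exposure category exactly as the pipeline derives it
    flags = classify_generated_regions(regions)
    df["is_enclave"] = [
        flags[(r, p)] for r, p in zip(df["region_id"], df["period"])
    ]
    averages = window_average_table(
        exposure, df, config.outcome_window, vocs=[config.outcome_voc]
    )
    level_map = dichotomize_high(averages, config.outcome_voc, config.outcome_window)
    levels = df["pregnancy_id"].map(level_map)
    category = joint_category_column(levels, df["is_enclave"])
    df["true_joint_category"] = category

    eff = config.covariate_effects
    eta = np.full(n_births, config.baseline_gdm_logit)
    eta += eff["age_per_year"] * (df["age_years"].to_numpy() - 29.5)
    for cat_col, prefix, ref in (
        ("marital_status", "marital", "married"),
        ("insurance", "insurance", "private"),
        ("season_of_conception", "season", "spring"),
        ("hospital_type", "hospital", "university"),
    ):
        vals = df[cat_col].to_numpy()
        for lv in np.unique(vals):
            if lv == ref:
                continue
            key = f"{prefix}_{lv}".replace("community_", "community_")
            eta += eff.get(key, 0.0) * (vals == lv)
    bmi_full = cov["bmi"].map(
        lambda b: "<18.5" if b < 18.5 else ("18.5-24.9" if b < 25 else ("25-29.9" if b < 30 else ">=30"))
    ).to_numpy()
    for lv in ("<18.5", "25-29.9", ">=30"):
        eta += eff[f"bmi_{lv}"] * (bmi_full == lv)
    eta += eff["parity_multiparous"] * (df["parity"].to_numpy() == "multiparous")
    eta += eff["poverty_per_unit"] * (
        df["area_poverty"].to_numpy() - np.mean(list(regions.poverty.values()))
    )
    for cat, lor in config.true_log_ors.items():
        eta += lor * (category.to_numpy() == cat)
    b_region = {
        rid: rng_out.normal(0.0, config.random_intercept_sd)
        for rid in regions.region_ids
    }
    eta += np.array([b_region[r] for r in df["region_id"]])
    df["gdm"] = (rng_out.random(n_births) < 1.0 / (1.0 + np.exp(-eta))).astype(int)

    truth = SyntheticTruth(
        designated_enclaves=list(regions.designated_enclaves),
        classified_enclaves=flags,
        true_log_ors=dict(config.true_log_ors),
        random_intercepts=b_region,
        joint_category=df.set_index("pregnancy_id")["true_joint_category"],
        baseline_gdm_logit=config.baseline_gdm_logit,
    )
    return df, truth


def simulate(config: GeneratorConfig, seed: int) -> SimulatedStudy:
    """Full deterministic draw: regions, exposure series, cohort, truth."""
    ss = np.random.SeedSequence(seed).spawn(3)
    s_reg, s_exp, s_coh = (int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss)
    regions = gen_regions(config, s_reg)
    exposure = gen_exposure(config, regions, s_exp)
    cohort, truth = gen_cohort(config, regions, s_coh, exposure=exposure)
    return SimulatedStudy(
        config=config, regions=regions, exposure=exposure, cohort=cohort, truth=truth
    )
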