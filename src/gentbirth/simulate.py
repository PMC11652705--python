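"""Synthetic regions, tract trajectories and birth cohorts.

The generator emulates the data structure the pipeline consumes — no
real census or birth data are involved — while guaranteeing known
ground truth:

* **Tracts.**  Each region is a ring of tracts (ring adjacency).  Half
  the tracts are scripted to be gentrification-eligible (urban,
  low-income, low recent construction) and the rest ineligible, with
  comparator margins wide enough that the intended label survives the
  small drift of regional medians.  Within each region, designated
  tracts realize every typology category: the scripted clauses
  (appreciation, education growth, end-of-period cost, low-income
  household loss) are set relative to the region's own provisional
  medians with 10–30 % margins.
* **Births.**  Outcomes follow a random-intercept logistic model on
  the log-odds scale: logit P = alpha + beta_exposure + gamma'covariates
  + u_tract, u ~ N(0, sigma_u^2).  Gestational age is sampled
  conditional on the preterm latent draw and birth weight conditional
  on the small-for-gestational-age latent draw (through a latent
  growth percentile), so the cohort module re-derives the flags from
  realistic marginals.  Implausible values and missingness are
  injected at configurable rates to exercise the exclusion cascade.

Default effect sizes sit in the modest range (odds ratios roughly
0.9–1.2) typical of neighborhood-exposure studies, and the default
race/ethnicity mix mirrors a large, diverse state birth registry.

All randomness flows through one ``numpy.random.default_rng(seed)``
(PCG64): identical seed and config give bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .census import Period, TractPeriodMeasures, write_tract_measures
from .classify import DGCategory, FreemanLabel
from .cohort import BIRTH_COLUMNS, GrowthReference

__all__ = [
    "SimConfig",
    "SimTruth",
    "default_growth_reference",
    "simulate_tracts",
    "simulate_births",
    "simulate_clustered_binary",
    "make_fixture",
    "FIXTURES",
]

PERIODS = (Period("2000-2010", 2000, 2010), Period("2007-2017", 2007, 2017))
YEARS_OF_PERIOD = {
    "2000-2010": tuple(range(2005, 2012)),
    "2007-2017": tuple(range(2012, 2018)),
}

# Approximate fetal-growth means (grams) by completed week, used to
# build the package's synthetic sex-specific growth reference (normal
# within each sex-week cell, SD = 12.5% of the mean, males +55 g,
# females -55 g).  Synthetic stand-in, not a published standard.
_WEEK_MEAN_G = {
    22: 500, 23: 580, 24: 670, 25: 770, 26: 890, 27: 1030, 28: 1180,
    29: 1350, 30: 1530, 31: 1720, 32: 1930, 33: 2150, 34: 2380,
    35: 2600, 36: 2810, 37: 3000, 38: 3180, 39: 3330, 40: 3440,
    41: 3500, 42: 3520, 43: 3500, 44: 3470,
}
_SGA_Z = -1.2815515655446004  # 10th percentile of the standard normal


def default_growth_reference() -> GrowthReference:
    """Synthetic sex-by-week growth reference consistent with the
    generator's weight model (p10 = mean + z_0.10 * sd exactly)."""
    rows = []
    for week, mean in _WEEK_MEAN_G.items():
        for sex, shift in (("F", -55.0), ("M", 55.0)):
            mu = mean + shift
            sd = 0.125 * mu
            rows.append(
                {"sex": sex, "week": week, "p10_g": mu + _SGA_Z * sd, "mean_g": mu, "sd_g": sd}
            )
    return GrowthReference(pd.DataFrame(rows))


# GA distributions conditional on the preterm latent draw.  Preterm
# weights put ~13% of preterm mass before week 32 (very preterm); the
# non-preterm distribution peaks at 39-40 weeks with a sliver of
# extremely early (22-24 week) births that are neither PTB nor term.
_PTB_WEEKS = np.arange(25, 37)
_PTB_W = np.array([1.0, 1.2, 1.5, 2.0, 2.5, 3.2, 4.0, 6.5, 9.0, 13.0, 20.0, 30.0])
_PTB_W /= _PTB_W.sum()
_NONPTB_WEEKS = np.array([22, 23, 24, 37, 38, 39, 40, 41, 42, 43, 44])
_NONPTB_W = np.array([0.0006, 0.0008, 0.0016, 0.07, 0.20, 0.31, 0.27, 0.10, 0.04, 0.007, 0.003])
_NONPTB_W /= _NONPTB_W.sum()


@dataclass(frozen=True)
class SimConfig:
    """Study-condition knobs for the generator.

    The defaults define the standard synthetic study: 10 regions of 30
    tracts, ~150 births per tract over 2005–2017, tract random-
    intercept SD 0.3 on the log-odds scale, and exposure odds ratios
    of roughly 0.94 (ineligible) and 1.1 (gentrifying) against the
    eligible-not-gentrifying referent.
    """

    seed: int = 20240901
    n_regions: int = 10
    tracts_per_region: int = 30
    births_per_tract_mean: float = 150.0

    # tract-measure scales
    income_median: float = 62_000.0
    home_value_median: float = 360_000.0
    rent_median: float = 1_150.0
    regional_growth_range: tuple[float, float] = (0.15, 0.35)
    regional_bachelors_drift: float = 0.02
    frac_gentrifying_of_eligible: float = 0.30
    frac_rural_of_ineligible: float = 0.30

    # outcome model (log-odds scale); referent = ELIGIBLE_NOT_GENTRIFYING
    sigma_u: float = 0.3
    baseline_logit: dict = field(
        default_factory=lambda: {"ptb": -2.46, "sga": -2.27}
    )  # ~8% PTB, ~9.4% SGA at referent covariate values
    exposure_log_or: dict = field(
        default_factory=lambda: {
            "ptb": {"EXCLUDED": np.log(0.94), "ELIGIBLE_GENTRIFYING": np.log(1.09)},
            "sga": {"EXCLUDED": np.log(0.96), "ELIGIBLE_GENTRIFYING": np.log(0.96)},
        }
    )
    race_log_or: dict = field(
        default_factory=lambda: {
            "ptb": {"BLACK": 0.45, "AIAN": 0.25, "API": -0.05, "HISPANIC": 0.10},
            "sga": {"BLACK": 0.50, "AIAN": 0.10, "API": 0.40, "HISPANIC": 0.05},
        }
    )
    # exposure x race interaction log-ORs, {outcome: {race: {level: log-OR}}}
    interaction_log_or: dict = field(default_factory=dict)
    covariate_log_or: dict = field(
        default_factory=lambda: {
            "ptb": {"age_per_year": 0.01, "PUBLIC": 0.15, "UNINSURED_OTHER": 0.05,
                    "primiparous": -0.05, "adequate_care": 0.10},
            "sga": {"age_per_year": 0.00, "PUBLIC": 0.10, "UNINSURED_OTHER": 0.05,
                    "primiparous": 0.45, "adequate_care": -0.10},
        }
    )

    # covariate marginals (race mix mirrors a diverse state registry)
    race_mix: dict = field(
        default_factory=lambda: {
            "WHITE": 0.280, "HISPANIC": 0.515, "API": 0.148, "BLACK": 0.054, "AIAN": 0.003,
        }
    )
    race_other_rate: float = 0.015
    maternal_age_mean: float = 28.9
    maternal_age_sd: float = 6.0
    payer_mix: dict = field(
        default_factory=lambda: {"PUBLIC": 0.482, "PRIVATE": 0.477, "UNINSURED_OTHER": 0.041}
    )
    primiparous_rate: float = 0.396
    adequate_care_rate: float = 0.779
    prop_female: float = 0.49

    # dirty-data injection rates (a record receives at most one)
    inject_unlinkable: float = 0.004
    inject_implausible_ga: float = 0.001
    inject_implausible_age: float = 0.0005
    inject_implausible_weight: float = 0.0005
    inject_plural: float = 0.015
    inject_missing_covariate: float = 0.005

    def validate(self) -> None:
        rates = [
            self.inject_unlinkable, self.inject_implausible_ga, self.inject_implausible_age,
            self.inject_implausible_weight, self.inject_plural, self.inject_missing_covariate,
            self.race_other_rate, self.frac_gentrifying_of_eligible,
            self.frac_rural_of_ineligible, self.primiparous_rate,
            self.adequate_care_rate, self.prop_female,
        ]
        if any(not (0.0 <= r <= 1.0) for r in rates):
            raise ValueError("all rates must lie in [0, 1]")
        if self.sigma_u < 0:
            raise ValueError("sigma_u must be non-negative")
        if self.tracts_per_region < 12:
            raise ValueError("need at least 12 tracts per region to realize the label script")
        n_eligible = self.tracts_per_region // 2
        n_gent = max(2, round(self.frac_gentrifying_of_eligible * n_eligible))
        if n_gent + 4 > n_eligible:
            raise ValueError(
                "gentrification script infeasible: too many gentrifying tracts "
                "requested for the eligible pool"
            )
        if abs(sum(self.race_mix.values()) - 1.0) > 1e-9:
            raise ValueError("race_mix must sum to 1")


@dataclass
class SimTruth:
    """Ground truth serialized alongside the synthetic data."""

    intended_freeman: dict  # (tract_id, period_label) -> label str (scripted tracts)
    intended_dg: dict  # (tract_id, period_label) -> category str (designated tracts)
    sigma_u: float
    exposure_log_or: dict
    tract_intercepts: dict  # (tract_id, outcome) -> u
    birth_latents: pd.DataFrame | None = None  # birth_id, eta/flag per outcome

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        pd.DataFrame(
            [
                {"tract_id": t, "period": p, "intended_freeman": v,
                 "intended_dg": self.intended_dg.get((t, p), "")}
                for (t, p), v in sorted(self.intended_freeman.items())
            ]
        ).to_csv(directory / "truth_labels.csv", index=False)
        params = {
            "sigma_u": self.sigma_u,
            "exposure_log_or": {
                oc: {k: float(v) for k, v in d.items()}
                for oc, d in self.exposure_log_or.items()
            },
        }
        (directory / "truth_params.json").write_text(json.dumps(params, indent=2))
        if self.birth_latents is not None:
            self.birth_latents.to_csv(directory / "truth_latents.csv", index=False)


def _script_region(
    cfg: SimConfig, rng: np.random.Generator, region_id: str, period: Period
) -> tuple[list[TractPeriodMeasures], dict, dict]:
    """One region-period: scripted measures plus intended labels."""
    n = cfg.tracts_per_region
    n_elig = n // 2
    n_gent = max(2, round(cfg.frac_gentrifying_of_eligible * n_elig))
    n_inelig = n - n_elig
    n_rural = max(1, round(cfg.frac_rural_of_ineligible * (n_inelig - 4)))

    scale = rng.uniform(0.8, 1.25)
    G = rng.uniform(*cfg.regional_growth_range)  # regional home-value drift
    B = cfg.regional_bachelors_drift
    rentG = 0.6 * G

    inc0, hv0, built, urban, bach0, li0 = (np.zeros(n) for _ in range(6))
    hv_growth = np.zeros(n)
    bach_pp = np.zeros(n)
    rent_growth = rentG + rng.uniform(-0.02, 0.02, n)
    li_end_delta = rng.uniform(0.0, 0.02, n)
    hh = rng.integers(800, 2500, n)
    loss = -rng.integers(0, 30, n)  # default: no loss of low-income households

    intended_f: dict[int, FreemanLabel] = {}
    intended_dg: dict[int, DGCategory] = {}

    # Home values are one smooth distribution across all tracts (they do
    # not enter Freeman eligibility), so the median-of-levels benchmark
    # change tracks the regional drift G to within a few points and the
    # scripted growth margins (+0.22 / -0.15) dominate it.
    hv0[:] = cfg.home_value_median * scale * np.exp(rng.normal(0.0, 0.25, n))
    hv_growth[:] = G + rng.uniform(-0.03, 0.03, n)

    # --- eligible block: ring positions 0 .. n_elig-1 ------------------
    elig = np.arange(n_elig)
    inc0[elig] = cfg.income_median * scale * rng.uniform(0.50, 0.85, n_elig)
    built[elig] = rng.uniform(0.05, 0.30, n_elig)
    urban[elig] = rng.uniform(0.55, 0.95, n_elig)
    bach0[elig] = rng.uniform(0.10, 0.30, n_elig)
    li0[elig] = rng.uniform(0.45, 0.70, n_elig)

    # gentrifying designates occupy one contiguous arc so that the
    # displacement designates further along the ring keep cold neighbors
    gent_idx = list(range(n_gent))  # 0=advanced, rest early-type
    at_risk_idx = n_gent
    ongoing_idx = n_gent + 2  # n_gent+1 is a cold buffer tract
    susceptible_idx = n_gent + 3

    for i in gent_idx:
        hv_growth[i] = G + 0.22 + rng.uniform(0, 0.04)
        bach0[i] = rng.uniform(0.10, 0.22)
        bach_pp[i] = 0.09 + rng.uniform(0, 0.02)
        intended_f[i] = FreemanLabel.ELIGIBLE_GENTRIFYING
    hv_growth[at_risk_idx] = G + 0.22 + rng.uniform(0, 0.04)
    bach_pp[at_risk_idx] = 0.0
    intended_f[at_risk_idx] = FreemanLabel.ELIGIBLE_NOT_GENTRIFYING
    intended_dg[at_risk_idx] = DGCategory.AT_RISK_OF_GENTRIFICATION
    for i in range(n_gent + 1, n_elig):
        hv_growth[i] = G - 0.15 - rng.uniform(0, 0.04)
        bach_pp[i] = 0.0
        intended_f[i] = FreemanLabel.ELIGIBLE_NOT_GENTRIFYING
    loss[ongoing_idx] = 60  # net loss of low-income households
    intended_dg[ongoing_idx] = DGCategory.ONGOING_DISPLACEMENT
    for i in range(susceptible_idx, n_elig):
        intended_dg[i] = DGCategory.LOW_INCOME_SUSCEPTIBLE

    # --- ineligible block: positions n_elig .. n-1 ---------------------
    stable_mod_idx = n_elig  # cold buffer adjacent to the eligible block
    at_risk_excl_idx = n_elig + 1
    becoming_idx = n_elig + 2
    stable_adv_idx = n_elig + 3
    others = list(range(n_elig + 4, n))
    rural = others[:n_rural]
    inelig = np.arange(n_elig, n)
    built[inelig] = rng.uniform(0.35, 0.70, n_inelig)
    urban[inelig] = rng.uniform(0.55, 0.95, n_inelig)
    bach0[inelig] = rng.uniform(0.34, 0.55, n_inelig)
    li0[inelig] = rng.uniform(0.10, 0.35, n_inelig)
    bach_pp[inelig] = B + rng.uniform(-0.01, 0.01, n_inelig)

    # rural tracts take the lowest ineligible incomes so that an odd-n
    # median falling on an ineligible tract is still excluded (urban)
    inc0[rural] = cfg.income_median * scale * rng.uniform(1.02, 1.15, len(rural))
    urban[rural] = rng.uniform(0.05, 0.45, len(rural))
    non_rural = [i for i in inelig if i not in rural]
    inc0[non_rural] = cfg.income_median * scale * rng.uniform(1.20, 1.90, len(non_rural))
    inc0[stable_adv_idx] = cfg.income_median * scale * 2.0
    for i in inelig:
        intended_f[i] = FreemanLabel.EXCLUDED

    li_end_delta[becoming_idx] = -0.05  # low-income share declining

    hv_end = hv0 * (1.0 + hv_growth)

    # cost clauses are set against the region's own provisional medians;
    # 15-40% margins dominate the small median drift the overrides cause
    med_start, med_end = float(np.median(hv0)), float(np.median(hv_end))
    hv0[stable_adv_idx] = 1.40 * med_start
    hv_end[stable_adv_idx] = hv0[stable_adv_idx] * (1.0 + G)
    hv0[becoming_idx] = 0.80 * med_start
    hv_end[becoming_idx] = 1.25 * med_end
    hv0[at_risk_excl_idx] = 0.80 * med_start
    hv_end[at_risk_excl_idx] = hv0[at_risk_excl_idx] * (1.0 + G + 0.22)
    hv0[stable_mod_idx] = 0.80 * med_start
    hv_end[stable_mod_idx] = hv0[stable_mod_idx] * (1.0 + G - 0.15)
    # early-type gentrifying designates must end below the regional
    # median value (otherwise they script as advanced)
    for i in gent_idx[1:]:
        hv0[i] = med_start * rng.uniform(0.50, 0.70)
        hv_end[i] = hv0[i] * (1.0 + hv_growth[i])
    hv0[0] = 0.70 * med_start  # advanced-gentrification designate
    hv_end[0] = 1.25 * med_end
    intended_dg[0] = DGCategory.ADVANCED_GENTRIFICATION
    for i in gent_idx[1:]:
        intended_dg[i] = DGCategory.EARLY_ONGOING_GENTRIFICATION
    intended_dg[stable_mod_idx] = DGCategory.STABLE_MODERATE_MIXED
    intended_dg[at_risk_excl_idx] = DGCategory.AT_RISK_BECOMING_EXCLUSIVE
    intended_dg[becoming_idx] = DGCategory.BECOMING_EXCLUSIVE
    intended_dg[stable_adv_idx] = DGCategory.STABLE_ADVANCED_EXCLUSIVE

    bach_end = np.clip(bach0 + bach_pp, 0.0, 1.0)
    li_end = np.clip(li0 + li_end_delta, 0.0, 1.0)
    rent0 = cfg.rent_median * scale * rng.uniform(0.7, 1.4, n)
    rent_end = rent0 * (1.0 + rent_growth)
    count0 = np.round(li0 * hh).astype(int)
    count_end = np.maximum(0, count0 - loss)

    tracts = []
    f_map, dg_map = {}, {}
    for i in range(n):
        tract_id = f"{region_id}-T{i:03d}"
        tracts.append(
            TractPeriodMeasures(
                tract_id=tract_id,
                region_id=region_id,
                period=period,
                urban_block_share=round(float(urban[i]), 6),
                median_hh_income_start=round(float(inc0[i]), 2),
                housing_built_prior_two_decades_share_start=round(float(built[i]), 6),
                median_home_value_start=round(float(hv0[i]), 2),
                median_home_value_end=round(float(hv_end[i]), 2),
                bachelors_share_start=round(float(bach0[i]), 6),
                bachelors_share_end=round(float(bach_end[i]), 6),
                median_rent_start=round(float(rent0[i]), 2),
                median_rent_end=round(float(rent_end[i]), 2),
                low_income_hh_count_start=int(count0[i]),
                low_income_hh_count_end=int(count_end[i]),
                low_income_hh_share_start=round(float(li0[i]), 6),
                low_income_hh_share_end=round(float(li_end[i]), 6),
            )
        )
        if i in intended_f:
            f_map[(tract_id, period.label)] = intended_f[i].value
        if i in intended_dg:
            dg_map[(tract_id, period.label)] = intended_dg[i].value
    return tracts, f_map, dg_map


def simulate_tracts(
    cfg: SimConfig,
) -> tuple[list[TractPeriodMeasures], dict[str, set[str]], SimTruth]:
    """Simulate tract measures for all regions and both periods.

    Returns the measures, a ring adjacency map per region, and the
    ground truth with intended labels for every scripted tract.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    tracts: list[TractPeriodMeasures] = []
    f_map: dict = {}
    dg_map: dict = {}
    adjacency: dict[str, set[str]] = {}
    for r in range(cfg.n_regions):
        region_id = f"R{r:02d}"
        for period in PERIODS:
            t, f, d = _script_region(cfg, rng, region_id, period)
            tracts.extend(t)
            f_map.update(f)
            dg_map.update(d)
        n = cfg.tracts_per_region
        for i in range(n):
            a = f"{region_id}-T{i:03d}"
            b = f"{region_id}-T{(i + 1) % n:03d}"
            adjacency.setdefault(a, set()).add(b)
            adjacency.setdefault(b, set()).add(a)
    truth = SimTruth(
        intended_freeman=f_map,
        intended_dg=dg_map,
        sigma_u=cfg.sigma_u,
        exposure_log_or=cfg.exposure_log_or,
        tract_intercepts={},
    )
    return tracts, adjacency, truth


def _draw_choice(rng, levels, probs, size):
    return rng.choice(np.asarray(levels, dtype=object), size=size, p=np.asarray(probs))


def simulate_births(
    cfg: SimConfig, labels: pd.DataFrame, truth: SimTruth
) -> pd.DataFrame:
    """Simulate the birth-record table given per-(tract, period) labels.

    ``labels`` must carry ``tract_id, period, freeman_label`` — the
    generating exposure is the Freeman label.  Outcomes are drawn from
    the random-intercept logistic model; gestational age and weight are
    sampled conditional on the latent preterm / growth-restriction
    draws so the derived flags match the latent ones.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    ref = default_growth_reference()
    lab = labels.set_index(["tract_id", "period"])["freeman_label"]
    tract_ids = sorted(set(labels["tract_id"]))

    u = {
        (t, oc): rng.normal(0.0, cfg.sigma_u)
        for t in tract_ids
        for oc in ("ptb", "sga")
    }
    truth.tract_intercepts = u

    races = list(cfg.race_mix)
    race_p = np.array([cfg.race_mix[r] for r in races])
    payers = list(cfg.payer_mix)
    payer_p = np.array([cfg.payer_mix[p] for p in payers])

    rows: list[dict] = []
    latents: list[dict] = []
    counter = 0
    all_years = np.array(sum((list(v) for v in YEARS_OF_PERIOD.values()), []))
    for tract in tract_ids:
        n_births = rng.poisson(cfg.births_per_tract_mean)
        if n_births == 0:
            continue
        years = rng.choice(all_years, size=n_births)
        race = _draw_choice(rng, races, race_p, n_births)
        other = rng.random(n_births) < cfg.race_other_rate
        race = np.where(other, "OTHER", race)
        age = np.clip(rng.normal(cfg.maternal_age_mean, cfg.maternal_age_sd, n_births), 14, 52)
        payer = _draw_choice(rng, payers, payer_p, n_births)
        primip = rng.random(n_births) < cfg.primiparous_rate
        care = rng.random(n_births) < cfg.adequate_care_rate
        sex = np.where(rng.random(n_births) < cfg.prop_female, "F", "M")

        for b in range(n_births):
            year = int(years[b])
            period = "2000-2010" if year <= 2011 else "2007-2017"
            level = lab.get((tract, period), "UNCLASSIFIABLE")
            birth_id = f"B{counter:07d}"
            counter += 1
            rec = {
                "birth_id": birth_id,
                "year": year,
                "tract_id": tract,
                "sex": str(sex[b]),
                "plurality": 1,
                "maternal_age": round(float(age[b]), 1),
                "race_ethnicity": str(race[b]),
                "payer": str(payer[b]),
                "primiparous": bool(primip[b]),
                "adequate_care": bool(care[b]),
            }
            lat = {"birth_id": birth_id}
            flags = {}
            for oc in ("ptb", "sga"):
                eta = cfg.baseline_logit[oc]
                eta += cfg.exposure_log_or[oc].get(level, 0.0)
                eta += cfg.race_log_or[oc].get(str(race[b]), 0.0)
                eta += cfg.interaction_log_or.get(oc, {}).get(str(race[b]), {}).get(level, 0.0)
                cov = cfg.covariate_log_or[oc]
                eta += cov["age_per_year"] * (float(age[b]) - cfg.maternal_age_mean)
                eta += cov.get(str(payer[b]), 0.0)
                eta += cov["primiparous"] * primip[b] + cov["adequate_care"] * care[b]
                eta += u[(tract, oc)]
                flags[oc] = rng.random() < 1.0 / (1.0 + np.exp(-eta))
                lat[f"eta_{oc}"] = round(float(eta), 6)
                lat[f"latent_{oc}"] = bool(flags[oc])
            if flags["ptb"]:
                week = int(rng.choice(_PTB_WEEKS, p=_PTB_W))
            else:
                week = int(rng.choice(_NONPTB_WEEKS, p=_NONPTB_W))
            # latent growth percentile; margins around 0.10 keep the
            # derived SGA flag consistent after rounding to grams
            q = rng.uniform(0.002, 0.098) if flags["sga"] else rng.uniform(0.102, 0.998)
            _, mean, sd = ref.lookup(rec["sex"], week)
            from scipy.stats import norm

            weight = max(120.0, mean + sd * norm.ppf(q))
            rec["gestational_age"] = week
            rec["birth_weight"] = int(round(weight))
            rows.append(rec)
            latents.append(lat)

    df = pd.DataFrame(rows)
    _inject_dirty(cfg, rng, df)
    df = df[list(BIRTH_COLUMNS)]
    truth.birth_latents = pd.DataFrame(latents)
    return df


def _inject_dirty(cfg: SimConfig, rng: np.random.Generator, df: pd.DataFrame) -> None:
    """In-place injection of at most one defect per record."""
    n = len(df)
    rates = [
        ("unlinkable", cfg.inject_unlinkable),
        ("ga", cfg.inject_implausible_ga),
        ("age", cfg.inject_implausible_age),
        ("weight", cfg.inject_implausible_weight),
        ("plural", cfg.inject_plural),
        ("missing", cfg.inject_missing_covariate),
    ]
    edges = np.cumsum([r for _, r in rates])
    if edges[-1] > 1.0:
        raise ValueError("injection rates sum above 1")
    roll = rng.random(n)
    kind = np.full(n, "", dtype=object)
    prev = 0.0
    for (name, _), edge in zip(rates, edges):
        kind[(roll >= prev) & (roll < edge)] = name
        prev = edge
    df["maternal_age"] = df["maternal_age"].astype(float)
    df["birth_weight"] = df["birth_weight"].astype(float)
    for i in np.flatnonzero(kind == "unlinkable"):
        df.iat[i, df.columns.get_loc("tract_id")] = "UNLINKED"
    for i in np.flatnonzero(kind == "ga"):
        df.iat[i, df.columns.get_loc("gestational_age")] = int(rng.choice([18, 20, 21, 46, 50]))
    for i in np.flatnonzero(kind == "age"):
        df.iat[i, df.columns.get_loc("maternal_age")] = float(rng.choice([8.0, 9.0, 63.0, 70.0]))
    for i in np.flatnonzero(kind == "weight"):
        df.iat[i, df.columns.get_loc("birth_weight")] = float(rng.choice([50.0, 80.0, 9300.0]))
    for i in np.flatnonzero(kind == "plural"):
        df.iat[i, df.columns.get_loc("plurality")] = int(rng.choice([2, 2, 2, 3]))
    missing_rows = np.flatnonzero(kind == "missing")
    if len(missing_rows):
        df["adequate_care"] = df["adequate_care"].astype(object)
        for i in missing_rows:
            col = str(rng.choice(["payer", "maternal_age", "adequate_care"]))
            df.iat[i, df.columns.get_loc(col)] = np.nan


def simulate_clustered_binary(
    n_clusters: int,
    n_per_cluster: int,
    *,
    log_or: float,
    sigma_u: float,
    baseline_logit: float,
    rng: np.random.Generator,
    exposure_rate: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Minimal clustered-binary generator for estimator validation.

    A cluster-level binary exposure and a cluster random intercept feed
    logit P(y=1) = baseline + log_or * x + u.  Returns (y, x, groups).
    """
    x_cluster = rng.binomial(1, exposure_rate, n_clusters).astype(float)
    u_cluster = rng.normal(0.0, sigma_u, n_clusters) if sigma_u > 0 else np.zeros(n_clusters)
    groups = np.repeat(np.arange(n_clusters), n_per_cluster)
    x = x_cluster[groups]
    eta = baseline_logit + log_or * x + u_cluster[groups]
    y = rng.binomial(1, 1.0 / (1.0 + np.exp(-eta))).astype(float)
    return y, x, groups


FIXTURES = {
    "tiny": dict(n_regions=2, tracts_per_region=12, births_per_tract_mean=50.0),
    "standard": dict(n_regions=10, tracts_per_region=30, births_per_tract_mean=150.0),
    "stress": dict(n_regions=20, tracts_per_region=40, births_per_tract_mean=250.0),
}
_STRESS_CAP = 250_000  # total birth records


def make_fixture(
    name: str, out_dir: str | Path, *, seed: int | None = None, **overrides
) -> SimConfig:
    """Write a named synthetic dataset (tiny / standard / stress) to disk.

    Emits ``tracts_<period>.csv``, ``regions.csv``, ``adjacency.csv``,
    ``births.csv`` and the ground-truth files, in exactly the formats
    the reader functions consume.
    """
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; choose from {sorted(FIXTURES)}")
    params = dict(FIXTURES[name])
    params.update(overrides)
    if seed is not None:
        params["seed"] = seed
    cfg = SimConfig(**params)
    if name == "stress":
        expected = cfg.n_regions * cfg.tracts_per_region * cfg.births_per_tract_mean
        if expected > _STRESS_CAP:
            raise ValueError(f"stress fixture would exceed the {_STRESS_CAP}-record cap")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    tracts, adjacency, truth = simulate_tracts(cfg)
    from .census import summarize_all_regions
    from .classify import ClassifierThresholds, label_tracts

    frames = []
    for period in PERIODS:
        sub = [t for t in tracts if t.period.label == period.label]
        write_tract_measures(sub, out / f"tracts_{period.label}.csv")
        summaries = summarize_all_regions(sub, period)
        frames.append(label_tracts(sub, summaries, ClassifierThresholds(), adjacency))
    labels = pd.concat(frames, ignore_index=True)

    births = simulate_births(cfg, labels, truth)
    births.to_csv(out / "births.csv", index=False)
    pd.DataFrame(
        sorted({(t.tract_id, t.region_id) for t in tracts}),
        columns=["tract_id", "region_id"],
    ).to_csv(out / "regions.csv", index=False)
    pd.DataFrame(
        [(a, b) for a, nbs in sorted(adjacency.items()) for b in sorted(nbs) if a < b],
        columns=["tract_id", "neighbor_tract_id"],
    ).to_csv(out / "adjacency.csv", index=False)
    truth.save(out)
    (out / "sim_config.json").write_text(
        json.dumps({k: v for k, v in asdict(cfg).items()}, indent=2, default=float)
    )
    return cfg
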