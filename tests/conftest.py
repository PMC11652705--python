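from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from gentbirth.census import Period, RegionPeriodSummary, TractPeriodMeasures
from gentbirth.classify import ClassifierThresholds
from gentbirth.simulate import PERIODS, SimConfig, make_fixture

PERIOD1 = PERIODS[0]


def random_tract(rng: np.random.Generator, i: int, period: Period = PERIOD1,
                 *, allow_missing: bool = True) -> TractPeriodMeasures:
    """A fully random tract, occasionally with missing optional fields."""

    def maybe(value, p=0.1):
        return None if (allow_missing and rng.random() < p) else value

    return TractPeriodMeasures(
        tract_id=f"T{i:05d}",
        region_id="R",
        period=period,
        urban_block_share=maybe(float(rng.uniform(0, 1)), 0.05),
        median_hh_income_start=maybe(float(rng.uniform(20_000, 150_000)), 0.05),
        housing_built_prior_two_decades_share_start=maybe(float(rng.uniform(0, 1)), 0.05),
        median_home_value_start=float(rng.uniform(80_000, 900_000)),
        median_home_value_end=float(rng.uniform(80_000, 1_100_000)),
        bachelors_share_start=maybe(float(rng.uniform(0, 0.8))),
        bachelors_share_end=maybe(float(rng.uniform(0, 0.9))),
        median_rent_start=maybe(float(rng.uniform(500, 3_000))),
        median_rent_end=maybe(float(rng.uniform(500, 4_000))),
        low_income_hh_count_start=int(rng.integers(0, 2_000)),
        low_income_hh_count_end=int(rng.integers(0, 2_000)),
        low_income_hh_share_start=maybe(float(rng.uniform(0, 1)), 0.08),
        low_income_hh_share_end=maybe(float(rng.uniform(0, 1)), 0.08),
    )


def random_summary(rng: np.random.Generator, period: Period = PERIOD1) -> RegionPeriodSummary:
    return RegionPeriodSummary(
        region_id="R",
        period=period,
        n_tracts=100,
        median_income=float(rng.uniform(40_000, 90_000)),
        median_housing_built_share=float(rng.uniform(0.2, 0.6)),
        home_value_pct_change=float(rng.uniform(0.0, 0.5)),
        bachelors_pp_change=float(rng.uniform(-0.02, 0.08)),
        median_home_value_start=float(rng.uniform(200_000, 500_000)),
        median_home_value_end=float(rng.uniform(250_000, 650_000)),
        appreciation_p75=float(rng.uniform(0.1, 0.6)),
        rent_pct_change=float(rng.uniform(0.0, 0.3)),
        low_income_share=float(rng.uniform(0.2, 0.6)),
    )


@pytest.fixture(scope="session")
def thresholds() -> ClassifierThresholds:
    return ClassifierThresholds()


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory) -> Path:
    """The tiny synthetic dataset written to disk once per session."""
    out = tmp_path_factory.mktemp("tiny")
    make_fixture("tiny", out, seed=20240901)
    return out


@pytest.fixture(scope="session")
def tiny_cohort(tiny_dataset) -> pd.DataFrame:
    """Tiny dataset pushed through classification, exclusions and
    outcome derivation."""
    from gentbirth.census import read_tract_measures, summarize_all_regions
    from gentbirth.census import read_adjacency
    from gentbirth.classify import label_tracts
    from gentbirth.cohort import apply_exclusions, derive_outcomes_frame, read_births
    from gentbirth.simulate import default_growth_reference

    adjacency = read_adjacency(tiny_dataset / "adjacency.csv")
    frames = []
    for period in PERIODS:
        tracts = read_tract_measures(tiny_dataset / f"tracts_{period.label}.csv", period)
        summaries = summarize_all_regions(tracts, period)
        frames.append(label_tracts(tracts, summaries, ClassifierThresholds(), adjacency))
    labels = pd.concat(frames, ignore_index=True)
    births = read_births(tiny_dataset / "births.csv")
    cohort, report = apply_exclusions(births, labels)
    cohort = derive_outcomes_frame(cohort, default_growth_reference())
    cohort.attrs["report"] = report
    cohort.attrs["labels"] = labels
    cohort.attrs["births"] = births
    return cohort
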