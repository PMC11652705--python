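"""Analytic birth cohort construction.

Birth records arrive as a table (one row per birth) and pass through a
fixed exclusion cascade before any outcome is derived:

1. not linkable to a labelled census tract,
2. implausible gestational age (< 22 or > 45 completed weeks),
3. implausible maternal age (< 10 or > 60 years),
4. implausible birth weight (< 100 g or > 9000 g),
5. plural birth,
6. missing exposure, outcome or covariate information,
7. race/ethnicity reported as "Other" or mixed.

A record violating several rules is attributed to the first failing
rule, so the report reads like a CONSORT flow: input n equals the
survivors plus the per-rule removals.

Outcomes are derived per record against a sex-by-gestational-week
growth reference: preterm (PTB, after 24 and before 37 completed
weeks), very preterm (VPTB, before 32 weeks), small-for-gestational-age
(SGA, weight strictly below the sex-specific 10th percentile), low
birth weight (LBW, strictly below 2500 g), the birth-weight z-score,
and term birth weight for births of 37–44 weeks.

Each birth links to the gentrification measurement period whose start
lies five or more years before the birth year: births 2005–2011 to the
2000–2010 period and births 2012–2017 to the 2007–2017 period.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RACE_LEVELS",
    "PAYER_LEVELS",
    "BIRTH_COLUMNS",
    "GrowthReference",
    "ExclusionReport",
    "link_exposure",
    "apply_exclusions",
    "derive_outcomes",
    "derive_outcomes_frame",
    "build_reference_from_cohort",
    "read_births",
    "write_births",
]

RACE_LEVELS = ("BLACK", "AIAN", "API", "HISPANIC", "WHITE", "OTHER")
PAYER_LEVELS = ("PUBLIC", "PRIVATE", "UNINSURED_OTHER")

BIRTH_COLUMNS = (
    "birth_id",
    "year",
    "tract_id",
    "gestational_age",
    "birth_weight",
    "sex",
    "plurality",
    "maternal_age",
    "race_ethnicity",
    "payer",
    "primiparous",
    "adequate_care",
)

COVARIATE_COLUMNS = ("maternal_age", "payer", "primiparous", "adequate_care")

# Period linkage: five-year lag from period start to the earliest
# linked birth year.
PERIOD_OF_YEAR = {y: "2000-2010" for y in range(2005, 2012)}
PERIOD_OF_YEAR.update({y: "2007-2017" for y in range(2012, 2018)})


def link_exposure(year: int) -> str:
    """Measurement period label for a birth year (2005–2017)."""
    try:
        return PERIOD_OF_YEAR[int(year)]
    except (KeyError, ValueError):
        raise ValueError(f"birth year {year!r} outside the linkable range 2005-2017") from None


class GrowthReference:
    """Sex-specific weight-for-gestational-age reference.

    Holds, per (sex, completed week), the 10th-percentile weight used
    for the SGA flag and the mean/SD used for the birth-weight z-score.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"sex", "week", "p10_g", "mean_g", "sd_g"}
        missing = required.difference(table.columns)
        if missing:
            raise ValueError(f"growth reference missing column(s) {sorted(missing)}")
        bad = table[(table["p10_g"] >= table["mean_g"]) | (table["sd_g"] <= 0)]
        if len(bad):
            raise ValueError(
                "growth reference violates p10 < mean or sd > 0 at rows "
                f"{bad.index.tolist()}"
            )
        self.table = table.set_index(["sex", "week"]).sort_index()

    @classmethod
    def from_csv(cls, path: str | Path) -> "GrowthReference":
        return cls(pd.read_csv(path))

    def lookup(self, sex: str, week: int) -> tuple[float, float, float]:
        """Return (p10, mean, sd) in grams; KeyError if uncovered."""
        row = self.table.loc[(sex, int(week))]
        return float(row["p10_g"]), float(row["mean_g"]), float(row["sd_g"])

    def covers(self, sex: str, week: int) -> bool:
        return (sex, int(week)) in self.table.index


@dataclass
class ExclusionReport:
    """Per-rule removal counts, in cascade order."""

    n_input: int = 0
    unlinkable_tract: int = 0
    implausible_gestational_age: int = 0
    implausible_maternal_age: int = 0
    implausible_birth_weight: int = 0
    plural_birth: int = 0
    missing_exposure_outcome_covariate: int = 0
    race_other_or_mixed: int = 0
    n_final: int = 0

    RULES = (
        "unlinkable_tract",
        "implausible_gestational_age",
        "implausible_maternal_age",
        "implausible_birth_weight",
        "plural_birth",
        "missing_exposure_outcome_covariate",
        "race_other_or_mixed",
    )

    def total_removed(self) -> int:
        return sum(getattr(self, r) for r in self.RULES)

    def to_dict(self) -> dict:
        d = {"n_input": self.n_input}
        d.update({r: getattr(self, r) for r in self.RULES})
        d["n_final"] = self.n_final
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _first_failing_rule(row: pd.Series, linkable: bool, exposure_missing: bool) -> str | None:
    ga, age, bw = row["gestational_age"], row["maternal_age"], row["birth_weight"]
    if not linkable:
        return "unlinkable_tract"
    if pd.isna(ga) or ga < 22 or ga > 45:
        return "implausible_gestational_age"
    if pd.isna(age) or age < 10 or age > 60:
        return "implausible_maternal_age"
    if pd.isna(bw) or bw < 100 or bw > 9000:
        return "implausible_birth_weight"
    if pd.isna(row["plurality"]) or row["plurality"] != 1:
        return "plural_birth"
    if (
        exposure_missing
        or pd.isna(row["sex"])
        or any(pd.isna(row[c]) for c in COVARIATE_COLUMNS)
    ):
        return "missing_exposure_outcome_covariate"
    if pd.isna(row["race_ethnicity"]) or row["race_ethnicity"] == "OTHER":
        return "race_other_or_mixed"
    return None


def apply_exclusions(
    records: pd.DataFrame, labels: pd.DataFrame
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the exclusion cascade and link exposures.

    ``labels`` is the classifier output with columns ``tract_id,
    period, freeman_label, dg_stage``.  A tract absent from the label
    table is unlinkable; a tract whose linked-period label is
    UNCLASSIFIABLE counts as missing exposure.  Survivors gain
    ``period``, ``freeman_label`` and ``dg_stage`` columns.
    """
    report = ExclusionReport(n_input=len(records))
    lab = labels.set_index(["tract_id", "period"])
    labelled_tracts = set(labels["tract_id"])

    keep_idx: list = []
    freeman_col: list[str] = []
    stage_col: list[str] = []
    period_col: list[str] = []
    for idx, row in records.iterrows():
        tract = row["tract_id"]
        year = row["year"]
        linkable = (
            not pd.isna(tract)
            and tract in labelled_tracts
            and not pd.isna(year)
            and int(year) in PERIOD_OF_YEAR
        )
        exposure_missing = True
        freeman = stage = period = None
        if linkable:
            period = PERIOD_OF_YEAR[int(year)]
            try:
                lrow = lab.loc[(tract, period)]
            except KeyError:
                linkable = False
            else:
                freeman, stage = lrow["freeman_label"], lrow["dg_stage"]
                exposure_missing = (
                    freeman == "UNCLASSIFIABLE" or stage == "UNCLASSIFIABLE"
                )
        rule = _first_failing_rule(row, linkable, exposure_missing)
        if rule is None:
            keep_idx.append(idx)
            freeman_col.append(freeman)
            stage_col.append(stage)
            period_col.append(period)
        else:
            setattr(report, rule, getattr(report, rule) + 1)

    cohort = records.loc[keep_idx].copy()
    cohort["period"] = period_col
    cohort["freeman_label"] = freeman_col
    cohort["dg_stage"] = stage_col
    report.n_final = len(cohort)
    assert report.n_input == report.n_final + report.total_removed()
    return cohort, report


def derive_outcomes(
    gestational_age: int,
    birth_weight: float,
    sex: str,
    ref: GrowthReference,
    *,
    ptb_lower_inclusive: bool = False,
) -> dict:
    """Outcome flags and continuous measures for one birth.

    PTB spans completed weeks 25–36 by default ("after 24 and before
    37"); with ``ptb_lower_inclusive`` week 24 also counts.  VPTB spans
    the same lower bound to week 31.  SGA and LBW use strict
    less-than comparisons, so a weight exactly at the 10th percentile
    or exactly 2500 g is not flagged.
    """
    ga = int(gestational_age)
    lower = 24 if ptb_lower_inclusive else 25
    ptb = lower <= ga <= 36
    vptb = lower <= ga <= 31
    if not ref.covers(sex, ga):
        raise KeyError(f"growth reference does not cover sex={sex!r}, week={ga}")
    p10, mean, sd = ref.lookup(sex, ga)
    return {
        "ptb": ptb,
        "vptb": vptb,
        "sga": birth_weight < p10,
        "lbw": birth_weight < 2500.0,
        "bw_zscore": (birth_weight - mean) / sd,
        "term_bw": float(birth_weight) if 37 <= ga <= 44 else np.nan,
    }


def derive_outcomes_frame(
    cohort: pd.DataFrame, ref: GrowthReference, *, ptb_lower_inclusive: bool = False
) -> pd.DataFrame:
    """Vectorised :func:`derive_outcomes` over an analytic cohort."""
    ga = cohort["gestational_age"].astype(int).to_numpy()
    bw = cohort["birth_weight"].astype(float).to_numpy()
    lower = 24 if ptb_lower_inclusive else 25
    key = pd.MultiIndex.from_arrays([cohort["sex"], ga], names=["sex", "week"])
    missing = ~key.isin(ref.table.index)
    if missing.any():
        bad = sorted(set(key[missing]))
        raise KeyError(f"growth reference does not cover cells {bad[:5]}")
    rows = ref.table.loc[key]
    p10 = rows["p10_g"].to_numpy()
    mean = rows["mean_g"].to_numpy()
    sd = rows["sd_g"].to_numpy()
    out = cohort.copy()
    out["ptb"] = (ga >= lower) & (ga <= 36)
    out["vptb"] = (ga >= lower) & (ga <= 31)
    out["sga"] = bw < p10
    out["lbw"] = bw < 2500.0
    out["bw_zscore"] = (bw - mean) / sd
    out["term_bw"] = np.where((ga >= 37) & (ga <= 44), bw, np.nan)
    return out


def build_reference_from_cohort(
    records: pd.DataFrame, *, min_cell: int = 20
) -> GrowthReference:
    """Empirical growth reference from observed births.

    Per (sex, completed week) cell the 10th percentile uses the
    lower-order-statistic (type-1, inverted-CDF) quantile.  Cells with
    fewer than ``min_cell`` births borrow the pooled-sex cell for that
    week, with a warning; a week empty in both sexes errors out.
    """
    df = records[["sex", "gestational_age", "birth_weight"]].dropna()
    df = df.assign(week=df["gestational_age"].astype(int))
    rows = []
    weeks = sorted(df["week"].unique())
    for week in weeks:
        pooled = df.loc[df["week"] == week, "birth_weight"].to_numpy(dtype=float)
        for sex in ("F", "M"):
            cell = df.loc[(df["week"] == week) & (df["sex"] == sex), "birth_weight"]
            values = cell.to_numpy(dtype=float)
            if len(values) < min_cell:
                if len(pooled) < max(min_cell, 2):
                    raise ValueError(
                        f"week {week}: too few births ({len(pooled)}) even pooling sexes"
                    )
                warnings.warn(
                    f"growth reference cell (sex={sex}, week={week}) has "
                    f"{len(values)} births; borrowing pooled-sex cell",
                    stacklevel=2,
                )
                values = pooled
            sd = float(np.std(values, ddof=1))
            if sd <= 0:
                raise ValueError(f"degenerate cell (sex={sex}, week={week}): sd = 0")
            rows.append(
                {
                    "sex": sex,
                    "week": week,
                    "p10_g": float(np.quantile(values, 0.10, method="inverted_cdf")),
                    "mean_g": float(np.mean(values)),
                    "sd_g": sd,
                }
            )
    return GrowthReference(pd.DataFrame(rows))


def read_births(path: str | Path) -> pd.DataFrame:
    """Read a births CSV, preserving missingness for the cascade."""
    df = pd.read_csv(
        path,
        dtype={
            "birth_id": str,
            "tract_id": str,
            "sex": str,
            "race_ethnicity": str,
            "payer": str,
        },
    )
    missing = [c for c in BIRTH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing birth column(s) {missing}")
    for col in ("primiparous", "adequate_care"):
        df[col] = df[col].map(
            {True: True, False: False, "True": True, "False": False, 1: True, 0: False,
             "1": True, "0": False}
        )
    return df


def write_births(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False)
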