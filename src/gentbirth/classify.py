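"""Neighborhood-change classifiers.

Two exposure-assessment methodologies are implemented:

**Freeman method** — a tract is *eligible* for gentrification when it is
urban (at least half its census blocks urban) and sits at or below the
regional medians of household income and of housing built in the prior
two decades; an eligible tract is *gentrifying* when both its home-value
percent change and its bachelor's-degree percentage-point change exceed
the corresponding regional change, strictly (ties are not gentrifying).
Everything else is excluded (ineligible).

**Displacement & Gentrification (D&G) typology** — nine categories built
around housing affordability for low-income households, collapsed to
three stages: displacement, gentrification, exclusive.  The category
rules form an explicit precedence table (see :func:`classify_dg_category`)
over boolean clauses: whether the tract is low-income relative to its
region, whether home values / rents / education outpace the region,
whether the tract ends the period high-cost, whether low-income
households were lost, and whether the tract sits next to a "hot"
(top-quartile appreciation) housing market.  The in-migration clause of
the original "Becoming exclusive" category is deliberately omitted.

Tracts missing a required input are UNCLASSIFIABLE — reported, never
folded into a referent group.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .census import (
    RegionPeriodSummary,
    TractChange,
    TractPeriodMeasures,
    compute_tract_change,
)

__all__ = [
    "FreemanLabel",
    "DGCategory",
    "DGStage",
    "ClassifierThresholds",
    "classify_freeman",
    "classify_dg_category",
    "collapse_dg_stage",
    "hot_market_flag",
    "label_tracts",
    "crosstab_labels",
    "write_labels",
    "read_labels",
]


class FreemanLabel(str, Enum):
    ELIGIBLE_NOT_GENTRIFYING = "ELIGIBLE_NOT_GENTRIFYING"
    ELIGIBLE_GENTRIFYING = "ELIGIBLE_GENTRIFYING"
    EXCLUDED = "EXCLUDED"
    UNCLASSIFIABLE = "UNCLASSIFIABLE"


class DGCategory(str, Enum):
    LOW_INCOME_SUSCEPTIBLE = "LOW_INCOME_SUSCEPTIBLE"
    ONGOING_DISPLACEMENT = "ONGOING_DISPLACEMENT"
    AT_RISK_OF_GENTRIFICATION = "AT_RISK_OF_GENTRIFICATION"
    EARLY_ONGOING_GENTRIFICATION = "EARLY_ONGOING_GENTRIFICATION"
    ADVANCED_GENTRIFICATION = "ADVANCED_GENTRIFICATION"
    STABLE_MODERATE_MIXED = "STABLE_MODERATE_MIXED"
    AT_RISK_BECOMING_EXCLUSIVE = "AT_RISK_BECOMING_EXCLUSIVE"
    BECOMING_EXCLUSIVE = "BECOMING_EXCLUSIVE"
    STABLE_ADVANCED_EXCLUSIVE = "STABLE_ADVANCED_EXCLUSIVE"
    UNCLASSIFIABLE = "UNCLASSIFIABLE"


class DGStage(str, Enum):
    DISPLACEMENT = "DISPLACEMENT"
    GENTRIFICATION = "GENTRIFICATION"
    EXCLUSIVE = "EXCLUSIVE"
    UNCLASSIFIABLE = "UNCLASSIFIABLE"


_STAGE_OF_CATEGORY: dict[DGCategory, DGStage] = {
    DGCategory.LOW_INCOME_SUSCEPTIBLE: DGStage.DISPLACEMENT,
    DGCategory.ONGOING_DISPLACEMENT: DGStage.DISPLACEMENT,
    DGCategory.AT_RISK_OF_GENTRIFICATION: DGStage.GENTRIFICATION,
    DGCategory.EARLY_ONGOING_GENTRIFICATION: DGStage.GENTRIFICATION,
    DGCategory.ADVANCED_GENTRIFICATION: DGStage.GENTRIFICATION,
    DGCategory.STABLE_MODERATE_MIXED: DGStage.EXCLUSIVE,
    DGCategory.AT_RISK_BECOMING_EXCLUSIVE: DGStage.EXCLUSIVE,
    DGCategory.BECOMING_EXCLUSIVE: DGStage.EXCLUSIVE,
    DGCategory.STABLE_ADVANCED_EXCLUSIVE: DGStage.EXCLUSIVE,
    DGCategory.UNCLASSIFIABLE: DGStage.UNCLASSIFIABLE,
}


@dataclass(frozen=True)
class ClassifierThresholds:
    """Tunable comparator margins and cutoffs, serialized with outputs.

    ``urban_share_min`` is the Freeman urbanicity floor (half the
    tract's blocks urban).  ``hot_market_quantile`` sets the regional
    appreciation percentile that marks a hot market.
    ``low_income_loss_min`` is the minimum net loss of low-income
    households counted as ongoing displacement.
    ``high_cost_multiplier`` scales the regional median end home value
    in the "high-cost at period end" clause.  The ``*_margin`` fields
    are additive slacks on the strict tract-versus-region comparisons
    (zero by default, i.e. any strict excess counts).
    """

    urban_share_min: float = 0.5
    low_income_cutoff_frac_of_region_median: float = 0.8
    hot_market_quantile: float = 0.75
    low_income_loss_min: int = 1
    high_cost_multiplier: float = 1.0
    appreciation_margin: float = 0.0
    education_margin: float = 0.0
    rent_margin: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.urban_share_min <= 1.0):
            raise ValueError("urban_share_min must lie in [0, 1]")
        if not (0.0 < self.hot_market_quantile < 1.0):
            raise ValueError("hot_market_quantile must lie in (0, 1)")
        if self.low_income_loss_min < 0:
            raise ValueError("low_income_loss_min must be non-negative")
        if self.high_cost_multiplier <= 0:
            raise ValueError("high_cost_multiplier must be positive")

    def digest(self) -> str:
        """Short stable hash, embedded in outputs for provenance."""
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ClassifierThresholds":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def classify_freeman(
    t: TractPeriodMeasures,
    tc: TractChange,
    r: RegionPeriodSummary,
    th: ClassifierThresholds = ClassifierThresholds(),
) -> FreemanLabel:
    """Freeman three-class label for one tract-period.

    Eligibility comparators are "lower than or equal to" the regional
    medians; growth comparators are strictly "larger than" the regional
    change, so a tract exactly matching the regional change is not
    gentrifying.
    """
    required = (
        t.urban_block_share,
        t.median_hh_income_start,
        t.housing_built_prior_two_decades_share_start,
    )
    if any(v is None for v in required):
        return FreemanLabel.UNCLASSIFIABLE
    if (
        t.urban_block_share < th.urban_share_min
        or t.median_hh_income_start > r.median_income
        or t.housing_built_prior_two_decades_share_start > r.median_housing_built_share
    ):
        return FreemanLabel.EXCLUDED
    if tc.home_value_pct_change is None or tc.bachelors_pp_change is None:
        return FreemanLabel.UNCLASSIFIABLE
    gentrifying = (
        tc.home_value_pct_change > r.home_value_pct_change + th.appreciation_margin
        and tc.bachelors_pp_change > r.bachelors_pp_change + th.education_margin
    )
    return (
        FreemanLabel.ELIGIBLE_GENTRIFYING
        if gentrifying
        else FreemanLabel.ELIGIBLE_NOT_GENTRIFYING
    )


def hot_market_flag(
    tract_id: str,
    changes: Mapping[str, TractChange],
    adjacency: Mapping[str, set[str]] | None,
    r: RegionPeriodSummary,
    th: ClassifierThresholds = ClassifierThresholds(),
) -> bool:
    """True when the tract borders (or, without adjacency, is itself)
    a top-quartile-appreciation housing market in its region.

    Neighbors with missing change values are treated as not hot.
    """
    if tract_id not in changes:
        raise KeyError(f"tract {tract_id!r} absent from change table")
    if adjacency is None:
        own = changes[tract_id].home_value_pct_change
        return own is not None and own >= r.appreciation_p75
    for nb in adjacency.get(tract_id, ()):
        c = changes.get(nb)
        if c is not None and c.home_value_pct_change is not None:
            if c.home_value_pct_change >= r.appreciation_p75:
                return True
    return False


def classify_dg_category(
    t: TractPeriodMeasures,
    tc: TractChange,
    r: RegionPeriodSummary,
    hot: bool,
    th: ClassifierThresholds = ClassifierThresholds(),
) -> DGCategory:
    """D&G typology category via an exhaustive precedence table.

    Boolean clauses (missing optional inputs evaluate ``False``):

    * ``LI`` — tract low-income at period start: low-income household
      share above the regional share.
    * ``APP`` — home-value % change above the regional change.
    * ``RENT`` — rent % change above the regional change.
    * ``GENTRY`` — bachelor's pp change above the regional change.
    * ``COSTHIGH_START`` / ``COSTHIGH_END`` — home value above the
      regional median (times ``high_cost_multiplier``) at start / end.
    * ``LOSS`` — net loss of low-income households at or above the
      configured minimum.
    * ``HOT`` — the spatial hot-market flag.

    Low-income tracts: advanced gentrification when education and home
    values outpace the region and the tract ends high-cost; early /
    ongoing gentrification when education outpaces with appreciating
    values or rents; at risk of gentrification under market pressure
    (hot or appreciating); ongoing displacement when low-income
    households are being lost; otherwise susceptible.

    Non-low-income tracts: stable/advanced exclusive when persistently
    high-cost and high-income; becoming exclusive when ending high-cost
    with above-regional appreciation and a declining low-income share;
    at risk of becoming exclusive when appreciating; otherwise stable
    moderate / mixed income.
    """
    if t.low_income_hh_share_start is None or r.low_income_share is None:
        return DGCategory.UNCLASSIFIABLE
    if tc.home_value_pct_change is None or tc.bachelors_pp_change is None:
        return DGCategory.UNCLASSIFIABLE

    li = t.low_income_hh_share_start > r.low_income_share
    app = tc.home_value_pct_change > r.home_value_pct_change + th.appreciation_margin
    rent = (
        tc.rent_pct_change is not None
        and r.rent_pct_change is not None
        and tc.rent_pct_change > r.rent_pct_change + th.rent_margin
    )
    gentry = tc.bachelors_pp_change > r.bachelors_pp_change + th.education_margin
    cost_end = (
        t.median_home_value_end is not None
        and t.median_home_value_end > th.high_cost_multiplier * r.median_home_value_end
    )
    cost_start = (
        t.median_home_value_start is not None
        and t.median_home_value_start > th.high_cost_multiplier * r.median_home_value_start
    )
    loss = (
        tc.low_income_hh_loss is not None
        and tc.low_income_hh_loss >= th.low_income_loss_min
    )
    income_high = (
        t.median_hh_income_start is not None
        and t.median_hh_income_start > r.median_income
    )
    li_share_declining = (
        t.low_income_hh_share_start is not None
        and t.low_income_hh_share_end is not None
        and t.low_income_hh_share_end < t.low_income_hh_share_start
    )

    if li:
        if gentry and app and cost_end:
            return DGCategory.ADVANCED_GENTRIFICATION
        if gentry and (app or rent):
            return DGCategory.EARLY_ONGOING_GENTRIFICATION
        if hot or app:
            return DGCategory.AT_RISK_OF_GENTRIFICATION
        if loss:
            return DGCategory.ONGOING_DISPLACEMENT
        return DGCategory.LOW_INCOME_SUSCEPTIBLE
    if cost_start and cost_end and income_high:
        return DGCategory.STABLE_ADVANCED_EXCLUSIVE
    if cost_end and app and li_share_declining:
        return DGCategory.BECOMING_EXCLUSIVE
    if app:
        return DGCategory.AT_RISK_BECOMING_EXCLUSIVE
    return DGCategory.STABLE_MODERATE_MIXED


def collapse_dg_stage(c: DGCategory) -> DGStage:
    """Collapse the nine categories into displacement (2),
    gentrification (3) and exclusive (4) stages."""
    return _STAGE_OF_CATEGORY[c]


def label_tracts(
    tracts: Sequence[TractPeriodMeasures],
    summaries: Mapping[str, RegionPeriodSummary],
    th: ClassifierThresholds = ClassifierThresholds(),
    adjacency: Mapping[str, set[str]] | None = None,
) -> pd.DataFrame:
    """Label every tract with both classifiers.

    Returns a frame with columns ``tract_id, region_id, period,
    freeman_label, dg_category, dg_stage, thresholds_hash``.
    """
    changes = {t.tract_id: compute_tract_change(t) for t in tracts}
    rows = []
    for t in tracts:
        r = summaries[t.region_id]
        tc = changes[t.tract_id]
        freeman = classify_freeman(t, tc, r, th)
        hot = hot_market_flag(t.tract_id, changes, adjacency, r, th)
        cat = classify_dg_category(t, tc, r, hot, th)
        rows.append(
            {
                "tract_id": t.tract_id,
                "region_id": t.region_id,
                "period": t.period.label,
                "freeman_label": freeman.value,
                "dg_category": cat.value,
                "dg_stage": collapse_dg_stage(cat).value,
                "thresholds_hash": th.digest(),
            }
        )
    return pd.DataFrame(rows)


def crosstab_labels(
    freeman: Mapping[str, FreemanLabel], dg: Mapping[str, DGStage]
) -> dict:
    """Cross-tabulate Freeman labels against D&G stages.

    Returns the contingency table plus the two directional overlap
    percentages among gentrifying tracts: the share of
    Freeman-gentrifying tracts also D&G-gentrifying and vice versa.
    """
    fset, dset = set(freeman), set(dg)
    if fset != dset:
        diff = sorted(fset.symmetric_difference(dset))
        raise ValueError(f"tract sets differ; symmetric difference: {diff}")
    table = pd.crosstab(
        pd.Series({k: v.value for k, v in freeman.items()}, name="freeman"),
        pd.Series({k: v.value for k, v in dg.items()}, name="dg_stage"),
    )
    f_gent = {k for k, v in freeman.items() if v is FreemanLabel.ELIGIBLE_GENTRIFYING}
    d_gent = {k for k, v in dg.items() if v is DGStage.GENTRIFICATION}
    both = f_gent & d_gent
    return {
        "table": table,
        "n_freeman_gentrifying": len(f_gent),
        "n_dg_gentrifying": len(d_gent),
        "n_both": len(both),
        "pct_of_freeman_also_dg": 100.0 * len(both) / len(f_gent) if f_gent else float("nan"),
        "pct_of_dg_also_freeman": 100.0 * len(both) / len(d_gent) if d_gent else float("nan"),
    }


def write_labels(labels: pd.DataFrame, path: str | Path) -> None:
    labels.to_csv(path, index=False)


def read_labels(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    required = {"tract_id", "period", "freeman_label", "dg_stage"}
    missing = required.difference(df.columns)
    if missing:
        raise ValueError(f"{path}: missing label column(s) {sorted(missing)}")
    return df
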