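"""Independent straight-line re-implementations used as test oracles.

These deliberately avoid the package's own code paths: each function
recomputes its answer directly from raw record fields with plain
Python, so agreement with the library is a genuine cross-check.
"""

from __future__ import annotations


def freeman_oracle(t, r, th) -> str:
    """Straight-line Freeman rules from raw measures."""
    if (
        t.urban_block_share is None
        or t.median_hh_income_start is None
        or t.housing_built_prior_two_decades_share_start is None
    ):
        return "UNCLASSIFIABLE"
    if t.urban_block_share < th.urban_share_min:
        return "EXCLUDED"
    if t.median_hh_income_start > r.median_income:
        return "EXCLUDED"
    if t.housing_built_prior_two_decades_share_start > r.median_housing_built_share:
        return "EXCLUDED"
    if t.median_home_value_start is None or t.median_home_value_end is None:
        return "UNCLASSIFIABLE"
    if t.median_home_value_start <= 0:
        return "UNCLASSIFIABLE"
    if t.bachelors_share_start is None or t.bachelors_share_end is None:
        return "UNCLASSIFIABLE"
    growth = (t.median_home_value_end - t.median_home_value_start) / t.median_home_value_start
    bach = t.bachelors_share_end - t.bachelors_share_start
    if growth > r.home_value_pct_change + th.appreciation_margin and (
        bach > r.bachelors_pp_change + th.education_margin
    ):
        return "ELIGIBLE_GENTRIFYING"
    return "ELIGIBLE_NOT_GENTRIFYING"


def dg_oracle(t, r, hot: bool, th) -> str:
    """Straight-line D&G typology precedence rules from raw measures."""
    if t.low_income_hh_share_start is None or r.low_income_share is None:
        return "UNCLASSIFIABLE"
    if (
        t.median_home_value_start is None
        or t.median_home_value_end is None
        or t.median_home_value_start <= 0
        or t.bachelors_share_start is None
        or t.bachelors_share_end is None
    ):
        return "UNCLASSIFIABLE"
    growth = (t.median_home_value_end - t.median_home_value_start) / t.median_home_value_start
    bach = t.bachelors_share_end - t.bachelors_share_start
    app = growth > r.home_value_pct_change + th.appreciation_margin
    gentry = bach > r.bachelors_pp_change + th.education_margin
    rent = False
    if (
        t.median_rent_start is not None
        and t.median_rent_end is not None
        and t.median_rent_start > 0
        and r.rent_pct_change is not None
    ):
        rent = (
            (t.median_rent_end - t.median_rent_start) / t.median_rent_start
            > r.rent_pct_change + th.rent_margin
        )
    cost_end = t.median_home_value_end > th.high_cost_multiplier * r.median_home_value_end
    cost_start = t.median_home_value_start > th.high_cost_multiplier * r.median_home_value_start
    loss = False
    if t.low_income_hh_count_start is not None and t.low_income_hh_count_end is not None:
        loss = (t.low_income_hh_count_start - t.low_income_hh_count_end) >= th.low_income_loss_min
    income_high = (
        t.median_hh_income_start is not None and t.median_hh_income_start > r.median_income
    )
    declining = (
        t.low_income_hh_share_end is not None
        and t.low_income_hh_share_end < t.low_income_hh_share_start
    )
    if t.low_income_hh_share_start > r.low_income_share:
        if gentry and app and cost_end:
            return "ADVANCED_GENTRIFICATION"
        if gentry and (app or rent):
            return "EARLY_ONGOING_GENTRIFICATION"
        if hot or app:
            return "AT_RISK_OF_GENTRIFICATION"
        if loss:
            return "ONGOING_DISPLACEMENT"
        return "LOW_INCOME_SUSCEPTIBLE"
    if cost_start and cost_end and income_high:
        return "STABLE_ADVANCED_EXCLUSIVE"
    if cost_end and app and declining:
        return "BECOMING_EXCLUSIVE"
    if app:
        return "AT_RISK_BECOMING_EXCLUSIVE"
    return "STABLE_MODERATE_MIXED"


def hot_oracle(tract_id, changes, adjacency, r) -> bool:
    """Plain neighbor scan for the hot-market flag."""
    if adjacency is None:
        c = changes[tract_id].home_value_pct_change
        return c is not None and c >= r.appreciation_p75
    found = False
    for nb in adjacency.get(tract_id, set()):
        if nb in changes:
            c = changes[nb].home_value_pct_change
            if c is not None and c >= r.appreciation_p75:
                found = True
    return found


def exclusion_oracle_keep(row, labelled, required_covariates=("maternal_age", "payer", "primiparous", "adequate_care")) -> bool:
    """Predicate filter: True iff a raw birth row survives every rule."""
    import pandas as pd

    tract, year = row["tract_id"], row["year"]
    if pd.isna(tract) or pd.isna(year):
        return False
    period = (
        "2000-2010" if 2005 <= int(year) <= 2011
        else "2007-2017" if 2012 <= int(year) <= 2017
        else None
    )
    if period is None or (tract, period) not in labelled:
        return False
    fl, dg = labelled[(tract, period)]
    ga, age, bw = row["gestational_age"], row["maternal_age"], row["birth_weight"]
    if pd.isna(ga) or not (22 <= ga <= 45):
        return False
    if pd.isna(age) or not (10 <= age <= 60):
        return False
    if pd.isna(bw) or not (100 <= bw <= 9000):
        return False
    if pd.isna(row["plurality"]) or row["plurality"] != 1:
        return False
    if fl == "UNCLASSIFIABLE" or dg == "UNCLASSIFIABLE":
        return False
    if pd.isna(row["sex"]):
        return False
    for c in required_covariates:
        if pd.isna(row[c]):
            return False
    if pd.isna(row["race_ethnicity"]) or row["race_ethnicity"] == "OTHER":
        return False
    return True
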