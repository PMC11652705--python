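"""Both neighborhood-change classifiers against independent oracles."""

from __future__ import annotations

import numpy as np
import pytest

from gentbirth.census import compute_tract_change
from gentbirth.classify import (
    ClassifierThresholds,
    DGCategory,
    DGStage,
    FreemanLabel,
    classify_dg_category,
    classify_freeman,
    collapse_dg_stage,
    crosstab_labels,
    hot_market_flag,
)
from conftest import PERIOD1, random_summary, random_tract
from oracles import dg_oracle, freeman_oracle, hot_oracle
from test_census import make_tract


def summary_for(r_income=50_000.0, r_built=0.3, r_growth=0.15, r_bach=0.03, **kw):
    from gentbirth.census import RegionPeriodSummary

    defaults = dict(
        region_id="R", period=PERIOD1, n_tracts=10,
        median_income=r_income, median_housing_built_share=r_built,
        home_value_pct_change=r_growth, bachelors_pp_change=r_bach,
        median_home_value_start=250_000.0, median_home_value_end=300_000.0,
        appreciation_p75=0.3, rent_pct_change=0.1, low_income_share=0.4,
    )
    defaults.update(kw)
    return RegionPeriodSummary(**defaults)


class TestFreeman:
    def test_all_clauses_satisfied_is_gentrifying(self):
        t = make_tract(0, 45_000.0, built=0.25, urban=0.6,
                       hv=(200_000.0, 250_000.0), bach=(0.10, 0.15))
        r = summary_for()
        label = classify_freeman(t, compute_tract_change(t), r)
        assert label is FreemanLabel.ELIGIBLE_GENTRIFYING

    def test_low_urban_share_is_excluded(self):
        t = make_tract(0, 45_000.0, urban=0.4)
        label = classify_freeman(t, compute_tract_change(t), summary_for())
        assert label is FreemanLabel.EXCLUDED

    def test_growth_tie_is_not_gentrifying(self):
        # strictly-greater comparator: matching the regional change exactly
        t = make_tract(0, 45_000.0, hv=(200_000.0, 230_000.0), bach=(0.10, 0.13))
        r = summary_for(r_growth=0.15, r_bach=0.03)
        label = classify_freeman(t, compute_tract_change(t), r)
        assert label is FreemanLabel.ELIGIBLE_NOT_GENTRIFYING

    def test_income_at_regional_median_remains_eligible(self):
        t = make_tract(0, 50_000.0, hv=(200_000.0, 200_000.0))
        label = classify_freeman(t, compute_tract_change(t), summary_for())
        assert label is FreemanLabel.ELIGIBLE_NOT_GENTRIFYING

    def test_missing_required_field_unclassifiable(self):
        t = make_tract(0, None)
        label = classify_freeman(t, compute_tract_change(t), summary_for())
        assert label is FreemanLabel.UNCLASSIFIABLE

    def test_matches_oracle_on_random_tracts(self, thresholds):
        rng = np.random.default_rng(101)
        mism = 0
        for i in range(1500):
            t = random_tract(rng, i)
            r = random_summary(rng)
            got = classify_freeman(t, compute_tract_change(t), r, thresholds)
            want = freeman_oracle(t, r, thresholds)
            mism += got.value != want
        assert mism == 0

    def test_monotone_in_home_value_growth(self):
        # raising appreciation can never undo a gentrifying call
        rng = np.random.default_rng(17)
        for i in range(300):
            t = random_tract(rng, i, allow_missing=False)
            r = random_summary(rng)
            lo = classify_freeman(t, compute_tract_change(t), r)
            t.median_home_value_end *= 1.5
            hi = classify_freeman(t, compute_tract_change(t), r)
            if lo is FreemanLabel.ELIGIBLE_GENTRIFYING:
                assert hi is FreemanLabel.ELIGIBLE_GENTRIFYING


class TestDGTypology:
    def test_quiet_low_income_tract_is_susceptible(self):
        t = make_tract(0, 45_000.0, hv=(200_000.0, 210_000.0), bach=(0.1, 0.1),
                       low_income_hh_share_start=0.6, low_income_hh_share_end=0.6,
                       low_income_hh_count_start=500, low_income_hh_count_end=510)
        r = summary_for()
        c = classify_dg_category(t, compute_tract_change(t), r, hot=False)
        assert c is DGCategory.LOW_INCOME_SUSCEPTIBLE

    def test_booming_low_income_tract_is_advanced_gentrification(self):
        t = make_tract(0, 45_000.0, hv=(200_000.0, 330_000.0), bach=(0.10, 0.20),
                       low_income_hh_share_start=0.6, low_income_hh_share_end=0.55)
        r = summary_for()
        c = classify_dg_category(t, compute_tract_change(t), r, hot=False)
        assert c is DGCategory.ADVANCED_GENTRIFICATION

    def test_missing_low_income_fields_unclassifiable(self):
        t = make_tract(0, 45_000.0, low_income_hh_share_start=None)
        c = classify_dg_category(t, compute_tract_change(t), summary_for(), hot=False)
        assert c is DGCategory.UNCLASSIFIABLE

    def test_matches_oracle_on_random_tracts(self, thresholds):
        rng = np.random.default_rng(202)
        mism = 0
        for i in range(1500):
            t = random_tract(rng, i)
            r = random_summary(rng)
            hot = bool(rng.random() < 0.3)
            got = classify_dg_category(t, compute_tract_change(t), r, hot, thresholds)
            want = dg_oracle(t, r, hot, thresholds)
            mism += got.value != want
        assert mism == 0

    def test_every_boolean_combination_yields_exactly_one_category(self, thresholds):
        """Exhaustive grid over the rule clauses; the precedence table
        must be total and agree with the enumeration oracle."""
        r = summary_for(r_income=50_000.0, r_growth=0.15, r_bach=0.03,
                        median_home_value_start=250_000.0,
                        median_home_value_end=300_000.0,
                        rent_pct_change=0.10, low_income_share=0.4)
        seen = set()
        for li in (0.6, 0.2):
            for app in (True, False):
                for rent in (True, False):
                    for gentry in (True, False):
                        for cost_end in (True, False):
                            for cost_start in (True, False):
                                for lossy in (True, False):
                                    for hot in (True, False):
                                        for inc_hi in (True, False):
                                            for decl in (True, False):
                                                t = make_tract(
                                                    0,
                                                    70_000.0 if inc_hi else 45_000.0,
                                                    hv=(
                                                        260_000.0 if cost_start else 200_000.0,
                                                        (301_000.0 if cost_end else 220_000.0),
                                                    ),
                                                    bach=(0.10, 0.18 if gentry else 0.10),
                                                    median_rent_start=1000.0,
                                                    median_rent_end=1200.0 if rent else 1050.0,
                                                    low_income_hh_share_start=li,
                                                    low_income_hh_share_end=(li - 0.05) if decl else li,
                                                    low_income_hh_count_start=500,
                                                    low_income_hh_count_end=440 if lossy else 520,
                                                )
                                                if app:
                                                    # scale both values, preserving cost flags
                                                    t.median_home_value_start /= 1.5
                                                tc = compute_tract_change(t)
                                                got = classify_dg_category(t, tc, r, hot, thresholds)
                                                want = dg_oracle(t, r, hot, thresholds)
                                                assert got.value == want
                                                seen.add(got)
        assert DGCategory.UNCLASSIFIABLE not in seen
        assert len(seen) == 9

    def test_collapse_partitions_nine_categories_2_3_4(self):
        from collections import Counter

        stages = Counter(
            collapse_dg_stage(c) for c in DGCategory if c is not DGCategory.UNCLASSIFIABLE
        )
        assert stages == {
            DGStage.DISPLACEMENT: 2,
            DGStage.GENTRIFICATION: 3,
            DGStage.EXCLUSIVE: 4,
        }

    def test_collapse_spot_values(self):
        assert collapse_dg_stage(DGCategory.EARLY_ONGOING_GENTRIFICATION) is DGStage.GENTRIFICATION
        assert collapse_dg_stage(DGCategory.STABLE_MODERATE_MIXED) is DGStage.EXCLUSIVE
        assert collapse_dg_stage(DGCategory.UNCLASSIFIABLE) is DGStage.UNCLASSIFIABLE


class TestHotMarket:
    def _changes(self, rng, n):
        tracts = [random_tract(rng, i, allow_missing=False) for i in range(n)]
        return {t.tract_id: compute_tract_change(t) for t in tracts}

    def test_isolated_tract_fallback_uses_own_change(self):
        rng = np.random.default_rng(0)
        changes = self._changes(rng, 1)
        tid = next(iter(changes))
        r = random_summary(rng)
        r.appreciation_p75 = changes[tid].home_value_pct_change + 1.0
        assert hot_market_flag(tid, changes, None, r) is False

    def test_neighbor_at_regional_maximum_is_hot(self):
        rng = np.random.default_rng(1)
        changes = self._changes(rng, 5)
        ids = list(changes)
        adjacency = {ids[0]: {ids[1]}}
        r = random_summary(rng)
        r.appreciation_p75 = changes[ids[1]].home_value_pct_change  # p75 <= max
        assert hot_market_flag(ids[0], changes, adjacency, r) is True

    def test_matches_neighbor_scan_oracle_on_random_graphs(self):
        rng = np.random.default_rng(33)
        for _ in range(30):
            n = int(rng.integers(5, 40))
            changes = self._changes(rng, n)
            ids = list(changes)
            adjacency: dict[str, set] = {i: set() for i in ids}
            for _ in range(n * 2):
                a, b = rng.choice(ids, 2, replace=False)
                adjacency[a].add(b)
                adjacency[b].add(a)
            r = random_summary(rng)
            for tid in ids:
                assert hot_market_flag(tid, changes, adjacency, r) == hot_oracle(
                    tid, changes, adjacency, r
                )


class TestCrosstab:
    def test_identical_gentrifying_sets_full_overlap(self):
        freeman = {f"T{i}": FreemanLabel.ELIGIBLE_GENTRIFYING for i in range(5)}
        dg = {f"T{i}": DGStage.GENTRIFICATION for i in range(5)}
        ct = crosstab_labels(freeman, dg)
        assert ct["pct_of_freeman_also_dg"] == 100.0
        assert ct["pct_of_dg_also_freeman"] == 100.0

    def test_disjoint_gentrifying_sets_zero_overlap(self):
        freeman = {
            "A": FreemanLabel.ELIGIBLE_GENTRIFYING,
            "B": FreemanLabel.EXCLUDED,
        }
        dg = {"A": DGStage.EXCLUSIVE, "B": DGStage.GENTRIFICATION}
        ct = crosstab_labels(freeman, dg)
        assert ct["pct_of_freeman_also_dg"] == 0.0
        assert ct["pct_of_dg_also_freeman"] == 0.0

    def test_mismatched_tract_sets_error_lists_difference(self):
        with pytest.raises(ValueError, match="B"):
            crosstab_labels(
                {"A": FreemanLabel.EXCLUDED}, {"B": DGStage.EXCLUSIVE}
            )

    def test_random_labels_match_hand_count(self):
        rng = np.random.default_rng(55)
        f_levels = [l for l in FreemanLabel]
        d_levels = [s for s in DGStage]
        freeman = {f"T{i}": f_levels[rng.integers(len(f_levels))] for i in range(200)}
        dg = {f"T{i}": d_levels[rng.integers(len(d_levels))] for i in range(200)}
        ct = crosstab_labels(freeman, dg)
        n_f = sum(v is FreemanLabel.ELIGIBLE_GENTRIFYING for v in freeman.values())
        n_both = sum(
            freeman[k] is FreemanLabel.ELIGIBLE_GENTRIFYING
            and dg[k] is DGStage.GENTRIFICATION
            for k in freeman
        )
        assert ct["n_both"] == n_both
        assert ct["pct_of_freeman_also_dg"] == pytest.approx(100 * n_both / n_f)
        assert int(ct["table"].to_numpy().sum()) == 200


class TestThresholds:
    def test_digest_stable_and_sensitive(self):
        a, b = ClassifierThresholds(), ClassifierThresholds()
        assert a.digest() == b.digest()
        assert a.digest() != ClassifierThresholds(hot_market_quantile=0.9).digest()

    def test_yaml_round_trip(self, tmp_path):
        th = ClassifierThresholds(low_income_loss_min=5, appreciation_margin=0.01)
        th.to_yaml(tmp_path / "th.yaml")
        assert ClassifierThresholds.from_yaml(tmp_path / "th.yaml") == th

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            ClassifierThresholds(urban_share_min=1.5)
        with pytest.raises(ValueError):
            ClassifierThresholds(hot_market_quantile=0.0)
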