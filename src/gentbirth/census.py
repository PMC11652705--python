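"""Tract- and region-level census measures.

A *tract* is the neighborhood unit; a *region* (CBSA-style) is the
benchmark against which tract change is judged.  Each measurement
period compares a tract's characteristics at the period start with
those at the period end, and the two neighborhood-change classifiers
consume three objects built here:

* :class:`TractPeriodMeasures` — one tract's raw measures for a period,
* :class:`TractChange` — the tract's own change quantities,
* :class:`RegionPeriodSummary` — regional medians and benchmark changes.

Monetary measures (income, home value, rent) are nominal: tract and
region use same-period values so the tract-versus-region comparison is
internally consistent without a CPI adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Period",
    "TractPeriodMeasures",
    "TractChange",
    "RegionPeriodSummary",
    "SchemaError",
    "ValidationError",
    "read_tract_measures",
    "write_tract_measures",
    "read_region_map",
    "read_adjacency",
    "summarize_region",
    "summarize_all_regions",
    "compute_tract_change",
    "write_region_summaries",
]


class SchemaError(ValueError):
    """A required column is missing or a cell cannot be parsed."""


class ValidationError(ValueError):
    """One or more rows violate a field invariant."""


@dataclass(frozen=True)
class Period:
    """A measurement window, e.g. ``Period("2000-2010", 2000, 2010)``."""

    label: str
    start_year: int
    end_year: int

    def __post_init__(self) -> None:
        if self.start_year >= self.end_year:
            raise ValueError(
                f"period {self.label!r}: start_year {self.start_year} "
                f"must precede end_year {self.end_year}"
            )

    @classmethod
    def from_label(cls, label: str) -> "Period":
        """Parse ``"2000-2010"`` into a Period."""
        try:
            start, end = label.split("-")
            return cls(label, int(start), int(end))
        except Exception as exc:  # noqa: BLE001
            raise ValueError(f"cannot parse period label {label!r}") from exc


# Columns of the tract-measures CSV dialect (comma-delimited, UTF-8,
# header required, empty string = missing).
_REQUIRED_COLUMNS = (
    "tract_id",
    "region_id",
    "urban_block_share",
    "median_hh_income_start",
    "housing_built_prior_two_decades_share_start",
    "median_home_value_start",
    "median_home_value_end",
    "bachelors_share_start",
    "bachelors_share_end",
)
_OPTIONAL_COLUMNS = (
    "median_rent_start",
    "median_rent_end",
    "low_income_hh_count_start",
    "low_income_hh_count_end",
    "low_income_hh_share_start",
    "low_income_hh_share_end",
)

_SHARE_FIELDS = (
    "urban_block_share",
    "housing_built_prior_two_decades_share_start",
    "bachelors_share_start",
    "bachelors_share_end",
    "low_income_hh_share_start",
    "low_income_hh_share_end",
)
_CURRENCY_FIELDS = (
    "median_hh_income_start",
    "median_home_value_start",
    "median_home_value_end",
    "median_rent_start",
    "median_rent_end",
)
_COUNT_FIELDS = ("low_income_hh_count_start", "low_income_hh_count_end")


@dataclass
class TractPeriodMeasures:
    """Census measures for one tract over one period.

    Optional fields are ``None`` when the source table is missing them;
    the classifiers treat missing required inputs as unclassifiable
    rather than coercing them.
    """

    tract_id: str
    region_id: str
    period: Period
    urban_block_share: float | None
    median_hh_income_start: float | None
    housing_built_prior_two_decades_share_start: float | None
    median_home_value_start: float | None
    median_home_value_end: float | None
    bachelors_share_start: float | None
    bachelors_share_end: float | None
    median_rent_start: float | None = None
    median_rent_end: float | None = None
    low_income_hh_count_start: int | None = None
    low_income_hh_count_end: int | None = None
    low_income_hh_share_start: float | None = None
    low_income_hh_share_end: float | None = None

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems: list[str] = []
        for name in _SHARE_FIELDS:
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                problems.append(f"{name}={v} outside [0, 1]")
        for name in _CURRENCY_FIELDS:
            v = getattr(self, name)
            if v is not None and v < 0:
                problems.append(f"{name}={v} negative")
        for name in _COUNT_FIELDS:
            v = getattr(self, name)
            if v is not None and (v < 0 or v != int(v)):
                problems.append(f"{name}={v} not a non-negative integer")
        return problems


@dataclass
class TractChange:
    """A tract's own change quantities over a period.

    Percent changes are ``(end - start) / start`` and require a strictly
    positive start value; an undefined change is ``None``, never
    infinity.  The bachelor's-degree change is in percentage points
    (end share minus start share) so it is comparable across regions of
    different education levels.
    """

    tract_id: str
    period: Period
    home_value_pct_change: float | None
    bachelors_pp_change: float | None
    rent_pct_change: float | None = None
    low_income_hh_loss: float | None = None


@dataclass
class RegionPeriodSummary:
    """Regional benchmarks for one period.

    Medians are taken over member tracts with non-missing values.  The
    benchmark changes are computed from the median of tract start
    values to the median of tract end values (robust to outlier
    tracts); ``mode="mean_of_changes"`` in :func:`summarize_region`
    averages the per-tract changes instead.  ``appreciation_p75`` is
    the 75th percentile of member-tract home-value percent change and
    marks a regionally "hot" housing market.
    """

    region_id: str
    period: Period
    n_tracts: int
    median_income: float
    median_housing_built_share: float
    home_value_pct_change: float
    bachelors_pp_change: float
    median_home_value_start: float
    median_home_value_end: float
    appreciation_p75: float
    rent_pct_change: float | None = None
    low_income_share: float | None = None


def _parse_cell(raw: object, column: str, row_number: int) -> float | None:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    if isinstance(raw, str):
        raw = raw.strip()
        if raw == "":
            return None
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise SchemaError(
            f"row {row_number}, column {column!r}: cannot parse {raw!r} as a number"
        ) from None


def read_tract_measures(path: str | Path, period: Period) -> list[TractPeriodMeasures]:
    """Read and validate a tract-measures CSV for one period.

    Raises :class:`SchemaError` when a required column is absent or a
    cell fails to parse, and :class:`ValidationError` listing the
    offending rows when any record violates a field invariant.
    Row numbers in messages are 1-based data rows (header excluded).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")

    records: list[TractPeriodMeasures] = []
    problems: list[str] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row_d = dict(zip(df.columns, row))
        kwargs: dict = {
            "tract_id": str(row_d["tract_id"]).strip(),
            "region_id": str(row_d["region_id"]).strip(),
            "period": period,
        }
        for col in _REQUIRED_COLUMNS[2:] + _OPTIONAL_COLUMNS:
            if col in df.columns:
                kwargs[col] = _parse_cell(row_d.get(col), col, i)
            elif col in _OPTIONAL_COLUMNS:
                kwargs[col] = None
        for col in _COUNT_FIELDS:
            if kwargs.get(col) is not None:
                kwargs[col] = int(kwargs[col]) if kwargs[col] == int(kwargs[col]) else kwargs[col]
        rec = TractPeriodMeasures(**kwargs)
        if rec.tract_id in seen:
            problems.append(f"row {i}: duplicate tract_id {rec.tract_id!r} for period {period.label}")
        seen.add(rec.tract_id)
        for p in rec.validate():
            problems.append(f"row {i} (tract {rec.tract_id}): {p}")
        records.append(rec)
    if problems:
        raise ValidationError(f"{path}: " + "; ".join(problems))
    return records


def _fmt(v: float | int | None) -> str:
    if v is None:
        return ""
    if isinstance(v, float) and v.is_integer():
        return str(int(v))
    return repr(v)


def write_tract_measures(records: Sequence[TractPeriodMeasures], path: str | Path) -> None:
    """Write records in the CSV dialect read by :func:`read_tract_measures`.

    ``repr``-based float formatting makes the write → read round trip
    bit-exact.
    """
    cols = list(_REQUIRED_COLUMNS) + list(_OPTIONAL_COLUMNS)
    rows = []
    for r in records:
        row = {"tract_id": r.tract_id, "region_id": r.region_id}
        for c in cols[2:]:
            row[c] = _fmt(getattr(r, c))
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_region_map(path: str | Path) -> dict[str, str]:
    """Read a ``tract_id,region_id`` mapping CSV."""
    df = pd.read_csv(path, dtype=str)
    for col in ("tract_id", "region_id"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    return dict(zip(df["tract_id"], df["region_id"]))


def read_adjacency(path: str | Path) -> dict[str, set[str]]:
    """Read a symmetric tract adjacency list (``tract_id,neighbor_tract_id``)."""
    df = pd.read_csv(path, dtype=str)
    for col in ("tract_id", "neighbor_tract_id"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    adj: dict[str, set[str]] = {}
    for a, b in zip(df["tract_id"], df["neighbor_tract_id"]):
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    return adj


def compute_tract_change(t: TractPeriodMeasures) -> TractChange:
    """Derive a tract's change quantities from its period measures."""

    def pct(start: float | None, end: float | None) -> float | None:
        if start is None or end is None or start <= 0:
            return None
        return (end - start) / start

    bach = None
    if t.bachelors_share_start is not None and t.bachelors_share_end is not None:
        bach = t.bachelors_share_end - t.bachelors_share_start
    loss = None
    if t.low_income_hh_count_start is not None and t.low_income_hh_count_end is not None:
        loss = t.low_income_hh_count_start - t.low_income_hh_count_end
    return TractChange(
        tract_id=t.tract_id,
        period=t.period,
        home_value_pct_change=pct(t.median_home_value_start, t.median_home_value_end),
        bachelors_pp_change=bach,
        rent_pct_change=pct(t.median_rent_start, t.median_rent_end),
        low_income_hh_loss=loss,
    )


def _median(values: list[float]) -> float:
    return float(np.median(np.asarray(values, dtype=float)))


def summarize_region(
    tracts: Iterable[TractPeriodMeasures],
    region_id: str,
    period: Period,
    *,
    mode: str = "median_of_levels",
    urban_only: bool = False,
    urban_share_min: float = 0.5,
) -> RegionPeriodSummary:
    """Compute regional benchmark quantities for one region-period.

    ``mode`` selects how the benchmark *change* is aggregated:
    ``"median_of_levels"`` (default) takes the percent/point change
    between the medians of tract start and end values;
    ``"mean_of_changes"`` averages the per-tract changes.  With
    ``urban_only=True`` only tracts whose urban block share is at least
    ``urban_share_min`` enter the benchmark.
    """
    if mode not in ("median_of_levels", "mean_of_changes"):
        raise ValueError(f"unknown mode {mode!r}")
    members = [
        t
        for t in tracts
        if t.region_id == region_id and t.period.label == period.label
    ]
    if urban_only:
        members = [
            t
            for t in members
            if t.urban_block_share is not None and t.urban_block_share >= urban_share_min
        ]
    if not members:
        raise ValueError(f"region {region_id!r} has no tracts for period {period.label!r}")

    def column(name: str) -> list[float]:
        return [getattr(t, name) for t in members if getattr(t, name) is not None]

    incomes = column("median_hh_income_start")
    built = column("housing_built_prior_two_decades_share_start")
    if not incomes or not built:
        raise ValueError(
            f"region {region_id!r}: no tracts with non-missing income/housing-built inputs"
        )

    hv_start = column("median_home_value_start")
    hv_end = [
        t.median_home_value_end
        for t in members
        if t.median_home_value_start is not None and t.median_home_value_end is not None
    ]
    hv_start_paired = [
        t.median_home_value_start
        for t in members
        if t.median_home_value_start is not None and t.median_home_value_end is not None
    ]
    if not hv_start_paired:
        raise ValueError(f"region {region_id!r}: no tracts with paired home values")

    changes = [compute_tract_change(t) for t in members]
    appreciations = [c.home_value_pct_change for c in changes if c.home_value_pct_change is not None]
    if not appreciations:
        raise ValueError(f"region {region_id!r}: no tract home-value changes computable")

    bach_start = [
        t.bachelors_share_start
        for t in members
        if t.bachelors_share_start is not None and t.bachelors_share_end is not None
    ]
    bach_end = [
        t.bachelors_share_end
        for t in members
        if t.bachelors_share_start is not None and t.bachelors_share_end is not None
    ]

    rent_start = [
        t.median_rent_start
        for t in members
        if t.median_rent_start is not None and t.median_rent_end is not None and t.median_rent_start > 0
    ]
    rent_end = [
        t.median_rent_end
        for t in members
        if t.median_rent_start is not None and t.median_rent_end is not None and t.median_rent_start > 0
    ]

    if mode == "median_of_levels":
        ms, me = _median(hv_start_paired), _median(hv_end)
        hv_change = (me - ms) / ms
        bach_change = (_median(bach_end) - _median(bach_start)) if bach_start else 0.0
        rent_change = (
            (_median(rent_end) - _median(rent_start)) / _median(rent_start)
            if rent_start
            else None
        )
    else:
        hv_change = float(np.mean(appreciations))
        bpp = [c.bachelors_pp_change for c in changes if c.bachelors_pp_change is not None]
        bach_change = float(np.mean(bpp)) if bpp else 0.0
        rpc = [c.rent_pct_change for c in changes if c.rent_pct_change is not None]
        rent_change = float(np.mean(rpc)) if rpc else None

    li_shares = column("low_income_hh_share_start")
    return RegionPeriodSummary(
        region_id=region_id,
        period=period,
        n_tracts=len(members),
        median_income=_median(incomes),
        median_housing_built_share=_median(built),
        home_value_pct_change=hv_change,
        bachelors_pp_change=bach_change,
        median_home_value_start=_median(hv_start),
        median_home_value_end=_median(hv_end),
        appreciation_p75=float(np.percentile(np.asarray(appreciations, dtype=float), 75)),
        rent_pct_change=rent_change,
        low_income_share=_median(li_shares) if li_shares else None,
    )


def summarize_all_regions(
    tracts: Sequence[TractPeriodMeasures], period: Period, **kwargs
) -> dict[str, RegionPeriodSummary]:
    """Summaries for every region present in ``tracts``."""
    region_ids = sorted({t.region_id for t in tracts if t.period.label == period.label})
    return {rid: summarize_region(tracts, rid, period, **kwargs) for rid in region_ids}


def write_region_summaries(
    summaries: dict[str, RegionPeriodSummary], path: str | Path
) -> None:
    rows = []
    for rid in sorted(summaries):
        s = summaries[rid]
        rows.append(
            {
                "region_id": s.region_id,
                "period": s.period.label,
                "n_tracts": s.n_tracts,
                "median_income": s.median_income,
                "median_housing_built_share": s.median_housing_built_share,
                "home_value_pct_change": s.home_value_pct_change,
                "bachelors_pp_change": s.bachelors_pp_change,
                "median_home_value_start": s.median_home_value_start,
                "median_home_value_end": s.median_home_value_end,
                "appreciation_p75": s.appreciation_p75,
                "rent_pct_change": "" if s.rent_pct_change is None else s.rent_pct_change,
                "low_income_share": "" if s.low_income_share is None else s.low_income_share,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
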