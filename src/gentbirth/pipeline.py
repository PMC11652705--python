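"""End-to-end pipeline: classify → cohort → models → tables.

:func:`run_pipeline` drives the full analysis from a :class:`RunConfig`
and writes every artifact (exposure labels, exclusion report,
descriptive tables, model results, interaction tests, classifier
overlap, provenance manifest) into one run directory.  Any stage
failure aborts with the stage named in the exception.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .census import Period, read_adjacency, read_tract_measures, summarize_all_regions, write_region_summaries
from .classify import (
    ClassifierThresholds,
    DGStage,
    FreemanLabel,
    crosstab_labels,
    label_tracts,
    write_labels,
)
from .cohort import (
    GrowthReference,
    apply_exclusions,
    derive_outcomes_frame,
    read_births,
)
from .models import (
    BINARY_OUTCOMES,
    ModelSpec,
    fit_mixed_linear,
    fit_mixed_logistic,
    fit_stratified,
    prevalence_tables,
    results_to_frame,
    test_interaction,
)

log = logging.getLogger("gentbirth")

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Validated inputs and options for one pipeline run."""

    tracts_by_period: dict  # period label -> tract-measures CSV path
    births: str
    out_dir: str
    adjacency: str | None = None
    growth_reference: str | None = None  # CSV; None = empirical from cohort
    thresholds: ClassifierThresholds = field(default_factory=ClassifierThresholds)
    outcomes: tuple = BINARY_OUTCOMES
    continuous_outcomes: tuple = ()
    exposures: tuple = ("FREEMAN", "DG_STAGE")
    freeman_referent: str = "ELIGIBLE_NOT_GENTRIFYING"
    adjustments: tuple = ("MODEL1", "MODEL2")
    stratify: bool = False
    interaction: bool = False
    n_quad: int = 50
    region_mode: str = "median_of_levels"
    urban_only_benchmark: bool = False
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        th = ClassifierThresholds(**raw.pop("thresholds", {}))
        for key in ("outcomes", "continuous_outcomes", "exposures", "adjustments"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(thresholds=th, **raw)

    def validate(self) -> None:
        for period, path in self.tracts_by_period.items():
            Period.from_label(period)
            if not Path(path).exists():
                raise FileNotFoundError(f"tract measures for {period}: {path} not found")
        if not Path(self.births).exists():
            raise FileNotFoundError(f"births file {self.births} not found")
        if self.freeman_referent not in ("ELIGIBLE_NOT_GENTRIFYING", "EXCLUDED"):
            raise ValueError("freeman_referent must be ELIGIBLE_NOT_GENTRIFYING or EXCLUDED")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


@_stage("classify")
def _run_classify(cfg: RunConfig, out: Path) -> pd.DataFrame:
    adjacency = read_adjacency(cfg.adjacency) if cfg.adjacency else None
    frames = []
    for label, path in sorted(cfg.tracts_by_period.items()):
        period = Period.from_label(label)
        tracts = read_tract_measures(path, period)
        summaries = summarize_all_regions(
            tracts, period, mode=cfg.region_mode, urban_only=cfg.urban_only_benchmark
        )
        write_region_summaries(summaries, out / f"region_summary_{label}.csv")
        labels = label_tracts(tracts, summaries, cfg.thresholds, adjacency)
        write_labels(labels, out / f"exposure_labels_{label}.csv")
        frames.append(labels)
        log.info("classified %d tracts for period %s", len(labels), label)
    cfg.thresholds.to_yaml(out / "thresholds.yaml")
    all_labels = pd.concat(frames, ignore_index=True)

    # classifier agreement on the most recent period
    last = frames[-1]
    freeman = {r.tract_id: FreemanLabel(r.freeman_label) for r in last.itertuples()}
    dg = {r.tract_id: DGStage(r.dg_stage) for r in last.itertuples()}
    ct = crosstab_labels(freeman, dg)
    ct["table"].to_csv(out / "label_crosstab.csv")
    (out / "label_overlap.json").write_text(
        json.dumps({k: v for k, v in ct.items() if k != "table"}, indent=2)
    )
    return all_labels


@_stage("cohort")
def _run_cohort(cfg: RunConfig, out: Path, labels: pd.DataFrame) -> pd.DataFrame:
    births = read_births(cfg.births)
    cohort, report = apply_exclusions(births, labels)
    report.to_json(out / "exclusion_report.json")
    log.info("cohort: %d of %d births retained", report.n_final, report.n_input)
    if cfg.growth_reference:
        ref = GrowthReference.from_csv(cfg.growth_reference)
    else:
        from .simulate import default_growth_reference

        ref = default_growth_reference()
    cohort = derive_outcomes_frame(cohort, ref)
    cohort.to_csv(out / "cohort.csv", index=False)
    return cohort


@_stage("models")
def _run_models(cfg: RunConfig, out: Path, cohort: pd.DataFrame) -> pd.DataFrame:
    results = []
    interactions = []
    for exposure in cfg.exposures:
        referent = cfg.freeman_referent if exposure == "FREEMAN" else None
        for outcome in cfg.outcomes:
            for adj in cfg.adjustments:
                spec = ModelSpec(outcome=outcome, exposure=exposure, referent=referent,
                                 adjustment=adj)
                results.append(fit_mixed_logistic(cohort, spec, n_quad=cfg.n_quad))
                log.info("fitted %s ~ %s (%s)", outcome, exposure, adj)
            if cfg.stratify:
                spec = ModelSpec(outcome=outcome, exposure=exposure, referent=referent,
                                 adjustment="MODEL2")
                results.extend(fit_stratified(cohort, spec, n_quad=cfg.n_quad).values())
            if cfg.interaction:
                spec = ModelSpec(outcome=outcome, exposure=exposure, referent=referent,
                                 adjustment="MODEL2")
                interactions.append(test_interaction(cohort, spec, n_quad=cfg.n_quad))
        for outcome in cfg.continuous_outcomes:
            for adj in cfg.adjustments:
                spec = ModelSpec(outcome=outcome, exposure=exposure, referent=referent,
                                 adjustment=adj)
                results.append(fit_mixed_linear(cohort, spec))
    frame = results_to_frame(results)
    frame.to_csv(out / "model_results.csv", index=False)
    if interactions:
        pd.DataFrame(
            [
                {"outcome": t.outcome, "exposure": t.exposure,
                 "lr_statistic": t.lr_statistic, "df": t.df, "p_value": t.p_value}
                for t in interactions
            ]
        ).to_csv(out / "interaction_tests.csv", index=False)
    return frame


@_stage("report")
def _run_report(cfg: RunConfig, out: Path, cohort: pd.DataFrame) -> None:
    tables = prevalence_tables(cohort)
    tables["prevalence"].to_csv(out / "table1_prevalence.csv", index=False)
    if tables["by_race"] is not None:
        tables["by_race"].to_csv(out / "table2_by_race.csv", index=False)


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    labels = _run_classify(cfg, out)
    cohort = _run_cohort(cfg, out, labels)
    _run_models(cfg, out, cohort)
    _run_report(cfg, out, cohort)

    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "seed": cfg.seed,
        "thresholds_hash": cfg.thresholds.digest(),
        "config": _jsonable(asdict(cfg)),
        "config_hash": hashlib.sha256(
            json.dumps(_jsonable(asdict(cfg)), sort_keys=True).encode()
        ).hexdigest()[:16],
        "artifacts": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("pipeline complete: %s", out)
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj
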