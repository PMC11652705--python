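"""Exposure–outcome association models.

Binary outcomes (PTB, VPTB, SGA, LBW) are fitted with random-intercept
logistic regression (tract intercept, Gauss–Hermite maximum
likelihood); continuous outcomes (birth-weight z-score, term birth
weight) with random-intercept linear mixed models.  Two adjustment
sets mirror the analysis design:

* Model 1 — maternal age (years, linear) and payer at delivery;
* Model 2 — Model 1 plus primiparity and prenatal-care adequacy.

Odds ratios are Wald: exp(estimate ± 1.96 · SE) on the log-odds scale.
Race/ethnicity-stratified fits and a likelihood-ratio test for
exposure × race interaction complete the surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .glmm import LogitMixedFit, fit_random_intercept_logit

__all__ = [
    "EXPOSURE_LEVELS",
    "DEFAULT_REFERENTS",
    "ModelSpec",
    "LevelEstimate",
    "ModelResult",
    "InteractionTest",
    "fit_mixed_logistic",
    "fit_mixed_linear",
    "fit_stratified",
    "test_interaction",
    "prevalence_tables",
    "results_to_frame",
]

EXPOSURE_LEVELS = {
    "FREEMAN": ("ELIGIBLE_NOT_GENTRIFYING", "EXCLUDED", "ELIGIBLE_GENTRIFYING"),
    "DG_STAGE": ("EXCLUSIVE", "DISPLACEMENT", "GENTRIFICATION"),
}
DEFAULT_REFERENTS = {"FREEMAN": "ELIGIBLE_NOT_GENTRIFYING", "DG_STAGE": "EXCLUSIVE"}
_EXPOSURE_COLUMN = {"FREEMAN": "freeman_label", "DG_STAGE": "dg_stage"}

BINARY_OUTCOMES = ("ptb", "vptb", "sga", "lbw")
CONTINUOUS_OUTCOMES = ("bw_zscore", "term_bw")

ADJUSTMENT_SETS = {
    "MODEL1": ("maternal_age", "payer"),
    "MODEL2": ("maternal_age", "payer", "primiparous", "adequate_care"),
    "NONE": (),
}


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: outcome, exposure coding, adjustment, stratum."""

    outcome: str
    exposure: str = "FREEMAN"
    referent: str | None = None
    adjustment: str = "MODEL2"
    stratum: str = "ALL"
    age_categorical: bool = False

    def __post_init__(self) -> None:
        if self.exposure not in EXPOSURE_LEVELS:
            raise ValueError(f"unknown exposure {self.exposure!r}")
        ref = self.referent or DEFAULT_REFERENTS[self.exposure]
        if ref not in EXPOSURE_LEVELS[self.exposure]:
            raise ValueError(f"referent {ref!r} not a level of {self.exposure}")
        if self.adjustment not in ADJUSTMENT_SETS:
            raise ValueError(f"unknown adjustment set {self.adjustment!r}")

    @property
    def referent_level(self) -> str:
        return self.referent or DEFAULT_REFERENTS[self.exposure]

    @property
    def exposure_column(self) -> str:
        return _EXPOSURE_COLUMN[self.exposure]


@dataclass
class LevelEstimate:
    level: str
    estimate: float  # log-odds (logistic) or mean difference (linear)
    se: float
    ci_low: float
    ci_high: float
    or_: float | None = None
    or_ci_low: float | None = None
    or_ci_high: float | None = None


@dataclass
class ModelResult:
    spec: ModelSpec
    estimates: dict[str, LevelEstimate]
    intercept_variance: float
    n_obs: int
    n_clusters: int
    converged: bool
    loglik: float | None = None
    family: str = "logistic"
    inestimable_levels: list[str] = field(default_factory=list)


@dataclass
class InteractionTest:
    outcome: str
    exposure: str
    lr_statistic: float
    df: int
    p_value: float


def _design(
    cohort: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str], pd.DataFrame]:
    """Build (y, X, groups) for a spec; complete cases only."""
    df = cohort
    if spec.stratum != "ALL":
        df = df[df["race_ethnicity"] == spec.stratum]
    col = spec.exposure_column
    levels = EXPOSURE_LEVELS[spec.exposure]
    df = df[df[col].isin(levels)]
    needed = [spec.outcome, col, "tract_id", *ADJUSTMENT_SETS[spec.adjustment]]
    df = df.dropna(subset=needed)

    ref = spec.referent_level
    cols: list[np.ndarray] = [np.ones(len(df))]
    names = ["intercept"]
    for lev in levels:
        if lev == ref:
            continue
        cols.append((df[col] == lev).to_numpy(dtype=float))
        names.append(f"exposure[{lev}]")
    for cov in ADJUSTMENT_SETS[spec.adjustment]:
        if cov == "maternal_age":
            if spec.age_categorical:
                age = df["maternal_age"].to_numpy(dtype=float)
                cols.append((age < 20).astype(float))
                names.append("age[<20]")
                cols.append((age >= 35).astype(float))
                names.append("age[>=35]")
            else:
                cols.append(df["maternal_age"].to_numpy(dtype=float))
                names.append("maternal_age")
        elif cov == "payer":
            for lev in ("PUBLIC", "UNINSURED_OTHER"):  # referent PRIVATE
                cols.append((df["payer"] == lev).to_numpy(dtype=float))
                names.append(f"payer[{lev}]")
        else:
            cols.append(df[cov].astype(float).to_numpy())
            names.append(cov)
    X = np.column_stack(cols)
    y = df[spec.outcome].to_numpy(dtype=float)
    groups = df["tract_id"].to_numpy()
    return y, X, groups, names, df


def _package_logit(
    fit: LogitMixedFit, names: list[str], spec: ModelSpec, df: pd.DataFrame
) -> ModelResult:
    z = stats.norm.ppf(0.975)
    estimates: dict[str, LevelEstimate] = {}
    inestimable: list[str] = []
    col = spec.exposure_column
    for i, name in enumerate(names):
        if not name.startswith("exposure["):
            continue
        level = name[len("exposure[") : -1]
        cell = df[df[col] == level]
        if len(cell) == 0 or cell[spec.outcome].sum() in (0, len(cell)):
            inestimable.append(level)
        est, se = float(fit.beta[i]), float(fit.se_beta[i])
        lo, hi = est - z * se, est + z * se
        estimates[level] = LevelEstimate(
            level, est, se, lo, hi,
            or_=float(np.exp(est)), or_ci_low=float(np.exp(lo)), or_ci_high=float(np.exp(hi)),
        )
    return ModelResult(
        spec=spec,
        estimates=estimates,
        intercept_variance=fit.intercept_variance,
        n_obs=fit.n_obs,
        n_clusters=fit.n_clusters,
        converged=fit.converged,
        loglik=fit.loglik,
        family="logistic",
        inestimable_levels=inestimable,
    )


def fit_mixed_logistic(
    cohort: pd.DataFrame, spec: ModelSpec, *, n_quad: int = 50
) -> ModelResult:
    """Random-intercept logistic fit for a binary outcome.

    Non-convergence is flagged on the result; there is no silent
    fallback to an unclustered fit.
    """
    y, X, groups, names, df = _design(cohort, spec)
    if len(np.unique(groups)) < 2:
        raise ValueError("need at least 2 tracts to fit a random-intercept model")
    fit = fit_random_intercept_logit(y, X, groups, n_quad=n_quad)
    return _package_logit(fit, names, spec, df)


def fit_mixed_linear(cohort: pd.DataFrame, spec: ModelSpec, *, reml: bool = True) -> ModelResult:
    """Random-intercept linear fit for a continuous outcome (profiled
    REML by default; ``reml=False`` gives maximum likelihood)."""
    from .glmm import fit_random_intercept_linear

    y, X, groups, names, df = _design(cohort, spec)
    if np.allclose(np.var(y), 0.0):
        # degenerate outcome: all effects zero, flagged unconverged
        estimates = {
            name[len("exposure[") : -1]: LevelEstimate(
                name[len("exposure[") : -1], 0.0, 0.0, 0.0, 0.0
            )
            for name in names
            if name.startswith("exposure[")
        }
        return ModelResult(
            spec=spec, estimates=estimates, intercept_variance=0.0,
            n_obs=len(y), n_clusters=len(np.unique(groups)), converged=False,
            family="linear",
        )
    res = fit_random_intercept_linear(y, X, groups, reml=reml)
    z = stats.norm.ppf(0.975)
    estimates: dict[str, LevelEstimate] = {}
    for i, name in enumerate(names):
        if not name.startswith("exposure["):
            continue
        level = name[len("exposure[") : -1]
        est, se = float(res.beta[i]), float(res.se_beta[i])
        estimates[level] = LevelEstimate(level, est, se, est - z * se, est + z * se)
    return ModelResult(
        spec=spec,
        estimates=estimates,
        intercept_variance=res.sigma_u2,
        n_obs=res.n_obs,
        n_clusters=res.n_clusters,
        converged=res.converged,
        loglik=res.loglik,
        family="linear",
    )


def fit_stratified(
    cohort: pd.DataFrame, spec: ModelSpec, *, min_obs: int = 50, n_quad: int = 50
) -> dict[str, ModelResult]:
    """One fit per race/ethnicity level present in the cohort.

    Small strata are fitted and reported with their wide intervals, not
    suppressed; strata below ``min_obs`` complete cases are skipped
    with a warning.
    """
    results: dict[str, ModelResult] = {}
    for race in sorted(cohort["race_ethnicity"].dropna().unique()):
        sub_spec = ModelSpec(
            outcome=spec.outcome, exposure=spec.exposure, referent=spec.referent,
            adjustment=spec.adjustment, stratum=race, age_categorical=spec.age_categorical,
        )
        n = (cohort["race_ethnicity"] == race).sum()
        if n < min_obs:
            warnings.warn(f"stratum {race}: only {n} records, skipping", stacklevel=2)
            continue
        if spec.outcome in CONTINUOUS_OUTCOMES:
            results[race] = fit_mixed_linear(cohort, sub_spec)
        else:
            results[race] = fit_mixed_logistic(cohort, sub_spec, n_quad=n_quad)
    return results


def test_interaction(
    cohort: pd.DataFrame, spec: ModelSpec, *, n_quad: int = 50
) -> InteractionTest:
    """Likelihood-ratio test for exposure × race/ethnicity interaction.

    Compares the main-effects model (exposure + race + covariates)
    with the model adding all exposure × race product terms; the LR
    statistic is referred to chi-square with
    (exposure levels − 1) × (race levels − 1) degrees of freedom.

    Race levels with an inestimable exposure cell (no events or no
    non-events) are dropped from both nested fits with a warning —
    their interaction coefficients are not identified.
    """
    y, X, groups, names, df = _design(cohort, spec)
    col = spec.exposure_column
    estimable = []
    for race, sub in df.groupby("race_ethnicity", dropna=True):
        cells = sub.groupby(col)[spec.outcome].agg(["sum", "count"])
        if ((cells["sum"] > 0) & (cells["sum"] < cells["count"])).all():
            estimable.append(race)
        else:
            warnings.warn(
                f"race level {race!r} has an inestimable exposure cell; "
                "dropped from the interaction test", stacklevel=2,
            )
    if len(estimable) < df["race_ethnicity"].dropna().nunique():
        y, X, groups, names, df = _design(
            cohort[cohort["race_ethnicity"].isin(estimable)], spec
        )
    races = sorted(df["race_ethnicity"].dropna().unique())
    if len(races) < 2:
        raise ValueError("interaction test needs at least 2 race/ethnicity levels")
    race_ref = races[0]
    race_cols, race_names = [], []
    for race in races[1:]:
        race_cols.append((df["race_ethnicity"] == race).to_numpy(dtype=float))
        race_names.append(f"race[{race}]")
    X_main = np.column_stack([X] + race_cols)

    exp_idx = [i for i, nm in enumerate(names) if nm.startswith("exposure[")]
    inter_cols = []
    for i in exp_idx:
        for rc in race_cols:
            inter_cols.append(X[:, i] * rc)
    X_inter = np.column_stack([X_main] + inter_cols)

    fit_main = fit_random_intercept_logit(y, X_main, groups, n_quad=n_quad)
    start = np.concatenate([fit_main.beta, np.zeros(len(inter_cols)), [fit_main.sigma_u]])
    fit_inter = fit_random_intercept_logit(y, X_inter, groups, n_quad=n_quad, start=start)
    if not (fit_main.converged and fit_inter.converged):
        raise RuntimeError("interaction test requires both nested fits to converge")
    lr = max(0.0, 2.0 * (fit_inter.loglik - fit_main.loglik))
    df_test = len(exp_idx) * (len(races) - 1)
    p = float(stats.chi2.sf(lr, df_test))
    return InteractionTest(spec.outcome, spec.exposure, lr, df_test, p)


def prevalence_tables(cohort: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Descriptive tables: outcome prevalence (%) by exposure category
    and covariate level, and the distribution of characteristics by
    race/ethnicity (column percent)."""
    outcomes = [c for c in BINARY_OUTCOMES if c in cohort.columns]
    groupers = {
        "freeman": "freeman_label",
        "dg_stage": "dg_stage",
        "race_ethnicity": "race_ethnicity",
        "payer": "payer",
        "primiparous": "primiparous",
        "adequate_care": "adequate_care",
    }
    prevalence_rows = []
    overall = {"characteristic": "overall", "level": "", "n": len(cohort)}
    for oc in outcomes:
        overall[f"{oc}_pct"] = 100.0 * cohort[oc].mean()
    prevalence_rows.append(overall)
    for label, col in groupers.items():
        if col not in cohort.columns:
            continue
        for level, sub in cohort.groupby(col, dropna=True):
            row = {"characteristic": label, "level": str(level), "n": len(sub)}
            for oc in outcomes:
                row[f"{oc}_pct"] = 100.0 * sub[oc].mean()
            prevalence_rows.append(row)
    prevalence = pd.DataFrame(prevalence_rows)

    by_race = None
    if "race_ethnicity" in cohort.columns:
        dist_rows = []
        for label, col in groupers.items():
            if col == "race_ethnicity" or col not in cohort.columns:
                continue
            ct = pd.crosstab(cohort[col], cohort["race_ethnicity"], normalize="columns") * 100
            ct.insert(0, "characteristic", label)
            dist_rows.append(ct.reset_index(names="level"))
        if dist_rows:
            by_race = pd.concat(dist_rows, ignore_index=True)
    return {"prevalence": prevalence, "by_race": by_race}


def results_to_frame(results: list[ModelResult]) -> pd.DataFrame:
    """Flatten model results to one row per exposure level (Table-3/4
    shape): outcome × exposure level × stratum × adjustment set."""
    rows = []
    for r in results:
        for level, e in r.estimates.items():
            rows.append(
                {
                    "outcome": r.spec.outcome,
                    "exposure": r.spec.exposure,
                    "referent": r.spec.referent_level,
                    "level": level,
                    "adjustment": r.spec.adjustment,
                    "stratum": r.spec.stratum,
                    "family": r.family,
                    "estimate": e.estimate,
                    "se": e.se,
                    "or": e.or_,
                    "ci_low": e.or_ci_low if r.family == "logistic" else e.ci_low,
                    "ci_high": e.or_ci_high if r.family == "logistic" else e.ci_high,
                    "intercept_variance": r.intercept_variance,
                    "n_obs": r.n_obs,
                    "n_clusters": r.n_clusters,
                    "converged": r.converged,
                }
            )
    return pd.DataFrame(rows)
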