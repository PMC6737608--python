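"""Fitting PAF ingredients from subject-level case-control data.

The estimable PAF expressions need three ingredients per risk factor:
confounder-adjusted log-odds ratios relative to a reference level (from a
logistic regression of case status on the exposure and confounders), the
exposure distribution among cases (for the exact expression), and the
exposure prevalence among controls (for the approximation).  This module
extracts all three from a :class:`CaseControlDataset`, composes them with
the formula layer in :mod:`pafkit.core`, and attaches stratified
nonparametric percentile bootstrap confidence intervals.

Continuous exposures are modelled with a natural cubic spline basis inside
the logistic fit; the reference value is chosen as the minimum of the
fitted log-odds curve over a trimmed quantile range of the observed
exposure (the reference must be a realizable value), and the curve is
re-anchored to vanish there.

The bootstrap resamples cases and controls separately (respecting the
outcome-dependent sampling design) and refits the identical model on
resampled rows of the design matrix, warm-started at the full-data
estimate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
import statsmodels.formula.api as smf

from . import core
from .core import ContinuousSummary, LevelSummary, PAFResult
from .exceptions import (
    BootstrapFailureError,
    DegenerateLevelError,
    FitFailureError,
    InvalidArgumentError,
)

__all__ = [
    "ExposureSpec",
    "CaseControlDataset",
    "FittedExposureModel",
    "BootstrapCI",
    "fit_exposure_model",
    "select_reference_level",
    "control_case_distributions",
    "estimate_paf",
    "bootstrap_ci",
    "read_case_control_csv",
    "results_to_frame",
    "frame_to_results",
    "read_summary_csv",
    "write_summary_csv",
    "SUMMARY_COLUMNS",
]

logger = logging.getLogger("pafkit")

SUMMARY_COLUMNS = [
    "factor",
    "kind",
    "prevalence",
    "beta_ave",
    "or_ave",
    "approx_paf",
    "exact_paf",
    "ci_lower",
    "ci_upper",
]

_DEFAULT_TRIM = (0.01, 0.99)
_REFERENCE_GRID_SIZE = 501


@dataclass(frozen=True)
class ExposureSpec:
    """Declaration of one exposure column.

    ``kind`` is "binary", "multicategory" or "continuous"; ``reference``
    is the minimum-risk level label for discrete exposures (defaults to 0
    if present in the data, otherwise the smallest observed label).
    """

    kind: str
    reference: Optional[object] = None

    def __post_init__(self):
        if self.kind not in ("binary", "multicategory", "continuous"):
            raise InvalidArgumentError(f"unknown exposure kind {self.kind!r}")


@dataclass
class CaseControlDataset:
    """Subject-level case-control table with column declarations."""

    df: pd.DataFrame
    outcome: str
    exposures: dict
    confounders: list

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        outcome: str,
        exposures: dict,
        confounders: Sequence[str] = (),
    ) -> "CaseControlDataset":
        exposures = {
            name: (spec if isinstance(spec, ExposureSpec) else ExposureSpec(**spec))
            for name, spec in exposures.items()
        }
        declared = [outcome, *exposures, *confounders]
        missing_cols = [c for c in declared if c not in df.columns]
        if missing_cols:
            raise InvalidArgumentError(f"columns not found: {missing_cols}")
        sub = df[declared].copy()
        n_before = len(sub)
        sub = sub.dropna()
        dropped = n_before - len(sub)
        if dropped:
            logger.info("dropped %d rows with missing declared values", dropped)
        y = sub[outcome]
        if not set(np.unique(y)).issubset({0, 1}):
            raise InvalidArgumentError("outcome must be strictly 0/1")
        if y.sum() == 0 or (1 - y).sum() == 0:
            raise InvalidArgumentError("need at least one case and one control")
        for name, spec in exposures.items():
            if spec.kind != "continuous" and spec.reference is not None:
                if spec.reference not in set(sub[name]):
                    raise InvalidArgumentError(
                        f"declared reference {spec.reference!r} absent from "
                        f"exposure {name!r}"
                    )
        return cls(
            df=sub.reset_index(drop=True),
            outcome=outcome,
            exposures=exposures,
            confounders=list(confounders),
        )

    @property
    def n_cases(self) -> int:
        return int(self.df[self.outcome].sum())

    @property
    def n_controls(self) -> int:
        return len(self.df) - self.n_cases

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def read_case_control_csv(
    path, outcome: str, exposures: dict, confounders: Sequence[str] = ()
) -> CaseControlDataset:
    """Load a subject-level CSV (header row required) and declare columns."""
    df = pd.read_csv(path)
    if len(df) == 0:
        raise InvalidArgumentError(f"no rows in {path}")
    return CaseControlDataset.from_dataframe(df, outcome, exposures, confounders)


@dataclass
class FittedExposureModel:
    """One fitted logistic exposure model.

    For discrete exposures ``betas`` maps each level to its log-odds ratio
    versus the reference (exactly 0 at the reference).  For continuous
    exposures :meth:`curve` evaluates the fitted log-odds curve anchored
    at ``reference_value``.
    """

    exposure: str
    exposure_kind: str
    intercept: float
    confounder_effects: dict
    converged: bool
    n_cases: int
    n_controls: int
    levels: Optional[tuple] = None
    betas: Optional[dict] = None
    beta_se: Optional[dict] = None
    reference_value: Optional[float] = None
    _params: np.ndarray = field(default=None, repr=False)
    _cov: np.ndarray = field(default=None, repr=False)
    _lp_raw: Callable = field(default=None, repr=False)
    _exposure_values: np.ndarray = field(default=None, repr=False)

    def curve(self, values):
        """Log-odds ratio curve beta(j), zero at ``reference_value``."""
        if self.exposure_kind != "continuous":
            raise InvalidArgumentError("curve() is only defined for continuous models")
        values = np.asarray(values, dtype=float)
        anchor = self._lp_raw(np.array([self.reference_value]))[0]
        return self._lp_raw(values) - anchor


def _exposure_levels(values: pd.Series, spec: ExposureSpec) -> list:
    uniq = sorted(pd.unique(values))
    ref = spec.reference
    if ref is None:
        ref = 0 if 0 in uniq else uniq[0]
    if ref not in uniq:
        raise InvalidArgumentError(f"reference level {ref!r} absent from data")
    return [ref] + [u for u in uniq if u != ref]


def _confounder_terms(data: CaseControlDataset, confounders: Sequence[str]) -> list:
    terms = []
    for name in confounders:
        col = data.df[name]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 2:
            terms.append(f"Q('{name}')")
        elif pd.api.types.is_numeric_dtype(col):
            terms.append(f"Q('{name}')")  # 0/1 indicator enters linearly
        else:
            terms.append(f"C(Q('{name}'))")
    return terms


def fit_exposure_model(
    data: CaseControlDataset,
    exposure: str,
    confounders: Optional[Sequence[str]] = None,
    spline_df: int = 4,
    trim=_DEFAULT_TRIM,
) -> FittedExposureModel:
    """Maximum-likelihood logistic fit of outcome on one exposure.

    Discrete exposures enter as indicator contrasts against the declared
    reference; continuous exposures as a natural cubic spline with
    ``spline_df`` degrees of freedom.  Confounders enter additively
    (numeric: linear; non-numeric: indicator contrasts).  Coefficients are
    re-expressed relative to the reference level/value.
    """
    if exposure not in data.exposures:
        raise InvalidArgumentError(f"exposure {exposure!r} not declared")
    spec = data.exposures[exposure]
    if confounders is None:
        confounders = data.confounders
    df = data.df
    y = df[data.outcome]

    if spec.kind == "continuous":
        if spline_df < 2:
            raise InvalidArgumentError("spline_df must be >= 2")
        expo_term = f"cr(Q('{exposure}'), df={int(spline_df)})"
    else:
        levels = _exposure_levels(df[exposure], spec)
        for level in levels:
            mask = df[exposure] == level
            if not (y[mask] == 1).any() or not (y[mask] == 0).any():
                raise DegenerateLevelError(
                    f"exposure level {level!r} absent among "
                    f"{'cases' if not (y[mask] == 1).any() else 'controls'}"
                )
        expo_term = f"C(Q('{exposure}'), Treatment(reference={levels[0]!r}))"

    rhs = " + ".join([expo_term, *_confounder_terms(data, confounders)])
    formula = f"Q('{data.outcome}') ~ {rhs}"
    try:
        model = smf.logit(formula, data=df)
        fit = model.fit(disp=0, maxiter=200)
    except Exception as exc:  # separation, singular Hessian, ...
        raise FitFailureError(f"logistic fit failed: {exc}", diagnostics=exc) from exc
    if not fit.mle_retvals.get("converged", False):
        raise FitFailureError(
            "logistic fit did not converge", diagnostics=fit.mle_retvals
        )

    design_info = model.data.design_info
    params = np.asarray(fit.params)
    cov = np.asarray(fit.cov_params())
    conf_effects = {
        name: float(val)
        for name, val in fit.params.items()
        if not name.startswith(("Intercept", "C(Q('" + exposure, "cr(Q('" + exposure))
    }
    fixed = {name: df[name].iloc[0] for name in confounders}

    def lp_for(exposure_values: np.ndarray) -> np.ndarray:
        new = pd.DataFrame({exposure: exposure_values})
        for name, val in fixed.items():
            new[name] = val
        (X,) = patsy.build_design_matrices([design_info], new)
        return np.asarray(X) @ params

    common = dict(
        exposure=exposure,
        intercept=float(fit.params.get("Intercept", 0.0)),
        confounder_effects=conf_effects,
        converged=True,
        n_cases=data.n_cases,
        n_controls=data.n_controls,
        _params=params,
        _cov=cov,
        _lp_raw=lp_for,
        _exposure_values=df[exposure].to_numpy(),
    )

    if spec.kind == "continuous":
        result = FittedExposureModel(
            exposure_kind="continuous", reference_value=np.nan, **common
        )
        select_reference_level(result, trim=trim)
        return result

    # discrete: betas as linear-predictor differences vs the reference row
    level_values = np.asarray(levels, dtype=object)
    new = pd.DataFrame({exposure: level_values})
    for name, val in fixed.items():
        new[name] = val
    (L,) = patsy.build_design_matrices([design_info], new)
    L = np.asarray(L)
    lp = L @ params
    diffs = L - L[0]
    betas = {lev: float(lp[i] - lp[0]) for i, lev in enumerate(levels)}
    se = {
        lev: float(math.sqrt(max(diffs[i] @ cov @ diffs[i], 0.0)))
        for i, lev in enumerate(levels)
    }
    return FittedExposureModel(
        exposure_kind=spec.kind,
        levels=tuple(levels),
        betas=betas,
        beta_se=se,
        **common,
    )


def select_reference_level(
    model: FittedExposureModel, trim=_DEFAULT_TRIM
) -> float:
    """Pick the minimum-risk value of a continuous exposure.

    Scans the fitted log-odds curve over a grid spanning the
    [trim_low, trim_high] observed quantiles (the reference must be a
    realizable value with data nearby) and re-anchors the curve at the
    argmin, ties broken toward the smallest value.  Returns the chosen
    reference value and updates the model in place.
    """
    if model.exposure_kind != "continuous":
        raise InvalidArgumentError(
            "reference-level selection applies to continuous models only"
        )
    lo, hi = np.quantile(model._exposure_values, [trim[0], trim[1]])
    grid = np.linspace(lo, hi, _REFERENCE_GRID_SIZE)
    lp = model._lp_raw(grid)
    j0 = float(grid[int(np.argmin(lp))])
    model.reference_value = j0
    return j0


@dataclass(frozen=True)
class DiscreteDistributions:
    levels: tuple
    control_probs: tuple
    case_probs: tuple

    @property
    def degenerate(self) -> bool:
        """True when all controls sit at the reference level."""
        return self.control_probs[0] >= 1.0


@dataclass(frozen=True)
class ContinuousSamples:
    control_values: np.ndarray
    case_values: np.ndarray


def control_case_distributions(data: CaseControlDataset, exposure: str):
    """Empirical exposure distributions split by outcome.

    Discrete: per-level proportions among controls and among cases
    (reference level first).  Continuous: the raw value samples.
    """
    spec = data.exposures[exposure]
    y = data.df[data.outcome].to_numpy()
    values = data.df[exposure]
    if spec.kind == "continuous":
        return ContinuousSamples(
            control_values=values[y == 0].to_numpy(dtype=float),
            case_values=values[y == 1].to_numpy(dtype=float),
        )
    levels = _exposure_levels(values, spec)
    controls = values[y == 0]
    cases = values[y == 1]
    control_probs = tuple(float((controls == lev).mean()) for lev in levels)
    case_probs = tuple(float((cases == lev).mean()) for lev in levels)
    return DiscreteDistributions(
        levels=tuple(levels), control_probs=control_probs, case_probs=case_probs
    )


@dataclass(frozen=True)
class BootstrapCI:
    """Percentile bootstrap intervals for the exact and approximate PAF."""

    exact: tuple
    approx: tuple
    level: float
    n_reps: int
    n_failed: int


def estimate_paf(
    data: CaseControlDataset,
    exposure: str,
    confounders: Optional[Sequence[str]] = None,
    spline_df: int = 4,
    trim=_DEFAULT_TRIM,
    n_boot: Optional[int] = None,
    ci_level: float = 0.99,
    seed: Optional[int] = None,
) -> PAFResult:
    """Exact and approximate PAF for one declared exposure.

    Fits the logistic exposure model, combines the fitted log-odds ratios
    with the empirical case-side distribution (exact PAF) and with the
    control prevalence and control-weighted average log-OR (approximate
    PAF).  For continuous exposures the control prevalence is 1 by
    convention (every non-reference value counts as exposed).  With
    ``n_boot`` set, attaches stratified percentile bootstrap intervals.
    """
    model = fit_exposure_model(data, exposure, confounders, spline_df, trim)
    dist = control_case_distributions(data, exposure)

    if model.exposure_kind == "continuous":
        summary = ContinuousSummary(
            control_values=dist.control_values,
            case_values=dist.case_values,
            beta_curve=model.curve,
            reference_value=model.reference_value,
        )
        beta_ave = core.beta_ave_continuous(summary)
        exact = core.exact_paf_continuous(summary)
        prevalence = 1.0
    else:
        summary = LevelSummary(
            level_labels=dist.levels,
            control_probs=dist.control_probs,
            case_probs=dist.case_probs,
            betas=tuple(model.betas[lev] for lev in dist.levels),
        )
        beta_ave = core.beta_ave_discrete(summary)
        exact = core.exact_paf_discrete(summary)
        prevalence = summary.control_prevalence

    result = PAFResult.build(
        factor_name=exposure,
        exposure_kind=model.exposure_kind,
        control_prevalence=prevalence,
        beta_ave=beta_ave,
        exact_paf=exact,
        ci_level=ci_level,
    )
    if n_boot:
        ci = bootstrap_ci(
            data,
            exposure,
            confounders,
            n_reps=n_boot,
            level=ci_level,
            seed=seed,
            spline_df=spline_df,
            trim=trim,
        )
        result.ci_lower, result.ci_upper = ci.exact
        result.approx_ci_lower, result.approx_ci_upper = ci.approx
    return result


def bootstrap_ci(
    data: CaseControlDataset,
    exposure: str,
    confounders: Optional[Sequence[str]] = None,
    n_reps: int = 999,
    level: float = 0.99,
    seed: Optional[int] = None,
    spline_df: int = 4,
    trim=_DEFAULT_TRIM,
) -> BootstrapCI:
    """Stratified nonparametric percentile bootstrap for both PAF estimators.

    Cases and controls are resampled separately with replacement,
    preserving the stratum sizes, and the identical logistic model is
    refit on the resampled design-matrix rows (warm-started at the
    full-data estimate).  Replicates whose refit fails (separation on a
    resample, a level dropping out) are skipped and counted; more than 10%
    failures raise.  The resample stream depends only on ``seed`` and the
    data, so intervals at different confidence levels from the same seed
    are nested.
    """
    if n_reps < 2:
        raise InvalidArgumentError("n_reps must be >= 2")
    if not (0.0 < level < 1.0):
        raise InvalidArgumentError("level must be in (0, 1)")
    spec = data.exposures[exposure]
    if confounders is None:
        confounders = data.confounders

    full = fit_exposure_model(data, exposure, confounders, spline_df, trim)
    # rebuild the full design once; bootstrap refits resample its rows
    expo = data.df[exposure]
    if spec.kind == "continuous":
        expo_term = f"cr(Q('{exposure}'), df={int(spline_df)})"
        levels = None
    else:
        levels = _exposure_levels(expo, spec)
        expo_term = f"C(Q('{exposure}'), Treatment(reference={levels[0]!r}))"
    rhs = " + ".join([expo_term, *_confounder_terms(data, confounders)])
    y_full, X_full = patsy.dmatrices(
        f"Q('{data.outcome}') ~ {rhs}", data.df, return_type="dataframe"
    )
    design_info = X_full.design_info
    y_arr = np.asarray(y_full).ravel()
    X_arr = np.asarray(X_full)
    start = full._params

    fixed = {name: data.df[name].iloc[0] for name in confounders}

    if spec.kind == "continuous":
        # per-subject and reference-grid exposure bases (confounders fixed;
        # differences of linear predictors cancel the fixed part)
        lo, hi = np.quantile(expo.to_numpy(dtype=float), [trim[0], trim[1]])
        grid = np.linspace(lo, hi, _REFERENCE_GRID_SIZE)

        def expo_rows(values):
            new = pd.DataFrame({exposure: values})
            for name, val in fixed.items():
                new[name] = val
            (M,) = patsy.build_design_matrices([design_info], new)
            return np.asarray(M)

        E = expo_rows(expo.to_numpy(dtype=float))
        G = expo_rows(grid)
        level_codes = None
        L = None
    else:
        new = pd.DataFrame({exposure: np.asarray(levels, dtype=object)})
        for name, val in fixed.items():
            new[name] = val
        (L,) = patsy.build_design_matrices([design_info], new)
        L = np.asarray(L)
        lookup = {lev: i for i, lev in enumerate(levels)}
        level_codes = expo.map(lookup).to_numpy()
        E = G = None

    case_idx = np.flatnonzero(y_arr == 1)
    control_idx = np.flatnonzero(y_arr == 0)
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    exact_reps, approx_reps = [], []
    n_failed = 0
    for rep in range(n_reps):
        take = np.concatenate(
            [
                rng.choice(case_idx, size=case_idx.size, replace=True),
                rng.choice(control_idx, size=control_idx.size, replace=True),
            ]
        )
        try:
            fit = sm.Logit(y_arr[take], X_arr[take]).fit(
                disp=0, start_params=start, maxiter=100, warn_convergence=False
            )
            if not fit.mle_retvals.get("converged", False):
                raise FitFailureError("bootstrap refit did not converge")
            theta = np.asarray(fit.params)
            case_take = take[: case_idx.size]
            control_take = take[case_idx.size:]
            if spec.kind == "continuous":
                lp_grid = G @ theta
                anchor = lp_grid.min()
                lp_subj = E @ theta - anchor
                beta_ave = float(np.mean(lp_subj[control_take]))
                exact = float(np.mean(1.0 - np.exp(-lp_subj[case_take])))
                prevalence = 1.0
            else:
                lp_levels = L @ theta
                betas = lp_levels - lp_levels[0]
                codes_case = level_codes[case_take]
                codes_control = level_codes[control_take]
                case_probs = np.bincount(codes_case, minlength=len(levels)) / len(
                    codes_case
                )
                control_probs = np.bincount(
                    codes_control, minlength=len(levels)
                ) / len(codes_control)
                prevalence = 1.0 - control_probs[0]
                if prevalence <= 0:
                    raise FitFailureError("no exposed controls in resample")
                beta_ave = float(
                    np.sum(control_probs[1:] * betas[1:]) / prevalence
                )
                exact = float(np.sum(case_probs[1:] * (1.0 - np.exp(-betas[1:]))))
            exact_reps.append(exact)
            approx_reps.append(prevalence * beta_ave)
        except Exception:
            n_failed += 1
            logger.debug("bootstrap replicate %d failed", rep)

    if not exact_reps:
        raise BootstrapFailureError("all bootstrap resamples failed to refit")
    if n_failed > 0.1 * n_reps:
        raise BootstrapFailureError(
            f"{n_failed}/{n_reps} bootstrap resamples failed to refit"
        )
    alpha = (1.0 - level) / 2.0
    q = [100 * alpha, 100 * (1 - alpha)]
    exact_ci = tuple(np.percentile(exact_reps, q))
    approx_ci = tuple(np.percentile(approx_reps, q))
    return BootstrapCI(
        exact=exact_ci,
        approx=approx_ci,
        level=level,
        n_reps=n_reps,
        n_failed=n_failed,
    )


# ---------------------------------------------------------------------------
# summary-table IO (the schema of a published risk-factor summary table:
# factor, kind, prevalence, beta_ave, or_ave, approx_paf, exact_paf, CI)
# ---------------------------------------------------------------------------


def results_to_frame(results: Sequence[PAFResult]) -> pd.DataFrame:
    """Summary table from PAF results, ranked by approximate PAF descending."""
    rows = [
        {
            "factor": r.factor_name,
            "kind": r.exposure_kind,
            "prevalence": r.control_prevalence,
            "beta_ave": r.beta_ave,
            "or_ave": r.or_ave,
            "approx_paf": r.approx_paf,
            "exact_paf": r.exact_paf,
            "ci_lower": r.ci_lower,
            "ci_upper": r.ci_upper,
        }
        for r in results
    ]
    df = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    return df.sort_values("approx_paf", ascending=False, kind="mergesort").reset_index(
        drop=True
    )


def frame_to_results(df: pd.DataFrame) -> list:
    """Rebuild PAF results from a summary table.

    This is the summary-only entry path: only ``factor``, ``prevalence``
    and ``beta_ave`` are required; the approximate PAF is recomputed as
    their product and other columns pass through when present.
    """
    required = {"factor", "prevalence", "beta_ave"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidArgumentError(f"summary table missing columns: {sorted(missing)}")
    results = []
    for _, row in df.iterrows():
        exact = row.get("exact_paf")
        results.append(
            PAFResult.build(
                factor_name=row["factor"],
                exposure_kind=row.get("kind", "binary"),
                control_prevalence=float(row["prevalence"]),
                beta_ave=float(row["beta_ave"]),
                exact_paf=None if exact is None or pd.isna(exact) else float(exact),
                ci_lower=None if pd.isna(row.get("ci_lower")) else row.get("ci_lower"),
                ci_upper=None if pd.isna(row.get("ci_upper")) else row.get("ci_upper"),
            )
        )
    return results


def write_summary_csv(results_or_frame, path) -> None:
    df = (
        results_or_frame
        if isinstance(results_or_frame, pd.DataFrame)
        else results_to_frame(results_or_frame)
    )
    df.to_csv(path, index=False)


def read_summary_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if len(df) == 0:
        raise InvalidArgumentError(f"no rows in {path}")
    return df
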