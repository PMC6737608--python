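"""Synthetic case-control data with known counterfactual truth.

Cohorts are generated from the same logistic disease model the estimators
assume: a confounder ``C`` influences both exposure and outcome, the
exposure ``A`` is binary, multicategory or continuous, and the disease
indicator follows

    logit P(Y = 1 | A = j, C = c) = mu + beta_j + gamma_y * c.

Potential outcomes ``Y^{a=j}`` are materialized for every discrete level
(or for the reference value only, for continuous exposures) using a single
shared uniform draw per subject, so counterfactuals are monotonically
coupled and consistency (``Y == Y^{a}`` at the subject's own exposure)
holds by construction.  The true PAF is then a Monte-Carlo average of the
counterfactual definition — the proportion of disease removed by setting
everyone to the reference level — and serves as the oracle against which
the case-control estimators are checked.

Randomness is organised as named substreams spawned from one root seed
(confounder, exposure, outcome, sampling), so adding a stage never
perturbs earlier draws.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .exceptions import InvalidArgumentError
from .estimation import CaseControlDataset, ExposureSpec

__all__ = [
    "ConfounderSpec",
    "SimulationConfig",
    "SimulatedCohort",
    "simulate_cohort",
    "sample_case_control",
    "true_paf_monte_carlo",
]

_STREAMS = ("confounder", "exposure", "outcome", "sampling")


@dataclass(frozen=True)
class ConfounderSpec:
    """A single confounder affecting both exposure and outcome odds.

    ``kind`` is "binary" (Bernoulli(``prevalence``)) or "normal"
    (mean 0, sd 1).  ``effect_on_exposure`` shifts the exposure log-odds
    (binary/multicategory exposure: log-odds of each non-reference level;
    continuous exposure: shifts the mean); ``effect_on_outcome`` is the
    gamma coefficient in the outcome logit.
    """

    kind: str = "binary"
    prevalence: float = 0.5
    effect_on_exposure: float = 0.0
    effect_on_outcome: float = 0.0

    def __post_init__(self):
        if self.kind not in ("binary", "normal"):
            raise InvalidArgumentError(f"unknown confounder kind {self.kind!r}")
        if self.kind == "binary" and not (0.0 < self.prevalence < 1.0):
            raise InvalidArgumentError("confounder prevalence must be in (0, 1)")


@dataclass(frozen=True)
class SimulationConfig:
    """Generating model for one synthetic cohort.

    Defaults describe a rare-disease binary-exposure study: baseline
    exposure prevalence 0.3, odds ratio 1.5 (beta = ln 1.5), baseline
    disease log-odds logit(0.01), and a balanced binary confounder with
    moderate effects on both exposure and outcome.

    For continuous exposures the curve is ``beta(j) =
    curve_slope * (j - curve_reference) + curve_quad * (j - curve_reference)**2``
    and exposure values are Normal(``continuous_mean`` + confounder shift,
    ``continuous_sd``).
    """

    exposure_kind: str = "binary"
    prevalence: float = 0.3  # baseline P(A=1 | C at its reference) for binary
    level_probs: Optional[tuple] = None  # multicategory baseline probabilities
    betas: tuple = (0.0, math.log(1.5))
    mu: float = logit(0.01)
    confounder: Optional[ConfounderSpec] = field(
        default_factory=lambda: ConfounderSpec(
            kind="binary", prevalence=0.5,
            effect_on_exposure=0.4, effect_on_outcome=0.7,
        )
    )
    n: int = 1_000_000
    seed: int = 0
    # continuous-exposure parameters
    continuous_mean: float = 0.0
    continuous_sd: float = 1.0
    curve_slope: float = 0.4
    curve_quad: float = 0.0
    curve_reference: float = 0.0

    def __post_init__(self):
        if self.exposure_kind not in ("binary", "multicategory", "continuous"):
            raise InvalidArgumentError(f"unknown exposure kind {self.exposure_kind!r}")
        if self.n < 1:
            raise InvalidArgumentError("cohort size n must be >= 1")
        if self.exposure_kind == "binary":
            if not (0.0 < self.prevalence < 1.0):
                raise InvalidArgumentError("exposure prevalence must be in (0, 1)")
            if len(self.betas) != 2 or self.betas[0] != 0.0:
                raise InvalidArgumentError("binary betas must be (0, beta1)")
        elif self.exposure_kind == "multicategory":
            if self.level_probs is None:
                raise InvalidArgumentError("multicategory config needs level_probs")
            probs = np.asarray(self.level_probs, dtype=float)
            if probs.size < 2 or abs(probs.sum() - 1.0) > 1e-9 or np.any(probs < 0):
                raise InvalidArgumentError("level_probs must be a probability vector")
            if len(self.betas) != probs.size or self.betas[0] != 0.0:
                raise InvalidArgumentError(
                    "betas must match level_probs length with betas[0] == 0"
                )
        if not (0.0 < expit(self.mu) < 1.0):
            raise InvalidArgumentError("mu implies a degenerate disease probability")

    def beta_curve(self, values):
        """Log-OR curve for the continuous exposure kind."""
        d = np.asarray(values, dtype=float) - self.curve_reference
        return self.curve_slope * d + self.curve_quad * d ** 2

    @property
    def levels(self) -> tuple:
        if self.exposure_kind == "binary":
            return (0, 1)
        return tuple(range(len(self.level_probs)))

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        conf = d.get("confounder")
        if conf is not None and not isinstance(conf, ConfounderSpec):
            d["confounder"] = ConfounderSpec(**conf)
        for key in ("betas", "level_probs"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        """Load a config from a JSON or YAML file."""
        text = open(path).read()
        if str(path).endswith((".yml", ".yaml")):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


@dataclass
class SimulatedCohort:
    """A cohort with factual and counterfactual outcomes.

    ``table`` has one row per subject: confounder ``c``, exposure ``a``,
    factual outcome ``y``, and potential-outcome columns ``y_pot_<j>`` for
    each discrete level ``j`` (continuous kind: ``y_pot_ref`` only).
    """

    table: pd.DataFrame
    config: SimulationConfig

    @property
    def n_cases(self) -> int:
        return int(self.table["y"].sum())

    @property
    def n_controls(self) -> int:
        return int((1 - self.table["y"]).sum())


def _spawn_streams(seed: int) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(s) for name, s in zip(_STREAMS, children)}


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Draw a cohort from the generating model (reproducible given seed)."""
    rng = _spawn_streams(config.seed)
    n = config.n

    conf = config.confounder
    if conf is None:
        c = np.zeros(n)
        g_a = g_y = 0.0
    else:
        if conf.kind == "binary":
            c = (rng["confounder"].random(n) < conf.prevalence).astype(float)
        else:
            c = rng["confounder"].standard_normal(n)
        g_a, g_y = conf.effect_on_exposure, conf.effect_on_outcome

    u_expo = rng["exposure"].random(n)
    if config.exposure_kind == "binary":
        p_a = expit(logit(config.prevalence) + g_a * c)
        a = (u_expo < p_a).astype(int)
        betas = np.asarray(config.betas)
        linpred_by_level = config.mu + betas[:, None] + g_y * c[None, :]
    elif config.exposure_kind == "multicategory":
        # confounder multiplies the odds of every non-reference level
        base = np.asarray(config.level_probs, dtype=float)
        w = np.tile(base, (n, 1))
        w[:, 1:] *= np.exp(g_a * c)[:, None]
        w /= w.sum(axis=1, keepdims=True)
        cum = np.cumsum(w, axis=1)
        a = (u_expo[:, None] > cum).sum(axis=1)
        betas = np.asarray(config.betas)
        linpred_by_level = config.mu + betas[:, None] + g_y * c[None, :]
    else:  # continuous
        a = (
            config.continuous_mean
            + g_a * c
            + config.continuous_sd * rng["exposure"].standard_normal(n)
        )
        linpred_by_level = None

    u_out = rng["outcome"].random(n)
    cols = {"c": c, "a": a}
    if config.exposure_kind == "continuous":
        p_ref = expit(config.mu + g_y * c)  # beta(reference) == 0
        p_fact = expit(config.mu + config.beta_curve(a) + g_y * c)
        if np.any(p_fact <= 0) or np.any(p_fact >= 1):
            raise InvalidArgumentError("config implies degenerate disease probability")
        cols["y_pot_ref"] = (u_out < p_ref).astype(int)
        cols["y"] = (u_out < p_fact).astype(int)
    else:
        p_by_level = expit(linpred_by_level)  # (K+1, n)
        y_pot = (u_out[None, :] < p_by_level).astype(int)
        for j in range(y_pot.shape[0]):
            cols[f"y_pot_{j}"] = y_pot[j]
        cols["y"] = y_pot[a, np.arange(n)]  # consistency
    return SimulatedCohort(table=pd.DataFrame(cols), config=config)


def sample_case_control(
    cohort: SimulatedCohort, n_cases: int, n_controls: int, seed: int
) -> CaseControlDataset:
    """Outcome-dependent sample: draw cases and controls without replacement.

    Potential-outcome columns are stripped; the returned dataset carries
    the exposure and confounder declarations matching the generating model.
    """
    tab = cohort.table
    case_idx = np.flatnonzero(tab["y"].to_numpy() == 1)
    control_idx = np.flatnonzero(tab["y"].to_numpy() == 0)
    if len(case_idx) < n_cases or len(control_idx) < n_controls:
        raise InvalidArgumentError(
            f"cohort has {len(case_idx)} cases / {len(control_idx)} controls; "
            f"requested {n_cases} / {n_controls}"
        )
    rng = _spawn_streams(seed)["sampling"]
    take = np.concatenate(
        [
            rng.choice(case_idx, size=n_cases, replace=False),
            rng.choice(control_idx, size=n_controls, replace=False),
        ]
    )
    df = tab.iloc[take][["y", "a", "c"]].reset_index(drop=True)
    kind = cohort.config.exposure_kind
    reference = None if kind == "continuous" else 0
    has_conf = cohort.config.confounder is not None
    return CaseControlDataset.from_dataframe(
        df,
        outcome="y",
        exposures={"a": ExposureSpec(kind=kind, reference=reference)},
        confounders=["c"] if has_conf else [],
    )


def true_paf_monte_carlo(config: SimulationConfig, n: int, seed: int):
    """Monte-Carlo truth for the counterfactual PAF under ``config``.

    Simulates a cohort of size ``n`` and returns ``(paf, se)`` where
    ``paf = (P(Y=1) - P(Y^{a=ref}=1)) / P(Y=1)`` and ``se`` is a
    delta-method standard error of the ratio of means.
    """
    if n < 1000:
        raise InvalidArgumentError("n must be >= 1000 for a meaningful MC estimate")
    cfg = SimulationConfig.from_dict({**config.to_dict(), "n": n, "seed": seed})
    cohort = simulate_cohort(cfg)
    y = cohort.table["y"].to_numpy(dtype=float)
    ref_col = "y_pot_ref" if cfg.exposure_kind == "continuous" else "y_pot_0"
    y0 = cohort.table[ref_col].to_numpy(dtype=float)
    py = y.mean()
    if py == 0.0:
        raise InvalidArgumentError(
            "no cases in the simulated cohort; increase n or raise mu"
        )
    d = y - y0
    paf = d.mean() / py
    # delta method for mean(d)/mean(y)
    var = (
        np.var(d) / n + paf ** 2 * np.var(y) / n - 2 * paf * np.cov(d, y)[0, 1] / n
    ) / py ** 2
    return float(paf), float(math.sqrt(max(var, 0.0)))
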