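"""Exact and approximate population attributable fractions (PAF).

The population attributable fraction is the proportion of disease
prevalence that would be removed if everyone in the population were moved
to the minimum-risk (reference) level of an exposure.  Under the standard
causal identification assumptions (consistency, positivity, conditional
exchangeability), no exposure-confounder interaction on the multiplicative
scale, and a rare disease, the PAF for a discrete exposure with levels
``j = 0..K`` (``0`` = reference) is estimable from case-control data as

    PAF = sum_j P(A=j | Y=1) * (1 - exp(-beta_j)),

where ``beta_j`` is the confounder-adjusted log-odds ratio of level ``j``
versus the reference.  A first-order (Taylor) approximation re-expresses
this as the product of two interpretable quantities,

    PAF_a = P(A != 0 | Y=0) * beta_ave,

the prevalence of a non-reference exposure level among controls times a
control-distribution-weighted average log-odds ratio.  ``PAF_a`` is what
the fan plot and the attributable-fraction nomogram draw; its accuracy as
a stand-in for the exact expression is quantified in :mod:`pafkit.bias`.

All log-odds ratios in this module are natural logs.  Base-10 appears only
inside nomogram axis rendering (:mod:`pafkit.plots`).

Continuous exposures replace the sums above with integrals against the
conditional exposure densities in cases/controls; this module estimates
those integrals by plug-in empirical means over the observed case and
control samples, which avoids any bandwidth choice.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .exceptions import (
    ApproximationRangeWarning,
    DegenerateExposureError,
    InvalidArgumentError,
    NegativeEffectWarning,
)

__all__ = [
    "LevelSummary",
    "ContinuousSummary",
    "PAFResult",
    "approx_paf",
    "exact_paf_discrete",
    "beta_ave_discrete",
    "beta_ave_continuous",
    "exact_paf_continuous",
    "impact_fraction_approx",
]

_PROB_TOL = 1e-9


def _check_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise InvalidArgumentError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class LevelSummary:
    """Per-level summary of a binary or multicategory exposure.

    Index 0 is the reference (minimum-risk) level; ``betas[0]`` is fixed
    at 0 by definition.  ``control_probs``/``case_probs`` are the exposure
    distributions P(A=j | Y=0) and P(A=j | Y=1).
    """

    level_labels: tuple
    control_probs: tuple
    case_probs: tuple
    betas: tuple

    def __post_init__(self):
        labels = tuple(self.level_labels)
        cp = tuple(float(x) for x in self.control_probs)
        qp = tuple(float(x) for x in self.case_probs)
        betas = tuple(float(b) for b in self.betas)
        object.__setattr__(self, "level_labels", labels)
        object.__setattr__(self, "control_probs", cp)
        object.__setattr__(self, "case_probs", qp)
        object.__setattr__(self, "betas", betas)
        n = len(labels)
        if n < 2:
            raise InvalidArgumentError("need at least two exposure levels")
        if not (len(cp) == len(qp) == len(betas) == n):
            raise InvalidArgumentError(
                "level_labels, control_probs, case_probs and betas must share length"
            )
        for name, probs in (("control_probs", cp), ("case_probs", qp)):
            if any(p < -_PROB_TOL or p > 1 + _PROB_TOL for p in probs):
                raise InvalidArgumentError(f"{name} entries must lie in [0, 1]")
            if abs(sum(probs) - 1.0) > _PROB_TOL:
                raise InvalidArgumentError(f"{name} must sum to 1 (got {sum(probs)!r})")
        if betas[0] != 0.0:
            raise InvalidArgumentError("betas[0] (reference level) must be 0")
        if any(not math.isfinite(b) for b in betas):
            raise InvalidArgumentError("betas must be finite")

    @property
    def n_levels(self) -> int:
        return len(self.level_labels)

    @property
    def control_prevalence(self) -> float:
        """P(A != reference | Y=0)."""
        return 1.0 - self.control_probs[0]


@dataclass(frozen=True)
class ContinuousSummary:
    """Empirical summary of a continuous exposure.

    ``beta_curve`` maps an exposure value to the log-odds ratio relative to
    the reference value ``reference_value`` (where the curve must vanish).
    ``control_values``/``case_values`` are the observed exposure samples in
    controls and cases; they stand in for the conditional densities
    f(j | Y=0) and f(j | Y=1).
    """

    control_values: np.ndarray
    case_values: np.ndarray
    beta_curve: Callable[[np.ndarray], np.ndarray]
    reference_value: float

    def __post_init__(self):
        cv = np.asarray(self.control_values, dtype=float)
        qv = np.asarray(self.case_values, dtype=float)
        object.__setattr__(self, "control_values", cv)
        object.__setattr__(self, "case_values", qv)
        if cv.size == 0 or qv.size == 0:
            raise InvalidArgumentError("control and case samples must be non-empty")
        at_ref = float(np.asarray(self.beta_curve(np.array([self.reference_value])))[0])
        if abs(at_ref) > _PROB_TOL:
            raise InvalidArgumentError(
                f"beta_curve(reference_value) must be 0, got {at_ref!r}"
            )


@dataclass
class PAFResult:
    """Exact and approximate PAF for one risk factor.

    ``approx_paf`` is always ``control_prevalence * beta_ave`` and
    ``or_ave`` always ``exp(beta_ave)``; use :meth:`build` so those
    identities hold by construction.  ``control_prevalence`` is fixed at 1
    for continuous exposures (every value except the single reference point
    is a non-reference level).
    """

    factor_name: str
    exposure_kind: str  # binary | multicategory | continuous
    control_prevalence: float
    beta_ave: float
    or_ave: float
    exact_paf: Optional[float]
    approx_paf: float
    ci_lower: Optional[float] = None
    ci_upper: Optional[float] = None
    ci_level: float = 0.99
    approx_ci_lower: Optional[float] = field(default=None, repr=False)
    approx_ci_upper: Optional[float] = field(default=None, repr=False)

    @classmethod
    def build(
        cls,
        factor_name: str,
        exposure_kind: str,
        control_prevalence: float,
        beta_ave: float,
        exact_paf: Optional[float] = None,
        **kwargs,
    ) -> "PAFResult":
        return cls(
            factor_name=factor_name,
            exposure_kind=exposure_kind,
            control_prevalence=float(control_prevalence),
            beta_ave=float(beta_ave),
            or_ave=math.exp(beta_ave),
            exact_paf=None if exact_paf is None else float(exact_paf),
            approx_paf=approx_paf(control_prevalence, beta_ave),
            **kwargs,
        )


def approx_paf(control_prevalence: float, beta_ave: float) -> float:
    """First-order approximate PAF: control prevalence times average log-OR.

    Parameters
    ----------
    control_prevalence
        P(A != reference | Y=0), in (0, 1].
    beta_ave
        Average log-odds ratio (natural log).  A negative value means the
        declared reference is not the minimum-risk level; a warning is
        emitted and the (negative) product returned.

    Returns
    -------
    float
        ``control_prevalence * beta_ave``.  May exceed 1 for large odds
        ratios, in which case a warning is emitted but the value is
        returned unclipped.
    """
    p = _check_finite("control_prevalence", control_prevalence)
    b = _check_finite("beta_ave", beta_ave)
    if not (0.0 < p <= 1.0):
        raise InvalidArgumentError(f"control_prevalence must be in (0, 1], got {p}")
    if b < 0:
        warnings.warn(
            "beta_ave is negative: the reference level is not minimum-risk",
            NegativeEffectWarning,
            stacklevel=2,
        )
    result = p * b
    if result > 1.0:
        warnings.warn(
            f"approximate PAF {result:.3f} exceeds 1; the linear approximation "
            "is unreliable at this odds ratio",
            ApproximationRangeWarning,
            stacklevel=2,
        )
    return result


def exact_paf_discrete(summary: LevelSummary) -> float:
    """Exact (logistic plug-in) PAF for a discrete exposure.

    Computes ``sum_{j>=1} P(A=j|Y=1) * (1 - exp(-beta_j))``; for a binary
    exposure this is the familiar ``pi_c * (OR - 1) / OR`` with ``pi_c``
    the exposure prevalence among cases.
    """
    case_probs = np.asarray(summary.case_probs[1:])
    betas = np.asarray(summary.betas[1:])
    return float(np.sum(case_probs * (1.0 - np.exp(-betas))))


def beta_ave_discrete(summary: LevelSummary) -> float:
    """Control-weighted average log-odds ratio over non-reference levels.

    Returns ``sum_{j>=1} P(A=j|Y=0) beta_j / (1 - P(A=0|Y=0))``; for a
    binary exposure this reduces to ``beta_1`` exactly.
    """
    p0 = summary.control_probs[0]
    if p0 >= 1.0 - _PROB_TOL:
        raise DegenerateExposureError(
            "all controls are at the reference level; the average log-odds "
            "ratio is undefined"
        )
    control_probs = np.asarray(summary.control_probs[1:])
    betas = np.asarray(summary.betas[1:])
    return float(np.sum(control_probs * betas) / (1.0 - p0))


def beta_ave_continuous(summary: ContinuousSummary) -> float:
    """Average log-odds ratio of a continuous exposure.

    Empirical version of the integral of the log-OR curve against the
    control exposure density: the mean of ``beta_curve`` over the observed
    control sample.
    """
    return float(np.mean(np.asarray(summary.beta_curve(summary.control_values))))


def exact_paf_continuous(summary: ContinuousSummary) -> float:
    """Exact (plug-in) PAF for a continuous exposure.

    Empirical version of the integral of ``(e^beta - 1)/e^beta`` against
    the case exposure density: mean over cases of ``1 - exp(-beta(a))``.
    """
    betas = np.asarray(summary.beta_curve(summary.case_values))
    return float(np.mean(1.0 - np.exp(-betas)))


def impact_fraction_approx(
    control_prevalence: float, new_prevalence: float, beta_ave: float
) -> float:
    """Approximate impact fraction of a partial intervention.

    The impact fraction of an intervention that lowers exposure prevalence
    from ``control_prevalence`` to ``new_prevalence`` is the difference of
    the two approximate PAFs,

        (control_prevalence - new_prevalence) * beta_ave.

    For a halving of prevalence this coincides numerically with the
    approximate PAF evaluated at the halved prevalence; full elimination
    (``new_prevalence == 0``) recovers :func:`approx_paf`.
    """
    p = _check_finite("control_prevalence", control_prevalence)
    q = _check_finite("new_prevalence", new_prevalence)
    b = _check_finite("beta_ave", beta_ave)
    if not (0.0 <= q <= p <= 1.0):
        raise InvalidArgumentError(
            "need 0 <= new_prevalence <= control_prevalence <= 1, got "
            f"new={q}, control={p}"
        )
    return (p - q) * b


def binary_summary(
    control_prevalence: float,
    case_prevalence: float,
    beta: float,
    labels: Sequence = (0, 1),
) -> LevelSummary:
    """Convenience constructor for a K=1 (binary) :class:`LevelSummary`."""
    return LevelSummary(
        level_labels=tuple(labels),
        control_probs=(1.0 - control_prevalence, control_prevalence),
        case_probs=(1.0 - case_prevalence, case_prevalence),
        betas=(0.0, float(beta)),
    )
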