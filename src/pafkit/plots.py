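"""Fan plots and attributable-fraction nomograms.

Two graphical devices make the decomposition ``PAF_a = P * beta_ave``
visible for many risk factors at once:

* **Fan plot** — each factor is the point ``(1/P, beta_ave)``; the line
  through the origin and that point has slope ``P * beta_ave`` (the
  approximate PAF), which is also its intercept on a vertical axis placed
  at ``1/P = 1``.  Factors fan out on lines of increasing slope as their
  attributable fraction grows; a secondary axis labels ``beta_ave`` as an
  odds ratio.

* **Nomogram** — three parallel vertical axes (Fagan-style).  Taking logs
  of ``PAF_a = P * beta_ave`` makes ``log beta_ave`` the average of
  ``log P`` and ``log PAF_a`` (up to sign), so with the middle axis drawn
  at half scale each factor's prevalence, odds ratio and approximate PAF
  are exactly collinear.  With the OR on the left axis, a factor's line
  can be tilted about its left-axis point to show the approximate PAF
  under a different prevalence — either an intervention that lowers
  prevalence (an impact fraction) or an alternative population where the
  prevalence differs.

Layouts are computed in abstract plot coordinates first (exportable as
JSON and unit-testable without a graphics backend), then rendered with
matplotlib.  Display coordinates use base-10 logs for readable tick
labels; the computation layer stays in natural logs.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .bias import BiasSurface
from .core import PAFResult
from .exceptions import ApproximationRangeWarning, InvalidArgumentError

__all__ = [
    "FanPlotLayout",
    "NomogramLayout",
    "fan_layout",
    "nomogram_layout",
    "render",
    "bias_heatmap",
]

_SVG_HASHSALT = "pafkit"

PREVALENCE_TICKS = (0.01, 0.02, 0.05, 0.10, 0.20, 0.30, 0.50, 0.70, 0.90)
OR_TICKS = (1.1, 1.2, 1.5, 2.0, 3.0, 5.0)
PAF_TICKS = (0.01, 0.02, 0.05, 0.10, 0.20, 0.50, 1.00)


def _validate_results(results: Sequence[PAFResult]) -> None:
    if not results:
        raise InvalidArgumentError("no results to plot")
    for r in results:
        if not (0.0 < r.control_prevalence <= 1.0):
            raise InvalidArgumentError(
                f"{r.factor_name}: control prevalence must be in (0, 1]"
            )
        if r.beta_ave <= 0.0:
            raise InvalidArgumentError(
                f"{r.factor_name}: non-positive average log-odds ratio; plots "
                "require the reference to be the minimum-risk level"
            )
        if r.approx_paf <= 0.0:
            raise InvalidArgumentError(
                f"{r.factor_name}: non-positive approximate PAF"
            )


def _ranks(results: Sequence[PAFResult]) -> list:
    order = sorted(
        range(len(results)), key=lambda i: -results[i].approx_paf
    )  # stable: ties keep input order
    ranks = [0] * len(results)
    for rank, i in enumerate(order, start=1):
        ranks[i] = rank
    return ranks


@dataclass(frozen=True)
class FanFactor:
    name: str
    x: float  # 1 / control prevalence
    y: float  # beta_ave
    slope: float  # approx PAF; also the intercept on the axis at x = 1
    prevalence: float
    rank: int


@dataclass(frozen=True)
class FanPlotLayout:
    """Abstract coordinates of a fan plot.

    Each factor sits at ``(1/P, beta_ave)``; the origin line through it has
    slope (and x=1 intercept) equal to the approximate PAF.  The right
    axis relabels ordinates ``y`` as odds ratios ``e^y``.
    """

    factors: tuple
    prevalence_axis_labels: bool = True  # label x ticks in prevalence units

    def to_dict(self) -> dict:
        return {
            "kind": "fan",
            "factors": [asdict(f) for f in self.factors],
            "prevalence_axis_labels": self.prevalence_axis_labels,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def fan_layout(
    results: Sequence[PAFResult], prevalence_axis_labels: bool = True
) -> FanPlotLayout:
    """Fan-plot coordinates for a set of PAF results.

    Ranks are 1..N in descending order of approximate PAF.  Factors with
    prevalence 1 (continuous exposures) sit on the left boundary ``x = 1``
    where point ordinate and intercept coincide.
    """
    _validate_results(results)
    ranks = _ranks(results)
    factors = tuple(
        FanFactor(
            name=r.factor_name,
            x=1.0 / r.control_prevalence,
            y=r.beta_ave,
            slope=r.approx_paf,
            prevalence=r.control_prevalence,
            rank=rank,
        )
        for r, rank in zip(results, ranks)
    )
    return FanPlotLayout(factors=factors, prevalence_axis_labels=prevalence_axis_labels)


@dataclass(frozen=True)
class NomogramLine:
    name: str
    prevalence: float
    or_ave: float
    approx_paf: float
    y_left: float
    y_mid: float
    y_right: float
    rank: Optional[int] = None
    role: str = "factor"  # factor | intervention | alternative


@dataclass(frozen=True)
class NomogramLayout:
    """Three parallel axes at x = 0, 1/2, 1 with log-scale ordinates.

    ``ordering`` "prevalence-left" puts prevalence on the left axis, the
    odds ratio in the middle and the approximate PAF on the right;
    "or-left" swaps the first two.  The middle axis is drawn at half
    scale, which makes every factor's three points exactly collinear.
    """

    ordering: str
    lines: tuple
    axis_positions: tuple = (0.0, 0.5, 1.0)

    def to_dict(self) -> dict:
        return {
            "kind": "nomogram",
            "ordering": self.ordering,
            "axis_positions": list(self.axis_positions),
            "lines": [asdict(l) for l in self.lines],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _nomogram_ordinates(ordering: str, prevalence: float, beta_ave: float):
    paf = prevalence * beta_ave
    if ordering == "prevalence-left":
        return (-math.log10(prevalence), 0.5 * math.log10(beta_ave), math.log10(paf))
    return (-math.log10(beta_ave), 0.5 * math.log10(prevalence), math.log10(paf))


def nomogram_layout(
    results: Sequence[PAFResult],
    ordering: str = "prevalence-left",
    tilts: Optional[Sequence[tuple]] = None,
) -> NomogramLayout:
    """Nomogram coordinates for a set of PAF results.

    ``tilts`` is a list of ``(factor_name, new_prevalence)`` pairs; each
    adds a line pivoting at the factor's left-axis (odds ratio) point with
    the middle and right values recomputed at the new prevalence.  Tilting
    therefore requires the "or-left" ordering — in the prevalence-left
    ordering the pivot itself would move.  A tilt to a lower prevalence is
    an intervention (its right-axis value is the approximate impact
    fraction of a partial elimination); to a higher prevalence, an
    alternative population.
    """
    ordering = ordering.replace("_", "-")
    if ordering not in ("prevalence-left", "or-left"):
        raise InvalidArgumentError(f"unknown nomogram ordering {ordering!r}")
    _validate_results(results)
    ranks = _ranks(results)
    by_name = {r.factor_name: r for r in results}

    lines = []
    for r, rank in zip(results, ranks):
        if r.approx_paf >= 1.0:
            warnings.warn(
                f"{r.factor_name}: approximate PAF {r.approx_paf:.3f} >= 1; "
                "the nomogram line exceeds the natural right-axis range",
                ApproximationRangeWarning,
                stacklevel=2,
            )
        y_l, y_m, y_r = _nomogram_ordinates(ordering, r.control_prevalence, r.beta_ave)
        lines.append(
            NomogramLine(
                name=r.factor_name,
                prevalence=r.control_prevalence,
                or_ave=r.or_ave,
                approx_paf=r.approx_paf,
                y_left=y_l,
                y_mid=y_m,
                y_right=y_r,
                rank=rank,
            )
        )

    for name, new_prev in tilts or ():
        if ordering != "or-left":
            raise InvalidArgumentError(
                "tilted lines pivot at the left-axis odds-ratio point and are "
                "only available with the 'or-left' ordering"
            )
        if name not in by_name:
            raise InvalidArgumentError(f"unknown factor {name!r} in tilt")
        if not (0.0 < new_prev <= 1.0):
            raise InvalidArgumentError(f"tilt prevalence must be in (0, 1], got {new_prev}")
        r = by_name[name]
        y_l, y_m, y_r = _nomogram_ordinates(ordering, new_prev, r.beta_ave)
        role = "intervention" if new_prev < r.control_prevalence else "alternative"
        lines.append(
            NomogramLine(
                name=f"{name} @ prevalence {new_prev:g}",
                prevalence=float(new_prev),
                or_ave=r.or_ave,
                approx_paf=new_prev * r.beta_ave,
                y_left=y_l,
                y_mid=y_m,
                y_right=y_r,
                role=role,
            )
        )
    return NomogramLayout(ordering=ordering, lines=tuple(lines))


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

_DEFAULT_STYLE = {
    "figsize": (8.0, 6.0),
    "line_color": "black",
    "line_style": "--",
    "intervention_color": "red",
    "alternative_color": "blue",
    "dpi": 150,
}


def _save(fig, path, fmt: str) -> None:
    try:
        with matplotlib.rc_context({"svg.hashsalt": _SVG_HASHSALT}):
            if fmt == "svg":
                fig.savefig(path, format="svg", metadata={"Date": None})
            else:
                fig.savefig(path, format=fmt)
    except OSError as exc:
        raise OSError(f"could not write figure to {path}: {exc}") from exc
    finally:
        plt.close(fig)


def _render_fan(layout: FanPlotLayout, style: dict):
    fig, ax = plt.subplots(figsize=style["figsize"], dpi=style["dpi"])
    xmax = max(f.x for f in layout.factors) * 1.08
    for f in sorted(layout.factors, key=lambda f: f.rank):
        xs = np.array([1.0, max(f.x, 1.0 + 1e-9)])
        ax.plot(xs, f.slope * xs, style["line_style"], color=style["line_color"], lw=1)
        ax.plot([f.x], [f.y], "o", color=style["line_color"], ms=4)
        ax.annotate(
            f"{f.rank}: {f.name}",
            (f.x, f.y),
            textcoords="offset points",
            xytext=(4, 4),
            fontsize=8,
        )
    ax.set_xlim(1.0, xmax)
    ax.set_ylim(0, None)
    if layout.prevalence_axis_labels:
        ticks = [1.0 / p for p in PREVALENCE_TICKS if 1.0 / p <= xmax]
        ax.set_xticks(ticks)
        ax.set_xticklabels(
            [f"{p * 100:g}%" for p in PREVALENCE_TICKS if 1.0 / p <= xmax]
        )
        ax.set_xlabel("prevalence in controls (decreasing left to right)")
    else:
        ax.set_xlabel("1 / prevalence in controls")
    ax.set_ylabel("approximate PAF (left-axis intercept)")
    right = ax.twinx()
    right.set_ylim(ax.get_ylim())
    or_ticks = [o for o in OR_TICKS if math.log(o) <= ax.get_ylim()[1]]
    right.set_yticks([math.log(o) for o in or_ticks])
    right.set_yticklabels([f"{o:g}" for o in or_ticks])
    right.set_ylabel("odds ratio")
    return fig


def _axis_ticks(ordering: str, which: str):
    """(label, [(tick value, ordinate), ...]) for one nomogram axis."""
    if which == "right":
        return "approximate PAF", [(v, math.log10(v)) for v in PAF_TICKS]
    left_is_prev = (ordering == "prevalence-left") == (which == "left")
    if left_is_prev:
        ticks = [
            (p, -math.log10(p) if which == "left" else 0.5 * math.log10(p))
            for p in PREVALENCE_TICKS
        ]
        return "prevalence in controls", ticks
    ticks = [
        (
            o,
            -math.log10(math.log(o))
            if which == "left"
            else 0.5 * math.log10(math.log(o)),
        )
        for o in OR_TICKS
    ]
    return "odds ratio", ticks


def _render_nomogram(layout: NomogramLayout, style: dict):
    fig, ax = plt.subplots(figsize=style["figsize"], dpi=style["dpi"])
    ys = [y for l in layout.lines for y in (l.y_left, l.y_mid, l.y_right)]
    pad = 0.3
    lo, hi = min(ys) - pad, max(ys) + pad
    xpos = layout.axis_positions
    for x, which in zip(xpos, ("left", "mid", "right")):
        ax.plot([x, x], [lo, hi], color="grey", lw=1)
        label, ticks = _axis_ticks(layout.ordering, which)
        for value, ordinate in ticks:
            if lo <= ordinate <= hi:
                ax.plot([x - 0.01, x + 0.01], [ordinate, ordinate], color="grey", lw=1)
                txt = f"{value * 100:g}%" if label != "odds ratio" else f"{value:g}"
                ax.annotate(
                    txt, (x, ordinate), textcoords="offset points",
                    xytext=(-28 if which == "left" else 6, -3), fontsize=7,
                )
        ax.annotate(label, (x, hi), textcoords="offset points", xytext=(-20, 8),
                    fontsize=9)
    for l in layout.lines:
        if l.role == "factor":
            color, ls = style["line_color"], "-"
        elif l.role == "intervention":
            color, ls = style["intervention_color"], "--"
        else:
            color, ls = style["alternative_color"], "--"
        ax.plot(xpos, [l.y_left, l.y_mid, l.y_right], ls, color=color, lw=1)
        if l.rank is not None:
            ax.annotate(
                f"{l.rank}: {l.name}", (xpos[2], l.y_right),
                textcoords="offset points", xytext=(20, -3), fontsize=7,
            )
    ax.set_xlim(-0.15, 1.35)
    ax.set_ylim(lo, hi)
    ax.axis("off")
    return fig


def render(layout, path, format: str = "svg", style: Optional[dict] = None) -> None:
    """Render a fan or nomogram layout to an SVG or PNG file.

    Output is deterministic for fixed layout and style (fixed SVG hash
    salt, no embedded timestamps).
    """
    fmt = format.lower()
    if fmt not in ("svg", "png"):
        raise InvalidArgumentError(f"unsupported format {format!r}")
    sty = {**_DEFAULT_STYLE, **(style or {})}
    if isinstance(layout, FanPlotLayout):
        fig = _render_fan(layout, sty)
    elif isinstance(layout, NomogramLayout):
        fig = _render_nomogram(layout, sty)
    else:
        raise InvalidArgumentError(f"cannot render object of type {type(layout)!r}")
    _save(fig, path, fmt)


def bias_heatmap(
    surface: BiasSurface,
    which: str = "b_r",
    path=None,
    format: str = "svg",
    style: Optional[dict] = None,
) -> None:
    """Heatmap of the absolute or relative approximation bias surface."""
    if which not in ("b_abs", "b_r"):
        raise InvalidArgumentError("which must be 'b_abs' or 'b_r'")
    sty = {**_DEFAULT_STYLE, **(style or {})}
    values = getattr(surface, which)
    fig, ax = plt.subplots(figsize=sty["figsize"], dpi=sty["dpi"])
    mesh = ax.pcolormesh(
        surface.or_grid, surface.prevalence_grid, values, shading="nearest",
        cmap="RdBu_r",
    )
    fig.colorbar(mesh, ax=ax, label=(
        "relative bias  PAF_a / PAF" if which == "b_r" else "absolute bias  PAF_a - PAF"
    ))
    ax.set_xlabel("odds ratio")
    ax.set_ylabel("prevalence in controls")
    _save(fig, path, format.lower())
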