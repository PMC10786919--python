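"""Dose-response normalization, EC50 fitting with censoring, half-lives.

Cellular readouts (p53 reporter, LDH release, counterscreen,
proliferation) arrive as raw plate signals and are normalized against
on-plate controls: 100% is the maximum-control signal (e.g. the
reporter activity induced by a saturating reference compound, or LDH
release induced by a lytic peptide) and 0% is the minimum control.
Normalized activity may legitimately exceed 100% — hyperactive
compounds in the counterscreen do.

Potency is summarized as the EC50 of a four-parameter logistic (4PL)

    y(c) = bottom + (top − bottom) / (1 + (ec50 / c)^hill)

with bottom fixed at 0% by default and top free (so efficacy > 100% is
representable).  When the response never reaches half of the fitted
top inside the tested range, the EC50 is reported as censored at the
highest tested concentration (a ``>`` bound), never as an extrapolated
point estimate.

Stability half-lives come from log-linear regression of %-remaining
time courses; a slope indistinguishable from zero (p > 0.05) yields a
censored ``> last timepoint`` result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, stats

from .censored import Bound, CensoredValue

__all__ = [
    "DoseResponseCurve",
    "Ec50Fit",
    "normalize_response",
    "fit_ec50",
    "half_life",
]

AssayKind = Literal["p53_reporter", "LDH", "counterscreen", "proliferation"]


def normalize_response(raw, max_control, min_control):
    """Raw signal → % activity relative to plate controls.

    ``100 · (raw − min_control) / (max_control − min_control)``;
    affine-invariant and allowed to exceed 100%.
    """
    if max_control == min_control:
        raise ValueError("degenerate controls: max_control == min_control")
    return 100.0 * (np.asarray(raw, dtype=float) - min_control) / (
        max_control - min_control
    )


@dataclass(frozen=True)
class DoseResponseCurve:
    """Normalized dose-response series (conc in µM, response in %)."""

    conc: tuple[float, ...]
    response: tuple[float, ...]
    assay: AssayKind = "p53_reporter"
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        c = np.asarray(self.conc, dtype=float)
        r = np.asarray(self.response, dtype=float)
        if len(self.conc) != len(self.response):
            raise ValueError("conc and response must have equal length")
        if np.any(np.diff(c) <= 0) or np.any(c <= 0):
            raise ValueError("concentrations must be positive and increasing")
        if not np.all(np.isfinite(r)):
            raise ValueError("responses must be finite")


@dataclass(frozen=True)
class Ec50Fit:
    """4PL fit summary; ``ec50`` may carry a '>' censoring bound."""

    ec50: CensoredValue
    hill: float
    efficacy: float          # fitted top, % of control max
    converged: bool
    residual_norm: float = float("nan")

    def __post_init__(self) -> None:
        if not self.ec50.value > 0:
            raise ValueError("ec50 must be positive")


def _logistic(c, bottom, top, ec50, hill):
    return bottom + (top - bottom) / (1.0 + (ec50 / c) ** hill)


def fit_ec50(curve: DoseResponseCurve,
             top_constraint: float | None = None) -> Ec50Fit:
    """Fit a 4PL and report EC50 with ceiling censoring.

    ``top_constraint`` pins the plateau (e.g. 100 for % inhibition in
    proliferation assays); otherwise the top is free.  Bottom is fixed
    at 0%.  EC50 and Hill slope are fit on log scale for positivity.
    """
    if len(curve.conc) < 5:
        raise ValueError("need at least 5 concentrations")
    c = np.asarray(curve.conc, dtype=float)
    y = np.asarray(curve.response, dtype=float)
    cmax = float(c[-1])

    top_free = top_constraint is None
    top0 = max(float(np.max(y)), 1.0) if top_free else float(top_constraint)

    # flat-at-baseline shortcut: nothing to fit, report the ceiling
    if float(np.max(y)) < max(0.25 * top0, 5.0):
        return Ec50Fit(
            CensoredValue(cmax, Bound.GREATER_THAN, "uM"),
            hill=float("nan"), efficacy=float(np.max(y)), converged=False,
        )

    def unpack(p):
        if top_free:
            return p[2], math.exp(p[0]), math.exp(p[1])
        return top0, math.exp(p[0]), math.exp(p[1])

    def resid(p):
        top, ec50, hill = unpack(p)
        return _logistic(c, 0.0, top, ec50, hill) - y

    p0 = [math.log(float(np.median(c))), 0.0]
    if top_free:
        p0.append(top0)
    sol = optimize.least_squares(resid, p0, method="trf",
                                 xtol=1e-14, ftol=1e-14, gtol=1e-14)
    top, ec50, hill = unpack(sol.x)
    rnorm = float(np.linalg.norm(sol.fun))

    # censor when the fitted half-max is not reached in the tested range
    half_reached = _logistic(cmax, 0.0, top, ec50, hill) >= 0.5 * top
    if not sol.success or ec50 > cmax or not half_reached:
        return Ec50Fit(CensoredValue(cmax, Bound.GREATER_THAN, "uM"),
                       hill=hill, efficacy=top,
                       converged=bool(sol.success), residual_norm=rnorm)
    return Ec50Fit(CensoredValue(ec50, Bound.NONE, "uM"),
                   hill=hill, efficacy=top, converged=True,
                   residual_norm=rnorm)


def half_life(timepoints_h: Sequence[float],
              pct_remaining: Sequence[float],
              alpha: float = 0.05) -> CensoredValue:
    """Half-life from a %-remaining time course (hours).

    Log-linear least squares of ln(% remaining) vs time; t½ = ln 2 / k.
    If the decay slope is not significantly negative (one-sided
    p > ``alpha``), the result is censored as ``> last timepoint`` —
    the compound outlived the experiment.
    """
    t = np.asarray(timepoints_h, dtype=float)
    y = np.asarray(pct_remaining, dtype=float)
    if t.shape != y.shape or t.size < 3:
        raise ValueError("need >= 3 matched timepoints")
    if t[0] != 0:
        raise ValueError("first timepoint must be 0 h (the 100% reference)")
    if np.any(y <= 0):
        raise ValueError("% remaining must be positive for log regression")

    res = stats.linregress(t, np.log(y))
    one_sided_p = res.pvalue / 2 if res.slope < 0 else 1.0 - res.pvalue / 2
    if res.slope >= 0 or one_sided_p > alpha:
        return CensoredValue(float(t[-1]), Bound.GREATER_THAN, "h")
    return CensoredValue(math.log(2.0) / (-res.slope), Bound.NONE, "h")
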