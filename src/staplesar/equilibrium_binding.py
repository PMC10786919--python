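"""Fluorescence-anisotropy binding models and K_D fitting.

Two experiment geometries are covered, both at thermodynamic
equilibrium:

**Direct titration.**  Protein P is titrated against a fixed, low
concentration of fluorescently labeled probe peptide L*.  The measured
anisotropy interpolates between that of free probe (r0) and of the
P·L* complex (rb) in proportion to the probe fraction bound, which for
1:1 binding follows the exact (depletion-corrected) quadratic solution

    fb = [(Kd + Lt + Pt) − sqrt((Kd + Lt + Pt)² − 4·Lt·Pt)] / (2·Lt).

**Competition titration.**  An unlabeled competitor L is titrated into
a preformed P·L* mix (probe total Lst, protein total Pt, probe affinity
Kd1 known from a direct fit).  The ternary equilibrium

    P + L* ⇌ P·L*   (Kd1),    P + L ⇌ P·L   (Kd2)

reduces to a cubic in free protein whose physical root has the exact
trigonometric form (Wang, FEBS Lett. 1995):

    d = Kd1 + Kd2 + Lst + Lt − Pt
    e = (Lt − Pt)·Kd1 + (Lst − Pt)·Kd2 + Kd1·Kd2
    f = −Kd1·Kd2·Pt
    θ = arccos[(−2d³ + 9de − 27f) / (2·sqrt((d² − 3e)³))]
    [P]free = 2·sqrt(d² − 3e)·cos(θ/3) − d) / 3
    fb = [P]free / (Kd1 + [P]free)
       = (2·sqrt(d² − 3e)·cos(θ/3) − d) / (3·Kd1 + 2·sqrt(d² − 3e)·cos(θ/3) − d)

Every closed-form value is certified against
:func:`solve_equilibrium_numeric`, an independent bracketed root solve
of the free-protein mass balance — the two routes agree to better than
1e-9 relative across the tested parameter space.

All concentrations in this module are nanomolar; convert at the I/O
boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "AnisotropyEndpoints",
    "CompetitionConfig",
    "TitrationCurve",
    "FitResult",
    "direct_anisotropy",
    "competitive_anisotropy",
    "probe_fraction_bound_direct",
    "probe_fraction_bound_competition",
    "solve_equilibrium_numeric",
    "fit_direct",
    "fit_competition",
    "validate_curve",
]

#: slack allowed on the arccos argument before declaring the regime invalid
_ACOS_TOL = 1e-9


@dataclass(frozen=True)
class AnisotropyEndpoints:
    """Anisotropy of free probe (r0) and of the saturated complex (rb)."""

    r0: float
    rb: float

    def __post_init__(self) -> None:
        if not self.rb > self.r0:
            raise ValueError(f"need rb > r0, got r0={self.r0}, rb={self.rb}")

    @property
    def dynamic_range(self) -> float:
        return self.rb - self.r0


@dataclass(frozen=True)
class CompetitionConfig:
    """Fixed species in a competition titration (all nM)."""

    Lst: float  # total labeled probe
    Pt: float   # total protein
    Kd1: float  # probe dissociation constant, from a prior direct fit

    def __post_init__(self) -> None:
        if min(self.Lst, self.Pt, self.Kd1) <= 0:
            raise ValueError("Lst, Pt and Kd1 must all be positive")
        if not self.Pt > self.Lst:
            raise ValueError(
                "competition mode assumes protein in excess of probe (Pt > Lst)"
            )


@dataclass(frozen=True)
class TitrationCurve:
    """One titration: x = titrant concentration (nM), r = anisotropy.

    ``mode='direct'``: x is total protein.  ``mode='competition'``:
    x is total unlabeled competitor and ``config`` must be set.
    """

    x: tuple[float, ...]
    r: tuple[float, ...]
    mode: Literal["direct", "competition"]
    endpoints: AnisotropyEndpoints | None = None
    config: CompetitionConfig | None = None
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        if len(self.x) != len(self.r):
            raise ValueError("x and r must have equal length")
        if np.any(x < 0):
            raise ValueError("concentrations must be non-negative")
        if np.any(np.diff(x) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if self.mode == "competition" and self.config is None:
            raise ValueError("competition curve needs a CompetitionConfig")


# ---------------------------------------------------------------------------
# closed-form models
# ---------------------------------------------------------------------------

def probe_fraction_bound_direct(Kd, Lt, Pt):
    """Bound fraction of probe for 1:1 binding (exact quadratic)."""
    Kd, Lt, Pt = (np.asarray(v, dtype=float) for v in (Kd, Lt, Pt))
    if np.any(Kd <= 0) or np.any(Lt <= 0) or np.any(Pt < 0):
        raise ValueError("need Kd > 0, Lt > 0, Pt >= 0")
    s = Kd + Lt + Pt
    disc = np.maximum(s * s - 4.0 * Lt * Pt, 0.0)
    return (s - np.sqrt(disc)) / (2.0 * Lt)


def direct_anisotropy(Kd, Lt, Pt, endpoints: AnisotropyEndpoints):
    """Predicted anisotropy for a direct protein-into-probe titration."""
    fb = probe_fraction_bound_direct(Kd, Lt, Pt)
    return endpoints.r0 + endpoints.dynamic_range * fb


def probe_fraction_bound_competition(Kd2, Lt, config: CompetitionConfig):
    """Probe bound fraction in the ternary system (exact cubic root).

    Vectorized over ``Lt``.  Raises ``ValueError`` if the arccos
    argument leaves [−1, 1] by more than 1e-9 (an invalid parameter
    regime); smaller excursions are clamped.
    """
    if np.any(np.asarray(Kd2, dtype=float) <= 0):
        raise ValueError("Kd2 must be positive")
    Lt = np.asarray(Lt, dtype=float)
    if np.any(Lt < 0):
        raise ValueError("competitor concentrations must be non-negative")
    Kd1, Lst, Pt = config.Kd1, config.Lst, config.Pt

    d = Kd1 + Kd2 + Lst + Lt - Pt
    e = (Lt - Pt) * Kd1 + (Lst - Pt) * Kd2 + Kd1 * Kd2
    f = -Kd1 * Kd2 * Pt

    q = d * d - 3.0 * e          # > 0 whenever Pt > 0 (distinct real roots)
    sq = np.sqrt(q)
    arg = (-2.0 * d**3 + 9.0 * d * e - 27.0 * f) / (2.0 * sq**3)
    if np.any(np.abs(arg) > 1.0 + _ACOS_TOL):
        raise ValueError(
            f"arccos argument {np.max(np.abs(arg)):.6g} outside [-1, 1]; "
            "invalid parameter regime"
        )
    theta = np.arccos(np.clip(arg, -1.0, 1.0))
    p = (2.0 * sq * np.cos(theta / 3.0) - d) / 3.0   # free protein

    # The trigonometric root loses precision when d, e, f span many
    # orders (very weak or very strong competitor): the arccos argument
    # is a ratio of ~cancelling large terms.  The cubic
    # g(p) = p^3 + d p^2 + e p + f shares its non-negative roots with
    # the protein mass balance, which is monotone there, so g has
    # exactly one root in [0, Pt]; safeguarded Newton on that bracket,
    # started from the trigonometric root, restores full precision.
    p = _polish_cubic_root(np.asarray(p, dtype=float).copy(), d, e, f, Pt)
    return p / (Kd1 + p)


def _polish_cubic_root(p, d, e, f, Pt):
    """Safeguarded Newton for the unique root of p^3+dp^2+ep+f in [0, Pt]."""
    lo = np.zeros_like(p)
    hi = np.full_like(p, Pt)
    p = np.clip(p, lo, hi)
    for _ in range(80):
        g = ((p + d) * p + e) * p + f
        lo = np.where(g < 0.0, p, lo)
        hi = np.where(g > 0.0, p, hi)
        dg = (3.0 * p + 2.0 * d) * p + e
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(dg != 0.0, g / np.where(dg != 0.0, dg, 1.0), 0.0)
        cand = p - step
        # bisect wherever Newton leaves the current bracket
        outside = (cand <= lo) | (cand >= hi) | ~np.isfinite(cand)
        cand = np.where(outside, 0.5 * (lo + hi), cand)
        if np.allclose(cand, p, rtol=1e-16, atol=0.0):
            p = cand
            break
        p = cand
    return p


def competitive_anisotropy(Kd2, Lt, config: CompetitionConfig,
                           endpoints: AnisotropyEndpoints):
    """Predicted anisotropy for a competitor-into-complex titration."""
    fb = probe_fraction_bound_competition(Kd2, Lt, config)
    return endpoints.r0 + endpoints.dynamic_range * fb


# ---------------------------------------------------------------------------
# independent numerical oracle
# ---------------------------------------------------------------------------

def solve_equilibrium_numeric(Kd1: float, Kd2: float, Lst: float,
                              Lt: float, Pt: float) -> float:
    """Probe fraction bound by bracketed root-finding on the mass balance.

    Solves for free protein p in

        Pt = p + Lst·p/(Kd1 + p) + Lt·p/(Kd2 + p)

    on [0, Pt] (the left side is monotone in p, so the bracket always
    works), then returns p/(Kd1 + p).  Deliberately independent of the
    closed form above so the two can certify each other.
    """
    if Kd1 <= 0 or Kd2 <= 0:
        raise ValueError("dissociation constants must be positive")
    if min(Lst, Lt, Pt) < 0:
        raise ValueError("concentrations must be non-negative")
    if Pt == 0:
        return 0.0

    def balance(p: float) -> float:
        return p + Lst * p / (Kd1 + p) + Lt * p / (Kd2 + p) - Pt

    p = optimize.brentq(balance, 0.0, Pt, xtol=1e-300, rtol=1e-15,
                        maxiter=200)
    return p / (Kd1 + p)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitResult:
    """Outcome of a least-squares K_D fit."""

    estimate: float
    standard_error: float
    endpoints: AnisotropyEndpoints
    residual_norm: float
    converged: bool
    qc_flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.converged and not self.estimate > 0:
            raise ValueError("converged fit must have a positive estimate")


def _identifiable(r: np.ndarray) -> bool:
    """A titration with no signal swing cannot constrain a Kd."""
    span = float(np.max(r) - np.min(r))
    scale = max(abs(float(np.mean(r))), 1e-12)
    return span > 1e-3 * scale


def _ls_fit(residual_fn, p0, n_obs):
    """Trust-region least squares + SEs from the Jacobian at the optimum."""
    sol = optimize.least_squares(residual_fn, p0, method="trf", xtol=1e-14,
                                 ftol=1e-14, gtol=1e-14)
    dof = max(n_obs - len(p0), 1)
    s2 = float(np.sum(sol.fun**2)) / dof
    JTJ = sol.jac.T @ sol.jac
    try:
        cov = s2 * np.linalg.inv(JTJ)
        perr = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        perr = np.full(len(p0), np.nan)
    return sol, perr


def fit_direct(curve: TitrationCurve,
               fix_endpoints: AnisotropyEndpoints | None = None) -> FitResult:
    """Fit the 1:1 direct-binding model to a protein titration.

    Estimates Kd (log-parameterized to enforce positivity) and, unless
    ``fix_endpoints`` is given, the r0/rb endpoints.  ``Lt`` (probe
    total, nM) is read from ``curve.meta['Lst']`` and defaults to the
    probe concentration stored on the attached config, if any.
    """
    if curve.mode != "direct":
        raise ValueError("fit_direct needs a direct-mode curve")
    if len(curve.x) < 5:
        raise ValueError("need at least 5 titration points")
    Lt = curve.meta.get("Lst")
    if Lt is None and curve.config is not None:
        Lt = curve.config.Lst
    if Lt is None:
        raise ValueError("probe concentration missing (curve.meta['Lst'])")

    x = np.asarray(curve.x, dtype=float)
    r = np.asarray(curve.r, dtype=float)
    flags: list[str] = []
    if not _identifiable(r):
        return FitResult(float("nan"), float("nan"),
                         fix_endpoints or AnisotropyEndpoints(0.0, 1.0),
                         float("nan"), converged=False,
                         qc_flags=("unidentifiable_flat_curve",))

    kd0 = math.log(max(float(np.median(x)), 1e-6))
    if fix_endpoints is None:
        p0 = [kd0, float(np.min(r)), max(float(np.max(r)),
                                         float(np.min(r)) + 1e-6)]

        def resid(p):
            ep = AnisotropyEndpoints(p[1], max(p[2], p[1] + 1e-12))
            return direct_anisotropy(math.exp(p[0]), Lt, x, ep) - r
    else:
        p0 = [kd0]

        def resid(p):
            return direct_anisotropy(math.exp(p[0]), Lt, x, fix_endpoints) - r

    sol, perr = _ls_fit(resid, p0, len(x))
    kd = math.exp(sol.x[0])
    se = kd * perr[0]  # delta method for the log parameterization
    endpoints = (fix_endpoints if fix_endpoints is not None
                 else AnisotropyEndpoints(sol.x[1],
                                          max(sol.x[2], sol.x[1] + 1e-12)))
    flags.extend(validate_curve(curve, endpoints))
    return FitResult(kd, se, endpoints, float(np.linalg.norm(sol.fun)),
                     converged=bool(sol.success), qc_flags=tuple(flags))


def fit_competition(curve: TitrationCurve,
                    config: CompetitionConfig | None = None,
                    fix_endpoints: AnisotropyEndpoints | None = None
                    ) -> FitResult:
    """Fit the exact ternary competition model for the competitor Kd2.

    Kd1, Lst and Pt are held fixed at the values in ``config`` (or the
    curve's attached config); only Kd2 and, optionally, the anisotropy
    endpoints are free.
    """
    if curve.mode != "competition":
        raise ValueError("fit_competition needs a competition-mode curve")
    if len(curve.x) < 5:
        raise ValueError("need at least 5 titration points")
    cfg = config or curve.config
    if cfg is None:
        raise ValueError("no CompetitionConfig supplied")

    x = np.asarray(curve.x, dtype=float)
    r = np.asarray(curve.r, dtype=float)
    flags: list[str] = []
    if not _identifiable(r):
        return FitResult(float("nan"), float("nan"),
                         fix_endpoints or AnisotropyEndpoints(0.0, 1.0),
                         float("nan"), converged=False,
                         qc_flags=("unidentifiable_flat_curve",))

    kd0 = math.log(cfg.Kd1)
    if fix_endpoints is None:
        p0 = [kd0, float(np.min(r)), max(float(np.max(r)),
                                         float(np.min(r)) + 1e-6)]

        def resid(p):
            ep = AnisotropyEndpoints(p[1], max(p[2], p[1] + 1e-12))
            return competitive_anisotropy(math.exp(p[0]), x, cfg, ep) - r
    else:
        p0 = [kd0]

        def resid(p):
            return competitive_anisotropy(math.exp(p[0]), x, cfg,
                                          fix_endpoints) - r

    sol, perr = _ls_fit(resid, p0, len(x))
    kd2 = math.exp(sol.x[0])
    se = kd2 * perr[0]
    endpoints = (fix_endpoints if fix_endpoints is not None
                 else AnisotropyEndpoints(sol.x[1],
                                          max(sol.x[2], sol.x[1] + 1e-12)))
    flags.extend(validate_curve(curve, endpoints))
    return FitResult(kd2, se, endpoints, float(np.linalg.norm(sol.fun)),
                     converged=bool(sol.success), qc_flags=tuple(flags))


# ---------------------------------------------------------------------------
# curve validity checks
# ---------------------------------------------------------------------------

def validate_curve(curve: TitrationCurve,
                   endpoints: AnisotropyEndpoints,
                   noise_sd: float | None = None) -> list[str]:
    """Quality checks mirroring standard anisotropy-assay validity rules.

    * ``baseline_below_free_probe`` — the final baseline of a
      competition titration falls significantly below r0, indicating an
      unintended competitor/probe interaction.
    * ``start_anisotropy_mismatch`` — the first point of a direct
      titration differs significantly from free-probe anisotropy.
    * ``non_monotonic_beyond_noise`` — the curve reverses direction by
      more than the noise allows.

    ``noise_sd`` defaults to a robust estimate from successive
    differences; thresholds are 3σ.
    """
    r = np.asarray(curve.r, dtype=float)
    if r.size == 0:
        raise ValueError("empty curve")
    if noise_sd is None:
        if r.size >= 3:
            noise_sd = float(np.median(np.abs(np.diff(r)))) / 0.6745 / math.sqrt(2)
        else:
            noise_sd = 0.0
    tol = max(3.0 * noise_sd, 1e-3 * endpoints.dynamic_range)

    flags: list[str] = []
    if curve.mode == "competition":
        if r[-1] < endpoints.r0 - tol:
            flags.append("baseline_below_free_probe")
        expected_sign = -1.0   # displacement: r falls with competitor
    else:
        # check against r0 only where the first point has ~no titrant yet
        if curve.x[0] < 0.05 * curve.x[-1] and abs(r[0] - endpoints.r0) > tol:
            flags.append("start_anisotropy_mismatch")
        expected_sign = 1.0    # binding: r rises with protein

    # successive differences carry sqrt(2)·σ of noise; 5σ keeps the
    # false-positive rate negligible on 12-point curves
    steps = np.diff(r)
    if np.any(expected_sign * steps < -5.0 * max(noise_sd * math.sqrt(2), 1e-12)
              - 1e-3 * endpoints.dynamic_range):
        flags.append("non_monotonic_beyond_noise")
    return flags
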