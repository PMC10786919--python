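"""Synthetic inputs with known ground truth for every pipeline stage.

No raw screening data is bundled with the package, so each analysis
stage is exercised on simulated inputs whose generating parameters are
known exactly:

* titration curves from the same closed-form binding models the fitter
  uses (plus Gaussian anisotropy noise),
* dose-response plates from the 4PL (10-point, 3× serial dilution from
  a 10 mM DMSO stock, i.e. a 50 µM top in-well concentration),
* far-UV CD spectra as a linear mix of analytic helix and coil basis
  spectra,
* whole peptide libraries that encode the statistical structure the
  SAR analysis is meant to detect: lipophilicity (LogD) drives
  permeability with a configurable slope on log10(cell ratio); a
  configurable fraction of records is planted "toxic" with measurable
  LDH/counterscreen potencies (emulating the cationic-peptide
  liability); poorly soluble records receive large serum shifts.

Ground truth travels with each output (curve ``meta`` / record
``extra`` under ``truth_*`` keys) and is never read by the analysis
stages.  Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .censored import Bound, CensoredValue
from .cd_helicity import CdSpectrum, THETA_COIL, theta_helix
from .dose_response import DoseResponseCurve
from .equilibrium_binding import (
    AnisotropyEndpoints,
    CompetitionConfig,
    TitrationCurve,
    competitive_anisotropy,
    direct_anisotropy,
)
from .peptide_model import parse_sequence
from .sar_metrics import LibraryRecord, LibraryTable

__all__ = [
    "LibrarySimConfig",
    "DEFAULT_ENDPOINTS",
    "DEFAULT_COMPETITION_CONFIG",
    "default_protein_grid",
    "default_competitor_grid",
    "default_dilution_series",
    "simulate_direct_titration",
    "simulate_competition_titration",
    "simulate_dose_response",
    "simulate_cd_spectrum",
    "simulate_library",
    "random_peptide_notation",
    "TAIL_ARCHETYPES",
]

#: typical FP endpoints: free FAM probe ~0.05, saturated complex ~0.25
DEFAULT_ENDPOINTS = AnisotropyEndpoints(r0=0.05, rb=0.25)

#: assay configuration of the reference competition experiment:
#: 50 nM labeled probe, 250 nM protein, probe Kd1 = 13.0 nM
DEFAULT_COMPETITION_CONFIG = CompetitionConfig(Lst=50.0, Pt=250.0, Kd1=13.0)


def default_protein_grid(n: int = 12, lo: float = 1.0,
                         hi: float = 2000.0) -> np.ndarray:
    """Log-spaced protein grid (nM) spanning the binding transition."""
    return np.geomspace(lo, hi, n)


def default_competitor_grid(Kd2: float, n: int = 12) -> np.ndarray:
    """Log-spaced competitor grid covering 1e-2–1e3 × Kd2 (nM)."""
    return np.geomspace(1e-2 * Kd2, 1e3 * Kd2, n)


def default_dilution_series(top_uM: float = 50.0, n: int = 10,
                            factor: float = 3.0) -> np.ndarray:
    """Plate scheme: n-point serial dilution, ascending (µM)."""
    return top_uM / factor ** np.arange(n - 1, -1, -1, dtype=float)


# ---------------------------------------------------------------------------
# titrations
# ---------------------------------------------------------------------------

def _replicate_mean_noise(rng: np.random.Generator, shape,
                          noise_sd: float, n_replicates: int) -> np.ndarray:
    """Mean of n i.i.d. Gaussian noise draws per point."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    return rng.normal(0.0, noise_sd, size=(n_replicates, *shape)).mean(axis=0)


def simulate_direct_titration(Kd: float,
                              endpoints: AnisotropyEndpoints = DEFAULT_ENDPOINTS,
                              Lst: float = 50.0,
                              Pt_grid: Sequence[float] | None = None,
                              noise_sd: float = 0.0,
                              seed: int = 0,
                              n_replicates: int = 3) -> TitrationCurve:
    """Forward-simulate a protein-into-probe titration.

    ``noise_sd`` is the SD of i.i.d. Gaussian noise in anisotropy units
    per individual measurement (0.02 · dynamic range models a 2% assay
    CV); the curve stores the mean over ``n_replicates`` replicate
    measurements per point, emulating the at-least-triplicate assay
    protocol.
    """
    grid = np.asarray(Pt_grid if Pt_grid is not None else
                      default_protein_grid(), dtype=float)
    rng = np.random.default_rng(seed)
    r = direct_anisotropy(Kd, Lst, grid, endpoints)
    r = r + _replicate_mean_noise(rng, grid.shape, noise_sd, n_replicates)
    return TitrationCurve(
        tuple(grid), tuple(r), mode="direct", endpoints=endpoints,
        meta={"Lst": Lst, "truth_Kd": Kd, "noise_sd": noise_sd,
              "n_replicates": n_replicates, "seed": seed},
    )


def simulate_competition_titration(
        Kd2: float,
        config: CompetitionConfig = DEFAULT_COMPETITION_CONFIG,
        Lt_grid: Sequence[float] | None = None,
        noise_sd: float = 0.0,
        seed: int = 0,
        endpoints: AnisotropyEndpoints = DEFAULT_ENDPOINTS,
        n_replicates: int = 3) -> TitrationCurve:
    """Forward-simulate a competitor-into-complex titration.

    Noise handling as in :func:`simulate_direct_titration`.
    """
    grid = np.asarray(Lt_grid if Lt_grid is not None else
                      default_competitor_grid(Kd2), dtype=float)
    rng = np.random.default_rng(seed)
    r = competitive_anisotropy(Kd2, grid, config, endpoints)
    r = r + _replicate_mean_noise(rng, grid.shape, noise_sd, n_replicates)
    return TitrationCurve(
        tuple(grid), tuple(r), mode="competition", endpoints=endpoints,
        config=config,
        meta={"truth_Kd2": Kd2, "noise_sd": noise_sd,
              "n_replicates": n_replicates, "seed": seed},
    )


# ---------------------------------------------------------------------------
# dose response
# ---------------------------------------------------------------------------

def simulate_dose_response(ec50_uM: float, hill: float = 1.0,
                           top: float = 100.0,
                           conc_scheme: Sequence[float] | None = None,
                           noise_sd: float = 0.0,
                           seed: int = 0,
                           assay: str = "p53_reporter") -> DoseResponseCurve:
    """Forward-simulate a normalized dose-response curve.

    ``noise_sd`` is in percentage points of activity (3.0 models a 3%
    plate CV at full signal).
    """
    conc = np.asarray(conc_scheme if conc_scheme is not None else
                      default_dilution_series(), dtype=float)
    rng = np.random.default_rng(seed)
    y = top / (1.0 + (ec50_uM / conc) ** hill)
    y = y + rng.normal(0.0, noise_sd, size=conc.shape)
    return DoseResponseCurve(
        tuple(conc), tuple(y), assay=assay,  # type: ignore[arg-type]
        meta={"truth_ec50_uM": ec50_uM, "truth_hill": hill,
              "truth_top": top, "noise_sd": noise_sd, "seed": seed},
    )


# ---------------------------------------------------------------------------
# CD spectra
# ---------------------------------------------------------------------------

def _helix_basis(wl: np.ndarray, n_residues: int) -> np.ndarray:
    """Analytic 100%-helix MRE basis, anchored to theta_helix(n) at 222 nm."""
    shape = (np.exp(-((wl - 222.0) / 9.0) ** 2)
             + 0.95 * np.exp(-((wl - 208.0) / 7.0) ** 2)
             - 1.9 * np.exp(-((wl - 192.0) / 6.5) ** 2))
    return shape * (theta_helix(n_residues) / shape[np.argmin(np.abs(wl - 222.0))])


def _coil_basis(wl: np.ndarray) -> np.ndarray:
    """Analytic random-coil MRE basis (~theta_coil at 222 nm)."""
    return (-15000.0 * np.exp(-((wl - 198.0) / 8.0) ** 2)
            + THETA_COIL * np.exp(-((wl - 230.0) / 60.0) ** 2))


def simulate_cd_spectrum(helix_weight: float, n_residues: int = 16,
                         conc_uM: float = 50.0, path_cm: float = 0.2,
                         noise_sd: float = 0.0, seed: int = 0) -> CdSpectrum:
    """Two-basis CD spectrum with known helix mixing weight.

    MRE(λ) = w·helix(λ) + (1−w)·coil(λ), converted to measured
    millidegrees for the stated concentration/path/length, plus
    Gaussian noise (``noise_sd`` in mdeg).
    """
    if not 0.0 <= helix_weight <= 1.0:
        raise ValueError("helix_weight must lie in [0, 1]")
    wl = np.arange(190.0, 301.0, 1.0)
    mre = (helix_weight * _helix_basis(wl, n_residues)
           + (1.0 - helix_weight) * _coil_basis(wl))
    mdeg = mre * (10.0 * path_cm * conc_uM * 1e-6 * (n_residues - 1))
    rng = np.random.default_rng(seed)
    mdeg = mdeg + rng.normal(0.0, noise_sd, size=wl.shape)
    return CdSpectrum(tuple(wl), tuple(mdeg), conc_uM=conc_uM,
                      n_residues=n_residues, path_cm=path_cm)


# ---------------------------------------------------------------------------
# peptide library
# ---------------------------------------------------------------------------

#: C-terminal tail archetypes in extended notation (no caps)
TAIL_ARCHETYPES: dict[str, str] = {
    "SAA": "SAA",
    "A6": "AAAAAA",
    "A5-dA": "AAAAA[dA]",
    "A5": "AAAAA",
    "G6": "GGGGGG",
    "P6": "PPPPPP",
    "A-Sar5": "A[Sar][Sar][Sar][Sar][Sar]",
    "(A-dA)3": "A[dA]A[dA]A[dA]",
    "EEAAAA": "EEAAAA",
    "A2EA2-dA": "AAEAA[dA]",
    "A-Aib5": "A[Aib][Aib][Aib][Aib][Aib]",
}

_CORE = "Ac-[KN3][bA]LTF[R8]EYWAQ[Cba][S5]"


def random_peptide_notation(rng: np.random.Generator,
                            tail: str | None = None) -> str:
    """A random library member: the constant stapled core + a tail.

    ``tail`` selects an archetype by name; by default one is drawn at
    random, so a batch of generated peptides exercises both propensity
    classes and a range of net charges.
    """
    if tail is None:
        tail = str(rng.choice(list(TAIL_ARCHETYPES)))
    body = TAIL_ARCHETYPES[tail]
    return f"{_CORE}{body}-NH2"


@dataclass(frozen=True)
class LibrarySimConfig:
    """Generating parameters for a synthetic peptide library.

    ``permeability_slope`` is d log10(cell ratio) / d LogD; the
    negative default encodes the observed trend that lipophilic
    peptides are more permeable (smaller cell ratio).
    ``fraction_toxic`` records are planted with measurable off-target
    (LDH / counterscreen) potencies; all others are clean (censored at
    ``censor_limit_uM``).
    """

    n_peptides: int = 200
    seed: int = 0
    logd_range: tuple[float, float] = (0.0, 3.5)
    permeability_slope: float = -0.8
    permeability_intercept: float = 3.2   # log10(cell ratio) at LogD 0
    noise_sd: float = 0.3                 # SD on log10(cell ratio)
    censor_limit_uM: float = 50.0
    fraction_toxic: float = 0.1

    def __post_init__(self) -> None:
        if self.n_peptides < 1:
            raise ValueError("n_peptides must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.fraction_toxic <= 1.0:
            raise ValueError("fraction_toxic must lie in [0, 1]")


def simulate_library(config: LibrarySimConfig) -> LibraryTable:
    """Generate a peptide library with planted, recoverable structure.

    Per record: LogD uniform on ``logd_range``; K_D log-normal around
    5 nM; log10(cell ratio) = intercept + slope·LogD + N(0, noise_sd),
    giving the serum-free cellular EC50 = K_D · ratio; solubility
    anti-correlated with LogD; the 10%-serum EC50 right-shifted ~20×
    for poorly soluble records (<10 µM) and ~2× otherwise; exactly
    ``round(fraction_toxic · n)`` records carry planted LDH and
    counterscreen activity within 10× of their cellular EC50 (margin
    violations), the rest are clean at the censoring limit.  Identical
    seeds give identical tables.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_peptides
    limit = config.censor_limit_uM

    n_toxic = int(round(config.fraction_toxic * n))
    toxic = np.zeros(n, dtype=bool)
    toxic[rng.permutation(n)[:n_toxic]] = True

    records = []
    for i in range(n):
        logd = float(rng.uniform(*config.logd_range))
        kd_nM = float(np.exp(rng.normal(math.log(5.0), 0.8)))
        log_ratio = (config.permeability_intercept
                     + config.permeability_slope * logd
                     + rng.normal(0.0, config.noise_sd))
        ratio = 10.0 ** log_ratio
        ec50_0_uM = kd_nM * ratio / 1000.0

        # solubility falls with lipophilicity
        sol_uM = float(np.exp(rng.normal(math.log(150.0) - 0.9 * logd, 0.4)))
        shift = float(np.exp(rng.normal(math.log(20.0 if sol_uM < 10.0
                                                 else 2.0), 0.25)))
        ec50_10_uM = ec50_0_uM * shift

        if toxic[i]:
            # planted off-target activity within 10x of the cell potency
            margin = float(rng.uniform(1.0, 8.0))
            off_uM = min(ec50_0_uM * margin, limit * 0.9)
            ldh = CensoredValue(off_uM, Bound.NONE, "uM")
            counter = CensoredValue(off_uM * float(rng.uniform(0.8, 1.2)),
                                    Bound.NONE, "uM")
        else:
            ldh = CensoredValue(limit, Bound.GREATER_THAN, "uM")
            counter = CensoredValue(limit, Bound.GREATER_THAN, "uM")

        notation = random_peptide_notation(rng)
        peptide = parse_sequence(notation, name=f"SYN-{i:04d}")
        records.append(LibraryRecord(
            name=f"SYN-{i:04d}",
            peptide=peptide,
            sequence=notation,
            kd_nM=CensoredValue(kd_nM, Bound.NONE, "nM"),
            cell_ec50_0pct_uM=_censor_at(ec50_0_uM, limit),
            cell_ec50_10pct_uM=_censor_at(ec50_10_uM, limit),
            ldh_ec50_uM=ldh,
            counterscreen_ec50_uM=counter,
            logd=logd,
            solubility_uM=CensoredValue(sol_uM, Bound.NONE, "uM"),
            extra={
                "truth_log10_cell_ratio": log_ratio,
                "truth_serum_shift": shift,
                "truth_toxic": bool(toxic[i]),
            },
        ))
    return LibraryTable(
        tuple(records),
        (f"simulate_library(seed={config.seed}, n={n}, "
         f"slope={config.permeability_slope})",),
    )


def _censor_at(value_uM: float, limit_uM: float) -> CensoredValue:
    if value_uM > limit_uM:
        return CensoredValue(limit_uM, Bound.GREATER_THAN, "uM")
    return CensoredValue(value_uM, Bound.NONE, "uM")
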