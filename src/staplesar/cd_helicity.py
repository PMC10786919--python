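"""Circular-dichroism processing: mean residue ellipticity and % helix.

Raw far-UV CD ellipticity (millidegrees) depends on instrument path
length, peptide concentration and chain length; mean residue
ellipticity (MRE, deg·cm²·dmol⁻¹) removes those factors:

    MRE(λ) = θ_mdeg(λ) / (10 · l_cm · C_molar · n_bonds)

with n_bonds = n_residues − 1 peptide bonds by default (switchable to
n_residues for the alternative convention).

Fraction helix is estimated from the single 222 nm band — the n→π*
transition whose depth is the classic helix reporter — by linear
interpolation between a fully helical and a fully coiled reference:

    fH = (MRE222 − θ_coil) / (θ_helix(n) − θ_coil)
    θ_helix(n) = −40000 · (1 − 2.5 / n),   θ_coil = +640

(θ_helix carries the standard 1/n chain-length correction for the
fraying ends of short helices).  The estimate is clamped to [0, 100]%.
This single-wavelength estimator trades the accuracy of full spectral
deconvolution for transparency and zero external dependencies; use it
for rank ordering and synthetic-data round trips, not for absolute
secondary-structure content.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "CdSpectrum",
    "mean_residue_ellipticity",
    "fraction_helix",
    "THETA_COIL",
    "theta_helix",
]

THETA_COIL = 640.0          # deg·cm²·dmol⁻¹ at 222 nm, random coil
_THETA_HELIX_INF = -40000.0  # infinite-helix limit at 222 nm


def theta_helix(n_residues: int) -> float:
    """Length-corrected 100%-helix MRE at 222 nm."""
    if n_residues < 4:
        raise ValueError("helix estimator needs n >= 4 residues")
    return _THETA_HELIX_INF * (1.0 - 2.5 / n_residues)


@dataclass(frozen=True)
class CdSpectrum:
    """A far-UV CD scan with the acquisition metadata MRE needs."""

    wavelength_nm: tuple[float, ...]
    ellipticity_mdeg: tuple[float, ...]
    conc_uM: float
    n_residues: int
    path_cm: float

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength_nm, dtype=float)
        if len(self.wavelength_nm) != len(self.ellipticity_mdeg):
            raise ValueError("wavelength and ellipticity lengths differ")
        d = np.diff(wl)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavelengths must be strictly monotone")
        if self.conc_uM <= 0 or self.path_cm <= 0 or self.n_residues <= 0:
            raise ValueError("conc, path length and residue count must be > 0")

    def at(self, wavelength: float) -> float:
        """Ellipticity at the grid point nearest ``wavelength``."""
        wl = np.asarray(self.wavelength_nm, dtype=float)
        return float(np.asarray(self.ellipticity_mdeg)[
            int(np.argmin(np.abs(wl - wavelength)))])


def mean_residue_ellipticity(spectrum: CdSpectrum,
                             per_bond: bool = True) -> np.ndarray:
    """Convert measured ellipticity to MRE (deg·cm²·dmol⁻¹).

    ``per_bond=True`` divides by n_residues − 1 peptide bonds (the
    default convention here); ``False`` divides by n_residues.
    """
    n_units = spectrum.n_residues - 1 if per_bond else spectrum.n_residues
    if n_units <= 0:
        raise ValueError("need at least 2 residues for the per-bond convention")
    molar = spectrum.conc_uM * 1e-6
    theta = np.asarray(spectrum.ellipticity_mdeg, dtype=float)
    return theta / (10.0 * spectrum.path_cm * molar * n_units)


def fraction_helix(mre222: float, n_residues: int,
                   theta_coil: float = THETA_COIL,
                   theta_helix_inf: float = _THETA_HELIX_INF) -> float:
    """Percent helix in [0, 100] from the 222 nm mean residue ellipticity.

    Monotone decreasing in ``mre222`` (a deeper, more negative band
    means more helix).  Alternative reference constants may be passed
    for other calibrations.
    """
    if n_residues < 4:
        raise ValueError("helix estimator needs n >= 4 residues")
    th = theta_helix_inf * (1.0 - 2.5 / n_residues)
    f = (mre222 - theta_coil) / (th - theta_coil)
    return float(np.clip(f, 0.0, 1.0) * 100.0)
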