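"""Library-level SAR indices for stapled-peptide optimization.

Each peptide in a screening library carries a biochemical binding
constant (K_D against Mdm2, nM), cellular reporter EC50s under two
conditions (serum-free 4 h and 10%-serum 16 h, µM), off-target readouts
(LDH release, counterscreen), on/off-target proliferation EC50s
(p53-wild-type HCT116 vs p53-deficient Ca Ski), lipophilicity (LogD),
solubility and helicity.  The derived indices defined here condense
those columns into the quantities the design rules are phrased in:

* **cell ratio** = cellular EC50 / binding K_D — a permeability proxy
  (a potent binder with weak cell activity is poorly permeable, so
  larger = less permeable);
* **on-target index** = off-target / on-target proliferation EC50 —
  the therapeutic window;
* **serum shift** = EC50(10% serum, 16 h) / EC50(0% serum, 4 h) — a
  serum-protein-binding proxy;
* **fold improvement** = reference / improved EC50.

All four are ratios of possibly censored values and propagate bounds
via :meth:`CensoredValue.divide` (a ``>`` numerator makes the ratio a
``>`` bound, etc.).  The module also implements the permeability-vs-
lipophilicity filter-and-correlate analysis, the kinetic-solubility
formula, and xenograft summaries (caliper tumor volume, % tumor growth
inhibition).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .censored import Bound, CensoredArithmeticError, CensoredValue, parse_censored
from .peptide_model import Peptide

__all__ = [
    "LibraryRecord",
    "LibraryTable",
    "cell_ratio",
    "on_target_index",
    "serum_shift",
    "fold_improvement",
    "solubility_from_areas",
    "fig3b_filter",
    "permeability_filter",
    "correlate",
    "tumor_volume",
    "tgi_percent",
    "read_library_csv",
    "library_to_frame",
]

NM_PER_UM = 1000.0  # exact unit harmonization factor


@dataclass(frozen=True)
class LibraryRecord:
    """One peptide's assay profile.  Censorable fields are CensoredValue."""

    name: str
    peptide: Peptide | None = None
    sequence: str = ""
    kd_nM: CensoredValue | None = None
    cell_ec50_0pct_uM: CensoredValue | None = None
    cell_ec50_10pct_uM: CensoredValue | None = None
    ldh_ec50_uM: CensoredValue | None = None
    counterscreen_ec50_uM: CensoredValue | None = None
    prolif_on_uM: CensoredValue | None = None    # HCT116 (p53 WT)
    prolif_off_uM: CensoredValue | None = None   # Ca Ski (p53 deficient)
    logd: float | None = None
    alogp: float | None = None
    solubility_uM: CensoredValue | None = None
    helicity_pct: float | None = None
    tail_class: Literal["high", "low", ""] = ""
    extra: dict = field(default_factory=dict, compare=False)


@dataclass(frozen=True)
class LibraryTable:
    """An immutable list of records plus an append-only filter log."""

    records: tuple[LibraryRecord, ...]
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        names = [r.name for r in self.records]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate peptide names: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def logged(self, message: str) -> "LibraryTable":
        return replace(self, provenance=self.provenance + (message,))


# ---------------------------------------------------------------------------
# per-record indices
# ---------------------------------------------------------------------------

def cell_ratio(cell_ec50_uM: CensoredValue, kd_nM: CensoredValue) -> CensoredValue:
    """Permeability proxy: cellular EC50 / binding K_D (unitless).

    Units are harmonized (EC50 µM → nM) before dividing.  A censored
    (``>``) EC50 propagates to a ``>`` ratio; a below-bound or zero
    K_D is rejected as indeterminate.
    """
    if kd_nM.value <= 0:
        raise ValueError("Kd must be positive")
    if kd_nM.is_censored_below:
        # '<X' Kd: ratio only bounded below -> still a '>' bound, allowed
        pass
    return cell_ec50_uM.scaled(NM_PER_UM).divide(kd_nM)


def on_target_index(prolif_off_uM: CensoredValue,
                    prolif_on_uM: CensoredValue) -> CensoredValue:
    """Therapeutic window: off-target EC50 / on-target EC50.

    Requires a measured on-target potency; raises if the on-target
    value is itself a ``>`` ceiling (the window is then undefined).
    """
    if prolif_on_uM.is_censored_above:
        raise CensoredArithmeticError(
            "on-target EC50 is censored above; index undefined"
        )
    return prolif_off_uM.divide(prolif_on_uM)


def serum_shift(cell_ec50_10pct_uM: CensoredValue,
                cell_ec50_0pct_uM: CensoredValue) -> CensoredValue:
    """Serum-binding proxy: EC50 under 10% serum / EC50 serum-free."""
    return cell_ec50_10pct_uM.divide(cell_ec50_0pct_uM)


def fold_improvement(reference_uM: CensoredValue,
                     improved_uM: CensoredValue) -> CensoredValue:
    """Potency gain of an optimized analog: reference / improved EC50."""
    if improved_uM.is_censored_above:
        raise CensoredArithmeticError(
            "improved potency is censored above; fold improvement undefined"
        )
    return reference_uM.divide(improved_uM)


def solubility_from_areas(area_sample: float, area_standard: float,
                          standard_conc_uM: float) -> float:
    """Kinetic solubility from UPLC peak areas.

    Solubility [µM] = (sample area / standard area) · standard
    concentration; the standard is a fully dissolved reference of the
    same compound.
    """
    if area_standard <= 0:
        raise ValueError("standard peak area must be positive")
    if area_sample < 0:
        raise ValueError("sample peak area cannot be negative")
    return (area_sample / area_standard) * standard_conc_uM


# ---------------------------------------------------------------------------
# library filter + correlation
# ---------------------------------------------------------------------------

def _passes_permeability_filter(rec: LibraryRecord,
                                kd_limit_nM: float,
                                margin: float) -> bool:
    """Clean-pharmacology gate for the permeability/lipophilicity plot.

    Keep records whose binding is genuine (K_D below ``kd_limit_nM``)
    and whose cellular activity is at least ``margin``-fold more potent
    than both the counterscreen and the LDH readouts.  Censored ``>``
    entries are evaluated optimistically at their bound (a '>50 µM'
    counterscreen passes any margin its limit passes).
    """
    if rec.kd_nM is None or rec.cell_ec50_0pct_uM is None:
        return False
    if rec.kd_nM.is_censored_above:
        return False
    if rec.kd_nM.value >= kd_limit_nM:
        return False
    cell = rec.cell_ec50_0pct_uM.value
    for off in (rec.counterscreen_ec50_uM, rec.ldh_ec50_uM):
        if off is None:
            return False
        if off.is_censored_below:
            return False
        if cell * margin > off.value:
            return False
    return True


def permeability_filter(table: LibraryTable,
                        kd_limit_nM: float = 10_000.0,
                        margin: float = 10.0) -> LibraryTable:
    """Restrict a library to clean, genuinely binding records.

    Default limits: K_D < 10 µM and a 10× selectivity margin of the
    cellular EC50 over counterscreen and LDH potencies.  Idempotent;
    before/after counts are appended to the provenance log.
    """
    kept = tuple(
        r for r in table.records
        if _passes_permeability_filter(r, kd_limit_nM, margin)
    )
    msg = (f"permeability_filter(kd<{kd_limit_nM:g} nM, margin={margin:g}x): "
           f"{len(table.records)} -> {len(kept)} records")
    return LibraryTable(kept, table.provenance + (msg,))


#: name used in the figure the filter reproduces
fig3b_filter = permeability_filter


def correlate(table: LibraryTable, x_column: str, y_column: str,
              log_x: bool = False, log_y: bool = False,
              method: Literal["pearson", "spearman"] = "pearson"):
    """Correlation between two library columns, excluding censored rows.

    Returns ``(r, p_value, n, n_excluded)``.  Columns may name either
    plain-float fields (``logd``) or censored fields (``kd_nM`` …);
    censored entries and missing values are excluded and counted.
    Derived column ``log10_cell_ratio`` is understood directly.
    """
    xs, ys = [], []
    n_excluded = 0
    for rec in table.records:
        vx = _column_value(rec, x_column)
        vy = _column_value(rec, y_column)
        if vx is None or vy is None:
            n_excluded += 1
            continue
        xs.append(vx)
        ys.append(vy)
    if len(xs) < 3:
        raise ValueError(f"need >= 3 complete pairs, have {len(xs)}")
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if log_x:
        x = np.log10(x)
    if log_y:
        y = np.log10(y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant column; correlation undefined")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    else:
        r, p = stats.spearmanr(x, y)
    return float(r), float(p), len(xs), n_excluded


def _column_value(rec: LibraryRecord, column: str) -> float | None:
    """Uncensored numeric value of a column, or None if unusable."""
    if column == "log10_cell_ratio":
        if rec.cell_ec50_0pct_uM is None or rec.kd_nM is None:
            return None
        try:
            ratio = cell_ratio(rec.cell_ec50_0pct_uM, rec.kd_nM)
        except (ValueError, ZeroDivisionError):
            return None
        if ratio.is_censored or ratio.value <= 0:
            return None
        return math.log10(ratio.value)
    val = getattr(rec, column, None)
    if val is None:
        return None
    if isinstance(val, CensoredValue):
        return None if val.is_censored else val.value
    return float(val)


# ---------------------------------------------------------------------------
# xenograft summaries
# ---------------------------------------------------------------------------

def tumor_volume(a_mm: float, b_mm: float, c_mm: float,
                 convention: Literal["4pi_abc_3", "ellipsoid"] = "4pi_abc_3"
                 ) -> float:
    """Caliper tumor volume (mm³) from three measured diameters.

    The default reproduces the study convention V = 4πabc/3 exactly as
    reported.  Note that for diameters this is 8× the true ellipsoid
    volume π·a·b·c/6, available as ``convention='ellipsoid'``.
    """
    if min(a_mm, b_mm, c_mm) <= 0:
        raise ValueError("diameters must be positive")
    if convention == "4pi_abc_3":
        return 4.0 * math.pi * a_mm * b_mm * c_mm / 3.0
    return math.pi * a_mm * b_mm * c_mm / 6.0


def tgi_percent(treated_mean_volumes: Sequence[float],
                vehicle_mean_volumes: Sequence[float]) -> float:
    """Tumor growth inhibition, % = 100 · (1 − ΔT/ΔV).

    Growth Δ is baseline-to-endpoint change of the group mean volume;
    both series must share timepoints.  Requires positive vehicle
    growth.  Values above 100% (regression below baseline) are
    reported as computed.
    """
    t = np.asarray(treated_mean_volumes, dtype=float)
    v = np.asarray(vehicle_mean_volumes, dtype=float)
    if t.shape != v.shape or t.size < 2:
        raise ValueError("series must share >= 2 timepoints")
    if t[0] <= 0 or v[0] <= 0:
        raise ValueError("baseline volumes must be positive")
    dv = v[-1] - v[0]
    if dv <= 0:
        raise ValueError("vehicle group did not grow; TGI undefined")
    dt = t[-1] - t[0]
    return 100.0 * (1.0 - dt / dv)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

#: CSV column -> (record field, units) for censorable columns
_CENSORED_COLUMNS = {
    "kd_nM": "nM",
    "cell_ec50_0pct_uM": "uM",
    "cell_ec50_10pct_uM": "uM",
    "ldh_ec50_uM": "uM",
    "counterscreen_ec50_uM": "uM",
    "prolif_on_uM": "uM",
    "prolif_off_uM": "uM",
    "solubility_uM": "uM",
}
_FLOAT_COLUMNS = ("logd", "alogp", "helicity_pct")


def read_library_csv(path) -> LibraryTable:
    """Read a one-row-per-peptide library CSV.

    Required column: ``name``.  Optional: ``sequence``, the censorable
    assay columns (entries like ``0.47``, ``>50``, ``>>50``, ``<1``),
    ``logd``, ``alogp``, ``helicity_pct``, ``tail_class``.  Unknown
    columns are preserved in ``record.extra``.
    """
    df = pd.read_csv(path, dtype=str)
    if "name" not in df.columns:
        raise ValueError("library CSV must have a 'name' column")
    known = {"name", "sequence", "tail_class", *_CENSORED_COLUMNS,
             *_FLOAT_COLUMNS}
    records = []
    for _, row in df.iterrows():
        kwargs: dict = {"name": row["name"]}
        if "sequence" in df.columns and _present(row.get("sequence")):
            kwargs["sequence"] = row["sequence"]
        if "tail_class" in df.columns and _present(row.get("tail_class")):
            kwargs["tail_class"] = row["tail_class"].strip().lower()
        for col, units in _CENSORED_COLUMNS.items():
            if col in df.columns and _present(row.get(col)):
                kwargs[col] = parse_censored(row[col], units)
        for col in _FLOAT_COLUMNS:
            if col in df.columns and _present(row.get(col)):
                kwargs[col] = float(row[col])
        extra = {c: row[c] for c in df.columns if c not in known}
        records.append(LibraryRecord(extra=extra, **kwargs))
    return LibraryTable(tuple(records), (f"loaded {len(records)} records",))


def _present(value) -> bool:
    return isinstance(value, str) and value.strip() not in ("", "NA", "N.D.",
                                                            "P.B.", "nan")


def library_to_frame(table: LibraryTable) -> pd.DataFrame:
    """Flatten a LibraryTable to a DataFrame (censored values as text)."""
    rows = []
    for rec in table.records:
        row: dict = {"name": rec.name, "sequence": rec.sequence,
                     "tail_class": rec.tail_class, "logd": rec.logd,
                     "alogp": rec.alogp, "helicity_pct": rec.helicity_pct}
        for col in _CENSORED_COLUMNS:
            val = getattr(rec, col)
            row[col] = str(val).split()[0] if val is not None else ""
        rows.append(row)
    return pd.DataFrame(rows)
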