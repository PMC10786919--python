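import math

import numpy as np
import pytest

from staplesar import (
    LibraryRecord,
    LibraryTable,
    cell_ratio,
    correlate,
    fold_improvement,
    on_target_index,
    permeability_filter,
    serum_shift,
    solubility_from_areas,
    tgi_percent,
    tumor_volume,
)
from staplesar.censored import (
    Bound,
    CensoredArithmeticError,
    CensoredValue,
    parse_censored,
)
from staplesar.sar_metrics import library_to_frame, read_library_csv
from staplesar.synthetic_data import LibrarySimConfig, simulate_library


def cv(text, units=""):
    return parse_censored(text, units)


# ---------------------------------------------------------------------------
# worked examples from the published tables
# ---------------------------------------------------------------------------

def test_cell_ratio_template_peptide():
    # template: cellular EC50 0.47 uM over Kd 5.0 nM -> ratio 94
    ratio = cell_ratio(cv("0.47", "uM"), cv("5.0", "nM"))
    assert not ratio.is_censored
    assert ratio.value == pytest.approx(94.0)


def test_cell_ratio_units_and_censoring():
    assert cell_ratio(cv("0.005", "uM"), cv("5.0", "nM")).value == \
        pytest.approx(1.0)
    censored = cell_ratio(cv(">50", "uM"), cv("5.0", "nM"))
    assert censored.bound is Bound.GREATER_THAN
    assert censored.value == pytest.approx(10000.0)


def test_on_target_index_lead_peptide():
    # optimized di-alkyne lead: Ca Ski >> 50 uM over HCT116 0.013 uM
    idx = on_target_index(cv(">>50", "uM"), cv("0.013", "uM"))
    assert idx.bound is Bound.GREATER_THAN
    assert idx.value > 3800.0
    assert idx.value == pytest.approx(3846.15, rel=1e-3)


def test_on_target_index_narrow_window():
    # all-D analog: 31 uM off-target over 1.5 uM on-target, ~20-fold
    idx = on_target_index(cv("31", "uM"), cv("1.5", "uM"))
    assert not idx.is_censored
    assert idx.value == pytest.approx(20.67, rel=1e-2)
    assert on_target_index(cv("5", "uM"), cv("5", "uM")).value == 1.0


def test_on_target_index_requires_measured_on_target():
    with pytest.raises(CensoredArithmeticError):
        on_target_index(cv("31", "uM"), cv(">50", "uM"))


def test_serum_shift_di_phe_peptide():
    # di-Phe tail analog: 0.75 uM at 10% serum vs 0.036 uM serum-free
    shift = serum_shift(cv("0.75", "uM"), cv("0.036", "uM"))
    assert shift.value == pytest.approx(20.83, rel=1e-3)
    assert shift.value > 20.0
    assert serum_shift(cv("1.0"), cv("1.0")).value == 1.0
    censored = serum_shift(cv(">50"), cv("0.1"))
    assert censored.bound is Bound.GREATER_THAN
    assert censored.value == pytest.approx(500.0)


def test_fold_improvement_all_d_series():
    # inactive parent (>50 uM ceiling) vs optimized 0.28 uM analog
    fold = fold_improvement(cv(">50", "uM"), cv("0.28", "uM"))
    assert fold.bound is Bound.GREATER_THAN
    assert fold.value == pytest.approx(178.57, rel=1e-3)
    assert fold_improvement(cv("5"), cv("5")).value == 1.0
    with pytest.raises(CensoredArithmeticError):
        fold_improvement(cv("50"), cv(">50"))


@pytest.mark.parametrize(
    "sample, standard, conc, expected",
    [(1000.0, 1000.0, 100.0, 100.0),
     (500.0, 1000.0, 100.0, 50.0),
     (0.0, 1000.0, 100.0, 0.0)],
)
def test_solubility_from_areas(sample, standard, conc, expected):
    assert solubility_from_areas(sample, standard, conc) == \
        pytest.approx(expected)


def test_solubility_rejects_zero_standard():
    with pytest.raises(ValueError):
        solubility_from_areas(100.0, 0.0, 100.0)


# ---------------------------------------------------------------------------
# library filter
# ---------------------------------------------------------------------------

def _record(name, kd="5", cell="0.5", counter=">50", ldh=">50", **kw):
    return LibraryRecord(
        name=name,
        kd_nM=cv(kd, "nM"),
        cell_ec50_0pct_uM=cv(cell, "uM"),
        counterscreen_ec50_uM=cv(counter, "uM"),
        ldh_ec50_uM=cv(ldh, "uM"),
        **kw,
    )


def test_filter_keeps_clean_binder():
    table = LibraryTable((_record("ok"),))
    assert len(permeability_filter(table)) == 1


@pytest.mark.parametrize(
    "kw",
    [
        {"kd": "20000"},            # 20 uM binder: above the Kd limit
        {"counter": "3"},           # within 10x of the 0.5 uM cell EC50
        {"ldh": "4.9"},             # violates the LDH margin
        {"kd": ">50000"},           # unmeasurable binding
    ],
)
def test_filter_drops_violations(kw):
    table = LibraryTable((_record("bad", **kw),))
    assert len(permeability_filter(table)) == 0


def test_filter_is_idempotent_and_logged():
    records = tuple(
        _record(f"r{i}", counter=("3" if i % 3 == 0 else ">50"))
        for i in range(30)
    )
    table = LibraryTable(records)
    once = permeability_filter(table)
    twice = permeability_filter(once)
    assert once.records == twice.records
    assert len(once.provenance) == 1 and len(twice.provenance) == 2
    assert "30 -> 20" in once.provenance[0]


def test_filter_planted_violations_independent_recount():
    table = simulate_library(LibrarySimConfig(n_peptides=100, seed=42,
                                              fraction_toxic=0.37))
    survivors = permeability_filter(table)

    # independent brute-force re-check of every rule, record by record
    expected = 0
    for rec in table.records:
        ok = (not rec.kd_nM.is_censored_above
              and rec.kd_nM.value < 10_000.0)
        for off in (rec.counterscreen_ec50_uM, rec.ldh_ec50_uM):
            if rec.cell_ec50_0pct_uM.value * 10.0 > off.value:
                ok = False
        expected += ok
    assert len(survivors) == expected
    assert 0 < len(survivors) < len(table)


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def _mini_table(xs, ys):
    recs = tuple(
        LibraryRecord(name=f"p{i}", logd=x, alogp=y)
        for i, (x, y) in enumerate(zip(xs, ys))
    )
    return LibraryTable(recs)


def test_correlate_perfect_line():
    x = [0.0, 1.0, 2.0, 3.0]
    r, p, n, nex = correlate(_mini_table(x, [2 * v + 1 for v in x]),
                             "logd", "alogp")
    assert r == pytest.approx(1.0)
    assert n == 4 and nex == 0


def test_correlate_constant_column_rejected():
    with pytest.raises(ValueError, match="constant"):
        correlate(_mini_table([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]),
                  "logd", "alogp")


def test_correlate_excludes_censored_and_counts():
    recs = (
        LibraryRecord(name="a", logd=1.0, kd_nM=cv("10", "nM")),
        LibraryRecord(name="b", logd=2.0, kd_nM=cv("100", "nM")),
        LibraryRecord(name="c", logd=2.5, kd_nM=cv(">500", "nM")),
        LibraryRecord(name="d", logd=3.0, kd_nM=cv("1000", "nM")),
    )
    r, p, n, nex = correlate(LibraryTable(recs), "logd", "kd_nM", log_y=True)
    assert n == 3 and nex == 1
    assert r == pytest.approx(1.0)


def test_correlate_recovers_planted_lipophilicity_trend():
    hits = 0
    n_runs = 40
    for seed in range(n_runs):
        table = simulate_library(LibrarySimConfig(n_peptides=200, seed=seed))
        r, p, n, _ = correlate(table, "logd", "log10_cell_ratio")
        if r < -0.6:
            hits += 1
    assert hits >= math.ceil(0.95 * n_runs)


def test_correlate_null_slope_gives_no_correlation():
    hits = 0
    n_runs = 20
    for seed in range(n_runs):
        table = simulate_library(LibrarySimConfig(
            n_peptides=200, seed=seed, permeability_slope=0.0))
        r, p, n, _ = correlate(table, "logd", "log10_cell_ratio")
        if abs(r) < 0.2:
            hits += 1
    assert hits >= 0.9 * n_runs


# ---------------------------------------------------------------------------
# xenograft summaries
# ---------------------------------------------------------------------------

def test_tumor_volume_printed_convention():
    assert tumor_volume(1.0, 1.0, 1.0) == pytest.approx(4.18879, rel=1e-5)
    assert tumor_volume(2.0, 3.0, 4.0) == tumor_volume(4.0, 3.0, 2.0)
    # the printed convention is 8x the ellipsoid-from-diameters volume
    assert tumor_volume(2.0, 3.0, 4.0) == pytest.approx(
        8.0 * tumor_volume(2.0, 3.0, 4.0, convention="ellipsoid"))
    with pytest.raises(ValueError):
        tumor_volume(0.0, 1.0, 1.0)


def test_tgi_worked_examples():
    assert tgi_percent([100.0, 400.0], [100.0, 400.0]) == pytest.approx(0.0)
    assert tgi_percent([100.0, 100.0], [100.0, 400.0]) == pytest.approx(100.0)
    assert tgi_percent([100.0, 201.0], [100.0, 400.0]) == \
        pytest.approx(66.33, rel=1e-3)
    with pytest.raises(ValueError):
        tgi_percent([100.0, 90.0], [100.0, 80.0])   # vehicle shrank


# ---------------------------------------------------------------------------
# I/O round trip
# ---------------------------------------------------------------------------

def test_library_csv_round_trip(tmp_path):
    table = simulate_library(LibrarySimConfig(n_peptides=25, seed=7))
    path = tmp_path / "lib.csv"
    library_to_frame(table).to_csv(path, index=False)
    loaded = read_library_csv(path)
    assert len(loaded) == 25
    for orig, back in zip(table.records, loaded.records):
        assert back.name == orig.name
        assert back.kd_nM.bound is orig.kd_nM.bound
        assert back.kd_nM.value == pytest.approx(orig.kd_nM.value, rel=1e-4)
        assert back.cell_ec50_0pct_uM.bound is orig.cell_ec50_0pct_uM.bound


def test_library_requires_unique_names():
    rec = LibraryRecord(name="dup")
    with pytest.raises(ValueError, match="duplicate"):
        LibraryTable((rec, rec))


def test_library_csv_requires_name_column(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("kd_nM\n5\n")
    with pytest.raises(ValueError, match="name"):
        read_library_csv(path)
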