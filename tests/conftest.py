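import pytest

from staplesar import parse_sequence

#: reference C-terminal tail series: (name, tail notation fragment,
#: published aqueous helical-propensity class)
TAIL_SERIES = [
    ("MP-081", "SAA", "high"),
    ("MP-685", "AAAAA", "high"),
    ("MP-032", "AAAAAA", "high"),
    ("MP-464", "AAAAA[dA]", "high"),
    ("MP-470", "AAAAAAA", "high"),
    ("MP-471", "AAAAAAA", "high"),
    ("MP-759", "AAAAAAAAA", "high"),
    ("MP-684", "AAA", "high"),          # cleaved tail, free acid C-terminus
    ("MP-688", "AAAAAA", "high"),
    ("ALRN-6924", "AAAAA[dA]", "high"),
    ("MP-413", "A[Aib][Aib][Aib][Aib][Aib]", "high"),
    ("MP-966", "AQAAA[dA]", "high"),
    ("MP-425", "AA[dA]AA[dA]", "low"),
    ("MP-056", "A[dA]A[dA]A[dA]", "low"),
    ("MP-443", "A[Sar][Sar][Sar][Sar][Sar]", "low"),
    ("MP-289", "GGGGGG", "low"),
    ("MP-093", "PPPPPP", "low"),
    ("MP-094", "PPPPPP", "low"),
    ("MP-896", "[dP][dP][dP][dP][dP][dP]", "low"),
]


def tail_residues(fragment: str):
    """Residue tuple for a tail fragment written without caps."""
    return parse_sequence(f"Ac-{fragment}-NH2").residues


@pytest.fixture(scope="session")
def tail_series():
    return TAIL_SERIES
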