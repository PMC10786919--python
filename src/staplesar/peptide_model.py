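"""Stapled-peptide sequence model: parsing, charge, wheel geometry.

Stapled α-helical peptides mix natural amino acids with non-natural
building blocks: olefin-bearing α-methyl residues that form hydrocarbon
staples ((R)-2-(7'-octenyl)alanine, "R8"; (S)-2-(4'-pentenyl)alanine,
"S5"), di-alkyne staple arms, cyclobutylalanine, γ-carboxyglutamate,
α-methylated and D-configured residues, and so on.  This module gives
them a strict textual grammar, a registry of per-residue physical
properties, and the sequence-level quantities the SAR analysis needs:

* net formal charge at pH 7.4 (side chains plus termini; side chains
  consumed by a staple contribute nothing),
* ideal-helix wheel projection (100°/residue, 3.6 residues per turn),
* a hydrophobic moment quantifying amphipathicity,
* a helical-propensity class for C-terminal tail extensions.

Sequence notation
-----------------
``Ac-LTF[R8]EYWAQL[S5]AAAAA[dA]-NH2``

* mandatory N-terminal cap prefix: ``Ac-`` (acetyl) or ``H-`` (free amine)
* one-letter codes for the 20 L-amino acids; bracketed tokens for
  everything else (``[dA]`` D-alanine, ``[R8]``, ``[S5]``, ``[X]``
  di-alkyne arm, ``[Cba]``, ``[Aib]``, ``[Sar]``, ``[Gla]``, ``[aMeE]``,
  ``[aMeF]``, ``[hS]``, ``[hR]``, ``[KN3]`` azido-lysine, ``[bA]``
  β-alanine)
* mandatory C-terminal cap suffix: ``-NH2`` (amide) or ``-OH`` (free acid)

Olefin and di-alkyne staples are inferred from their arm residues:
an R8→S5 pair seven positions apart is an i,i+7 olefin staple, an
S5→S5 pair four apart an i,i+4 olefin, an X→X pair seven apart a
di-alkyne.  Lactam and triazole crosslinks reuse ordinary side chains
and are declared explicitly via :class:`StapleSpec`.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Literal, Sequence

__all__ = [
    "Residue",
    "Peptide",
    "StapleSpec",
    "WheelProjection",
    "load_registry",
    "parse_sequence",
    "format_peptide",
    "net_charge",
    "helical_wheel",
    "hydrophobic_moment",
    "classify_tail_propensity",
    "tail_after_staple",
    "SequenceError",
]

DEGREES_PER_RESIDUE = 100.0  # ideal alpha helix, 3.6 residues/turn


class SequenceError(ValueError):
    """Malformed sequence notation or unregistered residue token."""


# ---------------------------------------------------------------------------
# residue registry
# ---------------------------------------------------------------------------

Chirality = Literal["L", "D", "achiral"]
PolarityClass = Literal["apolar", "acidic", "basic", "polar_uncharged"]


@dataclass(frozen=True)
class Residue:
    """One registered residue type with its pH 7.4 properties."""

    code: str
    chirality: Chirality
    side_chain_charge: int
    polarity_class: PolarityClass
    hydrophobicity: float
    helix_propensity_class: Literal["high", "low"]
    is_staple_residue: bool

    def __post_init__(self) -> None:
        if self.side_chain_charge not in (-2, -1, 0, 1):
            raise ValueError(
                f"side-chain charge {self.side_chain_charge} outside {{-2,-1,0,+1}}"
            )


def load_registry(path: str | None = None) -> dict[str, Residue]:
    """Load the residue registry (code → :class:`Residue`).

    The default table ships with the package as editable JSON; pass
    ``path`` to use a customized copy.
    """
    if path is None:
        text = (
            resources.files("staplesar").joinpath("data/residues.json").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    raw = json.loads(text)
    return {code: Residue(code=code, **props) for code, props in raw.items()}


_DEFAULT_REGISTRY: dict[str, Residue] | None = None


def _registry() -> dict[str, Residue]:
    global _DEFAULT_REGISTRY
    if _DEFAULT_REGISTRY is None:
        _DEFAULT_REGISTRY = load_registry()
    return _DEFAULT_REGISTRY


# ---------------------------------------------------------------------------
# peptide and staple types
# ---------------------------------------------------------------------------

StapleChemistry = Literal["olefin_i4", "olefin_i7", "lactam", "dialkyne", "triazole"]

#: residue-index span each chemistry crosslinks (i -> i + span)
_STAPLE_SPANS: dict[StapleChemistry, int] = {
    "olefin_i4": 4,
    "olefin_i7": 7,
    "dialkyne": 7,
    "lactam": 4,
    "triazole": 7,
}


@dataclass(frozen=True)
class StapleSpec:
    """A covalent crosslink between two residue positions (1-based)."""

    positions: tuple[int, int]
    chemistry: StapleChemistry

    def __post_init__(self) -> None:
        i, j = self.positions
        if j <= i:
            raise ValueError("staple positions must be ordered i < j")
        expected = _STAPLE_SPANS[self.chemistry]
        if j - i != expected:
            raise ValueError(
                f"{self.chemistry} staple spans i,i+{expected}; got positions {i},{j}"
            )

    @property
    def span(self) -> int:
        return self.positions[1] - self.positions[0]


NCap = Literal["acetyl", "free"]
CCap = Literal["amide", "free_acid"]

_NCAP_CHARGE = {"acetyl": 0, "free": 1}
_CCAP_CHARGE = {"amide": 0, "free_acid": -1}


@dataclass(frozen=True)
class Peptide:
    """An ordered residue chain with explicit terminal caps and staples."""

    residues: tuple[Residue, ...]
    n_term_cap: NCap
    c_term_cap: CCap
    staples: tuple[StapleSpec, ...] = ()
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError("peptide needs at least one residue")
        n = len(self.residues)
        for sp in self.staples:
            for pos in sp.positions:
                if not 1 <= pos <= n:
                    raise ValueError(
                        f"staple position {pos} outside 1..{n}"
                    )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def stapled_positions(self) -> frozenset[int]:
        return frozenset(p for sp in self.staples for p in sp.positions)

    def with_name(self, name: str) -> "Peptide":
        return replace(self, name=name)


# ---------------------------------------------------------------------------
# parsing / formatting
# ---------------------------------------------------------------------------

#: the 20 canonical L-amino-acid one-letter codes (written unbracketed)
_NATURAL_CODES = frozenset("ACDEFGHIKLMNPQRSTVWY")

_TOKEN_RE = re.compile(r"\[([^\[\]]+)\]|([A-Z])")


def _tokenize(body: str) -> list[str]:
    tokens: list[str] = []
    pos = 0
    while pos < len(body):
        m = _TOKEN_RE.match(body, pos)
        if m is None:
            raise SequenceError(
                f"unparseable sequence at {body[pos:pos+8]!r} (offset {pos})"
            )
        tokens.append(m.group(1) or m.group(2))
        pos = m.end()
    return tokens


def _infer_staples(residues: Sequence[Residue]) -> tuple[StapleSpec, ...]:
    """Pair up olefin / di-alkyne arm residues into staples."""
    arms = [(i + 1, r.code) for i, r in enumerate(residues) if r.is_staple_residue]
    if not arms:
        return ()
    if len(arms) % 2:
        raise SequenceError(
            f"odd number of staple arm residues: {[c for _, c in arms]}"
        )
    staples = []
    for (i, ci), (j, cj) in zip(arms[::2], arms[1::2]):
        span = j - i
        if (ci, cj) == ("R8", "S5") and span == 7:
            chem: StapleChemistry = "olefin_i7"
        elif (ci, cj) == ("S5", "S5") and span == 4:
            chem = "olefin_i4"
        elif (ci, cj) == ("X", "X") and span == 7:
            chem = "dialkyne"
        else:
            raise SequenceError(
                f"staple arms {ci}@{i} / {cj}@{j} (span {span}) match no "
                "registered chemistry"
            )
        staples.append(StapleSpec((i, j), chem))
    return tuple(staples)


def parse_sequence(
    notation: str,
    registry: dict[str, Residue] | None = None,
    name: str = "",
) -> Peptide:
    """Parse extended peptide notation into a :class:`Peptide`.

    Raises :class:`SequenceError` for empty input, unknown residue
    tokens, missing terminal cap annotations, or staple arm residues
    that cannot be paired into a registered staple chemistry.
    """
    reg = registry if registry is not None else _registry()
    s = notation.strip()
    if not s:
        raise SequenceError("empty sequence")

    if s.startswith("Ac-"):
        n_cap: NCap = "acetyl"
        s = s[3:]
    elif s.startswith("H-"):
        n_cap = "free"
        s = s[2:]
    else:
        raise SequenceError(
            f"missing N-terminal cap annotation ('Ac-' or 'H-') in {notation!r}"
        )

    if s.endswith("-NH2"):
        c_cap: CCap = "amide"
        s = s[:-4]
    elif s.endswith("-OH"):
        c_cap = "free_acid"
        s = s[:-3]
    else:
        raise SequenceError(
            f"missing C-terminal cap annotation ('-NH2' or '-OH') in {notation!r}"
        )

    tokens = _tokenize(s)
    if not tokens:
        raise SequenceError(f"no residues in {notation!r}")
    residues = []
    for tok in tokens:
        if tok not in reg:
            raise SequenceError(f"unknown residue token {tok!r}")
        residues.append(reg[tok])
    residues = tuple(residues)
    return Peptide(residues, n_cap, c_cap, _infer_staples(residues), name)


def format_peptide(peptide: Peptide) -> str:
    """Canonical notation for a peptide; inverse of :func:`parse_sequence`."""
    prefix = "Ac-" if peptide.n_term_cap == "acetyl" else "H-"
    suffix = "-NH2" if peptide.c_term_cap == "amide" else "-OH"
    body = "".join(
        r.code if r.code in _NATURAL_CODES else f"[{r.code}]"
        for r in peptide.residues
    )
    return f"{prefix}{body}{suffix}"


# ---------------------------------------------------------------------------
# net charge
# ---------------------------------------------------------------------------

def net_charge(peptide: Peptide) -> int:
    """Net formal charge at pH 7.4.

    Sum of registered side-chain charges plus terminal contributions
    (free N-terminus +1, acetyl 0; free-acid C-terminus −1, amide 0).
    His counts 0 (pKa ≈ 6).  Side chains at staple positions contribute
    0: olefin/di-alkyne arms are apolar anyway, and a lactam bridge
    consumes both the Lys amine and the Glu carboxylate.
    """
    stapled = peptide.stapled_positions
    total = _NCAP_CHARGE[peptide.n_term_cap] + _CCAP_CHARGE[peptide.c_term_cap]
    for idx, res in enumerate(peptide.residues, start=1):
        if idx in stapled:
            continue
        total += res.side_chain_charge
    return total


# ---------------------------------------------------------------------------
# helical wheel & amphipathicity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WheelProjection:
    """Residues projected onto an ideal α-helical wheel.

    ``entries`` holds ``(residue_index, angle_degrees, polarity_class)``
    with angle = (index − 1) · 100° mod 360°.
    """

    entries: tuple[tuple[int, float, str], ...] = field(default=())


def helical_wheel(peptide: Peptide) -> WheelProjection:
    """Project the sequence onto the ideal 100°/residue helical wheel."""
    if len(peptide) < 2:
        raise ValueError("helical wheel needs at least 2 residues")
    entries = tuple(
        (i, (i - 1) * DEGREES_PER_RESIDUE % 360.0, r.polarity_class)
        for i, r in enumerate(peptide.residues, start=1)
    )
    return WheelProjection(entries)


def hydrophobic_moment(
    peptide: Peptide, window: tuple[int, int] | None = None
) -> float:
    """Per-residue hydrophobic moment on the ideal helical wheel.

    Magnitude of the vector sum of residue hydrophobicities placed at
    their wheel angles, divided by the number of residues considered.
    An amphipathic sequence (hydrophobic residues clustered on one
    face) gives a large moment; a hydrophobically uniform one gives a
    moment near zero.

    ``window`` is an inclusive 1-based ``(start, stop)`` residue range;
    the default covers the whole sequence.
    """
    n = len(peptide)
    if window is None:
        start, stop = 1, n
    else:
        start, stop = window
    if not (1 <= start <= stop <= n):
        raise ValueError(f"window {window} empty or outside 1..{n}")
    sx = sy = 0.0
    for i in range(start, stop + 1):
        theta = math.radians((i - 1) * DEGREES_PER_RESIDUE)
        h = peptide.residues[i - 1].hydrophobicity
        sx += h * math.cos(theta)
        sy += h * math.sin(theta)
    return math.hypot(sx, sy) / (stop - start + 1)


# ---------------------------------------------------------------------------
# tail helical propensity
# ---------------------------------------------------------------------------

def tail_after_staple(peptide: Peptide) -> tuple[Residue, ...]:
    """C-terminal extension after the last staple arm position."""
    stapled = peptide.stapled_positions
    if not stapled:
        raise ValueError("peptide has no staple; tail is undefined")
    return peptide.residues[max(stapled):]


def classify_tail_propensity(
    tail: Peptide | Sequence[Residue],
) -> Literal["high", "low"]:
    """Classify a C-terminal tail as high or low aqueous helical propensity.

    The tail is *low* propensity iff it contains a canonical helix
    breaker (Gly, Pro, or sarcosine, anywhere) or a D-configured residue
    at a non-C-terminal position; a single terminal D-residue (a common
    protease-resistance cap, as in the -AAAAA-dA-NH2 tail) does not
    disturb the helix and leaves the tail *high*.  This reverse-
    engineered rule reproduces every printed propensity label in the
    reference tail series.
    """
    residues: Sequence[Residue]
    residues = tail.residues if isinstance(tail, Peptide) else tuple(tail)
    if len(residues) == 0:
        raise ValueError("empty tail")
    last = len(residues) - 1
    for i, res in enumerate(residues):
        if res.helix_propensity_class == "low":  # G, P, Sar
            return "low"
        if res.chirality == "D" and i != last:
            return "low"
    return "high"
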