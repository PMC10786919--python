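"""Censored assay values and their propagation through ratios.

Screening tables routinely report bounds rather than point estimates:
an EC50 that never crossed its half-maximal threshold inside the tested
range is written ">50" (µM), a binding constant below the assay floor is
written "<1" (nM), and an emphatically inactive compound may be written
">>50".  Downstream indices built from such numbers (potency ratios,
fold improvements, therapeutic windows) must carry the bound instead of
silently treating the censoring limit as a measurement.

:class:`CensoredValue` is the single container used across the package;
the arithmetic here implements the bound-propagation rules for division,
the only operation the SAR indices need.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, replace
from enum import Enum


class Bound(str, Enum):
    """Censoring direction attached to a reported value."""

    NONE = "none"
    GREATER_THAN = "greater_than"
    MUCH_GREATER_THAN = "much_greater_than"
    LESS_THAN = "less_than"


#: bounds that mean "the true value is at least this large"
_UPPER = (Bound.GREATER_THAN, Bound.MUCH_GREATER_THAN)


class CensoredArithmeticError(ValueError):
    """Raised when a ratio of censored values has no defined bound."""


@dataclass(frozen=True)
class CensoredValue:
    """A number that may be a censoring limit rather than an estimate.

    Parameters
    ----------
    value:
        The point estimate, or the censoring limit when ``bound`` is set.
    bound:
        Direction of censoring; ``Bound.NONE`` for a point estimate.
        ``MUCH_GREATER_THAN`` (rendered ``>>``) is arithmetically
        identical to ``GREATER_THAN`` and differs only in display.
    units:
        Free-text unit label carried along for display and sanity checks.
    """

    value: float
    bound: Bound = Bound.NONE
    units: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError(f"censored value must be finite, got {self.value!r}")

    # -- predicates ---------------------------------------------------

    @property
    def is_censored(self) -> bool:
        return self.bound is not Bound.NONE

    @property
    def is_censored_above(self) -> bool:
        """True for '>' / '>>' values (true value exceeds the limit)."""
        return self.bound in _UPPER

    @property
    def is_censored_below(self) -> bool:
        return self.bound is Bound.LESS_THAN

    # -- arithmetic ---------------------------------------------------

    def divide(self, other: "CensoredValue", units: str = "") -> "CensoredValue":
        """Ratio ``self / other`` with bound propagation.

        Rules (numerator = self, denominator = other):

        * point / point            -> point
        * '>' num / point den      -> '>' ratio
        * '<' num / point den      -> '<' ratio
        * point num / '>' den      -> '<' ratio
        * point num / '<' den      -> '>' ratio
        * both censored            -> defined only when the directions
          reinforce (e.g. '>' num with '<' den gives '>'); opposing
          directions are indeterminate and raise.
        """
        if other.value == 0:
            raise ZeroDivisionError("denominator censoring limit is zero")
        ratio = self.value / other.value

        num_up = self.is_censored_above
        num_lo = self.is_censored_below
        den_up = other.is_censored_above
        den_lo = other.is_censored_below

        lower = num_up or den_lo   # pushes the ratio up
        upper = num_lo or den_up   # pushes the ratio down
        if lower and upper:
            raise CensoredArithmeticError(
                f"ratio of {self} / {other} has no defined bound"
            )
        if lower:
            bound = Bound.GREATER_THAN
        elif upper:
            bound = Bound.LESS_THAN
        else:
            bound = Bound.NONE
        return CensoredValue(ratio, bound, units)

    def scaled(self, factor: float) -> "CensoredValue":
        """Multiply by a positive constant (unit conversions)."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return replace(self, value=self.value * factor)

    # -- display ------------------------------------------------------

    _GLYPH = {
        Bound.NONE: "",
        Bound.GREATER_THAN: ">",
        Bound.MUCH_GREATER_THAN: ">>",
        Bound.LESS_THAN: "<",
    }

    def __str__(self) -> str:
        glyph = self._GLYPH[self.bound]
        txt = f"{glyph}{self.value:g}"
        return f"{txt} {self.units}".strip()


_CENSOR_RE = re.compile(r"^\s*(>>|>|<|≫)?\s*([-+0-9.eE]+)\s*$")

_BOUND_FOR_GLYPH = {
    None: Bound.NONE,
    "": Bound.NONE,
    ">": Bound.GREATER_THAN,
    ">>": Bound.MUCH_GREATER_THAN,
    "≫": Bound.MUCH_GREATER_THAN,  # '≫'
    "<": Bound.LESS_THAN,
}


def parse_censored(text: str | float | int, units: str = "") -> CensoredValue:
    """Parse a table entry like ``">50"``, ``">>50"``, ``"<1"`` or ``"0.47"``.

    Plain numbers (including ``float``/``int`` inputs) give uncensored
    values.  Raises ``ValueError`` on anything else.
    """
    if isinstance(text, (int, float)):
        return CensoredValue(float(text), Bound.NONE, units)
    m = _CENSOR_RE.match(text)
    if m is None:
        raise ValueError(f"cannot parse censored value from {text!r}")
    glyph, num = m.groups()
    return CensoredValue(float(num), _BOUND_FOR_GLYPH[glyph], units)
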