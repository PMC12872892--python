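"""Element identities and per-element concentration panels.

The analysis tracks ten measured essential elements (five macro, five
micro).  Supply-only elements such as Mo may appear in fertigation recipes
but are excluded from uptake and deviation analysis.  A "panel" is a plain
mapping ``{element symbol -> concentration}``; helper functions validate
membership and sign rather than wrapping the mapping in a custom container.
"""

from __future__ import annotations

import math
from collections.abc import Mapping

from .errors import InvalidInputError

MACRO_ELEMENTS: tuple[str, ...] = ("N", "P", "K", "Ca", "Mg")
MICRO_ELEMENTS: tuple[str, ...] = ("Fe", "Mn", "B", "Cu", "Zn")
#: Elements quantified in both solution and tissue; the analysis set.
MEASURED_ELEMENTS: tuple[str, ...] = MACRO_ELEMENTS + MICRO_ELEMENTS
#: Elements present in supply recipes but never assayed in uptake analysis.
SUPPLY_ONLY_ELEMENTS: tuple[str, ...] = ("Mo",)
KNOWN_ELEMENTS: tuple[str, ...] = MEASURED_ELEMENTS + SUPPLY_ONLY_ELEMENTS

#: Plant organs recognised in tissue profiles.
ORGANS: tuple[str, ...] = ("leaf", "stem", "root", "flower")

#: Prediction sources for solution input concentrations.
PREDICTION_SOURCES: tuple[str, ...] = ("leaf", "stem", "root", "weighted")


def is_measured(symbol: str) -> bool:
    """True if ``symbol`` belongs to the measured (analysed) element set."""
    return symbol in MEASURED_ELEMENTS


def validate_panel(
    panel: Mapping[str, float],
    *,
    context: str = "panel",
    allow_supply_only: bool = True,
    nonnegative: bool = True,
) -> dict[str, float]:
    """Validate an element->concentration mapping and return a plain dict.

    Raises :class:`InvalidInputError` for unknown symbols, non-finite or
    (optionally) negative values.
    """
    out: dict[str, float] = {}
    for symbol, raw in panel.items():
        if symbol not in KNOWN_ELEMENTS or (
            not allow_supply_only and symbol in SUPPLY_ONLY_ELEMENTS
        ):
            raise InvalidInputError(f"{context}: unknown element symbol {symbol!r}")
        value = float(raw)
        if not math.isfinite(value):
            raise InvalidInputError(f"{context}: non-finite value for {symbol}")
        if nonnegative and value < 0:
            raise InvalidInputError(
                f"{context}: negative concentration {value} for {symbol}"
            )
        out[symbol] = value
    return out
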