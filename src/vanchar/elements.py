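"""Standard atomic weights.

One fixed table of IUPAC-style standard atomic weights (abridged values)
ships with the package as ``data/atomic_weights.csv`` so that two-decimal
masses and percentages are reproducible across installations regardless of
any other chemistry library present.
"""

from __future__ import annotations

import csv
from functools import lru_cache
from importlib import resources


class UnknownElementError(ValueError):
    """Raised when a symbol is not in the atomic-weight table."""


@lru_cache(maxsize=1)
def atomic_weights() -> dict[str, float]:
    """Return the symbol -> standard atomic weight (g/mol) table."""
    ref = resources.files("vanchar.data").joinpath("atomic_weights.csv")
    with ref.open("r", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        return {row["symbol"]: float(row["atomic_weight"]) for row in reader}


def atomic_weight(symbol: str) -> float:
    """Standard atomic weight of ``symbol`` in g/mol."""
    try:
        return atomic_weights()[symbol]
    except KeyError:
        raise UnknownElementError(f"unknown element symbol: {symbol!r}") from None


def is_element(symbol: str) -> bool:
    return symbol in atomic_weights()
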