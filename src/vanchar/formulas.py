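"""Molecular-formula arithmetic for elemental analysis and mass-loss assignment.

Empirical formulas of metal complexes are written in a loose dialect:
``C42H52Cl2N4O9V``, ``[VO(SO4)(CBZ)] 8H2O`` (hydrate segment with a leading
integer multiplicity), sometimes with typographic subscript underscores
(``C_42_H_52_...``).  :func:`parse_formula` accepts that dialect, and the
remaining operations provide the mass arithmetic behind calculated
elemental compositions and thermogravimetric mass-loss assignment:
percent composition, fragment mass-loss percentages, and a bounded
enumeration that suggests fragments matching an observed loss.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Optional, Sequence

from ._rounding import round_half_away
from .elements import atomic_weight, is_element

__all__ = [
    "FormulaError",
    "MolecularFormula",
    "CompoundRecord",
    "CompositionReport",
    "parse_formula",
    "molar_mass",
    "percent_composition",
    "mass_loss_percent",
    "suggest_fragments",
]


class FormulaError(ValueError):
    """Raised for malformed or chemically impossible formula input."""


# Characters stripped or normalized before tokenization: subscript
# underscores and typographic hydrate dots.
_DOT_CHARS = "·⋅∙*"
_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """An empirical formula: element counts plus an integer multiplicity.

    ``multiplicity`` covers hydrate/adduct multiples such as the ``8`` in
    ``8H2O``; the composition of the formula is the ``multiplicity``-fold
    expansion of ``element_counts``.
    """

    element_counts: Mapping[str, int]
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if not self.element_counts:
            raise FormulaError("formula has no elements")
        if self.multiplicity < 1:
            raise FormulaError(f"multiplicity must be >= 1, got {self.multiplicity}")
        for symbol, count in self.element_counts.items():
            if not is_element(symbol):
                raise FormulaError(f"unknown element symbol: {symbol!r}")
            if count < 1:
                raise FormulaError(f"count for {symbol} must be >= 1, got {count}")
        object.__setattr__(self, "element_counts", dict(self.element_counts))

    @property
    def composition(self) -> dict[str, int]:
        """Expanded element counts (multiplicity folded in)."""
        return {el: n * self.multiplicity for el, n in self.element_counts.items()}

    @property
    def n_atoms(self) -> int:
        return sum(self.composition.values())

    def __str__(self) -> str:
        prefix = "" if self.multiplicity == 1 else str(self.multiplicity)
        return prefix + _hill_string(self.element_counts)

    def expand(self) -> "MolecularFormula":
        """Equivalent formula with multiplicity folded into the counts."""
        return MolecularFormula(self.composition, 1)


def _hill_string(counts: Mapping[str, int]) -> str:
    """Hill convention: C then H then alphabetical (alphabetical if no C)."""
    symbols = sorted(counts)
    if "C" in counts:
        symbols = ["C"] + (["H"] if "H" in counts else []) + [
            s for s in symbols if s not in ("C", "H")
        ]
    return "".join(f"{s}{counts[s] if counts[s] != 1 else ''}" for s in symbols)


@dataclass
class CompoundRecord:
    """A row of a compound table: identifier, formula and role."""

    identifier: str
    formula: MolecularFormula
    role: str  # ligand | complex | fragment
    nominal_mass: Optional[float] = None

    _ROLES = ("ligand", "complex", "fragment")

    def __post_init__(self) -> None:
        if self.role not in self._ROLES:
            raise ValueError(f"role must be one of {self._ROLES}, got {self.role!r}")
        if self.nominal_mass is not None and not self.nominal_mass > 0:
            raise ValueError(f"nominal_mass must be > 0, got {self.nominal_mass}")

    def mass_deviation(self) -> Optional[float]:
        """Recomputed molar mass minus the user-supplied nominal mass."""
        if self.nominal_mass is None:
            return None
        return molar_mass(self.formula) - self.nominal_mass


@dataclass
class CompositionReport:
    """Percent-by-mass composition of a formula.

    ``percent_by_element`` carries full-precision values; use
    :meth:`rounded` for the conventional two-decimal report.
    """

    percent_by_element: dict[str, float]
    mass: float
    elements_requested: Optional[tuple[str, ...]] = None

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        return {
            el: round_half_away(pct, ndigits)
            for el, pct in self.percent_by_element.items()
        }

    def to_dict(self) -> dict:
        return {
            "mass_g_per_mol": round_half_away(self.mass, 2),
            "percent_by_element": self.rounded(),
        }


def _parse_segment(text: str) -> tuple[dict[str, int], int]:
    """Parse one dot/space-separated segment into (counts, multiplicity)."""
    m = re.match(r"(\d+)(.*)", text)
    multiplicity = 1
    if m and m.group(2):
        multiplicity = int(m.group(1))
        text = m.group(2)
    counts: dict[str, int] = {}
    _parse_group(text, counts, 1)
    return counts, multiplicity


def _parse_group(text: str, counts: dict[str, int], outer: int) -> None:
    """Parse element tokens and (possibly nested) bracketed groups."""
    pos = 0
    openers, closers = "([{", ")]}"
    while pos < len(text):
        ch = text[pos]
        if ch in openers:
            depth, end = 1, pos + 1
            while end < len(text) and depth:
                if text[end] in openers:
                    depth += 1
                elif text[end] in closers:
                    depth -= 1
                end += 1
            if depth:
                raise FormulaError(f"unbalanced bracket in {text!r}")
            inner = text[pos + 1 : end - 1]
            mult_match = re.match(r"\d+", text[end:])
            mult = int(mult_match.group()) if mult_match else 1
            _parse_group(inner, counts, outer * mult)
            pos = end + (mult_match.end() if mult_match else 0)
            continue
        m = _TOKEN_RE.match(text, pos)
        if not m or not m.group(1):
            raise FormulaError(f"cannot parse formula at {text[pos:]!r}")
        symbol, digits = m.groups()
        if not is_element(symbol):
            raise FormulaError(f"unknown element symbol: {symbol!r}")
        if digits == "0" or (digits and int(digits) == 0):
            raise FormulaError(f"zero count for element {symbol!r}")
        counts[symbol] = counts.get(symbol, 0) + outer * (int(digits) if digits else 1)
        pos = m.end()


def parse_formula(text: str) -> MolecularFormula:
    """Parse a formula string into a :class:`MolecularFormula`.

    Accepts Hill-style strings (``C42H52Cl2N4O9V``), bracketed complex
    notation, subscript underscores (``C_42_H_52_``), and hydrate segments
    separated by a centered dot or whitespace with an optional leading
    integer multiplicity (``CuSO4 5H2O``, ``2H2O``).  A single-segment
    string keeps its leading integer as the formula multiplicity; a
    multi-segment string is combined into one expanded composition.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    cleaned = text.replace("_", "")
    for ch in _DOT_CHARS:
        cleaned = cleaned.replace(ch, " ")
    segments = cleaned.split()
    if not segments:
        raise FormulaError("empty formula string")
    if len(segments) == 1:
        counts, multiplicity = _parse_segment(segments[0])
        return MolecularFormula(counts, multiplicity)
    total: dict[str, int] = {}
    for seg in segments:
        counts, multiplicity = _parse_segment(seg)
        for el, n in counts.items():
            total[el] = total.get(el, 0) + n * multiplicity
    return MolecularFormula(total, 1)


def molar_mass(f: MolecularFormula) -> float:
    """Molar mass in g/mol from the fixed standard-atomic-weight table."""
    return sum(atomic_weight(el) * n for el, n in f.composition.items())


def percent_composition(
    f: MolecularFormula, elements: Optional[Iterable[str]] = None
) -> CompositionReport:
    """Percent by mass per element.

    When ``elements`` restricts the report, the full molar mass is still the
    denominator and elements absent from the formula report as 0.0.
    """
    total = molar_mass(f)
    comp = f.composition
    if elements is None:
        selected: Sequence[str] = sorted(comp)
        requested = None
    else:
        selected = list(elements)
        requested = tuple(selected)
        for el in selected:
            if not is_element(el):
                raise FormulaError(f"unknown element symbol: {el!r}")
    percents = {
        el: 100.0 * atomic_weight(el) * comp.get(el, 0) / total for el in selected
    }
    return CompositionReport(percents, total, requested)


def _sub_multiset_excess(
    fragment: Mapping[str, int], parent: Mapping[str, int]
) -> list[str]:
    return [el for el, n in fragment.items() if n > parent.get(el, 0)]


def mass_loss_percent(fragment: MolecularFormula, parent: MolecularFormula) -> float:
    """Mass of ``fragment`` as a percentage of the parent's molar mass."""
    excess = _sub_multiset_excess(fragment.composition, parent.composition)
    if excess:
        raise FormulaError(
            "fragment is not contained in parent; exceeded elements: "
            + ", ".join(sorted(excess))
        )
    return 100.0 * molar_mass(fragment) / molar_mass(parent)


@dataclass
class FragmentCandidate:
    formula: MolecularFormula
    percent: float
    deviation: float


def suggest_fragments(
    parent: MolecularFormula,
    target_percent: float,
    tolerance: float,
    element_pool: Optional[Iterable[str]] = None,
    max_atoms: int = 12,
) -> list[FragmentCandidate]:
    """Enumerate sub-multisets of ``parent`` matching a target mass loss.

    Exhaustive bounded enumeration over all fragments drawn from
    ``element_pool`` (default: every element of the parent) with at most
    ``max_atoms`` atoms; candidates whose mass-loss percentage lies within
    ``tolerance`` of ``target_percent`` are returned sorted by absolute
    deviation, ties broken by fewer atoms then by formula string.
    """
    if not 0 < target_percent <= 100:
        raise ValueError(f"target_percent must be in (0, 100], got {target_percent}")
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    if max_atoms < 1:
        raise ValueError("max_atoms must be >= 1")
    comp = parent.composition
    pool = sorted(comp if element_pool is None else set(element_pool) & set(comp))
    parent_mass = molar_mass(parent)
    results: list[FragmentCandidate] = []
    ranges = [range(0, min(comp[el], max_atoms) + 1) for el in pool]
    for combo in product(*ranges):
        n_total = sum(combo)
        if n_total == 0 or n_total > max_atoms:
            continue
        counts = {el: n for el, n in zip(pool, combo) if n}
        pct = 100.0 * sum(atomic_weight(el) * n for el, n in counts.items()) / parent_mass
        dev = pct - target_percent
        # small epsilon so tolerance 0 still accepts exact-mass matches
        if abs(dev) <= tolerance + 1e-9:
            results.append(FragmentCandidate(MolecularFormula(counts), pct, dev))
    results.sort(key=lambda c: (abs(c.deviation), c.formula.n_atoms, str(c.formula)))
    return results
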