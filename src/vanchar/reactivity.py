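"""Conceptual-DFT global reactivity descriptors and the V=O bond correlation.

From a frontier-orbital pair (E_HOMO, E_LUMO, both in eV) the standard
global descriptors follow:

    gap        ΔE = E_LUMO − E_HOMO
    electronegativity  χ = −(E_HOMO + E_LUMO)/2
    hardness   η = (E_LUMO − E_HOMO)/2
    potential  μ = −χ
    softness   S = 1/(2η)
    electrophilicity  ω = μ²/(2η)        (Parr)
    max charge transfer  ΔN_max = χ/η

The second half of the module is the empirical correlation between the
vanadyl V=O stretching frequency ν (cm⁻¹) and the V=O bond length R (Å),

    ν = 21349 · exp(−1.9176 · R),

which lets an IR band position stand in for a structural bond length.
Published descriptor tables are not always internally consistent with
their own orbital energies; :func:`consistency_report` recomputes every
derived column and flags deviating cells instead of reproducing them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd

from ._rounding import round_half_away
from .constants import VO_CORR_DECAY, VO_CORR_PREFACTOR

__all__ = [
    "DegenerateGapError",
    "FrontierOrbitals",
    "ReactivityProfile",
    "VOBond",
    "descriptors_from_orbitals",
    "bond_length_from_frequency",
    "frequency_from_bond_length",
    "consistency_report",
]


class DegenerateGapError(ValueError):
    """Raised when E_HOMO >= E_LUMO (hardness would be non-positive)."""


@dataclass(frozen=True)
class FrontierOrbitals:
    """A HOMO/LUMO energy pair in eV."""

    e_homo: float
    e_lumo: float

    @property
    def degenerate(self) -> bool:
        return not self.e_homo < self.e_lumo


@dataclass(frozen=True)
class ReactivityProfile:
    """Global reactivity descriptors derived from one orbital pair (eV)."""

    e_homo: float
    e_lumo: float
    delta_e: float
    chi: float
    eta: float
    mu: float
    softness_s: float
    omega: float
    dn_max: float

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        return {
            name: round_half_away(getattr(self, name), ndigits)
            for name in (
                "e_homo", "e_lumo", "delta_e", "chi", "eta",
                "mu", "softness_s", "omega", "dn_max",
            )
        }


@dataclass(frozen=True)
class VOBond:
    """A vanadyl bond characterized by stretch frequency and length."""

    frequency: float  # cm^-1
    length: float     # Angstrom

    @classmethod
    def from_frequency(cls, nu: float) -> "VOBond":
        return cls(nu, bond_length_from_frequency(nu))

    @classmethod
    def from_length(cls, r: float) -> "VOBond":
        return cls(frequency_from_bond_length(r), r)


def descriptors_from_orbitals(orb: FrontierOrbitals) -> ReactivityProfile:
    """Compute the seven global descriptors from a HOMO/LUMO pair."""
    if orb.degenerate:
        raise DegenerateGapError(
            f"E_HOMO ({orb.e_homo}) must lie below E_LUMO ({orb.e_lumo}); "
            "hardness would be non-positive"
        )
    delta_e = orb.e_lumo - orb.e_homo
    chi = -(orb.e_homo + orb.e_lumo) / 2.0
    eta = delta_e / 2.0
    mu = -chi
    return ReactivityProfile(
        e_homo=orb.e_homo,
        e_lumo=orb.e_lumo,
        delta_e=delta_e,
        chi=chi,
        eta=eta,
        mu=mu,
        softness_s=1.0 / (2.0 * eta),
        omega=mu * mu / (2.0 * eta),
        dn_max=chi / eta,
    )


def bond_length_from_frequency(nu: float) -> float:
    """V=O bond length (Å) from the stretch frequency (cm⁻¹).

    Strictly decreasing in ν; only 0 < ν < 21349 maps to a positive length.
    """
    if not 0 < nu < VO_CORR_PREFACTOR:
        raise ValueError(
            f"frequency must be in (0, {VO_CORR_PREFACTOR:g}) cm^-1, got {nu}"
        )
    return math.log(VO_CORR_PREFACTOR / nu) / VO_CORR_DECAY


def frequency_from_bond_length(r: float) -> float:
    """V=O stretch frequency (cm⁻¹) from the bond length (Å)."""
    if not r > 0:
        raise ValueError(f"bond length must be > 0 Angstrom, got {r}")
    return VO_CORR_PREFACTOR * math.exp(-VO_CORR_DECAY * r)


# Printed-table column -> how to recompute it from a ReactivityProfile.
_CHECKABLE = {
    "delta_e": lambda p: p.delta_e,
    "chi": lambda p: p.chi,
    "eta": lambda p: p.eta,
    "mu": lambda p: p.mu,
    "softness_s": lambda p: p.softness_s,
    "omega": lambda p: p.omega,
    "dn_max": lambda p: p.dn_max,
}


def consistency_report(
    entries: Iterable[tuple[str, FrontierOrbitals, Mapping[str, float]]],
    tol: float = 0.01,
) -> pd.DataFrame:
    """Recompute printed descriptor columns and flag inconsistent cells.

    ``entries`` yields ``(identifier, orbitals, printed)`` where ``printed``
    maps descriptor names (keys of the profile fields) to the published
    values.  Each printed cell is compared with the value recomputed from
    the orbital energies; cells deviating by more than ``tol`` (after
    allowing for the table's own rounding) are flagged ``consistent=False``.

    Returns a tidy frame with columns ``id, quantity, printed, recomputed,
    deviation, consistent``.
    """
    rows = []
    for ident, orb, printed in entries:
        profile = descriptors_from_orbitals(orb)
        for name, value in printed.items():
            if name not in _CHECKABLE:
                raise KeyError(f"unknown descriptor column {name!r}")
            recomputed = _CHECKABLE[name](profile)
            deviation = recomputed - value
            rows.append(
                {
                    "id": ident,
                    "quantity": name,
                    "printed": value,
                    "recomputed": recomputed,
                    "deviation": deviation,
                    "consistent": abs(deviation) <= tol + 1e-12,
                }
            )
    return pd.DataFrame(rows)
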