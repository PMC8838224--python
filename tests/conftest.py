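"""Shared fixtures: published descriptor-table rows and formula anchors."""

import pytest

from vanchar import FrontierOrbitals, parse_formula

# Published frontier energies (eV) and derived-descriptor columns for the
# four ligands and their oxidovanadium(IV) complexes.  Several printed
# cells are internally inconsistent with the energies in the same row;
# the consistency checker is expected to flag those, not reproduce them.
TABLE7 = [
    # id, HOMO, LUMO, ΔE, χ, η, S, ω, ΔN_max
    ("CBZ", -5.55, -1.00, 4.55, 3.28, 2.28, 1.14, 2.36, 1.44),
    ("VO-CBZ", -7.09, -3.27, 3.83, 5.18, 1.91, 0.96, 2.59, 2.71),
    ("SCZ", -6.75, -2.78, 3.97, 4.77, 1.99, 0.99, 2.38, 2.40),
    ("VO-SCZ", -7.41, -3.64, 3.77, 5.53, 1.89, 0.94, 2.76, 2.93),
    ("LOR", -3.96, -1.99, 1.97, 2.98, 0.98, 0.49, 1.49, 3.03),
    ("VO-LOR", -3.93, -2.74, 1.19, 3.34, 0.59, 0.30, 1.67, 5.62),
    ("CTZ", -6.59, -4.68, 1.91, 5.64, 0.95, 0.48, 2.82, 5.91),
    ("VO-CTZ", -10.26, -8.84, 1.42, 10.05, 1.21, 0.61, 5.03, 8.31),
]

# Experimental nu(V=O) (cm^-1) vs the bond length (Å) the correlation yields.
VO_BANDS = [
    ("VO-CBZ", 980.0, 1.607),
    ("VO-CTZ", 963.0, 1.616),
    ("VO-LOR", 968.0, 1.613),
    ("VO-SCZ", 987.0, 1.603),
]


@pytest.fixture(scope="session")
def table7_entries():
    """(id, orbitals, printed-descriptor dict) triples for consistency checks."""
    return [
        (
            ident,
            FrontierOrbitals(homo, lumo),
            {
                "delta_e": de,
                "chi": chi,
                "eta": eta,
                "softness_s": s,
                "omega": omega,
                "dn_max": dn,
            },
        )
        for ident, homo, lumo, de, chi, eta, s, omega, dn in TABLE7
    ]


@pytest.fixture(scope="session")
def ctz_complex():
    """Empirical formula of the bis-cetirizine vanadyl complex dihydrate."""
    return parse_formula("C42H52Cl2N4O9V")
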