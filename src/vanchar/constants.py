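"""Physical constants and fixed empirical parameters.

All physical constants are CODATA values taken from :mod:`scipy.constants`
so that every module in the package computes against a single table.
"""

from scipy import constants as _c

#: Molar gas constant, J mol^-1 K^-1.
R_GAS = _c.R

#: Planck constant, J s.
PLANCK_H = _c.h

#: Boltzmann constant, J K^-1.
BOLTZMANN_K = _c.k

#: Pre-factor of the empirical nu(V=O) <-> bond-length correlation, cm^-1.
#: nu = VO_CORR_PREFACTOR * exp(-VO_CORR_DECAY * R[Angstrom])
VO_CORR_PREFACTOR = 21349.0

#: Exponential decay constant of the correlation, 1/Angstrom.
VO_CORR_DECAY = 1.9176
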