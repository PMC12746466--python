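"""Physical constants in spectroscopic units.

All energies in this package are carried as wavenumbers (cm^-1); Planck's
constant never appears explicitly.
"""

#: Boltzmann constant in cm^-1 per kelvin (k_B / hc).
KB_CM1_PER_K = 0.695034800

#: Speed of light in cm per femtosecond; converts a wavenumber to a linear
#: frequency per fs (nu[cm^-1] * C_CM_PER_FS -> cycles/fs).
C_CM_PER_FS = 2.99792458e-5

#: 1 eV in cm^-1 (convenience for energy-window defaults).
EV_CM1 = 8065.543937

#: Harmonic mode energy E[cm^-1] = MW_ENERGY_CM1 * nu^2 * q^2 for a
#: mass-weighted displacement q in sqrt(amu)*Angstrom along a mode of
#: wavenumber nu[cm^-1]:  2 pi^2 c nu^2 q^2 * (amu Ang^2) / h.
MW_ENERGY_CM1 = 0.0148302
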