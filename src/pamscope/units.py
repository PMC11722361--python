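"""Unit conventions and physical constants.

Internal units follow the GROMACS-style consistent system:

==========  ==========================
length      nm
energy      kJ/mol
mass        amu
time        ps
temperature K
charge      elementary charge (e)
==========  ==========================

In this system 1 kJ/mol == 1 amu * nm^2 / ps^2, so angular frequencies
obtained from energies and mass-weighted covariances come out directly in
1/ps.  Angstrom and kcal/mol appear only at user-facing boundaries.
"""

from __future__ import annotations

#: Boltzmann constant, kJ/mol/K.
KB = 0.0083144621

#: Reduced Planck constant, kJ/mol * ps.
#: hbar = 1.054571817e-34 J*s * N_A / 1000 * 1e12 ps/s
HBAR = 1.054571817e-34 * 6.02214076e23 * 1e12 / 1000.0

#: Molar gas constant, J/mol/K (entropies are conventionally reported in J).
R_GAS = 8.3144621

#: Coulomb prefactor 1/(4 pi eps0), kJ/mol * nm / e^2.
COULOMB_CONSTANT = 138.935458

#: kcal <-> kJ.
KCAL_TO_KJ = 4.184
KJ_TO_KCAL = 1.0 / KCAL_TO_KJ

#: Angstrom <-> nm.
ANGSTROM_TO_NM = 0.1
NM_TO_ANGSTROM = 10.0


def kT(temperature: float) -> float:
    """Thermal energy kB*T in kJ/mol for a temperature in K."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB * temperature
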