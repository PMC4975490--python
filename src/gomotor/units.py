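"""Unit conventions and physical constants.

Internally everything runs in reduced units:

* length — nm (PDB Angstrom are divided by 10 on read),
* energy — units of the native-contact depth ``eps_h`` (with the default
  ``eps_h`` = 1 kcal/mol, reduced and kcal/mol values coincide),
* mass — one per bead,
* time — the "internal" unit t* = nm * sqrt(m / eps_h).  The Langevin time
  unit quoted in configs is tau_L = sqrt(m sigma^2 / eps_h) = sigma * t*
  (numerically 0.4 t* for the default sigma = 0.4 nm).

External strain forces are quoted in kJ mol^-1 nm^-1 and converted to
reduced (eps_h/nm) units in exactly one place, :func:`force_kj_to_reduced`.
"""

from __future__ import annotations

#: Boltzmann constant, kcal / (mol K)
KB_KCAL = 0.0019872041

#: kcal per kJ
KCAL_PER_KJ = 1.0 / 4.184

#: repulsion length sigma, nm (also sets tau_L)
SIGMA_NM = 0.4

#: Angstrom -> nm
NM_PER_ANGSTROM = 0.1


def reduced_temperature(T_kelvin: float, eps_h_kcal: float = 1.0) -> float:
    """k_B T in units of eps_h."""
    return KB_KCAL * T_kelvin / eps_h_kcal


def tau_L(mass: float = 1.0, sigma_nm: float = SIGMA_NM, eps_h: float = 1.0) -> float:
    """Langevin time unit sqrt(m sigma^2 / eps_h), in internal time units."""
    return sigma_nm * (mass / eps_h) ** 0.5


def force_kj_to_reduced(f_kj_mol_nm: float, eps_h_kcal: float = 1.0) -> float:
    """Convert a force in kJ mol^-1 nm^-1 to eps_h nm^-1."""
    return f_kj_mol_nm * KCAL_PER_KJ / eps_h_kcal
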