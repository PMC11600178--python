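"""Unit system and physical constants.

The toolkit works throughout in "real" coarse-grained MD units:

===========  =========================
length       angstrom (Å)
energy       kcal/mol
mass         g/mol
temperature  kelvin (K)
time         nanosecond (ns)
===========  =========================

Because (Å, kcal/mol, g/mol) do not form a self-consistent mechanical
unit system with the nanosecond, every dynamical formula that mixes
kinetic and potential energy carries an explicit mass conversion:
masses are converted to ``kcal·ns²/(mol·Å²)`` (see :data:`MASS_TO_ENERGY`),
after which all expressions are dimensionally consistent in
(Å, ns, kcal/mol).  Moduli come out in kcal/(mol·Å³) and viscosities in
kcal·ns/(mol·Å³); :func:`modulus_to_pa` converts to SI-like units.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Boltzmann constant, kcal/(mol K).
KB = 1.987204259e-3

#: J per kcal (thermochemical calorie).
_J_PER_KCAL = 4184.0

#: Avogadro constant, 1/mol.
NA = 6.02214076e23

#: 1 (g/mol)(Å/ns)^2 expressed in kcal/mol.  Equivalently the factor
#: converting a mass in g/mol to kcal·ns²/(mol·Å²).
MASS_TO_ENERGY = 1e-5 / _J_PER_KCAL  # = 2.390057...e-9


def intrinsic_time_fs(length_A: float = 1.0, mass_gmol: float = 1.0,
                      energy_kcalmol: float = 1.0) -> float:
    """Intrinsic MD time unit ``L·sqrt(m/E)`` in femtoseconds.

    For the default real units (1 Å, 1 g/mol, 1 kcal/mol) this evaluates
    to 48.89 fs.
    """
    length_m = length_A * 1e-10
    mass_kg = mass_gmol * 1e-3
    energy_j = energy_kcalmol * _J_PER_KCAL
    return length_m * (mass_kg / energy_j) ** 0.5 * 1e15


@dataclass(frozen=True)
class UnitSystem:
    """Fixed real-unit system used by every module in the package."""

    length: str = "angstrom"
    energy: str = "kcal/mol"
    mass: str = "g/mol"
    temperature: str = "K"
    kB: float = KB

    @property
    def derived_time_fs(self) -> float:
        """One intrinsic time unit, in fs (≈48.89 fs for real units)."""
        return intrinsic_time_fs()


REAL_UNITS = UnitSystem()


def modulus_to_pa(g_kcal_mol_A3: float) -> float:
    """Convert a modulus from kcal/(mol·Å³) to pascal."""
    return g_kcal_mol_A3 * _J_PER_KCAL / NA / 1e-30


def viscosity_to_pa_s(eta_kcal_ns_mol_A3: float) -> float:
    """Convert a viscosity from kcal·ns/(mol·Å³) to Pa·s."""
    return modulus_to_pa(eta_kcal_ns_mol_A3) * 1e-9
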