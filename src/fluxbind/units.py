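"""Units and physical constants.

Working units throughout the package: length nm, time ps, mass amu (g/mol),
energy kcal/mol, charge in elementary charges, temperature K.  The "internal"
dynamical energy unit implied by (amu, nm, ps) is kJ/mol: 1 amu nm^2/ps^2 =
1 kJ/mol exactly, so kcal/mol quantities are scaled by 4.184 before they enter
the equations of motion.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import InvalidInputError

#: Boltzmann constant, kcal/(mol K).
KB_KCAL: float = 0.0019872041

#: kcal -> internal (amu nm^2/ps^2 == kJ/mol) conversion.
KCAL_TO_INTERNAL: float = 4.184

#: Boltzmann constant in internal units, kJ/(mol K).
KB_INTERNAL: float = KB_KCAL * KCAL_TO_INTERNAL

#: Avogadro's number, 1/mol (2019 SI exact value).
AVOGADRO: float = 6.02214076e23

#: Coulomb constant in vacuum, kcal nm/(mol e^2).  332.0637 kcal A/(mol e^2) / 10.
COULOMB_KCAL_NM: float = 33.20637

#: Vacuum permittivity, F/m.
EPSILON_0: float = 8.8541878128e-12

#: Volume per molecule at the 1 mol/L reference concentration, nm^3.
#: 1 L = 1e24 nm^3, so 1e24 / N_A = 1.66054 nm^3 per molecule.
NM3_PER_MOLECULE_AT_1M: float = 1.0e24 / AVOGADRO

#: ps^-1 -> s^-1.
PS_TO_S_RATE: float = 1.0e12


@dataclass(frozen=True)
class UnitsContext:
    """Thermodynamic context: temperature, Boltzmann constant and the
    standard-state reference concentration C0 (mol/L, default 1)."""

    temperature: float = 300.0
    k_B: float = KB_KCAL
    C0: float = 1.0

    def __post_init__(self) -> None:
        if not (self.temperature > 0):
            raise InvalidInputError(f"temperature must be > 0 K, got {self.temperature}")
        if not (self.C0 > 0):
            raise InvalidInputError(f"C0 must be > 0 mol/L, got {self.C0}")

    @property
    def kT(self) -> float:
        """Thermal energy k_B*T in kcal/mol."""
        return self.k_B * self.temperature

    @property
    def beta(self) -> float:
        """Inverse thermal energy 1/(k_B*T) in mol/kcal."""
        return 1.0 / self.kT


def kT(units: UnitsContext) -> float:
    """Thermal energy k_B*T in kcal/mol."""
    return units.kT


def concentration_from_volume(v_box_nm3: float) -> float:
    """Concentration of a single molecule in a box of ``v_box_nm3`` nm^3, in mol/L.

    One molecule per 1.66054 nm^3 corresponds to 1 mol/L, so the
    single-ligand concentration is C = 1.66054 / V[nm^3]; an 80.2 nm^3 box
    gives 0.0207 M.
    """
    if not (v_box_nm3 > 0):
        raise InvalidInputError(f"box volume must be positive, got {v_box_nm3}")
    return NM3_PER_MOLECULE_AT_1M / v_box_nm3
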