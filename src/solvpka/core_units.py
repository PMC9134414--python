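"""Physical constants, energy-unit conversion, and gas-phase proton thermodynamics.

The internal canonical energy unit of the whole package is **eV per
particle**: every ingested energy is normalized to eV, and every pKa-scale
quantity is anchored by ``rt_ln10`` (one pKa unit ≡ R·T·ln10 ≈ 0.0592 eV at
298.15 K).

Constants are CODATA 2018. The SI-exact constants (R, N_A, k_B, h, e and
hence F) are exact by definition; the proton mass and the hartree carry the
CODATA uncertainty, quoted here to well beyond 10 significant digits.
"""

from __future__ import annotations

import math

__all__ = [
    "R",
    "N_A",
    "K_B",
    "H_PLANCK",
    "E_CHARGE",
    "F",
    "PROTON_MASS",
    "T_DEFAULT",
    "P_STANDARD",
    "C_STANDARD",
    "LN10",
    "EV_PER_HARTREE",
    "KCAL_MOL_PER_HARTREE",
    "KJ_MOL_PER_HARTREE",
    "SUPPORTED_UNITS",
    "normalize_unit",
    "convert_energy",
    "rt_ln10",
    "sackur_tetrode_entropy",
    "gas_phase_proton_free_energy",
    "standard_state_correction",
]

# --- CODATA 2018 ----------------------------------------------------------
R = 8.31446261815324  # gas constant, J mol^-1 K^-1 (exact)
N_A = 6.02214076e23  # Avogadro constant, mol^-1 (exact)
K_B = 1.380649e-23  # Boltzmann constant, J K^-1 (exact)
H_PLANCK = 6.62607015e-34  # Planck constant, J s (exact)
E_CHARGE = 1.602176634e-19  # elementary charge, C (exact)
F = N_A * E_CHARGE  # Faraday constant, C mol^-1 (= 96485.33212... exact)
PROTON_MASS = 1.67262192369e-27  # kg

T_DEFAULT = 298.15  # K; all operations default to standard temperature
P_STANDARD = 101325.0  # Pa (1 atm)
C_STANDARD = 1000.0  # mol m^-3 (1 mol/L)
LN10 = math.log(10.0)

# Energy of 1 hartree in the other supported units (CODATA 2018).
EV_PER_HARTREE = 27.211386245988
KCAL_MOL_PER_HARTREE = 627.5094740631
KJ_MOL_PER_HARTREE = 2625.4996394799

# value of one unit of each supported energy unit, expressed in hartree
_UNIT_IN_HARTREE = {
    "hartree": 1.0,
    "eV": 1.0 / EV_PER_HARTREE,
    "kcal/mol": 1.0 / KCAL_MOL_PER_HARTREE,
    "kJ/mol": 1.0 / KJ_MOL_PER_HARTREE,
}

_UNIT_ALIASES = {
    "hartree": "hartree",
    "hartrees": "hartree",
    "ha": "hartree",
    "eh": "hartree",
    "au": "hartree",
    "a.u.": "hartree",
    "ev": "eV",
    "kcal/mol": "kcal/mol",
    "kcal_mol": "kcal/mol",
    "kcalmol": "kcal/mol",
    "kj/mol": "kJ/mol",
    "kj_mol": "kJ/mol",
    "kjmol": "kJ/mol",
}

SUPPORTED_UNITS = ("hartree", "eV", "kcal/mol", "kJ/mol")


def normalize_unit(unit: str) -> str:
    """Return the canonical spelling of an energy unit name.

    Raises :class:`ValueError` naming the offending token for anything
    outside the supported set {hartree, eV, kcal/mol, kJ/mol}.
    """
    key = str(unit).strip().lower()
    try:
        return _UNIT_ALIASES[key]
    except KeyError:
        raise ValueError(
            f"unknown energy unit {unit!r}; supported units are "
            + ", ".join(SUPPORTED_UNITS)
        ) from None


def convert_energy(value, from_unit: str, to_unit: str):
    """Convert an energy (scalar or array) between supported units.

    Conversion is an exact linear scaling by CODATA factors; identical
    units return the input unchanged (bit-for-bit).
    """
    src = normalize_unit(from_unit)
    dst = normalize_unit(to_unit)
    if src == dst:
        return value
    return value * (_UNIT_IN_HARTREE[src] / _UNIT_IN_HARTREE[dst])


def rt_ln10(T: float = T_DEFAULT) -> float:
    """R·T·ln10 in eV per particle: the free-energy equivalent of one pKa unit.

    0.059159 eV at 298.15 K.
    """
    if not T > 0:
        raise ValueError(f"temperature must be positive, got {T} K")
    return R * T * LN10 / F


def sackur_tetrode_entropy(
    T: float = T_DEFAULT, p: float = P_STANDARD, mass: float = PROTON_MASS
) -> float:
    """Translational entropy of a structureless ideal-gas particle, J mol^-1 K^-1.

    S = R·[ (3/2)·ln(2π m k_B T / h²) + ln(k_B T / p) + 5/2 ].
    """
    if not T > 0:
        raise ValueError(f"temperature must be positive, got {T} K")
    if not p > 0:
        raise ValueError(f"pressure must be positive, got {p} Pa")
    lam = 2.0 * math.pi * mass * K_B * T / H_PLANCK**2  # 1/Λ² with Λ the thermal wavelength
    return R * (1.5 * math.log(lam) + math.log(K_B * T / p) + 2.5)


def gas_phase_proton_free_energy(
    T: float = T_DEFAULT, p: float = P_STANDARD
) -> float:
    """Gibbs free energy of a bare proton in the gas phase, eV per particle.

    G = H − T·S with H = (5/2)·R·T (translation + pV) and S from the
    Sackur–Tetrode equation. At 298.15 K and 1 atm this is −0.272 eV
    (−6.28 kcal/mol), the conventional 1 atm standard state; use
    :func:`standard_state_correction` to move to a 1 mol/L state — it is
    never applied implicitly.
    """
    S = sackur_tetrode_entropy(T, p, PROTON_MASS)
    G_molar = 2.5 * R * T - T * S  # J mol^-1
    return G_molar / F


def standard_state_correction(T: float = T_DEFAULT) -> float:
    """Free energy of compressing an ideal gas from 1 atm to 1 mol/L, in eV.

    R·T·ln(c°·R·T/p°) with c° = 1 mol/L, p° = 1 atm; +0.0821 eV at
    298.15 K. Opt-in: add it to a 1 atm gas-phase free energy to obtain the
    solution-phase (1 mol/L) standard state.
    """
    if not T > 0:
        raise ValueError(f"temperature must be positive, got {T} K")
    return R * T * math.log(C_STANDARD * R * T / P_STANDARD) / F
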