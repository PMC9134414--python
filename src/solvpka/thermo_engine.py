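"""Thermodynamic core: isodesmic pKa, effective proton energies, and the
computational-SHE machinery that transfers them between solvents.

The model
---------
The isodesmic (indirect) route predicts the pKa of an acid AH from a
balanced proton exchange with a reference acid BH of known pKa::

    AH + B-  ->  A- + BH
    pKa(AH) = pKa(BH) + dG_isodes / (R T ln10)

Because the reaction is balanced, systematic solvation-model errors cancel.
The same reference defines an *effective* total free energy of the solvated
proton,

    G_eff(H+) = G(BH) - G(B-) + R T ln10 * pKa_ref,

which turns the direct route, dG_diss = G(A-) + G_eff(H+) - G(AH), into an
exact algebraic equivalent of the isodesmic one.

To reach a solvent with no reliable reference, G_eff(H+) computed in water
is shifted by a conversion factor F*(E_abs(X) - E_abs(water)) built from
per-solvent absolute potentials of the standard hydrogen electrode; the
computational SHE anchor (1/2 H2 <-> H+ + e- at 0 V) interconverts
G_eff(H+) and E_abs. All sign conventions are centralized here: absolute
potentials are on the reduction convention (E_abs(SHE, water) ~ +4 V) and

    E_abs = (G_eff(H+) - 1/2 G(H2)) / F.

With energies in eV per particle, division by F is numerically a no-op
(1 eV per particle across 1 V), so potentials in volts and energies in eV
share magnitudes throughout.
"""

from __future__ import annotations

import math

from .core_units import P_STANDARD, T_DEFAULT, gas_phase_proton_free_energy, rt_ln10
from .data_io import EnergyTable, SolventTable
from .records import (
    GAS_MEDIUM,
    ConjugatePair,
    PkaPrediction,
    ProtonEnergies,
    SolventEntry,
    normalize_name,
)

__all__ = [
    "SolventEntry",
    "ProtonEnergies",
    "PkaPrediction",
    "deprotonation_energy",
    "isodesmic_pka",
    "effective_proton_energy_from_reference",
    "pcet_potential",
    "pcet_potential_for_pair",
    "abs_she_from_g_eff",
    "g_eff_from_abs_she",
    "conversion_factor",
    "solvent_conversion_factor",
    "proton_energy_in_solvent",
    "proton_energies_for_solvent",
    "direct_pka",
    "proton_solvation_energy",
]


def _as_energy(value, name: str) -> float:
    """Accept a float or an EnergyRecord-like object; return eV."""
    g = getattr(value, "g_total", value)
    g = float(g)
    if not math.isfinite(g):
        raise ValueError(f"{name} energy must be finite, got {g}")
    return g


def deprotonation_energy(g_acid, g_base) -> float:
    """G(base) − G(acid) in eV.

    Arguments may be plain energies (eV) or :class:`EnergyRecord` objects;
    when both are records their media must agree.
    """
    medium_a = getattr(g_acid, "medium", None)
    medium_b = getattr(g_base, "medium", None)
    if medium_a is not None and medium_b is not None:
        if normalize_name(medium_a) != normalize_name(medium_b):
            raise ValueError(
                f"acid and base are in different media: '{medium_a}' vs '{medium_b}'"
            )
    return _as_energy(g_base, "base") - _as_energy(g_acid, "acid")


def _lookup_species(
    energies: EnergyTable,
    solvent: str,
    species: list[str],
    method_tag: str | None,
) -> dict[str, float]:
    if normalize_name(solvent) == GAS_MEDIUM:
        raise ValueError(
            "pKa operations act in a solvent; the reserved 'gas' medium is "
            "not allowed here"
        )
    found: dict[str, float] = {}
    missing: list[str] = []
    for sid in species:
        try:
            found[sid] = energies.g(sid, solvent, method_tag)
        except KeyError:
            missing.append(sid)
    if missing:
        raise KeyError(
            f"missing energy record(s) in solvent '{solvent}' for species: "
            + ", ".join(missing)
        )
    return found


def isodesmic_pka(
    target: ConjugatePair,
    reference: ConjugatePair,
    pka_ref: float,
    energies: EnergyTable,
    solvent: str,
    T: float = T_DEFAULT,
    method_tag: str | None = None,
) -> PkaPrediction:
    """pKa of the target acid via proton exchange with an in-solvent reference.

    dG_isodes = [G(A−) + G(BH)] − [G(AH) + G(B−)];
    pKa = pKa_ref + dG_isodes / (R·T·ln10). All four species must be present
    in the given solvent.
    """
    g = _lookup_species(
        energies,
        solvent,
        [target.acid_id, target.base_id, reference.acid_id, reference.base_id],
        method_tag,
    )
    u = rt_ln10(T)
    dg_isodes = (g[target.base_id] + g[reference.acid_id]) - (
        g[target.acid_id] + g[reference.base_id]
    )
    dg_diss = dg_isodes + pka_ref * u
    return PkaPrediction(
        species_id=target.acid_id,
        solvent=solvent,
        pka_raw=dg_diss / u,
        dg_diss=dg_diss,
        reference_id=reference.acid_id,
        relation_used=None,
        temperature=T,
    )


def effective_proton_energy_from_reference(
    reference: ConjugatePair,
    pka_ref: float,
    energies: EnergyTable,
    solvent: str,
    T: float = T_DEFAULT,
    p: float = P_STANDARD,
    method_tag: str | None = None,
) -> ProtonEnergies:
    """Back-calculate G_eff(H+) in a solvent from a reference acid's pKa.

    G_eff(H+) = G(BH) − G(B−) + R·T·ln10·pKa_ref. The companion solvation
    free energy subtracts the Sackur–Tetrode gas-phase proton at (T, p).
    """
    g = _lookup_species(
        energies, solvent, [reference.acid_id, reference.base_id], method_tag
    )
    g_eff = g[reference.acid_id] - g[reference.base_id] + rt_ln10(T) * pka_ref
    return ProtonEnergies(
        solvent=solvent,
        g_eff=g_eff,
        dg_solv=g_eff - gas_phase_proton_free_energy(T, p),
        provenance="from-reference",
        temperature=T,
        pressure=p,
    )


def pcet_potential(
    g_acid: float,
    g_radical: float,
    g_h2: float,
    pH: float = 0.0,
    T: float = T_DEFAULT,
) -> float:
    """Potential of the proton-coupled oxidation B–H → B· + H+ + e−, in volts.

    Referenced to the computational SHE in the same solvent:
    E = [G(B·) + ½G(H2) − G(B–H)]/F − (R·T·ln10/F)·pH. ``g_h2`` is the
    gas-phase H2 free energy (eV); the Nernstian activity term vanishes at
    unit proton activity (pH 0).
    """
    numerator = (
        _as_energy(g_radical, "radical") + 0.5 * _as_energy(g_h2, "H2")
        - _as_energy(g_acid, "acid")
    )
    return numerator - rt_ln10(T) * pH  # eV per particle / e == volts


def pcet_potential_for_pair(
    pair: ConjugatePair,
    energies: EnergyTable,
    solvent: str,
    g_h2: float,
    pH: float = 0.0,
    T: float = T_DEFAULT,
    method_tag: str | None = None,
) -> float:
    """:func:`pcet_potential` with table lookup; requires the radical record."""
    if pair.radical_id is None:
        raise ValueError(
            f"pair '{pair.acid_id}' has no radical species; the PCET potential "
            "needs the H-abstracted radical record"
        )
    g = _lookup_species(energies, solvent, [pair.acid_id, pair.radical_id], method_tag)
    return pcet_potential(g[pair.acid_id], g[pair.radical_id], g_h2, pH, T)


def abs_she_from_g_eff(g_eff_h: float, g_h2: float) -> float:
    """Absolute SHE potential (V) from the effective proton energy (eV).

    E_abs = (G_eff(H+) − ½G(H2)) / F, anchored on ½H2 ⇌ H+ + e− at 0 V.
    """
    return _as_energy(g_eff_h, "G_eff(H+)") - 0.5 * _as_energy(g_h2, "H2")


def g_eff_from_abs_she(e_abs: float, g_h2: float) -> float:
    """Inverse of :func:`abs_she_from_g_eff`: G_eff(H+) = ½G(H2) + F·E_abs."""
    return 0.5 * _as_energy(g_h2, "H2") + float(e_abs)


def conversion_factor(
    e_abs_x: float,
    e_abs_water: float,
    convention_x: str | None = None,
    convention_water: str | None = None,
) -> float:
    """Water→solvent proton-energy correction: F·(E_abs(X) − E_abs(water)), eV.

    Both potentials must sit on the same (inner/Galvani or outer/Volta)
    convention; when convention metadata is present on both sides and
    disagrees, the comparison is refused rather than silently mixing scales
    that differ by the surface potential χ.
    """
    if (
        convention_x is not None
        and convention_water is not None
        and convention_x != convention_water
    ):
        raise ValueError(
            "mixed potential conventions: "
            f"'{convention_x}' vs '{convention_water}' (inner/Galvani and "
            "outer/Volta potentials differ by the surface potential)"
        )
    return float(e_abs_x) - float(e_abs_water)


def solvent_conversion_factor(
    solvents: SolventTable, name: str, water_name: str = "water"
) -> float:
    """Conversion factor (eV) for a solvent-table entry.

    Uses the tabulated factor when present; otherwise derives it lazily from
    the absolute SHE potentials of the solvent and of water (which must then
    both be tabulated, on the same potential convention).
    """
    entry = solvents.get(name)
    if normalize_name(name) == normalize_name(water_name):
        return 0.0
    if entry.conversion_factor is not None:
        return entry.conversion_factor
    water = solvents.get(water_name)
    if entry.e_abs_she is None or water.e_abs_she is None:
        raise ValueError(
            f"solvent '{name}': no conversion factor and no absolute SHE "
            "potential pair (solvent + water) to derive one"
        )
    return conversion_factor(
        entry.e_abs_she,
        water.e_abs_she,
        entry.potential_convention,
        water.potential_convention,
    )


def proton_energy_in_solvent(
    water: ProtonEnergies, factor: float, solvent: str
) -> ProtonEnergies:
    """Transfer proton energetics from water to another solvent.

    G_eff(H+, X) = G_eff(H+, water) + factor; the solvation energy shifts by
    the same amount, so the (G_eff − ΔG_solv) gauge is preserved exactly.
    """
    return ProtonEnergies(
        solvent=solvent,
        g_eff=water.g_eff + factor,
        dg_solv=water.dg_solv + factor,
        provenance="from-conversion-factor",
        temperature=water.temperature,
        pressure=water.pressure,
    )


def proton_energies_for_solvent(
    solvents: SolventTable,
    water_protons: ProtonEnergies,
    name: str,
    water_name: str = "water",
) -> ProtonEnergies:
    """Water protons + tabulated conversion factor, by solvent name."""
    factor = solvent_conversion_factor(solvents, name, water_name)
    return proton_energy_in_solvent(water_protons, factor, solvents.get(name).name)


def direct_pka(
    target: ConjugatePair,
    proton: ProtonEnergies,
    energies: EnergyTable,
    solvent: str | None = None,
    T: float | None = None,
    method_tag: str | None = None,
) -> PkaPrediction:
    """pKa from the absolute dissociation free energy with an explicit proton.

    dG_diss = G(A−) + G_eff(H+) − G(AH); pKa = dG_diss / (R·T·ln10). When the
    proton energy comes from the same reference in the same solvent this is
    algebraically identical to :func:`isodesmic_pka`.
    """
    if solvent is None:
        solvent = proton.solvent
    elif normalize_name(solvent) != normalize_name(proton.solvent):
        raise ValueError(
            f"solvent mismatch: energies requested in '{solvent}' but the "
            f"proton entry is for '{proton.solvent}'"
        )
    if T is None:
        T = proton.temperature
    g = _lookup_species(energies, solvent, [target.acid_id, target.base_id], method_tag)
    dg_diss = g[target.base_id] + proton.g_eff - g[target.acid_id]
    return PkaPrediction(
        species_id=target.acid_id,
        solvent=solvent,
        pka_raw=dg_diss / rt_ln10(T),
        dg_diss=dg_diss,
        reference_id=f"proton:{proton.provenance}",
        temperature=T,
    )


def proton_solvation_energy(
    proton: ProtonEnergies | float,
    T: float = T_DEFAULT,
    p: float = P_STANDARD,
) -> float:
    """ΔG_solv(H+) = G_eff(H+) − G(H+, gas) in eV.

    Accepts a :class:`ProtonEnergies` (using its own T, p) or a bare
    effective energy in eV.
    """
    if isinstance(proton, ProtonEnergies):
        return proton.g_eff - gas_phase_proton_free_energy(
            proton.temperature, proton.pressure
        )
    return float(proton) - gas_phase_proton_free_energy(T, p)
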