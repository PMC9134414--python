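"""Shared frozen dataclasses used across the table-IO and thermodynamic layers.

These are deliberately plain containers; all behaviour (lookup, validation,
thermodynamics) lives in :mod:`solvpka.data_io` and
:mod:`solvpka.thermo_engine`, which re-export these types.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core_units import P_STANDARD, T_DEFAULT

__all__ = [
    "GAS_MEDIUM",
    "normalize_name",
    "EnergyRecord",
    "ConjugatePair",
    "PkaObservation",
    "SolventEntry",
    "ProtonEnergies",
    "PkaPrediction",
]

#: reserved medium token for gas-phase records (e.g. H2 for the SHE anchor)
GAS_MEDIUM = "gas"


def normalize_name(name: str) -> str:
    """Case-insensitive, whitespace-normalized matching key for free-text names."""
    return " ".join(str(name).split()).lower()


@dataclass(frozen=True)
class EnergyRecord:
    """One total Gibbs free energy for a species in a named medium.

    ``g_total`` is always in eV per particle (normalized at ingestion).
    ``lowest_frequency`` is the lowest vibrational frequency in cm^-1
    (negative values denote imaginary modes); ``line`` is the source-row
    provenance for diagnostics.
    """

    species_id: str
    medium: str
    g_total: float
    charge: int = 0
    method_tag: str = "default"
    lowest_frequency: float | None = None
    line: int | None = None

    def key(self) -> tuple[str, str, str]:
        return (
            normalize_name(self.species_id),
            normalize_name(self.medium),
            normalize_name(self.method_tag),
        )


@dataclass(frozen=True)
class ConjugatePair:
    """An acid/base species pair defining a single-site dissociation.

    ``radical_id`` (the H-abstracted neutral radical) is needed only by the
    PCET-potential operation and may be absent for the pKa pipeline.
    """

    acid_id: str
    base_id: str
    radical_id: str | None = None
    group_label: str | None = None


@dataclass(frozen=True)
class PkaObservation:
    """One experimental pKa for a species in a solvent."""

    species_id: str
    solvent: str
    pka: float
    source_tag: str = ""
    n_sources: int = 1


@dataclass(frozen=True)
class SolventEntry:
    """Per-solvent electrochemical and solvatochromic metadata.

    At least one of ``e_abs_she`` (absolute SHE potential, V) or
    ``conversion_factor`` (eV relative to water) must be present.
    ``potential_convention`` may label the absolute potential as ``inner``
    (Galvani) or ``outer`` (Volta); mixing conventions is an error, and the
    surface potential χ is never added (it cancels for charge-neutral
    reactions handled consistently).
    """

    name: str
    solvent_class: str  # "protic" | "aprotic"
    e_abs_she: float | None = None
    conversion_factor: float | None = None
    pi_star: float | None = None
    alpha: float | None = None
    beta: float | None = None
    potential_convention: str | None = None

    def has_kamlet_taft(self) -> bool:
        return None not in (self.pi_star, self.alpha, self.beta)


@dataclass(frozen=True)
class ProtonEnergies:
    """Effective solvated-proton energetics for one solvent.

    ``g_eff`` is the effective total free energy assigned to the solvated
    proton (eV); ``dg_solv`` = g_eff − G(H+, gas) is the conventional proton
    solvation free energy. The two always differ by the gas-phase proton
    free energy at (temperature, pressure), by construction.
    """

    solvent: str
    g_eff: float
    dg_solv: float
    provenance: str  # from-reference | from-abs-she | from-conversion-factor
    temperature: float = T_DEFAULT
    pressure: float = P_STANDARD


@dataclass(frozen=True)
class PkaPrediction:
    """A predicted pKa with full provenance.

    ``pka_raw`` = dg_diss / (R·T·ln10) exactly; ``pka_scaled`` is filled in
    once a linear scaling relation is applied.
    """

    species_id: str
    solvent: str
    pka_raw: float
    dg_diss: float
    reference_id: str
    relation_used: str | None = None
    pka_scaled: float | None = None
    temperature: float = T_DEFAULT
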