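"""Self-contained synthetic inputs with known ground truth.

The generator inverts the forward model: it writes species free energies
such that, given the designated reference acid and its aqueous pKa, the
thermodynamic engine reproduces a prescribed "true" pKa for every species
in every solvent exactly when no noise is requested. Gaussian perturbations
are applied to the *energies* (eV), not to pKa values, so that error
propagation through the isodesmic/direct algebra is exercised; at 298.15 K,
one pKa unit corresponds to 0.059159 eV.

Default study conditions: a formic-acid stand-in reference with aqueous
pKa 3.77, a water effective proton energy of −11.85 eV, ½G(H2) = −15.90 eV
(hence E_abs(SHE, water) = 4.05 V), and six solvents whose proton-energy
shifts relative to water equal the differences of the printed solvation
energies packaged in :func:`packaged_printed_solvent_table`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core_units import T_DEFAULT, gas_phase_proton_free_energy, rt_ln10
from .data_io import EnergyTable, SolventTable, solvent_table_to_frame
from .records import (
    GAS_MEDIUM,
    ConjugatePair,
    EnergyRecord,
    ProtonEnergies,
    SolventEntry,
    normalize_name,
)

__all__ = [
    "FixtureSolvent",
    "FixtureSpec",
    "FixtureResult",
    "DEFAULT_SOLVENTS",
    "generate_energy_table",
    "generate_scaling_dataset",
    "PackagedSolvent",
    "packaged_printed_solvent_table",
]


@dataclass(frozen=True)
class FixtureSolvent:
    """A synthetic solvent: name, proton-energy shift vs water (eV), class."""

    name: str
    shift: float
    solvent_class: str


#: Default solvent panel; shifts are the water-relative differences of the
#: six packaged printed proton solvation energies.
DEFAULT_SOLVENTS: tuple[FixtureSolvent, ...] = (
    FixtureSolvent("water", 0.0, "protic"),
    FixtureSolvent("methanol", 0.29, "protic"),
    FixtureSolvent("acetonitrile", 0.63, "aprotic"),
    FixtureSolvent("DMSO", 0.66, "aprotic"),
    FixtureSolvent("acetic acid", 0.64, "protic"),
    FixtureSolvent("dimethylamine", 0.97, "protic"),
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic energy-table fixture.

    ``true_pka`` maps species id → aqueous pKa; when absent, ``n_species``
    values are drawn uniformly on ``pka_range``. ``noise_sigma`` is the
    standard deviation (eV) of independent Gaussian perturbations added to
    every target-species energy record; the reference couple stays
    noise-free (it defines the energy gauge). Seeds fully determine output.
    """

    n_species: int = 12
    solvents: tuple[FixtureSolvent, ...] = DEFAULT_SOLVENTS
    true_pka: dict[str, float] | None = None
    noise_sigma: float = 0.0
    seed: int = 0
    pka_range: tuple[float, float] = (-2.0, 20.0)
    reference_id: str = "formic_acid"
    reference_pka: float = 3.77
    g_eff_water: float = -11.85
    half_g_h2: float = -15.90
    method_tag: str = "synthetic"


@dataclass(frozen=True)
class FixtureResult:
    """A generated fixture: tables, pairs, and the ground truth."""

    spec: FixtureSpec
    energies: EnergyTable
    solvents: SolventTable
    pairs: tuple[ConjugatePair, ...]
    reference: ConjugatePair
    truth: pd.DataFrame  # species_id, solvent, pka_true
    g_h2: float

    @property
    def energy_frame(self) -> pd.DataFrame:
        return self.energies.to_frame()

    @property
    def solvent_frame(self) -> pd.DataFrame:
        return solvent_table_to_frame(self.solvents)

    def true_pka(self, species_id: str, solvent: str) -> float:
        mask = (self.truth["species_id"] == species_id) & (
            self.truth["solvent"] == solvent
        )
        return float(self.truth.loc[mask, "pka_true"].iloc[0])

    def pka_exp_frame(self) -> pd.DataFrame:
        """Ground truth in the experimental-pKa table schema."""
        return pd.DataFrame(
            {
                "species_id": self.truth["species_id"],
                "solvent": self.truth["solvent"],
                "pka": self.truth["pka_true"],
                "source_tag": "ground-truth",
            }
        )

    def write(self, directory) -> dict[str, Path]:
        """Write energies/solvents/pairs CSVs and ground-truth files."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "energies": directory / "energies.csv",
            "solvents": directory / "solvents.csv",
            "pairs": directory / "pairs.csv",
            "truth_csv": directory / "ground_truth.csv",
            "truth_json": directory / "ground_truth.json",
        }
        self.energy_frame.to_csv(paths["energies"], index=False)
        self.solvent_frame.to_csv(paths["solvents"], index=False)
        all_pairs = (self.reference, *self.pairs)  # reference first
        pd.DataFrame(
            {
                "acid_id": [p.acid_id for p in all_pairs],
                "base_id": [p.base_id for p in all_pairs],
                "radical_id": [p.radical_id for p in all_pairs],
                "group_label": [p.group_label for p in all_pairs],
            }
        ).to_csv(paths["pairs"], index=False)
        self.truth.to_csv(paths["truth_csv"], index=False)
        paths["truth_json"].write_text(
            json.dumps(
                {
                    "reference_id": self.spec.reference_id,
                    "reference_pka": self.spec.reference_pka,
                    "seed": self.spec.seed,
                    "noise_sigma": self.spec.noise_sigma,
                    "records": json.loads(
                        self.truth.to_json(orient="records", double_precision=15)
                    ),
                },
                indent=1,
                sort_keys=True,
            )
            + "\n",
            encoding="utf-8",
        )
        return paths


def _species_ids(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"acid_{i + 1:0{width}d}" for i in range(n)]


def generate_energy_table(spec: FixtureSpec) -> FixtureResult:
    """Construct a species energy table consistent with prescribed pKa values.

    In water the reference base energy is placed so the reference acid
    reproduces ``reference_pka`` with G_eff(H+) = ``g_eff_water``; each
    target anion is placed so the acid's aqueous pKa equals its true value.
    Moving to solvent X shifts only the proton: G_eff(H+, X) = G_eff(H+,
    water) + shift, so the true pKa in X exceeds the aqueous value by
    shift / (R·T·ln10), while the species energies themselves are
    solvent-independent (before noise). A gas-phase H2 record anchors the
    absolute-potential route.
    """
    names = {normalize_name(s.name) for s in spec.solvents}
    if "water" not in names:
        raise ValueError("fixture solvents must include water")
    if spec.noise_sigma < 0:
        raise ValueError(f"noise_sigma must be >= 0, got {spec.noise_sigma}")
    if len(names) != len(spec.solvents):
        raise ValueError("duplicate solvent names in fixture spec")

    rng = np.random.default_rng(spec.seed)
    u = rt_ln10(T_DEFAULT)
    ids = _species_ids(spec.n_species)
    if spec.true_pka is not None:
        true_water = dict(spec.true_pka)
        ids = list(true_water)
    else:
        lo, hi = spec.pka_range
        true_water = {sid: float(v) for sid, v in zip(ids, rng.uniform(lo, hi, len(ids)))}

    # deterministic but loosely "quantum-chemistry-sized" acid energies
    g_acid_water = {
        sid: float(-3000.0 - 40.0 * i + rng.normal(0.0, 10.0))
        for i, sid in enumerate(ids)
    }
    g_ref_acid = -5162.0  # formic-acid-like total free energy, eV

    records: list[EnergyRecord] = []
    truth_rows = []

    g_h2 = 2.0 * spec.half_g_h2
    records.append(
        EnergyRecord("H2", GAS_MEDIUM, g_h2, 0, spec.method_tag, None, None)
    )

    for solvent in spec.solvents:
        g_eff_x = spec.g_eff_water + solvent.shift
        # reference couple: exact in every solvent (defines the gauge)
        records.append(
            EnergyRecord(
                spec.reference_id, solvent.name, g_ref_acid, 0, spec.method_tag
            )
        )
        records.append(
            EnergyRecord(
                spec.reference_id + "_base",
                solvent.name,
                g_ref_acid - g_eff_x + u * spec.reference_pka,
                -1,
                spec.method_tag,
            )
        )
        for sid in ids:
            pka_x = true_water[sid] + solvent.shift / u
            g_acid = g_acid_water[sid]
            g_base = g_acid - g_eff_x + u * pka_x
            if spec.noise_sigma > 0:
                g_acid += rng.normal(0.0, spec.noise_sigma)
                g_base += rng.normal(0.0, spec.noise_sigma)
            records.append(
                EnergyRecord(sid, solvent.name, g_acid, 0, spec.method_tag)
            )
            records.append(
                EnergyRecord(sid + "_base", solvent.name, g_base, -1, spec.method_tag)
            )
            truth_rows.append(
                {"species_id": sid, "solvent": solvent.name, "pka_true": pka_x}
            )

    solvent_entries = [
        SolventEntry(
            name=s.name,
            solvent_class=s.solvent_class,
            e_abs_she=(spec.g_eff_water + s.shift) - spec.half_g_h2,
            conversion_factor=s.shift,
        )
        for s in spec.solvents
    ]
    pairs = tuple(
        ConjugatePair(acid_id=sid, base_id=sid + "_base", group_label="synthetic")
        for sid in ids
    )
    reference = ConjugatePair(
        acid_id=spec.reference_id,
        base_id=spec.reference_id + "_base",
        group_label="carboxylic acid",
    )
    return FixtureResult(
        spec=spec,
        energies=EnergyTable(records),
        solvents=SolventTable(solvent_entries),
        pairs=pairs,
        reference=reference,
        truth=pd.DataFrame(truth_rows),
        g_h2=g_h2,
    )


def generate_scaling_dataset(
    slope: float,
    intercept: float,
    n: int,
    noise_sigma: float = 0.0,
    outlier_fraction: float = 0.0,
    seed: int = 0,
    x_range: tuple[float, float] = (-5.0, 25.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Computed-vs-experimental style scatter with known line and gross outliers.

    x is uniform on ``x_range``; y = slope·x + intercept + N(0, noise_sigma),
    with ``outlier_fraction`` of the points displaced by ±(10–30) pKa units
    to emulate irreconcilable experimental values.
    """
    if n < 2:
        raise ValueError(f"need n >= 2 points, got {n}")
    if not 0.0 <= outlier_fraction < 0.5:
        raise ValueError(
            f"outlier_fraction must be in [0, 0.5), got {outlier_fraction}"
        )
    rng = np.random.default_rng(seed)
    x = rng.uniform(x_range[0], x_range[1], n)
    y = slope * x + intercept
    if noise_sigma > 0:
        y = y + rng.normal(0.0, noise_sigma, n)
    m = int(round(outlier_fraction * n))
    if m:
        idx = rng.choice(n, size=m, replace=False)
        y[idx] = y[idx] + rng.choice([-1.0, 1.0], size=m) * rng.uniform(10.0, 30.0, m)
    return x, y


@dataclass(frozen=True)
class PackagedSolvent:
    """One row of the packaged printed-values consistency table."""

    entry: SolventEntry
    protons: ProtonEnergies
    note: str


# literature-reported proton solvation free energies (eV; CCSD(T)/SMD with
# a formic-acid reference) for six solvents; consistency testing only,
# never a predictive default. Kamlet-Taft parameters are the standard
# Marcus solvatochromic-table values; dimethylamine has no tabulated set.
_PRINTED = (
    ("water", -11.58, "protic", 1.09, 1.17, 0.47),
    ("methanol", -11.29, "protic", 0.60, 0.98, 0.66),
    ("acetonitrile", -10.95, "aprotic", 0.75, 0.19, 0.40),
    ("DMSO", -10.92, "aprotic", 1.00, 0.00, 0.76),
    ("acetic acid", -10.94, "protic", 0.64, 1.12, 0.45),
    ("dimethylamine", -10.61, "protic", None, None, None),
)


def packaged_printed_solvent_table() -> tuple[PackagedSolvent, ...]:
    """The six printed proton solvation energies as a consistency table.

    Effective proton energies are reconstructed with the Sackur–Tetrode
    gas-phase proton at 298.15 K / 1 atm; conversion factors are the
    water-relative differences. Water is the most negative entry — the
    solvent best suited for stabilizing protons.
    """
    gas = gas_phase_proton_free_energy()
    water_dg = _PRINTED[0][1]
    out = []
    for name, dg, cls, pi_star, alpha, beta in _PRINTED:
        g_eff = dg + gas
        out.append(
            PackagedSolvent(
                entry=SolventEntry(
                    name=name,
                    solvent_class=cls,
                    conversion_factor=dg - water_dg,
                    pi_star=pi_star,
                    alpha=alpha,
                    beta=beta,
                ),
                protons=ProtonEnergies(
                    solvent=name,
                    g_eff=g_eff,
                    dg_solv=dg,
                    provenance="from-reference",
                ),
                note="literature proton solvation free energy (CCSD(T)/SMD, "
                "formic-acid reference)",
            )
        )
    return tuple(out)
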