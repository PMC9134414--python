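"""Reading, validating and writing the input and result tables.

Three input tables drive the pipeline:

* **energies** — one total Gibbs free energy per (species, medium,
  method); columns ``species_id, medium, g_total, unit`` plus optional
  ``charge, method_tag, lowest_frequency_cm``. Energies may be given in
  hartree, eV, kcal/mol or kJ/mol and are normalized to eV at ingestion.
* **solvents** — per-solvent absolute SHE potential (V) and/or
  water-relative conversion factor (eV), a protic/aprotic class and
  optional Kamlet–Taft parameters π*, α, β.
* **pka_exp** — experimental pKa observations (species, solvent, value,
  source).

Both CSV (comma separated, ``.`` decimal, UTF-8, mandatory header) and JSON
(list of row objects mirroring the column names) are accepted. All
validation errors carry the offending row.

Data-hygiene rules implemented here: replicate experimental pKa values are
merged by unweighted arithmetic mean (no judgement of source quality), and
structures whose lowest imaginary frequency is below the convergence screen
(−100 cm⁻¹ by default) are *flagged*, never silently dropped.
"""

from __future__ import annotations

import io
import json
import logging
import math
import os
from collections import OrderedDict
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .core_units import convert_energy
from .records import (
    GAS_MEDIUM,
    ConjugatePair,
    EnergyRecord,
    PkaObservation,
    SolventEntry,
    normalize_name,
)

__all__ = [
    "TableError",
    "EnergyTable",
    "SolventTable",
    "read_energy_table",
    "read_solvent_table",
    "read_pka_table",
    "read_pairs_table",
    "qc_filter_frequencies",
    "aggregate_replicates",
    "write_results",
    "read_results",
    "EnergyRecord",
    "ConjugatePair",
    "PkaObservation",
    "SolventEntry",
    "GAS_MEDIUM",
]

logger = logging.getLogger(__name__)

SOLVENT_CLASSES = ("protic", "aprotic")
POTENTIAL_CONVENTIONS = ("inner", "outer")


class TableError(ValueError):
    """A malformed input table; the message names the offending row/column."""


# --------------------------------------------------------------------------
# generic row loading (CSV or JSON) with row provenance
# --------------------------------------------------------------------------

def _load_rows(source) -> list[tuple[int, dict]]:
    """Return (row_location, {column -> string-or-value}) pairs.

    ``source`` may be a path, a file-like object, raw text, or a pandas
    DataFrame. Row locations are 1-based file lines for CSV (header on
    line 1) and 1-based record indices for JSON/DataFrame input.
    """
    if isinstance(source, pd.DataFrame):
        return [(i + 1, row._asdict() if hasattr(row, "_asdict") else dict(row))
                for i, (_, row) in enumerate(source.iterrows())]
    if hasattr(source, "read"):
        text = source.read()
    else:
        path = Path(source)
        text = path.read_text(encoding="utf-8")
    stripped = text.lstrip()
    if stripped.startswith("[") or stripped.startswith("{"):
        payload = json.loads(text)
        if isinstance(payload, dict):
            for key in ("records", "rows", "results"):
                if key in payload:
                    payload = payload[key]
                    break
            else:
                raise TableError(
                    "JSON table must be a list of row objects or contain a "
                    "'records' key"
                )
        return [(i + 1, dict(row)) for i, row in enumerate(payload)]
    if not stripped:
        return []
    frame = pd.read_csv(
        io.StringIO(text), dtype=str, keep_default_na=False, skipinitialspace=True
    )
    rows = []
    for i, (_, row) in enumerate(frame.iterrows()):
        rows.append((i + 2, {str(k): v for k, v in row.items()}))
    return rows


def _get(row: dict, aliases: Sequence[str]):
    """Case-insensitive column lookup; returns None for absent/blank cells."""
    lowered = {str(k).strip().lower(): v for k, v in row.items()}
    for name in aliases:
        if name in lowered:
            value = lowered[name]
            if value is None:
                return None
            if isinstance(value, str) and value.strip() == "":
                return None
            if isinstance(value, float) and math.isnan(value):
                return None
            return value
    return None


def _require(row: dict, aliases: Sequence[str], table: str, loc: int):
    value = _get(row, aliases)
    if value is None:
        raise TableError(
            f"{table} table, row {loc}: missing required column/value "
            f"'{aliases[0]}'"
        )
    return value


def _parse_float(value, column: str, table: str, loc: int) -> float:
    try:
        out = float(value)
    except (TypeError, ValueError):
        raise TableError(
            f"{table} table, row {loc}: cannot parse {column}={value!r} as a number"
        ) from None
    if not math.isfinite(out):
        raise TableError(f"{table} table, row {loc}: {column} must be finite, got {value!r}")
    return out


# --------------------------------------------------------------------------
# energy table
# --------------------------------------------------------------------------

class EnergyTable:
    """Indexed collection of :class:`EnergyRecord` with case-insensitive lookup.

    Uniqueness of (species_id, medium, method_tag) is enforced at
    construction. Species/medium names are matched case-insensitively after
    whitespace normalization; no synonym registry is applied ("DMSO" and
    "dimethyl sulfoxide" are distinct unless the caller aliases them).
    """

    def __init__(self, records: Iterable[EnergyRecord] = ()):
        self._records: list[EnergyRecord] = []
        self._index: dict[tuple[str, str, str], EnergyRecord] = {}
        self._by_species_medium: dict[tuple[str, str], list[EnergyRecord]] = {}
        self._media: dict[str, str] = {}  # normalized -> first-seen spelling
        for rec in records:
            self.add(rec)

    def add(self, rec: EnergyRecord) -> None:
        key = rec.key()
        if key in self._index:
            other = self._index[key]
            raise TableError(
                f"duplicate energy record for species '{rec.species_id}' in "
                f"medium '{rec.medium}' with method '{rec.method_tag}' "
                f"(rows {other.line} and {rec.line})"
            )
        if not math.isfinite(rec.g_total):
            raise TableError(
                f"non-finite energy for species '{rec.species_id}' in medium "
                f"'{rec.medium}' (row {rec.line})"
            )
        self._index[key] = rec
        self._records.append(rec)
        self._by_species_medium.setdefault(key[:2], []).append(rec)
        self._media.setdefault(key[1], rec.medium)

    @property
    def records(self) -> tuple[EnergyRecord, ...]:
        return tuple(self._records)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records)

    def media(self) -> tuple[str, ...]:
        """First-seen spellings of all media in the table, gas included."""
        return tuple(self._media.values())

    def solvents(self) -> tuple[str, ...]:
        return tuple(m for m in self.media() if normalize_name(m) != GAS_MEDIUM)

    def has(self, species_id: str, medium: str, method_tag: str | None = None) -> bool:
        try:
            self.get(species_id, medium, method_tag)
            return True
        except KeyError:
            return False

    def get(
        self, species_id: str, medium: str, method_tag: str | None = None
    ) -> EnergyRecord:
        pair_key = (normalize_name(species_id), normalize_name(medium))
        candidates = self._by_species_medium.get(pair_key, [])
        if method_tag is not None:
            wanted = normalize_name(method_tag)
            candidates = [
                r for r in candidates if normalize_name(r.method_tag) == wanted
            ]
        if not candidates:
            raise KeyError(
                f"no energy record for species '{species_id}' in medium "
                f"'{medium}'"
                + (f" with method '{method_tag}'" if method_tag else "")
            )
        if len(candidates) > 1:
            tags = sorted({r.method_tag for r in candidates})
            raise KeyError(
                f"ambiguous energy record for species '{species_id}' in medium "
                f"'{medium}': present under methods {tags}; pass method_tag"
            )
        return candidates[0]

    def g(self, species_id: str, medium: str, method_tag: str | None = None) -> float:
        """Total free energy in eV."""
        return self.get(species_id, medium, method_tag).g_total

    def shifted(self, medium: str, delta: float) -> "EnergyTable":
        """New table with every record in ``medium`` shifted by ``delta`` eV.

        Convenience for gauge checks: a constant per-medium shift must leave
        every balanced (isodesmic) reaction energy unchanged.
        """
        wanted = normalize_name(medium)
        out = []
        for rec in self._records:
            if normalize_name(rec.medium) == wanted:
                rec = EnergyRecord(
                    rec.species_id, rec.medium, rec.g_total + delta, rec.charge,
                    rec.method_tag, rec.lowest_frequency, rec.line,
                )
            out.append(rec)
        return EnergyTable(out)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species_id": [r.species_id for r in self._records],
                "medium": [r.medium for r in self._records],
                "charge": [r.charge for r in self._records],
                "g_total": [r.g_total for r in self._records],
                "unit": ["eV"] * len(self._records),
                "method_tag": [r.method_tag for r in self._records],
                "lowest_frequency_cm": [r.lowest_frequency for r in self._records],
            }
        )


def read_energy_table(source) -> EnergyTable:
    """Parse an energy table (CSV or JSON), normalizing all energies to eV.

    Required columns: ``species_id, medium, g_total, unit``; optional:
    ``charge, method_tag, lowest_frequency_cm``. Duplicate
    (species, medium, method) keys, unknown units and unparseable numbers
    are rejected with the row named.
    """
    rows = _load_rows(source)
    if not rows:
        logger.warning("energy table is empty; returning an empty collection")
        return EnergyTable()
    table = EnergyTable()
    for loc, row in rows:
        species = str(_require(row, ("species_id", "species"), "energy", loc))
        medium = str(_require(row, ("medium", "solvent"), "energy", loc))
        raw_g = _require(row, ("g_total", "g", "energy", "value"), "energy", loc)
        unit = str(_require(row, ("unit", "energy_unit"), "energy", loc))
        g_val = _parse_float(raw_g, "g_total", "energy", loc)
        try:
            g_ev = convert_energy(g_val, unit, "eV")
        except ValueError as exc:
            raise TableError(f"energy table, row {loc}: {exc}") from None
        charge_raw = _get(row, ("charge",))
        try:
            charge = int(charge_raw) if charge_raw is not None else 0
        except (TypeError, ValueError):
            raise TableError(
                f"energy table, row {loc}: cannot parse charge={charge_raw!r}"
            ) from None
        method = _get(row, ("method_tag", "method"))
        freq_raw = _get(
            row, ("lowest_frequency_cm", "lowest_frequency", "freq_cm")
        )
        freq = (
            _parse_float(freq_raw, "lowest_frequency_cm", "energy", loc)
            if freq_raw is not None
            else None
        )
        table.add(
            EnergyRecord(
                species_id=species,
                medium=medium,
                g_total=float(g_ev),
                charge=charge,
                method_tag=str(method) if method is not None else "default",
                lowest_frequency=freq,
                line=loc,
            )
        )
    return table


def qc_filter_frequencies(
    records: Iterable[EnergyRecord] | EnergyTable, threshold: float = -100.0
) -> tuple[list[EnergyRecord], list[EnergyRecord]]:
    """Convergence screen on the lowest (imaginary) frequency.

    A structure counts as converged when its lowest frequency is above the
    threshold (default −100 cm⁻¹). Records failing the screen are returned
    in the ``flagged`` list — never silently dropped — and records without
    frequency metadata pass with a logged notice.
    """
    if threshold > 0:
        raise ValueError(
            f"frequency threshold must be <= 0 cm^-1, got {threshold}"
        )
    passing: list[EnergyRecord] = []
    flagged: list[EnergyRecord] = []
    missing = 0
    for rec in records:
        if rec.lowest_frequency is None:
            missing += 1
            passing.append(rec)
        elif rec.lowest_frequency < threshold:
            flagged.append(rec)
        else:
            passing.append(rec)
    if missing:
        logger.info(
            "%d energy record(s) carry no frequency metadata; passed unscreened",
            missing,
        )
    if flagged:
        logger.warning(
            "%d energy record(s) fail the %g cm^-1 convergence screen: %s",
            len(flagged),
            threshold,
            ", ".join(f"{r.species_id}/{r.medium}" for r in flagged),
        )
    return passing, flagged


# --------------------------------------------------------------------------
# experimental pKa table
# --------------------------------------------------------------------------

def read_pka_table(source) -> list[PkaObservation]:
    """Parse experimental pKa observations (species_id, solvent, pka, source_tag)."""
    rows = _load_rows(source)
    if not rows:
        logger.warning("experimental pKa table is empty")
        return []
    out = []
    for loc, row in rows:
        species = str(_require(row, ("species_id", "species"), "pka_exp", loc))
        solvent = str(_require(row, ("solvent", "medium"), "pka_exp", loc))
        pka = _parse_float(
            _require(row, ("pka", "value"), "pka_exp", loc), "pka", "pka_exp", loc
        )
        source_tag = _get(row, ("source_tag", "source"))
        out.append(
            PkaObservation(
                species_id=species,
                solvent=solvent,
                pka=pka,
                source_tag=str(source_tag) if source_tag is not None else "",
            )
        )
    return out


def aggregate_replicates(
    observations: Iterable[PkaObservation],
) -> list[PkaObservation]:
    """Merge replicate measurements per (species, solvent) by arithmetic mean.

    Every source contributes with equal weight — no assumption about
    measurement quality is made, however discordant the values — and the
    merged observation records all contributing sources and their count.
    Idempotent.
    """
    groups: "OrderedDict[tuple[str, str], list[PkaObservation]]" = OrderedDict()
    for obs in observations:
        key = (normalize_name(obs.species_id), normalize_name(obs.solvent))
        groups.setdefault(key, []).append(obs)
    merged = []
    for members in groups.values():
        total = sum(o.pka * o.n_sources for o in members)
        count = sum(o.n_sources for o in members)
        sources = ";".join(o.source_tag for o in members if o.source_tag)
        merged.append(
            PkaObservation(
                species_id=members[0].species_id,
                solvent=members[0].solvent,
                pka=total / count,
                source_tag=sources,
                n_sources=count,
            )
        )
    return merged


# --------------------------------------------------------------------------
# solvent table
# --------------------------------------------------------------------------

class SolventTable:
    """Case-insensitive registry of :class:`SolventEntry`."""

    def __init__(self, entries: Iterable[SolventEntry] = ()):
        self._entries: "OrderedDict[str, SolventEntry]" = OrderedDict()
        for entry in entries:
            self.add(entry)

    def add(self, entry: SolventEntry) -> None:
        key = normalize_name(entry.name)
        if key in self._entries:
            raise TableError(f"duplicate solvent entry '{entry.name}'")
        if entry.solvent_class not in SOLVENT_CLASSES:
            raise TableError(
                f"solvent '{entry.name}': unknown class "
                f"'{entry.solvent_class}' (expected one of {SOLVENT_CLASSES})"
            )
        if entry.e_abs_she is None and entry.conversion_factor is None:
            raise TableError(
                f"solvent '{entry.name}': needs an absolute SHE potential "
                "(e_abs_she_v) or a conversion factor (conversion_factor_ev)"
            )
        if (
            entry.potential_convention is not None
            and entry.potential_convention not in POTENTIAL_CONVENTIONS
        ):
            raise TableError(
                f"solvent '{entry.name}': unknown potential convention "
                f"'{entry.potential_convention}'"
            )
        self._entries[key] = entry

    def __contains__(self, name: str) -> bool:
        return normalize_name(name) in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries.values())

    @property
    def entries(self) -> tuple[SolventEntry, ...]:
        return tuple(self._entries.values())

    def get(self, name: str) -> SolventEntry:
        try:
            return self._entries[normalize_name(name)]
        except KeyError:
            raise KeyError(f"no solvent entry for '{name}'") from None


def read_solvent_table(source, water_name: str = "water") -> SolventTable:
    """Parse the solvent table.

    Columns: ``name, class`` plus at least one of ``e_abs_she_v`` /
    ``conversion_factor_ev``; optional ``pi_star, alpha, beta,
    potential_convention``. A water entry carrying an explicit conversion
    factor must have it equal to zero (water is the gauge origin).
    """
    rows = _load_rows(source)
    if not rows:
        logger.warning("solvent table is empty")
        return SolventTable()
    table = SolventTable()
    for loc, row in rows:
        name = str(_require(row, ("name", "solvent"), "solvent", loc))
        cls = str(_require(row, ("class", "solvent_class"), "solvent", loc)).strip().lower()
        e_abs_raw = _get(row, ("e_abs_she_v", "e_abs_she", "e_abs"))
        factor_raw = _get(row, ("conversion_factor_ev", "conversion_factor"))
        e_abs = (
            _parse_float(e_abs_raw, "e_abs_she_v", "solvent", loc)
            if e_abs_raw is not None
            else None
        )
        factor = (
            _parse_float(factor_raw, "conversion_factor_ev", "solvent", loc)
            if factor_raw is not None
            else None
        )
        optional = {}
        for column in ("pi_star", "alpha", "beta"):
            raw = _get(row, (column,))
            optional[column] = (
                _parse_float(raw, column, "solvent", loc) if raw is not None else None
            )
        convention = _get(row, ("potential_convention", "convention"))
        if (
            normalize_name(name) == normalize_name(water_name)
            and factor is not None
            and abs(factor) > 1e-9
        ):
            raise TableError(
                f"solvent table, row {loc}: water must have conversion factor 0, "
                f"got {factor}"
            )
        try:
            table.add(
                SolventEntry(
                    name=name,
                    solvent_class=cls,
                    e_abs_she=e_abs,
                    conversion_factor=factor,
                    potential_convention=(
                        str(convention).strip().lower() if convention is not None else None
                    ),
                    **optional,
                )
            )
        except TableError as exc:
            raise TableError(f"solvent table, row {loc}: {exc}") from None
    return table


def solvent_table_to_frame(table: SolventTable) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "name": [e.name for e in table],
            "class": [e.solvent_class for e in table],
            "e_abs_she_v": [e.e_abs_she for e in table],
            "conversion_factor_ev": [e.conversion_factor for e in table],
            "pi_star": [e.pi_star for e in table],
            "alpha": [e.alpha for e in table],
            "beta": [e.beta for e in table],
        }
    )


# --------------------------------------------------------------------------
# conjugate pairs
# --------------------------------------------------------------------------

def read_pairs_table(source) -> list[ConjugatePair]:
    """Parse acid/base pairs (acid_id, base_id, optional radical_id, group_label)."""
    rows = _load_rows(source)
    out = []
    for loc, row in rows:
        acid = str(_require(row, ("acid_id", "acid"), "pairs", loc))
        base = str(_require(row, ("base_id", "base"), "pairs", loc))
        radical = _get(row, ("radical_id", "radical"))
        group = _get(row, ("group_label", "group"))
        out.append(
            ConjugatePair(
                acid_id=acid,
                base_id=base,
                radical_id=str(radical) if radical is not None else None,
                group_label=str(group) if group is not None else None,
            )
        )
    return out


# --------------------------------------------------------------------------
# results
# --------------------------------------------------------------------------

def write_results(
    predictions, csv_path, provenance: dict | None = None
) -> Path:
    """Write predictions as a CSV table plus a JSON twin with provenance.

    ``predictions`` is a sequence of :class:`PkaPrediction` or a DataFrame.
    The JSON twin lives next to the CSV with a ``.json`` suffix and carries
    the full provenance block (reference compound, relation used,
    temperature, configuration hash) alongside every row.
    """
    csv_path = Path(csv_path)
    if isinstance(predictions, pd.DataFrame):
        frame = predictions.copy()
    else:
        frame = pd.DataFrame(
            {
                "species_id": [p.species_id for p in predictions],
                "solvent": [p.solvent for p in predictions],
                "pka_raw": [p.pka_raw for p in predictions],
                "pka_scaled": [p.pka_scaled for p in predictions],
                "relation_used": [p.relation_used for p in predictions],
                "reference_id": [p.reference_id for p in predictions],
                "dg_diss_ev": [p.dg_diss for p in predictions],
                "temperature_k": [p.temperature for p in predictions],
            }
        )
    os.makedirs(csv_path.parent, exist_ok=True)
    frame.to_csv(csv_path, index=False)
    payload = {
        "provenance": provenance or {},
        "results": json.loads(frame.to_json(orient="records", double_precision=15)),
    }
    json_path = csv_path.with_suffix(".json")
    json_path.write_text(
        json.dumps(payload, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    return json_path


def read_results(csv_path) -> pd.DataFrame:
    """Round-trip reader for result CSVs."""
    return pd.read_csv(csv_path)
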