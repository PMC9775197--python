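"""Bioassay curation: structure standardization, activity normalization,
classification and deduplication.

The raw input is one row per compound-assay measurement (SMILES, an IC50/Ki
value with its unit, the assay control's value, species, year, reference).
Curation produces one row per unique standardized structure (InChIKey) with a
control-normalized activity ratio and a binary activity class:

* concentrations are converted to micromolar at ingest;
* qualitative "inactive" records without a value are imputed an excess
  concentration of 1000 uM before normalization;
* ratio = activity / control, falling back to a 20 uM control (a typical
  thiourea IC50) when the assay did not report one;
* ratio < 1 (more potent than the control) => active, otherwise inactive;
* metal complexes, multi-component mixtures and unparsable entries are
  rejected with a reason, never silently dropped;
* duplicates (same InChIKey) are merged keeping the most potent ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

#: Default control concentration in uM used when an assay reports none
#: (typical thiourea IC50 against jack bean urease).
DEFAULT_CONTROL_UM = 20.0

#: Concentration imputed (uM) for records only described as "inactive".
QUALITATIVE_INACTIVE_UM = 1000.0

#: Elements regarded as "organic" for the purposes of metal-complex
#: rejection. Anything outside this set remaining after counterion removal
#: flags the record as a metal complex. Overridable per call.
ALLOWED_ELEMENTS = frozenset(
    {"H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Se", "Br", "I"}
)

#: Accepted concentration units and their factor to uM.
UNIT_TO_UM = {"nM": 1e-3, "uM": 1.0, "µM": 1.0, "μM": 1.0, "mM": 1e3, "M": 1e6}

ACTIVITY_TYPES = ("IC50", "Ki", "qualitative_inactive")


class StructureError(ValueError):
    """Raised when a SMILES cannot be parsed or standardized."""

    def __init__(self, message: str, record_id: str | None = None):
        super().__init__(message if record_id is None else f"{record_id}: {message}")
        self.record_id = record_id


@dataclass(frozen=True)
class RawActivityRecord:
    """One compound-assay measurement with provenance.

    Concentrations are in uM (convert at ingest; see :func:`read_raw_csv`).
    """

    record_id: str
    smiles: str
    activity_value: float | None
    activity_type: str
    control_value: float | None
    species: str
    year: int | None
    reference_id: str

    def __post_init__(self):
        if self.activity_type not in ACTIVITY_TYPES:
            raise ValueError(f"unknown activity_type {self.activity_type!r}")
        if self.activity_value is not None and not self.activity_value > 0:
            raise ValueError(f"activity_value must be > 0, got {self.activity_value}")


@dataclass(frozen=True)
class CuratedCompound:
    """A deduplicated structure with its normalized activity."""

    canonical_smiles: str
    inchikey: str
    ratio: float
    activity_class: str
    best_value_um: float
    species_set: frozenset[str]
    first_year: int | None
    n_merged: int


# ---------------------------------------------------------------------------
# structure handling

_cleanup_params = rdMolStandardize.CleanupParameters()
_fragment_remover = rdMolStandardize.FragmentRemover()
_uncharger = rdMolStandardize.Uncharger()


def _prepare(smiles: str) -> Chem.Mol | None:
    """Parse + cleanup + strip counterions/solvents. None on parse failure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    mol = rdMolStandardize.Cleanup(mol, _cleanup_params)
    stripped = _fragment_remover.remove(mol)
    # a pure salt record strips to nothing; keep the cleaned original so the
    # exclusion step can classify it
    return stripped if stripped.GetNumAtoms() > 0 else mol


def standardize_structure(
    smiles: str, record_id: str | None = None
) -> tuple[str, str]:
    """Standardize a SMILES into ``(canonical_smiles, inchikey)``.

    The standardization pipeline is cleanup (sanitize, normalize functional
    groups, reionize), counterion/solvent removal, and neutralization of
    remaining charges. Tautomers are *not* canonicalized: two genuinely
    different tautomer drawings keep distinct InChIKeys. Deterministic:
    identical inputs always give identical outputs, and any two drawings of
    the same molecule agree after standardization.
    """
    mol = _prepare(smiles)
    if mol is None:
        raise StructureError(f"unparsable SMILES {smiles!r}", record_id)
    mol = _uncharger.uncharge(mol)
    canonical = Chem.MolToSmiles(mol)
    inchikey = Chem.MolToInchiKey(mol)
    if not inchikey:
        raise StructureError(f"InChIKey generation failed for {smiles!r}", record_id)
    return canonical, inchikey


def exclude_structure(
    smiles: str, allowed_elements: frozenset[str] = ALLOWED_ELEMENTS
) -> str | None:
    """Decide whether a structure enters the curated set.

    Returns ``None`` to keep, or a rejection reason: ``"metal_complex"`` when
    a non-organic element remains after counterion stripping (covalent or
    coordinated metal), ``"mixture"`` when more than one organic fragment
    remains, ``"parse_error"`` when the SMILES does not parse.
    """
    mol = _prepare(smiles)
    if mol is None:
        return "parse_error"
    if any(a.GetSymbol() not in allowed_elements for a in mol.GetAtoms()):
        return "metal_complex"
    if len(Chem.GetMolFrags(mol)) > 1:
        return "mixture"
    return None


# ---------------------------------------------------------------------------
# activity handling

def impute_qualitative_inactive(record: RawActivityRecord) -> RawActivityRecord:
    """Give valueless qualitative-inactive records an excess 1000 uM value."""
    if record.activity_type == "qualitative_inactive" and record.activity_value is None:
        return replace(record, activity_value=QUALITATIVE_INACTIVE_UM)
    return record


def normalize_activity(
    activity_value: float,
    control_value: float | None,
    default_control_um: float = DEFAULT_CONTROL_UM,
) -> float:
    """Activity ratio = activity / control, both in uM.

    Falls back to ``default_control_um`` when the assay reported no control.
    """
    if not activity_value > 0:
        raise ValueError(f"activity_value must be > 0, got {activity_value}")
    control = default_control_um if control_value is None else control_value
    if not control > 0:
        raise ValueError(f"control must be > 0, got {control}")
    return activity_value / control


def classify_activity(ratio: float) -> str:
    """Active iff strictly more potent than the control (ratio < 1)."""
    if not ratio > 0:
        raise ValueError(f"ratio must be > 0, got {ratio}")
    return "active" if ratio < 1 else "inactive"


# ---------------------------------------------------------------------------
# record-level normalization and deduplication

#: Columns of the per-record normalized table produced by normalize_records.
NORMALIZED_COLUMNS = [
    "record_id",
    "inchikey",
    "canonical_smiles",
    "ratio",
    "activity_class",
    "value_um",
    "species",
    "year",
    "reference_id",
]


def normalize_records(
    records: Iterable[RawActivityRecord],
    default_control_um: float = DEFAULT_CONTROL_UM,
    allowed_elements: frozenset[str] = ALLOWED_ELEMENTS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standardize, filter and normalize raw records.

    Returns ``(normalized, rejects)``: one row per surviving record (columns
    :data:`NORMALIZED_COLUMNS`) and one row per rejected record
    (``record_id, smiles, reason``). Together they account for every input.
    """
    rows, rejects = [], []
    for rec in records:
        reason = exclude_structure(rec.smiles, allowed_elements)
        if reason is not None:
            rejects.append({"record_id": rec.record_id, "smiles": rec.smiles, "reason": reason})
            logger.info("rejected %s: %s", rec.record_id, reason)
            continue
        rec = impute_qualitative_inactive(rec)
        if rec.activity_value is None:
            rejects.append({"record_id": rec.record_id, "smiles": rec.smiles, "reason": "missing_value"})
            continue
        canonical, inchikey = standardize_structure(rec.smiles, rec.record_id)
        ratio = normalize_activity(rec.activity_value, rec.control_value, default_control_um)
        rows.append(
            {
                "record_id": rec.record_id,
                "inchikey": inchikey,
                "canonical_smiles": canonical,
                "ratio": ratio,
                "activity_class": classify_activity(ratio),
                "value_um": rec.activity_value,
                "species": rec.species,
                "year": rec.year,
                "reference_id": rec.reference_id,
            }
        )
    normalized = pd.DataFrame(rows, columns=NORMALIZED_COLUMNS)
    rejects_df = pd.DataFrame(rejects, columns=["record_id", "smiles", "reason"])
    return normalized, rejects_df


#: Columns of the curated (deduplicated) compound table.
CURATED_COLUMNS = [
    "inchikey",
    "canonical_smiles",
    "ratio",
    "activity_class",
    "best_value_um",
    "species",
    "first_year",
    "n_merged",
]


def deduplicate(normalized: pd.DataFrame) -> pd.DataFrame:
    """Merge normalized records into one row per InChIKey.

    Keeps the most potent (minimum) ratio; ratio ties break on the
    lexicographically smallest reference_id. Species are unioned
    (';'-joined, sorted), first_year is the minimum reported year, and
    n_merged counts merged records. Output is sorted by InChIKey.
    """
    if normalized.empty:
        return pd.DataFrame(columns=CURATED_COLUMNS)
    out = []
    for inchikey, grp in normalized.groupby("inchikey", sort=True):
        best = grp.sort_values(["ratio", "reference_id"], kind="mergesort").iloc[0]
        years = grp["year"].dropna()
        out.append(
            {
                "inchikey": inchikey,
                "canonical_smiles": best["canonical_smiles"],
                "ratio": float(best["ratio"]),
                "activity_class": classify_activity(float(best["ratio"])),
                "best_value_um": float(best["value_um"]),
                "species": ";".join(sorted(set(grp["species"]))),
                "first_year": int(years.min()) if len(years) else None,
                "n_merged": int(len(grp)),
            }
        )
    curated = pd.DataFrame(out, columns=CURATED_COLUMNS)
    curated["first_year"] = curated["first_year"].astype("Int64")
    return curated


def curate(
    records: Iterable[RawActivityRecord],
    default_control_um: float = DEFAULT_CONTROL_UM,
    allowed_elements: frozenset[str] = ALLOWED_ELEMENTS,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full curation: returns ``(curated, normalized, rejects)``."""
    normalized, rejects = normalize_records(records, default_control_um, allowed_elements)
    return deduplicate(normalized), normalized, rejects


def curated_records(curated: pd.DataFrame) -> list[CuratedCompound]:
    """View a curated table as :class:`CuratedCompound` objects."""
    return [
        CuratedCompound(
            canonical_smiles=r.canonical_smiles,
            inchikey=r.inchikey,
            ratio=r.ratio,
            activity_class=r.activity_class,
            best_value_um=r.best_value_um,
            species_set=frozenset(r.species.split(";")),
            first_year=None if pd.isna(r.first_year) else int(r.first_year),
            n_merged=r.n_merged,
        )
        for r in curated.itertuples()
    ]


# ---------------------------------------------------------------------------
# I/O

RAW_CSV_COLUMNS = [
    "record_id",
    "smiles",
    "activity_value",
    "activity_unit",
    "activity_type",
    "control_value",
    "control_unit",
    "species",
    "year",
    "reference_id",
]


def _to_um(value: float | None, unit: str | None) -> float | None:
    if value is None or pd.isna(value):
        return None
    unit = "uM" if unit is None or (isinstance(unit, float) and pd.isna(unit)) or unit == "" else unit
    try:
        return float(value) * UNIT_TO_UM[unit]
    except KeyError:
        raise ValueError(f"unknown concentration unit {unit!r}") from None


def read_raw_csv(path: str | Path) -> list[RawActivityRecord]:
    """Read a raw bioassay CSV (columns :data:`RAW_CSV_COLUMNS`) to records.

    Concentrations are converted to uM exactly using the unit columns
    (accepted units: nM, uM, mM, M; missing unit means uM).
    """
    df = pd.read_csv(path, dtype={"record_id": str, "reference_id": str})
    missing = set(RAW_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"raw CSV missing columns: {sorted(missing)}")
    records = []
    for r in df.itertuples(index=False):
        year = None if pd.isna(r.year) else int(r.year)
        records.append(
            RawActivityRecord(
                record_id=str(r.record_id),
                smiles=str(r.smiles),
                activity_value=_to_um(r.activity_value, r.activity_unit),
                activity_type=str(r.activity_type),
                control_value=_to_um(r.control_value, r.control_unit),
                species="unknown" if pd.isna(r.species) else str(r.species),
                year=year,
                reference_id=str(r.reference_id),
            )
        )
    return records


def records_to_frame(records: Sequence[RawActivityRecord]) -> pd.DataFrame:
    """Serialize records to the raw CSV schema (values already in uM)."""
    return pd.DataFrame(
        [
            {
                "record_id": r.record_id,
                "smiles": r.smiles,
                "activity_value": r.activity_value,
                "activity_unit": "uM",
                "activity_type": r.activity_type,
                "control_value": r.control_value,
                "control_unit": "uM",
                "species": r.species,
                "year": r.year,
                "reference_id": r.reference_id,
            }
            for r in records
        ],
        columns=RAW_CSV_COLUMNS,
    )
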