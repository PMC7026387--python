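"""Compound-table curation: unit normalization, canonicalization, dedup.

Raw solubility tables arrive with heterogeneous units (ug/mL, mg/mL, mg/L,
g/L, mol/L).  Curation converts every value to mol/L, takes log10 to obtain
the regression target logS, canonicalizes SMILES, derives InChIKeys, and
removes duplicate structures by InChIKey.  Every exclusion or transformation
is recorded in a provenance log; rows are never silently dropped.

Censored measurements ("insoluble below X") are retained with
``censored=True`` and excluded from regression targets downstream.
"""

from __future__ import annotations

import enum
import json
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Protocol

import numpy as np
import pandas as pd

__all__ = [
    "SolubilityUnit",
    "CompoundRecord",
    "CuratedDataset",
    "convert_to_logs",
    "parse_compound_table",
    "canonicalize_and_key",
    "deduplicate",
    "curate",
    "RDKitBackend",
]


class SolubilityUnit(enum.Enum):
    UG_PER_ML = "ug_per_mL"
    MG_PER_ML = "mg_per_mL"
    MG_PER_L = "mg_per_L"
    G_PER_L = "g_per_L"
    MOL_PER_L = "mol_per_L"


# accepted spellings in input tables -> unit enum
_UNIT_ALIASES = {
    "ug/ml": SolubilityUnit.UG_PER_ML,
    "µg/ml": SolubilityUnit.UG_PER_ML,
    "μg/ml": SolubilityUnit.UG_PER_ML,
    "ug_per_ml": SolubilityUnit.UG_PER_ML,
    "mg/ml": SolubilityUnit.MG_PER_ML,
    "mg_per_ml": SolubilityUnit.MG_PER_ML,
    "mg/l": SolubilityUnit.MG_PER_L,
    "mg_per_l": SolubilityUnit.MG_PER_L,
    "g/l": SolubilityUnit.G_PER_L,
    "g_per_l": SolubilityUnit.G_PER_L,
    "mol/l": SolubilityUnit.MOL_PER_L,
    "mol_per_l": SolubilityUnit.MOL_PER_L,
    "m": SolubilityUnit.MOL_PER_L,
}

# grams per litre represented by one unit of each mass-based unit
_MASS_TO_G_PER_L = {
    SolubilityUnit.UG_PER_ML: 1e-3,   # ug/mL == mg/L
    SolubilityUnit.MG_PER_ML: 1.0,    # mg/mL == g/L
    SolubilityUnit.MG_PER_L: 1e-3,
    SolubilityUnit.G_PER_L: 1.0,
}

_INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$|^[A-Z]{14}-[A-Z]{8}[SN][A-Z]-[A-Z]$")


def parse_unit(text: str) -> SolubilityUnit:
    try:
        return _UNIT_ALIASES[str(text).strip().lower()]
    except KeyError:
        raise ValueError(f"unrecognized solubility unit: {text!r}") from None


def convert_to_logs(value: float, unit: SolubilityUnit, molecular_weight: float | None = None) -> float:
    """logS = log10 of solubility expressed in mol/L.

    Mass-based units require a positive molecular weight (g/mol); asking for
    a mass conversion without one is a hard error, never a silent skip.
    A zero or negative value is rejected (log undefined) — censored entries
    are handled at the record level, not here.
    """
    if not isinstance(unit, SolubilityUnit):
        unit = parse_unit(unit)
    if value <= 0 or not math.isfinite(value):
        raise ValueError(f"solubility value must be positive and finite, got {value}")
    if unit is SolubilityUnit.MOL_PER_L:
        mol_per_l = float(value)
    else:
        if molecular_weight is None or not (molecular_weight > 0):
            raise ValueError(
                f"molecular weight required (and > 0) to convert {unit.value}; got {molecular_weight}"
            )
        mol_per_l = float(value) * _MASS_TO_G_PER_L[unit] / float(molecular_weight)
    return math.log10(mol_per_l)


def logs_to_value(log_s: float, unit: SolubilityUnit, molecular_weight: float | None = None) -> float:
    """Inverse of :func:`convert_to_logs` (used for round-trip checks)."""
    mol_per_l = 10.0 ** log_s
    if unit is SolubilityUnit.MOL_PER_L:
        return mol_per_l
    if molecular_weight is None or molecular_weight <= 0:
        raise ValueError("molecular weight required for mass units")
    return mol_per_l * molecular_weight / _MASS_TO_G_PER_L[unit]


@dataclass
class CompoundRecord:
    """One curated molecule with solubility provenance."""

    compound_id: str
    smiles: str
    solubility_value: float | None = None
    solubility_unit: SolubilityUnit | None = None
    molecular_weight: float | None = None
    canonical_smiles: str | None = None
    inchikey: str | None = None
    log_s: float | None = None
    censored: bool = False
    valid: bool = True

    def validate(self) -> None:
        if self.solubility_value is not None and self.solubility_value < 0:
            raise ValueError("solubility_value must be >= 0")
        if self.molecular_weight is not None and self.molecular_weight <= 0:
            raise ValueError("molecular_weight must be > 0")
        if not self.censored and self.log_s is not None and not math.isfinite(self.log_s):
            raise ValueError("log_s must be finite for non-censored records")
        if self.inchikey is not None and not _INCHIKEY_RE.match(self.inchikey):
            raise ValueError(f"malformed InChIKey: {self.inchikey!r}")


@dataclass
class CuratedDataset:
    """Ordered records plus a per-record audit trail."""

    records: list[CompoundRecord] = field(default_factory=list)
    provenance_log: list[dict] = field(default_factory=list)

    def log(self, stage: str, action: str, compound_id: str | None = None, **detail) -> None:
        entry = {"stage": stage, "action": action}
        if compound_id is not None:
            entry["compound_id"] = compound_id
        entry.update(detail)
        self.provenance_log.append(entry)

    @property
    def valid_records(self) -> list[CompoundRecord]:
        return [r for r in self.records if r.valid]

    @property
    def modeling_records(self) -> list[CompoundRecord]:
        """Valid, non-censored records with a finite logS (regression rows)."""
        return [r for r in self.valid_records if not r.censored and r.log_s is not None]

    def to_frame(self) -> pd.DataFrame:
        """Curated table of the valid records (invalid rows live in the log)."""
        recs = self.valid_records
        return pd.DataFrame(
            {
                "compound_id": [r.compound_id for r in recs],
                "canonical_smiles": [r.canonical_smiles for r in recs],
                "inchikey": [r.inchikey for r in recs],
                "molecular_weight": [r.molecular_weight for r in recs],
                "log_s": [r.log_s for r in recs],
                "censored": [r.censored for r in recs],
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def write_provenance(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for entry in self.provenance_log:
                fh.write(json.dumps(entry) + "\n")


class ChemBackend(Protocol):
    """Pluggable chemistry provider: canonical SMILES, InChIKey, MW."""

    name: str

    def canonical_smiles(self, smiles: str) -> str: ...
    def inchikey(self, smiles: str) -> str: ...
    def molecular_weight(self, smiles: str) -> float: ...


class RDKitBackend:
    """Default chemistry backend built on RDKit.

    Canonical forms are toolkit-specific; the guarantee is internal
    consistency (two SMILES of the same molecule map to one canonical
    string and one InChIKey), not cross-toolkit identity.
    """

    name = "rdkit"

    def __init__(self) -> None:
        from rdkit import Chem, RDLogger
        from rdkit.Chem import Descriptors

        RDLogger.DisableLog("rdApp.*")  # parse errors are reported via provenance
        self._Chem = Chem
        self._Descriptors = Descriptors

    def _mol(self, smiles: str):
        mol = self._Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"SMILES rejected by RDKit: {smiles!r}")
        return mol

    def canonical_smiles(self, smiles: str) -> str:
        return self._Chem.MolToSmiles(self._mol(smiles))

    def inchikey(self, smiles: str) -> str:
        return self._Chem.MolToInchiKey(self._mol(smiles))

    def molecular_weight(self, smiles: str) -> float:
        return float(self._Descriptors.MolWt(self._mol(smiles)))


DEFAULT_COLUMNS = {
    "id": "id",
    "smiles": "smiles",
    "solubility": "solubility",
    "unit": "unit",
    "molecular_weight": "molecular_weight",  # optional
}


def parse_compound_table(
    path: str | Path,
    format_config: dict | None = None,
    sep: str | None = None,
) -> CuratedDataset:
    """Read a raw compound CSV/TSV into a pre-curation dataset.

    ``format_config`` maps the logical column names (id, smiles, solubility,
    unit, molecular_weight) to the file's headers.  A solubility cell
    beginning with '<' marks a censored ("below detection limit") entry; the
    threshold is kept as the value.  Rows that fail validation are retained
    as invalid records and logged with a reason.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cols = dict(DEFAULT_COLUMNS)
    if format_config:
        cols.update(format_config)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.empty:
        raise ValueError(f"empty compound table: {path}")
    for logical in ("smiles", "solubility", "unit"):
        if cols[logical] not in df.columns:
            raise KeyError(
                f"mandatory column {cols[logical]!r} (for {logical!r}) missing; "
                f"found {list(df.columns)}"
            )
    has_id = cols["id"] in df.columns
    has_mw = cols["molecular_weight"] in df.columns

    ds = CuratedDataset()
    ds.log("parse", "read_table", path=str(path), n_rows=int(len(df)))
    for i, row in df.iterrows():
        cid = str(row[cols["id"]]) if has_id and pd.notna(row[cols["id"]]) else f"row{i}"
        smiles = row[cols["smiles"]]
        raw_value = row[cols["solubility"]]
        raw_unit = row[cols["unit"]]
        try:
            if pd.isna(smiles) or not str(smiles).strip():
                raise ValueError("missing SMILES")
            unit = parse_unit(raw_unit)
            text = str(raw_value).strip()
            censored = text.startswith("<")
            value = float(text.lstrip("<"))
            if value < 0:
                raise ValueError("negative solubility")
            if value == 0 and not censored:
                raise ValueError("zero solubility (logS undefined); mark censored with '<'")
            mw = None
            if has_mw and pd.notna(row[cols["molecular_weight"]]):
                mw = float(row[cols["molecular_weight"]])
                if mw <= 0:
                    raise ValueError("non-positive molecular weight")
            rec = CompoundRecord(
                compound_id=cid,
                smiles=str(smiles).strip(),
                solubility_value=value,
                solubility_unit=unit,
                molecular_weight=mw,
                censored=censored,
            )
            ds.records.append(rec)
        except (ValueError, KeyError) as exc:
            ds.records.append(CompoundRecord(compound_id=cid, smiles=str(smiles), valid=False))
            ds.log("parse", "reject_row", compound_id=cid, reason=str(exc), row=int(i))
    return ds


def canonicalize_and_key(dataset: CuratedDataset, chem_backend: ChemBackend | None = None) -> CuratedDataset:
    """Populate canonical SMILES, InChIKey and (if absent) molecular weight.

    Records whose SMILES the backend rejects are flagged invalid and logged;
    they are excluded from all downstream modeling but never deleted.
    Computes logS once the molecular weight is known.
    """
    backend = chem_backend or RDKitBackend()
    dataset.log("canonicalize", "backend", backend=backend.name)
    for rec in dataset.records:
        if not rec.valid:
            continue
        try:
            rec.canonical_smiles = backend.canonical_smiles(rec.smiles)
            rec.inchikey = backend.inchikey(rec.smiles)
            if rec.molecular_weight is None:
                rec.molecular_weight = backend.molecular_weight(rec.smiles)
        except ValueError as exc:
            rec.valid = False
            dataset.log("canonicalize", "reject_smiles", compound_id=rec.compound_id, reason=str(exc))
            continue
        if not rec.censored and rec.log_s is None and rec.solubility_value is not None:
            try:
                rec.log_s = convert_to_logs(rec.solubility_value, rec.solubility_unit, rec.molecular_weight)
            except ValueError as exc:
                rec.valid = False
                dataset.log("canonicalize", "reject_conversion", compound_id=rec.compound_id, reason=str(exc))
        rec.validate()
    return dataset


def deduplicate(dataset: CuratedDataset) -> CuratedDataset:
    """Collapse duplicate structures by InChIKey.

    Among valid non-censored records sharing an InChIKey, the first
    occurrence is kept; when the group's logS values conflict the kept
    record carries the group's median logS.  All removed source values are
    logged.  Censored records are kept as-is (their logS is not comparable).
    """
    out = CuratedDataset(provenance_log=dataset.provenance_log)
    seen: dict[str, list[CompoundRecord]] = {}
    order: list[CompoundRecord] = []
    for rec in dataset.records:
        if not rec.valid or rec.censored or rec.inchikey is None:
            order.append(rec)
            continue
        group = seen.setdefault(rec.inchikey, [])
        group.append(rec)
        if len(group) == 1:
            order.append(rec)
        else:
            out.log(
                "deduplicate", "remove_duplicate",
                compound_id=rec.compound_id,
                inchikey=rec.inchikey,
                kept_id=group[0].compound_id,
                log_s=rec.log_s,
            )
    for rec in order:
        if rec.valid and not rec.censored and rec.inchikey in seen:
            group = seen[rec.inchikey]
            if len(group) > 1:
                values = [g.log_s for g in group if g.log_s is not None]
                med = float(np.median(values))
                if not math.isclose(med, rec.log_s, rel_tol=0, abs_tol=1e-12):
                    out.log(
                        "deduplicate", "median_logS",
                        compound_id=rec.compound_id,
                        inchikey=rec.inchikey,
                        source_values=values,
                        median=med,
                    )
                rec = replace(rec, log_s=med)
        out.records.append(rec)
    return out


def read_curated_csv(path: str | Path) -> CuratedDataset:
    """Load a curated table written by :meth:`CuratedDataset.write_csv`."""
    df = pd.read_csv(path)
    required = {"compound_id", "log_s", "censored"}
    if not required.issubset(df.columns):
        raise KeyError(f"curated table missing columns {sorted(required - set(df.columns))}")
    ds = CuratedDataset()
    ds.log("load", "read_curated", path=str(path), n_rows=int(len(df)))
    for _, row in df.iterrows():
        mw = row.get("molecular_weight")
        ls = row.get("log_s")
        ds.records.append(
            CompoundRecord(
                compound_id=str(row["compound_id"]),
                smiles=str(row.get("canonical_smiles", "")),
                canonical_smiles=row.get("canonical_smiles"),
                inchikey=row.get("inchikey") if pd.notna(row.get("inchikey")) else None,
                molecular_weight=float(mw) if pd.notna(mw) else None,
                log_s=float(ls) if pd.notna(ls) else None,
                censored=bool(row["censored"]),
            )
        )
    return ds


def curate(
    path: str | Path,
    format_config: dict | None = None,
    chem_backend: ChemBackend | None = None,
) -> CuratedDataset:
    """Full pipeline: parse -> canonicalize/key -> deduplicate."""
    ds = parse_compound_table(path, format_config=format_config)
    ds = canonicalize_and_key(ds, chem_backend=chem_backend)
    return deduplicate(ds)
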