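"""Reading, standardization, deduplication and labelling of probe libraries.

The curation pipeline mirrors common practice for literature-derived probe
datasets: every structure is canonicalized (keeping all disconnected
fragments — counterions carry targeting signal), hashed to an InChIKey for
duplicate detection, deduplicated within each label while cross-label
duplicates are retained, and finally distributed into the four task tables
of the multilevel framework:

* ``B-PvsC``  — mitochondria-targeted probes vs mitochondria-targeted
  non-probe compounds,
* ``B-MvsP``  — mitochondria-targeted probes vs probes for other organelles,
* ``M-PvsP``  — six-way organelle classification of probes,
* ``B-McoL``  — good vs weak mitochondrial colocalization, from MitoTracker
  correlation coefficients (mean r >= 0.8 is "good").
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

ORGANELLES = (
    "golgi",
    "endoplasmic_reticulum",
    "lysosome",
    "cell_membrane",
    "mitochondria",
    "nucleus",
)
ROLES = ("probe", "np_compound")
DESIGN_SETS = ("ESIPT", "ICT", "ALP", "ROS", "VIS")
TASKS = ("B-PvsC", "B-MvsP", "M-PvsP", "B-McoL")

#: MitoTracker Green / MitoTracker Red — the colocalization reference dyes.
DEFAULT_DYE_FILTER = frozenset({"MTG", "MTR"})

GOOD, WEAK, NOT_APPLICABLE = "good", "weak", "not_applicable"


class CurationError(ValueError):
    """Fatal curation failure (missing file/column, unkeyed record...)."""


@dataclass
class MoleculeRecord:
    smiles: str
    inchikey: Optional[str] = None
    role_label: Optional[str] = None
    organelle_label: Optional[str] = None
    coloc_records: list = field(default_factory=list)  # list[(dye, r)]
    design_set: Optional[str] = None
    source_id: Optional[str] = None

    def __post_init__(self):
        if self.role_label is not None and self.role_label not in ROLES:
            raise CurationError(f"unknown role label {self.role_label!r}")
        if self.organelle_label is not None and self.organelle_label not in ORGANELLES:
            raise CurationError(f"unknown organelle label {self.organelle_label!r}")
        for dye, r in self.coloc_records:
            if not -1.0 <= float(r) <= 1.0:
                raise CurationError(
                    f"colocalization coefficient {r} outside [-1, 1] for dye {dye!r}"
                )


@dataclass
class Reject:
    index: int
    smiles: str
    reason: str


@dataclass
class TaskTable:
    """Labelled rows for one prediction task, with the label domain enforced."""

    task: str
    rows: list = field(default_factory=list)  # list[(MoleculeRecord, label)]

    DOMAINS = {
        "B-PvsC": set(ROLES),
        "B-MvsP": {"mitochondria", "other"},
        "M-PvsP": set(ORGANELLES),
        "B-McoL": {GOOD, WEAK},
    }

    def __post_init__(self):
        if self.task not in self.DOMAINS:
            raise CurationError(f"unknown task {self.task!r}")
        domain = self.DOMAINS[self.task]
        seen = set()
        for rec, label in self.rows:
            if label not in domain:
                raise CurationError(f"label {label!r} outside domain of {self.task}")
            key = (rec.inchikey, label)
            if key in seen:
                raise CurationError(f"duplicate (inchikey, label) row {key} in {self.task}")
            seen.add(key)

    def __len__(self):
        return len(self.rows)

    @property
    def labels(self) -> list:
        return [label for _, label in self.rows]

    @property
    def records(self) -> list:
        return [rec for rec, _ in self.rows]


# ---------------------------------------------------------------------------
# parsing

CSV_COLUMNS = ("smiles", "role", "organelle", "coloc_dye", "coloc_r", "set", "id")


def _parse_coloc_cell(dye_cell, r_cell) -> list:
    """Parse semicolon-separated dye/r cells into (dye, r) pairs."""
    if pd.isna(r_cell) or str(r_cell).strip() == "":
        return []
    dyes = [d.strip() for d in str(dye_cell).split(";")] if not pd.isna(dye_cell) else []
    rs = [float(x) for x in str(r_cell).split(";")]
    if len(dyes) < len(rs):
        dyes += [""] * (len(rs) - len(dyes))
    return list(zip(dyes[: len(rs)], rs))


def parse_molecules(path, fmt: Optional[str] = None):
    """Read molecules from CSV / SMI / SDF.

    Returns ``(records, rejects)``; unparsable structures are collected as
    :class:`Reject` rows rather than silently dropped, so that
    ``len(records) + len(rejects)`` equals the number of input rows.
    """
    path = Path(path)
    if not path.exists():
        raise CurationError(f"input file not found: {path}")
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower() or "csv"
    fmt = fmt.lower()
    if fmt == "csv":
        return _parse_csv(path)
    if fmt == "smi":
        return _parse_smi(path)
    if fmt == "sdf":
        return _parse_sdf(path)
    raise CurationError(f"unsupported input format {fmt!r}")


def _check_parsable(smiles: str) -> Optional[str]:
    if not isinstance(smiles, str) or not smiles.strip():
        return "empty SMILES"
    if Chem.MolFromSmiles(smiles) is None:
        return "unparsable SMILES"
    return None


def _parse_csv(path):
    df = pd.read_csv(path, dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    if "smiles" not in df.columns:
        raise CurationError(f"{path}: no 'smiles' column (found {list(df.columns)})")
    records, rejects = [], []
    for i, row in df.iterrows():
        smiles = row.get("smiles")
        reason = _check_parsable(smiles if isinstance(smiles, str) else "")
        if reason:
            rejects.append(Reject(int(i), str(smiles), reason))
            continue

        def get(col):
            v = row.get(col)
            return None if v is None or pd.isna(v) or str(v).strip() == "" else str(v).strip()

        try:
            coloc = _parse_coloc_cell(row.get("coloc_dye"), row.get("coloc_r"))
            records.append(
                MoleculeRecord(
                    smiles=smiles.strip(),
                    role_label=get("role"),
                    organelle_label=get("organelle"),
                    coloc_records=coloc,
                    design_set=get("set"),
                    source_id=get("id"),
                )
            )
        except (CurationError, ValueError) as exc:
            rejects.append(Reject(int(i), str(smiles), str(exc)))
    return records, rejects


def _parse_smi(path):
    records, rejects = [], []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            source_id = parts[1].strip() if len(parts) > 1 else None
            reason = _check_parsable(smiles)
            if reason:
                rejects.append(Reject(i, smiles, reason))
            else:
                records.append(MoleculeRecord(smiles=smiles, source_id=source_id))
    return records, rejects


def _parse_sdf(path):
    records, rejects = [], []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            rejects.append(Reject(i, "", "unparsable SDF record"))
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else None
        records.append(MoleculeRecord(smiles=Chem.MolToSmiles(mol), source_id=name))
    return records, rejects


# ---------------------------------------------------------------------------
# standardization / dedup

def standardize_and_key(record: MoleculeRecord) -> MoleculeRecord:
    """Canonicalize the SMILES (keeping ALL fragments) and attach the InChIKey.

    Counterions are never stripped: disconnection and charge are predictive
    substructure signal (MACCS key 166 fires on multi-fragment structures),
    so salts are keyed and featurized as the full multi-component structure.
    """
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        raise CurationError(f"unparsable SMILES: {record.smiles!r}")
    canonical = Chem.MolToSmiles(mol)
    inchikey = Chem.MolToInchiKey(mol)
    if not inchikey:
        raise CurationError(f"InChI generation failed for {record.smiles!r}")
    return replace(record, smiles=canonical, inchikey=inchikey)


def standardize_all(records: Iterable[MoleculeRecord]):
    out, rejects = [], []
    for i, rec in enumerate(records):
        try:
            out.append(standardize_and_key(rec))
        except CurationError as exc:
            rejects.append(Reject(i, rec.smiles, str(exc)))
    return out, rejects


def deduplicate(records: Sequence[MoleculeRecord], merge_coloc: bool = True):
    """Drop within-label duplicates; keep cross-label duplicates.

    The label of a record is its (role, organelle) pair; within each label
    group the first occurrence of an InChIKey is kept (deterministic given
    input order).  With ``merge_coloc`` the colocalization records of dropped
    duplicates are folded into the kept record, so the per-molecule mean over
    multiple literature measurements is preserved.
    """
    seen = {}
    out = []
    for rec in records:
        if rec.inchikey is None:
            raise CurationError(f"record without InChIKey: {rec.smiles!r}")
        key = (rec.role_label, rec.organelle_label, rec.inchikey)
        if key in seen:
            if merge_coloc and rec.coloc_records:
                kept = seen[key]
                existing = set(map(tuple, kept.coloc_records))
                for pair in rec.coloc_records:
                    if tuple(pair) not in existing:
                        kept.coloc_records.append(pair)
            continue
        kept = replace(rec, coloc_records=list(rec.coloc_records))
        seen[key] = kept
        out.append(kept)
    return out


def label_colocalization(
    record: MoleculeRecord,
    threshold: float = 0.8,
    dye_filter: frozenset = DEFAULT_DYE_FILTER,
) -> str:
    """Label mitochondrial colocalization as good / weak / not_applicable.

    Only records whose dye is in ``dye_filter`` (MitoTracker Green/Red by
    default) count; the arithmetic mean of the matching coefficients is
    compared against ``threshold``, with the boundary mean == threshold
    labelled good ("not < 0.8").
    """
    if not 0.0 < threshold < 1.0:
        raise CurationError(f"threshold {threshold} outside (0, 1)")
    rs = []
    for dye, r in record.coloc_records:
        r = float(r)
        if not -1.0 <= r <= 1.0:
            raise CurationError(f"corrupt colocalization coefficient {r}")
        if dye in dye_filter:
            rs.append(r)
    if not rs:
        return NOT_APPLICABLE
    mean = sum(rs) / len(rs)
    return GOOD if mean >= threshold else WEAK


# ---------------------------------------------------------------------------
# task tables

def build_task_tables(
    records: Sequence[MoleculeRecord],
    coloc_threshold: float = 0.8,
    dye_filter: frozenset = DEFAULT_DYE_FILTER,
):
    """Assemble the four task tables; returns ``(tables, rejects)``.

    Membership rules: B-PvsC compares mitochondria-targeted probes with
    mitochondria-targeted non-probe compounds; B-MvsP compares mitochondria
    probes with all other-organelle probes; M-PvsP is the 6-class organelle
    table over probes; B-McoL covers mitochondria probes with applicable
    MitoTracker records.  A molecule may appear in several tables.
    """
    rows = {task: [] for task in TASKS}
    rejects = []
    for i, rec in enumerate(records):
        if rec.organelle_label is not None and rec.role_label is None:
            rejects.append(Reject(i, rec.smiles, "organelle label without role label"))
            continue
        if rec.role_label == "np_compound":
            if rec.organelle_label == "mitochondria":
                rows["B-PvsC"].append((rec, "np_compound"))
            continue
        if rec.role_label != "probe" or rec.organelle_label is None:
            continue
        rows["M-PvsP"].append((rec, rec.organelle_label))
        if rec.organelle_label == "mitochondria":
            rows["B-PvsC"].append((rec, "probe"))
            rows["B-MvsP"].append((rec, "mitochondria"))
            coloc = label_colocalization(rec, coloc_threshold, dye_filter)
            if coloc != NOT_APPLICABLE:
                rows["B-McoL"].append((rec, coloc))
        else:
            rows["B-MvsP"].append((rec, "other"))
    tables = {task: TaskTable(task, rows[task]) for task in TASKS}
    return tables, rejects


# ---------------------------------------------------------------------------
# I/O of curated tables

def write_curated(records: Sequence[MoleculeRecord], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["smiles", "inchikey", "role", "organelle", "coloc_dye", "coloc_r", "set", "id"])
        for rec in records:
            dyes = ";".join(d for d, _ in rec.coloc_records)
            rs = ";".join(repr(float(r)) for _, r in rec.coloc_records)
            w.writerow(
                [rec.smiles, rec.inchikey or "", rec.role_label or "",
                 rec.organelle_label or "", dyes, rs, rec.design_set or "",
                 rec.source_id or ""]
            )


def read_curated(path):
    records, rejects = _parse_csv(Path(path))
    df = pd.read_csv(path, dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    if "inchikey" in df.columns:
        # re-attach stored inchikeys by row order of successfully parsed rows
        reject_rows = {r.index for r in rejects}
        keys = [str(row["inchikey"]) for i, row in df.iterrows() if i not in reject_rows]
        for rec, key in zip(records, keys):
            if key and key != "nan":
                rec.inchikey = key
    return records, rejects


def write_rejects(rejects: Sequence[Reject], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["row", "smiles", "reason"])
        for r in rejects:
            w.writerow([r.index, r.smiles, r.reason])
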