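"""Molecular representations and the variance/correlation selection pipeline.

Fingerprint families:

``MACCS``
    The 166 published substructure keys, 1-based names ``MACCS1``..``MACCS166``
    (the toolkit's unused bit 0 is truncated), so key numbers cited in the
    structure-activity analysis resolve directly by name.
``ECFP4``
    Morgan circular fingerprint of radius 2 (diameter 4) hashed to ``nbits``
    (default 1024).
``AtomPair``
    Hashed atom-pair fingerprint.
``2D``
    The full RDKit 2D physicochemical/topological descriptor set (~210
    continuous and discrete descriptors: logP estimate, formal charge
    totals, surface-area proxies, topological indices, counts).

PubChem and CDK fingerprints are plug-in slots: external implementations can
be registered in :data:`FINGERPRINT_PLUGINS`; without a plug-in they raise
:class:`UnsupportedFamilyError`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, MACCSkeys, rdFingerprintGenerator

FAMILIES = ("MACCS", "ECFP4", "AtomPair", "PubChem", "CDK", "2D")
FINGERPRINT_PLUGINS: Dict[str, Callable] = {}


class UnsupportedFamilyError(ValueError):
    pass


class FeaturizationError(ValueError):
    pass


@dataclass
class FeatureMatrix:
    values: np.ndarray
    feature_names: list
    family: str
    row_keys: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FeaturizationError("feature matrix must be 2-D")
        n, d = self.values.shape
        if len(self.feature_names) != d:
            raise FeaturizationError("feature_names length mismatch")
        if len(set(self.feature_names)) != d:
            raise FeaturizationError("feature names must be unique")
        if len(self.row_keys) != n:
            raise FeaturizationError("row_keys length mismatch")

    @property
    def shape(self):
        return self.values.shape

    def subset_rows(self, idx) -> "FeatureMatrix":
        idx = np.asarray(idx)
        return FeatureMatrix(
            self.values[idx], list(self.feature_names), self.family,
            [self.row_keys[i] for i in idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.feature_names, index=self.row_keys)


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FeaturizationError(f"unparsable SMILES: {smiles!r}")
    return mol


_MACCS_NAMES = [f"MACCS{i}" for i in range(1, 167)]


def maccs_names() -> list:
    return list(_MACCS_NAMES)


def compute_fingerprint(smiles: str, family: str, nbits: int = 1024) -> np.ndarray:
    """Compute one bit-vector fingerprint; deterministic for a given input."""
    fam = family.upper() if family.lower() != "atompair" else "AtomPair"
    if fam == "MACCS":
        bv = MACCSkeys.GenMACCSKeys(_mol(smiles))  # 167 bits, bit 0 unused
        arr = np.zeros(166, dtype=float)
        for b in bv.GetOnBits():
            if b >= 1:
                arr[b - 1] = 1.0
        return arr
    if fam == "ECFP4":
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=nbits)
        return np.array(gen.GetFingerprintAsNumPy(_mol(smiles)), dtype=float)
    if fam == "ATOMPAIR" or family == "AtomPair":
        gen = rdFingerprintGenerator.GetAtomPairGenerator(fpSize=nbits)
        return np.array(gen.GetFingerprintAsNumPy(_mol(smiles)), dtype=float)
    if family in FINGERPRINT_PLUGINS:
        return np.asarray(FINGERPRINT_PLUGINS[family](smiles, nbits), dtype=float)
    if fam in ("PUBCHEM", "CDK"):
        raise UnsupportedFamilyError(
            f"{family} fingerprints require an external toolkit plug-in; "
            "register one in orgprobe.featurize.FINGERPRINT_PLUGINS"
        )
    raise UnsupportedFamilyError(f"unknown fingerprint family {family!r}")


_DESCRIPTOR_NAMES = [name for name, _ in Descriptors.descList]


def descriptor_names() -> list:
    return list(_DESCRIPTOR_NAMES)


def compute_descriptors2d(smiles: str) -> np.ndarray:
    """Fixed-length vector of 2D descriptors; failures are recorded as NaN
    and handled downstream by :func:`select_features` cleaning."""
    mol = _mol(smiles)
    out = np.empty(len(_DESCRIPTOR_NAMES), dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, (_, fn) in enumerate(Descriptors.descList):
            try:
                v = fn(mol)
                out[i] = float(v) if np.isfinite(float(v)) else np.nan
            except Exception:
                out[i] = np.nan
    return out


def _canonical_family(family: str) -> str:
    low = family.lower()
    if low == "2d":
        return "2D"
    if low == "atompair":
        return "AtomPair"
    return family.upper()


def _family_feature_names(family: str, nbits: int) -> list:
    if family == "2D":
        return descriptor_names()
    if family == "MACCS":
        return maccs_names()
    return [f"{family}{i}" for i in range(nbits)]


def featurize_records(records: Sequence, family: str, nbits: int = 1024) -> FeatureMatrix:
    """Featurize curated molecule records; rows keyed by InChIKey (or SMILES)."""
    fam = _canonical_family(family)
    names = _family_feature_names(fam, nbits)
    rows, keys = [], []
    for rec in records:
        smiles = rec.smiles if hasattr(rec, "smiles") else str(rec)
        key = getattr(rec, "inchikey", None) or smiles
        if fam == "2D":
            rows.append(compute_descriptors2d(smiles))
        else:
            rows.append(compute_fingerprint(smiles, fam, nbits))
        keys.append(key)
    values = np.vstack(rows) if rows else np.empty((0, len(names)))
    return FeatureMatrix(values, names, fam, keys)


# ---------------------------------------------------------------------------
# feature selection

@dataclass
class SelectionReport:
    kept: list = field(default_factory=list)
    dropped: list = field(default_factory=list)  # list[(name, reason)]
    imputed: dict = field(default_factory=dict)  # name -> median used


def select_features(
    matrix: FeatureMatrix,
    corr_cut: float = 0.95,
    nan_frac_cut: float = 0.10,
):
    """Variance / correlation feature selection.

    Deterministic greedy scan in column order: (0) columns with more than
    ``nan_frac_cut`` missing values are dropped, remaining NaNs are imputed
    with the column median; (1) zero-variance columns are dropped; (2) a
    column is dropped when its absolute Pearson correlation with any
    already-kept column exceeds ``corr_cut`` (keep-first tie policy).
    Returns ``(selected_matrix, SelectionReport)``.
    """
    n, d = matrix.shape
    if n < 2:
        raise FeaturizationError("feature selection needs at least 2 rows")
    X = matrix.values.copy()
    report = SelectionReport()

    usable = []
    for j in range(d):
        col = X[:, j]
        nan_mask = ~np.isfinite(col)
        if nan_mask.mean() > nan_frac_cut:
            report.dropped.append((matrix.feature_names[j], "missing"))
            continue
        if nan_mask.any():
            med = float(np.nanmedian(col))
            col = np.where(nan_mask, med, col)
            X[:, j] = col
            report.imputed[matrix.feature_names[j]] = med
        usable.append(j)

    kept_idx = []
    Z = np.empty((n, 0))
    for j in usable:
        col = X[:, j]
        sd = col.std()
        if sd == 0:
            report.dropped.append((matrix.feature_names[j], "zero_variance"))
            continue
        z = (col - col.mean()) / sd
        if kept_idx:
            corr = np.abs(Z.T @ z) / n
            if np.any(corr > corr_cut):
                anchor = kept_idx[int(np.argmax(corr))]
                report.dropped.append(
                    (matrix.feature_names[j], f"corr>{corr_cut} with {matrix.feature_names[anchor]}")
                )
                continue
        kept_idx.append(j)
        Z = np.column_stack([Z, z])

    report.kept = [matrix.feature_names[j] for j in kept_idx]
    selected = FeatureMatrix(
        X[:, kept_idx], report.kept, matrix.family, list(matrix.row_keys)
    )
    return selected, report


def apply_selection(matrix: FeatureMatrix, report: SelectionReport) -> FeatureMatrix:
    """Apply a fitted selection (kept columns + imputation medians) to new data,
    e.g. a test partition, without refitting (leakage-safe)."""
    name_to_idx = {n: i for i, n in enumerate(matrix.feature_names)}
    idx = [name_to_idx[n] for n in report.kept]
    X = matrix.values[:, idx].copy()
    for col_pos, name in enumerate(report.kept):
        if name in report.imputed:
            mask = ~np.isfinite(X[:, col_pos])
            X[mask, col_pos] = report.imputed[name]
        else:
            X[:, col_pos] = np.nan_to_num(X[:, col_pos], nan=0.0)
    return FeatureMatrix(X, list(report.kept), matrix.family, list(matrix.row_keys))
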