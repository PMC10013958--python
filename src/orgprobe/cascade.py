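"""The multilevel predictor: chain the four trained models.

Level 1 (probe vs non-probe compound) always runs.  For predicted probes,
level 2 (mitochondria vs other, binary) and level 3 (six-way organelle)
both run — level 3 re-examines every probe regardless of level 2's verdict,
and a disagreement between the two on mitochondria-vs-other is flagged
rather than silently resolved.  Level 4 (good vs weak colocalization) is
gated on the level-3 verdict being mitochondria: the multiclass
probabilities carry more information than the binary output label under
class imbalance.  Each level may use its own feature family; molecules are
featurized per level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .featurize import featurize_records
from .imbalance import smote
from .model_lab import FittedModel, ModelSpec, train_model
from .molecule_io import (
    GOOD,
    MoleculeRecord,
    ORGANELLES,
    Reject,
    build_task_tables,
)

LEVELS = ("b_pvsc", "b_mvsp", "m_pvsp", "b_mcol")

#: feature family per level used by default (the best-performing pairing:
#: ECFP4 for probe detection, MACCS for targeting, 2D for colocalization).
DEFAULT_FAMILIES = {
    "b_pvsc": "ECFP4",
    "b_mvsp": "MACCS",
    "m_pvsp": "MACCS",
    "b_mcol": "2D",
}

DEFAULT_ALGORITHMS = {
    "b_pvsc": "logistic_regression",
    "b_mvsp": "lightgbm",
    "m_pvsp": "lightgbm",
    "b_mcol": "lightgbm",
}


class CascadeError(ValueError):
    pass


@dataclass
class CascadeModels:
    models: Dict[str, FittedModel]
    families: Dict[str, str]
    nbits: int = 1024

    def __post_init__(self):
        missing = [lv for lv in LEVELS if lv not in self.models]
        if missing:
            raise CascadeError(f"missing cascade levels: {missing}")


@dataclass
class CascadeResult:
    key: str
    design_set: Optional[str]
    level1: str = ""
    level1_prob: float = np.nan           # P(probe)
    level2: Optional[str] = None
    level2_prob: float = np.nan           # P(mitochondria)
    level3: Optional[str] = None
    level3_probs: Optional[dict] = None   # organelle -> probability
    level4: Optional[str] = None
    level4_prob: float = np.nan           # P(good)
    terminal_category: str = ""
    disagreement: bool = False
    uncertain: bool = False


def train_cascade(
    records: Sequence[MoleculeRecord],
    seed: int = 0,
    families: Optional[Dict[str, str]] = None,
    algorithms: Optional[Dict[str, str]] = None,
    nbits: int = 1024,
    oversample_mcol: bool = True,
) -> CascadeModels:
    """Train the four level models from a curated, deduplicated library.

    The colocalization level is SMOTE-balanced (minority oversampled to
    parity) before fitting, mirroring how the weak class is handled.
    """
    families = {**DEFAULT_FAMILIES, **(families or {})}
    algorithms = {**DEFAULT_ALGORITHMS, **(algorithms or {})}
    tables, _ = build_task_tables(records)
    task_of = {"b_pvsc": "B-PvsC", "b_mvsp": "B-MvsP", "m_pvsp": "M-PvsP", "b_mcol": "B-McoL"}
    models = {}
    for level in LEVELS:
        table = tables[task_of[level]]
        if len(table) == 0:
            raise CascadeError(f"empty task table for level {level}")
        fm = featurize_records(table.records, families[level], nbits)
        X, y = fm.values, np.asarray(table.labels)
        X = np.nan_to_num(X, nan=0.0, posinf=0.0, neginf=0.0)
        if level == "b_mcol" and oversample_mcol and len(np.unique(y)) == 2:
            res = smote(X, y, seed=seed)
            X, y = res.X_out, res.y_out
        spec = ModelSpec(algorithms[level], seed=seed)
        models[level] = train_model(
            spec, X, y, feature_names=list(fm.feature_names), family=fm.family
        )
    return CascadeModels(models, families, nbits)


def _batch_features(records, family: str, nbits: int) -> np.ndarray:
    fm = featurize_records(records, family, nbits)
    return np.nan_to_num(fm.values, nan=0.0, posinf=0.0, neginf=0.0)


def _prob_of(model: FittedModel, proba_row: np.ndarray, label) -> float:
    idx = np.flatnonzero(model.classes == label)
    return float(proba_row[idx[0]]) if len(idx) else 0.0


def predict_cascade(
    molecule: MoleculeRecord,
    models: CascadeModels,
    consensus: bool = False,
) -> CascadeResult:
    """Run one molecule through the four levels."""
    results, rejects = run_library([molecule], models, consensus=consensus)
    if rejects:
        raise CascadeError(rejects[0].reason)
    return results[0]


def run_library(
    library: Sequence[MoleculeRecord],
    models: CascadeModels,
    consensus: bool = False,
):
    """Run a molecule library through the cascade.

    Returns ``(results, rejects)``; use :func:`flow_table` for the
    level-to-level (Sankey) accounting.
    """
    if len(library) == 0:
        raise CascadeError("empty library")
    valid, rejects = [], []
    from rdkit import Chem

    for i, rec in enumerate(library):
        if Chem.MolFromSmiles(rec.smiles) is None:
            rejects.append(Reject(i, rec.smiles, "unparsable SMILES"))
        else:
            valid.append(rec)
    if not valid:
        return [], rejects

    results = [
        CascadeResult(
            key=rec.inchikey or rec.smiles, design_set=rec.design_set
        )
        for rec in valid
    ]

    # level 1: probe vs np_compound, always evaluated
    m1 = models.models["b_pvsc"]
    X1 = _batch_features(valid, models.families["b_pvsc"], models.nbits)
    p1 = m1.predict_proba(X1)
    lab1 = m1.predict(X1)
    probe_idx = []
    for i, res in enumerate(results):
        res.level1 = str(lab1[i])
        res.level1_prob = _prob_of(m1, p1[i], "probe")
        if lab1[i] == "probe":
            probe_idx.append(i)
        else:
            res.terminal_category = "np_compound"

    if probe_idx:
        probes = [valid[i] for i in probe_idx]
        # level 2: binary mitochondria vs other
        m2 = models.models["b_mvsp"]
        X2 = _batch_features(probes, models.families["b_mvsp"], models.nbits)
        p2, lab2 = m2.predict_proba(X2), m2.predict(X2)
        # level 3: six-way organelle — runs for every probe, even when level 2
        # said "other"
        m3 = models.models["m_pvsp"]
        X3 = _batch_features(probes, models.families["m_pvsp"], models.nbits)
        p3, lab3 = m3.predict_proba(X3), m3.predict(X3)

        mito_idx = []
        for j, i in enumerate(probe_idx):
            res = results[i]
            res.level2 = str(lab2[j])
            res.level2_prob = _prob_of(m2, p2[j], "mitochondria")
            res.level3 = str(lab3[j])
            res.level3_probs = {
                str(c): float(p) for c, p in zip(m3.classes, p3[j])
            }
            l2_mito = lab2[j] == "mitochondria"
            l3_mito = lab3[j] == "mitochondria"
            res.disagreement = l2_mito != l3_mito
            if consensus and l3_mito and res.level3_probs.get("mitochondria", 0.0) < 0.5:
                res.uncertain = True
            if l3_mito:
                mito_idx.append(i)
            else:
                res.terminal_category = res.level3

        if mito_idx:
            mitos = [valid[i] for i in mito_idx]
            m4 = models.models["b_mcol"]
            X4 = _batch_features(mitos, models.families["b_mcol"], models.nbits)
            p4, lab4 = m4.predict_proba(X4), m4.predict(X4)
            for j, i in enumerate(mito_idx):
                res = results[i]
                res.level4 = str(lab4[j])
                res.level4_prob = _prob_of(m4, p4[j], GOOD)
                res.terminal_category = f"mitochondria / {lab4[j]} colocalization"
    return results, rejects


def flow_table(results: Sequence[CascadeResult]) -> pd.DataFrame:
    """Per design-set counts of every level-to-level transition (source node,
    target node, count) — the Sankey accounting."""
    edges = {}

    def add(ds, src, dst):
        k = (ds or "all", src, dst)
        edges[k] = edges.get(k, 0) + 1

    for res in results:
        ds = res.design_set
        add(ds, "library", res.level1)
        if res.level1 != "probe":
            continue
        add(ds, "probe", f"L2:{res.level2}")
        add(ds, f"L2:{res.level2}", f"L3:{res.level3}")
        if res.level4 is not None:
            add(ds, "L3:mitochondria", f"L4:{res.level4}")
    rows = [
        {"set": ds, "source": src, "target": dst, "count": n}
        for (ds, src, dst), n in sorted(edges.items())
    ]
    return pd.DataFrame(rows, columns=["set", "source", "target", "count"])


def results_frame(results: Sequence[CascadeResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "key": r.key, "set": r.design_set, "level1": r.level1,
            "p_probe": r.level1_prob, "level2": r.level2,
            "p_mito_binary": r.level2_prob, "level3": r.level3,
            "level4": r.level4, "p_good_coloc": r.level4_prob,
            "terminal": r.terminal_category, "disagreement": r.disagreement,
            "uncertain": r.uncertain,
        }
        for org in ORGANELLES:
            row[f"p_{org}"] = (r.level3_probs or {}).get(org, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
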