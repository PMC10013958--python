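"""Feature attribution: SHAP values, gain importance, consensus rankings.

SHAP values for gradient-boosting models are the exact tree-path (TreeSHAP)
attributions computed natively by LightGBM and XGBoost; linear models use
the closed-form ``coef * (x - mean(x))`` attribution.  Per-sample
attributions plus the base value reproduce the model margin exactly
(additivity), which is asserted by the test suite.

Rankings from mean |SHAP| and from split-gain importance are Min-Max
normalized and intersected at Top-k (k = 15/30/50) to extract consensus
structural rules; the shipped MACCS key-definition table supports
heteroatom/charge composition analysis of the consensus sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .featurize import FeatureMatrix
from .model_lab import FittedModel


class InterpretError(ValueError):
    pass


@dataclass
class Attribution:
    """Per-sample, per-feature SHAP values.

    ``values`` has shape (n, d) for binary/linear models (positive-class
    margin) and (n, k, d) for multiclass models; ``base`` is the scalar (or
    per-class) expected margin.
    """

    values: np.ndarray
    base: np.ndarray
    feature_names: list
    classes: Optional[np.ndarray] = None

    def for_class(self, label=None) -> np.ndarray:
        """Attributions oriented toward ``label``.

        Binary margins are emitted for the second class; asking for the
        first class flips the sign so 'positive' always means 'pushes the
        prediction toward the requested class'.
        """
        if self.values.ndim == 2:
            if label is None or self.classes is None:
                return self.values
            hits = np.flatnonzero(self.classes == label)
            if len(hits) == 0:
                raise InterpretError(f"unknown class label {label!r}")
            return self.values if hits[0] == len(self.classes) - 1 else -self.values
        if label is None:
            raise InterpretError("multiclass attribution needs a class label")
        hits = np.flatnonzero(self.classes == label)
        if len(hits) == 0:
            raise InterpretError(f"unknown class label {label!r}")
        return self.values[:, int(hits[0]), :]


def _unwrap(model):
    if isinstance(model, FittedModel):
        return model.estimator, model.scaler, model.feature_names, model.classes
    return model, None, None, None


def shap_attributions(model, X) -> Attribution:
    """Exact SHAP attribution matrix for a supported model.

    Supported: LightGBM and XGBoost classifiers (native TreeSHAP) and linear
    models with ``coef_`` (closed form).  Anything else raises with the
    offending type named.
    """
    est, scaler, names, classes = _unwrap(model)
    if isinstance(X, FeatureMatrix):
        names = names or list(X.feature_names)
        X = X.values
    X = np.asarray(X, dtype=float)
    if scaler is not None:
        X = scaler.transform(X)
    if names is None:
        names = [f"f{i}" for i in range(X.shape[1])]
    d = X.shape[1]

    kind = type(est).__name__
    mod = type(est).__module__
    if mod.startswith("lightgbm"):
        contrib = est.booster_.predict(X, pred_contrib=True)
        n_classes = est.n_classes_
        if n_classes > 2:
            contrib = contrib.reshape(X.shape[0], n_classes, d + 1)
            return Attribution(
                contrib[:, :, :d], contrib[0, :, d], list(names), classes
            )
        return Attribution(contrib[:, :d], np.asarray(contrib[0, d]), list(names), classes)
    if mod.startswith("xgboost"):
        import xgboost as xgb

        booster = est.get_booster()
        contrib = booster.predict(xgb.DMatrix(X), pred_contribs=True)
        if contrib.ndim == 3:  # (n, k, d+1)
            return Attribution(
                contrib[:, :, :d], contrib[0, :, d], list(names), classes
            )
        return Attribution(contrib[:, :d], np.asarray(contrib[0, d]), list(names), classes)
    if hasattr(est, "coef_"):
        coef = np.asarray(est.coef_, dtype=float)
        mean = X.mean(axis=0)
        if coef.shape[0] == 1:
            phi = (X - mean) * coef[0]
            base = float(mean @ coef[0] + np.ravel(est.intercept_)[0])
            return Attribution(phi, np.asarray(base), list(names), classes)
        phi = (X[:, None, :] - mean) * coef[None, :, :]
        base = mean @ coef.T + np.asarray(est.intercept_, dtype=float)
        return Attribution(phi, base, list(names), classes)
    raise InterpretError(f"unsupported model type for SHAP attribution: {kind}")


def gain_importance(model) -> pd.Series:
    """Split-gain feature importance of a gradient-boosting model."""
    est, _, names, _ = _unwrap(model)
    mod = type(est).__module__
    if mod.startswith("lightgbm"):
        gains = est.booster_.feature_importance(importance_type="gain")
        feat = est.booster_.feature_name()
    elif mod.startswith("xgboost"):
        booster = model.estimator.get_booster() if isinstance(model, FittedModel) else est.get_booster()
        score = booster.get_score(importance_type="gain")
        feat = [f"f{i}" for i in range(len(names or []))] if names else list(score)
        gains = [score.get(f, 0.0) for f in feat]
    elif hasattr(est, "feature_importances_"):
        gains = est.feature_importances_
        feat = None
    else:
        raise InterpretError(
            f"no gain importance for model type {type(est).__name__}"
        )
    if names is not None and len(names) == len(gains):
        feat = names
    return pd.Series(np.asarray(gains, dtype=float), index=feat, name="gain")


def split_count_importance(model) -> pd.Series:
    est, _, names, _ = _unwrap(model)
    mod = type(est).__module__
    if mod.startswith("lightgbm"):
        counts = est.booster_.feature_importance(importance_type="split")
    elif hasattr(est, "feature_importances_"):
        counts = est.feature_importances_
    else:
        raise InterpretError(f"no split importance for {type(est).__name__}")
    idx = names if names and len(names) == len(counts) else None
    return pd.Series(np.asarray(counts, dtype=float), index=idx, name="split")


# ---------------------------------------------------------------------------
# rankings

def minmax_normalize(scores: pd.Series) -> pd.Series:
    """Scale scores to [0, 1] with max = 1; constant input maps to zeros."""
    s = scores.astype(float)
    lo, hi = s.min(), s.max()
    if hi == lo:
        return pd.Series(np.zeros(len(s)), index=s.index, name=s.name)
    return (s - lo) / (hi - lo)


def rank_features(scores: pd.Series) -> list:
    """Features ordered by descending score, ties broken by name."""
    df = pd.DataFrame({"score": scores.astype(float)})
    df["name"] = df.index
    df = df.sort_values(["score", "name"], ascending=[False, True], kind="mergesort")
    return list(df["name"])


def mean_abs_shap(attribution: Attribution, class_label=None) -> pd.Series:
    vals = attribution.for_class(class_label)
    return pd.Series(
        np.abs(vals).mean(axis=0), index=attribution.feature_names, name="mean_abs_shap"
    )


def topk_consensus(rank_a: Sequence[str], rank_b: Sequence[str], k: int) -> set:
    """Intersection of the two Top-k ranking prefixes."""
    if set(rank_a) != set(rank_b):
        raise InterpretError("rankings cover different feature universes")
    if k > len(rank_a):
        raise InterpretError(f"k={k} exceeds universe size {len(rank_a)}")
    return set(rank_a[:k]) & set(rank_b[:k])


# ---------------------------------------------------------------------------
# MACCS key composition

def load_maccs_table() -> pd.DataFrame:
    with resources.files("orgprobe.data").joinpath("maccs_keys.csv").open() as fh:
        return pd.read_csv(fh).set_index("name")


@dataclass
class KeyComposition:
    fraction: float
    heteroatom_keys: set
    charge_keys: set
    disconnection_keys: set


def classify_keys(features: Sequence[str], table: Optional[pd.DataFrame] = None) -> KeyComposition:
    if table is None:
        table = load_maccs_table()
    het, charge, disc = set(), set(), set()
    features = list(features)
    for f in features:
        if f not in table.index:
            raise InterpretError(f"unknown MACCS feature name {f!r}")
        row = table.loc[f]
        if row["heteroatom_nop"]:
            het.add(f)
        if row["charge"]:
            charge.add(f)
        if row["disconnection"]:
            disc.add(f)
    frac = len(het) / len(features) if features else 0.0
    return KeyComposition(frac, het, charge, disc)


def heteroatom_fraction(features: Sequence[str], table: Optional[pd.DataFrame] = None) -> float:
    """Fraction of the feature set whose key definition mentions N, O or P;
    charge/disconnection keys are reported separately by :func:`classify_keys`."""
    return classify_keys(features, table).fraction


# ---------------------------------------------------------------------------
# directional summary

def directional_summary(
    attribution: Attribution,
    X,
    class_label=None,
    dead_zone: float = 1e-6,
) -> pd.DataFrame:
    """Per-feature sign of the mean SHAP among samples where the feature is
    active (value > 0); |mean| below ``dead_zone`` is 'neutral'."""
    if isinstance(X, FeatureMatrix):
        X = X.values
    X = np.asarray(X, dtype=float)
    vals = attribution.for_class(class_label)
    rows = []
    for j, name in enumerate(attribution.feature_names):
        active = X[:, j] > 0
        mean = float(vals[active, j].mean()) if active.any() else 0.0
        sign = "neutral" if abs(mean) < dead_zone else ("positive" if mean > 0 else "negative")
        rows.append({"feature": name, "n_active": int(active.sum()),
                     "mean_shap_active": mean, "sign": sign})
    return pd.DataFrame(rows).set_index("feature")


# ---------------------------------------------------------------------------
# combined report

@dataclass
class AttributionReport:
    table: pd.DataFrame                 # per-feature scores/ranks
    consensus: Dict[int, set]           # k -> consensus feature set
    heteroatom_fraction_top50: Optional[float]
    directional: pd.DataFrame
    shap_rank: list
    gain_rank: list


def attribution_report(
    model,
    X,
    ks: Sequence[int] = (15, 30, 50),
    class_label=None,
    maccs: Optional[bool] = None,
) -> AttributionReport:
    """Full attribution analysis of one trained model on matrix ``X``."""
    attr = shap_attributions(model, X)
    shap_scores = mean_abs_shap(attr, class_label)
    signed = pd.Series(
        attr.for_class(class_label).mean(axis=0),
        index=attr.feature_names, name="mean_signed_shap",
    )
    gain = gain_importance(model)
    gain = gain.reindex(shap_scores.index).fillna(0.0)

    shap_rank = rank_features(shap_scores)
    gain_rank = rank_features(gain)
    consensus = {k: topk_consensus(shap_rank, gain_rank, k) for k in ks if k <= len(shap_rank)}

    table = pd.DataFrame({
        "mean_abs_shap": shap_scores,
        "mean_signed_shap": signed,
        "gain": gain,
        "shap_norm": minmax_normalize(shap_scores),
        "gain_norm": minmax_normalize(gain),
    })
    table["shap_rank"] = [shap_rank.index(f) + 1 for f in table.index]
    table["gain_rank"] = [gain_rank.index(f) + 1 for f in table.index]

    if maccs is None:
        maccs = all(str(f).startswith("MACCS") for f in shap_scores.index)
    het = None
    if maccs and len(shap_rank) >= 50:
        het = heteroatom_fraction(shap_rank[:50])

    directional = directional_summary(attr, X, class_label)
    return AttributionReport(table, consensus, het, directional, shap_rank, gain_rank)
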