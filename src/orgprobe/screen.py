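"""Post-cascade candidate screening on precomputed ADMET-style properties.

Properties arrive as a table (they come from a hosted prediction platform,
not from this package): ``toxicity`` is the probability of high rat oral
acute toxicity in [0, 1], ``sa`` the synthetic accessibility score in
[1, 10] (1 = very easy), ``logp`` the octanol/water partition estimate.
Candidates that terminate the cascade at "mitochondria / good
colocalization" and satisfy every screening rule are ranked by
(low toxicity, low synthetic accessibility, high logP); rule flags are
reported per candidate, and a manual ``keep`` list can override filtering
(human judgment legitimately overrides the lipophilicity rule).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

PROPERTY_RANGES = {"toxicity": (0.0, 1.0), "sa": (1.0, 10.0)}

GOOD_TERMINAL = "mitochondria / good colocalization"


class ScreenError(ValueError):
    pass


@dataclass(frozen=True)
class ScreeningRule:
    prop: str
    direction: str  # max_allowed | min_allowed | range
    low: Optional[float] = None
    high: Optional[float] = None
    rationale: str = ""

    def __post_init__(self):
        if self.direction not in ("max_allowed", "min_allowed", "range"):
            raise ScreenError(f"unknown rule direction {self.direction!r}")
        if self.direction == "range" and not (self.low is not None and self.high is not None and self.low < self.high):
            raise ScreenError("range rule needs low < high")

    def passes(self, value: float) -> bool:
        if not np.isfinite(value):
            return False
        if self.direction == "max_allowed":
            return value <= self.high
        if self.direction == "min_allowed":
            return value >= self.low
        return self.low <= value <= self.high

    @property
    def label(self) -> str:
        if self.direction == "max_allowed":
            return f"{self.prop}<={self.high}"
        if self.direction == "min_allowed":
            return f"{self.prop}>={self.low}"
        return f"{self.prop} in {self.low}..{self.high}"


_RULE_RE = re.compile(
    r"^\s*(?P<prop>\w+)\s*(?:(?P<op><=|>=)\s*(?P<val>[-\d.]+)"
    r"|in\s*(?P<lo>[-\d.]+)\s*\.\.\s*(?P<hi>[-\d.]+))\s*$"
)


def parse_rule(text: str) -> ScreeningRule:
    """Parse rules like ``"toxicity<=0.3"``, ``"sa<=6"``, ``"logp in 1..6"``."""
    m = _RULE_RE.match(text)
    if not m:
        raise ScreenError(f"cannot parse screening rule {text!r}")
    prop = m.group("prop").lower()
    if m.group("op") == "<=":
        return ScreeningRule(prop, "max_allowed", high=float(m.group("val")))
    if m.group("op") == ">=":
        return ScreeningRule(prop, "min_allowed", low=float(m.group("val")))
    return ScreeningRule(prop, "range", low=float(m.group("lo")), high=float(m.group("hi")))


def load_property_table(source, key_column: str = "key"):
    """Load and validate the property table; returns ``(table, rejects)``.

    Rows with non-numeric or out-of-range values (toxicity outside [0, 1],
    synthetic accessibility outside [1, 10]) are rejected with a reason.
    """
    df = source.copy() if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    df.columns = [c.strip().lower() for c in df.columns]
    if key_column not in df.columns:
        raise ScreenError(f"property table needs a {key_column!r} column")
    rejects = []
    keep_mask = np.ones(len(df), dtype=bool)
    for i, row in df.iterrows():
        for col in df.columns:
            if col == key_column:
                continue
            try:
                v = float(row[col])
            except (TypeError, ValueError):
                rejects.append((row[key_column], col, f"non-numeric value {row[col]!r}"))
                keep_mask[df.index.get_loc(i)] = False
                break
            lo, hi = PROPERTY_RANGES.get(col, (-np.inf, np.inf))
            if not (lo <= v <= hi) and np.isfinite(v):
                rejects.append((row[key_column], col, f"value {v} outside [{lo}, {hi}]"))
                keep_mask[df.index.get_loc(i)] = False
                break
    table = df.loc[keep_mask].set_index(key_column)
    table = table.astype(float)
    return table, rejects


def filter_candidates(
    cascade_results,
    properties: pd.DataFrame,
    rules: Sequence[ScreeningRule],
    keep: Optional[Sequence[str]] = None,
    terminal: str = GOOD_TERMINAL,
) -> pd.DataFrame:
    """Rank-screen the cascade's good-colocalization candidates.

    Returns one row per candidate with per-rule pass flags; rows passing all
    rules (or listed in ``keep``) are flagged ``selected`` and the frame is
    ordered by (toxicity asc, synthetic accessibility asc, logP desc),
    selected rows first.
    """
    if not isinstance(cascade_results, pd.DataFrame):
        from .cascade import results_frame

        cascade_results = results_frame(cascade_results)
    if not rules:
        warnings.warn("empty rule set: pass-through screening", stacklevel=2)
    for rule in rules:
        if rule.prop not in properties.columns:
            raise ScreenError(f"rule on missing property {rule.prop!r}")

    cand = cascade_results[cascade_results["terminal"] == terminal].copy()
    missing = [k for k in cand["key"] if k not in properties.index]
    if missing:
        warnings.warn(
            f"{len(missing)} cascade candidates missing from the property table",
            stacklevel=2,
        )
    cand = cand[cand["key"].isin(properties.index)]
    rows = []
    for _, c in cand.iterrows():
        props = properties.loc[c["key"]]
        row = {"key": c["key"], "set": c.get("set")}
        for col in properties.columns:
            row[col] = float(props[col])
        passed = True
        for rule in rules:
            ok = rule.passes(float(props[rule.prop]))
            row[f"pass[{rule.label}]"] = ok
            passed = passed and ok
        row["passes_all"] = passed
        row["kept_manually"] = bool(keep and c["key"] in set(keep))
        row["selected"] = passed or row["kept_manually"]
        rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    sort_cols, ascending = ["selected"], [False]
    for col, asc in (("toxicity", True), ("sa", True), ("logp", False)):
        if col in out.columns:
            sort_cols.append(col)
            ascending.append(asc)
    return out.sort_values(sort_cols, ascending=ascending, kind="mergesort").reset_index(drop=True)


def property_summary(properties: pd.DataFrame, quantiles=(0.05, 0.25, 0.5, 0.75, 0.95)) -> pd.DataFrame:
    """Distribution summary (quantiles, mean) per property over a library."""
    rows = []
    for col in properties.columns:
        v = properties[col].astype(float).dropna()
        row = {"property": col, "mean": v.mean()}
        for q in quantiles:
            row[f"q{q}"] = float(v.quantile(q))
        rows.append(row)
    return pd.DataFrame(rows).set_index("property")
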