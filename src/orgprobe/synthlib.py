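"""Seeded synthetic molecule-library generator with planted, recoverable signal.

The generator emulates the statistical shape of a literature-curated
organelle-probe library without any external data:

* mitochondria-class molecules carry a cationic anchor (triarylphosphonium,
  vinyl-pyridinium or quaternary ammonium, with a halide counterion) with
  probability ``1 - label_noise``, plus extra lipophilic alkyl branches —
  the charge/phosphorus/vinyl/ethyl/fragment MACCS keys this plants are the
  generator's declared ground truth;
* lysosome-class molecules carry basic amine heads (morpholine,
  dimethylamino), deliberately confusable with mitochondria;
* the remaining organelle classes and the non-probe compounds get their own
  neutral decorations on the shared conjugated scaffolds;
* colocalization coefficients for mitochondria probes follow a logistic
  model in the lipophilic-branch count with Gaussian noise, clipped to
  [0, 1] and concentrated between 0.8 and 1;
* class sizes default to the skewed organelle proportions of real curated
  libraries (mitochondria dominant, Golgi/membrane rare).

Label noise flips the mitochondria-vs-other semantics of a probe's organelle
label with the given probability (structures are never perturbed), so at
noise 0.5 the binary targeting task is information-free by construction
while the ground truth stays exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from rdkit import Chem

from .molecule_io import (
    DESIGN_SETS,
    MoleculeRecord,
    ORGANELLES,
    standardize_and_key,
)


class GeneratorError(ValueError):
    pass


# ---------------------------------------------------------------------------
# fragment grammar (ring-closure digits 8/9 avoid clashes with scaffold rings)

SCAFFOLDS = (
    "c1ccc2cc({R})ccc2c1",                 # naphthalene
    "c1ccc(-c2ccc({R})cc2)cc1",            # biphenyl
    "c1ccc2c(c1)oc1cc({R})ccc12",          # dibenzofuran
    "c1ccc2c(c1)sc1cc({R})ccc12",          # dibenzothiophene
    "c1ccc2nc3cc({R})ccc3cc2c1",           # acridine
    "O=c1ccc2cc({R})ccc2o1",               # coumarin
    "c1ccc(-c2nc3cc({R})ccc3o2)cc1",       # 2-phenylbenzoxazole
)

CATIONIC_ANCHORS = (
    "CC[P+](c8ccccc8)(c8ccccc8)c8ccccc8",  # alkyl triphenylphosphonium
    "/C=C/c8cc[n+](C)cc8",                 # vinyl N-methylpyridinium (hemicyanine-like)
    "CC[N+](C)(C)C",                       # quaternary ammonium
)
ANCHOR_WEIGHTS = (0.40, 0.35, 0.25)
#: carboxylate counterions: their substructure footprint (C=O, C-O) is
#: already ubiquitous in the library, so the disconnected-fragment key stays
#: the unique carrier of the "salt" information
COUNTERIONS = ("CC(=O)[O-]", "C(=O)[O-]")

LIPO_CHAINS = ("CCCC", "CCCCCC", "CCCCCCCC")

#: basic amine heads, written without CH3-CH2 motifs so the ethyl key tracks
#: the mitochondria lipophilicity signal rather than amine substituents
LYSO_HEADS = (
    "CN(C)C",
    "CCN8CCOCC8",
    "CN8CCOCC8",
    "CCN8CCCCC8",
    "CCCN8CCOCC8",
)

#: aromatic cation without the mitochondria anchors' P / vinyl / ethyl motifs:
#: nuclear (and some lysosomal) probes are also positively charged, so the
#: charge key alone cannot separate the classes.
AROMATIC_CATION = "c8cc[n+](C)cc8"

CLASS_DECOR = {
    "golgi": ("OCC(O)CO", "OC(=O)CO"),
    "endoplasmic_reticulum": (
        "S(=O)(=O)Nc8ccccc8", "S(=O)(=O)N(C)C", "S(=O)(=O)c8ccccc8", "Cl",
    ),
    "cell_membrane": ("CCCCCCCCCCCCCCCC", "OCCCCCCCCCCCC"),
    "nucleus": (AROMATIC_CATION, "C(=N)N"),
}
#: probability a lysosome probe carries the aromatic cation instead of an
#: amine head (charged decoys, confusable with mitochondria)
P_LYSO_CATION = 0.2
#: probability a cationic mitochondria anchor is recorded with its
#: counterion (structures are often drawn as the bare cation)
P_COUNTERION = 0.8
#: carboxylate branch making charged decoys inner salts (single fragment)
ZWITTERION_BRANCH = "CC(=O)[O-]"
NEUTRAL_DECOR = ("O", "OC", "C(=O)O", "C", "CO", "C(C)C")

SET_DECOR = {
    "ESIPT": ("O",),                        # intramolecular H-bond donor
    "ICT": ("N(C)C",),                      # donor-acceptor push-pull
    "ALP": ("OP(=O)(O)O",),                 # phosphate recognition site
    "ROS": ("B8OC(C)(C)C(C)(C)O8",),        # boronate ester ROS trigger
    "VIS": ("/C=C/C(=O)OC",),               # flexible rotor for viscosity
}

#: MACCS keys the mitochondria signal is expected to light up: charge (49),
#: phosphorus (29), C=C (99), ethyl (114), disconnected counterion (166).
PLANTED_KEYS = ("MACCS29", "MACCS49", "MACCS99", "MACCS114", "MACCS166")


@dataclass
class ColocModel:
    """Logistic model for the colocalization coefficient:
    r = clip(sigmoid(intercept + slope * n_lipo + eps), 0, 1)."""

    intercept: float = 0.5
    slope: float = 1.5
    noise_sd: float = 0.4
    threshold: float = 0.8

    def draw(self, n_lipo: int, rng: np.random.Generator) -> float:
        z = self.intercept + self.slope * n_lipo + rng.normal(0.0, self.noise_sd)
        return float(np.clip(1.0 / (1.0 + np.exp(-z)), 0.0, 1.0))


@dataclass
class SyntheticSpec:
    """Cell counts and nuisance parameters of the synthetic library."""

    probe_counts: Dict[str, int]
    np_counts: Dict[str, int]
    label_noise: float = 0.05
    coloc: ColocModel = field(default_factory=ColocModel)
    p_no_lipo: float = 0.12
    seed: int = 7

    def __post_init__(self):
        for counts in (self.probe_counts, self.np_counts):
            for org, n in counts.items():
                if org not in ORGANELLES:
                    raise GeneratorError(f"unknown organelle {org!r}")
                if n < 0:
                    raise GeneratorError("cell counts must be >= 0")
        if not 0.0 <= self.label_noise <= 1.0:
            raise GeneratorError("label_noise must be in [0, 1]")

    @property
    def n_total(self) -> int:
        return sum(self.probe_counts.values()) + sum(self.np_counts.values())


#: organelle proportions of a realistic curated probe library
#: (mitochondria-dominant; Golgi / membrane / nucleus rare).
_PROBE_PROPORTIONS = {
    "golgi": 40, "endoplasmic_reticulum": 153, "lysosome": 361,
    "cell_membrane": 36, "mitochondria": 982, "nucleus": 50,
}
_NP_FRACTION = 236 / 1622  # non-probe compounds relative to the probe pool


def default_spec(n: int = 1200, label_noise: float = 0.05, seed: int = 7) -> SyntheticSpec:
    """Default library: ``n`` probes allocated by the skewed organelle
    proportions (largest-remainder rounding) plus a proportional pool of
    mitochondria-localized non-probe compounds."""
    total = sum(_PROBE_PROPORTIONS.values())
    raw = {k: n * v / total for k, v in _PROBE_PROPORTIONS.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    remainder = n - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - np.floor(raw[k]), reverse=True)[:remainder]:
        counts[k] += 1
    return SyntheticSpec(
        probe_counts=counts,
        np_counts={"mitochondria": int(round(_NP_FRACTION * n))},
        label_noise=label_noise,
        seed=seed,
    )


@dataclass
class GroundTruth:
    planted_keys: Tuple[str, ...]
    true_class: Dict[str, str]        # source_id -> generating organelle / np tag
    n_lipo: Dict[str, int]            # source_id -> lipophilic branch count
    coloc_label: Dict[str, str]       # source_id -> good/weak (mito probes)
    has_anchor: Dict[str, bool]


# ---------------------------------------------------------------------------
# assembly

def _assemble(scaffold: str, branches: List[str], terminal: str,
              counterion: Optional[str]) -> str:
    sub = "".join(f"C({b})" for b in branches) + (terminal or "C")
    smiles = scaffold.replace("{R}", sub)
    if counterion:
        smiles = f"{smiles}.{counterion}"
    if Chem.MolFromSmiles(smiles) is None:  # grammar self-check
        raise GeneratorError(f"generator produced invalid SMILES: {smiles!r}")
    return smiles


def _choice(rng: np.random.Generator, seq):
    return seq[int(rng.integers(0, len(seq)))]


def _draw_structure(rng, true_class: str, label_noise: float, p_no_lipo: float,
                    extra_decor: Tuple[str, ...] = ()):
    """Build one molecule; returns (smiles, n_lipo, has_anchor)."""
    scaffold = _choice(rng, SCAFFOLDS)
    branches: List[str] = []
    for decor in extra_decor:
        branches.append(decor)

    if true_class == "mitochondria":
        tail = int(rng.integers(0, 6))
        if tail:
            branches.append("C" * tail)
        if rng.random() < p_no_lipo:
            n_lipo = 0
        else:
            n_lipo = int(rng.integers(1, 4))
        branches += [_choice(rng, LIPO_CHAINS) for _ in range(n_lipo)]
        has_anchor = rng.random() >= label_noise
        if has_anchor:
            terminal = CATIONIC_ANCHORS[
                int(rng.choice(len(CATIONIC_ANCHORS), p=ANCHOR_WEIGHTS))
            ]
            # structures are sometimes recorded without the counterion
            counterion = _choice(rng, COUNTERIONS) if rng.random() < P_COUNTERION else None
        else:
            terminal, counterion = _choice(rng, NEUTRAL_DECOR), None
        return _assemble(scaffold, branches, terminal, counterion), n_lipo, has_anchor

    if true_class == "np":
        # non-probe compounds: short alkyls allowed (not a targeting task)
        tail = int(rng.integers(0, 4))
        if tail:
            branches.append("C" * tail)
        branches += [_choice(rng, ("C", "CC")) for _ in range(int(rng.integers(0, 3)))]
        terminal = _choice(rng, NEUTRAL_DECOR)
        return _assemble(scaffold, branches, terminal, None), 0, False

    # other-organelle probes: methyl/methoxy-only decoration keeps the ethyl
    # motif a mitochondria (lipophilicity) marker
    branches += ["C"] * int(rng.integers(0, 6))
    if rng.random() < 0.5:
        branches.append("OC")
    if true_class == "lysosome":
        if rng.random() < P_LYSO_CATION:
            terminal = AROMATIC_CATION
            branches.append(ZWITTERION_BRANCH)  # inner salt, single fragment
        else:
            terminal = _choice(rng, LYSO_HEADS)
    elif true_class in CLASS_DECOR:
        terminal = _choice(rng, CLASS_DECOR[true_class])
        if terminal == AROMATIC_CATION:
            branches.append(ZWITTERION_BRANCH)
    else:  # np compounds: bare scaffold with neutral/hydrophilic decoration
        terminal = _choice(rng, NEUTRAL_DECOR)
    return _assemble(scaffold, branches, terminal, None), 0, False


def _noisy_label(rng, true_org: str, label_noise: float) -> str:
    """Flip the mitochondria-vs-other semantics with probability
    ``label_noise``: a mitochondria probe is relabelled to a random other
    organelle; a non-mitochondria probe is relabelled mitochondria."""
    if rng.random() >= label_noise:
        return true_org
    if true_org == "mitochondria":
        others = [o for o in ORGANELLES if o != "mitochondria"]
        return _choice(rng, others)
    return "mitochondria"


def generate_library(spec: SyntheticSpec):
    """Generate the labelled library; returns ``(records, GroundTruth)``.

    Molecules are unique across the library (rejection sampling on the
    canonical SMILES); every emitted SMILES is parsed as a self-check.
    Fully reproducible for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    records: List[MoleculeRecord] = []
    truth = GroundTruth(PLANTED_KEYS, {}, {}, {}, {})
    counter = 0
    seen = set()  # global: duplicate structures across classes would collide
    # in the task tables after labelling

    def emit(role: str, true_class: str, n: int):
        nonlocal counter
        made = 0
        attempts = 0
        while made < n:
            attempts += 1
            if attempts > 60 * n + 100:
                raise GeneratorError(
                    f"cannot generate {n} unique molecules for {role}/{true_class}"
                )
            smiles, n_lipo, has_anchor = _draw_structure(
                rng, true_class if role == "probe" else "np",
                spec.label_noise, spec.p_no_lipo,
            )
            rec = standardize_and_key(MoleculeRecord(smiles=smiles))
            if rec.smiles in seen:
                continue
            seen.add(rec.smiles)
            made += 1
            counter += 1
            sid = f"SYN{counter:06d}"
            rec.source_id = sid
            rec.role_label = role
            truth.true_class[sid] = true_class if role == "probe" else f"np:{true_class}"
            truth.n_lipo[sid] = n_lipo
            truth.has_anchor[sid] = has_anchor
            if role == "probe":
                rec.organelle_label = _noisy_label(rng, true_class, spec.label_noise)
                if true_class == "mitochondria":
                    n_rec = int(rng.integers(1, 3))
                    rs = [spec.coloc.draw(n_lipo, rng) for _ in range(n_rec)]
                    dyes = [_choice(rng, ("MTR", "MTG")) for _ in rs]
                    rec.coloc_records = list(zip(dyes, rs))
                    mean = float(np.mean(rs))
                    truth.coloc_label[sid] = (
                        "good" if mean >= spec.coloc.threshold else "weak"
                    )
            else:
                rec.organelle_label = true_class
            records.append(rec)

    for org in ORGANELLES:
        n = spec.probe_counts.get(org, 0)
        if n:
            emit("probe", org, n)
    for org in ORGANELLES:
        n = spec.np_counts.get(org, 0)
        if n:
            emit("np_compound", org, n)
    return records, truth


# ---------------------------------------------------------------------------
# design sets

DESIGN_SET_SIZES = {"ESIPT": 70, "ICT": 451, "ALP": 21, "ROS": 37, "VIS": 54}


def generate_design_sets(
    spec: Optional[SyntheticSpec] = None,
    sizes: Optional[Dict[str, int]] = None,
    seed: Optional[int] = None,
):
    """Five tagged candidate sub-libraries for exercising the cascade flow.

    All molecules are generated with the mitochondria signal (cationic
    anchor + lipophilic branches) plus one set-specific recognition
    decoration; sizes default to 70/451/21/37/54 (ESIPT/ICT/ALP/ROS/VIS).
    Records carry only the design-set tag — they are prediction inputs, not
    labelled training data.
    """
    spec = spec or default_spec()
    sizes = dict(sizes or DESIGN_SET_SIZES)
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    out: Dict[str, List[MoleculeRecord]] = {}
    counter = 0
    for ds in DESIGN_SETS:
        n = sizes.get(ds, 0)
        seen = set()
        mols: List[MoleculeRecord] = []
        attempts = 0
        while len(mols) < n:
            attempts += 1
            if attempts > 60 * n + 100:
                raise GeneratorError(f"cannot generate {n} unique molecules for set {ds}")
            smiles, _, _ = _draw_structure(
                rng, "mitochondria", label_noise=0.0, p_no_lipo=spec.p_no_lipo,
                extra_decor=SET_DECOR[ds],
            )
            rec = standardize_and_key(MoleculeRecord(smiles=smiles))
            if rec.smiles in seen:
                continue
            seen.add(rec.smiles)
            counter += 1
            rec.source_id = f"DS{counter:05d}"
            rec.design_set = ds
            rec.role_label = None
            mols.append(rec)
        out[ds] = mols
    return out
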