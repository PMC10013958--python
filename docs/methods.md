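# Methods

## The prediction problem

A candidate fluorophore is judged along four questions arranged as a
cascade: probe vs non-probe compound; mitochondria vs other organelle;
which of six organelles; and, for mitochondria probes, whether the imaging
colocalization with the MitoTracker Green/Red reference dyes will be good.
Colocalization is summarized by the Pearson correlation r between the probe
channel and the dye channel; a molecule's label is computed from the
arithmetic mean of its r records **after** restricting to the MitoTracker
dye pair, and the boundary mean = 0.8 is labelled *good* (the threshold is
inclusive). Records with other dyes are excluded rather than rescaled,
because colocalization against a lysosomal or nuclear dye measures a
different quantity.

## Curation

Structures are canonicalized with RDKit keeping **all** disconnected
fragments: a cationic dye's counterion changes both the charge-related and
the fragment-count substructure keys, and those keys carry targeting
signal, so salts are never stripped. Deduplication uses the InChIKey within
each (role, organelle) label group, keeping the first occurrence —
deterministic and order-stable; the same structure may legitimately appear
under two labels (a molecule reported for two organelles), so cross-label
duplicates are retained. Because retention of cross-label duplicates can
leak a structure across a random train/test split, `split_dataset` accepts
`group_keys` (InChIKeys) to force all rows of one structure onto one side;
the default remains the plain stratified random split.

Colocalization records of within-label duplicates are merged before
labelling so the per-molecule mean covers all literature measurements.

## Representations

* **MACCS**: 166 keys, named `MACCS1`…`MACCS166` by the published 1-based
  numbering (the toolkit's unused bit 0 is truncated) so keys cited in
  structure–activity discussions are addressable by name. The shipped
  `data/maccs_keys.csv` maps each key to its SMARTS and to
  heteroatom (N/O/P), charge, and disconnection flags; the two keys without
  a SMARTS (aromatic-ring count, fragment count) are special-cased.
* **ECFP4**: Morgan fingerprint, radius 2, hashed to 1024 bits by default
  (configurable; the diameter-4 convention fixes only the radius, not the
  width).
* **AtomPair**: hashed atom-pair fingerprint, same interface.
* **2D**: the full RDKit 2D descriptor list (~210 values) as the open
  descriptor set: it covers the physicochemical and topological concepts
  that matter here (logP estimate, formal-charge totals, surface-area
  proxies, shape/topology indices). Descriptor failures are recorded as NaN
  and resolved by the selection pipeline.
* PubChem- and CDK-style fingerprints are plug-in slots
  (`FINGERPRINT_PLUGINS`); no bundled toolkit computes them, and the core
  analyses use MACCS/ECFP4/2D.

**Feature selection** (applied to descriptors, optional for fingerprints):
columns with > 10 % missing values are dropped, remaining NaNs are imputed
with the column median; zero-variance columns are dropped; then a greedy
scan in column order drops any column whose |Pearson r| with an
already-kept column exceeds 0.95 (keep-first tie policy — deterministic,
and idempotent on its own output). `apply_selection` re-applies a fitted
selection (kept columns + training medians) to new data, so the kept-column
list can be fitted on the training partition only.

## Class balancing

SMOTE is implemented from first principles: the minority class is raised to
parity by emitting x + u·(x′ − x) with u ~ U[0,1], x a minority point and
x′ one of its k = 5 nearest minority neighbours under the Euclidean metric
on the feature matrix as given (for binary fingerprints this is the square
root of the Hamming distance). Ties in the neighbour ranking break by row
index, so a fixed seed gives byte-identical output. Synthetic fingerprint
values are left fractional by default — gradient-boosted trees split on
them directly — with `round_bits=True` available to snap to hard bits. In
cross-validation SMOTE is applied inside each fold's training side only, so
no synthetic point is ever scored; the whole-dataset-first variant is a
deliberate non-default because it leaks interpolated copies of test
molecules into training.

## Model lab

Ten classical algorithms: decision tree, random forest, AdaBoost,
histogram gradient boosting, gradient boosting tree, XGBoost, LightGBM,
extremely randomized trees, logistic regression, and a linear-kernel SVM
(with Platt-scaled probabilities). Hyperparameters are library defaults,
recorded verbatim in the report — the object of study is the comparison
protocol, not tuning. Linear models receive standardized inputs via a
scaler fitted on their training partition; tree models see raw values.

Protocol: stratified 80/20 split (classes with fewer than two members stay
in train, with a warning), stratified 5-fold CV on the training partition
(fold count reduced with a warning when the smallest class is smaller than
the fold count), and test evaluation of every (family × algorithm) cell on
the same split. The best cell is the argmax of test accuracy with CV
accuracy and then (family, algorithm) name order as deterministic
tie-breaks. A failing cell records its error and the grid continues.

Metrics: accuracy; recall/precision on the positive class for binary tasks;
support-weighted one-vs-rest averages for multiclass, under which weighted
recall is *identically* accuracy — asserted to 1e-12 on every multiclass
report as a self-check. AUC is the rank statistic of the positive-class
probability (equivalently the exhaustive concordant-pair count with ties at
½); multiclass AUC is the support-weighted one-vs-rest average, with
classes absent from the evaluated labels skipped and the weights
renormalized (warned). Probability rows must sum to 1 within 1e-9;
predicted labels are the probability argmax with a lowest-index tie-break.

## Cascade

Level 1 always runs. For predicted probes, levels 2 **and** 3 both run —
the six-way model re-examines every probe regardless of the binary
verdict, because under class imbalance the multiclass probability vector is
more informative than the binary label; a mitochondria-vs-other
disagreement between the two levels is flagged, never silently resolved
(`consensus=True` additionally marks molecules whose mitochondria
probability is below 0.5 despite being the argmax). Level 4 runs exactly
when level 3 says mitochondria. Each level may use its own feature family;
the default pairing is ECFP4 + logistic regression for probe detection,
MACCS + LightGBM for both targeting levels, and selected 2D descriptors +
LightGBM for colocalization — the combination that performs best on the
synthetic benchmark and matches gradient-boosting practice for
substructure features. The flow table records (design set, source node,
target node, count) transitions; inbound and outbound counts at every level
are conserved by construction and asserted in the tests.

## Interpretation

SHAP values come from the exact TreeSHAP implementations built into
LightGBM and XGBoost (per-sample attributions plus the base value
reproduce the model margin to 1e-6, asserted), and from the closed form
coef·(x − mean) for linear models; other estimator types raise with the
type named. Binary tree margins are emitted for the second class, so
attributions are re-oriented when the first class is requested — "positive"
always means "pushes toward the requested class". Rankings use mean |SHAP|
(the standard summary-plot ordering) and split-gain importance
(split-count importance is also exposed); both are Min-Max normalized for
display, ties in ranking break by feature name. The Top-k consensus is the
intersection of the two Top-k prefixes (k = 15/30/50 by default). For
multiclass models the mitochondria-class attribution column is used. The
heteroatom analysis reports the fraction of a feature set whose MACCS
definition mentions N, O or P, with charge and disconnection keys flagged
separately. Directional summaries report the sign of the mean SHAP among
samples where the feature is active, with a 1e-6 dead zone.

## Screening

Properties arrive as a precomputed table (they are produced by a hosted
ADMET prediction service, not by this package): toxicity probability in
[0,1], synthetic accessibility in [1,10], logP unbounded; out-of-range or
non-numeric rows are rejected with reasons. Rules (`toxicity<=0.3`,
`sa<=6`, `logp in 1..6`) are evaluated per candidate and reported as
per-rule flags; passing candidates are ranked by (toxicity ascending,
synthetic accessibility ascending, logP descending). Because a practitioner
may deliberately keep a candidate that fails a rule — moderate logP can be
preferred for drug-likeness despite the lipophilicity rule — filtering
supports a manual `keep` override instead of hard-coding any final pick.
Screening is monotone: relaxing a bound never removes a passing candidate.

## Synthetic library generator

The generator is first-class, tested code: it emulates the statistical
shape of a literature-curated probe library so every claim the tests make
is checked against known ground truth.

* **Grammar**: seven conjugated scaffolds (naphthalene, biphenyl,
  dibenzofuran, dibenzothiophene, acridine, coumarin, phenylbenzoxazole)
  with one substitution slot; substituents are assembled from alkyl
  branches and a terminal recognition group. A fragment grammar was chosen
  over a generative model because it yields valid-by-construction SMILES
  (every emitted molecule is re-parsed as a self-check) and a transparent,
  exact ground truth.
* **Mitochondria probes** carry a cationic anchor — triarylphosphonium
  (40 %), vinyl-pyridinium (35 %), quaternary ammonium (25 %) — with
  probability 1 − noise, plus 1–3 lipophilic C4/C6/C8 branches (none with
  probability 0.12). Anchors carry a carboxylate counterion with
  probability 0.8; carboxylate was chosen because its substructure
  footprint is already ubiquitous in the library, leaving the
  disconnected-fragment key as the unique carrier of the "salt"
  information.
* **Decoys**: nuclear probes and 20 % of lysosomal probes carry an aromatic
  pyridinium cation as a single-fragment inner salt — charged but without
  the anchors' phosphorus/vinyl/ethyl motifs — so the charge key alone
  cannot separate the classes, mirroring the fact that nuclear and
  lysosomal stains are also cationic. Remaining lysosome probes get basic
  amine heads (morpholine/dimethylamino variants written without CH3–CH2
  motifs); the other organelle classes and the non-probe compounds get
  class-specific neutral decorations with methyl/methoxy-only alkylation,
  which keeps the ethyl key a lipophilicity (mitochondria) marker.
* **Planted keys**: phosphorus (MACCS29), formal charge (MACCS49), C=C
  (MACCS99), ethyl (MACCS114) and disconnected fragments (MACCS166) are
  declared in the ground truth as the keys the mitochondria signal sets.
* **Class sizes** default to the skewed organelle proportions of real
  curated libraries — mitochondria-dominant
  (golgi:ER:lysosome:membrane:mito:nucleus ≈ 40:153:361:36:982:50, scaled
  to the requested total by largest-remainder rounding) — plus a
  proportional pool (~15 %) of mitochondria-localized non-probe compounds,
  so imbalance pathologies (small classes misassigned to mitochondria) are
  reproducible in kind.
* **Colocalization**: r = clip(σ(0.5 + 1.5·n_lipo + ε), 0, 1) with
  ε ~ N(0, 0.4²), where n_lipo is the lipophilic-branch count. With the
  default parameters ≥ 80 % of mitochondria-class coefficients fall in
  [0.8, 1] and roughly one probe in eight is weak — the heavy-tail-of-good
  shape of published colocalization data. The generator's good/weak
  assignment round-trips exactly through the curation labelling rule.
* **Label noise** flips the mitochondria-vs-other semantics of a probe's
  organelle label with probability `label_noise` (mitochondria →
  uniformly-random other organelle; other → mitochondria) and independently
  withholds the cationic anchor from a mitochondria structure with the same
  probability. At noise 0.5 the binary targeting task is thus
  information-free by construction (CV accuracy ≈ 0.5), at noise 0 it is
  nearly perfectly separable; the default study condition is noise 0.05.
  The ground truth (generating class, anchor flag, branch count, coloc
  label) is always exact.
* **Design sets**: five tagged candidate sub-libraries of 70/451/21/37/54
  molecules (ESIPT/ICT/ALP/ROS/viscosity), all generated with the
  mitochondria signal plus one set-specific decoration (H-bond donor,
  dialkylamino donor, phosphate site, boronate ester, flexible rotor), used
  to exercise the cascade flow accounting.

Molecules are unique across the library (rejection sampling on the
canonical SMILES) because duplicate structures under one label would be
dropped by curation and distort the cell counts.

### What the generator does and does not emulate

It reproduces: the class-size skew, the charge/lipophilicity chemistry of
mitochondrial targeting, confusable cationic decoys, the [0.8, 1]
concentration of colocalization coefficients, and a tunable
separability/noise dial. It does **not** emulate: real scaffold diversity
(seven cores vs thousands), activity cliffs, assay and annotation noise
correlated with structure, synthesizability, or spectral properties.
Passing tests therefore demonstrate that the pipeline's machinery is
correct and that planted signal of the expected kind is recovered — not
that any particular accuracy will transfer to literature data.

## Problem sizes and numerical choices

The default study library is 1200 probes (+175 non-probe compounds), the
size at which the full grid, interpretation, and 633-molecule cascade run
comfortably on a single CPU; unit tests use a 240-probe library.
Tolerances: metric oracle agreement 1e-12; SHAP additivity 1e-6; SMOTE
segment residual 1e-9; probability row sums 1e-9; directional dead zone
1e-6. Ties everywhere break deterministically (lowest index for argmax,
name order for rankings, row index for neighbour lists), so fixed seeds
give reproducible reports end to end.

## Known limitations

* PubChem/CDK fingerprints require an external plug-in; conclusions about
  those families cannot be reproduced here.
* SHAP attributions are exact only for LightGBM/XGBoost and linear models;
  bagged sklearn ensembles are intentionally unsupported rather than
  approximated.
* The ten-algorithm set fills the categorical-boosting slot with sklearn's
  histogram gradient boosting, a closely related gradient-boosting
  implementation.
* The screening property values are consumed, never computed; garbage in,
  garbage out.
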