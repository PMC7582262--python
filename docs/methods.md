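# Methods

## Problem and model

`hotseq` classifies interface residues of protein–protein complexes as hot
spots (HS; alanine mutation raises ΔΔG_binding by more than 2.0 kcal·mol⁻¹)
or null spots (NS), from sequence alone. The model is a binary classifier
over a fixed 173-feature per-residue descriptor, an extremely randomized
trees ensemble, followed by a per-amino-acid probability correction. The
pipeline assumes (i) the 20 standard residue types only, (ii) labels
produced by alanine-scanning — hence no ALA ground truth can exist, and
(iii) a class imbalance of roughly one HS per three NS.

## Feature descriptor

Order is frozen and stored with every trained model: one-hot (20, alphabetical
`ACDEFGHIKLMNPQRSTVWY`), position quartile (1), raw properties (19), window
means (19 × 7 = 133).

* **Quartile** = ⌈4·i/L⌉ capped at 4. The ceiling assigns remainders to
  earlier quartiles deterministically; position 1 → 1 and position L → 4 for
  every L ≥ 1, including chains shorter than 4 residues (no special case).
  Note the rule is not mirror-symmetric unless 4 | L.
* **Windows** are symmetric with half-width w ∈ {2, 5, 7, 10, 25, 50, 75}
  residues on *each* side, target included, truncated at chain boundaries
  with no padding. Consequences used as test oracles: a window covering the
  whole chain equals the unweighted chain mean; covered index sets are
  nested as w grows; all non-positional features are invariant under
  sequence reversal. Trailing (one-sided) windows and total-width
  conventions were the design alternatives; the symmetric convention is the
  field's standard for residue-context features and keeps the reversal
  property testable.

## Property table

The 19 physicochemical properties per amino acid cover secondary-structure
propensity (Chou–Fasman helix/sheet/turn), pKa-associated values
(α-carboxyl, α-amino, side chain, pI), atomic composition (C, H, N, O, S,
heavy atoms of the free amino acid), average residue mass (Da), theoretical
maximum accessible surface area (Å², Tien et al. 2013), Kyte–Doolittle
hydropathy, Zamyatnin residue volume (Å³), Grantham polarity, and the
Bhaskaran–Ponnuswamy average flexibility index. Residues without an
ionizable side chain carry the sentinel 0.0 in `pka_side_chain`. The table
ships as CSV (`hotseq/data/amino_acid_properties.csv`), is immutable at run
time, is exported/auditable via `export_properties_csv`, and can be replaced
with `--property-table` — trained models store a checksum and refuse to
predict against a different table.

## Splitting

Per (amino acid, class) subset of size n: the test pool receives
round-half-up(0.4·n), floored at 1 when n ≥ 2; singletons stay in train.
Amino-acid types present in one class only are placed entirely in train —
a test set could never score them against both outcomes. The pooled test
residues are shuffled and halved; the tuning half receives the extra residue
when odd (tuning benefits most from data). All randomness comes from one
integer seed; per-subset counts are seed-invariant. The rounding convention
is one of several that are consistent with a 60:40 description; it is fixed
here and documented rather than inferred.

## Classifier

scikit-learn `ExtraTreesClassifier` with `n_estimators=500`,
`bootstrap=True`, `class_weight="balanced_subsample"` (class weights
recomputed inside each tree's bootstrap sample — the main defence against
the 1:3 imbalance), and a frozen default block for everything else:
unlimited depth, `max_features="sqrt"`, `min_samples_leaf=1`. Grid search
(exhaustive, stratified k-fold, default 10 folds) optimizes F1 by default —
accuracy would reward majority-class collapse under imbalance — and is
switchable via the `scoring` argument. Baseline models (MLP, random forest,
AdaBoost, SVC at library defaults) are exposed behind
`baseline_classifiers()` for comparison only.

## Probability correction

Fitted on the tuning half only, per amino acid: with mFN the maximum raw HS
probability among false negatives and mTN among true negatives, the
correction is clamp(0.50 − mFN, 0, 0.5) when false negatives exist and
mFN > mTN, else 0. When no true negative exists mTN is taken as −∞ (the
guard passes; there is nothing to protect). Amino acids absent from the
tuning set get 0 — no extrapolation across residue types — and residue
types never seen in training are flagged `unseen_in_training` in prediction
output.

Decision rules: pre-correction class is HS iff raw > 0.50 (strict);
post-correction class is HS iff raw > 0.50 or a **positive** correction
brings the probability to ≥ 0.50. The closed boundary exists to recover the
maximal lifted false negative (raw + correction = 0.50 exactly). Restricting
it to positive corrections matters: a residue sitting at raw = 0.50 exactly
with zero correction must not change class, otherwise the identity
calibration would create false positives. Guard soundness on the fitting
set is then provable: every true negative's raw probability is ≤ mTN < mFN,
so raw + (0.50 − mFN) < 0.50.

## Metrics

Accuracy, precision, recall (TPR), FPR and F1 follow their confusion-matrix
definitions with HS as the positive class; 0/0 cells return NaN (an explicit
"undefined" marker) rather than a silent 0 or 1, so degenerate predictors
are loudly visible. AUROC is the Mann–Whitney rank statistic (ties ½),
mathematically equal to trapezoidal ROC integration; tests verify both the
exhaustive pair-enumeration oracle and scikit-learn's trapezoidal
implementation to 1e-12. Class-frequency-weighted precision/recall/F1
variants are available behind a flag because some benchmark tables aggregate
that way; the binary HS-centric convention is primary. Per-amino-acid
reports carry pre- and post-correction rows plus a pooled `ALL` row whose
counts equal the column sums.

## Synthetic data generator

`hotseq.fixtures` emulates the statistical shape of curated alanine-scanning
collections. Defaults (the package's study conditions): 534 residues over 8
chains of 60–74 residues; no ALA anywhere; CYS/MET pinned NS; overall HS
fraction ≈ 0.24 with tyrosine-enriched hot spots.

Mechanism: each chain is background-composed with a hydrophilic tilt
(exp(−1.25·z) along the informative score) and carries contiguous **hot
segments** (12–22 residues, ≈25% coverage) composed with a hydrophobic tilt
(exp(+3.5·z)) and tyrosine raised to the maximal weight — the
interface-patch picture in miniature. The label probability of residue i is
sigmoid(effect_size · (score_i − q)) where score_i is the standardized mean
of the window-averaged informative properties (default: hydropathy and max
ASA over the ±5 window) and q the global quantile matching the overall HS
target; zero-ratio amino acids are pinned NS. The learnable signal therefore
lies inside the extractor's own 173-feature space by construction.
`effect_size` defaults to 6 (noisy, realistic); at `effect_size=0` every
residue receives the single overall rate with **no** per-type pinning — a
pure null in which not even residue identity predicts the label, which is
what a leakage control requires. `label_noise` flips labels (never for
single-class types, which must stay single-class).

What the generator does *not* emulate: real ΔΔG energetics, structural
context, protein-family redundancy, and the sparse labeling of real
alanine-scanning studies (here every residue of every chain is labeled).
Passing recovery tests therefore show the pipeline's machinery is sound, not
that real proteins reach these numbers.

## Measurement protocols and numerical choices

* End-to-end recovery (effect_size 100, zero noise) is summarized as the
  **median independent-test accuracy over 5 replicate seeds**: the study
  conditions leave only ~55–90 independent residues, so a single run carries
  ±0.03 binomial noise. Typical values: median ≈ 0.97.
* The null control runs 10 seeds at effect_size 0 and checks each
  independent-test AUROC against the chance band [0.35, 0.65] (±2.3 null
  standard deviations at these test sizes).
* Window means use prefix sums (O(L) per window/property); the float noise
  this introduces is at the last ulp and tests compare at rtol 1e-12.
* Splits, training, generation: all randomness flows from explicit integer
  seeds; identical seeds give bit-identical artifacts.

## Known limitations

* The published curated 534-residue dataset, its exact 19 property values
  and its split seed are external/unpublished; the bundled property table is
  a documented stand-in by category and `scripts/reproduce_published.py`
  only offers approximate reproduction against the downloadable data.
* Per-amino-acid corrections are fitted on ~5 tuning residues per type under
  the default conditions; off the tuning set the no-new-false-positive
  guarantee is statistical, not provable.
* Non-standard residues (X, B, Z, U) are rejected (or their chains skipped
  with `skip_invalid_chains=True`): the descriptor is undefined for them.
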