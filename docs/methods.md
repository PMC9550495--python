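# Methods

## Conservation labeling

A water of the reference structure is *conserved* when, after the homolog
is superposed into the reference frame, some water oxygen of the homolog
lies within 1.2 Å of it (nearest Euclidean distance, NED); otherwise it is
*free*.  This operationalises conservation as positional recurrence across
homologs, the standard ligand-free/bound comparison criterion.  The
procedure and its defaults:

1. **Superposition.** Optimal least-squares rigid fit (Kabsch, proper
   rotation enforced) over matched Cα atoms.  The default matching pairs
   chains greedily by global BLOSUM62 alignment score (gap open −11,
   extend −1) and takes Cα atoms of aligned residue pairs; an explicit
   atom pairing overrides this.  Degenerate inputs (< 3 pairs, collinear
   clouds, second singular value < 1e−8 of the first) are hard errors.
   The reported RMSD is the Cα RMSD over the matched set.
2. **Pair filter.** Pairs with RMSD > 2.0 Å are rejected with an explicit
   error (never a silently empty label set).  Waters compared across a bad
   superposition would be labeled by alignment noise, not conservation.
3. **Pocket.** Protein atoms and water oxygens within 7.0 Å (inclusive) of
   *any* ligand atom.  A centroid-based alternative (distance to the
   ligand's geometric centre) is available behind
   `LabelingConfig.pocket_mode="centroid"`; the any-atom rule is the
   default because it follows the pocket's actual shape.
4. **NED and label.** Candidate partners are all waters of the homolog
   (no pocket restriction on the homolog side — a conserved water near the
   pocket boundary should not flip label because its counterpart falls
   just outside a second pocket).  Both the 7.0 Å and 1.2 Å thresholds are
   inclusive.  No partner waters ⇒ NED = ∞ ⇒ FWM.

Waters are represented by their oxygen atom throughout; all distances are
oxygen–oxygen or oxygen–heavy-atom.  Labels are invariant under any common
rigid transform of both structures, monotone in the NED threshold, and
CWM + FWM counts partition the pocket waters — all property-tested.

## Features

Six per-water descriptors, letters A–F in every report:

- **A, atom density** — protein atoms within 3.6 Å (inclusive).  Ligand
  and water atoms are not counted: the feature reads the protein
  microenvironment only.
- **B, mobility** — `(BF_i/mean BF)/(O_i/mean O)`, means over all water
  oxygens of the structure (a pocket-only baseline is a config switch).
  Requires positive occupancy and a positive mean B; degenerate inputs
  are errors rather than silent zeros.
- **C, B-factor** — the PDB column, verbatim.  The conversion
  BF = 8π²·Ū² (`msd_to_bfactor`) exists for synthesising coordinate
  files, never to reinterpret parsed ones.
- **D/E, hydrophilicity/hydrophobicity** — Σ p_i·exp(−r_i/d₀) over
  protein atoms within 4 Å, with p the hydration propensity h (D) or the
  carbon propensity l (E).  The **negative exponent** is used for both:
  an interaction-weighted sum must decay with distance (a positive
  exponent would grow without bound and reward *distant* atoms);
  `FeatureConfig.positive_exponent=True` reproduces the alternative
  printed sign for comparison.  The distance scale d₀ is not fixed by the
  formulation; the default is 1.0 Å and the value is always explicit in a
  serialised config.  The shipped propensity table resolves
  (residue, atom-name) keys, then wildcard atom names, then element
  classes; polar oxygens/nitrogens carry high h, carbons carry l.  The
  table encodes the conventional ordering of hydration propensities, is
  versioned in the package data and is fully user-replaceable
  (`PropensityTable.from_tsv`); unresolvable atoms contribute 0 with a
  logged warning.
- **F, SASA** — Shrake–Rupley: 960 deterministic golden-spiral points on
  the sphere of radius vdW(O) + 1.4 Å around the oxygen; a point is buried
  inside any context atom's solvent-expanded sphere.  Context is the
  protein only by default (other waters and the ligand do not occlude),
  so the value reads as accessibility to bulk solvent.  vdW radii:
  C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, H 1.20 Å.  At 960 points the
  isolated-sphere and two-sphere closed forms are matched within 2%, and
  doubling the point count moves values by < 1%.

All cutoffs are inclusive, consistent with the labeling thresholds.
Features are invariant under rigid transforms (SASA up to quadrature
discretisation) and under atom reordering.

## Classifiers and evaluation

Seven families with fixed, documented defaults (all overridable):
SVM (RBF, C = 1, scaled gamma), KNN (k = 5, Euclidean), decision tree
(Gini, unlimited depth), logistic regression (L2, C = 1), linear
discriminant analysis, Gaussian naive Bayes, and "EL", a bagged-tree
ensemble of 100 trees.  Features are z-scored inside each training fold
for the scale-sensitive families (SVM/KNN/LR/DA); trees and NB run raw.

Evaluation is stratified five-fold cross-validation with a fixed seed.
Out-of-fold predictions are pooled and one metric set is computed on the
pooled counts (pooling keeps every ratio well-defined on small folds,
where per-fold averaging can hit empty denominators).  Rows are
canonically ordered (lexicographic on features + label) before the split,
so pooled metrics do not depend on input row order.  CWM is the positive
class:

    ACC = (TP+TN)/n,  SN = TP/(TP+FN),  PPV = TP/(TP+FP),
    F   = 2TP/(2TP+FP+FN),  AUC = P(score(pos) > score(neg)), ties ½.

Undefined ratios are reported as missing, never 0, and are excluded from
averages with a logged count.  AUC uses class probabilities where the
model provides them, otherwise the decision margin oriented to the
positive class (squashed through a logistic so a 0.5 score threshold
always reproduces the predicted label).

The **combination sweep** evaluates all 2⁶−1 = 63 feature subsets
(ordered largest-first, then lexicographic) under all seven families and
averages each criterion over the families.  Ranking treats values within
±0.001 of the per-criterion maximum as tied — values reported to three
decimals cannot be distinguished more finely — and the overall winner is
the combination appearing in the most per-criterion best sets (ties:
larger combination, then lexicographic).  The **model comparison** scores
each family on the winning combination by the mean of its five criteria.
The final model is fitted on all rows and persisted as a versioned joblib
artifact (family, combination, seed, config hash, format version);
loading verifies the version and reproduces in-memory predictions
exactly.

## Synthetic data

The generators define the conditions under which the pipeline is
validated.

**Homolog pairs.**  The reference is a spherical cage of ~60 coarse
residues (N, CA, C, O, CB) at 8.5 Å around a 6-atom ligand, with 40
pocket waters in the 2.5–6.9 Å shell (pairwise ≥ 2.7 Å apart) and 10 bulk
waters beyond 12.5 Å.  The homolog keeps a chosen fraction of pocket
waters in place (isotropic jitter, σ = 0.12 Å) and displaces the rest by
2.0–2.8 Å, then the whole structure is moved by a random rigid transform;
the protein gets σ = 0.04 Å jitter so the recovered RMSD is small but
non-zero.  The default conserved fraction 0.556 matches the ~1 : 1.25
FWM : CWM imbalance of curated homolog-pair corpora.  Placement is
rejection-sampled and then audited: every conserved water must have its
counterpart within 0.8 Å and every displaced water no homolog water
within 1.6 Å, so the 1.2 Å rule recovers the planted labels exactly, with
no boundary ambiguity.  Conserved waters draw low B-factors
(N(23.7, 5²)), displaced ones higher (N(36.4, 8²)).

**Feature tables.**  Per class and feature, values are drawn from a
truncated normal on the class's [min, max] range.  The scale puts ~99% of
the untruncated mass in bounds; the location is then solved by
fixed-point iteration so the *truncated* mean equals the target (naive
truncation would bias it).  Default targets and ranges encode the
class-wise pattern of real binding-site waters — conserved: density 3.03
vs 1.15, hydrophilicity 0.071 vs 0.029, hydrophobicity 0.116 vs 0.049,
SASA 6.7 vs 21.9 Å², B-factor 23.7 vs 36.4, mobility 1.10 vs 1.67 — at
the 1 : 1.25 class ratio.  A `separation` multiplier scales the distance
of the class means from their midpoint for sensitivity checks.

What the generator does **not** emulate: within-class correlation between
features (real density and SASA are strongly anticorrelated; here they
are independent given the class), multimodal shapes, crystallographic
noise, resolution effects, or structure-level clustering of waters.
Passing tests therefore demonstrate that the machinery — labeling
geometry, feature formulas, CV bookkeeping, selection logic — is correct
and self-consistent, not that the published accuracy transfers to real
corpora; on these independent-marginal tables the classes are more
separable than in real data (ensemble CV accuracy ≈ 0.99).

## Numerical choices and problem sizes

- Kabsch degeneracy tolerance 1e−8 (relative second singular value);
  exact-equality thresholds (≤) everywhere; PDB columns are parsed at
  their native precision (coordinates 3 decimals, occupancy/B 2).
- Report TSVs format floats to 3 decimals, making reruns byte-identical.
- Altlocs collapse to the highest-occupancy conformer (ties: first
  altloc); MODEL 1 only; water residue names {HOH, WAT, DOD} by default.
- `scripts/acceptance.py` runs the 63-combination × 7-family sweep at
  n = 900 rows and the headline ensemble CV at n = 4500 — the sweep's
  conclusions (63 reports, full-combination win, ensemble front-runner)
  are stable at this size while keeping the sweep to about a minute.

## Known limitations

- The default propensity table is a package default with conventional
  ordering, not a reproduction of any published per-atom fit; users with
  a calibrated table should supply it.
- d₀ = 1.0 Å is a convention, not a fitted value; hydrophilicity and
  hydrophobicity scale with it.
- The Cα-based matching assumes homologs with alignable chains; ligand
  superposition or pocket-restricted fitting is not implemented.
- mmCIF, symmetry mates and hydrogen placement are out of scope.
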