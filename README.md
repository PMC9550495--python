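# conswat

Identification of **conserved water molecules (CWMs)** in protein binding
sites by machine learning on microenvironment features.

Crystallographic waters in a ligand-binding pocket fall into two classes:
*conserved* waters that recur at (nearly) the same position across
homologous structures and often mediate protein–ligand hydrogen bonds, and
*free* waters (FWMs) that are displaced or highly variable.  Knowing which
pocket waters are conserved guides ligand design — a polar ligand atom can
target or displace a conserved water.  `conswat` is for structural
bioinformaticians and computational chemists who want to label, featurize
and predict water conservation from plain PDB files.

## What it does

**Labeling.**  A homologous structure is superposed onto the reference with
an optimal least-squares rigid fit (Kabsch) over sequence-aligned Cα atoms;
pairs with RMSD > 2.0 Å are rejected.  The binding pocket is every protein
atom and water oxygen within 7.0 Å of any ligand atom.  For each pocket
water *w* of the reference, the nearest Euclidean distance (NED) to any
water oxygen of the transformed homolog is computed, and

    label(w) = CWM  if NED(w) ≤ 1.2 Å,   FWM otherwise.

**Features.**  Each water oxygen gets six microenvironment descriptors
(letters as used in all reports):

| | feature | definition |
|---|---|---|
| A | atom density | # protein atoms within 3.6 Å |
| B | mobility | (BF_i / mean BF) / (O_i / mean O) over the structure's waters |
| C | B-factor | temperature factor, verbatim (BF = 8π²·Ū²) |
| D | hydrophilicity | Σ h_i·e^(−r_i/d₀) over protein atoms within 4 Å |
| E | hydrophobicity | Σ l_i·e^(−r_i/d₀), carbon propensities l_i |
| F | SASA | Shrake–Rupley accessible area of the water sphere (probe 1.4 Å) |

**Model selection.**  All 63 non-empty subsets of {A…F} are evaluated with
stratified five-fold cross-validation under seven classifier families
(SVM, KNN, decision tree, logistic regression, discriminant analysis,
naive Bayes, and a bagged-tree ensemble, "EL").  Per combination, each
criterion (ACC, SN, PPV, F-score, AUC) is averaged over the seven models;
the winning combination is the one topping the most criteria within a
±0.001 tolerance band.  Families are then compared on the winning
combination by the mean of their five criteria ("average performance"),
and the best family (typically the ensemble) is trained and persisted for
prediction.

A synthetic module generates (a) toy homolog PDB pairs with *planted*
CWM/FWM ground truth and (b) labeled feature tables whose class-wise
marginals emulate the published summary statistics of the two classes, so
the entire pipeline is testable offline.

## Worked example

```bash
conswat simulate structures --seed 7 --out demo/
conswat label --ref demo/reference_seed7.pdb --homolog demo/homolog_seed7.pdb \
              --ligand LIG --out demo/labels.tsv
# -> labeled 40 pocket waters -> demo/labels.tsv
head -3 demo/labels.tsv
# structure_id     chain  resnum  x       y       z       ned    label
# reference_seed7  W      1       -4.518  -1.411  -2.889  2.051  FWM
# reference_seed7  W      2       4.894   -3.725  -0.150  0.160  CWM
```

Water W/1's nearest homolog water lies 2.051 Å away after superposition —
beyond the 1.2 Å threshold, so it is a free water; W/2 has a counterpart at
0.160 Å and is conserved.  Continuing with features and model selection:

```bash
conswat featurize --pdb demo/reference_seed7.pdb --ligand LIG --out demo/features.tsv
conswat simulate features --seed 7 --n 300 --out demo/
conswat compare --features demo/features_seed7.tsv --out demo/models.tsv
# -> best model: NB -> demo/models.tsv
```

(On small tables any well-separated family may win; on the full emulated
training distribution the ensemble is the front-runner.)  From Python, the
same pipeline is three calls: `generate_homolog_pair` / `parse_pdb` →
`label_waters` → `featurize_model` → `evaluate_combinations`.

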