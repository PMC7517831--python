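# Methods

This note documents the models and procedures implemented in `ensemble_vs`,
the defaults that matter, the synthetic data used to exercise them, and the
design decisions taken where the underlying protocol left choices open.

## Binding-site ensemble clustering

All ensemble members are crystal forms of the *same* protein, so no
sequence or structural alignment search is needed: residue correspondence
is by residue key (chain, residue number) intersection, and superposition
is Cα-only least squares (Kabsch, SVD with the reflection branch excluded,
so det(R) = +1 always). A binding site is the set of residues with at least
one heavy atom within the extraction radius (default **10 Å**) of any
ligand heavy atom; hydrogens are ignored on both sides, and alternate
conformations other than blank/'A' are dropped.

The pairwise site-RMSD matrix feeds average-linkage agglomeration (UPGMA,
via `scipy.cluster.hierarchy.linkage`). Node heights follow the ultrametric
convention (merge distance / 2, so two leaves at distance *d* join at
height *d*/2). Because no cut rule is inherent to the tree, the number of
clusters **k** is a parameter (default 8); within each cluster the
representative is the structure with the numerically smallest (best)
resolution, ties broken by lexicographic id for determinism. The RMSD
matrix (TSV) and tree (Newick) are exported so alternative tree methods or
cut rules can be swapped in.

## Validation benchmark

Actives are deduplicated by canonical SMILES (earliest id kept,
unparseable structures logged and dropped). Decoys are drawn from a
candidate library — purged of any structure canonical-equal to an active,
to prevent label leakage — by MaxMin diversity picking on 2048-bit Morgan
fingerprints (radius 2) under Tanimoto distance, at a fixed decoy:active
ratio (default **20**). The first pick is drawn by a seeded RNG; later
picks greedily maximise the minimum distance to the picked set (RDKit's
MaxMin picker, which the test suite checks against a full-recomputation
reference on a fixture whose greedy trajectory is provably tie-free).

## Docking-score validation

Docking is deliberately *not* implemented; any engine's per-structure,
per-mode score tables are ingested (duplicate entries keep the better,
i.e. lower, score). Two validation metrics:

* **Scoring power.** Re-docked pose vs crystallographic pose, heavy-atom
  RMSD in the receptor frame *without* re-superposition (matching re-docking
  practice). With symmetry correction the RMSD is minimised over the
  molecular graph's automorphisms, so a 60°-flipped benzene scores 0. Pass
  threshold 2.0 Å, inclusive.
* **Screening power.** Two-sided Welch *t*-test between active and decoy
  score distributions. Welch was chosen over the pooled-variance variant
  because the benchmark groups are strongly unbalanced (800 vs 16,000) and
  need no equal-variance assumption. Degenerate zero-variance groups with
  equal means report t = 0, p = 1 with a warning. Missing scores are
  excluded with logged counts.

Per structure, the docking precision mode (SP/XP) with the *smaller*
p-value — the stronger separation — is selected, ties going to XP. The
protocol description this follows is ambiguous ("higher P-value"), but its
own tabulated best modes are the smaller p-values; the literal larger-p
reading remains available via `choose_mode(..., prefer="larger_p")`.

## Complex-based pharmacophores

Feature perception uses an editable SMARTS rule file
(`ensemble_vs/data/feature_rules.yaml`): donors/acceptors on the heavy
atom, negative/positive ionizable groups at the charged-group centroid
under physiological-pH conventions (carboxylic acids count as negative,
aliphatic amines as positive), hydrophobes at the centroid of each
contiguous apolar-carbon group of ≥ 2 atoms, and aromatic rings at the ring
centroid with the plane normal attached.

A ligand feature is kept only if the receptor complements it:

| feature | receptor requirement | cutoff (default) |
|---|---|---|
| HBD | an acceptor heavy atom (O) nearby | 3.5 Å |
| HBA | a donor heavy atom (N) nearby | 3.5 Å |
| HYD / RA | ≥ 3 apolar heavy atoms (C, S) near the centroid | 4.5 Å |
| NI / PI | an oppositely charged side-chain group nearby | 5.5 Å |

Receptor inputs are hydrogen-free PDB files, so H-bond partners are
approximated element-wise (acceptors = O, donors = N) and the criterion is
distance-only — angle terms would require protonation, which is
intentionally out of scope. Charged receptor groups are identified by
residue/atom-name tables (Lys NZ, Arg NE/NH1/NH2/CZ, His ND1/NE2; Asp
OD1/OD2, Glu OE1/OE2).

Candidate models are all subsets of ≥ `min_features` (default 3, max 8)
of the ≤ 12 complemented features, ranked by **empirical selectivity**
`−log10(max(m, 0.5)/N)`, where *m* of *N* background molecules match the
model (rarer match = more selective). This surrogate replaces a proprietary
selectivity regression whose functional form is unpublished; rank
correlation with rarity is the intent of any selectivity score, and the
scorer is pluggable. Ties are broken by fewer features, then letter code, so
the ranking is a total order.

The **fit value** of a molecule against a model maximises, over conformers
and injective type-compatible assignments of molecule features to *all*
model features, `Σ_f w_f (1 − d_f / t_f)` subject to every post-Kabsch
displacement `d_f ≤ t_f` (tolerance default 1.6 Å, weight default 1). The
linear displacement form was chosen as the simplest score that is maximal
(Σw) at perfect coincidence and 0 at the tolerance boundary; a squared
variant would only reweight the interior. Model discrimination is the AUC
of the fit value over a labeled benchmark, with AUC > 0.7 flagging an
acceptable model.

## Laplacian-corrected naive Bayes fusion

Continuous descriptors (chosen docking columns + fit values) are
discretised per column by equal-frequency binning (default **10** bins,
frozen at training); missing values get a reserved bin of their own —
failure to dock is informative, so it is never imputed. Each (column, bin)
feature F receives weight `w_F = ln((A+1)/(B·p+1))` (A = actives with F,
B = rows with F, p = base rate): the additive correction is equivalent to
K = 1/p virtual samples occurring at the base rate, so a feature seen in
all rows at the base rate has weight exactly 0, a never-seen feature
contributes ln(1/1) = 0, and rare features shrink toward 0 rather than
exploding. A row's score is the sum of its bins' weights.

The module follows the model/results pattern: `BayesianFusion(X, y).fit()`
returns a `BayesianFusionResults` carrying the weights, binning scheme,
apparent AUC and `summary()`; `fit_cross_validated()` adds a stratified
k-fold out-of-fold AUC, since an apparent (resubstitution) AUC on the same
validation set is optimistic. Both are reported separately.

## Screening funnel

Stage sizes default to **10,000 → 2,000 → 100**. Cross-structure docking
aggregation defaults to `best` (minimum over structures), since ranking "by
the best docking score" is the natural reading when every compound is
docked into all representatives; `mean` and `rank-sum` are flags. All
ranking is deterministic — ties at any cutoff break by lexicographic
compound id. The drug-likeness stage applies Lipinski with **zero**
violations allowed by default (the common one-violation tolerance is a
flag) plus Veber; logP is Crippen's atom-contribution estimate and the
estimator's identity is recorded in the report, because absolute logP
differs across implementations. The final purchasing-style manual
selection below 100 compounds is not modeled.

## Synthetic data: what it does and does not emulate

* **Score benchmarks** draw class-conditional Gaussian scores per
  (structure, mode) column, optionally with missing cells. Gaussians give
  the closed-form AUC `Φ((μ_decoy − μ_active)/(σ√2))` used as an external
  correctness check (e.g. d′ = √2 ⇒ AUC = Φ(1) ≈ 0.841). Real docking
  scores are heavier-tailed and correlated across structures; passing these
  tests shows the statistics are computed correctly, not that any docking
  engine separates real actives this well.
* **Toy complexes** plant one ligand fragment per requested feature type
  (hydroxyl for HBD, carbonyl for HBA, propane for HYD, acetate for NI,
  methylammonium for PI, benzene for RA) and place the complementary
  receptor group at a chosen distance, so survival of each feature under
  the complement filter is known a priori. Fragments are spaced 10 Å apart
  to prevent cross-talk. These are deliberately minimal files — isolated
  residues, no realistic protein geometry; they exercise the filter logic,
  not force fields.
* **SMILES libraries** decorate 19 curated low-lipophilicity scaffolds at
  up to five aromatic CH positions with {H, F, Cl, CH₃, OCH₃}; the full
  ~28k-variant enumeration was audited to satisfy every Lipinski/Veber rule.
  Violators come from a second curated list, each breaking at least one rule
  by a wide margin (alkyl-chain homologation preserves the violation).

## Problem sizes and numerical choices

The acceptance script and test suite run the validation-set construction at
the full 800/16,000 scale and the funnel on a 2,000,000-row synthetic score
table (~25 s); statistical checks use 16,800–20,000 rows, chosen so
sampling error (±0.005 on an AUC) sits well inside the asserted tolerances.
Tolerances: rigid-motion RMSD invariance at 1e-6 Å; Welch agreement with
the explicit formulas at 1e-10 relative; fit-value boundary comparisons
with a 1e-9 slack on the tolerance test to absorb floating-point noise.
Degenerate inputs (constant descriptor columns, all-missing compounds,
single-class labels, empty binding sites) raise explicit errors or collapse
to a single bin with warnings, as documented per module.

## Known limitations

* Docking poses and scores must come from an external engine; the toolkit
  validates and fuses them but computes neither.
* H-bond complementarity is distance-only and element-approximated on
  hydrogen-free receptors.
* The selectivity surrogate measures background rarity only; it is not a
  calibrated regression and its absolute values are not comparable to any
  proprietary score.
* Fit values have no absolute scale across models with different weights;
  downstream use (NB binning, ranking) is scale-free by construction.
* The assignment search in `fit_value` is exhaustive and capped at 8 model
  features; very feature-rich molecules with many repeated types grow
  combinatorially.
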