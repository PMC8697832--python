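# Methods

`fieldqsar` models small-molecule receptor affinity (pKi = −log10 Ki, Ki in
molar) from molecular interaction fields, and uses the fitted models for
virtual screening and scaffold hopping. This note documents the model, the
numerical choices, and what the synthetic benchmark does and does not show.

## Structure preparation

Input structures (SMILES or SDF) are protonated for pH 7 by a fixed rule
table rather than a pKa predictor: aliphatic/alicyclic amines and
amidines/guanidines gain a proton (+1; solution pKa ≈ 9–13), carboxylic,
sulfonic and phosphonic acids lose one (−1; pKa ≈ −1–5). Anilines, amides
and pyridines are left neutral (pKa < 7), and groups whose pKa sits near 7
(imidazoles, N-aryl piperazine-like amines) are *flagged* in the log rather
than guessed at. The table lives in `chemio.PH7_RULES` with the pKa
rationale per rule.

Geometry comes from ETKDG distance-geometry embedding followed by MMFF94
minimization to a force-norm cutoff of 0.1 kcal mol⁻¹ Å⁻¹ (UFF is the
fallback for MMFF-unparameterized molecules). Semi-empirical refinement is
deliberately out of scope; MMFF94 minima are the final geometries. Partial
charges are Gasteiger–Marsili PEOE monopoles — an iterative
electronegativity-equalization scheme — behind a pluggable `charge_scheme`
interface so alternatives can be swapped in.

The embedding seed for each molecule is derived from its canonical SMILES
(`chemio.molecule_seed`). This makes 3D geometry a deterministic property of
molecule identity: a compound met again during screening or scaffold
hopping reproduces its training-time conformer exactly, which keeps
field-descriptor predictions comparable across pipeline stages. The cost is
that conformational uncertainty is not resampled between stages; the
conformer ensemble machinery (below) is the intended tool for exploring
flexibility.

## Conformer ensembles

Ensembles are generated by ETKDG with a raw pool of
min(4 × max_conformers, 2000, 3^n_rotatable) embeddings, each MMFF94
minimized, then pruned by (1) an energy window of 2.5 kcal/mol above the
minimized global minimum, and (2) a duplicate cutoff of 0.5 Å best-fit
heavy-atom RMSD (graph-automorphism aware), keeping at most 500 members in
energy order. The window is applied to *minimized* energies. Equal-energy
duplicates resolve to the earlier-generated conformer. All four limits are
`EnsembleConfig` fields.

## Template alignment

Each ensemble is aligned onto reference template ligands fixed in a common
frame. Candidate poses are (conformer × template × MCS mapping) triples:
the maximum common substructure (heavy atoms, element- and bond-order
matched, ≥ 3 atoms) gives candidate atom mappings, each mapping is
superposed by Kabsch, and poses are scored

    score = 0.5 · (mapped heavy-atom fraction) + 0.5 · field_similarity

where the field similarity is a Carbó-type Gaussian overlap of the two
molecules' field-point values (per channel, width σ = 1 Å), normalized so
identical field-point sets score exactly 1. Weights and σ are
`AlignmentConfig` fields. Ties break deterministically by template order,
then conformer index, then mapping index. There is no interactive
inspection step; instead every alignment is reported (score, substructure
RMSD, template) and poses scoring below a gate (default 0.3) are flagged
for review.

## Fields, field points and descriptors

Four channels are evaluated around each aligned molecule:

- **electro_pos / electro_neg** — positive part and negative-part magnitude
  of the Coulomb potential per unit probe charge,
  V(p) = Σᵢ k qᵢ/(ε(rᵢ)·rᵢ), k = 332.063 kcal Å mol⁻¹ e⁻², with a
  distance-dependent dielectric ε(r) = r (so terms decay as 1/r²; a
  constant-ε mode is available). Values are clamped to ±100 kcal/mol near
  nuclei.
- **steric** — soft van der Waals overlap Σᵢ 10·exp(−rᵢ²/σᵢ²) kcal/mol with
  σᵢ the atomic vdW radius.
- **hydrophobic** — Crippen per-atom lipophilicity contributions weighted
  by exp(−r²/4 Å²); a dimensionless local lipophilicity score. This
  functional form is this package's own choice of a lipophilicity field;
  nothing deeper should be read into its absolute scale.

**Field points** are strict local extrema of each channel on a 1 Å grid
restricted to the 1.5–4.5 Å shell around the molecule, above per-channel
thresholds (1.0 kcal/mol electrostatic, 0.5 kcal/mol steric, 0.1
hydrophobic). The grid is built in a canonical molecular frame (heavy-atom
centroid, third-moment-signed principal axes) so field points follow the
molecule under rigid motion; near-symmetric molecules can flip this frame,
which in practice only reshuffles equivalent extrema.

The **sample-point set** is the union of the *training* molecules' field
points snapped to the shared 1 Å lattice of the template frame
(round-half-to-even per coordinate, duplicates merged). It is independent
of molecule ordering — a gauge-invariant descriptor space. Descriptor
columns are every (sample point × channel) pair; the matrix value is that
channel's field of the aligned molecule at that point.

## Models

- **Field model**: partial least squares fitted by SIMPLS — successive
  rank-one deflation of the cross-product s = Xᶜᵀyᶜ, each weight vector
  projected onto the orthocomplement of the previous loadings, giving
  mutually orthogonal score vectors and a nested coefficient path.
  Predictors are mean-centered only. Default 5 components; a q²-maximizing
  scan is available through `q2_kfold`/`q2_loo` with factories. At full
  rank SIMPLS reproduces least squares, which the tests verify against a
  normal-equations oracle.
- **SVM / kNN / RF**: ε-SVR with RBF kernel, k-nearest-neighbours and
  random-forest regression, hyperparameters chosen by inner 3-fold
  cross-validated grid search with fixed grids (`qsar.DEFAULT_GRIDS`):
  kernel widths are multiples {2⁻¹⁰…2⁻²} of the dimension-aware scale
  1/(p·var), C ∈ {2⁰…2¹⁰}, ε ∈ {0.1, 0.2}; k ∈ 1…15 with uniform/distance
  weighting; 200 trees with depth ∈ {∞, 8}.
- **RVM**: sparse Bayesian linear regression over an RBF kernel basis plus
  bias, with type-II maximum-likelihood (evidence) updates of the weight
  precisions and noise precision; bases with precision above 10⁹ are
  pruned. Iteration cap 1000, convergence tolerance 10⁻⁶ on the log
  evidence.
- **Consensus**: unweighted mean of the field-PLS and SVR predictions
  (weights configurable); the prediction always lies inside the member
  envelope.

Kernel and neighbour models see descriptors **centered and divided by one
global scale** (the overall descriptor standard deviation) rather than
per-column autoscaling. Most field columns are near-constant; unit-variance
scaling inflates them until they dominate every kernel distance, which
destroyed generalization in development experiments, while a single global
scale preserves the natural covariance of the fields (the same reasoning
behind classical CoMFA treatment). PLS centers only.

## Validation

Splits are activity-stratified: records sorted by pKi, cut into 10
equal-frequency bins, and the train fraction (default 0.8) sampled within
each bin; the total train count is exactly round(0.8·n), apportioned by
largest remainder (375 records → 300/75). q² is leave-one-out by default
(1 − PRESS/SStot); a 5-fold variant exists and is labelled distinctly. Test
performance is reported both as the coefficient of determination about the
test mean and as squared Pearson correlation, because the field's reports
often conflate the two. MAPE uses pKi-scale denominators. The ranking
diagnostic is an OLS fit of experimental log-potency on predicted pKi with
its r², plus top-m/bottom-m overlap counts.

## Screening and scaffold hopping

The pharmacophore is derived from the template ligands via a documented
SMARTS feature table (aromatic rings, H-bond donors/acceptors, positive
ionizable, hydrophobic; centers at matched-atom centroids, tolerance 1 Å).
Features of the same type co-located across ≥ 2 templates merge to their
centroid and become *required*. Matching assigns model features to
distinct same-type ligand features — required features claim ligand
features first — exhaustively for ≤ 8 features of a type, by Hungarian
assignment otherwise; matched centers are Kabsch-superposed and the RMSD of
matched distances is minimized over the conformer ensemble. Molecules pass
the filter when that RMSD is below the gate (default 0.75 Å; an exact
overlay always passes, so the 0 Å boundary stays meaningful). Survivors are
aligned, described on the model's sample points, and ranked by consensus
pKi (ties: RMSD, then id).

Scaffold hopping cuts designated acyclic bonds of a parent, partitioning it
into parts; non-frozen parts are replaced by library fragments of matching
attachment arity, products are re-embedded (molecule-identity seed), aligned
and rescored by the consensus. Frozen parts — e.g. a core responsible for a
conserved salt bridge — are never touched, and preserved parts are
guaranteed unchanged by construction (fragment-and-rezip of the remaining
parts).

## Synthetic benchmark

The generator builds a few hundred molecules from 3 phenethylamine-like
scaffolds × 12 × 12 R-group pairs (halogens, alkyl, methoxy/ethoxy, amino,
hydroxy, cyano, CF₃ — chosen to vary both electrostatics and sterics), runs
the real preparation pipeline, and plants

    pKi_i = offset + w · d_i + ε_i,  ε_i ~ N(0, σ²),

with d_i the descriptor vector on a generator-built sample-point set and w
a sum of 4 Gaussian patches (width 2 Å) centered on variance-weighted
anchor columns of the electrostatic and steric channels — a low-rank,
spatially smooth SAR like the localized interaction regions real receptor
maps show. Weights and offset are rescaled once so the noiseless activities
span pKi 5–10.5; defaults are n = 200 molecules and σ = 0.4 pKi. Everything
regenerates bit-for-bit from the seed, and changing σ rescales residuals
without touching the design (the noise stream is drawn independently of
σ). Ground truth (w, noiseless activities) ships with the data, so
parameter recovery, the noise ceiling q² ≤ 1 − σ²/var(pKi), and the
permutation null are all checkable.

What the benchmark does **not** emulate: real 5-HT2A SAR or chemotypes,
activity cliffs, assay heterogeneity, tautomers/stereochemistry, or
alignment failure modes of genuinely diverse chemotypes. Passing the
benchmark shows the machinery recovers a planted field-linear signal at
realistic noise, not that it predicts real receptor affinity.

## Problem sizes in the tests and acceptance script

The default benchmark is n = 200 (160/40 split, ~3000 descriptor columns).
The multi-seed robustness checks regenerate the full study for 20 seeds;
the permutation null uses an 80-molecule subset of the training descriptors
with 40 (tests) or 20 (script) permutations. These sizes were chosen so a
complete run stays in the minutes range on a single CPU while keeping the
statistics stable.

## Known limitations

- Gasteiger monopoles are a coarse stand-in for a polarizable multipole
  description; absolute field magnitudes should not be over-interpreted.
- Single-conformer training poses (with identity-derived seeds) trade pose
  uncertainty for reproducibility; ensemble alignment mitigates but does
  not remove this.
- The pH-7 rule table ignores microspecies equilibria; borderline groups
  are only flagged.
- The hydrophobic channel is an ad-hoc lipophilicity field.
- MCS-based alignment assumes some shared substructure with a template;
  molecules without one are excluded (and reported) rather than aligned by
  fields alone.
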