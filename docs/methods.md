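# Methods

This note documents the models and procedures implemented in `fdmoscreen`,
the parameters that matter, what the synthetic generators do and do not
emulate, and the numerical and design choices made where the design was
genuinely open.

## Stereochemistry from docked pose ensembles

### Geometry

A pose's chirality call is purely geometric. Three named atoms on the
substrate's aromatic (resorcinol) ring, in a fixed order, span the ring
plane; the unit normal is the normalized cross product
(a₂−a₁) × (a₃−a₁), so the atom order fixes the normal's sign by the
right-hand rule. The pose angle θ is measured between this normal and the
vector from the ligand's mean heavy-atom coordinate to the FAD reference
atom — C4α, the flavin ring atom that bonds the hydroperoxyl group in the
activated cofactor, i.e. the atom the substrate must approach to react.
θ ∈ [0°, 90°) calls S and θ ∈ (90°, 180°] calls R. Exactly 90°
(within 1e−9°) is *degenerate*: neither face is presented, and such
clusters are counted as non-R (they contribute to the partition function
but never to the R numerator), with a warning. Collinear ring atoms
(cross-product norm < 1e−9 Å²) and a FAD reference coinciding with the
ligand centroid raise degenerate-geometry errors rather than returning an
arbitrary call.

Reversing the ring atom order maps θ → 180° − θ and therefore swaps every
R/S call — the chirality antisymmetry the test suite checks. Users must
therefore pick the ring triple once, consistently across a library.

### Clustering

Poses are clustered with a deterministic greedy leader algorithm: visit
poses in ascending energy order; a pose joins the first existing cluster
whose *leader* is within the radius (default 1 Å) in heavy-atom RMSD,
else founds a new cluster. RMSD is computed in the fixed receptor frame —
no least-squares superposition, since all poses of one complex share the
receptor frame by construction. Because the visit order is ascending in
energy, every leader is also its cluster's lowest-energy member, which
makes it the representative; clusters are ranked by representative energy
with ties broken by lower representative pose id. Leader clustering was
chosen over k-means-style refinement because it is deterministic,
order-reproducible and exactly analyzable on planted data; the radius and
the no-superposition convention are the parameters that matter.

### Boltzmann weighting

Each cluster is a mesostate with degeneracy g_i (size) and energy E_i
(representative, kcal/mol). The R fraction is

R_frac = Σ_{i∈R} g_i exp(−E_i/k_BT) / Σ_i g_i exp(−E_i/k_BT).

The exponent is negative — lower-energy mesostates dominate, consistent
with ranking clusters by their lowest representative energy. E_min is
subtracted before exponentiation; this cancels in the ratio (shift
invariance) and keeps the exponentials in floating-point range.
Temperature defaults to 300 K with k_B = 0.0019872 kcal/(mol·K); both are
configurable (`ThermoParams`). As T → 0 the lowest-energy cluster decides
the call; as T → ∞ the call tends to the size-weighted fraction
Σ_R g_i / Σ g_i.

Labels: R_frac > 0.8 → R, R_frac < 0.2 → S, otherwise racemic (R/S). The
boundary values 0.2 and 0.8 fall in the racemic band (all three defining
inequalities are strict, so the endpoints had to be assigned; racemic is
the conservative choice). Consensus across ligands is the modal label,
racemic when the mode is not unique.

## Reactivity descriptors and classifier

Five descriptors summarize the top-ranked cluster representative:

| descriptor | definition | units |
|---|---|---|
| `fad_distance` | ligand mean heavy-atom coordinate to C4α | Å |
| `fad_angle` | θ of the top cluster | degrees |
| `anion_distance` | ligand anion oxygen to CZ of the active-site arginine | Å |
| `energy_efficiency` | docking energy / n heavy atoms | kcal/mol·atom |
| `pkd_efficiency` | predicted pK_d / n heavy atoms | 1/atom |

The ligand anion atom is user-designated (default: the phenolate oxygen of
the ligand topology) because the substrates are anions at a specific
oxygen; the arginine is located per enzyme through the reference-numbering
map (R206 in TropB numbering), and if no arginine CZ exists at the mapped
position the descriptor becomes a missing marker with a warning. External
affinity predictions (e.g. a CNN scoring function) enter only through the
`AffinityScorer` contract — a table lookup or user plug-in returning pK_d
or a missing marker; no affinity model is re-implemented here.

The classifier is a maximum-likelihood logistic regression (statsmodels)
of the binary any-conversion label on the descriptors, with Wald standard
errors and p-values. All five descriptors are kept by default — dropping
any (e.g. after a significance screen such as "p > 0.10 in 3 of 4
ligand-specific fits", provided by `screen_descriptors`) is an explicit
option. On (quasi-)separation — statsmodels raising, non-convergence, or
runaway coefficients — the model is refit by minimizing the ridge-penalized
negative log-likelihood (α = 1e−4 on slopes, intercept unpenalized) and
flagged; its standard errors then come from the penalized Hessian.
Classification threshold: 0.5 (none is canonical for this problem).
Consensus descriptors across ligands are plain means over non-missing
values.

## Sequence features

Reference numbering: the k-th non-gap character of the chosen reference
row is residue k (1-based); gap columns of the reference are unmapped.
Binding-site residues have any heavy atom within 4.5 Å (inclusive — the
conventional contact-cutoff reading) of any ligand heavy atom of any top
pose; second-shell residues are within 4.5 Å of a binding-site residue and
exclude binding-site members themselves (the shells are disjoint by
design). The residues-of-interest union is taken across enzymes after
translating each enzyme's residue numbers to the reference through the
alignment. Feature columns must be residues of interest AND have gap
fraction ≤ 0.10 (strictly more than 10 % gaps drops the column; exactly
10 % is retained). Encoding is one integer-coded categorical feature per
column over a fixed alphabet (gap is category 0), preserving
one-SHAP-value-per-residue semantics; one-hot encoding would smear a
residue's attribution over 21 indicator columns.

Stereochemistry training labels are −1 (S), 0 (R/S), +1 (R). The default
per-enzyme consensus is mode-based (ties → 0); a mean-based variant (sign
of the per-ligand label mean, |mean| < 0.25 → 0) is available behind
`stereo_labels_from_calls(method="mean")` for workflows that average
per-ligand calls instead of taking the mode.

## Sequence-function models and SHAP consensus

Cross-validation is stratified 5-fold with seed 17 by default, shared
across algorithms so fold-level aggregates are comparable; stratification
falls back to plain K-fold with a warning when a class has fewer members
than folds. Default backends: XGBoost and LightGBM (the two
gradient-boosting flavors) and a scikit-learn random forest. Backends are
pluggable behind one fit/predict/SHAP contract and degrade gracefully when
a library is absent; at least one must be available. Defaults are modest
(100 boosting rounds, depth 4 / 31 leaves; 200 trees for the forest) —
the planted-determinant problems this package validates against are
low-dimensional and strongly signaled, and an optional seeded random
search (≤ 16 configurations, inner 3-fold accuracy) is available via
`train_ensemble(tune=True)`.

SHAP values are computed on held-out rows only, with the
tree-path-dependent value function: the boosters' native `pred_contribs`,
and for the forest this package's own TreeSHAP (`fdmoscreen.treeshap`),
a numba-jitted implementation of the polynomial-time path algorithm whose
correctness is guarded by exact additivity and by brute-force Shapley
enumeration over feature subsets on small trees. Booster SHAP values live
in margin (log-odds) space and forest SHAP values in probability space;
this is immaterial downstream because every aggregate is normalized within
its own (algorithm, fold).

Consensus importance: per (algorithm, fold), a residue's importance is the
mean of |SHAP| over held-out rows and classes, min–max normalized to
[0, 1] across residues; the consensus is the unweighted mean of these
vectors over all (algorithm, fold) pairs — a symmetric mean, so the
ranking is invariant to algorithm and fold order. An all-zero fold
normalizes to zeros with a warning rather than dividing by zero.
Dependence profiles: per (algorithm, fold), the class-specific SHAP matrix
is divided by its maximum absolute entry (sign-preserving, → [−1, 1]) and
the chosen residue's column is grouped by the amino acid each row carries
there, pooled across folds and algorithms. For multiclass targets the
class-specific SHAP slice is used (e.g. the R class, +1).

Metrics: accuracy, Gorodkin's R_K multiclass generalization of the
Matthews correlation coefficient (reducing to the familiar binary formula
for two classes; undefined and reported as missing when a marginal is
single-class), and macro-F1 (classes with no support and no predictions
score 0). These are computed from the confusion matrix by this package and
cross-checked against scikit-learn in the test suite.

## Synthetic study conditions

The generators define the desk-scale conditions under which the pipeline
is validated; they are deterministic functions of their seed.

* **Toy complexes** place a planar six-carbon ring (plus in-plane
  decoration atoms that keep the heavy-atom mean on the ring axis) with
  the C4α reference atom at an exactly controlled angle, so the geometric
  stage can be tested with zero tolerance slack.
* **Pose ensembles** plant clusters as rigid-body *translations* of a
  template (no rotation), so fixed-frame RMSDs equal translation distances
  and the recovery guarantee is analytic: with jitter ≤ 0.4 × radius and
  centers ≥ 3 × radius apart, leader clustering recovers the planted
  partition exactly. Generation refuses configurations whose jitter
  reaches half the minimum inter-center distance.
* **Descriptor tables** draw standard-normal descriptors and Bernoulli
  labels from a stated logistic model — the recovery target for the fit.
* **Screen datasets** default to 300 enzymes × 60 columns with an F/Y
  stereo switch (F → S, Y → R), an I/V reactivity switch (I → reactive),
  10 % label noise (stereo noise replaces the label by a uniform draw from
  the other two classes, including racemic; reactivity noise flips the
  bit), uniform background composition over the 20 amino acids and 2 %
  gaps in non-switch columns. Switch columns carry no gaps (determinant
  positions). Noise ≥ 0.5 is refused — the signal must dominate.

What the generators do **not** emulate: phylogenetic correlation between
sequences (real families are not i.i.d. across rows), realistic amino-acid
composition or conservation gradients, docking physics (rotamers,
force-field energies), or multi-residue epistasis. Passing the recovery
studies therefore shows that the pipeline's statistics behave as designed
under clean planted signal — not that real screens reach these accuracies.

## Validation studies (`fdmoscreen.benchmarks`)

Problem sizes were chosen so each study finishes in minutes on one CPU:
500 random cluster sets for the Boltzmann oracle; 7 probe angles for the
geometry rule; 200 ensembles (half free-form invariants, half planted
recovery) for clustering; 20 seeds × n = 5000 for logistic recovery; 20
screen replicates for SHAP switch recovery and 20 for the shuffled-label
control; 200 random confusion matrices for the metric oracles.

A note on the shuffled-label control: with fold-level min–max
normalization, each fold's maximum importance is exactly 1 by
construction, and CV folds share most of their training rows, so the same
finite-sample spurious correlation tops every fold. Under pure noise the
consensus maximum therefore sits well above twice the median importance —
the control measures and reports this concentration rather than asserting
flatness away. Interpreting a consensus ranking on real data should
likewise rest on the margin between the top residues and the bulk (in the
planted studies the switch scores ~1.0 against a bulk below 0.1), not on
any residue merely exceeding a median multiple.

## Known limitations

* Pose generation, structure prediction, cofactor placement and
  minimization are out of scope: inputs are receptors with FAD already
  placed and pose ensembles with energies already assigned.
* Leader clustering is one deterministic stand-in for distance-based pose
  clustering; tools that refine assignments iteratively can split
  borderline poses differently near the radius boundary.
* The logistic model assumes descriptor effects are linear on the log-odds
  scale; strongly non-monotone descriptor-reactivity relations would
  require the tree models instead.
* Alignments are consumed, not computed; an external aligner must produce
  the MSA, and column shifts between aligner versions propagate into
  residue numbering.
* SHAP consensus ranks association, not mechanism: a residue correlated
  with a functional clade will rank highly whether or not it is causal.
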