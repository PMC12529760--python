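# Methods

`deamidkit` computes six structural-dynamics descriptors per asparagine
site from MD trajectory ensembles and feeds them to an imbalanced-learning
classification protocol. This note records the model behind each
descriptor, the numerical choices, what the synthetic generators emulate,
and the known limitations.

## Reaction model and which step each descriptor probes

At neutral-to-basic pH, Asn deamidation proceeds through deprotonation of
the backbone N–H of the residue following the Asn (the *n+1* residue),
intramolecular attack of the resulting nitrogen anion on the side-chain
amide carbon (ring closure to a tetrahedral intermediate, then
succinimide), and hydrolysis to Asp/isoAsp. Succinimide formation is
rate-determining, so the descriptors target the first two steps:

| feature | step | group | what it measures |
|---|---|---|---|
| `CN` | deprotonation | solvation | first-shell water count around N(n+1) |
| `VolE` | deprotonation | electrostatics | spread of the environment field at the backbone segment |
| `pctN` | deprotonation | H-bonds | % frames N(n+1) accepts an H-bond |
| `pctNH` | deprotonation | H-bonds | % frames the N(n+1)–H donates an H-bond |
| `dAconf` | ring closure | conformation | free-energy cost of reactive-like fragment geometry |
| `RCS` | ring closure | electrostatics | environment (de)stabilisation of the cyclisation TS |

All coordinates are held in nm internally; Å-based formats are converted
on read, because every geometric cutoff (0.4 nm solvation shell, 0.25 nm
H-bond distance, 0.15 nm RMSD gate) is natural in nm.

## Ensemble handling

Frames from all replicate runs are concatenated for descriptor estimation;
per-replicate statistics remain available for error bars, reported as half
the sample standard deviation across replicates. `load_ensemble` keeps the
trailing `1 − discard_fraction` of each run (equilibration discard). Only
orthorhombic boxes are supported; all pair distances use the minimum-image
convention. Water residues are recognised by name (HOH/SOL/WAT/TIP3…),
with the first oxygen atom per water as the RDF species. The side-chain
amide N/O accept both the PDB names (ND2/OD1) and the Nγ/Oγ-style aliases
(NG/OG) via a small alias table. Sites with proline at n+1 are excluded
(no backbone amide); unannotated sites are featurizable but excluded from
the ML table.

## Coordination number

The RDF of water oxygens around N(n+1) is histogrammed in 0.002 nm bins to
1.0 nm by default (the bin width is ours; it makes the discretisation error
of the integral far below one water molecule) and normalised by shell
volume × water density × frames, with density = water count over the mean
box volume. CN integrates `4π ρ r² g(r)` by the midpoint rule from 0 to
0.4 nm. CN is checked against the exact per-frame count of shell waters
(`direct_shell_count`); the two agree to within one bin's discretisation.

## Hydrogen-bond classes

Per frame, a Baker–Hubbard-style geometric criterion is applied: H···A ≤
0.25 nm and D–H···A angle ≥ 120°. The source method's standard thresholds
are used because no alternative values were specified. Hydrogens are
assigned to their covalent donor as the nearest N/O *of their own residue*
within 0.125 nm in the first frame — the same-residue restriction is
chemically exact and makes the assignment invariant under frame
reordering. A frame contributes at most once per class regardless of how
many partners qualify, so each class percentage is normalised to 100 =
persistent through the whole trajectory. Partners are protein atoms by
default; water can be included with a flag. Only the two N-based classes
enter the models; the O-acceptor class is computed and reported.

## Local PCA and the conformational feature

For each site, the 10 heavy atoms of the Asn + (N, CA) of n+1 are
extracted per frame, least-squares superposed (Kabsch) onto a reference
geometry, and the covariance of the 30 Cartesian coordinates, taken about
the ensemble mean, is diagonalised. Two references are used: R (the
ring-closure reactant of the AsnNHMe model) and R*, which differs from R
only in the N(n+1)–Cγ distance (resembling the tetrahedral intermediate).
These reference geometries and the R/TS dipoles are QM-derived *inputs*
read from a JSON file; the package does not compute them. PC sign is fixed
so the reference projects at PC1 ≥ 0, remaining signs by largest-component
positivity — pure reporting conventions.

The free-energy profile along PC1 is `−kB T ln(n_bin/n_max)` with kB =
0.0019872 kcal/(mol K), T defaulting to 310 K and 0.005 nm bins. The
feature `dAconf` averages the profile values in the bins containing PC1 =
±0.02 and ±0.05 nm over both references; the absolute-value reading (both
signs averaged) resolves a sign ambiguity in how the reactive-like PC1
location is stated. A site that never visits any targeted bin carries a
sentinel, resolved at table assembly to 10× the dataset's maximum finite
`dAconf` — an explicit "no reactive conformation observed" penalty.
Covariance about the ensemble mean (rather than about the reference) was
chosen because it is the standard estimator; the reference enters through
the superposition target and the projection origin. Replicate convergence
is assessed by the RMSIP of the leading two-PC subspaces across replicates.

## Electric-field descriptors

One field vector per frame is evaluated at the mass-weighted COM of the
five-atom backbone segment (CA, C, O, N(n+1), CA(n+1)) as the direct
Coulomb sum `k_e Σ q_i (r−r_i)/|r−r_i|³` over *all* charged atoms outside
the site's own fragment∪segment — protein, water and ions alike, with no
distance cutoff (fields decay as r⁻² and the minimum-image sum is cheap at
these sizes); `k_e = 33.206 kcal mol⁻¹ nm e⁻²`. `VolE` counts the occupied
cells of a 50³ grid over the field-vector heads times the cell volume. The
grid extent is the bounding cube over all sites of a dataset, shared so
volumes are comparable across sites, and recorded in the output; occupied
cells are also counted per replicate as the convergence check.

For the ring-closure step, frames whose fragment superposes onto R below
0.15 nm RMSD are selected, and for each `δ = E·μ_TS − E·μ_R` is computed
(dipoles converted to e·nm, 1 D = 0.020819 e·nm, so `E·μ` is in kcal/mol
directly). Frames with |δ| ≥ 6 kcal/mol are labelled (de)stabilising. The
RCS product uses the percentage of frames with δ > 0 as the Δ(E·μ) term by
default — the percentage formulation is the one used as a descriptor — with
a mean-δ mode available since the product formula can also be read as a
difference of means; both are always reported. A sentinel-valued `dAconf`
forces RCS = 0 (the damping factor uses the dataset maximum including
resolved sentinels, so sentinel sites land exactly at zero: no reactive
conformation, no ring-closure stabilisation to speak of).

## Classification protocol

The table is split 70/30 stratified by label under three different seeds.
The training set is balanced by SMOTE (synthetic minority rows as convex
combinations `x + u(x_nn − x)`, u~U(0,1), of a minority point and one of
its k = 5 nearest minority neighbours; k is clipped to minority−1 when the
class is tiny). Implemented in-package and verified against its convexity
and balance contracts. Hyperparameters are tuned by exhaustive grid search
with stratified 8-fold CV scored by mean ROC-AUC, ties to the first grid
point, then refit on the full training set. Families and grids:

* Gaussian Naive Bayes — smoothing: 50 log-spaced values in [1e-9, 10];
* Logistic Regression — liblinear L2, max 100 iterations, C: 20 log-spaced
  values in [0.01, 10] (the endpoints are stated; the 20-point
  discretisation is ours);
* Random Forest — trees {10,50,100,200,300}, depth {5,10,20,30,∅},
  min-split {2,5,10}, min-leaf {1,2}, max-features {sqrt, log2} (ranges as
  stated; the discretisation of trees/depth is ours). A reduced grid
  (`SMALL_RF_GRID`) spanning the same ranges is provided for interactive
  use and is what the shipped end-to-end checks run.

Evaluation reports macro (unweighted) precision/recall/F1, accuracy,
rank-statistic ROC-AUC (midranks for ties), and MCC (0 when a denominator
factor vanishes). The deamidation score is the predicted probability of
reactivity; scores exactly at the 0.5 threshold classify positive (the
boundary rule had to be fixed somewhere; positive is the conservative
choice for a liability screen). Reports contain each split, the best split
and the across-split averages.

LOFO importance removes a feature (or a chemical group: Conf = dAconf,
Solv = CN, HB = pctN+pctNH, El = VolE+RCS) from the SMOTE-balanced training
set and the test set, retrains with the tuned hyperparameters (a retune
switch exists; reusing the full-model hyperparameters is the default
reading of "the same model with one feature removed"), and reports the
accuracy drop averaged over the three split seeds.

## Synthetic generators

`make_toy_ensemble` emits a desk-scale Asn–Gly system whose statistical
structure matches what each descriptor measures: an exact number of
first-shell waters (bulk waters are kept outside 0.45 nm so the shell
count is the analytic CN), rigid ideal H-bond partners recomputed each
frame from the jittered amide geometry (so an enabled class is satisfied
in every frame), a discrete conformer mixture with chosen populations, and
a fixed point-charge layout. The reference states it ships are
hand-constructed synthetic stand-ins for the QM inputs, preserving the
defining property that R and R* differ only in the N(n+1)–Cγ distance;
dipole magnitudes are amide-scale (~0.1 e·nm ≈ 5 D). These fixtures are
not physical MD: there are no forces, no Boltzmann sampling beyond the
imposed conformer populations, and no solvent structure. Passing tests
therefore demonstrate the *estimators* are correct, not that descriptors
computed on real trajectories will separate reactive from nonreactive
residues.

`make_feature_dataset` draws Gaussian class-conditional features at the
study scale (63 sites, 13 reactive) with reactive-class mean shifts whose
signs follow each feature's mechanistic role. The default shift of 1.75 sd
per feature yields a ≈4.3 sd Mahalanobis separation — a well-separated
regime in which all three model families should succeed; it is the
end-to-end check's operating point, not a claim about real data.

## Problem sizes and numerical choices

The shipped checks use: 2,000 frames for the ideal-gas CN closed form,
100 frames for H-bond oracle equivalence, 5×10⁴ frames for the two-state
free-energy recovery (basin gaps are compared via basin partition sums
over the profile, which removes the dependence of single-bin readings on
histogram phase), 10⁴ samples for the isotropic-field favouring fraction,
and the reduced RF grid for the three-seed end-to-end run. Degenerate
inputs fail loudly: single-frame PCA, empty ensembles, missing charges,
r_max beyond half the box, singleton minority classes.

## Known limitations

* Triclinic boxes are unsupported; orthorhombic minimum image only.
* H-bond hydrogen assignment is geometric (first frame); formats carrying
  explicit bond topology are not exploited.
* The electric field is a fixed-point-charge sum — no polarisation, no
  Ewald; it is a descriptor, not an energy model.
* `dAconf` readings depend on histogram binning at very low sampling; the
  sentinel rule handles the unsampled case but sparsely-sampled bins are
  noisy.
* Real-protein reproduction requires the original trajectories and QM
  reference data; the package consumes both as inputs.
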