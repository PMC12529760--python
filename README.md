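# deamidkit

Mechanism-driven descriptors and machine-learning protocol for predicting
asparagine (Asn) deamidation liability from molecular-dynamics trajectory
ensembles.

Asn deamidation is a spontaneous post-translational modification — and a
critical quality attribute for biotherapeutics — that proceeds through
deprotonation of the backbone N–H of the residue following the Asn, ring
closure to a tetrahedral intermediate, succinimide formation (the
rate-determining stage) and hydrolysis to Asp/isoAsp. Sequence rules
(AsnGly/AsnSer "hotspots") miss both protected canonical motifs and
reactive noncanonical ones. `deamidkit` instead computes, per Asn site,
six structural-dynamics descriptors tied to the first two reaction steps
and trains classifiers on them. It is aimed at computational chemists and
biologics developability groups who already have equilibrium MD ensembles
of their proteins.

## The descriptors

For each Asn and its *n+1* residue (sites with Pro at *n+1* are excluded —
no backbone amide):

* **CN** — first-shell water coordination of N(n+1):
  `CN = 4πρ ∫₀^{0.4nm} r² g(r) dr`, with g(r) the water-oxygen RDF around
  N(n+1) and ρ the water number density.
* **VolE** — volume of field-vector-head space occupied on a 50³ grid by
  the per-frame electric field `E = k_e Σ qᵢ(r−rᵢ)/|r−rᵢ|³` evaluated at
  the backbone-segment centre of mass (environment charges only).
* **pctN / pctNH** — percentage of frames in which N(n+1) accepts,
  respectively the N(n+1)–H donates, a hydrogen bond (geometric criterion,
  H···A ≤ 0.25 nm, angle ≥ 120°); persistent bonds flag structured,
  deprotonation-protected amides.
* **dAconf** — conformational free energy `−k_B T ln(n/n_max)` along PC1
  of a local Cartesian PCA of the 10-heavy-atom Asn/(n+1) fragment
  superposed onto QM-derived reactive references (R and R*), read at
  PC1 = ±0.02 and ±0.05 nm and averaged; sites that never sample the
  reactive-like region get a 10×-dataset-max sentinel.
* **RCS** — ring-closure stabilisation
  `RCS = Δ(E·μ) × (1 − dA_conf/dA_conf^max)` over reactant-like frames
  (fragment RMSD to R < 0.15 nm), where Δ(E·μ) summarises how often the
  environment field stabilises the cyclisation transition-state dipole
  over the reactant dipole.

The labeled feature table feeds a protocol built for small, imbalanced
datasets: stratified 70/30 splits under three seeds, SMOTE oversampling of
the training minority, grid-searched Random Forest / Gaussian Naive Bayes
/ Logistic Regression (8-fold CV, ROC-AUC scoring), macro metrics + MCC +
rank AUC, per-residue deamidation scores (probability of reactivity,
threshold 0.5), and leave-one-feature-out importances per feature and per
chemical group. See `docs/methods.md` for every convention and default.

## Worked example

Everything is testable without MD data: the package ships a synthetic
fixture generator with analytic ground truth.

```
$ deamidkit make-fixture demo_fix --frames 20 --replicates 2 --seed 7
$ deamidkit extract-features \
    --topology demo_fix/fixture.pdb \
    --charges demo_fix/fixture_charges.csv \
    --annotations demo_fix/fixture_annotations.csv \
    --references demo_fix/fixture_references.json \
    --protein-id fixture --out demo_features.csv
wrote 1 labeled sites to demo_features.csv
$ cat demo_features.csv
protein_id,residue,CN,VolE,pctN,pctNH,dAconf,RCS,label
fixture,1,2.9999899229110474,7.937294923951343e-06,0.0,100.0,0.9914652560726037,0.0,1
```

The fixture was built with exactly 3 first-shell waters and a persistent
ideal N–H donor bond, and the extracted features recover that: CN ≈ 3.00,
`pctNH` = 100%, `pctN` = 0%. `dAconf` ≈ 0.99 kcal/mol is the cost of the
reactive-like PC1 readings for this jittered single-conformer ensemble,
and RCS = 0 because a single site is trivially at the dataset maximum of
`dAconf`.

On a study-scale synthetic table (63 sites, 13 reactive — the class
balance of the deamidation problem):

```
$ python -c "from deamidkit.synthetic_fixtures import make_feature_dataset;
             make_feature_dataset(seed=11).to_csv('demo_table.csv', index=False)"
$ deamidkit evaluate demo_table.csv --model random_forest --seed 1
{
 "best_params": {"max_depth": 5, "max_features": "sqrt",
                 "min_samples_leaf": 1, "min_samples_split": 2,
                 "n_estimators": 10},
 "cv_roc_auc": 1.0,
 "metrics": {"precision": 1.0, "recall": 1.0, "f1": 1.0, "accuracy": 1.0,
             "auc": 1.0, "mcc": 1.0, "tp": 4, "tn": 15, "fp": 0, "fn": 0}
}
```

With the generator's default (well-separated) classes the Random Forest
classifies the held-out 19 residues perfectly — the expected behaviour at
a ~4 sd class separation, and a sanity check of the whole split → SMOTE →
tune → evaluate chain rather than a statement about real proteins.

For real systems, point `extract-features` at your topology (PDB/GRO), one
trajectory per replicate (XTC/DCD/TRR or multi-model PDB), a partial-charge
sidecar CSV, an annotation CSV (`protein_id,residue_number,label`) and a
reference-state JSON holding the QM fragment geometries and dipoles.

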