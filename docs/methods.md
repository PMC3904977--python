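# Methods

This note records the model, the conventions chosen where the design was
genuinely open, the numerical choices, and what the synthetic fixtures do
and do not establish.

## Interface definition and surface labeling

Solvent accessibility is computed with rolling-probe point sampling
(Shrake–Rupley style): each atom's sphere of radius `r_vdw + r_probe` is
covered with a Fibonacci lattice of quasi-uniform points and the
unoccluded fraction gives the exposed area. Defaults: probe 1.4 Å
(water), 960 points per atom. 960 points keep the single-atom closed-form
error well under 1% and the total-area deviation from a 20,000-point
reference within 2%; the resolution is configurable, and fewer than 12
points is refused as meaningless.

A residue is an **IFR** when its accessibility in isolation (its chain
alone) exceeds its accessibility in the complex by more than
`δ_area = 0.1 Å²`; the small positive threshold absorbs sampling noise —
with finite point sampling, two distant chains can otherwise differ in the
last digit. Non-IFR residues with relative accessibility ≥ 5% of the
type-specific maximum (extended Gly-X-Gly tripeptide reference values)
are **FSR**; the rest are buried. Both δ_area and the 5% surface
threshold are package conventions: the interface definition itself only
says "undergoes a change in accessibility", and the surface cutoff for
what counts as exposed is a standard but arbitrary choice in the field.

The per-chain interface area is the summed per-residue accessibility loss
(clipped at zero per residue). Size classes: ≤ 800 Å² small, 800–3,000 Å²
medium, > 3,000 Å² large. (An alternative "small = 200–500 Å²" convention
exists in the literature; the 800/3,000 scheme is used consistently here.)

## Dataset filter chain

`filter_dataset` applies, in order: resolution ≤ 3 Å; no nucleic-acid
polymer; oligomeric-state consistency flag; ≥ 2 chains; every chain ≥ 50
residues; interface area ≥ 200 Å²; not a UniProt-style fragment. The
oligomeric-state and fragment flags are accepted as input metadata, never
fetched from external services. The per-entry interface area is the
maximum over chains of the per-chain lost area. Redundancy reduction
clusters chains greedily (longest first) by global-alignment identity
(match +1, mismatch 0, gap open −10, extend −0.5; identity = matches /
alignment length) at a 30% cutoff; representatives are mutually below the
cutoff.

## Contact criteria and energies

The energy scale is fixed: hydrophobic 0.6, aromatic stacking 1.5,
hydrogen bond 2.6 (all direct and water-mediated flavours), charged pair
10.0 (attractive or repulsive — the repulsive magnitude is a package
convention), disulfide 85.0 kcal/mol. The geometric criteria are
conventions, exposed through `ContactCriteria`:

| type | criterion | default |
|---|---|---|
| hydrophobic | apolar-carbon pair | ≤ 3.9 Å |
| aromatic | ring-centroid distance | ≤ 5.0 Å |
| hydrogen bond | N/O–N/O | ≤ 3.2 Å |
| charged | charged-group N/O pair | ≤ 6.0 Å |
| disulfide | SG–SG | ≤ 2.5 Å |
| water-mediated | both partners H-bonded to 1 (W) or 2 mutually H-bonded (WW) waters | ≤ 3.2 Å per leg |

Disambiguation rules: at most one record per (residue pair, type), at the
closest qualifying atom pair; sequence-adjacent residues are skipped so
peptide-bond C=O···N geometry is not an H-bond; an atom pair in which
both atoms carry formal charge is a charged contact only, never
double-counted as an H-bond. Hydrogen-bond records are tagged
main-chain/side-chain (MM/MS/SS and the water-bridged variants) by the
backbone membership of the two protein atoms.

**Unused contact energy** is the gap between the per-amino-acid-type
maximum (per contact type and total) and the residue's realized energy,
floored at zero. The maxima are a corpus property: they are computed over
the training entries at fit time (per fold during cross-validation) and
persisted inside the classifier bundle, rather than screened over an
external database — this keeps training self-contained and leakage-free.

## Spatial descriptors

- **Density**: summed atomic masses (waters excluded, atoms counted by
  center inclusion) within spheres of radius 3–7 Å at the Cα and LHA
  anchors, divided by sphere volume. Center-inclusion rather than
  volume-overlap weighting is a convention.
- **Sponge**: sphere volume minus enclosed van der Waals volumes, clipped
  at zero, normalized by sphere volume — a local emptiness measure in
  [0, 1].
- **CED** (contact energy density): each intra-chain contact's energy is
  located at the midpoint of its closest atom pair; CED at an anchor is
  the summed energy of midpoints inside the sphere over its volume. The
  spatial attribution of a pair energy to one point is a convention.
- **CLO / CPO**: partners at sequence separation ≥ 30 — CLO counts
  distinct contact partners (anchor-free, since contacts are atom-pair
  based), CPO counts residues whose matching anchor (Cα, Cβ, or LHA) is
  within 8 Å.
- **LHA** (last heavy atom): terminal side-chain heavy atom by standard
  nomenclature; CA for Gly, CB for Ala; symmetric termini resolve to the
  lower branch (e.g. Asp OD1). The designation for symmetric side chains
  is a convention.
- **Hydrophobicity**: Radzicka (1988) cyclohexane→water scale × relative
  accessibility. Proline is absent from the published scale and assigned
  0.0 here.
- **Electrostatic potential**: a screened-Coulomb sum
  Σ q·exp(−d/λ)/(ε·d) with λ = 8 Å and ε = 80 over formal charges
  (Asp/Glu −1 at the carboxylate centroid, Lys/Arg/His +1 at the terminal
  N group, chain termini ±1), evaluated at Cα, LHA, averaged over the
  residue's atoms, or at its most exposed atom. This is a deliberately
  simple stand-in behind a provider-style interface — a full
  Poisson–Boltzmann solver can replace `screened_coulomb` without touching
  the descriptor table. Potentials are reported in the sum's natural
  dimensionless units.

## Weighted neighbor averages

For residue *i* and descriptor *D*, the WNA over neighbors *j* within
15 Å (Cα–Cα distance, the residue itself excluded) is
`Σ w_j D_j / Σ w_j` with `w_j = 1/d_ij` (WNADist) or `w_j = Acc_rel,j`
(WNASurf). A residue with no neighbors, all-zero weights, or only missing
neighbor values keeps its own value, so a constant field is a fixed point
of the operator and results always lie within the neighbors' range.
Angular descriptors (φ/ψ/χ) are excluded from neighbor averaging —
arithmetic means of circular quantities are not meaningful.

## Feature pipeline and classifier

Training rows are the surface residues (IFR = 1, FSR = 0; buried
excluded) of the corpus, one **datamart** per amino-acid type. Columns
entirely missing for a type (χ for Gly, Cβ-anchored values) or with zero
variance are dropped; remaining rows with any missing value are discarded
and counted. Descriptors are computed on each chain **in isolation**;
labels come from the isolation-vs-complex comparison. Computing features
on the assembled complex would let interface packing leak the label into
the features and make the predictor useless on unbound structures.

Correlation pruning removes, iteratively, the column participating in the
most pairs with |r| > 0.85 (ties: larger mean |r|, then column order)
until no pair exceeds the threshold. PCA is fit on the training
correlation matrix (columns standardized by training means/SDs); the
retained count k is the smallest with cumulative eigenvalue fraction
≥ 95%. During cross-validation k is frozen per type from the first fold's
training set so projections stay comparable across folds. Test rows are
standardized with training statistics and rotated — never re-fit.

The discriminant is the two-class Gaussian model with pooled within-class
covariance (what makes the boundary linear) and empirical class priors;
the posterior is the logistic of the linear discriminant score. A
singular pooled covariance receives a diagonal ridge of 1e-6 with a
warning. Nothing in PCA or LDA is randomized, so training is
deterministic given the data and the fold seed. Per-type predictions are
concatenated in chain/residue order without cross-type recalibration;
residues of a type with no model (too few training rows or one class) are
reported unpredicted, buried residues are reported without a prediction.

## Evaluation harness

ROC curves sweep the distinct posterior values (ties grouped), AUC is the
trapezoidal area — which then equals the Mann–Whitney concordant-pair
statistic with half-credit for ties — and MCC is tracked at every
threshold for the maximum-MCC operating point. Precision with zero
predicted positives is reported as undefined, never as 0, and excluded
from averages. Cross-validation folds are assigned at the entry level
(seeded shuffle, round-robin deal), never per residue. Classifier
families are compared with Welch's unequal-variance two-sided t-test on
per-fold AUCs. `precision_at_coverage` reports precision at the cutoff
achieving the smallest sensitivity above each requested coverage level.

## Synthetic fixtures: what they show and what they don't

`make_toy_complex` builds ideal extended backbones (N–Cα 1.46, Cα–C 1.52,
C–N 1.33 Å) in two parallel chains with planted contacts placed at exact
distances and side chains reduced to the single atoms the detectors need;
`make_gaussian_mart` draws labeled feature sets whose Bayes-optimal AUC is
Φ(Δ/√2) for class separation Δ under identity covariance. These fixtures
give exact ground truth for detection, labeling, pruning, projection, and
classification logic, and analytic targets for recovery tests. They do
not emulate real protein geometry: no rotamers, no secondary structure,
no crystallographic noise, no correlated descriptor structure beyond what
is planted. Passing them demonstrates the machinery is correct, not that
any particular accuracy will be reached on crystal structures; training
on a real corpus is the end-to-end path provided for users with local PDB
files.

Problem sizes used in the shipped checks were chosen to make the analytic
limits sharp at desk scale: 100,000 residues for the random-classifier
limits (binomial noise ≪ the ±0.01 band), 2,000 per class for LDA
parameter recovery, 5,000 rows for the PCA retention check.

## Known limitations

- The electrostatic stand-in ignores dielectric boundaries and salt
  asymmetry; magnitudes are not comparable to Poisson–Boltzmann outputs.
- Water-mediated contact detection trusts the deposited water positions;
  structures solved without ordered waters yield none.
- The redundancy filter's identity measure (matches / alignment length)
  penalizes length differences; fragments of an otherwise identical chain
  may survive the 30% cutoff.
- Nonstandard residues other than MSE are excluded from descriptors
  rather than parameterized.
- Training needs both classes per amino-acid type; small corpora silently
  lose rare types (with a warning), which the CV report makes visible.
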