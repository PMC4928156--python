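# Methods

## Scope and data flow

The package has five computational layers: structure handling (PDB parsing,
solvent accessibility, interfaces), the nine-feature variant encoding, the
support-vector regression of ΔΔG, the downstream cross-tabulation statistics,
and interactome degree analysis. A synthetic-data module generates seeded
fixtures for every layer; all tests run on generated or packaged inputs, no
downloads.

## Structures and solvent accessibility

PDB text is parsed through Biopython's `Bio.PDB` into a light per-chain
residue model. Alternate locations collapse to the highest-occupancy atom
(ties broken alphabetically by altloc id); HETATM residues, including waters
and modified residues, are excluded from residue lists; hydrogens are parsed
and flagged but excluded from all surface and contact calculations. Only the
first model of a multi-model file is used; resolution is read from the
header when present. Residue numbering is author numbering, assumed already
mapped to sequence positions; a TSV position map (chain, pdb_pos, seq_pos)
can renumber after parsing.

SASA is computed by Shrake–Rupley sphere sampling: each heavy atom's solvent
sphere (van-der-Waals radius + 1.4 Å probe) is sampled at 960 quasi-uniform
points (golden-spiral lattice), and a point is buried if it falls inside any
neighbour's expanded sphere. Radii are a Chothia-style element set
(C 1.87, N 1.65, O 1.40, S 1.85, P 1.90, default 1.80 Å), configurable.
With 960 points the per-residue agreement with an independent dense-sampling
implementation (Biopython's, 5000 points, same radii) is within ~1 % on the
test fixtures; the tolerance asserted is 5 %. An external per-residue
accessibility (e.g., DSSP ACC values) can be injected by setting
`ResidueSite.sasa` directly before normalisation.

RSA divides residue SASA by the residue type's maximum accessible area
(Rost & Sander-style theoretical maxima packaged as the default table,
pluggable). Ratios above 1 — possible in extended conformations — are
clamped to 1.0 for reporting and classification, with the raw ratio kept in
`rsa_raw`. The accessibility threshold is RSA ≥ 0.2 (boundary accessible).
Because published maxima tables differ by a few Å² per residue type,
borderline sites can change class under a different table; the table is
therefore an explicit, swappable input rather than a constant.

Interface residues of a biological assembly are the positions accessible
(RSA ≥ 0.2) in the isolated chain and buried (RSA < 0.2) in the complex,
with both structures required to carry the same residues for the chain.

## The variant encoding

Features 1–6 are table lookups (canonical BLOSUM62 via Biopython; the
Kyte–Doolittle hydropathy scale; Dayhoff-style relative mutability with
Ala = 100; average free-amino-acid masses). Feature 7 is the per-position
emission log-odds difference native-minus-mutant from an evolutionary
profile; since the two sequences differ at one site, the full
alignment-score difference reduces to the emission difference there provided
the alignment path is unchanged — an assumption, stated here, that holds
exactly for profile/HMM scoring without realignment. Profiles load from a
20-column TSV or an HMMER3 file; when none is supplied, a single-sequence
pseudo-profile (the site residue's BLOSUM62 row) is used and flagged in the
output, which keeps the feature computable offline at reduced information
content.

Feature 9 sums P(r, w) − P(r, m) over all residues r whose minimal
heavy-atom distance from the varied residue is ≤ 5.0 Å (boundary included)
in the native structure, across all chains, with no bonded-neighbour
exclusion (a configurable exclusion window exists for experimentation).
Multiple neighbours of one type each contribute. Mutant coordinates are
never modelled. Non-standard neighbour residues are skipped with a warning
rather than erroring, since real chains contain them.

The packaged default contact potential is authored in this package: a
transparent hydropathy-derived quasi-chemical form,
P(a, b) = −(kd(a) + kd(b))/3 − 1, which makes hydrophobic–hydrophobic
contacts favourable on the few-unit energy scale typical of statistical
potentials. It is a stand-in with the right qualitative structure, not a
contact potential estimated from structural databases; any published 20×20
matrix can be dropped in via TSV, and the regression layer is agnostic to
the choice since features are standardised before fitting.

## Regression

`StabilityModel.fit()` standardises features on the training data only and
fits an RBF-kernel SVR. Hyperparameters (C ∈ {1, 10, 100}, ε ∈ {0.01, 0.1,
0.5}, γ = {0.5, 1, 2} × 1/p on standardised features) are selected by an
inner grouped 3-fold CV minimising pooled squared error, so no protein
leaks between inner folds either; with `grid_search=False` the mid-grid
values are used. Constant features are dropped with a warning; a constant
target is fitted without search (the model then predicts the constant).
Fits are deterministic given data and seed.

Benchmarking uses per-protein cross-validation: leave-one-protein-out for
≤ 40 proteins, otherwise 10 grouped folds, proteins shuffled by the seed
and assigned round-robin. Fold disjointness is asserted on every run.
Reported scores are the Pearson correlation of pooled out-of-fold
predictions and the RMSE in kcal/mol. "Standard error" in this literature
is not always defined; here `std_err` **is the RMSE**, and the residual
standard deviation (RMSE about the mean residual) is reported alongside in
`extras` for comparability with either reading.

Antisymmetry under w↔m exchange is *not* enforced by construction; the
encoding is antisymmetric in features 7 and 9 and swaps 2/3 and 5/6, but the
regressor is free to fit asymmetric effects.

## Downstream statistics

Variants are non-perturbing iff |ΔΔG| ≤ 1.0 kcal/mol (boundary inside
non-perturbing) and accessible iff RSA ≥ 0.2. Cross-tabulations are 2×2
counts per phenotype label with per-cell percentages of the table total;
interaction-patch membership is an externally supplied input column whose
per-cell counts are carried along. Percentage rounding is half-up — one
decimal for cells, nearest integer for headline fractions; this convention
reproduces the packaged survey tables' published percentages except for
four cells whose printed figures are inconsistent with their own printed
counts under any rounding (documented in the acceptance tests, where the
count-implied values are asserted instead). Headline fractions pool the
monomeric-assembly table with the multimeric table's isolated-chain rows.
The accessible share among non-perturbing disease variants is exposed to
one decimal (46.5 % on the packaged counts) rather than asserted against
its published rounded counterpart.

Dataset filters retain proteins with structure coverage ≥ 0.70 and
resolution strictly < 3.0 Å; proteins without a resolution are excluded
with a warning. Figure-style summaries use 0.5 kcal/mol bins over [0, 5]
for |ΔΔG| and [−5, 5] for signed ΔΔG by default (configurable); quartiles
use the linear-interpolation (type-7) convention throughout.

## Interactome

PSI-MITAB 2.5/2.7 lines are parsed tolerantly: short lines are skipped with
a warning, UniProtKB accessions are extracted from `uniprotkb:`-prefixed
fields, isoform suffixes (P12345-2) collapse to the parent accession, and
the `negative` column is honoured when present. Degree is the number of
*distinct* partner accessions over non-negative records in which the query
appears on either side (interaction evidences are not counted twice); a
self-interaction contributes the protein itself as one partner. Proteins
absent from the interaction file are flagged "no interactomic data" and
excluded from binning, as are proteins with fewer than 5 disease variants.
Fraction bins are right-closed deciles by default.

## Synthetic data: what it emulates, and what it does not

The toy structures use idealised backbone geometry (α-helix: 3.6
residues/turn, 1.5 Å rise, CA on a 2.3 Å cylinder; extended chain: 3.5 Å
steps) with approximate bond vectors built from the CA trace — adequate for
surface, contact and parsing behaviour, not for force-field-grade geometry.
The training generator draws wild-type/mutant pairs and passes them through
the real feature scales, then plants ΔΔG = β·(f − center) + N(0, σ) with
defaults σ = 0.1 kcal/mol, 10 proteins × 50 variants, and β chosen to give
a ΔΔG spread of roughly ±3 kcal/mol, comparable to experimental stability
datasets. Passing recovery tests therefore shows the pipeline recovers a
planted linear signal under grouped CV — it does not certify accuracy on
experimental ΔΔG data, whose noise is non-Gaussian, whose features are
correlated through real structure, and whose per-protein variant counts are
highly skewed. The annotation generator likewise plants a wider, more
destabilising ΔΔG distribution for disease variants (N(−1.0, 1.5)) than
for polymorphisms (N(−0.3, 0.7)) so that the downstream statistics have a
signal to summarise; the published survey percentages are reproduced from
the packaged count tables, not from simulation. The degree testbed plants
degree = round(50·fraction) + N(0, 2), giving strictly monotone bin means
at 200 proteins.

## Numerical and design notes

- Sampling determinism: the sphere lattice is deterministic, so adding
  occluders can only reduce exposed points — occlusion monotonicity holds
  exactly, not just statistically.
- The 5 Å contact boundary is inclusive; distances are compared on exact
  floating-point values, and the brute-force equivalence test is bit-exact
  because both routes sum identical terms in chain order.
- Label-shuffled CV controls are run with fixed mid-grid hyperparameters:
  under the null there is nothing for model selection to find, and the
  control's purpose is the permutation distribution of r, not tuning.
- Model files serialise the scaler, the SVR, the hyperparameters and a
  SHA-256 data fingerprint with a format version; loading rejects unknown
  versions.
- Benchmark-scale evaluation against the published cross-validation/blind
  correlations requires the external ProTherm-derived training set, the
  blind variant sets, and alignment-derived profiles; the package supports
  their tabular formats but does not ship or fetch them.

## Known limitations

- mmCIF, NMR multi-model averaging, and automatic retrieval of biological
  assemblies are unsupported.
- Insertion codes and non-monotone author numbering are rejected rather
  than resolved; use a position map for such chains.
- The default contact potential and pseudo-profile are offline stand-ins;
  for production predictions supply a published potential and a real
  alignment-derived profile.
- Interaction-patch membership is an input, not a prediction.
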