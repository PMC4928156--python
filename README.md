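# stabilis

Structure-based prediction of the protein stability change (ΔΔG) caused by a
single residue variation, together with the downstream analyses that relate
predicted stability perturbation to solvent accessibility, protein–protein
interfaces, and interactome connectivity.

## Who this is for

Groups annotating missense variants (e.g., OMIM disease-related substitutions
versus neutral polymorphisms) who have a 3D structure of the native protein
and want to know (a) how much a substitution is expected to perturb folding
stability, and (b) whether weakly perturbing disease variants cluster on the
solvent-exposed surface where they may instead disrupt protein–protein
interactions.

## The model

A variant *w → m* at a site of a native structure is encoded by nine features:

1. BLOSUM62 substitution score s(w, m);
2–3. Kyte–Doolittle hydropathy of w and of m;
4. relative mutability of w (Dayhoff convention, Ala = 100);
5–6. molecular weight of w and of m (free amino acid, Da);
7. evolutionary-profile score difference at the site,
   profile(i, w) − profile(i, m);
8. relative solvent accessibility (RSA) of the varied site in the native
   structure — Shrake–Rupley SASA (probe 1.4 Å) normalised by the residue
   type's maximum accessible area;
9. contact-energy difference on native coordinates,

   ΔE = Σ_r [ P(r, w) − P(r, m) ],

   where P is a 20×20 statistical contact potential and r runs over all
   residues whose minimal heavy-atom distance from the varied residue is
   ≤ 5 Å (hydrogens excluded; multiple neighbours of the same type each
   contribute a term).

A support-vector regressor (RBF kernel, features standardised on the training
set, hyperparameters selected by grouped inner cross-validation) maps the
encoding to ΔΔG in kcal/mol. Sign convention: **positive = stabilising**,
negative = destabilising. Benchmarking uses *per-protein* cross-validation:
no protein's variants ever appear on both sides of a fold.

Downstream, variants are classified as non-perturbing (|ΔΔG| ≤ 1 kcal/mol)
or perturbing, and as accessible (RSA ≥ 0.2) or buried; interface residues of
a biological assembly are those accessible in the isolated chain but buried
in the complex; and per-protein counts of distinct physical-interaction
partners (PSI-MITAB, negative records excluded) are binned against variant
fractions.

## Worked example

```
$ stabilis simulate --what structure --n 12 --out helix.pdb
$ printf '>P1\nAAAAAAAAAAAA\n' > seq.fasta
$ printf 'protein_id\tpos\twt\tmut\nP1\t5\tA\tW\nP1\t6\tA\tG\n' > vars.tsv
$ stabilis --seed 3 simulate --what training --n 6 --out train.tsv
$ stabilis --seed 3 train --training train.tsv --no-grid-search --out model.pkl
$ stabilis predict --pdb helix.pdb --fasta seq.fasta --variants vars.tsv \
      --model model.pkl --out pred.tsv
$ cut -f1-4,15 pred.tsv
protein_id  pos  wt  mut  ddg_pred
P1          5    A   W    -0.0393...
P1          6    A   G    -0.2383...
```

Both substitutions on the toy helix are predicted mildly destabilising
(ΔΔG ≈ −0.04 and −0.24 kcal/mol; negative = destabilising). The model here
was trained on a seeded synthetic set — with real data, point `--training`
at a TSV with columns `protein_id, pos, wt, mut, ddg_exp` plus the nine
feature columns (produced by `stabilis features`). Benchmarking:

```
$ stabilis --seed 3 cv --training train.tsv --no-grid-search --out cv.json
per-protein CV on 6 proteins: r = 0.972, RMSE = 0.280 kcal/mol
```

Other commands: `stabilis rsa` (per-residue SASA/RSA/class table),
`stabilis interface` (interface residues between an isolated chain and its
biological assembly), `stabilis analyze` (cross-tabulations and headline
fractions from an annotation table), `stabilis interactome` (partner counts
and fraction-binned degree statistics). All thresholds (RSA 0.2, |ΔΔG|
1 kcal/mol, 5 Å contacts, 70 % coverage, 3.0 Å resolution, ≥5 variants) are
overridable via `--config config.yaml`.

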