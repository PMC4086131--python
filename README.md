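# varmod

Predicts whether a missense protein variant (e.g. `A45C`) alters protein
function, from a combination of sequence and structural evidence:

- **Conservation** — per-position Jensen–Shannon divergence between the
  alignment column's residue distribution and a BLOSUM62-derived background
  (base-2 logs, gap-penalised, bounded in [0, 1]).
- **Substitution chemistry** — residue mass ratio, an ordinal charge-group
  change value, and a side-chain functional-group change indicator; all
  tables are explicit and overridable from a JSON config.
- **Structure** — minimum heavy-atom distance from the variant residue to
  annotated ligand-binding and protein-interface sites, confidence
  pass-through features for variants inside a binding site, an eight-class
  secondary-structure assignment from Kabsch–Sander hydrogen-bond rules
  (reduced to helix/sheet/coil), and Shrake–Rupley solvent accessibility
  (absolute and relative). Missing structural coverage is encoded with a
  −1 sentinel plus explicit missingness indicators.
- **Classifier** — an ensemble of five soft-margin linear classifiers
  trained under protein-grouped five-fold cross-validation (variants from
  one protein never span folds), with a grid search over the error/margin
  trade-off C and the positive-class cost factor j. Each member's decision
  values are converted to probabilities by Platt sigmoid scaling fitted on
  its validation fold; the final score is the accuracy-weighted, normalised
  combination of the five member probabilities.

No external downloads are needed: the `varmod.fixtures` module generates
alignments, ideal-geometry structures (helices, antiparallel strand
pairs), site annotations and labelled variant sets synthetically, with a
controllable class effect size.

## CLI

```sh
# generate a synthetic labelled dataset (plain-text FASTA/PDB/TSV)
varmod make-fixtures --out fixtures/ --n-proteins 20 --effect-size 3 --seed 17

# train the five-member ensemble and save it as JSON
varmod train --fixtures-dir fixtures/ --out model.json --seed 17

# score variants on a query protein
varmod predict --seq query.fasta --msa query.aln.fasta \
    --pdb model.pdb --sites sites.tsv \
    --variants "A45C,R12Q" --model model.json --out predictions.json

# sensitivity/specificity/precision and ROC/PR on labelled data
varmod evaluate --model model.json --fixtures-dir fixtures/ --out metrics.json
```

Site annotations are TSV rows `site_type <TAB> positions <TAB>
confidence_a <TAB> confidence_b` with `site_type` either `ligand` or
`interface` and `positions` a comma-separated list of 1-based residue
positions. Labelled variants are TSV rows `protein_id <TAB> variant <TAB>
label` (1 = functional/pathogenic, 0 = neutral).

## Layout

- `varmod.core_io` — variant/alignment/structure/site/label parsing and
  writing (FASTA, PDB, TSV, JSON), validation.
- `varmod.conservation` — column profiles and JSD conservation scoring.
- `varmod.seq_features` — mass-ratio, charge-change and
  functional-group-change features.
- `varmod.struct_features` — site distances, secondary structure, SASA,
  structural feature block assembly.
- `varmod.predictor` — feature schema, Platt calibration, member and
  ensemble training, persistence, prediction.
- `varmod.evaluation` — grouped folds, confusion metrics, ROC/PR.
- `varmod.fixtures` — synthetic data generators.
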