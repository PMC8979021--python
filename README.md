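# smireg

Predict whether a small molecule **up- or down-regulates a miRNA's
expression**, from two cheap featurizations:

- **miRNA**: a 277-dimensional sequence descriptor — length, mononucleotide
  ratios (A/C/G/U), all 16 overlapping 2-mer frequencies and all 256
  overlapping 4-mer frequencies;
- **molecule**: the 166 public MACCS structural keys computed from SMILES
  (RDKit backend).

Known regulation pairs supply positives; credible negatives are *mined* by a
similarity screen: a candidate (molecule, miRNA) pair is scored by the mean
Tanimoto coefficient between the candidate molecule and the miRNA's known
regulators, and pairs scoring below 0.1 enter the negative pool, from which
a balanced sample is drawn.  Direction-specific classifiers (elastic-net
GLM, KNN, RBF-SVM, single-layer ANN, random forest) are tuned by 5-fold CV
on AUC over a 50/50 stratified split, and the final model gets an
F1-maximizing "suggestion" threshold: pairs predicted at or above it are
flagged worth experimental follow-up.

## CLI

All stages are subcommands of `smireg`; every run writes a `manifest.json`
recording inputs, parameters, seeds and versions.

```bash
# 1. generate a synthetic corpus with planted structure (no downloads needed)
smireg simulate --config cfg.json --out corpus/

# 2. validate + split the pair table by direction
smireg build-dataset --pairs corpus/pairs.tsv --fasta corpus/mirnas.fasta \
    --fingerprints corpus/fingerprints.tsv --out data/

# 3. mine balanced negatives (regulation score < 0.1)
smireg make-negatives --dataset data/up --other-dataset data/down \
    --seed 4 --out balanced/

# 4. train, tune, calibrate; writes the model bundle + CV report
smireg train --dataset balanced/ --algos glm,knn,svm,ann,rf --seed 4 --out bundle/

# 5. rank a molecule library for a query miRNA (or miRNAs for a SMILES)
smireg predict --bundle bundle/ --mode mirna-to-sm \
    --query query.fasta --library molecules.tsv --top 10 --out results.tsv
```

Also available: `featurize-rna`, `featurize-sm` (descriptor/fingerprint
tables), `evaluate` (AUC + ROC points on a labeled dataset) and
`select-threshold` (recalibrate the suggestion rate).

Real corpora use the same 4-column pair TSV (`sm_id`, `smiles`, `mirna_id`,
`direction`) plus a miRBase-style FASTA; `T` is tolerated and mapped to `U`,
anything outside A/C/G/U/T is rejected loudly. Pairs whose miRNA lacks a
sequence are dropped and logged.

## Layout

```
src/smireg/
  rna_features.py       sequence normalization, k-mer frequencies, 277-dim descriptor
  chem_features.py      MACCS fingerprints, Tanimoto, SMILES/fingerprint IO
  pair_data.py          pair-table loading, validation, direction split, dataset IO
  negative_sampling.py  regulation score, candidate enumeration, balanced sampling
  model_training.py     feature assembly, CV tuning, AUC, F1 threshold, bundles
  prediction.py         single-pair scoring and library ranking
  synthetic_data.py     corpora with planted fingerprint-family x motif structure
  cli.py                subcommand wiring + manifests
```
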