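# rxnaug

Preprocessing and evaluation toolkit for data-driven reaction prediction:

- **SMILES engine** (`rxnaug.smiles_engine`) — a self-contained parser,
  writer, canonicalizer and random enumerator over an attributed
  molecular-graph model. Supports organic-subset and bracket atoms, ring
  closures (incl. `%nn`), branches, charges, isotopes and verbatim stereo
  annotations. Canonical SMILES via iterative partition refinement with
  deterministic tie-breaking.
- **Augmentation** (`rxnaug.augmentation`) — N-level training-set expansion
  by SMILES enumeration: each compound on the model-input side is rewritten
  with an independently randomized atom order; level 1 is the canonical
  original dataset. Test partitions are refused.
- **Normalization** (`rxnaug.normalization`) — character-based splitting
  (one token per character) and atom-level tokenization (`Cl`, `Br`,
  bracket atoms, `%nn` kept whole); both lossless. Reaction-class tokens
  (`RX_n`) stay atomic under both schemes.
- **Reaction I/O** (`rxnaug.reaction_io`) — line-oriented
  `reactants>reagents>products` files with an optional class column
  (`Rx_1`..`Rx_10`), source/target preparation for forward, retro and
  class-conditioned retro tasks, and deterministic (optionally stratified)
  train/test splitting.
- **Evaluation** (`rxnaug.evaluation`) — top-k exact-match accuracy after
  canonicalization over ranked n-best beams, grammatical-invalid rate
  (pooled over candidates, per-source variant available) and per-class
  breakdowns.
- **Toy data** (`rxnaug.toy_data`) — synthetic reaction datasets built from
  rule-based templates (N-alkylation, acylation, ether deprotection) with
  imbalanced class labels, plus an edit-distance retrieval baseline standing
  in for a trained seq2seq model.

## CLI

All functionality is exposed through the `rxnaug` entry point:

```sh
# synthesize a 2,000-reaction dataset with class labels
rxnaug gen-toy --n 2000 --seed 1 --out toy.rsmi --classes-out toy_classes.tsv

# 90/10 split, stratified by class
rxnaug split --input toy.rsmi --no-class --test-frac 0.1 --seed 1 \
    --train-out train.rsmi --test-out test.rsmi

# 10-level augmentation of the training set (retro task: product side is
# the model input)
rxnaug augment --input train.rsmi --no-class --level 10 --seed 1 \
    --source-side products --out train_aug10.rsmi

# tokenized, line-aligned model files (character normalization)
rxnaug normalize --scheme char --task retro --input train_aug10.rsmi \
    --no-class --out-src src-train.txt --out-tgt tgt-train.txt

# raw source/target pairs for the test set
rxnaug prepare --task retro --input test.rsmi --no-class \
    --out-src src-test.txt --out-tgt tgt-test.txt

# score an n-best prediction file (10 lines per source, rank-major)
rxnaug evaluate --preds preds.txt --refs tgt-test.txt --beam 10 \
    --k 1,3,5,10 --out report.json
```

`--with-class/--no-class` controls whether the trailing tab-separated class
column is read/written; `retro-class` prepends the `RX_n` conditioning token
to each source line.

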