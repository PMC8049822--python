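# redpep

A toolkit for binary protein-sequence classification built on reduced
amino-acid alphabets. Sequences are rewritten over a smaller alphabet (an
ordered partition of the 20 standard amino acids into k groups), encoded as
overlapping N-peptide (N = 1, 2, 3) composition vectors, ranked by two-group
ANOVA F-score, pruned by incremental feature selection (IFS), and classified
with an RBF-kernel SVM tuned by grid search. Evaluation reports sensitivity,
specificity, accuracy and trapezoidal ROC/AUC from pooled out-of-fold
predictions of stratified cross-validation.

A family of 18 reduction schemes (sizes 2–19, derived by information
maximization over paired contact interactions) is bundled; arbitrary schemes
can be supplied via a plain-text catalog (`type size cluster-notation` per
line, e.g. `19 10 WY-F-ILMV-C-DE-K-GNQS-PT-A-HR`).

A synthetic data module generates labelled FASTA datasets with compositional
bias planted in reduced dipeptide space (first-order Markov chain over
reduced symbols, lifted uniformly to amino acids), so the whole pipeline is
testable without external data.

## CLI

```sh
# generate a synthetic labelled dataset (positive/negative FASTA + manifest)
redpep simulate --n-pos 40 --n-neg 240 --effect 0.1 --seed 1 --out data/

# cross-validated accuracy for every (scheme, N) pair
redpep scan --pos data/positive.fasta --neg data/negative.fasta \
    --n 1,2,3 --folds 5 --seed 1 --out scan.tsv

# full workflow: scan -> grid search -> ANOVA + IFS -> final model
redpep train --pos data/positive.fasta --neg data/negative.fasta \
    --grid COARSE --seed 1 --out run/

# evaluate the saved model on an independent labelled dataset
redpep evaluate --model run/model.joblib --pos indep_pos.fa --neg indep_neg.fa

# predict unlabelled sequences
redpep predict --model run/model.joblib --fasta query.fa
```

`train` writes five artifacts to `--out`: `scan_table.tsv`, `ifs_curve.tsv`,
`final_report.txt`, `model.joblib` and `run_log.txt`, all stamped with a
config hash and the seed; re-running the same config reproduces identical
bytes. `--scheme-catalog PATH` swaps the bundled scheme family for a custom
catalog; `--no-ifs` skips feature selection; `--grid` accepts `COARSE`,
`FULL` (the 10×9 exponent lattice) or a fixed `C:gamma` pair.

## Library

```python
from redpep import (
    load_builtin_family, parse_cluster_string, encode_dataset,
    anova_f_scores, incremental_feature_selection,
    grid_search, cross_validate, read_labeled_fasta,
)

records = read_labeled_fasta("pos.fa", "neg.fa")
scheme = next(s for s in load_builtin_family() if s.size == 10)
matrix = encode_dataset(records, scheme, n=2)          # 100 dipeptide features
ranking = anova_f_scores(matrix)                       # descending F-scores
```

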