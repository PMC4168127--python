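# sosbind

Supervised over-sampling (SOS) for imbalanced two-class learning, with the
baseline samplers it is compared against (ROS, SMOTE, ADASYN), a
sequence-profile feature pipeline for protein-nucleotide binding-residue
prediction, and an imbalance-aware evaluation harness.

## What's inside

| module | purpose |
| --- | --- |
| `sosbind.sampling` | ROS, SMOTE, ADASYN (plan + synthesis) and SOS: pair-interpolated minority synthesis filtered by an initial classifier's confidence interval `[c_low, c_high]` |
| `sosbind.classifiers` | probabilistic-classifier contract: Gaussian-kernel SVM with (C, gamma) grid search under stratified CV maximizing mean MCC, plus a deterministic mock for tests |
| `sosbind.features` | PSI-BLAST ASCII PSSM and PSIPRED `.ss2` parsers; logistic normalization; sliding-window features (window 17 gives 17x20 + 17x3 = 391 dimensions per residue) |
| `sosbind.evaluation` | Sen/Spe/Acc/MCC, ROC/AUC, MaxMCC / Balanced / fixed threshold policies, group-aware (protein-level) cross-validation with over-sampling applied to training folds only |
| `sosbind.simulate` | synthetic imbalanced datasets and toy protein profiles with a planted binding signal; on-disk fixture writers that round-trip through the parsers |
| `sosbind.cli` | `sosbind` command with subcommands `simulate`, `oversample`, `extract-features`, `train`, `predict`, `evaluate`, `cv` |

## CLI examples

```sh
# generate an imbalanced table (ratio 19) and balance it with SOS
sosbind simulate --kind table --n-min 100 --n-maj 1900 --seed 1 --out sim/
sosbind oversample --in-table sim/dataset.tsv --sampler sos \
    --alpha 19 --c-low 0.5 --c-high 0.95 --seed 1 --out-table sim/balanced.tsv

# build 391-D residue features from profile files
sosbind extract-features --fasta p.fasta --pssm p.pssm --ss2 p.ss2 \
    --annotations binding.tsv --out features.tsv

# five-fold protein-level cross-validation under the MaxMCC policy
sosbind cv --in-table features.tsv --sampler sos --policy max_mcc \
    --folds 5 --seed 1 --out report.json
```

Exit codes: 0 success, 2 validation error, 3 runtime failure (e.g. the SOS
attempt cap is reached because the confidence interval is unreachable).

File formats are plain text throughout: labeled tables are TSV
(features..., label in {1, -1}; optional `protein_id`/`residue_index`
provenance columns are used as CV groups), synthesis sidecars record
`parent_a, parent_b, lambda, confidence` per synthetic row, and binding
annotations are `protein_id <TAB> comma-separated 1-based indices`.

## Notes on defaults

The SOS defaults (`alpha` = majority/minority size ratio, confidence
interval `[0.5, 0.95]`) and the ADASYN/SMOTE neighborhood size `K = 5` are
artifact choices, configurable via flags or `--config` YAML. Window padding
beyond the sequence termini is all-zero rows in normalized space, so padding
is distinguishable from real signal (the logistic-normalized scores are
strictly inside (0, 1)).
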