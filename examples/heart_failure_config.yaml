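# Optional: final-model workflow for a user-supplied heart-failure
# clinical-records CSV (12 feature columns + a binary death-event target).
# The dataset is not bundled; point --data at your local copy:
#
#   nestpipe run --config examples/heart_failure_config.yaml \
#       --data heart_failure_clinical_records_dataset.csv \
#       --target DEATH_EVENT --out-dir out_hf
#
# CV is scaled down to 10 outer shuffle splits so a desk run finishes in
# minutes; widen n_splits for tighter estimates.
workflow:
  name: heart_failure_final
  outer_cv: {kind: shuffle_split, n_splits: 10, test_size: 0.2, seed: 1}
  inner_cv: {kind: k_fold, n_splits: 10, shuffle: true, seed: 2}
  metrics: [balanced_accuracy, f1_score, matthews_corrcoef, sensitivity, specificity]
  best_config_metric: f1_score
  optimizer: {name: grid_search}
  constraints:
    - {metric: f1_score, threshold: 0.7, strategy: mean}
  use_test_set: true
  task: classification
  verbosity: 1

elements:
  - element: StandardScaler
  - element: SimpleImputer
  - element: ImbalancedDataTransformer
    fixed_params: {random_state: 7}
    hyperparameters:
      method_name: [RandomUnderSampler, RandomOverSampler, SMOTE]
    test_disabled: true
  - element: RandomForestClassifier
    fixed_params: {criterion: gini, bootstrap: true, random_state: 7}
    hyperparameters:
      min_samples_split: {type: integer_range, start: 2, stop: 30, step: 7}
      max_features: [sqrt, log2]
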