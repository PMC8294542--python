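# Demonstration workflow: preprocessing, class rebalancing, and an
# OR-element comparing two reference learners, evaluated under nested
# cross-validation.  Run it on the built-in synthetic cohort with:
#
#   nestpipe run --config examples/demo_config.yaml --synthetic --out-dir out
#
workflow:
  name: demo
  outer_cv: {kind: shuffle_split, n_splits: 2, test_size: 0.2, seed: 1}
  inner_cv: {kind: k_fold, n_splits: 3, shuffle: true, seed: 2}
  metrics: [balanced_accuracy, f1_score, matthews_corrcoef, sensitivity, specificity]
  best_config_metric: f1_score
  optimizer: {name: grid_search}
  use_test_set: true
  task: classification
  verbosity: 0

elements:
  - element: MeanImputer
  - element: ReferenceScaler
  - element: ImbalancedDataTransformer
    fixed_params: {random_state: 7}
    hyperparameters:
      method_name: [RandomUnderSampler, RandomOverSampler, SMOTE]
    test_disabled: true
  - switch: estimator_selection
    elements:
      - element: NearestCentroidClassifier
      - element: MajorityClassifier

synthetic:
  n_samples: 299
  n_features: 12
  positive_rate: 0.32
  effect_size: 1.0
  n_informative: 4
  missing_rate: 0.05
  seed: 42
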