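{
  "config_hash": "22fbd8797eb5704a",
  "pooled": {
    "accuracy": 0.8533333333333334,
    "precision": 0.8541666666666666,
    "recall": 0.9111111111111111,
    "f1": 0.8817204301075269,
    "auc_roc": 0.9288888888888889,
    "tp": 41,
    "tn": 23,
    "fp": 7,
    "fn": 4
  },
  "folds": [
    {
      "accuracy": 0.84,
      "precision": 0.8235294117647058,
      "recall": 0.9333333333333333,
      "f1": 0.8749999999999999,
      "auc_roc": 0.94,
      "tp": 14,
      "tn": 7,
      "fp": 3,
      "fn": 1
    },
    {
      "accuracy": 0.88,
      "precision": 1.0,
      "recall": 0.8,
      "f1": 0.888888888888889,
      "auc_roc": 0.98,
      "tp": 12,
      "tn": 10,
      "fp": 0,
      "fn": 3
    },
    {
      "accuracy": 0.84,
      "precision": 0.7894736842105263,
      "recall": 1.0,
      "f1": 0.8823529411764706,
      "auc_roc": 0.8866666666666667,
      "tp": 15,
      "tn": 6,
      "fp": 4,
      "fn": 0
    }
  ]
}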