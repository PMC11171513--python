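{
  "HCMFS": {
    "KNN": {"params": {"n_neighbors": 19, "p": 1, "weights": "distance"}, "dataset": "IMV+OR+SS"},
    "RF": {"params": {"max_depth": 16, "random_state": 2, "n_estimators": 300}, "dataset": "IMV+SS"},
    "SVM": {"params": {"C": 1, "kernel": "linear"}, "dataset": "IMV"},
    "NB": {"params": {}, "dataset": "IMV+SS"},
    "LR": {"params": {"solver": "liblinear", "penalty": "L1", "C": 10}, "dataset": "IMV"}
  },
  "FS": {
    "KNN": {"params": {"n_neighbors": 30, "weights": "uniform"}, "dataset": "IMV+SS"},
    "RF": {"params": {"max_depth": 5, "random_state": 2, "n_estimators": 300}, "dataset": "IMV+SS"},
    "SVM": {"params": {"C": 1, "kernel": "linear"}, "dataset": "IMV+SS"},
    "NB": {"params": {}, "dataset": "IMV"},
    "LR": {"params": {"solver": "liblinear", "penalty": "L2", "C": 1}, "dataset": "IMV+SS"}
  },
  "R_F": {
    "KNN": {"params": {"n_neighbors": 18, "p": 1, "weights": "distance"}, "dataset": "IMV+SS"},
    "RF": {"params": {"max_depth": 3, "random_state": 1, "n_estimators": 100}, "dataset": "IMV+SS"},
    "SVM": {"params": {"C": 1, "kernel": "linear"}, "dataset": "IMV+OR+SS"},
    "NB": {"params": {}, "dataset": "IMV+OR+SS"},
    "LR": {"params": {"solver": "liblinear", "penalty": "L1", "C": 10}, "dataset": "IMV"}
  },
  "MI": {
    "KNN": {"params": {"n_neighbors": 20, "p": 1, "weights": "distance"}, "dataset": "IMV+SS"},
    "RF": {"params": {"max_depth": 19, "random_state": 1, "n_estimators": 200}, "dataset": "IMV+SS"},
    "SVM": {"params": {"C": 1, "kernel": "linear"}, "dataset": "IMV"},
    "NB": {"params": {}, "dataset": "IMV"},
    "LR": {"params": {"solver": "liblinear", "penalty": "L2", "C": 0.1}, "dataset": "IMV+SS"}
  },
  "DCFS": {
    "KNN": {"params": {"n_neighbors": 28, "weights": "uniform"}, "dataset": "IMV+SS"},
    "RF": {"params": {"max_depth": 4, "random_state": 2, "n_estimators": 100}, "dataset": "IMV+OR+SS"},
    "SVM": {"params": {"C": 1, "kernel": "linear"}, "dataset": "IMV+SS"},
    "NB": {"params": {}, "dataset": "IMV+SS"},
    "LR": {"params": {"solver": "liblinear", "penalty": "L2", "C": 1}, "dataset": "IMV+SS"}
  }
}
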