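"""Deterministic random datasets shared by tests and oracle generation.

The Cox datasets are small (n=30) with staggered entry, ~40% censoring, one
binary and one continuous covariate; half use discretized times so tied
event times exercise the Efron/Breslow corrections.
"""
import numpy as np

N_DATASETS = 50
SEED = 20240917


def small_cox_datasets(n_datasets=N_DATASETS, n=30, seed=SEED):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_datasets):
        entry = rng.uniform(0, 1.0, n)
        gap = rng.exponential(2.0, n)
        exit_ = entry + gap
        status = (rng.uniform(size=n) < 0.6).astype(int)
        if i % 2 == 1:  # discretize to force tied event times
            exit_ = entry + np.ceil(gap * 2) / 2.0
        x1 = (rng.uniform(size=n) < 0.5).astype(float)
        x2 = rng.normal(size=n)
        while x1.min() == x1.max() or status.sum() < 3:
            x1 = (rng.uniform(size=n) < 0.5).astype(float)
            status = (rng.uniform(size=n) < 0.6).astype(int)
        out.append({
            "entry": entry, "exit": exit_, "status": status,
            "X": np.column_stack([x1, x2]),
        })
    return out


def small_logistic_datasets(n_datasets=N_DATASETS, n=60, seed=SEED + 1):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_datasets):
        X = np.column_stack([
            (rng.uniform(size=n) < 0.4).astype(float),
            rng.normal(size=n),
            rng.uniform(size=n),
        ])
        eta = -0.3 + X @ np.array([0.8, -0.5, 1.0])
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(int)
        while y.min() == y.max():
            y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(int)
        out.append({"X": X, "y": y})
    return out
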