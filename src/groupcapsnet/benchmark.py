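"""Desk-scale phantom benchmark.

The reference clinical dataset behind this architecture is private, so the
package's end-to-end benchmark trains the reduced two-stage G2 variant
(64x64 inputs, halved stage depths) on easy synthetic phantoms: 200 training
slices, 50 held-out test slices, 12 epochs.  Problem sizes are fixed here so
the pytest suite, the CLI and the acceptance script all run the same
experiment; see docs/methods.md for the rationale behind each number.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .network import NetworkSpec, build_network
from .synthetic_data import PhantomConfig, generate_dataset
from .train_eval import TrainConfig, evaluate_model, train_model

N_TRAIN = 200
N_TEST = 50
EPOCHS = 16
IMAGE_SIZE = 64


def benchmark_data(seed: int, n_train: int = N_TRAIN, n_test: int = N_TEST):
    """Seeded easy-phantom train/test split (test seeds disjoint by offset)."""
    cfg = PhantomConfig.easy(IMAGE_SIZE)
    train = generate_dataset(cfg, n_train, seed=seed)
    test = generate_dataset(cfg, n_test, seed=seed + 1_000_003)
    return train, test


def run_desk_benchmark(nonlinearity: str = "modified_squash", seed: int = 0,
                       epochs: int = EPOCHS, n_train: int = N_TRAIN,
                       n_test: int = N_TEST, out_dir=None, log=None):
    """Train the reduced G2 network on easy phantoms and report test metrics.

    Deterministic given (nonlinearity, seed, sizes).  Optionally writes the
    per-epoch training log and the test metrics as CSVs.
    """
    train, test = benchmark_data(seed, n_train, n_test)
    spec = NetworkSpec.desk_scale(nonlinearity=nonlinearity)
    model = build_network(spec, seed=seed)
    config = TrainConfig(seed=seed)
    history = train_model(model, train, config, epochs=epochs, log=log)
    metrics, counts = evaluate_model(model, test, threshold=config.threshold)
    result = {"nonlinearity": nonlinearity, "seed": seed, "epochs": epochs,
              "n_train": n_train, "n_test": n_test,
              "history": history, "metrics": metrics, "counts": counts,
              "model": model}
    if out_dir is not None:
        out_dir = Path(out_dir)
        os.makedirs(out_dir, exist_ok=True)
        pd.DataFrame({"epoch": np.arange(1, len(history) + 1),
                      "bce": history}).to_csv(
            out_dir / f"train_log_{nonlinearity}.csv", index=False)
        pd.DataFrame([{**metrics.as_dict(), "nonlinearity": nonlinearity,
                       "seed": seed, "epochs": epochs}]).to_csv(
            out_dir / f"test_metrics_{nonlinearity}.csv", index=False)
    return result
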