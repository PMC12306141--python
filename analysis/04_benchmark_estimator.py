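#!/usr/bin/env python
"""Benchmark the estimator against known synthetic truths.

Three checks at analysis scale (smaller replicate counts than the test
suite, for a quick read): support recovery at 10x the protocol length,
false-positive control on white-noise data at protocol length, and
simulator fidelity against the discrete-Lyapunov stationary covariance.
Writes results/benchmarks.json.
"""

import json
from pathlib import Path

import numpy as np

import idionet as io_
from idionet.data import Schedule
from idionet.simulate import make_truth, recovery_metrics, simulate_ema, simulate_latent, stationary_covariance

import sys

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "tests"))
from conftest import white_noise_dataset  # reuse the null-data builder

SEED = 20260927
OUT = Path("results/benchmarks.json")


def main() -> None:
    import warnings

    warnings.filterwarnings("ignore")
    t_f1, c_f1 = [], []
    for k in range(10):
        truth = make_truth(seed=SEED + k)
        ds = simulate_ema(truth, schedule=Schedule(n_days=210), missing_rate=0.0, seed=SEED + k)
        std, _ = io_.standardize_pairs(io_.to_lagged_pairs(ds, truth.nodes), nodes=truth.nodes)
        fit, _ = io_.select_model(std, nodes=truth.nodes)
        m = recovery_metrics(truth, fit)
        t_f1.append(m.temporal_f1)
        c_f1.append(m.contemporaneous_f1)

    near_empty = 0
    for k in range(10):
        ds = white_noise_dataset(SEED + k)
        std, _ = io_.standardize_pairs(io_.to_lagged_pairs(ds, ds.item_ids), nodes=ds.item_ids)
        fit, _ = io_.select_model(std, nodes=ds.item_ids)
        off = ~np.eye(fit.p, dtype=bool)
        n_edges = int((np.abs(fit.B[off]) > 1e-6).sum()) + int(
            (np.abs(fit.K[np.triu_indices(fit.p, 1)]) > 1e-6).sum()
        )
        near_empty += n_edges <= 2

    truth = make_truth(seed=SEED)
    series = simulate_latent(truth, 50_000, seed=SEED + 1)
    sigma = stationary_covariance(truth)
    lyap = float(np.linalg.norm(np.cov(series.T, ddof=0) - sigma) / np.linalg.norm(sigma))

    results = {
        "recovery_median_f1_temporal": float(np.median(t_f1)),
        "recovery_median_f1_contemporaneous": float(np.median(c_f1)),
        "white_noise_near_empty_fraction": near_empty / 10,
        "lyapunov_relative_error": lyap,
    }
    OUT.parent.mkdir(parents=True, exist_ok=True)
    OUT.write_text(json.dumps(results, indent=2))
    for key, value in results.items():
        print(f"{key}: {value:.3f}")
    print(f"-> {OUT}")


if __name__ == "__main__":
    main()
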