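#!/usr/bin/env python
"""Soft accuracy check on a user-supplied voice-feature CSV.

Runs the full tuned pipeline (PCA 0.95 -> Z-score -> hybrid CS-PSO RBF-SVM at
the reference swarm settings) on the given CSV and reports whether the
holdout accuracy reaches 0.92. This is informational only: the exit code is
0 either way, because a single holdout split on a small clinical table is
split- and scheme-dependent.

Usage:  python scripts/real_data_check.py data.csv [--seed N] [--iters N] [--pop N]
"""

import argparse
import json

from svmswarm import ExperimentConfig, OptimizerConfig, run_experiment

BAR = 0.92


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("csv", help="CSV with name/status/feature columns")
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--iters", type=int, default=120)
    ap.add_argument("--pop", type=int, default=18)
    args = ap.parse_args()

    cfg = ExperimentConfig(
        input_path=args.csv,
        method="cspso",
        optimizer=OptimizerConfig(
            population=args.pop, iterations=args.iters, seed=args.seed
        ),
        seed=args.seed,
    )
    rep = run_experiment(cfg)
    acc = rep.holdout_metrics.accuracy
    print(
        json.dumps(
            {
                "holdout_accuracy": acc,
                "bar": BAR,
                "reaches_bar": bool(acc >= BAR),
                "best_C": rep.best_C,
                "best_gamma": rep.best_gamma,
                "cv_fitness": rep.cv_fitness,
                "test_rows": rep.test_rows,
            },
            indent=2,
        )
    )


if __name__ == "__main__":
    main()
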