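#!/usr/bin/env python
"""Simulate the synthetic eight-study suite.

The historical raw data are external, so the pipeline's inputs are ternary
tables sampled from a two-threshold-model ground truth (mu = -10 ms,
sigma = 40 ms, c_su = 30 ms, c_o = 60 ms, g = 0.6) on each study's d grid.
Writes one TSV per study design under results/tables/.
"""

import argparse
from pathlib import Path

import numpy as np

from tojmodels import (
    GeneratorSpec,
    LatencyDiffDistribution,
    TTMParams,
    simulate_response_table,
    study_presets,
    write_response_table,
)

TRUTH = TTMParams(LatencyDiffDistribution("normal", -10.0, 40.0), 30.0, 60.0, 0.6)

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--trials-per-soa", type=int, default=100)
parser.add_argument("--out", type=Path, default=Path("results/tables"))
args = parser.parse_args()

args.out.mkdir(parents=True, exist_ok=True)
rng = np.random.default_rng(args.seed)
for name, design in sorted(study_presets(args.trials_per_soa).items()):
    table = simulate_response_table(
        GeneratorSpec("ttm", TRUTH, design, seed=int(rng.integers(0, 2**31 - 1)))
    )
    path = args.out / f"{name}.tsv"
    write_response_table(table, path)
    print(f"{name}: {table.n_levels} levels x {args.trials_per_soa} trials/d "
          f"-> {path}")
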