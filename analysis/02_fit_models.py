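#!/usr/bin/env python
"""Fit REM, TSM, and TTM to every simulated study table.

Runs the multistart minimum-G² fits under both latency-difference families and
writes per-fit JSON, fitted-vs-observed curves, the comparison table, and the
NMI table under results/comparison/ (see 01_simulate_studies.py for inputs).
"""

import argparse
from pathlib import Path

from tojmodels import RunConfig, run_comparison

parser = argparse.ArgumentParser()
parser.add_argument("--tables", type=Path, default=Path("results/tables"))
parser.add_argument("--out", type=Path, default=Path("results/comparison"))
parser.add_argument("--seed", type=int, default=1)
args = parser.parse_args()

inputs = tuple(str(p) for p in sorted(args.tables.glob("*.tsv")))
if not inputs:
    raise SystemExit(f"no tables under {args.tables}; run 01_simulate_studies.py first")

config = RunConfig(
    inputs=inputs,
    models=("rem", "tsm", "ttm"),
    families=("normal", "laplace"),
    out_dir=str(args.out),
    seed=args.seed,
)
comparison = run_comparison(config)
model, family = comparison.winner
print(f"fitted {len(comparison.rows)} cells across {len(inputs)} tables")
print(f"winner by grand-sum BIC: {model}/{family}")
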