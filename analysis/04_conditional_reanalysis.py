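#!/usr/bin/env python
"""Conditional order-accuracy analysis of simulated dual-response trials.

Simulates SJ-then-forced-TOJ trials from the two-threshold ground truth (one
shared arrival-time difference per trial, unbiased guessing when simultaneity
was reported) and asks: is forced order accuracy at chance after an
(incorrect) simultaneity response, and above chance after a correct
successiveness response?  Writes the per-|d| table and pooled summary under
results/conditional/.
"""

import argparse
from pathlib import Path

import numpy as np

from tojmodels import (
    LatencyDiffDistribution,
    StudyDesign,
    TTMParams,
    order_accuracy_report,
    simulate_dual_trials,
    write_dual_trials,
)

TRUTH = TTMParams(LatencyDiffDistribution("normal", -10.0, 40.0), 30.0, 60.0, 0.6)

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--trials-per-soa", type=int, default=200)
parser.add_argument("--out", type=Path, default=Path("results/conditional"))
args = parser.parse_args()

args.out.mkdir(parents=True, exist_ok=True)
soa = np.array([-100.0, -75.0, -50.0, -25.0, 25.0, 50.0, 75.0, 100.0])
design = StudyDesign("allan_nonzero", soa, np.full(soa.size, args.trials_per_soa))
trials = simulate_dual_trials(TRUTH, design, seed=args.seed, forced_guess_si=0.5)
write_dual_trials(trials, args.out / "dual_trials.csv")

report = order_accuracy_report(trials)
report.to_tsv(args.out / "conditional_accuracy.tsv")
report.to_json(args.out / "conditional_accuracy.json")

pooled = report.pooled
print("pooled order accuracy over |d| > 0:")
print(f"  unconditional    {pooled['acc_unconditional']:.3f}")
print(f"  given correct SJ {pooled['acc_given_su']:.3f}")
print(f"  given R_si       {pooled['acc_given_si']:.3f} "
      f"(exact binomial p vs 0.5: {pooled['p_value_si_vs_chance']:.3f})")
print(f"per-|d| tests significant at 0.05: {report.n_significant}/{report.n_tested}")
print(f"tables under {args.out}")
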