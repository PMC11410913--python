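#!/usr/bin/env python
"""Summarize the model comparison and render the report.

Reads the run directory written by 02_fit_models.py, prints the summed-BIC
ranking (the analog of the published comparison tables, here on synthetic
data), and renders results/comparison/report.md with psychometric-function
plots.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from tojmodels import render_report

parser = argparse.ArgumentParser()
parser.add_argument("--run", type=Path, default=Path("results/comparison"))
args = parser.parse_args()

comparison = json.loads((args.run / "comparison.json").read_text())
summary = pd.DataFrame(comparison["summary"]).sort_values("sum_bic")
print("model ranking by grand-sum BIC (lower is better):")
print(summary.to_string(index=False))

nmi = pd.read_csv(args.run / "nmi.tsv", sep="\t")
print("\nnon-monotonicity index, observed vs fitted (means across tables):")
print(nmi.drop(columns="label").mean().round(4).to_string())

report = render_report(args.run)
print(f"\nreport rendered to {report}")
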