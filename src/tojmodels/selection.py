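"""Model selection: BIC, the non-monotonicity index, comparison tables, and
model-recovery simulation.

Selection is by the Bayesian information criterion BIC = G² + k·ln(n) with n
the total number of trials in the fitted table; lower is better.  Summed BIC
across studies decides the overall winner.  The non-monotonicity index (NMI)
quantifies decreasing stretches of the two increasing psychometric functions
P(R_xy|d) and 1 - P(R_yx|d) = P(R_xy ∪ R_si|d):

    NMI = Σ_R Σ_i max[0, P(R|d_i) - P(R|d_{i+1})],   R ∈ {R_xy, R_xy ∪ R_si},

which is 0 exactly when both curves are non-decreasing on the grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import ResponseTable, StudyDesign
from .fitting import FitConfig, FitResult, fit_model
from .models import response_probs

__all__ = [
    "bic",
    "nmi",
    "nmi_report",
    "compare_models",
    "ComparisonTable",
    "model_recovery",
    "RecoveryReport",
]


def bic(g_squared: float, k: int, n: int) -> float:
    """Bayesian information criterion G² + k·ln(n)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < 1:
        raise ValueError("n must be >= 1")
    return float(g_squared + k * np.log(n))


def nmi(curve_xy: np.ndarray, curve_xy_or_si: np.ndarray) -> float:
    """Non-monotonicity index over the two cumulative-response curves.

    Both curves must be given on the same increasing d grid; the index sums
    all positive consecutive decreases across the two curves.
    """
    a = np.asarray(curve_xy, dtype=float)
    b = np.asarray(curve_xy_or_si, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("curves must be 1-D and share a grid")
    total = 0.0
    for curve in (a, b):
        total += float(np.sum(np.maximum(0.0, curve[:-1] - curve[1:])))
    return total


def _curves_from_probs(probs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(P(R_xy|d), P(R_xy ∪ R_si|d)) from a (D, 3) probability array."""
    return probs[:, 0], probs[:, 0] + probs[:, 1]


def nmi_report(table: ResponseTable, fits: dict[str, FitResult]) -> dict[str, float]:
    """NMI of the observed proportions and of each fitted model's curves,
    evaluated on the observed d grid.  Zero-total levels are skipped."""
    keep = table.totals > 0
    obs = table.proportions()[keep]
    out = {"observed": nmi(*_curves_from_probs(obs))}
    for name, fit in fits.items():
        probs = response_probs(fit.params, table.soa_ms[keep])
        out[name] = nmi(*_curves_from_probs(probs))
    return out


@dataclass(frozen=True)
class ComparisonTable:
    """Per-fit G²/k/n/BIC rows plus per-study and grand BIC sums.

    ``rows``: one row per (label, model, family); ``summary``: summed G² and
    BIC per (model, family) with a winner flag on the minimal grand BIC.
    """

    rows: pd.DataFrame
    summary: pd.DataFrame

    @property
    def winner(self) -> tuple[str, str]:
        w = self.summary.loc[self.summary["winner"]]
        return str(w["model"].iloc[0]), str(w["family"].iloc[0])

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "rows": self.rows.to_dict(orient="records"),
                    "summary": self.summary.to_dict(orient="records"),
                },
                fh,
                indent=2,
            )


def compare_models(fits: list[FitResult]) -> ComparisonTable:
    """Build the comparison table from fits of several models to one or more
    study tables.

    Every compared (model, family) must be fitted to every label; missing
    cells raise a ValueError naming them.
    """
    if not fits:
        raise ValueError("no fits to compare")
    rows = pd.DataFrame(
        [
            {
                "label": f.label,
                "model": f.model,
                "family": f.family,
                "g_squared": f.g_squared,
                "k": f.k,
                "n": f.n,
                "bic": bic(f.g_squared, f.k, f.n),
            }
            for f in fits
        ]
    )
    labels = rows["label"].unique()
    cells = set(zip(rows["label"], rows["model"], rows["family"]))
    for mf in set(zip(rows["model"], rows["family"])):
        for lab in labels:
            if (lab, *mf) not in cells:
                raise ValueError(f"missing fit for table {lab!r}, model {mf}")
    summary = (
        rows.groupby(["model", "family"], as_index=False)[["g_squared", "bic"]]
        .sum()
        .rename(columns={"g_squared": "sum_g_squared", "bic": "sum_bic"})
    )
    summary["winner"] = summary["sum_bic"] == summary["sum_bic"].min()
    # per-study winner flag on rows
    rows["study_winner"] = False
    for lab in labels:
        sub = rows["label"] == lab
        idx = rows.loc[sub, "bic"].idxmin()
        rows.loc[idx, "study_winner"] = True
    return ComparisonTable(rows=rows, summary=summary)


@dataclass(frozen=True)
class RecoveryReport:
    """Winner frequencies of a seeded model-recovery experiment."""

    generator_model: str
    reps: int
    winner_counts: dict[str, int]
    mean_delta_bic: dict[str, float]  # mean BIC - winner BIC per model
    failures: int

    @property
    def winner_rate(self) -> dict[str, float]:
        return {m: c / self.reps for m, c in self.winner_counts.items()}

    def to_dict(self) -> dict:
        return {
            "generator_model": self.generator_model,
            "reps": self.reps,
            "winner_counts": self.winner_counts,
            "winner_rate": self.winner_rate,
            "mean_delta_bic": self.mean_delta_bic,
            "failures": self.failures,
        }


def model_recovery(
    design: StudyDesign,
    generator_params,
    generator_model: str,
    family: str,
    reps: int,
    seed: int,
    models: tuple[str, ...] = ("basic", "rem", "tsm", "ttm"),
    config: FitConfig | None = None,
) -> RecoveryReport:
    """Simulate tables from a generating model and record which model BIC
    selects in each replicate.

    Consistency of the BIC implies the true model's selection frequency
    approaches 1 as trials per level grow.
    """
    from .synthetic import GeneratorSpec, simulate_response_table

    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    winner_counts = {m: 0 for m in models}
    delta_bic_acc = {m: [] for m in models}
    failures = 0
    for rep in range(reps):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        spec = GeneratorSpec(
            model=generator_model, params=generator_params,
            design=design, seed=sub_seed,
        )
        table = simulate_response_table(spec)
        bics = {}
        try:
            for m in models:
                fit = fit_model(table, m, family, config)
                bics[m] = bic(fit.g_squared, fit.k, fit.n)
        except RuntimeError:
            failures += 1
            continue
        best = min(bics, key=bics.get)
        winner_counts[best] += 1
        for m in models:
            delta_bic_acc[m].append(bics[m] - bics[best])
    mean_delta = {
        m: float(np.mean(v)) if v else float("nan") for m, v in delta_bic_acc.items()
    }
    return RecoveryReport(
        generator_model=generator_model,
        reps=reps,
        winner_counts=winner_counts,
        mean_delta_bic=mean_delta,
        failures=failures,
    )
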