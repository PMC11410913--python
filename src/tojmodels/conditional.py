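"""Conditional order-accuracy analysis of dual-response (SJ then TOJ) data.

If order detection requires successiveness detection, the forced order
response should be at chance whenever the subject (incorrectly) judged two
non-simultaneous stimuli as simultaneous.  This module computes, per |d| and
pooled over all nonzero d: unconditional order accuracy, accuracy conditional
on a correct successiveness response (sj = "su" at d != 0), and accuracy
conditional on an incorrect simultaneity response (sj = "si" at d != 0) with a
two-sided exact binomial test against chance (0.5).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import DualResponseTrial

__all__ = ["exact_binomial_test", "order_accuracy_report", "ConditionalReport"]

ALPHA = 0.05


def exact_binomial_test(successes: int, trials: int, p0: float = 0.5) -> float:
    """Two-sided exact binomial p-value by the point-probability method.

    Sums the probabilities of all outcomes no more likely than the observed
    one under Binomial(trials, p0).  At p0 = 0.5 this equals doubling the
    smaller tail (capped at 1) by symmetry; conventions diverge only for
    asymmetric nulls.
    """
    if not (0 <= successes <= trials):
        raise ValueError("need 0 <= successes <= trials")
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must lie strictly between 0 and 1")
    k = np.arange(trials + 1)
    pmf = stats.binom.pmf(k, trials, p0)
    # relative tolerance guards against ties broken by float round-off
    cutoff = pmf[successes] * (1.0 + 1e-7)
    p = float(pmf[pmf <= cutoff].sum())
    # the full support sums to 1 analytically; snap accumulated round-off
    return 1.0 if p > 1.0 - 1e-12 else p


@dataclass(frozen=True)
class ConditionalReport:
    """Order accuracy by |d| and pooled, split by the preceding SJ response.

    ``by_level`` has one row per nonzero |d| with counts, accuracies (NaN where
    the conditioning set is empty), and the exact binomial p-value for the
    accuracy-after-R_si test against 0.5.  ``pooled`` aggregates over all
    nonzero d.  ``n_significant`` counts per-|d| tests with p < 0.05.
    """

    by_level: pd.DataFrame
    pooled: dict
    n_significant: int
    n_tested: int

    def to_tsv(self, path) -> None:
        self.by_level.to_csv(path, sep="\t", index=False)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "by_level": self.by_level.to_dict(orient="records"),
                    "pooled": self.pooled,
                    "n_significant": self.n_significant,
                    "n_tested": self.n_tested,
                },
                fh,
                indent=2,
                default=float,
            )


def _accuracy(correct: int, total: int) -> float:
    return correct / total if total > 0 else float("nan")


def order_accuracy_report(trials: list[DualResponseTrial]) -> ConditionalReport:
    """Conditional and unconditional order accuracy from dual-response trials.

    A TOJ is correct when it agrees with the sign convention d = t_y - t_x
    (d > 0 means x first, so "xy" is correct).  Trials at d = 0 are excluded
    from all accuracy computations.  Empty conditioning sets yield NaN, never
    0.
    """
    if not trials:
        raise ValueError("no trials")
    df = pd.DataFrame(
        [{"soa_ms": t.soa_ms, "sj": t.sj, "toj": t.toj} for t in trials]
    )
    df = df[df["soa_ms"] != 0].copy()
    if df.empty:
        raise ValueError("all trials are at d = 0; order accuracy is undefined")
    df["correct"] = np.where(df["soa_ms"] > 0, df["toj"] == "xy", df["toj"] == "yx")
    df["abs_d"] = df["soa_ms"].abs()

    rows = []
    for abs_d, grp in df.groupby("abs_d"):
        su = grp[grp["sj"] == "su"]
        si = grp[grp["sj"] == "si"]
        n_si, c_si = len(si), int(si["correct"].sum())
        rows.append(
            {
                "abs_d": float(abs_d),
                "n_trials": len(grp),
                "n_su": len(su),
                "n_si": n_si,
                "acc_unconditional": _accuracy(int(grp["correct"].sum()), len(grp)),
                "acc_given_su": _accuracy(int(su["correct"].sum()), len(su)),
                "acc_given_si": _accuracy(c_si, n_si),
                "p_value_si_vs_chance": (
                    exact_binomial_test(c_si, n_si, 0.5) if n_si > 0 else float("nan")
                ),
            }
        )
    by_level = pd.DataFrame(rows).sort_values("abs_d").reset_index(drop=True)

    su = df[df["sj"] == "su"]
    si = df[df["sj"] == "si"]
    n_si, c_si = len(si), int(si["correct"].sum())
    pooled = {
        "n_trials": len(df),
        "n_su": len(su),
        "n_si": n_si,
        "acc_unconditional": _accuracy(int(df["correct"].sum()), len(df)),
        "acc_given_su": _accuracy(int(su["correct"].sum()), len(su)),
        "acc_given_si": _accuracy(c_si, n_si),
        "p_value_si_vs_chance": (
            exact_binomial_test(c_si, n_si, 0.5) if n_si > 0 else float("nan")
        ),
    }
    tested = by_level["p_value_si_vs_chance"].dropna()
    return ConditionalReport(
        by_level=by_level,
        pooled=pooled,
        n_significant=int((tested < ALPHA).sum()),
        n_tested=int(tested.size),
    )
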