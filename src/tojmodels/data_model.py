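"""Domain types and on-disk formats for ternary-response timing-judgment data.

The central container is :class:`ResponseTable`: observed counts of the three
responses R_xy ("x first"), R_si ("simultaneous"), R_yx ("y first") at each
stimulus-onset difference ``d = t_y - t_x`` (ms; positive d means stimulus x
was presented first).  Tables are stored as UTF-8 TSV with header
``soa_ms\\tn_xy\\tn_si\\tn_yx`` (an optional ``n_su`` column holds counts of
overt "successive, order unclear" responses from quaternary tasks).

Recoding helpers convert historical response formats onto the ternary scheme:
dual SJ-then-TOJ responses, four-level confidence responses, and quaternary
counts with an explicit R_su response.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RESPONSES",
    "ResponseTable",
    "DualResponseTrial",
    "StudyDesign",
    "read_response_table",
    "write_response_table",
    "read_dual_trials",
    "write_dual_trials",
    "recode_dual_response",
    "recode_confidence",
    "collapse_quaternary",
    "pool_tables",
]

#: Ternary response labels, in column order.
RESPONSES = ("xy", "si", "yx")

_COLUMNS = ("soa_ms", "n_xy", "n_si", "n_yx")

#: Valid four-level confidence-rating tokens.
CONFIDENCE_LEVELS = ("xy_certain", "xy_uncertain", "yx_uncertain", "yx_certain")


@dataclass(frozen=True)
class ResponseTable:
    """Observed response counts per stimulus-onset difference.

    Parameters
    ----------
    label : str
        Free-text identifier (study / subject / condition).
    soa_ms : ndarray of float, shape (D,)
        Stimulus-onset differences d = t_y - t_x in ms, strictly increasing.
    counts : ndarray of int, shape (D, 3)
        Columns are counts of (R_xy, R_si, R_yx) at each d.
    """

    label: str
    soa_ms: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        soa = np.asarray(self.soa_ms, dtype=float)
        counts = np.asarray(self.counts)
        if soa.ndim != 1 or soa.size < 2:
            raise ValueError("need at least 2 SOA levels")
        if not np.all(np.isfinite(soa)):
            raise ValueError("non-finite SOA value")
        if np.any(np.diff(soa) <= 0):
            raise ValueError("soa_ms must be strictly increasing (no duplicates)")
        if counts.shape != (soa.size, 3):
            raise ValueError(f"counts must have shape ({soa.size}, 3), got {counts.shape}")
        if not np.issubdtype(counts.dtype, np.integer):
            as_int = counts.astype(np.int64)
            if not np.array_equal(as_int, counts):
                raise ValueError("counts must be integers")
            counts = as_int
        if np.any(counts < 0):
            bad = int(np.argwhere(counts < 0)[0][0])
            raise ValueError(f"negative count at soa_ms={soa[bad]:g}")
        if counts.sum() == 0:
            raise ValueError("table has no observed responses")
        object.__setattr__(self, "soa_ms", soa)
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def n_levels(self) -> int:
        return self.soa_ms.size

    @property
    def totals(self) -> np.ndarray:
        """Per-level multinomial denominators n_d."""
        return self.counts.sum(axis=1)

    @property
    def n_trials(self) -> int:
        """Total number of trials across all levels (the BIC n)."""
        return int(self.counts.sum())

    def proportions(self) -> np.ndarray:
        """Observed response proportions, NaN where a level has no trials."""
        tot = self.totals.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = self.counts / tot[:, None]
        return p

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "soa_ms": self.soa_ms,
                "n_xy": self.counts[:, 0],
                "n_si": self.counts[:, 1],
                "n_yx": self.counts[:, 2],
            }
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ResponseTable):
            return NotImplemented
        return (
            self.label == other.label
            and np.array_equal(self.soa_ms, other.soa_ms)
            and np.array_equal(self.counts, other.counts)
        )


@dataclass(frozen=True)
class DualResponseTrial:
    """One trial of Allan's (SJ followed by forced TOJ) dual-response task."""

    soa_ms: float
    sj: str  # "si" or "su"
    toj: str  # "xy" or "yx"

    def __post_init__(self) -> None:
        if self.sj not in ("si", "su"):
            raise ValueError(f"sj must be 'si' or 'su', got {self.sj!r}")
        if self.toj not in ("xy", "yx"):
            raise ValueError(f"toj must be 'xy' or 'yx', got {self.toj!r}")


@dataclass(frozen=True)
class StudyDesign:
    """A study's d grid and per-level trial count."""

    name: str
    soa_ms: np.ndarray
    trials_per_soa: np.ndarray

    def __post_init__(self) -> None:
        soa = np.asarray(self.soa_ms, dtype=float)
        trials = np.broadcast_to(np.asarray(self.trials_per_soa, dtype=np.int64), soa.shape).copy()
        if np.any(np.diff(soa) <= 0):
            raise ValueError("design grid must be strictly increasing")
        if np.any(trials < 1):
            raise ValueError("trials_per_soa must be >= 1 everywhere")
        object.__setattr__(self, "soa_ms", soa)
        object.__setattr__(self, "trials_per_soa", trials)

    def with_trials(self, trials_per_soa: int) -> "StudyDesign":
        """Copy of the design with a constant per-level trial count."""
        return StudyDesign(self.name, self.soa_ms, np.full(self.soa_ms.size, trials_per_soa))


# ---------------------------------------------------------------------------
# TSV / CSV input-output
# ---------------------------------------------------------------------------

def read_response_table(
    path: str | Path,
    label: str | None = None,
    collapse_su: bool = False,
) -> ResponseTable:
    """Read a ternary response table from TSV.

    The file must carry the header columns ``soa_ms  n_xy  n_si  n_yx``.
    An ``n_su`` column is only accepted when ``collapse_su=True``, in which
    case R_su trials are dropped (quaternary-to-ternary collapse).
    Rows are sorted by soa_ms.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    has_su = "n_su" in df.columns
    if has_su and not collapse_su:
        raise ValueError(
            f"{path}: found quaternary column n_su; pass collapse_su=True to drop R_su trials"
        )
    count_cols = ["n_xy", "n_si", "n_su", "n_yx"] if has_su else ["n_xy", "n_si", "n_yx"]
    for col in count_cols:
        vals = df[col]
        for i, v in enumerate(vals):
            if pd.isna(v) or float(v) != int(v):
                raise ValueError(f"{path}: non-integer count in row {i} field {col!r}")
            if int(v) < 0:
                raise ValueError(f"{path}: negative count in row {i} field {col!r}")
    if df["soa_ms"].duplicated().any():
        dup = df.loc[df["soa_ms"].duplicated(), "soa_ms"].iloc[0]
        raise ValueError(f"{path}: duplicated soa level {dup}")
    df = df.sort_values("soa_ms").reset_index(drop=True)
    if label is None:
        label = path.stem
    if has_su:
        counts4 = df[["n_xy", "n_si", "n_su", "n_yx"]].to_numpy(dtype=np.int64)
        return collapse_quaternary(df["soa_ms"].to_numpy(float), counts4, label=label)
    counts = df[["n_xy", "n_si", "n_yx"]].to_numpy(dtype=np.int64)
    return ResponseTable(label, df["soa_ms"].to_numpy(float), counts)


def write_response_table(table: ResponseTable, path: str | Path) -> None:
    """Write a ResponseTable as TSV readable by :func:`read_response_table`."""
    table.to_frame().to_csv(Path(path), sep="\t", index=False)


def read_dual_trials(path: str | Path) -> list[DualResponseTrial]:
    """Read trial-level dual responses from CSV with header ``soa_ms,sj,toj``."""
    df = pd.read_csv(path)
    missing = [c for c in ("soa_ms", "sj", "toj") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return [
        DualResponseTrial(float(r.soa_ms), str(r.sj), str(r.toj))
        for r in df.itertuples(index=False)
    ]


def write_dual_trials(trials: Iterable[DualResponseTrial], path: str | Path) -> None:
    pd.DataFrame(
        [{"soa_ms": t.soa_ms, "sj": t.sj, "toj": t.toj} for t in trials]
    ).to_csv(Path(path), index=False)


# ---------------------------------------------------------------------------
# Recoding rules for historical response formats
# ---------------------------------------------------------------------------

def recode_dual_response(sj: str, toj: str) -> str:
    """Map an (SJ, forced TOJ) response pair onto the ternary scheme.

    A "successive" judgment keeps the subsequent order report:
    (su, xy) -> xy and (su, yx) -> yx, while any "simultaneous" judgment
    is coded si regardless of the forced order response.
    """
    if sj not in ("si", "su"):
        raise ValueError(f"sj must be 'si' or 'su', got {sj!r}")
    if toj not in ("xy", "yx"):
        raise ValueError(f"toj must be 'xy' or 'yx', got {toj!r}")
    return "si" if sj == "si" else toj


def recode_confidence(resp: str) -> str:
    """Map a four-level confidence response onto the ternary scheme.

    Certain order reports keep their direction; uncertain reports of either
    direction are coded as simultaneity.
    """
    mapping = {
        "xy_certain": "xy",
        "xy_uncertain": "si",
        "yx_uncertain": "si",
        "yx_certain": "yx",
    }
    try:
        return mapping[resp]
    except KeyError:
        raise ValueError(f"unknown confidence response {resp!r}") from None


def collapse_quaternary(
    soa_ms: Sequence[float],
    counts4: np.ndarray,
    label: str = "",
) -> ResponseTable:
    """Drop the R_su column of quaternary counts (n_xy, n_si, n_su, n_yx).

    Per-level totals shrink by n_su; the other counts are unchanged.  Levels
    where every trial was R_su are retained with zero total.
    """
    counts4 = np.asarray(counts4)
    if counts4.ndim != 2 or counts4.shape[1] != 4:
        raise ValueError("counts4 must have shape (D, 4)")
    if np.any(counts4 < 0):
        raise ValueError("negative counts")
    counts = counts4[:, [0, 1, 3]]
    return ResponseTable(label, np.asarray(soa_ms, float), counts)


def pool_tables(tables: Sequence[ResponseTable], label: str | None = None) -> ResponseTable:
    """Sum counts cell-wise across tables sharing an identical soa grid."""
    if not tables:
        raise ValueError("no tables to pool")
    ref = tables[0]
    for t in tables[1:]:
        if not np.array_equal(t.soa_ms, ref.soa_ms):
            raise ValueError(f"table {t.label!r} has a mismatched soa grid")
    counts = np.sum([t.counts for t in tables], axis=0)
    if label is None:
        label = "+".join(t.label for t in tables)
    return ResponseTable(label, ref.soa_ms.copy(), counts)
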