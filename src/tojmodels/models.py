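"""Internal-state and response probabilities of the independent-channels models.

All four models share the decision variable dA = dL + d and a basic partition
of the real line by a successiveness threshold c_su: order of x before y is
perceived when dA >= c_su (internal state I_xy), order of y before x when
dA <= -c_su (I_yx), and simultaneity otherwise (I_si).  The three extensions
differ in how internal states map onto the overt ternary responses:

* REM (response-error model): a single threshold, but each internal state is
  misreported with probability eps, and a misreport lands on one of the two
  non-corresponding responses according to a conditional bias kappa.
* TSM (two-stage model): independent "successiveness" and "order" centers with
  their own latency differences and thresholds; I_si always yields R_si, while
  under I_su the order center's verdict (or a guess g when order is
  imperceptible) determines the response.
* TTM (two-threshold model): one latency difference but two thresholds
  c_o >= c_su.  Arrival differences between the two thresholds give the state
  I_su of unordered successiveness, which is resolved by a guess g.

With eps == 0 the REM, and with c_o == c_su the TTM, reduce exactly to the
basic three-parameter model — these nestings anchor the fitting tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .latency import LatencyDiffDistribution, diff_cdf

__all__ = [
    "BasicParams",
    "REMParams",
    "TSMParams",
    "TTMParams",
    "basic_state_probs",
    "ttm_state_probs",
    "tsm_state_probs",
    "basic_response_probs",
    "rem_response_probs",
    "tsm_response_probs",
    "ttm_response_probs",
    "response_probs",
    "MODEL_IDS",
]

MODEL_IDS = ("basic", "rem", "tsm", "ttm")

#: Probability floor applied before logarithms downstream (extreme-|d| underflow).
PROB_FLOOR = 1e-300


@dataclass(frozen=True)
class BasicParams:
    """Basic three-parameter model: dL law plus successiveness threshold."""

    dist: LatencyDiffDistribution
    c_su: float

    def __post_init__(self) -> None:
        if not (self.c_su > 0):
            raise ValueError("c_su must be > 0")

    def to_dict(self) -> dict:
        return {
            "family": self.dist.family,
            "mu": self.dist.location,
            "scale": self.dist.scale,
            "c_su": self.c_su,
        }


@dataclass(frozen=True)
class REMParams:
    """Response-error model parameters.

    ``basic.c_su`` plays the single REM threshold c.  eps_* are the misreport
    probabilities of I_xy / I_si / I_yx; kap_xy_yx, kap_si_xy, kap_yx_xy the
    conditional probabilities that a misreported I_xy goes to R_yx, a
    misreported I_si to R_xy, and a misreported I_yx to R_xy.  The complements
    (kappa_xy-si etc.) are derived, never stored.  ``active`` marks which
    (eps, kappa) pairs are free in the reduced-model hierarchy; inactive
    responses have eps fixed at 0 (kappa then has no effect, stored as 0.5).
    """

    basic: BasicParams
    eps_xy: float = 0.0
    eps_si: float = 0.0
    eps_yx: float = 0.0
    kap_xy_yx: float = 0.5
    kap_si_xy: float = 0.5
    kap_yx_xy: float = 0.5
    active: tuple[str, ...] = ("xy", "si", "yx")

    def __post_init__(self) -> None:
        for name in ("eps_xy", "eps_si", "eps_yx"):
            v = getattr(self, name)
            if not (0.0 <= v <= 0.8):
                raise ValueError(f"{name} must lie in [0, 0.8]")
        for name in ("kap_xy_yx", "kap_si_xy", "kap_yx_xy"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not set(self.active) <= {"xy", "si", "yx"}:
            raise ValueError("active must be a subset of {'xy','si','yx'}")
        for r in ("xy", "si", "yx"):
            if r not in self.active:
                eps = getattr(self, f"eps_{r}")
                if eps != 0.0:
                    raise ValueError(f"inactive response {r!r} must have eps fixed at 0")

    @property
    def n_free(self) -> int:
        return 3 + 2 * len(self.active)

    def to_dict(self) -> dict:
        d = self.basic.to_dict()
        d.update(
            eps_xy=self.eps_xy, eps_si=self.eps_si, eps_yx=self.eps_yx,
            kap_xy_yx=self.kap_xy_yx, kap_si_xy=self.kap_si_xy,
            kap_yx_xy=self.kap_yx_xy, active=list(self.active),
        )
        return d


@dataclass(frozen=True)
class TSMParams:
    """Two-stage model: separate latency differences and thresholds for the
    successiveness and order centers, plus guessing probability g."""

    dist_su: LatencyDiffDistribution
    c_su: float
    dist_o: LatencyDiffDistribution
    c_o: float
    g: float

    def __post_init__(self) -> None:
        if not (self.c_su > 0 and self.c_o > 0):
            raise ValueError("both thresholds must be > 0")
        if not (0.0 <= self.g <= 1.0):
            raise ValueError("g must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "family": self.dist_su.family,
            "mu_su": self.dist_su.location, "scale_su": self.dist_su.scale,
            "mu_o": self.dist_o.location, "scale_o": self.dist_o.scale,
            "c_su": self.c_su, "c_o": self.c_o, "g": self.g,
        }


@dataclass(frozen=True)
class TTMParams:
    """Two-threshold model: one dL law, thresholds c_o >= c_su, guess g."""

    dist: LatencyDiffDistribution
    c_su: float
    c_o: float
    g: float

    def __post_init__(self) -> None:
        if not (self.c_su > 0):
            raise ValueError("c_su must be > 0")
        if self.c_o < self.c_su:
            raise ValueError("TTM requires c_o >= c_su")
        if not (0.0 <= self.g <= 1.0):
            raise ValueError("g must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "family": self.dist.family,
            "mu": self.dist.location, "scale": self.dist.scale,
            "c_su": self.c_su, "c_o": self.c_o, "g": self.g,
        }


# ---------------------------------------------------------------------------
# Internal-state probabilities
# ---------------------------------------------------------------------------

def basic_state_probs(params: BasicParams, d) -> dict[str, np.ndarray | float]:
    """P(I_xy), P(I_si), P(I_yx) given d, for the basic model.

    With F the dL CDF: P(I_xy|d) = 1 - F(c_su - d), P(I_yx|d) = F(-c_su - d),
    P(I_si|d) is the remaining band mass.
    """
    d = np.asarray(d, dtype=float)
    F = lambda x: diff_cdf(params.dist, x)
    p_xy = 1.0 - F(params.c_su - d)
    p_yx = F(-params.c_su - d)
    p_si = F(params.c_su - d) - F(-params.c_su - d)
    return {"I_xy": p_xy, "I_si": p_si, "I_yx": p_yx}


def ttm_state_probs(params: TTMParams, d) -> dict[str, np.ndarray | float]:
    """Four-state partition of the TTM: order, simultaneity, and the two
    order-uncertainty bands c_su <= |dA| < c_o pooled into I_su."""
    d = np.asarray(d, dtype=float)
    F = lambda x: diff_cdf(params.dist, x)
    p_xy = 1.0 - F(params.c_o - d)
    p_yx = F(-params.c_o - d)
    p_si = F(params.c_su - d) - F(-params.c_su - d)
    p_su = (F(params.c_o - d) - F(params.c_su - d)) + (
        F(-params.c_su - d) - F(-params.c_o - d)
    )
    return {"I_xy": p_xy, "I_si": p_si, "I_su": p_su, "I_yx": p_yx}


def tsm_state_probs(params: TSMParams, d) -> dict[str, np.ndarray | float]:
    """TSM state probabilities: marginals of the two independent centers and
    their joint products.

    Successiveness center: I_si vs I_su by threshold c_su on its own dA.
    Order center: I_xy / I_? / I_yx by threshold c_o on its own dA.
    """
    d = np.asarray(d, dtype=float)
    F_su = lambda x: diff_cdf(params.dist_su, x)
    F_o = lambda x: diff_cdf(params.dist_o, x)
    p_si = F_su(params.c_su - d) - F_su(-params.c_su - d)
    p_su = 1.0 - p_si
    p_xy = 1.0 - F_o(params.c_o - d)
    p_yx = F_o(-params.c_o - d)
    p_unk = 1.0 - p_xy - p_yx
    out = {"I_si": p_si, "I_su": p_su, "I_xy": p_xy, "I_?": p_unk, "I_yx": p_yx}
    for su_state in ("I_si", "I_su"):
        for o_state in ("I_xy", "I_?", "I_yx"):
            out[f"{su_state}&{o_state}"] = out[su_state] * out[o_state]
    return out


# ---------------------------------------------------------------------------
# Response probabilities (the fitted psychometric functions)
# ---------------------------------------------------------------------------

def _stack(p_xy, p_si, p_yx) -> np.ndarray:
    probs = np.stack(np.broadcast_arrays(
        np.asarray(p_xy, float), np.asarray(p_si, float), np.asarray(p_yx, float)
    ), axis=-1)
    return np.clip(probs, PROB_FLOOR, 1.0)


def basic_response_probs(params: BasicParams, d) -> np.ndarray:
    """Response probabilities (p_xy, p_si, p_yx) of the basic model: the
    identity mapping from internal states to responses."""
    s = basic_state_probs(params, d)
    return _stack(s["I_xy"], s["I_si"], s["I_yx"])


def rem_response_probs(params: REMParams, d) -> np.ndarray:
    """REM response probabilities: row-stochastic error mixing of the basic
    internal states.

    p_xy = (1-eps_xy) P(I_xy) + eps_si kap_si_xy P(I_si) + eps_yx kap_yx_xy P(I_yx)
    p_si = eps_xy (1-kap_xy_yx) P(I_xy) + (1-eps_si) P(I_si) + eps_yx (1-kap_yx_xy) P(I_yx)
    p_yx = eps_xy kap_xy_yx P(I_xy) + eps_si (1-kap_si_xy) P(I_si) + (1-eps_yx) P(I_yx)
    """
    s = basic_state_probs(params.basic, d)
    e_xy, e_si, e_yx = params.eps_xy, params.eps_si, params.eps_yx
    k_xy_yx, k_si_xy, k_yx_xy = params.kap_xy_yx, params.kap_si_xy, params.kap_yx_xy
    p_xy = (
        (1 - e_xy) * s["I_xy"]
        + e_si * k_si_xy * s["I_si"]
        + e_yx * k_yx_xy * s["I_yx"]
    )
    p_si = (
        e_xy * (1 - k_xy_yx) * s["I_xy"]
        + (1 - e_si) * s["I_si"]
        + e_yx * (1 - k_yx_xy) * s["I_yx"]
    )
    p_yx = (
        e_xy * k_xy_yx * s["I_xy"]
        + e_si * (1 - k_si_xy) * s["I_si"]
        + (1 - e_yx) * s["I_yx"]
    )
    return _stack(p_xy, p_si, p_yx)


def tsm_response_probs(params: TSMParams, d) -> np.ndarray:
    """TSM response probabilities.

    p_xy = P(I_su & I_xy) + g P(I_su & I_?); p_si = P(I_si);
    p_yx = P(I_su & I_yx) + (1-g) P(I_su & I_?).
    """
    s = tsm_state_probs(params, d)
    p_xy = s["I_su&I_xy"] + params.g * s["I_su&I_?"]
    p_yx = s["I_su&I_yx"] + (1 - params.g) * s["I_su&I_?"]
    return _stack(p_xy, s["I_si"], p_yx)


def ttm_response_probs(params: TTMParams, d) -> np.ndarray:
    """TTM response probabilities.

    p_xy = P(I_xy) + g P(I_su); p_si = P(I_si); p_yx = P(I_yx) + (1-g) P(I_su).
    """
    s = ttm_state_probs(params, d)
    p_xy = s["I_xy"] + params.g * s["I_su"]
    p_yx = s["I_yx"] + (1 - params.g) * s["I_su"]
    return _stack(p_xy, s["I_si"], p_yx)


def response_probs(params, d) -> np.ndarray:
    """Dispatch on the parameter record's type."""
    if isinstance(params, REMParams):
        return rem_response_probs(params, d)
    if isinstance(params, TSMParams):
        return tsm_response_probs(params, d)
    if isinstance(params, TTMParams):
        return ttm_response_probs(params, d)
    if isinstance(params, BasicParams):
        return basic_response_probs(params, d)
    raise TypeError(f"unknown parameter record {type(params).__name__}")
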