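"""Fitting independent-channels models by minimum-G² multistart optimization.

Each model is fitted to the observed response frequencies by minimizing the
likelihood-ratio statistic

    G² = 2 · Σ_R Σ_d O_Rd · ln(O_Rd / E_Rd),

where E_Rd = n_d · P(R|d) are the model's expected frequencies, floored at 0.1
counts to tame the leverage of near-empty cells.  The search is a
box-constrained quasi-Newton (L-BFGS-B) local minimization launched from the
full factorial grid of two starting values per free parameter, i.e. 2^k starts
(512 for the nine-parameter REM, 128 for the TSM, 32 for the TTM, 8 for the
basic model).  The TTM's order threshold is reparameterized as
c_o = c_su + delta with delta in [0, 149] ms so that the hard constraint
c_o >= c_su is preserved by plain box bounds.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from .data_model import ResponseTable
from .models import (
    MODEL_IDS,
    BasicParams,
    REMParams,
    TSMParams,
    TTMParams,
    response_probs,
)
from .latency import LatencyDiffDistribution

try:  # fast JIT objective; the numpy route below is the tested fallback
    from . import _kernels
except ImportError:  # pragma: no cover
    _kernels = None

__all__ = [
    "FitConfig",
    "FitResult",
    "expected_counts",
    "g_squared",
    "fit_model",
    "fit_rem_hierarchy",
    "REM_MASKS",
]

#: The reduced-REM hierarchy: which responses carry free (eps, kappa) pairs.
REM_MASKS: tuple[tuple[str, ...], ...] = (
    (),
    ("xy",), ("si",), ("yx",),
    ("xy", "si"), ("xy", "yx"), ("si", "yx"),
    ("xy", "si", "yx"),
)


@dataclass(frozen=True)
class FitConfig:
    """Box constraints, factorial start values, and optimizer settings.

    Bounds/starts are keyed by parameter kind; every start lies strictly
    inside its bounds.  ``expected_floor`` is the lower bound (in counts)
    applied to expected frequencies before logs.
    """

    bounds: dict = field(default_factory=lambda: {
        "location": (-100.0, 100.0),
        "scale": (1.0, 100.0),
        "threshold": (1.0, 150.0),
        "delta": (0.0, 149.0),  # TTM: c_o = c_su + delta
        "eps": (0.0, 0.8),
        "prob": (0.0, 1.0),  # kappas and g
    })
    starts: dict = field(default_factory=lambda: {
        "location": (-33.0, 34.0),
        "scale": (33.0, 67.0),
        "threshold": (50.0, 100.0),
        "delta": (0.0, 50.0),
        "eps": (0.27, 0.53),
        "prob": (0.33, 0.67),
    })
    expected_floor: float = 0.1
    ftol: float = 1e-9
    maxiter: int = 2000

    def __post_init__(self) -> None:
        if not (self.expected_floor > 0):
            raise ValueError("expected_floor must be > 0")
        for kind, (a, b) in self.starts.items():
            lo, hi = self.bounds[kind]
            for s in (a, b):
                if not (lo <= s <= hi):
                    raise ValueError(f"start {s} for {kind!r} outside bounds [{lo}, {hi}]")


@dataclass(frozen=True)
class FitResult:
    """Outcome of one (table, model, family) fit."""

    model: str
    family: str
    params: object  # the best-fitting parameter record
    g_squared: float
    k: int  # free-parameter count
    n: int  # observation count used for BIC (total trials)
    n_starts: int
    per_start_g2: np.ndarray
    converged: bool
    label: str = ""

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "model": self.model,
            "family": self.family,
            "params": self.params.to_dict(),
            "g_squared": self.g_squared,
            "k": self.k,
            "n": self.n,
            "n_starts": self.n_starts,
            "per_start_g2": [float(v) for v in self.per_start_g2],
            "converged": self.converged,
        }

    @property
    def start_spread(self) -> float:
        """Range of per-start minima — a multistart-sensitivity diagnostic."""
        finite = self.per_start_g2[np.isfinite(self.per_start_g2)]
        return float(finite.max() - finite.min()) if finite.size else float("nan")


# ---------------------------------------------------------------------------
# Objective pieces
# ---------------------------------------------------------------------------

def expected_counts(
    model_params, table: ResponseTable, floor: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """Expected frequencies E_Rd = n_d · P(R|d), raw and floored.

    Returns ``(raw, floored)`` arrays of shape (D, 3).
    """
    probs = response_probs(model_params, table.soa_ms)
    raw = table.totals[:, None] * probs
    return raw, np.maximum(raw, floor)


def g_squared(observed: np.ndarray, expected: np.ndarray) -> float:
    """Likelihood-ratio statistic 2·Σ O·ln(O/E); empty cells contribute 0."""
    O = np.asarray(observed, dtype=float)
    E = np.asarray(expected, dtype=float)
    if O.shape != E.shape:
        raise ValueError("observed and expected must have matching shapes")
    if np.any(O < 0):
        raise ValueError("negative observed count")
    if np.any(E <= 0):
        raise ValueError("expected frequencies must be positive (after flooring)")
    mask = O > 0
    return float(2.0 * np.sum(O[mask] * np.log(O[mask] / E[mask])))


# --- fast per-family CDFs (raw arrays; the hot path of every fit) ----------

_SQRT2PI = np.sqrt(2.0 * np.pi)


def _cdf(family: str, x: np.ndarray, mu: float, scale: float) -> np.ndarray:
    z = (x - mu) / scale
    if family == "normal":
        return special.ndtr(z)
    return np.where(z < 0, 0.5 * np.exp(z), 1.0 - 0.5 * np.exp(-z))


def _cdf_pdf(family: str, x: np.ndarray, mu: float, scale: float):
    """CDF, density, and standardized coordinate at x — one shot.

    The derivative bookkeeping uses dF/dmu = -f, dF/dscale = -z f, dF/dx = f,
    identical in form for both families.
    """
    z = (x - mu) / scale
    if family == "normal":
        F = special.ndtr(z)
        f = np.exp(-0.5 * z * z) / (_SQRT2PI * scale)
    else:
        ez = np.exp(-np.abs(z))
        F = np.where(z < 0, 0.5 * ez, 1.0 - 0.5 * ez)
        f = 0.5 * ez / scale
    return F, f, z


def _basic_probs(family, d, mu, scale, c):
    hi = _cdf(family, c - d, mu, scale)
    lo = _cdf(family, -c - d, mu, scale)
    return 1.0 - hi, hi - lo, lo  # p_xy, p_si, p_yx


def _basic_probs_grad(family, d, mu, scale, c):
    """Basic-model state probabilities and their Jacobian w.r.t. (mu, scale, c).

    Returns (P, G): P of shape (D, 3) ordered (I_xy, I_si, I_yx), G of shape
    (D, 3, 3) with the last axis over (mu, scale, c).
    """
    Fa, fa, za = _cdf_pdf(family, c - d, mu, scale)
    Fb, fb, zb = _cdf_pdf(family, -c - d, mu, scale)
    P = np.stack([1.0 - Fa, Fa - Fb, Fb], axis=-1)
    G = np.empty(P.shape + (3,))
    # d/dmu: dFa = -fa, dFb = -fb
    G[:, 0, 0] = fa
    G[:, 1, 0] = -fa + fb
    G[:, 2, 0] = -fb
    # d/dscale: dFa = -za fa, dFb = -zb fb
    G[:, 0, 1] = za * fa
    G[:, 1, 1] = -za * fa + zb * fb
    G[:, 2, 1] = -zb * fb
    # d/dc: dFa = fa, dFb = -fb
    G[:, 0, 2] = -fa
    G[:, 1, 2] = fa + fb
    G[:, 2, 2] = -fb
    return P, G


def _probs_vector(model: str, family: str, vec: np.ndarray, d: np.ndarray,
                  active: tuple[str, ...]) -> np.ndarray:
    """Response probabilities (D, 3) from a flat parameter vector."""
    if model == "basic":
        mu, scale, c = vec
        p_xy, p_si, p_yx = _basic_probs(family, d, mu, scale, c)
    elif model == "rem":
        mu, scale, c = vec[:3]
        i_xy, i_si, i_yx = _basic_probs(family, d, mu, scale, c)
        eps = {"xy": 0.0, "si": 0.0, "yx": 0.0}
        kap = {"xy": 0.5, "si": 0.5, "yx": 0.5}
        for j, r in enumerate(active):
            eps[r] = vec[3 + 2 * j]
            kap[r] = vec[4 + 2 * j]
        p_xy = ((1 - eps["xy"]) * i_xy + eps["si"] * kap["si"] * i_si
                + eps["yx"] * kap["yx"] * i_yx)
        p_si = (eps["xy"] * (1 - kap["xy"]) * i_xy + (1 - eps["si"]) * i_si
                + eps["yx"] * (1 - kap["yx"]) * i_yx)
        p_yx = (eps["xy"] * kap["xy"] * i_xy + eps["si"] * (1 - kap["si"]) * i_si
                + (1 - eps["yx"]) * i_yx)
    elif model == "tsm":
        mu_su, sc_su, mu_o, sc_o, c_su, c_o, g = vec
        hi = _cdf(family, c_su - d, mu_su, sc_su)
        lo = _cdf(family, -c_su - d, mu_su, sc_su)
        p_si = hi - lo
        p_su = 1.0 - p_si
        o_xy = 1.0 - _cdf(family, c_o - d, mu_o, sc_o)
        o_yx = _cdf(family, -c_o - d, mu_o, sc_o)
        o_unk = 1.0 - o_xy - o_yx
        p_xy = p_su * (o_xy + g * o_unk)
        p_yx = p_su * (o_yx + (1 - g) * o_unk)
    elif model == "ttm":
        mu, scale, c_su, delta, g = vec
        c_o = c_su + delta
        hi_o = _cdf(family, c_o - d, mu, scale)
        lo_o = _cdf(family, -c_o - d, mu, scale)
        hi_s = _cdf(family, c_su - d, mu, scale)
        lo_s = _cdf(family, -c_su - d, mu, scale)
        i_xy = 1.0 - hi_o
        i_yx = lo_o
        p_si = hi_s - lo_s
        i_su = (hi_o - hi_s) + (lo_s - lo_o)
        p_xy = i_xy + g * i_su
        p_yx = i_yx + (1 - g) * i_su
    else:
        raise ValueError(f"unknown model {model!r}")
    probs = np.stack([p_xy, p_si, p_yx], axis=-1)
    return np.clip(probs, 1e-300, 1.0)


def _probs_and_grad(model: str, family: str, vec: np.ndarray, d: np.ndarray,
                    active: tuple[str, ...]):
    """Response probabilities (D, 3) and Jacobian (D, 3, k) w.r.t. the flat
    parameter vector.  Used to give L-BFGS-B an analytic gradient (one
    evaluation instead of k+1 finite-difference probes per iteration)."""
    D = d.size
    if model == "basic":
        return _basic_probs_grad(family, d, *vec)

    if model == "rem":
        mu, scale, c = vec[:3]
        S, Gs = _basic_probs_grad(family, d, mu, scale, c)
        eps = {"xy": 0.0, "si": 0.0, "yx": 0.0}
        kap = {"xy": 0.5, "si": 0.5, "yx": 0.5}
        for j, r in enumerate(active):
            eps[r] = vec[3 + 2 * j]
            kap[r] = vec[4 + 2 * j]
        e_xy, e_si, e_yx = eps["xy"], eps["si"], eps["yx"]
        k_xy, k_si, k_yx = kap["xy"], kap["si"], kap["yx"]
        # mixing matrix: rows = responses (xy, si, yx), cols = states
        M = np.array([
            [1 - e_xy, e_si * k_si, e_yx * k_yx],
            [e_xy * (1 - k_xy), 1 - e_si, e_yx * (1 - k_yx)],
            [e_xy * k_xy, e_si * (1 - k_si), 1 - e_yx],
        ])
        P = S @ M.T
        k = 3 + 2 * len(active)
        J = np.empty((D, 3, k))
        J[:, :, :3] = np.einsum("rs,dsj->drj", M, Gs)
        # per-response derivative directions of the mixing columns
        col = {"xy": 0, "si": 1, "yx": 2}
        d_eps = {
            "xy": np.array([-1.0, 1 - k_xy, k_xy]),
            "si": np.array([k_si, -1.0, 1 - k_si]),
            "yx": np.array([k_yx, 1 - k_yx, -1.0]),
        }
        d_kap = {
            "xy": np.array([0.0, -e_xy, e_xy]),
            "si": np.array([e_si, 0.0, -e_si]),
            "yx": np.array([e_yx, -e_yx, 0.0]),
        }
        for j, r in enumerate(active):
            s_col = S[:, col[r]][:, None]
            J[:, :, 3 + 2 * j] = s_col * d_eps[r]
            J[:, :, 4 + 2 * j] = s_col * d_kap[r]
        return P, J

    if model == "tsm":
        mu_su, sc_su, mu_o, sc_o, c_su, c_o, g = vec
        Ps, Gsu = _basic_probs_grad(family, d, mu_su, sc_su, c_su)
        Po, Go = _basic_probs_grad(family, d, mu_o, sc_o, c_o)
        p_si, dp_si = Ps[:, 1], Gsu[:, 1, :]  # over (mu_su, sc_su, c_su)
        p_su = 1.0 - p_si
        o_xy, o_unk, o_yx = Po[:, 0], Po[:, 1], Po[:, 2]
        A = o_xy + g * o_unk
        B = o_yx + (1 - g) * o_unk
        P = np.stack([p_su * A, p_si, p_su * B], axis=-1)
        J = np.zeros((D, 3, 7))
        su_idx, o_idx = (0, 1, 4), (2, 3, 5)
        for jj, src in zip(su_idx, range(3)):
            J[:, 0, jj] = -dp_si[:, src] * A
            J[:, 1, jj] = dp_si[:, src]
            J[:, 2, jj] = -dp_si[:, src] * B
        dA = Go[:, 0, :] + g * Go[:, 1, :]
        dB = Go[:, 2, :] + (1 - g) * Go[:, 1, :]
        for jj, src in zip(o_idx, range(3)):
            J[:, 0, jj] = p_su * dA[:, src]
            J[:, 2, jj] = p_su * dB[:, src]
        J[:, 0, 6] = p_su * o_unk
        J[:, 2, 6] = -p_su * o_unk
        return P, J

    if model == "ttm":
        mu, scale, c_su, delta, g = vec
        c_o = c_su + delta
        Fao, fao, zao = _cdf_pdf(family, c_o - d, mu, scale)
        Fbo, fbo, zbo = _cdf_pdf(family, -c_o - d, mu, scale)
        Fas, fas, zas = _cdf_pdf(family, c_su - d, mu, scale)
        Fbs, fbs, zbs = _cdf_pdf(family, -c_su - d, mu, scale)
        i_su = (Fao - Fas) + (Fbs - Fbo)
        P = np.stack(
            [1.0 - Fao + g * i_su, Fas - Fbs, Fbo + (1 - g) * i_su], axis=-1
        )
        # partials of each CDF term over (mu, scale, c_su, delta)
        dFao = np.stack([-fao, -zao * fao, fao, fao], axis=-1)
        dFbo = np.stack([-fbo, -zbo * fbo, -fbo, -fbo], axis=-1)
        dFas = np.stack([-fas, -zas * fas, fas, np.zeros_like(fas)], axis=-1)
        dFbs = np.stack([-fbs, -zbs * fbs, -fbs, np.zeros_like(fbs)], axis=-1)
        dIsu = dFao - dFas + dFbs - dFbo
        J = np.empty((D, 3, 5))
        J[:, 0, :4] = -dFao + g * dIsu
        J[:, 1, :4] = dFas - dFbs
        J[:, 2, :4] = dFbo + (1 - g) * dIsu
        J[:, 0, 4] = i_su
        J[:, 1, 4] = 0.0
        J[:, 2, 4] = -i_su
        return P, J

    raise ValueError(f"unknown model {model!r}")


def _vector_to_record(model, family, vec, active):
    """Flat optimizer vector -> user-facing parameter record."""
    if model == "basic":
        mu, scale, c = vec
        return BasicParams(LatencyDiffDistribution(family, mu, scale), c)
    if model == "rem":
        mu, scale, c = vec[:3]
        kw = {}
        for j, r in enumerate(active):
            # clip guards against optimizer boundary round-off
            kw[f"eps_{r}"] = float(np.clip(vec[3 + 2 * j], 0.0, 0.8))
            kw[f"kap_{'xy_yx' if r == 'xy' else ('si_xy' if r == 'si' else 'yx_xy')}"] = float(
                np.clip(vec[4 + 2 * j], 0.0, 1.0)
            )
        basic = BasicParams(LatencyDiffDistribution(family, mu, scale), c)
        return REMParams(basic, active=tuple(active), **kw)
    if model == "tsm":
        mu_su, sc_su, mu_o, sc_o, c_su, c_o, g = vec
        return TSMParams(
            LatencyDiffDistribution(family, mu_su, sc_su), c_su,
            LatencyDiffDistribution(family, mu_o, sc_o), c_o,
            float(np.clip(g, 0.0, 1.0)),
        )
    if model == "ttm":
        mu, scale, c_su, delta, g = vec
        return TTMParams(
            LatencyDiffDistribution(family, mu, scale),
            c_su, c_su + max(delta, 0.0), float(np.clip(g, 0.0, 1.0)),
        )
    raise ValueError(f"unknown model {model!r}")


def _param_kinds(model: str, active: tuple[str, ...]) -> list[str]:
    if model == "basic":
        return ["location", "scale", "threshold"]
    if model == "rem":
        kinds = ["location", "scale", "threshold"]
        for _ in active:
            kinds += ["eps", "prob"]
        return kinds
    if model == "tsm":
        return ["location", "scale", "location", "scale",
                "threshold", "threshold", "prob"]
    if model == "ttm":
        return ["location", "scale", "threshold", "delta", "prob"]
    raise ValueError(f"unknown model {model!r}")


def _make_objective(model, family, active, d, O, n_d, floor, mask, O_pos):
    """G²-and-gradient callable; JIT kernel when numba is importable."""
    if _kernels is not None:
        fam_code = 0 if family == "normal" else 1
        if model == "basic":
            return lambda v: _kernels.gsq_basic(v, d, O, n_d, floor, fam_code)
        if model == "rem":
            act = np.array(
                [1 if r in active else 0 for r in ("xy", "si", "yx")], dtype=np.int64
            )
            return lambda v: _kernels.gsq_rem(v, d, O, n_d, floor, fam_code, act)
        if model == "tsm":
            return lambda v: _kernels.gsq_tsm(v, d, O, n_d, floor, fam_code)
        return lambda v: _kernels.gsq_ttm(v, d, O, n_d, floor, fam_code)

    def objective(vec: np.ndarray) -> tuple[float, np.ndarray]:
        probs, jac = _probs_and_grad(model, family, vec, d, active)
        probs = np.clip(probs, 1e-300, 1.0)
        raw = n_d[:, None] * probs
        E = np.maximum(raw, floor)
        val = float(2.0 * np.sum(O_pos * np.log(O_pos / E[mask])))
        # dG²/dθ = -2 Σ (O/E)·n_d·dP, zero where the floor is binding or O = 0
        W = np.where((raw >= floor) & mask, O / E, 0.0) * n_d[:, None]
        grad = -2.0 * np.einsum("dr,drk->k", W, jac)
        return val, grad

    return objective


def fit_model(
    table: ResponseTable,
    model: str,
    family: str = "normal",
    config: FitConfig | None = None,
    active: tuple[str, ...] = ("xy", "si", "yx"),
) -> FitResult:
    """Fit one model to a response table by factorial-multistart minimum G².

    ``active`` only applies to the REM and selects which response-error /
    bias pairs are free (the reduced-REM hierarchy); the full REM is the
    default.  The fit is deterministic: no internal randomness.
    """
    if model not in MODEL_IDS:
        raise ValueError(f"model must be one of {MODEL_IDS}")
    config = config or FitConfig()
    active = tuple(r for r in ("xy", "si", "yx") if r in active)
    kinds = _param_kinds(model, active)
    k = len(kinds)
    n_cells = int(np.count_nonzero(table.totals > 0)) * 3
    if n_cells < k:
        warnings.warn(
            f"table {table.label!r} has {n_cells} cells but {k} free parameters",
            stacklevel=2,
        )

    bounds = [config.bounds[kind] for kind in kinds]
    starts = [config.starts[kind] for kind in kinds]
    d = table.soa_ms
    O = table.counts.astype(float)
    n_d = table.totals.astype(float)
    mask = O > 0
    O_pos = O[mask]
    floor = config.expected_floor

    objective = _make_objective(model, family, active, d, O, n_d, floor, mask, O_pos)

    best_vec = None
    best_val = np.inf
    per_start = np.full(2 ** k, np.inf)
    any_converged = False
    failures = []
    for i, x0 in enumerate(itertools.product(*starts)):
        res = optimize.minimize(
            objective,
            np.asarray(x0, dtype=float),
            method="L-BFGS-B",
            jac=True,
            bounds=bounds,
            options={"ftol": config.ftol, "maxiter": config.maxiter},
        )
        per_start[i] = res.fun
        if res.success:
            any_converged = True
        else:
            failures.append((x0, res.message))
        if res.fun < best_val:
            best_val = float(res.fun)
            best_vec = res.x
    if best_vec is None or not np.isfinite(best_val):
        raise RuntimeError(
            f"optimization failed from every start for {model}/{family}: {failures[:3]}"
        )
    return FitResult(
        model=model,
        family=family,
        params=_vector_to_record(model, family, best_vec, active),
        g_squared=best_val,
        k=k,
        n=table.n_trials,
        n_starts=2 ** k,
        per_start_g2=per_start,
        converged=any_converged,
        label=table.label,
    )


def fit_rem_hierarchy(
    table: ResponseTable,
    family: str = "normal",
    config: FitConfig | None = None,
) -> dict[tuple[str, ...], FitResult]:
    """Fit the eight-member REM hierarchy (zero model up to the full REM).

    Returns a mapping from active-response mask to FitResult: the 3-parameter
    zero model (no error parameters — identical to the basic model), three
    5-parameter, three 7-parameter, and the full 9-parameter REM.
    """
    out: dict[tuple[str, ...], FitResult] = {}
    for mask in REM_MASKS:
        if mask == ():
            fit = fit_model(table, "basic", family, config)
            # re-tag as the REM zero model with the same parameters
            rem_params = REMParams(fit.params, active=())
            fit = FitResult(
                model="rem", family=family, params=rem_params,
                g_squared=fit.g_squared, k=fit.k, n=fit.n,
                n_starts=fit.n_starts, per_start_g2=fit.per_start_g2,
                converged=fit.converged, label=fit.label,
            )
        else:
            fit = fit_model(table, "rem", family, config, active=mask)
        out[mask] = fit
    return out


def rem_min(hierarchy: dict[tuple[str, ...], FitResult]) -> FitResult:
    """The per-table best member of the REM hierarchy by BIC."""
    return min(
        hierarchy.values(),
        key=lambda f: f.g_squared + f.k * np.log(f.n),
    )
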