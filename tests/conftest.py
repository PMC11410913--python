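"""Shared fixtures and the trial-level Monte-Carlo oracle.

The oracle simulates individual trials by drawing arrival-latency differences
and applying each model's state/response mapping directly — fully independent
of the analytic probability formulas it is used to check.
"""

from __future__ import annotations

import numpy as np
import pytest

from tojmodels import (
    BasicParams,
    GeneratorSpec,
    LatencyDiffDistribution,
    REMParams,
    TSMParams,
    TTMParams,
    simulate_response_table,
    study_presets,
)


# ---------------------------------------------------------------------------
# Monte-Carlo oracle: forward-simulate trials, never touching analytic probs
# ---------------------------------------------------------------------------

def _strat_uniform(n: int, rng: np.random.Generator) -> np.ndarray:
    """Randomly permuted stratified uniforms (one per 1/n stratum)."""
    return rng.permutation((np.arange(n) + rng.random(n)) / n)


def _strat_sample(dist: LatencyDiffDistribution, n: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Stratified draw from a latency-difference law by inverse CDF."""
    from scipy import special, stats

    u = _strat_uniform(n, rng)
    if dist.family == "normal":
        return dist.location + dist.scale * special.ndtri(u)
    return stats.laplace.ppf(u, dist.location, dist.scale)


def mc_response_proportions(params, d_grid: np.ndarray, n: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Proportions of (R_xy, R_si, R_yx) from n trial-level simulations per d.

    Trials are simulated by drawing latent latency differences and decision
    uniforms and walking each trial through the model's state/response
    mapping — independent of the analytic probability formulas.  Latin-
    hypercube stratification (stratified marginals, randomly paired) keeps the
    estimator unbiased while pushing its error well below the iid binomial SE;
    common random numbers are shared across d levels (dA = dL + d).
    """
    out = np.empty((d_grid.size, 3))
    if isinstance(params, TSMParams):
        dl_su = _strat_sample(params.dist_su, n, rng)
        dl_o = _strat_sample(params.dist_o, n, rng)
        u = _strat_uniform(n, rng)
        for i, d in enumerate(d_grid):
            da_su = dl_su + d
            da_o = dl_o + d
            si = np.abs(da_su) < params.c_su
            xy_o = da_o >= params.c_o
            yx_o = da_o <= -params.c_o
            unk = ~(xy_o | yx_o)
            xy = ~si & (xy_o | (unk & (u < params.g)))
            yx = ~si & (yx_o | (unk & (u >= params.g)))
            out[i] = [xy.mean(), si.mean(), yx.mean()]
        return out

    if isinstance(params, (BasicParams, REMParams)):
        base = params.basic if isinstance(params, REMParams) else params
        dl = _strat_sample(base.dist, n, rng)
        c = base.c_su
        u_err = _strat_uniform(n, rng)
        u_dir = _strat_uniform(n, rng)
        for i, d in enumerate(d_grid):
            da = dl + d
            state = np.where(da >= c, 0, np.where(da <= -c, 2, 1))
            resp = state.copy()
            if isinstance(params, REMParams):
                eps = np.array([params.eps_xy, params.eps_si, params.eps_yx])
                # misreport directions: state xy -> yx w.p. kap_xy_yx else si,
                # si -> xy w.p. kap_si_xy else yx, yx -> xy w.p. kap_yx_xy else si
                err = u_err < eps[state]
                kap = np.array([params.kap_xy_yx, params.kap_si_xy, params.kap_yx_xy])
                first = u_dir < kap[state]
                to_first = np.array([2, 0, 0])  # target of the kappa direction
                to_second = np.array([1, 2, 1])  # the complementary target
                resp = np.where(err, np.where(first, to_first[state],
                                              to_second[state]), state)
            out[i] = [(resp == 0).mean(), (resp == 1).mean(), (resp == 2).mean()]
        return out

    if isinstance(params, TTMParams):
        dl = _strat_sample(params.dist, n, rng)
        u = _strat_uniform(n, rng)
        for i, d in enumerate(d_grid):
            da = dl + d
            mag = np.abs(da)
            xy_full = da >= params.c_o
            yx_full = da <= -params.c_o
            si = mag < params.c_su
            su = ~si & ~xy_full & ~yx_full
            xy = xy_full | (su & (u < params.g))
            yx = yx_full | (su & (u >= params.g))
            out[i] = [xy.mean(), si.mean(), yx.mean()]
        return out

    raise TypeError(type(params))


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

TTM_TRUTH = TTMParams(LatencyDiffDistribution("normal", -10.0, 40.0), 30.0, 60.0, 0.6)


@pytest.fixture(scope="session")
def allan_design_200():
    return study_presets(200)["allan1975"]


@pytest.fixture(scope="session")
def ttm_truth():
    return TTM_TRUTH


@pytest.fixture(scope="session")
def ttm_table(allan_design_200, ttm_truth):
    return simulate_response_table(
        GeneratorSpec("ttm", ttm_truth, allan_design_200, seed=42)
    )


def _suite_specs():
    """The synthetic-table suite used by the nesting acceptance check."""
    allan = study_presets(150)["allan1975"]
    jask = study_presets(150)["jaskowski"]
    n = LatencyDiffDistribution  # brevity
    return [
        ("ttm", TTMParams(n("normal", -10, 40), 30, 60, 0.6), allan, 101),
        ("ttm", TTMParams(n("laplace", 5, 30), 25, 55, 0.4), jask, 102),
        ("rem", REMParams(BasicParams(n("normal", 0, 35), 45),
                          eps_xy=0.05, eps_si=0.2, eps_yx=0.08,
                          kap_xy_yx=0.8, kap_si_xy=0.5, kap_yx_xy=0.7), allan, 103),
        ("tsm", TSMParams(n("normal", -5, 35), 30, n("normal", -15, 45), 55, 0.7),
         allan, 104),
        ("basic", BasicParams(n("laplace", 8, 30), 40), jask, 105),
    ]


@pytest.fixture(scope="session")
def synthetic_suite():
    """(table, generating family) pairs spanning all four models."""
    out = []
    for model, params, design, seed in _suite_specs():
        table = simulate_response_table(GeneratorSpec(model, params, design, seed))
        family = (params.dist_su.family if isinstance(params, TSMParams)
                  else params.dist.family if not isinstance(params, REMParams)
                  else params.basic.dist.family)
        out.append((table, family))
    return out
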