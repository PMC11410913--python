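import numpy as np
import pytest
from scipy import stats

from tojmodels import (
    BasicParams,
    LatencyDiffDistribution,
    REMParams,
    TSMParams,
    TTMParams,
    basic_response_probs,
    basic_state_probs,
    rem_response_probs,
    response_probs,
    tsm_response_probs,
    tsm_state_probs,
    ttm_response_probs,
    ttm_state_probs,
)

from conftest import mc_response_proportions

N50 = LatencyDiffDistribution("normal", 0, 50)


class TestBasicStates:
    def test_normal_example(self):
        s = basic_state_probs(BasicParams(N50, 50), 0.0)
        assert s["I_xy"] == pytest.approx(0.1587, abs=5e-5)
        assert s["I_si"] == pytest.approx(0.6827, abs=5e-5)
        assert s["I_yx"] == pytest.approx(0.1587, abs=5e-5)

    def test_laplace_example(self):
        s = basic_state_probs(
            BasicParams(LatencyDiffDistribution("laplace", 0, 50), 50), 0.0
        )
        assert s["I_si"] == pytest.approx(1 - np.exp(-1), abs=1e-10)

    def test_order_certain_at_extreme_d(self):
        s = basic_state_probs(BasicParams(N50, 50), 2000.0)
        assert s["I_xy"] == pytest.approx(1.0, abs=1e-12)

    def test_states_partition(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            dist = LatencyDiffDistribution(
                rng.choice(["normal", "laplace"]), rng.uniform(-50, 50),
                rng.uniform(5, 80),
            )
            s = basic_state_probs(BasicParams(dist, rng.uniform(1, 100)),
                                  rng.uniform(-200, 200, 7))
            total = s["I_xy"] + s["I_si"] + s["I_yx"]
            np.testing.assert_allclose(total, 1.0, atol=1e-12)


class TestTTMStates:
    def test_normal_example(self):
        s = ttm_state_probs(TTMParams(N50, 25, 75, 0.5), 0.0)
        assert s["I_xy"] == pytest.approx(0.0668, abs=5e-5)
        assert s["I_si"] == pytest.approx(0.3829, abs=5e-5)
        assert s["I_su"] == pytest.approx(0.4835, abs=5e-5)
        assert s["I_yx"] == pytest.approx(0.0668, abs=5e-5)

    def test_equal_thresholds_reduce_to_basic(self):
        d = np.linspace(-150, 150, 13)
        ttm = ttm_state_probs(TTMParams(N50, 40, 40, 0.5), d)
        basic = basic_state_probs(BasicParams(N50, 40), d)
        np.testing.assert_allclose(ttm["I_su"], 0.0, atol=1e-12)
        for state in ("I_xy", "I_si", "I_yx"):
            np.testing.assert_allclose(ttm[state], basic[state], atol=1e-12)

    def test_four_states_partition(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            c_su = rng.uniform(1, 80)
            p = TTMParams(
                LatencyDiffDistribution(rng.choice(["normal", "laplace"]),
                                        rng.uniform(-50, 50), rng.uniform(5, 80)),
                c_su, c_su + rng.uniform(0, 70), rng.random(),
            )
            s = ttm_state_probs(p, rng.uniform(-200, 200, 7))
            total = s["I_xy"] + s["I_si"] + s["I_su"] + s["I_yx"]
            np.testing.assert_allclose(total, 1.0, atol=1e-12)

    def test_constraint_enforced(self):
        with pytest.raises(ValueError, match="c_o >= c_su"):
            TTMParams(N50, 50, 40, 0.5)


class TestTSMStates:
    PARAMS = TSMParams(N50, 40, LatencyDiffDistribution("normal", 0, 60), 55, 0.5)

    def test_symmetric_order_center_at_zero(self):
        s = tsm_state_probs(self.PARAMS, 0.0)
        assert s["I_xy"] == pytest.approx(s["I_yx"], abs=1e-12)

    def test_joint_is_product(self):
        s = tsm_state_probs(self.PARAMS, 12.0)
        for su in ("I_si", "I_su"):
            for o in ("I_xy", "I_?", "I_yx"):
                assert s[f"{su}&{o}"] == pytest.approx(s[su] * s[o], abs=1e-14)

    def test_marginals_recovered_from_joint(self):
        s = tsm_state_probs(self.PARAMS, -30.0)
        marg_su = sum(s[f"I_su&{o}"] for o in ("I_xy", "I_?", "I_yx"))
        assert marg_su == pytest.approx(s["I_su"], abs=1e-12)


class TestREMResponses:
    def test_no_errors_is_identity(self):
        basic = BasicParams(N50, 40)
        rem = REMParams(basic)
        d = np.linspace(-100, 100, 9)
        np.testing.assert_allclose(
            rem_response_probs(rem, d), basic_response_probs(basic, d), atol=1e-14
        )

    def test_hand_computed_mixing(self):
        """States engineered to (0.2, 0.5, 0.3); eps_si=0.2, kap_si_xy=0.5
        then moves 0.05 of I_si mass to each order response."""
        # solve F(c) = 0.8, F(-c) = 0.3 for a normal(mu, 50) at d = 0
        sigma = 50.0
        z80, z30 = stats.norm.ppf(0.8), stats.norm.ppf(0.3)
        c = sigma * (z80 - z30) / 2
        mu = -(z80 + z30) / 2 * sigma
        basic = BasicParams(LatencyDiffDistribution("normal", mu, sigma), c)
        s = basic_state_probs(basic, 0.0)
        assert s["I_xy"] == pytest.approx(0.2, abs=1e-12)
        rem = REMParams(basic, eps_si=0.2, kap_si_xy=0.5, active=("si",))
        p = rem_response_probs(rem, 0.0)
        np.testing.assert_allclose(p, [0.25, 0.40, 0.35], atol=1e-12)

    def test_row_stochastic(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            rem = REMParams(
                BasicParams(LatencyDiffDistribution("laplace", rng.uniform(-40, 40),
                                                    rng.uniform(5, 60)),
                            rng.uniform(1, 90)),
                eps_xy=rng.uniform(0, 0.8), eps_si=rng.uniform(0, 0.8),
                eps_yx=rng.uniform(0, 0.8), kap_xy_yx=rng.random(),
                kap_si_xy=rng.random(), kap_yx_xy=rng.random(),
            )
            p = rem_response_probs(rem, rng.uniform(-150, 150, 5))
            np.testing.assert_allclose(p.sum(axis=-1), 1.0, atol=1e-12)

    def test_inactive_eps_must_be_zero(self):
        basic = BasicParams(N50, 40)
        with pytest.raises(ValueError, match="inactive"):
            REMParams(basic, eps_xy=0.1, active=("si",))

    def test_free_parameter_counts(self):
        basic = BasicParams(N50, 40)
        assert REMParams(basic, active=()).n_free == 3
        assert REMParams(basic, active=("si",)).n_free == 5
        assert REMParams(basic, active=("xy", "si", "yx")).n_free == 9


class TestTSMResponses:
    def test_hand_computed(self):
        """P(I_su)=0.5 with order states (0.3, 0.4, 0.3) and g=0.5 gives
        p_xy = 0.5·(0.3 + 0.5·0.4) = 0.25."""
        # successiveness center: make P(I_si) = 0.5 at d = 0
        c_su = 50 * stats.norm.ppf(0.75)
        # order center: make P(I_xy) = P(I_yx) = 0.3 at d = 0
        c_o = 60 * stats.norm.ppf(0.7)
        params = TSMParams(N50, c_su, LatencyDiffDistribution("normal", 0, 60),
                           c_o, 0.5)
        p = tsm_response_probs(params, 0.0)
        np.testing.assert_allclose(p, [0.25, 0.5, 0.25], atol=1e-12)

    def test_g_boundary_sends_all_unresolved_mass_to_xy(self):
        params = TSMParams(N50, 40, LatencyDiffDistribution("normal", 0, 60), 55, 1.0)
        s = tsm_state_probs(params, 10.0)
        p = tsm_response_probs(params, 10.0)
        assert p[0] == pytest.approx(s["I_su"] * (s["I_xy"] + s["I_?"]), abs=1e-12)

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            fam = rng.choice(["normal", "laplace"])
            params = TSMParams(
                LatencyDiffDistribution(fam, rng.uniform(-40, 40), rng.uniform(5, 60)),
                rng.uniform(1, 90),
                LatencyDiffDistribution(fam, rng.uniform(-40, 40), rng.uniform(5, 60)),
                rng.uniform(1, 90), rng.random(),
            )
            p = tsm_response_probs(params, rng.uniform(-150, 150, 5))
            np.testing.assert_allclose(p.sum(axis=-1), 1.0, atol=1e-12)


class TestTTMResponses:
    def test_hand_computed(self):
        p = ttm_response_probs(TTMParams(N50, 25, 75, 0.6), 0.0)
        assert p[0] == pytest.approx(0.0668 + 0.6 * 0.4835, abs=1e-4)

    def test_symmetric_guessing(self):
        p = ttm_response_probs(TTMParams(N50, 25, 75, 0.5), 0.0)
        assert p[0] == pytest.approx(p[2], abs=1e-12)

    def test_equal_thresholds_match_basic_for_any_g(self):
        d = np.linspace(-120, 120, 11)
        basic = basic_response_probs(BasicParams(N50, 35), d)
        for g in (0.0, 0.3, 1.0):
            ttm = ttm_response_probs(TTMParams(N50, 35, 35, g), d)
            np.testing.assert_allclose(ttm, basic, atol=1e-12)


class TestShapeProperties:
    def test_p_si_unimodal_with_peak_near_minus_mu(self):
        """The simultaneity curve of basic and TTM peaks where the arrival
        difference is centered, d = -mu."""
        for mu in (-30.0, 0.0, 20.0):
            dist = LatencyDiffDistribution("normal", mu, 40)
            for probs in (
                basic_response_probs(BasicParams(dist, 30), np.linspace(-200, 200, 801)),
                ttm_response_probs(TTMParams(dist, 30, 70, 0.7),
                                   np.linspace(-200, 200, 801)),
            ):
                d = np.linspace(-200, 200, 801)
                p_si = probs[:, 1]
                peak = d[np.argmax(p_si)]
                assert peak == pytest.approx(-mu, abs=1.0)
                rising, falling = d < peak, d > peak
                assert np.all(np.diff(p_si[rising]) >= -1e-12)
                assert np.all(np.diff(p_si[falling]) <= 1e-12)

    def test_ttm_nonmonotonic_only_inside_uncertainty_bands(self):
        """Any local decrease of P(R_xy|d) in d happens where P(I_su) > 0."""
        params = TTMParams(LatencyDiffDistribution("normal", -10, 30), 25, 80, 0.9)
        d = np.linspace(-250, 250, 2001)
        p = ttm_response_probs(params, d)
        su = ttm_state_probs(params, d)["I_su"]
        decreasing = np.diff(p[:, 0]) < -1e-12
        assert decreasing.any()  # this parameterization does produce a dip
        assert np.all(su[:-1][decreasing] > 1e-6)


class TestMonteCarloAgreement:
    """Light per-model check against the trial-level oracle (the full
    4 x 2 x 20-draw sweep runs in the acceptance suite)."""

    @pytest.mark.parametrize("family", ["normal", "laplace"])
    def test_all_models_match_oracle(self, family):
        rng = np.random.default_rng(21)
        dist = LatencyDiffDistribution(family, -10, 40)
        d = np.array([-100.0, -50.0, 0.0, 50.0, 100.0])
        n = 200_000
        cases = [
            BasicParams(dist, 40),
            REMParams(BasicParams(dist, 40), eps_xy=0.1, eps_si=0.2, eps_yx=0.05,
                      kap_xy_yx=0.7, kap_si_xy=0.4, kap_yx_xy=0.6),
            TSMParams(dist, 30, LatencyDiffDistribution(family, 5, 55), 60, 0.65),
            TTMParams(dist, 30, 60, 0.6),
        ]
        for params in cases:
            analytic = response_probs(params, d)
            mc = mc_response_proportions(params, d, n, rng)
            se = np.sqrt(analytic * (1 - analytic) / n)
            assert np.all(np.abs(mc - analytic) < 4 * se + 1e-4), type(params)
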