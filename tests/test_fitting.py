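import numpy as np
import pytest
from scipy.optimize import approx_fprime

from tojmodels import (
    FitConfig,
    GeneratorSpec,
    LatencyDiffDistribution,
    ResponseTable,
    TTMParams,
    expected_counts,
    fit_model,
    fit_rem_hierarchy,
    g_squared,
    simulate_response_table,
    study_presets,
)
from tojmodels.fitting import REM_MASKS, _probs_and_grad, _probs_vector, rem_min
from tojmodels.models import response_probs


class TestExpectedCounts:
    def setup_method(self):
        dist = LatencyDiffDistribution("normal", 0, 40)
        self.params = TTMParams(dist, 30, 60, 0.5)

    def test_scaling(self, ttm_table):
        raw, floored = expected_counts(self.params, ttm_table)
        probs = response_probs(self.params, ttm_table.soa_ms)
        np.testing.assert_allclose(raw, ttm_table.totals[:, None] * probs)

    def test_floor_binds_small_cells(self):
        table = ResponseTable(
            "tiny", np.array([-500.0, 500.0]), np.array([[0, 0, 100], [100, 0, 0]])
        )
        raw, floored = expected_counts(self.params, table, floor=0.1)
        assert raw.min() < 0.1
        assert floored.min() == pytest.approx(0.1)
        np.testing.assert_array_equal(floored[raw >= 0.1], raw[raw >= 0.1])

    def test_vanishing_floor_returns_raw(self, ttm_table):
        raw, floored = expected_counts(self.params, ttm_table, floor=1e-300)
        np.testing.assert_array_equal(raw, floored)


class TestGSquared:
    def test_zero_when_observed_equals_expected(self):
        O = np.array([[10.0, 20.0, 5.0]])
        assert g_squared(O, O) == 0.0

    def test_hand_value_20_ln_2(self):
        assert g_squared(np.array([10.0, 0.0]), np.array([5.0, 5.0])) == pytest.approx(
            20 * np.log(2), abs=1e-12
        )

    def test_homogeneous_of_degree_one(self):
        rng = np.random.default_rng(8)
        O = rng.integers(0, 50, (4, 3)).astype(float)
        E = rng.uniform(0.5, 50, (4, 3))
        assert g_squared(2 * O, 2 * E) == pytest.approx(2 * g_squared(O, E), rel=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="negative"):
            g_squared(np.array([-1.0]), np.array([1.0]))
        with pytest.raises(ValueError, match="positive"):
            g_squared(np.array([1.0]), np.array([0.0]))
        with pytest.raises(ValueError, match="shape"):
            g_squared(np.array([1.0, 2.0]), np.array([1.0]))


class TestObjectiveRoutes:
    """The numba kernels, the numpy gradient, and finite differences must all
    agree — they are independent routes to the same objective."""

    VECS = {
        "basic": np.array([5.0, 40.0, 35.0]),
        "rem": np.array([5.0, 40.0, 35.0, 0.1, 0.6, 0.2, 0.4, 0.05, 0.7]),
        "tsm": np.array([5.0, 40.0, -8.0, 55.0, 30.0, 60.0, 0.6]),
        "ttm": np.array([5.0, 40.0, 30.0, 25.0, 0.6]),
    }

    @pytest.mark.parametrize("model", ["basic", "rem", "tsm", "ttm"])
    @pytest.mark.parametrize("family", ["normal", "laplace"])
    def test_numpy_gradient_matches_finite_differences(self, model, family):
        d = np.array([-100.0, -50.0, -10.0, 0.0, 30.0, 80.0])
        vec = self.VECS[model]
        act = ("xy", "si", "yx")
        P, J = _probs_and_grad(model, family, vec, d, act)
        np.testing.assert_allclose(P, _probs_vector(model, family, vec, d, act),
                                   atol=1e-12)
        for r in range(3):
            for i in range(d.size):
                fd = approx_fprime(
                    vec, lambda v: _probs_vector(model, family, v, d, act)[i, r], 1e-7
                )
                np.testing.assert_allclose(J[i, r], fd, atol=2e-5)

    @pytest.mark.parametrize("model", ["basic", "rem", "tsm", "ttm"])
    @pytest.mark.parametrize("family_code,family", [(0, "normal"), (1, "laplace")])
    def test_kernel_matches_numpy_objective(self, model, family_code, family, ttm_table):
        from tojmodels import _kernels

        d = ttm_table.soa_ms
        O = ttm_table.counts.astype(float)
        n_d = ttm_table.totals.astype(float)
        vec = self.VECS[model]
        act = ("xy", "si", "yx")
        kern = {
            "basic": lambda v: _kernels.gsq_basic(v, d, O, n_d, 0.1, family_code),
            "rem": lambda v: _kernels.gsq_rem(v, d, O, n_d, 0.1, family_code,
                                              np.ones(3, dtype=np.int64)),
            "tsm": lambda v: _kernels.gsq_tsm(v, d, O, n_d, 0.1, family_code),
            "ttm": lambda v: _kernels.gsq_ttm(v, d, O, n_d, 0.1, family_code),
        }[model]
        P, J = _probs_and_grad(model, family, vec, d, act)
        raw = n_d[:, None] * np.clip(P, 1e-300, 1.0)
        E = np.maximum(raw, 0.1)
        mask = O > 0
        val_np = 2.0 * np.sum(O[mask] * np.log(O[mask] / E[mask]))
        W = np.where((raw >= 0.1) & mask, O / E, 0.0) * n_d[:, None]
        grad_np = -2.0 * np.einsum("dr,drk->k", W, J)
        val_k, grad_k = kern(vec)
        assert val_k == pytest.approx(val_np, rel=1e-12)
        np.testing.assert_allclose(grad_k, grad_np, rtol=1e-10, atol=1e-12)

    def test_reduced_rem_kernel_layout(self, ttm_table):
        """Reduced-REM vec layout (active si only) agrees across routes."""
        from tojmodels import _kernels

        d = ttm_table.soa_ms
        O = ttm_table.counts.astype(float)
        n_d = ttm_table.totals.astype(float)
        vec = np.array([5.0, 40.0, 35.0, 0.2, 0.4])
        P, J = _probs_and_grad("rem", "normal", vec, d, ("si",))
        raw = n_d[:, None] * P
        E = np.maximum(raw, 0.1)
        mask = O > 0
        val_np = 2.0 * np.sum(O[mask] * np.log(O[mask] / E[mask]))
        act = np.array([0, 1, 0], dtype=np.int64)
        val_k, grad_k = _kernels.gsq_rem(vec, d, O, n_d, 0.1, 0, act)
        assert val_k == pytest.approx(val_np, rel=1e-12)
        W = np.where((raw >= 0.1) & mask, O / E, 0.0) * n_d[:, None]
        np.testing.assert_allclose(grad_k, -2.0 * np.einsum("dr,drk->k", W, J),
                                   rtol=1e-10, atol=1e-12)


class TestFitModel:
    def test_multistart_counts(self, ttm_table):
        cfg = FitConfig(maxiter=50)  # counts don't depend on convergence depth
        assert fit_model(ttm_table, "ttm", "normal", cfg).n_starts == 32
        assert fit_model(ttm_table, "tsm", "normal", cfg).n_starts == 128
        assert fit_model(ttm_table, "basic", "normal", cfg).n_starts == 8

    def test_self_consistency_on_noise_free_counts(self):
        """Observed counts set to the TTM's (rounded) expected counts at large n
        are fitted back essentially perfectly."""
        truth = TTMParams(LatencyDiffDistribution("normal", -10, 40), 30, 60, 0.6)
        design = study_presets(1)["allan1975"]
        probs = response_probs(truth, design.soa_ms)
        n_per = 1_000_000
        counts = np.rint(n_per * probs).astype(np.int64)
        table = ResponseTable("exact", design.soa_ms, counts)
        fit = fit_model(table, "ttm", "normal")
        # integer rounding leaves a G² residue of order (0.5)^2/E ~ 1e-5
        assert fit.g_squared <= 1e-3
        p = fit.params
        assert p.dist.location == pytest.approx(-10, abs=0.1)
        assert p.dist.scale == pytest.approx(40, abs=0.1)
        assert p.c_su == pytest.approx(30, abs=0.1)
        assert p.c_o == pytest.approx(60, abs=0.1)
        assert p.g == pytest.approx(0.6, abs=1e-3)

    def test_deterministic(self, ttm_table):
        f1 = fit_model(ttm_table, "ttm", "normal")
        f2 = fit_model(ttm_table, "ttm", "normal")
        assert f1.g_squared == f2.g_squared
        assert f1.params.to_dict() == f2.params.to_dict()

    def test_row_order_of_input_file_is_irrelevant(self, tmp_path, ttm_table):
        from tojmodels import read_response_table, write_response_table

        path = tmp_path / "shuffled.tsv"
        write_response_table(ttm_table, path)
        lines = path.read_text().strip().split("\n")
        shuffled = [lines[0]] + lines[1:][::-1]
        path.write_text("\n".join(shuffled) + "\n")
        refit = fit_model(read_response_table(path), "ttm", "normal")
        direct = fit_model(ttm_table, "ttm", "normal")
        assert refit.g_squared == pytest.approx(direct.g_squared, abs=1e-9)

    def test_ttm_constraint_respected(self, ttm_table):
        fit = fit_model(ttm_table, "ttm", "laplace")
        assert fit.params.c_o >= fit.params.c_su

    def test_warns_when_underdetermined(self):
        table = ResponseTable("small", np.array([-20.0, 20.0]),
                              np.array([[5, 3, 1], [1, 3, 5]]))
        with pytest.warns(UserWarning, match="free parameters"):
            fit_model(table, "rem", "normal", FitConfig(maxiter=20))

    def test_result_serializable(self, ttm_table):
        import json

        fit = fit_model(ttm_table, "basic", "normal")
        blob = json.dumps(fit.to_dict())
        assert json.loads(blob)["k"] == 3


@pytest.fixture(scope="module")
def hierarchy(ttm_table):
    return fit_rem_hierarchy(ttm_table, "normal")


class TestREMHierarchy:
    def test_eight_members_with_expected_parameter_counts(self, hierarchy):
        assert len(hierarchy) == 8
        assert sorted(f.k for f in hierarchy.values()) == [3, 5, 5, 5, 7, 7, 7, 9]
        assert set(hierarchy) == set(REM_MASKS)

    def test_zero_model_equals_basic_fit(self, hierarchy, ttm_table):
        basic = fit_model(ttm_table, "basic", "normal")
        assert hierarchy[()].g_squared == pytest.approx(basic.g_squared, abs=1e-9)
        assert hierarchy[()].k == 3

    def test_full_rem_never_fits_worse(self, hierarchy):
        full = hierarchy[("xy", "si", "yx")].g_squared
        for mask, fit in hierarchy.items():
            assert full <= fit.g_squared + 1e-3, mask

    def test_rem_min_selects_lowest_bic(self, hierarchy):
        best = rem_min(hierarchy)
        bics = [f.g_squared + f.k * np.log(f.n) for f in hierarchy.values()]
        assert best.g_squared + best.k * np.log(best.n) == pytest.approx(min(bics))


class TestRecoveryPrecision:
    def test_mu_bias_shrinks_with_trials(self, ttm_truth):
        """Median |mu_hat - mu| over seeded fits falls as trials per d rise."""
        errors = {}
        for n_per in (200, 2000):
            design = study_presets(n_per)["allan1975"]
            errs = []
            for seed in range(6):
                table = simulate_response_table(
                    GeneratorSpec("ttm", ttm_truth, design, seed=1000 + seed)
                )
                fit = fit_model(table, "ttm", "normal")
                errs.append(abs(fit.params.dist.location - ttm_truth.dist.location))
            errors[n_per] = float(np.median(errs))
        assert errors[2000] < errors[200]
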