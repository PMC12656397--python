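"""Uncertainty equations, factorization correctness, diagnostics, stability."""

import numpy as np
import pytest

from pmfrisk import (
    align_factors,
    bootstrap_stability,
    build_uncertainty,
    compute_uncertainty,
    contribution_shares,
    diagnostics,
    fit_pmf,
    surveylike_dataset,
    profile_percentages,
    q_theoretical,
    scan_factors,
)
from pmfrisk.pmf import PMFModel


def exact_rank2():
    g = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
    f = np.array([[10.0, 0.0, 5.0], [0.0, 10.0, 5.0]])
    x = g @ f
    return x, np.ones_like(x)


class TestUncertainty:
    def test_above_mdl_equation(self):
        u, working, sub = compute_uncertainty(100.0, 5.0, 0.1)
        assert u == pytest.approx(np.sqrt(100 + 6.25), abs=1e-10)  # 10.3078
        assert working == 100.0
        assert not sub

    def test_below_mdl_substitution(self):
        u, working, sub = compute_uncertainty(2.0, 5.0, 0.1)
        assert u == pytest.approx(5.0 * 5 / 6, abs=1e-12)  # 4.1667
        assert working == 2.5
        assert sub

    def test_equality_goes_to_below_mdl_branch(self):
        u, working, sub = compute_uncertainty(5.0, 5.0, 0.1)
        assert u == pytest.approx(5.0 * 5 / 6)
        assert working == 2.5
        assert sub

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            compute_uncertainty(1.0, 0.0, 0.1)
        with pytest.raises(ValueError):
            compute_uncertainty(1.0, 1.0, 1.5)

    def test_matrix_construction(self, small_table, registry):
        um = build_uncertainty(small_table, registry, 0.1)
        assert (um.u > 0).all()
        # the below-MDL Cr cell gets (5/6)*MDL exactly and MDL/2 working value
        assert um.substituted[1, 1]
        assert um.u[1, 1] == pytest.approx(5.0 * 5 / 6)
        assert um.working_conc[1, 1] == 2.5


class TestQTheoretical:
    def test_formula(self):
        assert q_theoretical(100, 8, 4) == 368

    def test_zero_factors(self):
        assert q_theoretical(10, 8, 0) == 80

    def test_too_many_factors_errors(self):
        with pytest.raises(ValueError, match="smaller p"):
            q_theoretical(10, 8, 5)


class TestFit:
    def test_exact_rank2_factorization(self):
        x, u = exact_rank2()
        model = fit_pmf(x, u, 2, n_starts=20, seed=0)
        assert model.q_true <= 1e-6
        rel = np.linalg.norm(x - model.g @ model.f) / np.linalg.norm(x)
        assert rel <= 1e-4

    def test_exact_rank1_factorization(self):
        x = np.outer([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        model = fit_pmf(x, np.ones_like(x), 1, n_starts=20, seed=0)
        assert model.q_true <= 1e-6
        np.testing.assert_allclose(model.g @ model.f, x, rtol=1e-4)

    def test_nonnegativity_and_residual_identity(self):
        table, _ = surveylike_dataset(n=60, seed=2)
        x = table.conc.to_numpy()
        u = np.maximum(0.1 * x, 1e-3)
        model = fit_pmf(x, u, 3, n_starts=3, seed=1, max_iter=800)
        assert (model.g >= 0).all() and (model.f >= 0).all()
        np.testing.assert_allclose(
            model.scaled_residuals, (x - model.g @ model.f) / u, rtol=1e-12
        )
        assert model.q_true == pytest.approx(np.sum(model.scaled_residuals**2))

    def test_objective_never_increases(self):
        table, _ = surveylike_dataset(n=60, seed=2)
        x = table.conc.to_numpy()
        u = np.maximum(0.1 * x, 1e-3)
        model = fit_pmf(x, u, 3, n_starts=2, seed=0, max_iter=500)
        dq = np.diff(model.q_history)
        assert (dq <= 1e-9 * np.maximum(model.q_history[:-1], 1.0)).all()

    def test_best_start_is_kept(self):
        x, u = exact_rank2()
        best = fit_pmf(x, u, 2, n_starts=10, seed=3)
        singles = [fit_pmf(x, u, 2, n_starts=1, seed=3)]
        assert best.q_true <= min(s.q_true for s in singles) + 1e-9

    def test_invalid_p_rejected(self):
        x, u = exact_rank2()
        with pytest.raises(ValueError):
            fit_pmf(x, u, 4, n_starts=1, seed=0)

    def test_nonfinite_inputs_rejected(self):
        x, u = exact_rank2()
        x = x.copy()
        x[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit_pmf(x, u, 2, n_starts=1, seed=0)

    def test_matches_unweighted_nmf_oracle_on_exact_data(self):
        sklearn = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(11)
        g = rng.lognormal(0, 1, (40, 3))
        f = rng.uniform(0.5, 2.0, (3, 6))
        x = g @ f
        model = fit_pmf(x, np.ones_like(x), 3, n_starts=5, seed=0, max_iter=2000)
        oracle = sklearn.NMF(
            n_components=3, init="nndsvda", max_iter=5000, tol=1e-12
        ).fit(x)
        oracle_err = np.linalg.norm(x - oracle.transform(x) @ oracle.components_)
        ours = np.linalg.norm(x - model.g @ model.f)
        assert ours / np.linalg.norm(x) <= 1e-4
        assert ours <= oracle_err + 1e-6 * np.linalg.norm(x)


class TestScan:
    def test_noise_free_rank3_elbow(self):
        rng = np.random.default_rng(3)
        g = rng.lognormal(0, 1, (60, 3))
        f = rng.uniform(0.5, 2.0, (3, 6))
        x = g @ f
        u = np.full_like(x, 0.1)
        scan = scan_factors(x, u, range(2, 7), n_starts=4, seed=1, max_iter=1500)
        q = scan.report["q_true"]
        assert q[2] / max(q[3], 1e-12) > 1e3  # orders-of-magnitude drop to p=3
        assert q[3] < 1e-3
        assert scan.suggested_p == 3
        assert len(scan.report) == 5
        assert scan.report["resid_frac_within_3"].between(0, 1).all()


class TestDiagnostics:
    def test_exact_fit_fraction_is_one(self):
        x, u = exact_rank2()
        model = fit_pmf(x, u, 2, n_starts=5, seed=0)
        d = diagnostics(model)
        assert d["overall_fraction_within_3"] == 1.0

    def test_worst_cell_ordering(self):
        x, u = exact_rank2()
        model = fit_pmf(x, u, 2, n_starts=5, seed=0)
        model.scaled_residuals = model.scaled_residuals.copy()
        model.scaled_residuals[0, 1] = 5.0
        d = diagnostics(model, elements=["a", "b", "c"])
        assert d["worst_cells"][0]["element"] == "b"
        assert d["worst_cells"][0]["scaled_residual"] == 5.0


class TestShares:
    def test_single_factor_shares_are_100(self):
        x = np.outer([1.0, 2.0], [3.0, 4.0])
        model = fit_pmf(x, np.ones_like(x), 1, n_starts=2, seed=0)
        np.testing.assert_allclose(profile_percentages(model), 100.0)
        np.testing.assert_allclose(contribution_shares(model), 100.0)

    def test_profile_percentages_arithmetic(self):
        model = PMFModel(
            g=np.ones((2, 2)), f=np.array([[4.0, 1.0], [6.0, 1.0]]),
            q_true=0, q_robust=0, q_theoretical=0,
            scaled_residuals=np.zeros((2, 2)), converged=True, n_starts=1, seed=0,
        )
        np.testing.assert_allclose(
            profile_percentages(model)[:, 0], [40.0, 60.0]
        )

    def test_symmetric_factors_split_evenly(self):
        f = np.array([[1.0, 2.0], [1.0, 2.0]])
        model = PMFModel(
            g=np.ones((4, 2)), f=f, q_true=0, q_robust=0, q_theoretical=0,
            scaled_residuals=np.zeros((4, 2)), converged=True, n_starts=1, seed=0,
        )
        np.testing.assert_allclose(contribution_shares(model), [50.0, 50.0])


class TestAlign:
    def test_permutation_recovered(self):
        f_true = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        perm = [2, 0, 1]
        f_est = f_true[perm]
        p, cos = align_factors(f_est, f_true)
        np.testing.assert_allclose(cos, 1.0)
        np.testing.assert_array_equal(
            f_est[p], f_true
        )

    def test_scale_invariance(self):
        f_true = np.array([[1.0, 2.0], [3.0, 1.0]])
        _, cos = align_factors(3.0 * f_true, f_true)
        np.testing.assert_allclose(cos, 1.0)

    def test_orthogonal_profiles_have_zero_cosine(self):
        f_true = np.eye(4)[:2]  # spans e1, e2
        f_est = np.eye(4)[2:]   # spans e3, e4 — orthogonal to truth
        _, cos = align_factors(f_est, f_true)
        np.testing.assert_allclose(cos, 0.0, atol=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            align_factors(np.ones((2, 3)), np.ones((3, 3)))


class TestBootstrap:
    def test_exact_data_fully_stable(self):
        rng = np.random.default_rng(7)
        g = rng.lognormal(0, 1, (40, 2))
        f = np.array([[10.0, 1.0, 0.1], [0.1, 1.0, 10.0]])
        x = g @ f
        u = np.full_like(x, 0.1)
        model = fit_pmf(x, u, 2, n_starts=4, seed=0, max_iter=1500)
        rates = bootstrap_stability(x, u, model, n_boot=20, seed=0)
        np.testing.assert_allclose(rates, 1.0)
        assert ((rates >= 0) & (rates <= 1)).all()

    def test_reproducible_under_seed(self):
        x, u = exact_rank2()
        x = np.tile(x, (4, 1))
        u = np.tile(u, (4, 1))
        model = fit_pmf(x, u, 2, n_starts=3, seed=0)
        a = bootstrap_stability(x, u, model, n_boot=5, seed=9)
        b = bootstrap_stability(x, u, model, n_boot=5, seed=9)
        np.testing.assert_array_equal(a, b)
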