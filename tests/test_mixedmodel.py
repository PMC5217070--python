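"""BLUP solutions, explicit/implicit equivalence, REML, and u <-> a conversions."""

import math

import numpy as np
import pandas as pd
import pytest

from gengroups import (
    ModelError,
    Pedigree,
    PedigreeRecord,
    VarianceComponents,
    a_inverse,
    a_star,
    additive_relationship,
    assign_groups,
    breeding_values_from_total,
    build_model,
    fit_animal_model,
    q_matrix,
    reml_estimate,
    solve_blup,
    total_additive_effects,
    validate_and_order,
)
from gengroups.simulate import SimParams, simulate_population


def small_study(seed=3, n_gen=4, cohort=40, imm=8):
    sim = simulate_population(
        SimParams(n_generations=n_gen, cohort_size=cohort,
                  immigrants_per_generation=imm, seed=seed)
    )
    ped = sim.masked_pedigree
    gped = assign_groups(ped, "by_flag")
    data = build_model(ped, sim.phenotype_table(), trait="y")
    return sim, ped, gped, data


class TestBuildModel:
    def test_intercept_only(self):
        ped = validate_and_order(
            Pedigree([PedigreeRecord(c) for c in "ABC"])
        )
        phen = pd.DataFrame({"id": list("ABC"), "y": [1.0, 2.0, 3.0]})
        data = build_model(ped, phen)
        assert data.X.shape == (3, 1)
        assert np.all(data.X == 1.0)
        assert data.Z.shape == (3, 3)

    def test_unknown_id_error(self):
        ped = validate_and_order(Pedigree([PedigreeRecord("A")]))
        phen = pd.DataFrame({"id": ["Z"], "y": [1.0]})
        with pytest.raises(ModelError, match="'Z'"):
            build_model(ped, phen)

    def test_categorical_covariate(self):
        ped = validate_and_order(Pedigree([PedigreeRecord(c) for c in "ABCD"]))
        phen = pd.DataFrame(
            {"id": list("ABCD"), "y": [1.0, 2, 3, 4], "sex": ["F", "M", "F", "M"]}
        )
        data = build_model(ped, phen, fixed=["sex"])
        assert data.X.shape == (4, 2)  # intercept + one contrast

    def test_missing_phenotypes_dropped(self):
        ped = validate_and_order(Pedigree([PedigreeRecord(c) for c in "ABC"]))
        phen = pd.DataFrame({"id": list("ABC"), "y": [1.0, np.nan, 3.0]})
        data = build_model(ped, phen)
        assert data.n_records == 2
        assert data.Z.shape == (2, 3)  # unphenotyped C stays in the pedigree

    def test_simulation_bookkeeping(self):
        sim, ped, gped, data = small_study()
        assert data.n_records == sim.params.n_total
        assert data.Z.shape == (sim.params.n_total, sim.params.n_total)


class TestSolveBlup:
    def test_dense_normal_equations_oracle(self):
        """Basic mode equals the dense Henderson system on a hand fixture."""
        ped = validate_and_order(
            Pedigree(
                [
                    PedigreeRecord("A"),
                    PedigreeRecord("B"),
                    PedigreeRecord("C", "A", "B"),
                    PedigreeRecord("D", "A", "B"),
                    PedigreeRecord("E", "C", "D"),
                ]
            )
        )
        y = np.array([1.2, -0.3, 0.8, 0.1, 1.5])
        phen = pd.DataFrame({"id": ped.ids, "y": y})
        data = build_model(ped, phen)
        vc = VarianceComponents.from_values(0.8, 1.6)
        fit = solve_blup(data, a_inverse(ped), vc, mode="basic")
        lam = vc.lam
        X = data.X
        Z = data.Z.toarray()
        Ai = a_inverse(ped).toarray()
        C = np.block([[X.T @ X, X.T @ Z], [Z.T @ X, Z.T @ Z + lam * Ai]])
        sol = np.linalg.solve(C, np.concatenate([X.T @ y, Z.T @ y]))
        assert abs(sol[0] - fit.beta_hat[0]) < 1e-10
        np.testing.assert_allclose(fit.a_hat, sol[1:], atol=1e-10)

    def test_dense_gls_oracle(self):
        """BLUP equals generalized least squares with V = ZAZ'σ²A + Iσ²E."""
        sim, ped, gped, data = small_study(seed=9, n_gen=3, cohort=16, imm=3)
        vc = VarianceComponents.from_values(1.0, 1.0)
        Q = q_matrix(gped)
        fit = solve_blup(data, a_inverse(ped), vc, mode="explicit", Q=Q)
        A = additive_relationship(ped)
        Z = data.Z.toarray()
        X = np.column_stack([data.X, Z @ Q[:, 1:]])
        V = Z @ A @ Z.T * vc.sigma2_A + np.eye(data.n_records) * vc.sigma2_E
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ data.y)
        ahat = vc.sigma2_A * A @ Z.T @ Vi @ (data.y - X @ beta)
        np.testing.assert_allclose(fit.a_hat, ahat, atol=1e-8)
        np.testing.assert_allclose(
            np.r_[fit.beta_hat, fit.g_hat[1:]], beta, atol=1e-8
        )

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_explicit_implicit_equivalence(self, seed):
        sim, ped, gped, data = small_study(seed=seed, n_gen=5, cohort=60, imm=10)
        vc = VarianceComponents.from_values(1.0, 1.0)
        Q = q_matrix(gped)
        fe = solve_blup(data, a_inverse(ped), vc, mode="explicit", Q=Q)
        fi = solve_blup(data, a_star(gped), vc, mode="implicit", Q=Q)
        np.testing.assert_allclose(fe.g_hat, fi.g_hat, atol=1e-6)
        np.testing.assert_allclose(fe.beta_hat, fi.beta_hat, atol=1e-6)
        np.testing.assert_allclose(fe.a_hat, fi.a_hat, atol=1e-6)
        np.testing.assert_allclose(fe.u_hat, fi.u_hat, atol=1e-6)

    def test_single_group_implicit_equals_basic(self):
        """With r = 1 the A*-based model is the basic animal model (g ≡ 0)."""
        sim, ped, gped1, data = small_study(seed=4)
        gped = assign_groups(ped, "single_group")
        vc = VarianceComponents.from_values(1.0, 1.0)
        fb = solve_blup(data, a_inverse(ped), vc, mode="basic")
        fi = solve_blup(
            data, a_star(gped), vc, mode="implicit", Q=q_matrix(gped)
        )
        np.testing.assert_allclose(fi.u_hat, fb.a_hat, atol=1e-8)
        np.testing.assert_allclose(fi.g_hat, [0.0], atol=0)

    def test_infinite_lambda_shrinks_to_zero(self):
        sim, ped, gped, data = small_study(seed=6)
        vc = VarianceComponents.from_values(0.0, 1.0)
        fit = solve_blup(data, a_inverse(ped), vc, mode="basic")
        np.testing.assert_array_equal(fit.a_hat, 0.0)
        assert fit.beta_hat[0] == pytest.approx(data.y.mean(), abs=1e-10)

    def test_group_confounding_raises(self):
        """A second copy of the Q column in X makes the equations singular."""
        sim, ped, gped, data = small_study(seed=2)
        Q = q_matrix(gped)
        data.X = np.column_stack([data.X, (data.Z @ Q)[:, 1]])
        vc = VarianceComponents.from_values(1.0, 1.0)
        with pytest.raises(ModelError):
            solve_blup(data, a_inverse(ped), vc, mode="explicit", Q=Q)


class TestREML:
    def test_matches_dense_likelihood_oracle(self):
        sim, ped, gped, data = small_study(seed=3, n_gen=4, cohort=30, imm=6)
        Q = q_matrix(gped)
        vcr = reml_estimate(data, a_inverse(ped), mode="explicit", Q=Q)
        assert vcr.converged

        A = additive_relationship(ped)
        Z = data.Z.toarray()
        X = np.column_stack([data.X, Z @ Q[:, 1:]])
        N, p = X.shape

        def dense_neg2(s2a, s2e):
            V = Z @ A @ Z.T * s2a + np.eye(N) * s2e
            Vi = np.linalg.inv(V)
            XtViX = X.T @ Vi @ X
            beta = np.linalg.solve(XtViX, X.T @ Vi @ data.y)
            r = data.y - X @ beta
            return (
                (N - p) * math.log(2 * math.pi)
                + np.linalg.slogdet(V)[1]
                + np.linalg.slogdet(XtViX)[1]
                + r @ Vi @ r
            )

        at_opt = dense_neg2(vcr.sigma2_A, vcr.sigma2_E)
        assert at_opt == pytest.approx(-2 * vcr.loglik, rel=1e-8)
        # the estimate is a joint local optimum of the dense criterion
        for fa, fe in [(1.05, 1.0), (0.95, 1.0), (1.0, 1.05), (1.0, 0.95)]:
            assert dense_neg2(vcr.sigma2_A * fa, vcr.sigma2_E * fe) >= at_opt

    def test_implicit_equals_explicit_estimates(self):
        sim, ped, gped, data = small_study(seed=8)
        Q = q_matrix(gped)
        ve = reml_estimate(data, a_inverse(ped), mode="explicit", Q=Q)
        vi = reml_estimate(data, a_star(gped), mode="implicit", Q=Q)
        assert vi.sigma2_A == pytest.approx(ve.sigma2_A, rel=1e-6)
        assert vi.sigma2_E == pytest.approx(ve.sigma2_E, rel=1e-6)

    def test_zero_additive_variance_hits_boundary(self):
        # a ≡ 0, y = e ~ N(0, 1) on a structured pedigree: the additive
        # variance estimate collapses to the boundary and is flagged
        sim = simulate_population(
            SimParams(n_generations=5, cohort_size=200,
                      immigrants_per_generation=0, sigma2_A=0.0, seed=12)
        )
        data = build_model(sim.masked_pedigree, sim.phenotype_table(), trait="y")
        vc = reml_estimate(data, a_inverse(sim.masked_pedigree), mode="basic")
        assert vc.sigma2_A < 0.05
        assert vc.sigma2_A < 0.05 * vc.sigma2_E

    def test_recovers_known_variances(self):
        """Group-free populations simulated at σ²A = σ²E = 1: REML means within
        3 Monte-Carlo standard errors."""
        est_a, est_e = [], []
        for rep in range(6):
            sim = simulate_population(
                SimParams(n_generations=5, cohort_size=200,
                          immigrants_per_generation=0, seed=100 + rep)
            )
            data = build_model(sim.masked_pedigree, sim.phenotype_table(), trait="y")
            vc = reml_estimate(data, a_inverse(sim.masked_pedigree), mode="basic")
            est_a.append(vc.sigma2_A)
            est_e.append(vc.sigma2_E)
        for est, truth in ((est_a, 1.0), (est_e, 1.0)):
            mean = np.mean(est)
            se = np.std(est, ddof=1) / np.sqrt(len(est))
            assert abs(mean - truth) < 3 * max(se, 0.02)


class TestConversions:
    def test_identity_with_single_zero_group(self, rng):
        a = rng.normal(size=10)
        Q = np.ones((10, 1))
        np.testing.assert_array_equal(total_additive_effects(a, Q, [0.0]), a)

    def test_weighted_group_means(self):
        u = total_additive_effects(
            np.zeros(1), np.array([[0.25, 0.75]]), np.array([0.0, 4.0])
        )
        assert u[0] == 3.0

    def test_round_trip(self, rng):
        Q = rng.dirichlet(np.ones(3), size=20)
        a = rng.normal(size=20)
        g = np.array([0.0, 2.0, -1.0])
        u = total_additive_effects(a, Q, g)
        np.testing.assert_allclose(
            breeding_values_from_total(u, Q, g), a, atol=1e-12
        )
        np.testing.assert_array_equal(breeding_values_from_total(u, Q, 0 * g), u)

    def test_cross_mode_breeding_values(self):
        sim, ped, gped, data = small_study(seed=13)
        vc = VarianceComponents.from_values(1.0, 1.0)
        Q = q_matrix(gped)
        fe = solve_blup(data, a_inverse(ped), vc, mode="explicit", Q=Q)
        fi = solve_blup(data, a_star(gped), vc, mode="implicit", Q=Q)
        a_from_implicit = breeding_values_from_total(fi.u_hat, Q, fi.g_hat)
        np.testing.assert_allclose(a_from_implicit, fe.a_hat, atol=1e-6)


class TestPredictionErrorVariance:
    def test_matches_dense_mvn_oracle(self):
        """PEV of â equals Var(â − a) from the joint-normal formula."""
        from gengroups.mixedmodel import prediction_error_variance

        sim, ped, gped, data = small_study(seed=9, n_gen=3, cohort=16, imm=3)
        vc = VarianceComponents.from_values(1.0, 1.0)
        pev = prediction_error_variance(data, a_inverse(ped), vc, mode="basic")
        A = additive_relationship(ped)
        Z = data.Z.toarray()
        X = data.X
        V = Z @ A @ Z.T * vc.sigma2_A + np.eye(data.n_records) * vc.sigma2_E
        Vi = np.linalg.inv(V)
        P = Vi - Vi @ X @ np.linalg.solve(X.T @ Vi @ X, X.T @ Vi)
        G = vc.sigma2_A * A
        pev_oracle = np.diag(G - G @ Z.T @ P @ Z @ G)
        np.testing.assert_allclose(pev, pev_oracle, atol=1e-8)

    def test_size_gate(self):
        from gengroups.mixedmodel import prediction_error_variance

        sim, ped, gped, data = small_study(seed=9, n_gen=3, cohort=16, imm=3)
        vc = VarianceComponents.from_values(1.0, 1.0)
        with pytest.raises(ModelError, match="refused"):
            prediction_error_variance(
                data, a_inverse(ped), vc, mode="basic", max_n=10
            )


def test_fit_animal_model_pipeline():
    sim, ped, gped, data = small_study(seed=21)
    fit = fit_animal_model(
        gped, sim.phenotype_table(), mode="explicit",
        vc=VarianceComponents.from_values(1.0, 1.0), compute_se=True,
    )
    assert fit.g_hat is not None and fit.g_hat[0] == 0.0
    assert fit.g_se is not None and fit.g_se[1] > 0
    np.testing.assert_allclose(
        fit.u_hat, total_additive_effects(fit.a_hat, q_matrix(gped), fit.g_hat),
        atol=1e-8,
    )
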