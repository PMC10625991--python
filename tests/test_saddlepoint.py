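"""CGF machinery, saddlepoint solvers and the four-term tail approximation."""

import numpy as np
import pytest

from bvsign import (
    BivariateSample,
    ObservedStatistic,
    ScoreSystem,
    SaddlepointRootError,
    blumen_system,
    brown_system,
    cgf,
    cgf_gradient,
    cgf_hessian,
    exact_midp,
    lugannani_rice_cdf,
    marginal_cgf,
    saddlepoint_midp,
    solve_joint_saddlepoint,
    solve_marginal_saddlepoint,
    wang_components,
)

from conftest import enumerate_statistics, random_centered_system, random_sample

LOG4 = np.log(4.0)


@pytest.fixture
def single_score():
    """One score (1, 0) with offset (-1/2, 0): closed logistic forms apply."""
    return ScoreSystem(U=[(1.0, 0.0)], C=(-0.5, 0.0))


class TestCgf:
    def test_zero_at_origin(self, rng):
        system = random_centered_system(rng, 12)
        assert cgf(system, 0.0, 0.0) == pytest.approx(0.0, abs=1e-14)

    def test_closed_form_single_score(self, single_score):
        # log(1/2 + 1/2*4) - (1/2) log 4
        expected = np.log(2.5) - 0.5 * LOG4
        assert cgf(single_score, LOG4, 0.0) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.2231436, abs=1e-7)

    def test_no_overflow_for_huge_arguments(self, single_score):
        assert np.isfinite(cgf(single_score, 800.0, 0.0))
        assert np.isfinite(cgf(single_score, -800.0, 0.0))

    def test_gradient_closed_form(self, single_score):
        g = cgf_gradient(single_score, LOG4, 0.0)
        assert g[0] == pytest.approx(0.8 - 0.5, abs=1e-12)

    def test_gradient_zero_at_origin_for_centered(self, rng):
        system = random_centered_system(rng, 9)
        np.testing.assert_allclose(cgf_gradient(system, 0.0, 0.0), (0, 0), atol=1e-12)

    def test_gradient_matches_finite_differences(self, rng):
        h = 1e-6
        for _ in range(10):
            system = random_centered_system(rng, 8)
            t, u = rng.normal(scale=0.5, size=2)
            g = cgf_gradient(system, t, u)
            fd = np.array(
                [
                    (cgf(system, t + h, u) - cgf(system, t - h, u)) / (2 * h),
                    (cgf(system, t, u + h) - cgf(system, t, u - h)) / (2 * h),
                ]
            )
            np.testing.assert_allclose(g, fd, rtol=1e-6, atol=1e-8)

    def test_hessian_identity_quarter_at_origin(self, decoupled_system):
        assert cgf_hessian(decoupled_system, 0.0, 0.0) == pytest.approx((0.25, 0.0, 0.25))

    def test_hessian_psd_and_matches_second_differences(self, rng):
        h = 1e-4
        for _ in range(10):
            system = random_centered_system(rng, 8)
            t, u = rng.normal(scale=0.5, size=2)
            Ktt, Ktu, Kuu = cgf_hessian(system, t, u)
            assert Ktt * Kuu - Ktu**2 >= -1e-12
            fd_tt = (cgf(system, t + h, u) - 2 * cgf(system, t, u) + cgf(system, t - h, u)) / h**2
            fd_uu = (cgf(system, t, u + h) - 2 * cgf(system, t, u) + cgf(system, t, u - h)) / h**2
            fd_tu = (
                cgf(system, t + h, u + h)
                - cgf(system, t + h, u - h)
                - cgf(system, t - h, u + h)
                + cgf(system, t - h, u - h)
            ) / (4 * h**2)
            np.testing.assert_allclose((Ktt, Ktu, Kuu), (fd_tt, fd_tu, fd_uu), rtol=1e-5, atol=1e-6)


class TestMarginalCgf:
    def test_zero_at_origin(self, rng):
        system = random_centered_system(rng, 7)
        for axis in (1, 2):
            assert marginal_cgf(system, axis, 0.0)[0] == pytest.approx(0.0, abs=1e-14)

    def test_equals_joint_cgf_on_axis(self, rng):
        for _ in range(50):
            system = random_centered_system(rng, 6)
            s = float(rng.normal())
            assert marginal_cgf(system, 1, s)[0] == pytest.approx(cgf(system, s, 0.0), abs=1e-12)
            assert marginal_cgf(system, 2, s)[0] == pytest.approx(cgf(system, 0.0, s), abs=1e-12)

    def test_first_derivative_closed_form(self, single_score):
        assert marginal_cgf(single_score, 1, LOG4)[1] == pytest.approx(0.3, abs=1e-12)

    def test_invalid_axis(self, single_score):
        with pytest.raises(ValueError):
            marginal_cgf(single_score, 3, 0.0)


class TestSolvers:
    def test_decoupled_logit_closed_form(self, decoupled_system):
        sol = solve_joint_saddlepoint(decoupled_system, 0.3, 0.3)
        assert sol.converged
        assert sol.t0 == pytest.approx(LOG4, abs=1e-8)
        assert sol.u0 == pytest.approx(LOG4, abs=1e-8)

    def test_origin_maps_to_zero(self, rng):
        system = random_centered_system(rng, 10)
        sol = solve_joint_saddlepoint(system, 0.0, 0.0)
        assert abs(sol.t0) < 1e-8 and abs(sol.u0) < 1e-8

    def test_joint_round_trip(self, rng):
        for _ in range(40):
            system = random_centered_system(rng, 10)
            t_star, u_star = rng.normal(scale=1.0, size=2)
            target = cgf_gradient(system, t_star, u_star)
            sol = solve_joint_saddlepoint(system, *target)
            assert sol.t0 == pytest.approx(t_star, abs=1e-8)
            assert sol.u0 == pytest.approx(u_star, abs=1e-8)
            resid = cgf_gradient(system, sol.t0, sol.u0) - target
            assert np.max(np.abs(resid)) <= 1e-10 * (1 + np.abs(target).sum())

    def test_marginal_logit_closed_form(self, single_score):
        assert solve_marginal_saddlepoint(single_score, 1, 0.3) == pytest.approx(LOG4, abs=1e-8)

    def test_marginal_round_trip(self, rng):
        for _ in range(100):
            system = random_centered_system(rng, 8)
            s_star = float(rng.normal())
            target = marginal_cgf(system, 1, s_star)[1]
            s = solve_marginal_saddlepoint(system, 1, target)
            assert marginal_cgf(system, 1, s)[1] == pytest.approx(target, abs=1e-10 * (1 + abs(target)))

    def test_target_outside_support_raises(self, single_score):
        # attainable b1 range is (-1/2, 1/2)
        with pytest.raises(SaddlepointRootError, match="support"):
            solve_marginal_saddlepoint(single_score, 1, 0.7)

    def test_joint_target_outside_hull_raises(self, rng):
        system, _ = blumen_system(random_sample(rng, 8))
        with pytest.raises(SaddlepointRootError):
            solve_joint_saddlepoint(system, 100.0, 100.0)


class TestWangComponents:
    def test_ktu_zero_simplifications(self, decoupled_system):
        sol = solve_joint_saddlepoint(decoupled_system, 0.2, 0.3)
        comp = wang_components(decoupled_system, 0.2, 0.3, sol)
        assert comp.Ktu == pytest.approx(0.0, abs=1e-14)
        assert comp.b == pytest.approx(0.0, abs=1e-10)
        assert comp.rho1 == pytest.approx(0.0, abs=1e-10)
        assert comp.upsilon1 == pytest.approx(comp.upsilon0, abs=1e-10)
        assert comp.w_u0 == pytest.approx(comp.tau1, abs=1e-10)
        assert comp.G == pytest.approx(np.sqrt(comp.Kuu), abs=1e-12)

    def test_sign_conventions_and_schur_complement(self, rng):
        for _ in range(20):
            system = random_centered_system(rng, 10)
            t_star, u_star = rng.normal(scale=0.8, size=2)
            tau, upsilon = cgf_gradient(system, t_star, u_star)
            sol = solve_joint_saddlepoint(system, tau, upsilon)
            if min(abs(sol.t0), abs(sol.u0), abs(sol.t_hat0)) < 1e-4:
                continue
            comp = wang_components(system, tau, upsilon, sol)
            assert np.sign(comp.tau1) == np.sign(sol.t_hat0)
            assert np.sign(comp.w_u0) == np.sign(sol.t0)
            assert np.sign(comp.upsilon0) == np.sign(sol.u0)
            assert abs(comp.rho1) < 1.0
            assert comp.G**2 == pytest.approx(comp.Kuu - comp.Ktu**2 / comp.Ktt, abs=1e-12)
            assert comp.G > 0


class TestSaddlepointMidp:
    def test_ktu_zero_quadrant_factorizes_into_lugannani_rice_product(self, rng):
        # disjoint coordinate supports: P(b1>tau, b2>ups) must equal the
        # product of the univariate Lugannani-Rice upper tails exactly
        U = np.zeros((8, 2))
        U[:4, 0] = rng.normal(size=4)
        U[4:, 1] = rng.normal(size=4)
        system = ScoreSystem(U=U, C=-0.5 * U.sum(axis=0))
        tau, upsilon = 0.31 * np.abs(U[:4, 0]).sum() / 2, 0.27 * np.abs(U[4:, 1]).sum() / 2
        res = saddlepoint_midp(
            system, ObservedStatistic(tau, upsilon), tail_convention="quadrant", orient=False
        )
        product = (1 - lugannani_rice_cdf(system, 1, tau)) * (
            1 - lugannani_rice_cdf(system, 2, upsilon)
        )
        assert res.value == pytest.approx(product, abs=1e-10)

    def test_cdf_convention_tracks_enumeration(self, rng):
        for _ in range(15):
            sample = random_sample(rng, 12)
            system, observed = blumen_system(sample)
            sad = saddlepoint_midp(system, observed).value
            ex = exact_midp(system, observed).value
            assert 0.0 < sad < 1.0
            assert sad == pytest.approx(ex, abs=0.02)

    def test_complement_is_one_minus_cdf_form(self, rng):
        system, observed = brown_system(random_sample(rng, 9))
        a = saddlepoint_midp(system, observed, tail_convention="cdf").value
        b = saddlepoint_midp(system, observed, tail_convention="complement_cdf").value
        assert a + b == pytest.approx(1.0, abs=1e-10)

    def test_evaluation_at_mean_is_flagged_and_finite(self, rng):
        system, _ = blumen_system(random_sample(rng, 10))
        res = saddlepoint_midp(system, ObservedStatistic(0.0, 0.0))
        assert any("perturbation" in d for d in res.diagnostics)
        assert 0.0 < res.value < 1.0
        # the CDF at the centre of a symmetric lattice law is near the
        # orthant probability of a centred bivariate normal
        assert res.value == pytest.approx(0.25, abs=0.05)

    def test_boundary_observation_falls_back_to_counting(self):
        # all points in the first quadrant: every gamma is +1 and the
        # Blumen statistic attains a vertex of its support hull
        pts = np.column_stack([np.abs(np.linspace(1, 2, 8)), np.linspace(0.5, 3, 8)])
        system, observed = blumen_system(BivariateSample(points=pts))
        res = saddlepoint_midp(system, observed, tail_convention="quadrant", orient=True)
        assert any("boundary" in d for d in res.diagnostics)
        exact = exact_midp(system, observed, tail_convention="quadrant").value
        assert res.value == pytest.approx(exact, abs=1e-12)

    def test_unknown_convention_raises(self, rng):
        system, observed = blumen_system(random_sample(rng, 6))
        with pytest.raises(ValueError, match="tail_convention"):
            saddlepoint_midp(system, observed, tail_convention="upper")

    def test_solver_residuals_meet_contract(self, rng):
        # Newton converges for interior targets drawn across the support
        failures = 0
        for _ in range(400):
            system = random_centered_system(rng, 10)
            t_star, u_star = rng.normal(scale=1.2, size=2)
            tau, upsilon = cgf_gradient(system, t_star, u_star)
            sol = solve_joint_saddlepoint(system, tau, upsilon)
            assert sol.gradient_residual <= 1e-10 * (1 + abs(tau) + abs(upsilon))
        assert failures == 0
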