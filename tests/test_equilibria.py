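"""Equilibria, Jacobians and local stability classification."""

import numpy as np
import pytest

from cocontagion import (
    ConvergenceError,
    NoEndemicEquilibriumError,
    classify_stability,
    default_initial_state,
    dfe_full,
    dfe_racism,
    dfe_violence,
    endemic_full_numeric,
    endemic_racism,
    endemic_violence,
    integrate,
    jacobian,
    r0_racism,
    r0_violence,
    rhs_full,
    rhs_racism,
    rhs_violence,
)
from cocontagion.equilibria import report_dfe

from conftest import random_parameters


class TestBehaviourFreeEquilibria:
    @pytest.mark.parametrize("Lambda, expected_S", [(50.0, 5000.0), (5.0, 500.0)])
    def test_dfe_states(self, reconciled, Lambda, expected_S):
        p = reconciled.replace(Lambda=Lambda)
        assert dfe_violence(p) == (expected_S, 0, 0, 0)
        assert dfe_racism(p) == (expected_S, 0, 0)
        assert dfe_full(p)[0] == expected_S
        assert sum(dfe_full(p)[1:]) == 0.0

    def test_dfes_are_fixed_points(self, reconciled):
        p = reconciled
        np.testing.assert_allclose(rhs_violence(0, dfe_violence(p), p), 0, atol=1e-12)
        np.testing.assert_allclose(rhs_racism(0, dfe_racism(p), p), 0, atol=1e-12)
        np.testing.assert_allclose(rhs_full(0, dfe_full(p), p), 0, atol=1e-12)


class TestEndemicClosedForms:
    def test_violence_endemic_force_of_infection(self, reconciled):
        rep = endemic_violence(reconciled)
        # mu(d+mu)(a+mu)(e+mu)(R0-1) / [(a+mu)(e+mu)(d+mu) - a*e*d]
        assert rep.foi["lambda_v"] == pytest.approx(0.45184, rel=1e-4)
        assert all(v > 0 for v in rep.state)
        assert rep.kind == "endemic"

    def test_racism_endemic_force_of_infection(self, reconciled):
        rep = endemic_racism(reconciled)
        assert rep.foi["lambda_r"] == pytest.approx(1.65518, rel=1e-4)
        assert all(v > 0 for v in rep.state)

    @pytest.mark.parametrize("fn, r0_fn", [
        (endemic_violence, r0_violence),
        (endemic_racism, r0_racism),
    ])
    def test_residual_oracle_random_supercritical_draws(self, fn, r0_fn):
        rng = np.random.default_rng(99)
        count = 0
        while count < 50:
            p = random_parameters(rng)
            if r0_fn(p) <= 1.0:
                continue
            count += 1
            rep = fn(p)
            assert rep.residual_norm < 1e-10 * p.Lambda
            assert all(v > 0 for v in rep.state)

    @pytest.mark.parametrize("fn, r0_fn, beta_name", [
        (endemic_violence, r0_violence, "beta1"),
        (endemic_racism, r0_racism, "beta2"),
    ])
    def test_no_endemic_point_at_or_below_threshold(
        self, reconciled, fn, r0_fn, beta_name
    ):
        # scale beta so R0 lands exactly at / below 1
        beta_crit = getattr(reconciled, beta_name) / r0_fn(reconciled)
        for fac in (0.5, 1.0):
            p = reconciled.replace(**{beta_name: beta_crit * fac})
            assert r0_fn(p) <= 1.0 + 1e-12
            with pytest.raises(NoEndemicEquilibriumError):
                fn(p)

    def test_endemic_branch_emerges_continuously_from_dfe(self, reconciled):
        # just above threshold the endemic state is a small perturbation of
        # the behaviour-free state, with lambda_v* -> 0
        beta_crit = reconciled.beta1 / r0_violence(reconciled)
        p = reconciled.replace(beta1=beta_crit * (1.0 + 1e-6))
        rep = endemic_violence(p)
        assert rep.foi["lambda_v"] == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(rep.state, dfe_violence(p), rtol=1e-4,
                                   atol=1e-3)


class TestJacobianAndStability:
    def test_violence_dfe_spectrum_matches_closed_form(self, reconciled):
        p = reconciled
        J = jacobian(rhs_violence, dfe_violence(p), p)
        eig = np.sort_complex(np.linalg.eigvals(J)).real
        expected = np.sort([
            -p.mu,
            (p.delta + p.mu) * (r0_violence(p) - 1.0),
            -(p.epsilon + p.mu),
            -(p.alpha + p.mu),
        ])
        np.testing.assert_allclose(eig, expected, rtol=1e-8, atol=1e-10)
        # frozen arithmetic: (delta+mu)*(R0v-1) = 0.41 * 2.6585
        assert eig.max() == pytest.approx(1.09, rel=1e-3)

    def test_racism_dfe_quadratic_factor_matches_submodel(self, reconciled):
        # the (sigma+mu)(R0r-1) eigenvalue of the racism submodel must also
        # appear in the full-model DFE spectrum
        p = reconciled
        lam_expected = (p.sigma + p.mu) * (r0_racism(p) - 1.0)
        eig_full = np.linalg.eigvals(jacobian(rhs_full, dfe_full(p), p))
        assert np.min(np.abs(eig_full.real - lam_expected)) < 1e-6

    def test_classify_stability_verdicts(self):
        assert classify_stability([-1.0, -0.5 + 2j]) == "stable"
        assert classify_stability([-1.0, 1e-3]) == "unstable"
        assert classify_stability([-1.0, 1e-12]) == "marginal"

    @pytest.mark.parametrize("model, r0_fn, beta_name", [
        ("violence", r0_violence, "beta1"),
        ("racism", r0_racism, "beta2"),
    ])
    def test_dfe_verdict_flips_at_threshold(
        self, reconciled, model, r0_fn, beta_name
    ):
        beta_crit = getattr(reconciled, beta_name) / r0_fn(reconciled)
        for fac, expected in ((0.5, "stable"), (1.5, "unstable")):
            p = reconciled.replace(**{beta_name: beta_crit * fac})
            assert report_dfe(model, p).stable == expected

    def test_full_dfe_stable_iff_both_thresholds_below_one(self, eradication):
        assert report_dfe("full", eradication).stable == "stable"
        hot = eradication.replace(beta2=0.007)
        assert report_dfe("full", hot).stable == "unstable"


class TestFullModelNumericRoot:
    def test_subcritical_root_is_the_coexistence_free_point(self, eradication):
        p = eradication
        rep = endemic_full_numeric(p, guess=default_initial_state(p))
        assert rep.kind == "free"
        np.testing.assert_allclose(rep.state, dfe_full(p), rtol=1e-6, atol=1e-6)

    def test_supercritical_root_properties(self, persistence):
        rep = endemic_full_numeric(persistence)
        assert rep.kind == "endemic"
        assert rep.residual_norm < 1e-8 * persistence.Lambda
        assert min(rep.state) >= 0.0
        # conservation at any equilibrium: N = Lambda/mu exactly
        assert sum(rep.state) == pytest.approx(
            persistence.Lambda / persistence.mu, rel=1e-9)

    def test_root_matches_late_time_plateau(self, persistence):
        p = persistence
        traj = integrate("full", default_initial_state(p), p, t_end=500.0)
        rep = endemic_full_numeric(p)
        scale = p.Lambda / p.mu
        diff = np.abs(traj.final_state() - np.array(rep.state))
        assert np.all(diff <= 0.01 * np.array(rep.state) + 1e-6 * scale)


class TestGlobalBehaviourSpotCheck:
    def test_subcritical_trajectories_approach_the_dfe(self, eradication):
        # numeric stand-in for the global-stability results: random positive
        # starts with R0 < 1 all drain their infected classes
        p = eradication
        rng = np.random.default_rng(123)
        scale = p.Lambda / p.mu
        for _ in range(50):
            y0 = rng.uniform(0.0, scale / 8.0, size=8)
            traj = integrate("full", y0, p, t_end=300.0, n_report=50)
            end = traj.final_state()
            assert end[[1, 3, 4]].max() < 1e-6  # V, R, Ivr
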