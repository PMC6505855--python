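"""Equilibria, linear stability, damping and threshold formulas."""

import math

import numpy as np
import pytest

from sirews import (
    ModelParams,
    disease_free_equilibrium,
    eigenvalue_approximations,
    endemic_equilibrium,
    equilibria,
    jacobian,
    linear_solution,
    period_prediction,
    potential,
    sparked_equilibrium,
    stability,
    threshold_uptake,
    underdamped_boundary,
)
from sirews.model import endemic_eigenvalues_closed_form
from sirews.simulate import VaccineSchedule, ode_trajectory


class TestParams:
    def test_derived_quantities(self, ref_params):
        assert ref_params.N == pytest.approx(1e7)
        assert ref_params.beta == pytest.approx(17.0 * (365 / 22 + 0.02) / 1e7)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(b=-1.0),
            dict(mu=0.0),
            dict(gamma=-2.0),
            dict(eta=-1e-5),
            dict(nu=1.5),
            dict(R0=0.0),
        ],
    )
    def test_invalid_parameters_rejected(self, bad):
        values = dict(b=2e5, mu=0.02, gamma=365 / 22, eta=0.0, nu=0.0, R0=17.0)
        values.update(bad)
        with pytest.raises(ValueError):
            ModelParams(**values)


class TestThreshold:
    @pytest.mark.parametrize(
        "R0, expected", [(17.0, 0.941), (1.0, 0.0), (2.0, 0.5)]
    )
    def test_critical_uptake(self, R0, expected):
        p = ModelParams(b=2e5, mu=0.02, gamma=365 / 22, R0=R0)
        assert threshold_uptake(p) == pytest.approx(expected, abs=5e-4)

    def test_below_one_reproduction_number(self):
        p = ModelParams(b=2e5, mu=0.02, gamma=365 / 22, R0=0.5)
        assert threshold_uptake(p) < 0  # no vaccination needed


class TestEquilibria:
    def test_endemic_closed_form(self, ref_closed):
        p = ref_closed.with_nu(0.9)
        eq = endemic_equilibrium(p)
        assert eq.S_star == pytest.approx(588235.29, rel=1e-6)
        assert eq.I_star == pytest.approx(495.78, abs=0.01)

    def test_transcritical_point(self, ref_closed):
        p = ref_closed.with_nu(threshold_uptake(ref_closed))
        eq = endemic_equilibrium(p)
        assert eq.I_star == pytest.approx(0.0, abs=1e-9)
        assert eq.S_star == pytest.approx(disease_free_equilibrium(p).S_star, rel=1e-9)

    def test_transcritical_continuity(self, ref_closed):
        """Endemic prevalence vanishes continuously as uptake nears threshold."""
        nu_c = threshold_uptake(ref_closed)
        nus = nu_c - np.geomspace(1e-2, 1e-8, 7)
        I_stars = [endemic_equilibrium(ref_closed.with_nu(nu)).I_star for nu in nus]
        assert all(a > b > 0 for a, b in zip(I_stars, I_stars[1:]))
        assert I_stars[-1] < 1e-4 * I_stars[0]

    def test_branch_listing(self, ref_closed, ref_params):
        below = equilibria(ref_closed.with_nu(0.5))
        assert [e.branch for e in below] == ["disease_free", "endemic"]
        above = equilibria(ref_closed.with_nu(0.99))
        assert [e.branch for e in above] == ["disease_free"]
        assert [e.branch for e in equilibria(ref_params)] == ["sparked"]

    def test_sparked_positive_above_threshold(self, ref_params):
        eq = sparked_equilibrium(ref_params.with_nu(0.95))
        assert eq.I_star > 0

    def test_sparked_matches_ode_relaxation(self, ref_params):
        """The quadratic-root equilibrium agrees with the relaxed noise-free flow."""
        p = ref_params.with_nu(0.95)
        eq = sparked_equilibrium(p)
        run = ode_trajectory(
            p,
            VaccineSchedule.constant(0.95),
            T=2000.0,
            init=(p.N * 0.05, 10.0),
            sample_dt=10.0,
        )
        assert run.S[-1] == pytest.approx(eq.S_star, rel=1e-5)
        assert run.I[-1] == pytest.approx(eq.I_star, rel=1e-4)


class TestJacobian:
    def test_disease_free_eigenvalues(self, ref_closed):
        p = ref_closed.with_nu(0.95)
        lam = np.linalg.eigvals(jacobian(p, disease_free_equilibrium(p)))
        expected = {-p.mu, (p.gamma + p.mu) * (p.control - 1.0)}
        for e in expected:
            assert min(abs(lam - e)) < 1e-10 * max(1.0, abs(e))

    def test_decoupled_limit(self):
        # vanishing transmission: J is diagonal with rates -mu and -(gamma+mu)
        p = ModelParams(b=2e5, mu=0.02, gamma=365 / 22, R0=1e-14)
        eq = disease_free_equilibrium(p)
        J = jacobian(p, eq)
        assert abs(J[0, 1]) < 1e-6 and J[1, 0] == 0.0
        assert J[0, 0] == pytest.approx(-p.mu)
        assert J[1, 1] == pytest.approx(-(p.gamma + p.mu), rel=1e-6)

    def test_endemic_trace_and_determinant(self, ref_closed):
        rep = stability(ref_closed, endemic_equilibrium(ref_closed))
        assert rep.tau == pytest.approx(-0.34, rel=1e-10)
        assert rep.Delta == pytest.approx(5.3155, abs=5e-5)


class TestStability:
    def test_reference_endemic_report(self, ref_closed):
        rep = stability(ref_closed, endemic_equilibrium(ref_closed))
        lam = rep.dominant
        assert lam.real == pytest.approx(-0.17, rel=1e-10)
        assert abs(lam.imag) == pytest.approx(2.2993, abs=5e-5)
        assert rep.period == pytest.approx(2.733, abs=5e-4)
        assert rep.zeta == pytest.approx(0.0737, abs=5e-5)
        assert rep.regime == ("stable", "underdamped")

    def test_closed_form_eigenvalues_random_draws(self, rng):
        """Numerical eigenvalues match the endemic closed form to 1e-10."""
        for _ in range(20):
            p = ModelParams(
                b=float(rng.uniform(1e3, 1e6)),
                mu=float(rng.uniform(0.01, 0.1)),
                gamma=float(rng.uniform(1.0, 50.0)),
                eta=0.0,
                nu=float(rng.uniform(0.0, 0.5)),
                R0=float(rng.uniform(2.5, 20.0)),
            )
            if p.control <= 1.0:
                continue
            rep = stability(p, endemic_equilibrium(p))
            expected = endemic_eigenvalues_closed_form(p)
            got = sorted(rep.eigenvalues, key=lambda z: (z.real, z.imag))
            exp = sorted(expected, key=lambda z: (z.real, z.imag))
            for g, e in zip(got, exp):
                assert abs(g - e) <= 1e-10 * max(abs(e), 1e-3)

    def test_zero_eigenvalue_at_threshold(self, ref_closed):
        p = ref_closed.with_nu(threshold_uptake(ref_closed))
        rep = stability(p, disease_free_equilibrium(p))
        assert abs(rep.dominant.real) < 1e-10 and abs(rep.dominant.imag) < 1e-10

    def test_modulus_equals_sqrt_determinant(self, ref_closed):
        rep = stability(ref_closed.with_nu(0.5), endemic_equilibrium(ref_closed.with_nu(0.5)))
        assert rep.underdamped
        assert rep.modulus == pytest.approx(math.sqrt(rep.Delta), rel=1e-12)

    def test_trace_determinant_eigenvalue_identities(self, ref_params):
        rep = stability(ref_params.with_nu(0.7), sparked_equilibrium(ref_params.with_nu(0.7)))
        l1, l2 = rep.eigenvalues
        assert (l1 + l2).real == pytest.approx(rep.tau, rel=1e-10)
        assert (l1 * l2).real == pytest.approx(rep.Delta, rel=1e-10)

    def test_speed_distance_law(self, ref_closed):
        """|Re(dominant eigenvalue)| grows with the distance |R0(1-nu)-1|."""
        nu_c = threshold_uptake(ref_closed)
        below = [nu_c - d for d in (0.002, 0.01, 0.05, 0.2)]
        speeds = []
        for nu in below:
            p = ref_closed.with_nu(nu)
            speeds.append(abs(stability(p, endemic_equilibrium(p)).dominant.real))
        assert all(a < b for a, b in zip(speeds, speeds[1:]))
        # above threshold, the decay rate of the transmission eigenvalue
        # (gamma+mu)(R0(1-nu)-1) of the disease-free state grows with distance
        above = [nu_c + d for d in (0.002, 0.01, 0.04)]
        speeds_up = []
        for nu in above:
            p = ref_closed.with_nu(nu)
            lam = stability(p, disease_free_equilibrium(p)).eigenvalues
            trans = max(lam, key=lambda z: abs(z.real + p.mu))  # exclude the -mu mode
            speeds_up.append(abs(trans.real))
        assert all(a < b for a, b in zip(speeds_up, speeds_up[1:]))


class TestEigenvalueApproximations:
    def test_reference_values(self, ref_closed):
        re, im = eigenvalue_approximations(ref_closed)
        assert re == pytest.approx(-0.17)
        assert im == pytest.approx(math.sqrt(0.02 * 16 * 365 / 22), rel=1e-12)
        assert im == pytest.approx(2.3041, abs=5e-5)

    def test_accuracy_against_exact(self, ref_closed):
        _, im = eigenvalue_approximations(ref_closed)
        exact = stability(ref_closed, endemic_equilibrium(ref_closed)).dominant.imag
        assert abs(im - exact) / exact < 0.01

    def test_domain_error(self, ref_closed):
        with pytest.raises(ValueError):
            eigenvalue_approximations(ref_closed.with_nu(0.95))


class TestPeriodPrediction:
    def test_reference_values(self, ref_closed):
        pred = period_prediction(ref_closed)
        assert pred.A == pytest.approx(3.125)
        assert pred.D == pytest.approx(22 / 365)
        assert pred.period_approx == pytest.approx(2.727, abs=5e-4)
        assert pred.period_exact == pytest.approx(2.733, abs=5e-4)
        assert abs(pred.period_exact - pred.period_approx) / pred.period_exact < 0.003

    def test_monotone_increase_toward_threshold(self, ref_closed):
        periods = [period_prediction(ref_closed.with_nu(nu)).period_approx
                   for nu in (0.0, 0.5, 0.9, 0.93)]
        assert all(a < b for a, b in zip(periods, periods[1:]))

    def test_domain_error_above_threshold(self, ref_closed):
        with pytest.raises(ValueError):
            period_prediction(ref_closed.with_nu(0.95))


class TestPotential:
    def test_direct_values(self):
        assert potential(2.0, 0.0) == 0.0
        assert potential(2.0, 1.0) == 1.0

    def test_wells_shallower_near_threshold(self, ref_closed):
        z = 100.0
        values = []
        for nu in (0.5, 0.8, 0.9):
            p = ref_closed.with_nu(nu)
            values.append(potential(stability(p, endemic_equilibrium(p)).Delta, z))
        assert values[0] > values[1] > values[2] > 0


class TestUnderdampedBoundary:
    def test_reference_with_sparking(self, ref_params):
        assert underdamped_boundary(ref_params) == pytest.approx(0.939, abs=5e-4)

    def test_closed_model_against_quadratic_oracle(self, ref_closed):
        """With eta=0, zeta=1 solves mu x^2 = 4(mu+gamma)(x-1) in x = R0(1-nu)."""
        mu, gamma = ref_closed.mu, ref_closed.gamma
        roots = np.roots([mu, -4.0 * (mu + gamma), 4.0 * (mu + gamma)])
        # the root just above 1 is the boundary nearest the threshold
        x = min(r.real for r in roots if r.real > 1)
        expected = 1.0 - x / ref_closed.R0
        assert underdamped_boundary(ref_closed) == pytest.approx(expected, abs=2e-6)

    def test_boundary_approaches_threshold_for_fast_recovery(self):
        # closed model: as recovery speeds up the oscillatory window shrinks
        # onto the threshold
        gaps = []
        for gamma in (365 / 22, 30.0, 60.0, 120.0):
            p = ModelParams(b=2e5, mu=0.02, gamma=gamma, eta=0.0, nu=0.0, R0=17.0)
            gaps.append(threshold_uptake(p) - underdamped_boundary(p))
        assert all(a > b > 0 for a, b in zip(gaps, gaps[1:]))

    def test_no_bracket_error(self, ref_params):
        with pytest.raises(ValueError, match="does not change sign"):
            underdamped_boundary(ref_params, bracket=(0.1, 0.2))


class TestLinearSolution:
    def test_identity_at_t0(self):
        J = np.array([[-1.0, 2.0], [0.5, -3.0]])
        z0 = (1.0, -2.0)
        assert np.allclose(linear_solution(J, z0, 0.0), z0)

    def test_decoupled_exponentials(self):
        J = np.diag([-1.0, -2.0])
        out = linear_solution(J, (1.0, 1.0), math.log(2.0))
        assert np.allclose(out, [0.5, 0.25])

    def test_envelope_decay_rate(self, ref_closed):
        """Spiral amplitude decays at |Re(lambda)| = mu R0 (1-nu)/2."""
        p = ref_closed.with_nu(0.9)
        eq = endemic_equilibrium(p)
        rep = stability(p, eq)
        t = np.arange(0.0, 600.0, 0.05)
        traj = linear_solution(rep.J, (0.0, eq.I_star * 0.1), t)
        z_I = traj[:, 1]
        # successive |z_I| peak amplitudes fall on an exponential envelope
        peaks = [i for i in range(1, len(z_I) - 1)
                 if abs(z_I[i]) >= abs(z_I[i - 1]) and abs(z_I[i]) > abs(z_I[i + 1])]
        slope = np.polyfit(t[peaks], np.log(np.abs(z_I[peaks])), 1)[0]
        assert slope == pytest.approx(rep.dominant.real, rel=0.01)
        assert rep.dominant.real == pytest.approx(-0.017, rel=1e-10)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            linear_solution(np.diag([-1.0, -1.0]), (1.0, 1.0), -0.5)
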