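"""Model systems: parameter interpolation, soft-core pair physics, and the
exact free-energy oracles."""

import math

import numpy as np
import pytest
from scipy import integrate

from alchemkit import (
    CouplingState,
    DomainError,
    SoftCoreParams,
    ThermoContext,
    analytic_free_energy,
    as_system,
    clash_toy,
    coupled_quadratic_2d,
    harmonic_lambda_pair,
    interpolate_parameters,
    quadrature_free_energy,
    restraint_energy,
    softcore_pair_energy,
    system_energy,
)
from alchemkit.model_systems import (
    COULOMB_CONSTANT,
    FourStateToy,
    PerturbedAtomParams,
    QuadraticSystem,
    RestraintParams,
    _softcore_vec,
)

from conftest import CLASH_BOX

ATOM_GROW = PerturbedAtomParams(0.0, 0.2, 0.0, 2e-6, 0.0, 3e-3, "lam")
ATOM_BOTH = PerturbedAtomParams(0.1, -0.3, 3e-6, 1e-6, 2e-3, 4e-3, "kap")
ATOM_FIXED = PerturbedAtomParams.unperturbed(0.1, 3e-6, 2e-3)


class TestParameterInterpolation:
    def test_endpoints_are_exact(self):
        atom = ATOM_BOTH
        assert interpolate_parameters(atom, 0.0) == (atom.q_A, atom.C12_A, atom.C6_A)
        q1, c12, c6 = interpolate_parameters(atom, 1.0)
        assert q1 == atom.q_B
        assert c12 == pytest.approx(atom.C12_B, rel=1e-14)
        assert c6 == pytest.approx(atom.C6_B, rel=1e-14)

    def test_midpoint_arithmetic(self):
        # charge linear; C12 from the square of the interpolated root
        atom = PerturbedAtomParams(0.0, 0.4, 1.0, 4.0, 0.0, 0.0, "lam")
        q, c12, _ = interpolate_parameters(atom, 0.5)
        assert q == pytest.approx(0.2)
        assert c12 == pytest.approx((0.5 * 1.0 + 0.5 * 2.0) ** 2) == pytest.approx(2.25)

    def test_domain_error_outside_unit_interval(self):
        with pytest.raises(DomainError):
            interpolate_parameters(ATOM_GROW, 1.2)


class TestSoftCorePair:
    def test_unperturbed_pair_is_plain_lj_coulomb(self):
        a = PerturbedAtomParams(0.2, 0.2, 2e-6, 2e-6, 2e-3, 2e-3, "lam")
        b = ATOM_FIXED
        r = 0.33
        for state in (CouplingState(0.3, 0.8), CouplingState(0.0, 0.0)):
            e = softcore_pair_energy(r, a, b, state)
            c12 = math.sqrt(2e-6 * 3e-6)
            c6 = math.sqrt(2e-3 * 2e-3)
            plain = c12 / r**12 - c6 / r**6 + COULOMB_CONSTANT * 0.2 * 0.1 / r
            assert e.energy == pytest.approx(plain, rel=1e-12)
            assert e.dlam == 0.0 and e.dkap == 0.0

    def test_energy_decays_at_large_distance(self):
        state = CouplingState(0.5, 0.5)
        energies = [
            abs(softcore_pair_energy(r, ATOM_GROW, ATOM_BOTH, state).energy)
            for r in (3.0, 4.0, 6.0, 10.0)
        ]
        assert all(b < a for a, b in zip(energies, energies[1:]))
        # without charges the Lennard-Jones tail vanishes quickly
        neutral = PerturbedAtomParams(0.0, 0.0, 3e-6, 1e-6, 2e-3, 4e-3, "kap")
        tail = [
            abs(softcore_pair_energy(r, ATOM_GROW, neutral, state).energy)
            for r in (3.0, 4.0, 6.0, 10.0)
        ]
        assert all(b < a for a, b in zip(tail, tail[1:]))
        assert tail[-1] < 1e-6

    def test_fully_decoupled_partner_zero_energy_fd_derivative(self):
        # grower at lam=0 is a dummy: zero pair energy, derivative matches
        # central finite differences over a grid of (r, lam, kap) points
        rng = np.random.default_rng(11)
        h = 1e-6
        for _ in range(20):
            r = rng.uniform(0.1, 0.8)
            kap = rng.uniform(0.05, 0.95)
            st = CouplingState(0.0, kap)
            e = softcore_pair_energy(r, ATOM_GROW, ATOM_BOTH, st)
            assert e.energy == 0.0
            fd = (
                softcore_pair_energy(r, ATOM_GROW, ATOM_BOTH, CouplingState(h, kap)).energy
                - e.energy
            ) / h
            assert e.dlam == pytest.approx(fd, abs=1e-4)

    @pytest.mark.parametrize("pair", [(ATOM_GROW, ATOM_BOTH), (ATOM_BOTH, ATOM_FIXED)])
    def test_derivatives_match_finite_differences(self, pair):
        i, j = pair
        rng = np.random.default_rng(1)
        h = 1e-6
        for _ in range(20):
            r = rng.uniform(0.05, 0.8)
            lam, kap = rng.uniform(0.05, 0.95, size=2)
            e = softcore_pair_energy(r, i, j, CouplingState(lam, kap))
            fdl = (
                softcore_pair_energy(r, i, j, CouplingState(lam + h, kap)).energy
                - softcore_pair_energy(r, i, j, CouplingState(lam - h, kap)).energy
            ) / (2 * h)
            fdk = (
                softcore_pair_energy(r, i, j, CouplingState(lam, kap + h)).energy
                - softcore_pair_energy(r, i, j, CouplingState(lam, kap - h)).energy
            ) / (2 * h)
            assert e.dlam == pytest.approx(fdl, abs=1e-6 * max(1.0, abs(fdl)) * 10)
            assert e.dkap == pytest.approx(fdk, abs=1e-6 * max(1.0, abs(fdk)) * 10)

    def test_vectorized_form_matches_scalar(self):
        rng = np.random.default_rng(0)
        lam = rng.uniform(0, 1, 50)
        kap = rng.uniform(0, 1, 50)
        for r in (0.1, 0.35, 0.8):
            e, dl, dk = _softcore_vec(r, ATOM_GROW, ATOM_BOTH, lam, kap, SoftCoreParams())
            for t in range(50):
                s = softcore_pair_energy(r, ATOM_GROW, ATOM_BOTH, CouplingState(lam[t], kap[t]))
                assert s.energy == pytest.approx(e[t], abs=1e-12)
                assert s.dlam == pytest.approx(dl[t], abs=1e-12)
                assert s.dkap == pytest.approx(dk[t], abs=1e-12)

    def test_bounded_at_contact_for_interior_states(self):
        # soft-core boundedness: finite pair energy at r -> 0+ strictly
        # inside the unit square
        for lam, kap in ((0.5, 0.5), (0.1, 0.9), (0.99, 0.01)):
            e = softcore_pair_energy(1e-9, ATOM_GROW, ATOM_BOTH, CouplingState(lam, kap))
            assert math.isfinite(e.energy)

    def test_reversion_to_single_axis_softcore(self):
        # one perturbed partner + one unperturbed partner must reduce to
        # the single-axis soft-core expression, written out independently
        sc = SoftCoreParams(0.5, 0.5)
        i, j = ATOM_GROW, ATOM_FIXED
        for lam in (0.15, 0.5, 0.85):
            for r in (0.05, 0.2, 0.5):
                e = softcore_pair_energy(r, i, j, CouplingState(lam, 0.0), sc)
                # independent single-axis form: interpolated pair
                # coefficients, softness alpha*(1-lam)^2 on the reference
                # radius of the fully coupled pair
                s12 = lam * math.sqrt(i.C12_B) * math.sqrt(j.C12_A)
                s6 = lam * math.sqrt(i.C6_B) * math.sqrt(j.C6_A)
                qq = lam * i.q_B * j.q_A
                c126 = math.sqrt(i.C12_B * j.C12_A) / math.sqrt(i.C6_B * j.C6_A)
                L2 = (1.0 - lam) ** 2
                D = r**6 + sc.alpha_LJ * L2 * c126
                expected = s12 / D**2 - s6 / D + COULOMB_CONSTANT * qq / math.sqrt(
                    r**2 + sc.alpha_CRF * L2
                )
                assert e.energy == pytest.approx(expected, rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            softcore_pair_energy(0.0, ATOM_GROW, ATOM_BOTH, CouplingState(0.5, 0.5))
        with pytest.raises(DomainError):
            PerturbedAtomParams(0, 0, -1.0, 0, 0, 0, "lam")


class TestRestraint:
    @pytest.mark.parametrize(
        "k,target,displacement,expected",
        [
            (500.0, 0.1, 0.1, 0.0),  # at the target distance
            (500.0, 0.0, 0.1, 2.5),  # production force constant
            (150.0, 0.0, 0.2, 3.0),  # preliminary force constant
        ],
    )
    def test_harmonic_distance_values(self, k, target, displacement, expected):
        params = RestraintParams(force_constant=k, anchor=(0.0,), target_distance=target)
        assert restraint_energy([displacement], params) == pytest.approx(expected)

    def test_nonnegative_everywhere(self):
        params = RestraintParams(500.0, (0.1, -0.2), 0.05)
        rng = np.random.default_rng(5)
        for _ in range(50):
            pos = rng.uniform(-1, 1, 2)
            assert restraint_energy(pos, params) >= 0.0


class TestSystemEnergy:
    def test_state_independent_quadratic_has_zero_derivatives(self):
        spec = harmonic_lambda_pair(100.0, 100.0)
        _, dlam, dkap, _ = system_energy(spec, [0.3], CouplingState(0.7, 0.2))
        assert dlam == pytest.approx(0.0, abs=1e-9)
        assert dkap == 0.0

    def test_decoupled_corner_is_background_plus_restraint(self, clash_system):
        spec = clash_system.spec
        x = [0.21]
        h, dlam, dkap, ends = system_energy(spec, x, CouplingState(0.0, 0.0))
        assert h == pytest.approx(restraint_energy(x, spec.restraint), rel=1e-12)
        assert ends[(0.0, 0.0)] == pytest.approx(h, rel=1e-12)

    def test_derivatives_match_finite_differences(self, clash_system):
        rng = np.random.default_rng(21)
        h = 1e-6
        for _ in range(50):
            x = [rng.uniform(-0.6, 0.7)]
            lam, kap = rng.uniform(0.02, 0.98, size=2)
            e = clash_system.evaluate(x, CouplingState(lam, kap))
            fdl = (
                clash_system.evaluate(x, CouplingState(lam + h, kap)).energy
                - clash_system.evaluate(x, CouplingState(lam - h, kap)).energy
            ) / (2 * h)
            fdk = (
                clash_system.evaluate(x, CouplingState(lam, kap + h)).energy
                - clash_system.evaluate(x, CouplingState(lam, kap - h)).energy
            ) / (2 * h)
            assert e.dlam == pytest.approx(fdl, rel=1e-5, abs=1e-5)
            assert e.dkap == pytest.approx(fdk, rel=1e-5, abs=1e-5)

    def test_endpoint_consistency(self, clash_system):
        # coupled energy at lam=0 equals the pure A-state energy exactly:
        # the grower contributes nothing at its dummy end
        grower_off = clash_system.spec.grower_params
        assert grower_off.a_is_null
        for kap in (0.0, 0.4, 1.0):
            x = [0.18]
            e = clash_system.evaluate(x, CouplingState(0.0, kap))
            ends = clash_system.endstate_energies(x)
            if kap in (0.0, 1.0):
                assert e.energy == pytest.approx(ends[(0.0, kap)], rel=1e-12)

    def test_dimension_mismatch_raises(self, clash_system):
        from alchemkit import StructureError

        with pytest.raises(StructureError):
            clash_system.evaluate([0.1, 0.2], CouplingState(0.5, 0.5))


class TestFreeEnergyOracles:
    def test_constant_system_has_zero_differences(self, ctx):
        spec = harmonic_lambda_pair(250.0, 250.0)
        g0 = analytic_free_energy(spec, CouplingState(0.0, 0.0), ctx)
        g1 = analytic_free_energy(spec, CouplingState(1.0, 0.0), ctx)
        assert g1 - g0 == pytest.approx(0.0, abs=1e-12)

    def test_harmonic_closed_form(self, ctx):
        spec = harmonic_lambda_pair(100.0, 400.0)
        dg = analytic_free_energy(spec, CouplingState(1.0, 0.0), ctx) - analytic_free_energy(
            spec, CouplingState(0.0, 0.0), ctx
        )
        assert dg == pytest.approx(0.5 * ctx.kBT * math.log(4.0), rel=1e-12)
        assert dg == pytest.approx(1.7174, abs=5e-4)

    def test_coupled_2d_matches_quadrature(self, ctx):
        spec = coupled_quadratic_2d()
        box = [(-1.0, 1.0), (-1.0, 1.0)]
        for st in (CouplingState(0.0, 0.0), CouplingState(1.0, 1.0), CouplingState(0.4, 0.7)):
            ga = analytic_free_energy(spec, st, ctx)
            gq = quadrature_free_energy(spec, st, box, ctx)
            assert ga == pytest.approx(gq, abs=1e-6)

    def test_non_positive_definite_raises(self, ctx):
        spec = harmonic_lambda_pair(100.0, -300.0)
        with pytest.raises(DomainError):
            analytic_free_energy(spec, CouplingState(1.0, 0.0), ctx)

    def test_derivative_integral_consistency(self, ctx):
        # integrating the exact Gaussian mean derivative reproduces the
        # analytic free-energy difference
        spec = coupled_quadratic_2d()
        system = QuadraticSystem(spec)
        kBT = ctx.kBT

        def mean_dlam(lam):
            A, b = system._ab(lam, 0.6)
            dA, _ = spec.stiffness_grad(lam, 0.6)
            db, _ = spec.linear_grad(lam, 0.6)
            mu = np.linalg.solve(A, b)
            cov = kBT * np.linalg.inv(A)
            return 0.5 * (np.trace(cov @ dA) + mu @ dA @ mu) - db @ mu

        val, _ = integrate.quad(mean_dlam, 0.0, 1.0, epsabs=1e-10, epsrel=1e-10)
        exact = analytic_free_energy(spec, CouplingState(1.0, 0.6), ctx) - analytic_free_energy(
            spec, CouplingState(0.0, 0.6), ctx
        )
        assert val == pytest.approx(exact, abs=1e-6)

    def test_decoupled_corners_are_degenerate(self, clash_corners):
        # with the grower interacting only with the water, removing the
        # water makes the grower axis a null perturbation
        assert clash_corners[(1.0, 0.0)] == pytest.approx(clash_corners[(0.0, 0.0)], abs=1e-8)

    def test_box_doubling_is_irrelevant_for_confined_system(self, clash_system, ctx):
        g1 = quadrature_free_energy(clash_system, CouplingState(0.4, 0.6), CLASH_BOX, ctx)
        g2 = quadrature_free_energy(clash_system, CouplingState(0.4, 0.6), [(-3.0, 3.0)], ctx)
        assert g1 == pytest.approx(g2, abs=1e-8)

    def test_quadrature_cross_checks_analytic_on_quadratic(self, ctx):
        spec = harmonic_lambda_pair()
        st = CouplingState(0.3, 0.0)
        gq = quadrature_free_energy(spec, st, [(-1.0, 1.0)], ctx)
        assert gq == pytest.approx(analytic_free_energy(spec, st, ctx), abs=1e-6)

    def test_dimensionality_cap(self, ctx):
        spec = coupled_quadratic_2d()
        with pytest.raises(Exception):
            quadrature_free_energy(spec, CouplingState(0, 0), [(-1, 1)] * 4, ctx)


class TestClashProperties:
    def test_state_function_closure(self, clash_corners):
        diag = clash_corners[(1.0, 1.0)] - clash_corners[(0.0, 0.0)]
        edges = (clash_corners[(1.0, 0.0)] - clash_corners[(0.0, 0.0)]) + (
            clash_corners[(1.0, 1.0)] - clash_corners[(1.0, 0.0)]
        )
        assert diag == pytest.approx(edges, abs=1e-6)

    def test_strained_minimum_beyond_restraint_target(self, clash_system):
        spec = clash_system.spec
        xmin = clash_system.minimum(CouplingState(1.0, 1.0))
        assert abs(xmin[0]) > spec.restraint.target_distance + 0.1

    def test_core_penetration_is_rare(self, clash_system, ctx):
        # strain metric: the Boltzmann probability of penetrating the
        # strongly repulsive core (pair LJ above 10 kBT) stays below 5%
        spec = clash_system.spec
        c12 = math.sqrt(spec.grower_params.C12_B * spec.water_params.C12_B)
        c6 = math.sqrt(spec.grower_params.C6_B * spec.water_params.C6_B)

        def lj(r):
            return c12 / r**12 - c6 / r**6

        xs = np.linspace(-1.2, 1.2, 4801)
        energies = np.array(
            [clash_system.evaluate([x], CouplingState(1.0, 1.0)).energy for x in xs]
        )
        w = np.exp(-(energies - energies.min()) / ctx.kBT)
        p = w / w.sum()
        core = np.array([abs(x) > 1e-6 and lj(abs(x)) > 10 * ctx.kBT for x in xs])
        assert p[core].sum() < 0.05
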