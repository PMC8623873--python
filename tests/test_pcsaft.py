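"""PC-SAFT equation of state: term additivity, limits, derivative
consistency, association solver and independent-oracle equivalence."""

import numpy as np
import pytest

from nanosusp.constants import R_GAS
from nanosusp.pcsaft import (BinaryInteractionSet, Mixture,
                             PureComponentParams, combining_rules)

from reference_pcsaft import a_res_ref, liquid_density_ref

WATER = PureComponentParams("water", m=1.0, sigma=3.0, eps_k=366.0,
                            epsAB_k=2500.7, kappaAB=0.035, n_sites=2, Mw=18.015)
FEN = PureComponentParams("fenofibrate", m=3.85, sigma=4.76, eps_k=250.0,
                          Mw=360.831)
WATER_REF = {"m": 1.0, "sigma": 3.0, "eps_k": 366.0, "epsAB_k": 2500.7,
             "kappaAB": 0.035, "n_sites": 2}
FEN_REF = {"m": 3.85, "sigma": 4.76, "eps_k": 250.0}


class TestCombiningRules:
    def test_identity(self):
        cr = combining_rules(WATER, WATER, 0.0)
        assert cr["sigma_ij"] == 3.0 and cr["eps_ij_k"] == 366.0

    def test_arithmetic_mean_sigma(self):
        assert combining_rules(FEN, WATER)["sigma_ij"] == pytest.approx(3.88)

    def test_kij_annihilation(self):
        assert combining_rules(FEN, WATER, 0.999999999)["eps_ij_k"] == \
            pytest.approx(0.0, abs=1e-5)

    def test_kij_symmetric_and_bounded(self):
        ks = BinaryInteractionSet()
        ks.set("a", "b", 0.08)
        assert ks.get("b", "a") == 0.08
        with pytest.raises(ValueError):
            ks.set("a", "b", 1.5)


class TestAssociation:
    def test_no_association_when_kappa_zero(self):
        mix = Mixture([FEN])
        sol = mix.association_fractions(298.15, 5000.0, np.array([1.0]))
        assert sol.X["fenofibrate"] == 1.0
        assert np.all(sol.Delta == 0.0)

    def test_iterative_matches_closed_form_on_grid(self):
        """Damped successive substitution equals the quadratic closed form
        X = (-1+sqrt(1+4 rho Delta))/(2 rho Delta) for a pure 2B fluid."""
        mix = Mixture([WATER])
        # force the iterative path by bypassing the single-associator shortcut
        for T in (280.0, 300.0, 340.0, 360.0):
            for rho in (1000.0, 20000.0, 50000.0):
                sol = mix.association_fractions(T, rho, np.array([1.0]))
                rho_n = rho * 6.02214076e23 * 1e-30
                rd = rho_n * sol.Delta[0, 0]
                X_closed = (-1.0 + np.sqrt(1.0 + 4.0 * rd)) / (2.0 * rd)
                # iterate independently
                X_it = 1.0
                for _ in range(2000):
                    X_it = 0.5 * X_it + 0.5 / (1.0 + rd * X_it)
                assert sol.X["water"] == pytest.approx(X_closed, abs=1e-12)
                assert sol.X["water"] == pytest.approx(X_it, abs=1e-10)
                assert 0.0 < sol.X["water"] <= 1.0

    def test_cross_association_solver_consistency(self):
        """With a symmetric water/water-like binary and cross bonding on,
        the general fixed point reproduces the single-fluid closed form."""
        w2 = PureComponentParams("w2", m=1.0, sigma=3.0, eps_k=366.0,
                                 epsAB_k=2500.7, kappaAB=0.035, n_sites=2, Mw=18.015)
        mix = Mixture([WATER, w2],
                      assoc_pairs={("water", "water"), ("w2", "w2"), ("water", "w2")})
        pure = Mixture([WATER])
        rho, T = 40000.0, 300.0
        sol = mix.association_fractions(T, rho, np.array([0.5, 0.5]))
        ref = pure.association_fractions(T, rho, np.array([1.0]))
        assert sol.X["water"] == pytest.approx(ref.X["water"], abs=1e-9)
        assert sol.X["w2"] == pytest.approx(ref.X["water"], abs=1e-9)

    def test_high_temperature_limit(self):
        mix = Mixture([WATER])
        sol = mix.association_fractions(1e6, 30000.0, np.array([1.0]))
        assert sol.X["water"] == pytest.approx(1.0, abs=1e-4)

    def test_x_nonincreasing_in_density(self):
        mix = Mixture([WATER])
        xs = [mix.association_fractions(298.15, r, np.array([1.0])).X["water"]
              for r in np.linspace(100.0, 50000.0, 20)]
        assert np.all(np.diff(xs) <= 1e-15)


class TestResidualHelmholtz:
    def test_additivity_and_ideal_gas_limit(self, water_mixture):
        r = water_mixture.residual_helmholtz(298.15, 1e-6, np.array([1.0]))
        assert abs(r.a_hc) < 1e-8 and abs(r.a_disp) < 1e-8 and abs(r.a_assoc) < 1e-6
        r2 = water_mixture.residual_helmholtz(298.15, 50000.0, np.array([1.0]))
        assert r2.a_res == r2.a_hc + r2.a_disp + r2.a_assoc

    def test_packing_ceiling(self, water_mixture):
        with pytest.raises(ValueError, match="packing"):
            water_mixture.residual_helmholtz(298.15, 2e6, np.array([1.0]))

    def test_pressure_derivative_vs_finite_difference(self, fen_water):
        """Complex-step compressibility equals a central finite difference."""
        x = np.array([0.3, 0.7])
        for eta in (0.02, 0.2, 0.45):
            rho = fen_water.rho_from_eta(300.0, eta, x)
            P = fen_water.pressure(300.0, rho, x)
            h = rho * 1e-6
            a = lambda r: fen_water.residual_helmholtz(300.0, r, x).a_res
            dadr = (a(rho - 2 * h) - 8 * a(rho - h) + 8 * a(rho + h)
                    - a(rho + 2 * h)) / (12 * h)
            P_fd = (1.0 + rho * dadr) * rho * R_GAS * 300.0
            assert P == pytest.approx(P_fd, rel=1e-6)

    def test_terms_match_reference_oracle(self):
        """Term-by-term equality with the independent scalar transcription."""
        mix = Mixture([FEN, WATER])
        kij = {(0, 1): 0.0}
        for T in (280.0, 320.0, 360.0):
            for eta in (0.05, 0.35):
                for xf in (0.0, 0.2, 0.8):
                    x = np.array([xf, 1.0 - xf])
                    rho = mix.rho_from_eta(T, eta, x)
                    r = mix.residual_helmholtz(T, rho, x)
                    hc, disp, assoc = a_res_ref(T, rho, x, [FEN_REF, WATER_REF], kij)
                    assert r.a_hc == pytest.approx(hc, rel=1e-10, abs=1e-12)
                    assert r.a_disp == pytest.approx(disp, rel=1e-10, abs=1e-12)
                    assert r.a_assoc == pytest.approx(assoc, rel=1e-10, abs=1e-12)


class TestDensitySolve:
    def test_ideal_gas_limit(self, fen_water):
        rho = fen_water.density_solve(500.0, 100.0, [0.5, 0.5], "vapor")
        assert rho == pytest.approx(100.0 / (R_GAS * 500.0), rel=1e-3)

    def test_pressure_roundtrip(self, water_mixture):
        for phase in ("liquid", "vapor"):
            rho = water_mixture.density_solve(298.15, 101325.0, [1.0], phase)
            assert water_mixture.pressure(298.15, rho, [1.0]) == \
                pytest.approx(101325.0, rel=1e-8)

    def test_liquid_root_exceeds_vapor_root(self, water_mixture):
        rl = water_mixture.density_solve(298.15, 101325.0, [1.0], "liquid")
        rv = water_mixture.density_solve(298.15, 101325.0, [1.0], "vapor")
        assert rl > rv

    def test_water_density_vs_independent_oracle(self, water_mixture):
        """Liquid water density agrees with the independent implementation
        within 0.5% across temperature."""
        for T in (280.0, 298.15, 320.0, 360.0):
            rho = water_mixture.density_solve(T, 101325.0, [1.0], "liquid")
            rho_ref = liquid_density_ref(T, 101325.0, [1.0], [WATER_REF])
            assert rho == pytest.approx(rho_ref, rel=5e-3)

    def test_fen_water_binary_vs_oracle(self, fen_water):
        x = [0.1, 0.9]
        rho = fen_water.density_solve(310.0, 101325.0, x, "liquid")
        rho_ref = liquid_density_ref(310.0, 101325.0, x, [FEN_REF, WATER_REF])
        assert rho == pytest.approx(rho_ref, rel=5e-3)

    def test_water_density_magnitude_physical(self, water_mixture):
        """2B water parameters should land within a few percent of the
        experimental ambient liquid density (997 kg/m^3)."""
        rho = water_mixture.density_solve(298.15, 101325.0, [1.0], "liquid")
        assert rho * 18.015e-3 == pytest.approx(997.0, rel=0.05)


class TestFugacityActivity:
    def test_pure_component_limit(self, fen_water):
        fa = fen_water.fugacity_activity(300.0, 101325.0, np.array([1e-12, 1.0 - 1e-12]))
        assert fa["gamma"]["water"] == pytest.approx(1.0, abs=1e-6)

    def test_identical_components_ideal(self):
        a = PureComponentParams("a", m=2.0, sigma=3.5, eps_k=250.0, Mw=100.0)
        b = PureComponentParams("b", m=2.0, sigma=3.5, eps_k=250.0, Mw=100.0)
        mix = Mixture([a, b])
        for xa in (0.2, 0.5, 0.9):
            fa = mix.fugacity_activity(300.0, 101325.0, np.array([xa, 1.0 - xa]))
            assert fa["gamma"]["a"] == pytest.approx(1.0, abs=1e-8)
            assert fa["gamma"]["b"] == pytest.approx(1.0, abs=1e-8)

    def test_gibbs_duhem(self):
        """sum_i x_i dln(gamma_i)/dx = 0 along a binary composition path."""
        a = PureComponentParams("a", m=2.0, sigma=3.6, eps_k=280.0, Mw=150.0)
        b = PureComponentParams("b", m=1.5, sigma=3.1, eps_k=230.0, Mw=80.0)
        ks = BinaryInteractionSet()
        ks.set("a", "b", 0.03)
        mix = Mixture([a, b], kij=ks)
        T, P, h = 320.0, 101325.0, 1e-4

        def lng(xa):
            fa = mix.fugacity_activity(T, P, np.array([xa, 1.0 - xa]))
            return np.array([np.log(fa["gamma"]["a"]), np.log(fa["gamma"]["b"])])

        for xa in (0.3, 0.5, 0.7):
            d = (lng(xa + h) - lng(xa - h)) / (2 * h)
            gd = xa * d[0] + (1.0 - xa) * d[1]
            # normalize by the gradient magnitude
            assert abs(gd) <= 1e-6 + 1e-4 * np.abs(d).max()
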