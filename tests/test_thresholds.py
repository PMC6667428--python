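"""Steady-state cubics, asymptotic expansions and the threshold comparison suite."""

import numpy as np
import pytest

from pairsir import (
    CLOSURES,
    HouseholdParams,
    ModelParams,
    NoFeasibleRootError,
    ValidationError,
    cubic_coefficients,
    expansion,
    household_R_star,
    household_mu_D_from_phi,
    household_phi_from_mu_D,
    keeling_CSI_star,
    li_R0,
    miller_R0_regular,
    ngm_R0,
    quasi_equilibrium,
    solve_steady_state,
    threshold,
)
from pairsir.thresholds import threshold_table


class TestCubic:
    def test_simple_cubic_degenerates_to_quadratic_at_phi_zero(self):
        """At phi = 0 the cubic collapses to -n (alpha - (n-2)) (tau alpha + gamma)."""
        p = ModelParams(n=5, tau=0.7, gamma=1.3, phi=0.0)
        c = cubic_coefficients(p, "simple")
        assert c.c3 == 0.0
        expected = -p.n * np.polymul([1.0, -(p.n - 2)], [p.tau, p.gamma])
        np.testing.assert_allclose([c.c2, c.c1, c.c0], expected, rtol=1e-12)

    def test_compact_improved_intermediates(self):
        c = cubic_coefficients(ModelParams(n=5, tau=1.0, gamma=1.0, phi=0.2), "compact_improved")
        assert c.aux["A"] == pytest.approx(3.0 - 1.6)
        assert c.aux["B"] == pytest.approx(1.0)
        assert c.variable == "delta"

    def test_compact_improved_requires_positive_tau(self):
        with pytest.raises(ValidationError):
            cubic_coefficients(ModelParams(n=5, tau=0.0, gamma=1.0, phi=0.2), "compact_improved")

    def test_coefficients_continuous_in_phi(self):
        cs = [cubic_coefficients(ModelParams(n=5, phi=phi), "simple").as_array() for phi in (0.0, 1e-9)]
        np.testing.assert_allclose(cs[0], cs[1], atol=1e-7)


class TestSteadyStateRoot:
    def test_simple_unclustered_root(self):
        p = ModelParams(n=5, tau=1.0, gamma=1.0, phi=0.0)
        fast = solve_steady_state(cubic_coefficients(p, "simple"), p)
        assert fast.alpha == pytest.approx(3.0, abs=1e-12)  # -gamma/tau rejected
        assert fast.delta == pytest.approx(1.5, abs=1e-12)

    def test_compact_unclustered_delta_root(self):
        p = ModelParams(n=5, tau=1.0, gamma=1.0, phi=1e-12)
        fast = solve_steady_state(cubic_coefficients(p, "compact_improved"), p)
        assert fast.delta == pytest.approx(1.5, rel=1e-9)
        assert fast.alpha == pytest.approx(3.0, rel=1e-9)

    def test_simple_clustered_root_against_sign_scan(self, fig3_params):
        """Dense sign-change scan of the cubic on (0, n) as an independent oracle."""
        c = cubic_coefficients(fig3_params, "simple")
        grid = np.linspace(1e-6, fig3_params.n, 200_001)
        vals = np.polyval(c.as_array(), grid)
        crossings = grid[:-1][np.sign(vals[:-1]) != np.sign(vals[1:])]
        assert len(crossings) == 1
        fast = solve_steady_state(c, fig3_params)
        assert fast.alpha == pytest.approx(crossings[0], abs=1e-4)

    def test_no_feasible_root_raises(self):
        p = ModelParams(n=3, tau=1.0, gamma=1.0, phi=0.9)  # beyond (n-2)/(n-1) = 0.5
        with pytest.raises(NoFeasibleRootError):
            solve_steady_state(cubic_coefficients(p, "simple"), p)


class TestExpansion:
    def test_zeroth_order_is_unclustered(self):
        for closure in CLOSURES:
            e = expansion(ModelParams(n=7, tau=0.6, gamma=1.1, phi=0.0), closure)
            assert e.alpha_at_phi == pytest.approx(5.0)

    def test_simple_first_order_coefficient(self):
        e = expansion(ModelParams(n=5, tau=1.0, gamma=1.0, phi=0.3), "simple")
        assert e.order1 == pytest.approx(-(8.0 / 25.0) * (29.0 / 4.0))  # = -2.32
        assert e.value_at_phi == pytest.approx(3.0 - 0.3 * 2.32)

    def test_compact_improved_alpha_slope(self):
        e = expansion(ModelParams(n=5, tau=1.0, gamma=1.0, phi=0.4), "compact_improved")
        assert e.order0 == pytest.approx(1.5)  # delta_0 = 2 tau (n-2)/(gamma + tau(n-2))
        assert e.alpha_at_phi == pytest.approx(3.0 - 24.0 / 13.0 * 0.4)

    def test_requires_n_above_two(self):
        with pytest.raises(ValidationError):
            expansion(ModelParams(n=2, phi=0.1), "simple")


class TestThreshold:
    @pytest.mark.parametrize("closure", CLOSURES)
    def test_unclustered_threshold_closed_form(self, closure):
        p = ModelParams(n=5, tau=0.8, gamma=1.6, phi=1e-13 if closure == "compact_improved" else 0.0)
        res = threshold(p, closure, "cubic_numeric")
        assert res.R == pytest.approx(0.8 * 3.0 / 1.6, rel=1e-9)

    def test_asymptotic_simple_value_and_R_parametrisation(self):
        p = ModelParams(n=5, tau=1.0, gamma=1.0, phi=0.2)
        res = threshold(p, "simple", "asymptotic")
        assert res.R == pytest.approx(3.0 - 0.2 * 2.32)
        # the R-parametrised form R^c = R - phi a (tau/gamma)(aR+1)/(R+1) agrees
        assert res.extras["R_parametrised"] == pytest.approx(res.R, rel=1e-12)

    @pytest.mark.parametrize("closure", CLOSURES)
    def test_clustering_lowers_the_threshold(self, closure):
        """R^c <= R and R^cci <= R, and both decrease monotonically in phi."""
        R_flat = 3.0
        values = []
        for phi in (0.0, 0.15, 0.3, 0.45, 0.6):
            p = ModelParams(n=5, tau=1.0, gamma=1.0, phi=max(phi, 1e-13))
            values.append(threshold(p, closure, "cubic_numeric").R)
        assert all(v <= R_flat + 1e-9 for v in values)
        assert all(a > b for a, b in zip(values, values[1:]))


class TestKeelingCSI:
    def test_unclustered_closed_form(self):
        assert keeling_CSI_star(ModelParams(n=5, phi=0.0)) == pytest.approx(0.6)

    def test_equivalent_to_cubic_root(self):
        rng = np.random.default_rng(202)
        for _ in range(20):
            n = float(rng.integers(3, 11))
            phi = float(rng.uniform(0.0, 0.95) * (n - 2) / (n - 1))
            p = ModelParams(n=n, tau=float(rng.uniform(0.2, 2.0)), gamma=float(rng.uniform(0.3, 1.5)), phi=phi)
            alpha = solve_steady_state(cubic_coefficients(p, "simple"), p).alpha
            assert n * keeling_CSI_star(p) == pytest.approx(alpha, abs=1e-8)

    def test_infeasible_phi_raises(self):
        with pytest.raises(NoFeasibleRootError):
            keeling_CSI_star(ModelParams(n=3, phi=0.7))


class TestNGM:
    def test_unclustered_value(self):
        res = ngm_R0(ModelParams(n=5, tau=1.0, gamma=1.0, phi=0.0))
        assert res.R == pytest.approx(2.0)
        assert res.extras["r0"] == pytest.approx(2.0)

    def test_eigenvalue_matches_closed_form_rational_expression(self):
        """Leading eigenvalue of F V^{-1} vs the printed rational expression
        (independent code path)."""
        rng = np.random.default_rng(31)
        for _ in range(15):
            n = float(rng.integers(3, 11))
            phi = float(rng.uniform(0.0, 0.9) * (n - 2) / (n - 1))
            p = ModelParams(n=n, tau=float(rng.uniform(0.2, 2.0)), gamma=float(rng.uniform(0.3, 1.5)), phi=phi)
            qe = quasi_equilibrium(p, "simple", "root_find")
            res = ngm_R0(p, qe)
            closed_form = (
                p.tau * n * (n - 1) - p.tau * (n - 1) * (n - qe.alpha) * phi
            ) / (n * (p.tau + p.gamma) + p.tau * p.xi * qe.alpha * qe.delta * phi)
            assert res.R == pytest.approx(closed_form, abs=1e-10)

    def test_first_order_coefficient_matches_finite_difference(self):
        h = 1e-6
        base = ngm_R0(ModelParams(n=5, tau=1.3, gamma=0.7, phi=0.0))
        bumped = ngm_R0(ModelParams(n=5, tau=1.3, gamma=0.7, phi=h))
        assert (bumped.R - base.R) / h == pytest.approx(base.extras["r1"], rel=1e-3)


class TestLiMiller:
    def test_li_values_and_monotonicity(self):
        assert li_R0(ModelParams(n=5, tau=1, gamma=1, phi=0.0)).R == pytest.approx(2.0)
        vals = [li_R0(ModelParams(n=5, tau=1, gamma=1, phi=phi)).R for phi in np.linspace(0, 1, 6)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_miller_hand_value(self):
        assert miller_R0_regular(ModelParams(n=5, tau=1, gamma=1, phi=0.5)).R == pytest.approx(1.5)

    def test_zeroth_order_agreement_of_all_methods(self):
        p = ModelParams(n=8, tau=0.9, gamma=1.2, phi=0.0)
        r = p.tau * (p.n - 1) / (p.tau + p.gamma)
        assert li_R0(p).R == pytest.approx(r)
        assert miller_R0_regular(p).R == pytest.approx(r)
        assert ngm_R0(p).R == pytest.approx(r)

    def test_miller_equals_li_first_order_as_functions(self):
        """The percolation expansion and the motif-closure expansion coincide
        exactly as functions of (n, tau, gamma, phi)."""
        rng = np.random.default_rng(99)
        for _ in range(100):
            p = ModelParams(
                n=float(rng.integers(3, 12)),
                tau=float(rng.uniform(0.05, 3.0)),
                gamma=float(rng.uniform(0.1, 3.0)),
                phi=float(rng.uniform(0.0, 1.0)),
            )
            assert miller_R0_regular(p).R == pytest.approx(li_R0(p).extras["first_order"], abs=1e-10)


class TestHousehold:
    def test_equal_rates_escape_probability(self):
        hh = HouseholdParams(lambda_G=1.0, lambda_L=0.5, gamma=1.0, mu_D=4.0)
        res = household_R_star(hh)
        # M(lambda_G = gamma) = 1/2, so the global factor is 1/2
        assert res.R == pytest.approx(0.5 * ((1 + res.extras["mu_T"]) * 4.0 - 1.0))

    def test_full_clustering_means_no_global_contacts(self):
        assert household_mu_D_from_phi(1.0) == pytest.approx(0.0, abs=1e-12)

    def test_mu_D_phi_round_trip(self):
        for phi in np.linspace(0.01, 1.0, 50):
            assert household_phi_from_mu_D(household_mu_D_from_phi(phi)) == pytest.approx(phi, abs=1e-12)

    def test_decomposition_reconstructs_R_star(self):
        hh = HouseholdParams(lambda_G=0.8, lambda_L=1.7, gamma=1.0)
        for phi in (0.05, 0.3, 0.9):
            res = household_R_star(hh, phi=phi)
            recon = res.extras["T1"] + res.extras["T2"] * np.sqrt(1 + 8 / phi)
            assert res.R == pytest.approx(recon, abs=1e-12)

    def test_R_star_decreasing_in_phi(self):
        hh = HouseholdParams(lambda_G=1.0, lambda_L=1.0, gamma=1.0)
        vals = [household_R_star(hh, phi=phi).R for phi in np.linspace(0.05, 1.0, 20)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_phi_zero_rejected(self):
        with pytest.raises(ValidationError):
            household_R_star(HouseholdParams(lambda_G=1, lambda_L=1, gamma=1), phi=0.0)


def test_threshold_table_records_infeasible_rows():
    grid = [ModelParams(n=3, tau=1.0, gamma=1.0, phi=phi) for phi in (0.1, 0.9)]
    table = threshold_table(grid)
    assert set(table.columns) == {"n", "tau", "gamma", "phi", "closure", "method", "R", "valid"}
    bad = table[(table.phi == 0.9) & (table.closure == "simple") & (table.method == "cubic_numeric")]
    assert not bad["valid"].iloc[0] and np.isnan(bad["R"].iloc[0])
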