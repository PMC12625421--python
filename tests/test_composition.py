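"""Remainder density/concentration model, threshold solver and peeling fit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from huskmodel.composition import (
    KOREA_SEED,
    MaterialComposition,
    RegulatoryLimit,
    compliance_check,
    fit_peeling_series,
    mg_per_L_to_mg_per_kg,
    min_removal_for_limit,
    remainder_concentration,
    remainder_density,
    removal_result,
    simulate_removal_curve,
    whole_seed_concentration,
)
from huskmodel.errors import DomainError, EstimationError, InfeasibleError
from huskmodel.synthetic import gen_peeling_series

F_H, C_H, C_C = 0.10, 300.0, 2.0


class TestRemainderDensity:
    def test_intact_seed_is_1_05_rho_c(self):
        """10 % husk at 1.5x kernel density -> whole seed at 1.05 rho_c."""
        assert remainder_density(0.10, 1.0, 1.5, 0.0) == pytest.approx(1.05, abs=1e-12)

    def test_complete_husk_removal_gives_kernel_density(self):
        assert remainder_density(0.10, 1.0, 1.5, 0.10) == pytest.approx(1.0, abs=1e-12)
        assert remainder_density(0.25, 0.9, 1.4, 0.25) == pytest.approx(0.9, abs=1e-12)

    def test_halfway_value_hand_computed(self):
        # rho_H - (rho_H - rho_c) * V_C.max/V_r with V_C.max = 0.9, V_r = 0.95
        assert remainder_density(0.10, 1.0, 1.5, 0.05) == pytest.approx(
            1.5 - 0.5 * 0.9 / 0.95, rel=1e-12
        )
        assert remainder_density(0.10, 1.0, 1.5, 0.05) == pytest.approx(1.026316, abs=5e-7)

    def test_bounded_between_component_densities(self):
        for x in np.linspace(0.0, 0.10, 101):
            rho = remainder_density(0.10, 1.0, 1.5, x)
            assert 1.0 - 1e-12 <= rho <= 1.05 + 1e-12

    def test_over_extraction_returns_kernel_density(self):
        assert remainder_density(0.10, 1.0, 1.5, 0.5) == 1.0

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            remainder_density(0.10, 1.0, 1.5, 1.5)
        with pytest.raises(DomainError):
            remainder_density(0.10, -1.0, 1.5, 0.0)


class TestRemainderConcentration:
    @pytest.mark.parametrize(
        "x, expected",
        [(0.0, 31.8), (0.10, 2.0), (0.09084745762711866, 5.0)],
    )
    def test_reference_points(self, x, expected):
        assert remainder_concentration(F_H, C_H, C_C, x) == pytest.approx(expected, abs=1e-9)

    def test_boundary_is_exact(self):
        """At x = f_H the (1-f_H)/(1-x) factor is exactly 1: pure kernel."""
        assert remainder_concentration(F_H, C_H, C_C, F_H) == 2.0

    def test_strictly_decreasing_on_husk_branch(self):
        xs = np.linspace(0.0, F_H, 200)
        cs = [remainder_concentration(F_H, C_H, C_C, x) for x in xs]
        assert np.all(np.diff(cs) < 0)

    @given(
        f_H=st.floats(0.01, 0.6),
        c_h=st.floats(10.0, 1000.0),
        c_c=st.floats(0.0, 9.0),
        x=st.floats(0.0, 0.99),
    )
    def test_bounded_by_components(self, f_H, c_h, c_c, x):
        c = remainder_concentration(f_H, c_h, c_c, x)
        assert c_c - 1e-9 <= c <= c_h + 1e-9

    def test_shares_kernel_with_density_formula(self):
        """Concentration is the density formula under rho -> C substitution."""
        for x in np.linspace(0.0, 0.10, 11):
            assert remainder_concentration(0.10, 1.5, 1.0, x) == remainder_density(
                0.10, 1.0, 1.5, x
            )

    def test_nothing_remains_is_an_error(self):
        with pytest.raises(DomainError):
            remainder_concentration(F_H, C_H, C_C, 1.0)


class TestWholeSeed:
    def test_volume_weighted_default(self):
        assert whole_seed_concentration(F_H, C_H, C_C) == pytest.approx(31.8, rel=1e-12)

    def test_huskless_seed_is_kernel(self):
        assert whole_seed_concentration(0.0, C_H, C_C) == C_C

    def test_mass_weighted_variant(self):
        vol, mass = whole_seed_concentration(F_H, C_H, C_C, rho_c=1.0, rho_H=1.5)
        assert vol == pytest.approx(31.8, rel=1e-12)
        hand = (0.1 * 1.5 * 300 + 0.9 * 1.0 * 2) / (0.1 * 1.5 + 0.9 * 1.0)
        assert mass == pytest.approx(hand, rel=1e-12)

    def test_matches_remainder_at_zero(self):
        assert whole_seed_concentration(F_H, C_H, C_C) == remainder_concentration(
            F_H, C_H, C_C, 0.0
        )


class TestThresholdSolver:
    def test_korean_seed_limit_needs_9_1_percent(self):
        x_star = min_removal_for_limit(F_H, C_H, C_C, KOREA_SEED)
        assert round(100.0 * x_star, 1) == 9.1
        assert remainder_concentration(F_H, C_H, C_C, x_star) == pytest.approx(5.0, abs=1e-9)

    def test_already_compliant_seed_needs_nothing(self):
        assert min_removal_for_limit(F_H, C_H, C_C, 31.8) == 0.0
        assert min_removal_for_limit(F_H, C_H, C_C, 100.0) == 0.0

    def test_limit_approaching_kernel_needs_full_husk(self):
        x = min_removal_for_limit(F_H, C_H, C_C, C_C * (1 + 1e-9))
        assert x == pytest.approx(F_H, abs=1e-6)

    def test_limit_below_kernel_is_infeasible(self):
        with pytest.raises(InfeasibleError):
            min_removal_for_limit(F_H, C_H, C_C, 1.0)

    @given(
        f_H=st.floats(0.02, 0.5),
        c_h=st.floats(50.0, 500.0),
        c_c=st.floats(0.1, 4.0),
        frac=st.floats(0.05, 0.95),
    )
    def test_closed_form_agrees_with_bisection(self, f_H, c_h, c_c, frac):
        c0 = whole_seed_concentration(f_H, c_h, c_c)
        limit = c_c + frac * (c0 - c_c)
        a = min_removal_for_limit(f_H, c_h, c_c, limit)
        b = min_removal_for_limit(f_H, c_h, c_c, limit, method="bisect")
        assert a == pytest.approx(b, abs=1e-10)

    def test_closed_form_vs_bisection_bulk(self):
        rng = np.random.default_rng(7)
        n = 10_000
        f_H = rng.uniform(0.02, 0.5, n)
        c_h = rng.uniform(50, 500, n)
        c_c = rng.uniform(0.1, 4.0, n)
        lim = c_c + rng.uniform(0.05, 0.95, n) * (
            f_H * c_h + (1 - f_H) * c_c - c_c
        )
        closed = 1.0 - (c_h - c_c) * (1.0 - f_H) / (c_h - lim)
        # spot-check a random 100 against the Brent solver (full 10k closed form above)
        for i in rng.choice(n, 100, replace=False):
            b = min_removal_for_limit(f_H[i], c_h[i], c_c[i], lim[i], method="bisect")
            assert closed[i] == pytest.approx(b, abs=1e-10)


class TestRemovalCurve:
    def test_single_point_grids(self):
        assert simulate_removal_curve(F_H, C_H, C_C, [0.0])["C_remain_THC"].iloc[0] == (
            pytest.approx(31.8)
        )
        assert simulate_removal_curve(F_H, C_H, C_C, [F_H])["C_remain_THC"].iloc[0] == 2.0

    def test_curve_shape_and_crossing(self):
        """Strictly decreasing; the 5 mg/kg crossing lies inside (0.090, 0.091)."""
        grid = np.linspace(0.0, F_H, 101)
        df = simulate_removal_curve(F_H, C_H, C_C, grid)
        c = df["C_remain_THC"].to_numpy()
        assert np.all(np.diff(c) < 0)
        assert c[0] == pytest.approx(whole_seed_concentration(F_H, C_H, C_C))
        assert c[-1] == pytest.approx(C_C)
        crossing = df["x"][c <= 5.0].iloc[0]
        assert 0.090 < crossing <= 0.091


class TestCompliance:
    def test_kernel_passes_seed_limit(self):
        assert compliance_check(2.0, KOREA_SEED).passed

    def test_boundary_is_inclusive(self):
        report = compliance_check(5.0, KOREA_SEED)
        assert report.passed and report.margin == 0.0

    def test_whole_seed_fails(self):
        assert not compliance_check(31.8, KOREA_SEED).passed

    def test_limit_must_be_positive(self):
        with pytest.raises(DomainError):
            RegulatoryLimit("x", "seed", 0.0)

    def test_mg_per_L_conversion(self):
        assert mg_per_L_to_mg_per_kg(10.0, 0.92) == pytest.approx(10.0 / 0.92)


class TestRemovalResult:
    def test_regimes(self):
        comp = MaterialComposition(rho_c=1.0, rho_H=1.5, C_H_THC=300, C_C_THC=2, f_H=0.10)
        assert removal_result(comp, 0.05).regime == "partial_husk"
        assert removal_result(comp, 0.10).regime == "exact_husk"
        assert removal_result(comp, 0.20).regime == "over_extracted"
        assert removal_result(comp, 0.20).C_remain_THC == 2.0


class TestPeelingFit:
    def test_noiseless_recovery(self):
        df = gen_peeling_series(np.linspace(0.0, 0.12, 6), noise_sd=0.0)
        fit = fit_peeling_series(df)
        assert fit.C_H == pytest.approx(300.0, rel=1e-6)
        assert fit.C_C == pytest.approx(2.0, rel=1e-6)
        assert fit.f_H == pytest.approx(0.10, rel=1e-6)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-6)

    def test_noisy_estimates_near_truth(self):
        df = gen_peeling_series(np.linspace(0.0, 0.12, 50), noise_sd=1.0, seed=42)
        fit = fit_peeling_series(df, n_boot=100, random_state=0)
        assert abs(fit.C_H - 300.0) <= 3 * fit.se_C_H
        assert abs(fit.C_C - 2.0) <= 3 * fit.se_C_C
        assert abs(fit.f_H - 0.10) <= 3 * fit.se_f_H
        lo, hi = fit.bootstrap_ci["C_H"]
        assert lo < fit.C_H < hi

    def test_under_determined_series(self):
        with pytest.raises(EstimationError):
            fit_peeling_series(pd.DataFrame({"x": [0.0, 0.05], "C": [31.8, 17.0]}))

    def test_constant_x_is_singular(self):
        df = pd.DataFrame({"x": [0.05] * 6, "C": np.linspace(17, 18, 6)})
        with pytest.raises(EstimationError):
            fit_peeling_series(df)

    def test_series_without_plateau_is_non_identifiable(self):
        """On the husk branch alone, (C_C, f_H) share one degree of freedom."""
        df = gen_peeling_series(np.linspace(0.0, 0.08, 20), noise_sd=0.0)
        with pytest.raises(EstimationError):
            fit_peeling_series(df)
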