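"""Cell-level forward model: closed forms, roots, and their oracles."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from phytoalloc.core import (
    allocation_rules,
    allocation_state,
    chl_coefficients,
    chl_to_c,
    mu_max,
    mu_max_coefficients,
    n_to_c,
    n_to_p,
    nc_coefficients,
    p_to_c,
    pc_coefficients,
    photosynthesis_rate,
)
from phytoalloc.errors import (
    DomainError,
    InfeasibleAllocationError,
    SingularLightError,
)
from phytoalloc.params import ModelParams


def closure_residual(mu, i, params, ratios):
    """Independent carbon-closure residual via pool-by-pool assembly."""
    st = allocation_state(mu, i, params, ratios)
    return 1.0 - st.carbon_sum()


class TestPhotosynthesis:
    def test_identities(self, params):
        assert photosynthesis_rate(0.0, params) == 0.0
        assert photosynthesis_rate(1e9, params) == pytest.approx(params.v_i_max)
        half = math.log(2) / params.a_i
        assert photosynthesis_rate(half, params) == pytest.approx(params.v_i_max / 2)

    def test_strictly_increasing_and_bounded(self, params):
        i = np.linspace(0, 2000, 400)
        v = photosynthesis_rate(i, params)
        assert (np.diff(v) > 0).all()
        assert (v <= params.v_i_max).all()

    def test_negative_light_rejected(self, params):
        with pytest.raises(DomainError):
            photosynthesis_rate(-1.0, params)


class TestChlToC:
    def test_intercept_is_maintenance_over_photosynthesis(self, params):
        v = photosynthesis_rate(80.0, params)
        assert chl_to_c(0.0, 80.0, params) == pytest.approx(params.m / v)

    def test_full_allocation_limit(self, params):
        # with no maintenance, mu = v_I/(1+E) puts every carbon in the
        # chlorophyll balance: Q_C_Chl = 1
        p = params.replace(m=0.0)
        v = photosynthesis_rate(100.0, p)
        assert chl_to_c(v / (1 + p.e), 100.0, p) == pytest.approx(1.0)

    def test_against_independent_evaluation(self):
        # second implementation straight from the steady-state solution
        p = ModelParams(m=0.1, v_i_max=10.0, a_i=0.01, e=0.5)
        v = 10.0 * (1.0 - math.exp(-0.01 * 100.0))
        expected = (1.0 + 0.5) / v * 1.0 + 0.1 / v
        assert chl_to_c(1.0, 100.0, p) == pytest.approx(expected, rel=1e-14)

    def test_steady_state_residual_is_zero(self, params):
        for mu, i in [(0.0, 20.0), (0.4, 62.0), (1.0, 300.0)]:
            v = photosynthesis_rate(i, params)
            q = chl_to_c(mu, i, params)
            assert v * q - (1 + params.e) * mu - params.m == pytest.approx(0.0, abs=1e-12)

    def test_exactly_linear_in_mu(self, params):
        mus = np.linspace(0, 1, 21)
        q = chl_to_c(mus, 62.0, params)
        assert np.all(np.abs(np.diff(q, 2)) < 1e-15)

    def test_coefficients_decrease_with_light(self, params):
        i = np.linspace(5, 500, 100)
        a, b = chl_coefficients(i, params)
        assert (np.diff(a) < 0).all()
        assert (np.diff(b) < 0).all()

    def test_zero_light_singular(self, params):
        with pytest.raises(SingularLightError):
            chl_to_c(0.5, 0.0, params)


class TestAllocationRules:
    def test_zero_growth_leaves_minimum_rna(self, params, ratios):
        r = allocation_rules(0.0, 0.03, 0.4, params, ratios)
        assert r.q_p_rna == params.q_p_rna_min
        assert r.q_c_pro_bio == 0.0

    def test_proportional_to_chlorophyll(self, params, ratios):
        r = allocation_rules(0.5, 0.0, 0.4, params, ratios)
        assert r.q_c_pro_pho == 0.0
        assert r.q_p_thy == 0.0

    def test_biosynthetic_protein_linear(self, params, ratios):
        r1 = allocation_rules(0.3, 0.03, 0.4, params, ratios)
        r2 = allocation_rules(0.6, 0.03, 0.4, params, ratios)
        assert r2.q_c_pro_bio == pytest.approx(2 * r1.q_c_pro_bio)

    def test_carbon_equivalents_use_stoichiometry(self, params, ratios):
        r = allocation_rules(0.5, 0.03, 0.4, params, ratios)
        assert r.q_c_plip_thy == pytest.approx(ratios.y_plip_cp * r.q_p_thy)
        assert r.q_c_rna == pytest.approx(ratios.y_rna_cp * r.q_p_rna)


class TestMuMax:
    @pytest.mark.parametrize("i", [15.0, 62.0, 144.0, 600.0])
    def test_root_matches_closure_bisection(self, i, params, ratios):
        """The quadratic root equals the bracketing-root of the
        independently assembled carbon-closure residual."""
        oracle = brentq(
            lambda mu: closure_residual(mu, i, params, ratios),
            0.0, 20.0, xtol=1e-12,
        )
        assert mu_max(i, params, ratios) == pytest.approx(oracle, abs=1e-8)

    def test_back_substitution_residual(self, params, ratios):
        for i in (20.0, 90.0, 250.0):
            a, b, c = mu_max_coefficients(i, params, ratios)
            mu = mu_max(i, params, ratios)
            assert abs(a * mu * mu + b * mu + c) < 1e-10

    def test_zero_carbon_storage_at_mu_max(self, params, ratios):
        for i in (20.0, 90.0, 250.0):
            mu = mu_max(i, params, ratios)
            assert closure_residual(mu, i, params, ratios) == pytest.approx(0.0, abs=1e-10)

    def test_sign_analysis_unique_positive_root(self, params, ratios):
        a, b, c = mu_max_coefficients(62.0, params, ratios)
        assert a > 0 and c < 0
        roots = np.roots([a, b, c])
        assert (roots > 0).sum() == 1

    def test_infeasible_light_raises(self, params, ratios):
        # at very low light, maintenance plus fixed pools exceed the budget
        with pytest.raises(InfeasibleAllocationError):
            mu_max(0.5, params, ratios)

    def test_nondecreasing_and_saturating_in_light(self, params, ratios):
        i = np.linspace(10, 3000, 200)
        mx = np.array([mu_max(x, params, ratios) for x in i])
        assert (np.diff(mx) > -1e-12).all()
        assert mx[-1] - mx[len(mx) // 2] < 0.05 * mx[-1]

    def test_saturates_at_lower_light_than_photosynthesis(self, params, ratios):
        """Investment in photosynthetic apparatus makes the growth ceiling
        saturate earlier in light than the photosynthesis law itself."""
        asymptote = mu_max(1e7, params, ratios)
        i95_mu = brentq(
            lambda i: mu_max(i, params, ratios) - 0.95 * asymptote, 5.0, 1e7
        )
        i95_v = -math.log(0.05) / params.a_i
        assert i95_mu <= i95_v


class TestElementalRatios:
    @pytest.mark.parametrize("i", [20.0, 62.0, 144.0])
    def test_closed_form_equals_pool_sum(self, i, params, ratios):
        mx = mu_max(i, params, ratios)
        for mu in np.linspace(0, mx, 9):
            st = allocation_state(mu, i, params, ratios)
            assert n_to_c(mu, i, params, ratios) == pytest.approx(st.n_to_c, abs=1e-12)
            assert p_to_c(mu, i, params, ratios) == pytest.approx(st.p_to_c, abs=1e-12)

    def test_intercepts_at_zero_growth(self, params, ratios):
        _, _, c_n = nc_coefficients(62.0, params, ratios)
        _, _, c_p = pc_coefficients(62.0, params, ratios)
        assert n_to_c(0.0, 62.0, params, ratios) == pytest.approx(c_n)
        assert p_to_c(0.0, 62.0, params, ratios) == pytest.approx(c_p)

    def test_no_rna_slope_makes_nc_linear(self, params, ratios):
        p = params.replace(a_rna_p=0.0)
        a_n, _, _ = nc_coefficients(62.0, p, ratios)
        assert a_n == 0.0
        mus = np.linspace(0, 0.5, 11)
        vals = [n_to_c(m, 62.0, p, ratios, check_feasible=False) for m in mus]
        assert np.all(np.abs(np.diff(vals, 2)) < 1e-15)

    def test_no_rna_no_thylakoid_makes_pc_constant(self, params, ratios):
        p = params.replace(a_rna_p=0.0, a_pho_p_chl=0.0)
        vals = [p_to_c(m, 62.0, p, ratios, check_feasible=False)
                for m in np.linspace(0, 0.5, 7)]
        assert np.ptp(vals) < 1e-15

    def test_linear_nc_approximation_gap_is_minor_pools(self, params, ratios):
        """The protein-only linear N:C underestimates the full form by
        exactly the chlorophyll, RNA, and DNA nitrogen."""
        i, mu = 62.0, 0.4
        a_chl, b_chl = chl_coefficients(i, params)
        approx = ratios.y_pro_nc * (
            (a_chl * params.a_pho + params.a_bio) * mu
            + (b_chl * params.a_pho + params.q_c_pro_other)
        )
        st = allocation_state(mu, i, params, ratios)
        minor = st.q_n_chl + st.q_n_rna + st.q_n_dna
        assert n_to_c(mu, i, params, ratios) - approx == pytest.approx(minor, rel=1e-12)

    def test_protein_only_growth_ceiling_gap_is_chlorophyll(self, params, ratios):
        """With RNA and thylakoid-lipid carbon zeroed, the growth ceiling
        neglecting chlorophyll carbon exceeds the full root by exactly
        Q_C_Chl(mu_full) / (A_Pho A_Chl + A_Bio)."""
        p = params.replace(a_rna_p=0.0, q_p_rna_min=0.0, a_pho_p_chl=0.0)
        i = 62.0
        a_chl, b_chl = chl_coefficients(i, p)
        q_other = p.q_c_pro_other + p.q_c_dna + p.q_c_other
        v = photosynthesis_rate(i, p)
        approx = ((1 - q_other) * v - p.a_pho * p.m) / (
            p.a_bio * v + p.a_pho * (1 + p.e)
        )
        full = mu_max(i, p, ratios)
        gap = chl_to_c(full, i, p) / (p.a_pho * a_chl + p.a_bio)
        assert approx - full == pytest.approx(gap, rel=1e-10)

    def test_infeasible_growth_rejected(self, params, ratios):
        mx = mu_max(62.0, params, ratios)
        with pytest.raises(InfeasibleAllocationError):
            n_to_c(mx * 1.05, 62.0, params, ratios)
        with pytest.raises(InfeasibleAllocationError):
            p_to_c(mx * 1.05, 62.0, params, ratios)

    def test_n_to_p_identities(self, params, ratios):
        assert n_to_p(0.3, 62.0, params, ratios) == pytest.approx(
            n_to_c(0.3, 62.0, params, ratios) / p_to_c(0.3, 62.0, params, ratios)
        )
        with pytest.raises(DomainError):
            # a zero P:C denominator must be refused
            p = params.replace(a_rna_p=0.0, q_p_rna_min=0.0, a_pho_p_chl=0.0,
                               q_p_other=0.0, q_c_dna=0.0)
            n_to_p(0.3, 62.0, p, ratios)
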