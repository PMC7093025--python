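"""Culture-level layer: limitation, storage caps, carbon closure, biomass."""

import numpy as np
import pytest

from phytoalloc.chemostat import (
    Environment,
    apply_storage,
    biomass_if_limited,
    close_carbon,
    determine_limitation,
    evaluate_batch,
    solve_culture,
)
from phytoalloc.core import (
    allocation_state,
    chl_coefficients,
    mu_max,
    n_to_c,
    p_to_c,
)
from phytoalloc.errors import (
    ConsistencyError,
    DegenerateFeedError,
    DomainError,
    InfeasibleAllocationError,
    WashoutError,
)
from tests.conftest import random_conditions


def env_at(i=62.0, n_in=0.8, p_in=0.05, d=0.3):
    return Environment(i=i, n_in=n_in, p_in=p_in, d=d)


class TestBiomass:
    def test_simple_division(self):
        assert biomass_if_limited("N", env_at(n_in=0.5), 0.1) == pytest.approx(5.0)
        assert biomass_if_limited("P", env_at(p_in=0.01), 0.005) == pytest.approx(2.0)

    def test_zero_quota_rejected(self):
        with pytest.raises(DomainError):
            biomass_if_limited("N", env_at(), 0.0)

    def test_biomass_decreases_with_growth_under_n_limitation(self, params, ratios):
        # faster growth needs a larger N quota, so the same feed supports
        # less carbon biomass
        mus = np.linspace(0.05, 0.6, 8)
        q = [n_to_c(m, 62.0, params, ratios) for m in mus]
        b = [biomass_if_limited("N", env_at(d=m), qi) for m, qi in zip(mus, q)]
        assert (np.diff(b) < 0).all()


class TestLimitation:
    def test_inequality_rule(self):
        # required N:P = 15
        assert determine_limitation(env_at(n_in=10.0, p_in=1.0), 0.15, 0.01) == "N"
        assert determine_limitation(env_at(n_in=20.0, p_in=1.0), 0.15, 0.01) == "P"

    def test_tie_breaks_to_nitrogen(self):
        assert determine_limitation(env_at(n_in=15.0, p_in=1.0), 0.15, 0.01) == "N"

    def test_degenerate_feed(self):
        with pytest.raises(DegenerateFeedError):
            determine_limitation(env_at(n_in=0.0, p_in=0.0), 0.15, 0.01)

    def test_matches_biomass_argmin(self, params, ratios):
        """The feed-ratio rule always picks the element whose
        single-element biomass is smaller."""
        rng = np.random.default_rng(3)
        for _ in range(1000):
            qn = rng.uniform(0.02, 0.3)
            qp = rng.uniform(0.001, 0.03)
            env = env_at(n_in=rng.uniform(0.01, 2.0), p_in=rng.uniform(0.001, 0.2))
            by_rule = determine_limitation(env, qn, qp)
            b_n = biomass_if_limited("N", env, qn)
            b_p = biomass_if_limited("P", env, qp)
            by_argmin = "N" if b_n <= b_p else "P"
            assert by_rule == by_argmin


class TestStorage:
    def test_phosphorus_cap_binds(self, params, ratios):
        # a P-rich feed pushes the potential quota past the total-P cap
        st = allocation_state(0.8, 144.0, params, ratios, limitation="N")
        st = apply_storage(env_at(i=144.0, d=0.8, p_in=0.15), st, params, ratios)
        assert st.p_to_c == pytest.approx(params.q_p_max)
        assert st.q_p_sto > 0
        assert st.q_n_sto == 0.0

    def test_exact_feed_ratio_gives_zero_storage(self, params, ratios):
        mu, i = 0.3, 62.0
        qn = n_to_c(mu, i, params, ratios)
        qp = p_to_c(mu, i, params, ratios)
        env = env_at(i=i, d=mu, n_in=0.8, p_in=0.8 * qp / qn)  # feed at required N:P
        st = allocation_state(mu, i, params, ratios, limitation="N")
        st = apply_storage(env, st, params, ratios)
        assert st.q_p_sto == pytest.approx(0.0, abs=1e-15)

    def test_nitrogen_storage_cap_and_carbon_cost(self, params, ratios):
        st = allocation_state(0.3, 62.0, params, ratios, limitation="P")
        st = apply_storage(env_at(p_in=0.01, d=0.3), st, params, ratios)
        assert st.q_n_sto == pytest.approx(params.q_n_sto_max)
        assert st.q_c_nsto == pytest.approx(ratios.y_nsto_cn * st.q_n_sto)
        assert st.q_p_sto == 0.0

    def test_impossible_nonstorage_quota_raises(self, params, ratios):
        # a total-P cap below the functional P requirement cannot be met
        bad = params.replace(q_p_max=1e-4)
        st = allocation_state(0.3, 62.0, bad, ratios, limitation="N")
        with pytest.raises(ConsistencyError):
            apply_storage(env_at(d=0.3), st, bad, ratios)


class TestClosure:
    def test_pools_sum_to_one(self, params, ratios):
        st = close_carbon(allocation_state(0.3, 62.0, params, ratios))
        assert st.carbon_sum() == pytest.approx(1.0, abs=1e-15)

    def test_zero_growth_intercept(self, params, ratios):
        _, b_chl = chl_coefficients(62.0, params)
        st = close_carbon(allocation_state(0.0, 62.0, params, ratios))
        expected = (
            1.0
            - b_chl * (1 + params.a_pho + ratios.y_plip_cp * params.a_pho_p_chl)
            - params.q_c_pro_other - params.q_c_dna - params.q_c_other
            - ratios.y_rna_cp * params.q_p_rna_min
        )
        assert st.q_c_csto == pytest.approx(expected, abs=1e-14)

    def test_zero_storage_pool_at_mu_max(self, params, ratios):
        mx = mu_max(62.0, params, ratios)
        st = close_carbon(allocation_state(mx, 62.0, params, ratios))
        assert st.q_c_csto == pytest.approx(0.0, abs=1e-10)


class TestSolveCulture:
    def test_washout_above_mu_max(self, params, ratios):
        mx = mu_max(62.0, params, ratios)
        with pytest.raises(WashoutError) as err:
            solve_culture(env_at(d=mx * 1.01), params, ratios)
        assert err.value.mu_max == pytest.approx(mx)

    def test_near_ceiling_state_has_little_storage(self, params, ratios):
        mx = mu_max(62.0, params, ratios)
        st, _ = solve_culture(env_at(d=0.999 * mx), params, ratios)
        assert st.q_c_csto < 0.01

    def test_storage_only_for_nonlimiting_element(self, params, ratios):
        st_n, _ = solve_culture(env_at(p_in=0.05, d=0.3), params, ratios)
        assert st_n.limitation == "N" and st_n.q_n_sto == 0.0
        st_p, _ = solve_culture(env_at(p_in=0.005, d=0.3), params, ratios)
        assert st_p.limitation == "P" and st_p.q_p_sto == 0.0

    def test_steady_state_balances(self, params, ratios):
        """Residuals of the culture ODEs vanish with the returned state."""
        env = env_at(d=0.3)
        st, biomass = solve_culture(env, params, ratios)
        mu = env.d
        q_lim = st.n_to_c - st.q_n_sto if st.limitation == "N" else st.p_to_c - st.q_p_sto
        uptake = mu * q_lim  # V = mu Q at steady state
        feed = env.n_in if st.limitation == "N" else env.p_in
        # nutrient balance: D*feed - V*[C] = 0 (residual nutrient ~ 0)
        assert env.d * feed - uptake * biomass == pytest.approx(0.0, abs=1e-12)
        # quota balance: dQ/dt = V - mu Q = 0
        assert uptake - mu * q_lim == 0.0

    def test_conservation_over_random_conditions(self, params, ratios):
        rng = np.random.default_rng(11)
        for i, d, n_in, p_in in random_conditions(rng, params, ratios, 50):
            try:
                st, _ = solve_culture(Environment(i, n_in, p_in, d), params, ratios)
            except (ConsistencyError, InfeasibleAllocationError):
                continue  # N-storage carbon can exhaust the budget near the ceiling
            assert st.carbon_sum() == pytest.approx(1.0, abs=1e-12)
            assert st.n_to_c == pytest.approx(
                n_to_c(d, i, params, ratios, q_n_sto=st.q_n_sto), abs=1e-12
            )
            assert st.p_to_c == pytest.approx(
                p_to_c(d, i, params, ratios, q_p_sto=st.q_p_sto), abs=1e-12
            )


def test_evaluate_batch_flags_failures(params, ratios):
    import pandas as pd

    mx = mu_max(62.0, params, ratios)
    df = pd.DataFrame({
        "i": [62.0, 62.0], "d": [0.3, mx * 1.5],
        "n_in": [0.8, 0.8], "p_in": [0.05, 0.05],
    })
    out = evaluate_batch(df, params, ratios)
    assert list(out["status"]) == ["ok", "washout"]
    assert out.loc[0, "limitation"] == "N"
    assert out.loc[0, "n_to_p"] == pytest.approx(
        out.loc[0, "n_to_c"] / out.loc[0, "p_to_c"]
    )
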