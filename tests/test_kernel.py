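"""Rate matrices, propagators, distributions, IICR, closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

import nssc
from conftest import diff, random_model, same


class TestBuildRateMatrix:
    def test_two_island_rows(self):
        """Direct application of the per-event rates for a 2-island model."""
        sp = nssc.enumerate_states(2, 2)
        Q = nssc.build_rate_matrix(nssc.n_island(2, 3.0), sp).entries
        M = 3.0
        assert np.allclose(Q[sp.index0((2, 0))], [-1 - M, M, 0, 1])
        assert np.allclose(Q[sp.index0((1, 1))], [M / 2, -M, M / 2, 0])
        assert np.allclose(Q[sp.index0((0, 2))], [0, M, -1 - M, 1])

    def test_single_deme(self):
        sp = nssc.enumerate_states(2, 1)
        Q = nssc.build_rate_matrix(nssc.ModelEpoch([2.0], [[0.0]]), sp).entries
        assert np.allclose(Q, [[-0.5, 0.5], [0, 0]])

    def test_dimension_mismatch(self):
        with pytest.raises(nssc.ConfigError):
            nssc.build_rate_matrix(nssc.n_island(3, 1.0), nssc.enumerate_states(2, 4))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_generator_invariants_random(self, key):
        rng = np.random.default_rng(key)
        m = random_model(rng)
        sp = nssc.enumerate_states(2, m.n)
        Q = nssc.build_rate_matrix(m, sp).entries
        off = Q.copy()
        np.fill_diagonal(off, 0)
        assert np.all(off >= 0)
        assert np.abs(Q.sum(axis=1)).max() < 1e-12 * max(1, np.abs(Q).max())
        assert np.all(Q[-1] == 0)


class TestPropagator:
    def test_identity_at_zero(self):
        Q = nssc.reduced_n_island(4, 1.0)
        assert np.allclose(nssc.propagator(Q, 0.0).entries, np.eye(3))

    def test_single_deme_closed_form(self):
        sp = nssc.enumerate_states(2, 1)
        Q = nssc.build_rate_matrix(nssc.ModelEpoch([1.0], [[0.0]]), sp)
        for t in (0.3, 1.7):
            P = nssc.propagator(Q, t).entries
            assert np.allclose(P, [[np.exp(-t), 1 - np.exp(-t)], [0, 1]])

    def test_negative_time_rejected(self):
        with pytest.raises(nssc.ConfigError):
            nssc.propagator(nssc.reduced_n_island(3, 1.0), -0.1)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_semigroup_and_stochastic(self, key):
        rng = np.random.default_rng(key)
        m = random_model(rng)
        sp = nssc.enumerate_states(2, m.n)
        Q = nssc.build_rate_matrix(m, sp)
        t, u = rng.uniform(0.05, 3.0, 2)
        Pt = nssc.propagator(Q, t).entries
        Pu = nssc.propagator(Q, u).entries
        Ptu = nssc.propagator(Q, t + u).entries
        assert np.abs(Ptu - Pt @ Pu).max() < 1e-10
        assert np.abs(Pt.sum(axis=1) - 1).max() < 1e-10
        assert Pt.min() > -1e-12


class TestScenarioPropagator:
    def test_identical_epochs_collapse(self):
        e = nssc.n_island(3, 1.0)
        sc = nssc.make_scenario([e, e], [0.8])
        sp = nssc.enumerate_states(2, 3)
        Q = nssc.build_rate_matrix(e, sp)
        for t in (0.3, 0.8, 2.5):
            assert np.allclose(nssc.scenario_propagator(sc, sp, t).entries,
                               nssc.propagator(Q, t).entries, atol=1e-12)

    def test_before_first_change(self, single_deme_step):
        sp = nssc.enumerate_states(2, 1)
        P = nssc.scenario_propagator(single_deme_step, sp, 0.6).entries
        assert P[0, 1] == pytest.approx(1 - np.exp(-0.6), abs=1e-14)

    def test_survival_multiplies_across_epochs(self, single_deme_step):
        sp = nssc.enumerate_states(2, 1)
        P = nssc.scenario_propagator(single_deme_step, sp, 2.0).entries
        assert P[0, 1] == pytest.approx(1 - np.exp(-1) * np.exp(-1 / 5), abs=1e-14)


class TestDistributions:
    def test_cdf_zero_at_zero(self, island_9_1, space2_9):
        assert nssc.coalescence_cdf(island_9_1, space2_9, same(9), 0.0) == 0.0

    def test_single_deme_exponential(self):
        sc = nssc.make_scenario([nssc.ModelEpoch([1.0], [[0.0]])], [])
        sp = nssc.enumerate_states(2, 1)
        for t in (0.2, 1.0, 3.0):
            assert nssc.coalescence_cdf(sc, sp, same(1), t) == \
                pytest.approx(1 - np.exp(-t), abs=1e-12)
            assert nssc.coalescence_pdf(sc, sp, same(1), t) == \
                pytest.approx(np.exp(-t), abs=1e-12)

    def test_cdf_matches_closed_form_survival(self, island_9_1, space2_9):
        """Survival reconstructed by integrating the closed-form hazard."""
        k = nssc.n_island_constants(9, 1.0)
        for t in (0.5, 2.0, 10.0):
            hazard_integral = quad(
                lambda u: 1.0 / nssc.n_island_iicr_closed_form(9, 1.0, "s", u),
                0, t)[0]
            F = nssc.coalescence_cdf(island_9_1, space2_9, same(9), t)
            assert F == pytest.approx(1 - np.exp(-hazard_integral), abs=1e-9)

    def test_pdf_zero_from_different_demes(self, island_9_1, space2_9):
        assert nssc.coalescence_pdf(island_9_1, space2_9, diff(9), 0.0) == 0.0

    def test_pdf_normalises(self, island_9_1, space2_9):
        # the slow eigenvalue (beta ~ 0.06) still carries ~3e-6 of mass at
        # t = 200, so integrate to 400 to pin total mass at 1e-6 accuracy
        total = quad(
            lambda t: nssc.coalescence_pdf(island_9_1, space2_9, same(9), t),
            0, 400, limit=400)[0]
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_cdf_monotone_bounded(self, fixture_pair):
        human, _ = fixture_pair
        sp = nssc.enumerate_states(2, 10)
        ts = np.geomspace(1e-4, 1000, 220)
        F = nssc.coalescence_cdf(human, sp, same(10), ts)
        assert np.all(np.diff(F) >= -1e-12)
        assert F[0] >= 0 and F[-1] <= 1 and F[-1] > 0.999


class TestIICR:
    def test_single_deme_constant(self):
        sc = nssc.make_scenario([nssc.ModelEpoch([3.0], [[0.0]])], [])
        sp = nssc.enumerate_states(2, 1)
        v = nssc.iicr(sc, sp, same(1), np.geomspace(1e-3, 50, 64)).values
        assert np.allclose(v, 3.0, atol=1e-12)

    def test_piecewise_equals_size_function(self, single_deme_step):
        sp = nssc.enumerate_states(2, 1)
        ts = np.geomspace(1e-3, 50, 200)
        v = nssc.iicr(single_deme_step, sp, same(1), ts).values
        assert np.allclose(v, np.where(ts < 1.0, 1.0, 5.0), atol=1e-10)

    def test_same_deme_starts_at_deme_size(self, island_9_1, space2_9):
        v = nssc.iicr(island_9_1, space2_9, same(9), np.array([1e-8, 1e-4])).values
        assert v[0] == pytest.approx(1.0, abs=1e-6)

    def test_diff_demes_infinite_at_zero(self, island_9_1, space2_9):
        curve = nssc.iicr(island_9_1, space2_9, diff(9), np.array([1e-300, 1.0]))
        assert np.isinf(curve.values[0]) or curve.values[0] > 1e10

    def test_empty_grid_rejected(self, island_9_1, space2_9):
        with pytest.raises(nssc.ConfigError):
            nssc.iicr(island_9_1, space2_9, same(9), np.array([]))


class TestNIslandClosedForm:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(2, 30), st.floats(0.01, 50))
    def test_constants_identities(self, n, M):
        k = nssc.n_island_constants(n, M)
        assert k.alpha * k.beta == pytest.approx(k.gamma, rel=1e-12)
        assert k.alpha + k.beta == pytest.approx(1 + n * k.gamma, rel=1e-12)
        assert 0 < k.beta < 1 < k.alpha
        assert k.delta > 0

    def test_worked_constants(self):
        k = nssc.n_island_constants(2, 2.0)
        assert k.gamma == 2.0 and k.delta == pytest.approx(17.0)
        assert k.alpha == pytest.approx((5 + np.sqrt(17)) / 2)
        assert k.beta == pytest.approx((5 - np.sqrt(17)) / 2)

    def test_beta_vanishes_at_low_migration(self):
        betas = [nssc.n_island_constants(5, M).beta for M in (1e-2, 1e-4, 1e-6)]
        assert betas[0] > betas[1] > betas[2]
        assert betas[2] < 1e-6 * 2  # plateau 1/beta grows without bound

    def test_value_at_zero(self):
        assert nssc.n_island_iicr_closed_form(7, 3.0, "s", 0.0) == 1.0
        assert np.isinf(nssc.n_island_iicr_closed_form(7, 3.0, "d", 0.0))

    @pytest.mark.parametrize("n,M", [(9, 1.0), (9, 10.0), (2, 0.5)])
    def test_matrix_route_matches(self, n, M):
        sc = nssc.reduced_n_island(n, M)
        ts = np.geomspace(1e-3, 1e2, 128)
        for cfg, label in (("s", "s"), ("d", "d")):
            closed = nssc.n_island_iicr_closed_form(n, M, cfg, ts)
            matrix = nssc.iicr(sc, None, label, ts).values
            err = np.abs(matrix - closed) / np.maximum(1.0, np.abs(closed))
            assert err.max() < 1e-9


class TestMeanFirstCoalescence:
    @pytest.mark.parametrize("n,M", [(2, 0.5), (5, 1.0), (9, 10.0)])
    def test_n_island_identities(self, n, M):
        m = nssc.n_island(n, M)
        sp = nssc.enumerate_states(2, n)
        assert nssc.mean_first_coalescence(m, sp, same(n)) == \
            pytest.approx(n, abs=1e-10)
        assert nssc.mean_first_coalescence(m, sp, diff(n)) == \
            pytest.approx(n + (n - 1) / M, abs=1e-10)

    def test_single_deme(self):
        sp = nssc.enumerate_states(2, 1)
        m = nssc.ModelEpoch([4.0], [[0.0]])
        assert nssc.mean_first_coalescence(m, sp, same(1)) == pytest.approx(4.0)

    def test_unreachable(self):
        m = nssc.ModelEpoch([1, 1], [[0, 0], [0, 0]])
        sp = nssc.enumerate_states(2, 2)
        with pytest.raises(nssc.UnreachableAbsorptionError):
            nssc.mean_first_coalescence(m, sp, diff(2))


class TestGeneralK:
    def test_k3_single_deme(self):
        m = nssc.ModelEpoch([1.0], [[0.0]])
        for t in (0.1, 0.5, 2.0):
            assert nssc.general_k_first_coalescence(m, 3, 1, (3,), t) == \
                pytest.approx(1 - np.exp(-3 * t), abs=1e-10)

    def test_k2_reduces_to_pairwise(self, island_9_1, space2_9):
        ts = np.geomspace(1e-2, 20, 30)
        general = nssc.general_k_first_coalescence(island_9_1, 2, 9, same(9), ts)
        pair = nssc.coalescence_cdf(island_9_1, space2_9, same(9), ts)
        assert np.abs(general - pair).max() < 1e-12

    def test_strong_migration_panmictic_limit(self):
        m = nssc.n_island(2, 1e4)
        for t in (0.2, 0.5, 1.5):
            got = nssc.general_k_first_coalescence(m, 3, 2, (3, 0), t)
            panmictic = 1 - np.exp(-3 * t / 2)  # 3 pairs, total size 2
            assert got == pytest.approx(panmictic, rel=0.01)

    def test_cap_enforced(self):
        old = nssc.SETTINGS.state_count_cap
        nssc.SETTINGS.state_count_cap = 5
        try:
            with pytest.raises(nssc.StateSpaceTooLargeError, match="cap of 5"):
                nssc.general_k_first_coalescence(nssc.n_island(4, 1.0), 3, 4,
                                                 (3, 0, 0, 0), 1.0)
        finally:
            nssc.SETTINGS.state_count_cap = old
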