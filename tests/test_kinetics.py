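"""Single-site and three-site rate models: closed forms, solvers and the
stochastic simulator."""

import numpy as np
import pytest

from crownpore.kinetics import (ChainState, GillespieResult, RateSet,
                                current_from_occupancy, gillespie_chain,
                                single_site_current, stationary_distribution,
                                steady_state_chain, transient_chain)


def _random_rates(rng):
    kb, kbo, ka, kd, keo = 10 ** rng.uniform(-1, 1, 5)
    return RateSet(kb=kb, kb_out=kbo, ka=ka, kd=kd, kexit_out=keo)


class TestSingleSite:
    def test_symmetric_rates(self):
        current, P = single_site_current(2.0, 2.0)
        assert current == pytest.approx(1.0)
        assert P == pytest.approx(0.5)

    def test_association_limited(self):
        # ka << kd: pore always empty, I/q -> ka
        current, P = single_site_current(0.01, 100.0)
        assert current == pytest.approx(0.01, rel=1e-3)
        assert P < 1e-3

    def test_harmonic_sum(self):
        current, P = single_site_current(1.0, 3.0)
        assert current == pytest.approx(0.75)
        assert P == pytest.approx(0.25)

    def test_identities(self):
        current, P = single_site_current(1.7, 0.4)
        assert current == pytest.approx(0.4 * P, rel=1e-12)
        assert current == pytest.approx(1.7 * (1 - P), rel=1e-12)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            single_site_current(0.0, 0.0)


class TestCurrentFromOccupancy:
    def test_blocked_pore(self):
        assert current_from_occupancy(0.72, 12.0, 1.0) == 0.0

    def test_bulk_limited(self):
        # kb >> open association rate: pore term dominates
        assert current_from_occupancy(100.0, 0.012, 0.0) == pytest.approx(
            0.012, rel=1e-3)

    def test_blocked_pore_magnitude(self):
        # kb ~ 0.72/ns with an effective open rate of 0.012/ns
        val = current_from_occupancy(0.72, 12.0, 0.999)
        assert val == pytest.approx(0.0118, rel=0.02)

    def test_occupancy_bounds_enforced(self):
        with pytest.raises(ValueError, match="P2"):
            current_from_occupancy(1.0, 1.0, 1.5)


class TestSteadyState:
    def test_matches_closed_form_identity(self):
        # elimination of sites 1 and 3 is exact within the factorized model
        rng = np.random.default_rng(42)
        for _ in range(100):
            r = _random_rates(rng)
            st = steady_state_chain(r)
            ktilde = r.ka * r.kb / (r.kb + r.kb_out)
            assert st.current == pytest.approx(
                current_from_occupancy(r.kb, ktilde, st.P2), rel=1e-10)

    def test_stage_currents_agree(self):
        r = RateSet(kb=0.9, kb_out=0.3, ka=4.0, kd=2.5, kexit_out=30.0)
        st = steady_state_chain(r)
        in_flux = r.kb * (1 - st.P1) - r.kb_out * st.P1
        mid_flux = r.ka * st.P1 * (1 - st.P2)
        out_flux = r.kd * st.P2 * (1 - st.P3)
        assert in_flux == pytest.approx(st.current, rel=1e-9)
        assert mid_flux == pytest.approx(st.current, rel=1e-12)
        assert out_flux == pytest.approx(st.current, rel=1e-9)

    def test_fast_dissociation_limit(self):
        # kd, exit -> fast: P2 -> 0, current -> kb*ka/(kb+kb_out+ka)
        r = RateSet(kb=1.0, kb_out=0.5, ka=2.0, kd=1e7, kexit_out=1e9)
        st = steady_state_chain(r)
        assert st.P2 < 1e-5
        assert st.current == pytest.approx(1.0 * 2.0 / (1.0 + 0.5 + 2.0), rel=1e-4)

    def test_no_feed_no_current(self):
        st = steady_state_chain(RateSet(kb=0.0, ka=3.0, kd=2.0, kexit_out=10.0))
        assert st.current == 0.0
        assert st.P1 == 0.0

    def test_dead_end_blocks(self):
        # kd = 0: the pore fills and stays full
        st = steady_state_chain(RateSet(kb=1.0, ka=3.0, kd=0.0, kexit_out=10.0))
        assert st.P2 == pytest.approx(1.0)
        assert st.current == 0.0

    def test_current_monotone_in_each_rate(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            r = _random_rates(rng)
            base = steady_state_chain(r).current
            for attr in ("kb", "ka", "kd"):
                boosted = RateSet(**{**r.__dict__, attr: getattr(r, attr) * 1.5})
                assert steady_state_chain(boosted).current >= base - 1e-12

    def test_voltage_laws(self):
        drift = RateSet(kb0=0.5, kappa_b=2.2, ktilde_a=12.0)
        assert drift.kb_at(0.1) == pytest.approx(0.72)
        act = RateSet(kb0=0.79, beta=1.3, ktilde_a=10.0)
        assert act.kb_at(1.0) == pytest.approx(0.79 * np.exp(1.3))

    def test_ktilde_cannot_exceed_ka(self):
        with pytest.raises(ValueError, match="ktilde_a"):
            RateSet(kb=1.0, ka=2.0, ktilde_a=3.0)


class TestTransient:
    def test_fixed_point_stays_fixed(self):
        r = RateSet(kb=0.8, kb_out=0.2, ka=3.0, kd=1.5, kexit_out=20.0)
        st = steady_state_chain(r)
        P, cur = transient_chain(r, st.occupancies(), np.linspace(0, 50, 20))
        assert np.allclose(P, st.occupancies(), atol=1e-7)

    def test_converges_to_steady_state(self):
        r = RateSet(kb=0.8, kb_out=0.2, ka=3.0, kd=1.5, kexit_out=20.0)
        st = steady_state_chain(r)
        t_end = 100.0 / min(0.2, 0.8)
        P, cur = transient_chain(r, [1.0, 0.0, 1.0], [0.0, t_end])
        assert np.max(np.abs(P[-1] - st.occupancies())) < 1e-8

    def test_blocked_pore_fills_monotonically(self):
        r = RateSet(kb=1.0, ka=3.0, kd=0.0)
        P, _ = transient_chain(r, [0.0, 0.0, 0.0], np.linspace(0, 30, 40))
        p2 = P[:, 1]
        assert np.all(np.diff(p2) >= -1e-10)
        assert p2[-1] > 0.999

    def test_occupancy_bounds_respected(self):
        r = RateSet(kb=5.0, kb_out=0.1, ka=9.0, kd=0.3, kexit_out=2.0)
        P, _ = transient_chain(r, [0.0, 1.0, 0.0], np.linspace(0, 20, 50))
        assert np.all(P >= 0.0) and np.all(P <= 1.0)

    def test_bad_initial_state_rejected(self):
        with pytest.raises(ValueError, match="P_init"):
            transient_chain(RateSet(kb=1.0, ka=1.0, kd=1.0), [2.0, 0, 0], [0, 1])


class TestStationaryDistribution:
    def test_probabilities_normalized(self):
        st, p = stationary_distribution(RateSet(kb=0.7, kb_out=2.0, ka=3.0,
                                                kd=1.1, kexit_out=9.0))
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(p >= -1e-15)

    def test_factorized_model_accurate_with_fast_exchange(self):
        # the deterministic chain closes <n1(1-n2)> as P1(1-P2); that is
        # accurate when the boundary sites exchange with their reservoirs
        # much faster than with the pore
        rng = np.random.default_rng(3)
        for _ in range(20):
            kb, ka, kd = 10 ** rng.uniform(-0.5, 0.5, 3)
            r = RateSet(kb=kb, kb_out=20 * ka, ka=ka, kd=kd, kexit_out=20 * kd)
            exact, _ = stationary_distribution(r)
            approx = steady_state_chain(r)
            assert approx.current == pytest.approx(exact.current, rel=0.02)

    def test_factorization_error_visible_with_slow_exchange(self):
        # strong coupling: correlations make the factorized current deviate
        r = RateSet(kb=0.72, kb_out=0.0, ka=12.0, kd=0.4, kexit_out=400.0)
        exact, _ = stationary_distribution(r)
        approx = steady_state_chain(r)
        assert abs(approx.current / exact.current - 1) > 0.02


class TestGillespie:
    def test_matches_exact_stationary_state(self):
        rng = np.random.default_rng(11)
        for i in range(3):
            r = _random_rates(rng)
            exact, _ = stationary_distribution(r)
            g = gillespie_chain(r, t_end=150.0, seed=50 + i, n_replicas=20)
            assert abs(g.current - exact.current) <= 3 * g.current_se
            assert abs(g.occupancy[1] - exact.P2) <= 3 * g.occupancy_se[1]

    def test_no_dissociation_no_translocations(self):
        g = gillespie_chain(RateSet(kb=2.0, ka=5.0, kd=0.0), t_end=50.0,
                            seed=1, n_replicas=3)
        assert np.all(g.translocations <= 1)
        assert g.current == 0.0

    def test_bit_reproducible(self):
        r = RateSet(kb=1.0, kb_out=0.5, ka=2.0, kd=1.0, kexit_out=5.0)
        a = gillespie_chain(r, t_end=30.0, seed=9, record_events=True)
        b = gillespie_chain(r, t_end=30.0, seed=9, record_events=True)
        assert a.events == b.events
        assert np.array_equal(a.translocations, b.translocations)
        assert np.array_equal(a.occupancy, b.occupancy)
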