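"""Tests for the flow-rate limits, probabilistic intervals, realized
almost-sure bounds, and the deterministic support envelope."""

import math

import numpy as np
import pytest

from rfmd import (
    BoundReport,
    RFMDParams,
    WindowSet,
    deterministic_envelope,
    finite_bounds_iid_caps,
    finite_bounds_iid_rates,
    limit_random_caps,
    limit_random_rates,
    realized_bounds_caps,
    realized_bounds_full,
    realized_bounds_rates,
    steady_rate,
)


class TestWindowSet:
    def test_windows_are_consecutive_runs(self):
        ws = WindowSet(start=1, stop=4, s=2)
        assert [list(w) for w in ws.windows] == [[1, 2], [2, 3], [3, 4]]
        assert [list(h) for h in ws.h_extension] == [[1, 2, 3], [2, 3, 4], [3, 4, 5]]

    def test_extension_has_one_more_member(self):
        ws = WindowSet(start=1, stop=9, s=4)
        for w, h in zip(ws.windows, ws.h_extension):
            assert len(h) == len(w) + 1 == 5
            assert h[-1] == w[-1] + 1

    def test_too_long_window_rejected(self):
        with pytest.raises(ValueError):
            WindowSet(start=1, stop=3, s=4)


class TestLimits:
    @pytest.mark.parametrize(
        "q, m_inv_sqrt, expected",
        [(0.5, 2 ** -0.5, 0.125), (0.3, 1.0, 0.0225), (1.0, 1.0, 0.25)],
    )
    def test_limit_random_rates(self, q, m_inv_sqrt, expected):
        assert limit_random_rates(q, m_inv_sqrt) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("m_q, lam, expected", [(0.8, 1.0, 0.16), (0.7, 1.0, 0.1225)])
    def test_limit_random_caps(self, m_q, lam, expected):
        assert limit_random_caps(m_q, lam) == pytest.approx(expected, rel=1e-12)

    def test_two_limits_are_the_same_formula(self, rng):
        for _ in range(20):
            q = rng.uniform(0.05, 1)
            lam = rng.uniform(0.1, 5)
            assert limit_random_caps(q, lam) == pytest.approx(
                limit_random_rates(q, lam ** -0.5), rel=1e-12
            )


class TestFiniteBoundsRates:
    def test_lower_equals_asymptotic_limit(self):
        rep = finite_bounds_iid_rates(0.5, 0.5, 2 ** -0.5, eps=0.0, s=5, n=100, a_eps=0.3)
        assert rep.lower == pytest.approx(0.125, rel=1e-12)

    def test_upper_collapses_as_window_grows(self):
        m = 2 ** -0.5
        upper_prev = math.inf
        for s in (2, 10, 100, 1000):
            rep = finite_bounds_iid_rates(0.5, 0.5, m, eps=0.0, s=s, n=s + 2, a_eps=0.5)
            assert rep.upper < upper_prev
            upper_prev = rep.upper
        assert upper_prev == pytest.approx(0.125, rel=1e-5)

    def test_probability_guarantee_arithmetic(self):
        rep = finite_bounds_iid_rates(0.5, 0.5, 2 ** -0.5, eps=0.0, s=10, n=101, a_eps=0.5)
        assert rep.probability_guarantee == pytest.approx(
            1 - math.exp(-10 * 0.5 ** 10), rel=1e-12
        )
        assert rep.probability_guarantee == pytest.approx(0.009718, abs=1e-6)

    def test_eps_at_least_m_rejected(self):
        with pytest.raises(ValueError):
            finite_bounds_iid_rates(0.5, 0.5, 0.7, eps=0.7, s=2, n=10, a_eps=0.5)


class TestFiniteBoundsCaps:
    def test_degenerate_case_matches_limit(self):
        # homogeneous lam = 1, eta = 0, huge s: both ends at 0.16
        rep = finite_bounds_iid_caps(0.8, 1.0, 1.0, eta=0.0, s=10_000, n=10_002, b_eta=0.5)
        assert rep.lower == pytest.approx(0.16, rel=1e-12)
        assert rep.upper == pytest.approx(0.16, rel=1e-6)

    def test_eta_correction_factor(self):
        # (1 + eta/m)^2 with eta = 0.05, m = 0.8
        rep0 = finite_bounds_iid_caps(0.8, 1.0, 1.0, eta=0.0, s=50, n=100, b_eta=0.5)
        rep = finite_bounds_iid_caps(0.8, 1.0, 1.0, eta=0.05, s=50, n=100, b_eta=0.5)
        assert rep.upper / rep0.upper == pytest.approx(1.12890625, rel=1e-12)

    def test_probability_guarantee_arithmetic(self):
        rep = finite_bounds_iid_caps(0.8, 1.0, 1.0, eta=0.0, s=10, n=100, b_eta=0.5)
        assert rep.probability_guarantee == pytest.approx(0.009718, abs=1e-6)


class TestRealizedBounds:
    def test_rates_homogeneous_closed_form(self):
        # lam = 1: lower = q^2/4, upper = q^2 / (4 cos^2(pi/(n+1)))
        n, q = 8, 0.6
        rep = realized_bounds_rates(np.ones(n + 1), q, q)
        assert rep.lower == pytest.approx(q * q / 4, rel=1e-12)
        assert rep.upper == pytest.approx(
            q * q / (4 * math.cos(math.pi / (n + 1)) ** 2), rel=1e-12
        )
        assert rep.attaining_choice[0] == n - 1  # widest window wins

    def test_rates_two_site_contains_truth(self):
        rep = realized_bounds_rates([1, 1, 1], 1.0, 1.0)
        assert (rep.lower, rep.upper) == (pytest.approx(0.25), pytest.approx(1.0))
        R = steady_rate(RFMDParams([1, 1, 1], [1.0, 1.0])).R
        assert rep.contains(R)

    def test_caps_homogeneous_closed_form(self):
        n, q = 8, 0.6
        rep = realized_bounds_caps(np.full(n, q), 1.0, 1.0)
        assert rep.lower == pytest.approx(q * q / 4, rel=1e-12)
        assert rep.upper == pytest.approx(
            q * q / (4 * math.cos(math.pi / (n + 1)) ** 2), rel=1e-12
        )

    def test_caps_two_site_contains_truth(self):
        rep = realized_bounds_caps([1.0, 1.0], 1.0, 1.0)
        assert (rep.lower, rep.upper) == (pytest.approx(0.25), pytest.approx(1.0))
        assert rep.contains(steady_rate(RFMDParams([1, 1, 1], [1.0, 1.0])).R)

    def test_full_hand_example(self):
        # n = 3, lam = 1, q = 0.7: lower 0.1225, upper 0.245 at s = 2
        rep = realized_bounds_full(np.ones(4), np.full(3, 0.7))
        assert rep.lower == pytest.approx(0.1225, rel=1e-12)
        assert rep.upper == pytest.approx(0.245, rel=1e-12)
        assert rep.attaining_choice == (2, 1)

    def test_full_containment_random_draws(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 12))
            lam = rng.uniform(1, 2, n + 1)
            q = rng.uniform(0.5, 0.7, n)
            rep = realized_bounds_full(lam, q)
            R = steady_rate(RFMDParams(lam, q)).R
            assert rep.contains(R)

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError):
            realized_bounds_rates([1, 1], 0.5, 0.5)
        with pytest.raises(ValueError):
            realized_bounds_full([1, 1], [0.5])

    def test_report_orders_bounds(self):
        with pytest.raises(ValueError):
            BoundReport(lower=1.0, upper=0.5)


class TestDeterministicEnvelope:
    def test_asymptotic_envelope(self):
        assert deterministic_envelope(1, 2, 0.5, 0.7) == (
            pytest.approx(0.0625),
            pytest.approx(0.245),
        )

    def test_finite_window_envelope(self):
        lower, upper = deterministic_envelope(1, 2, 0.5, 0.7, s=2)
        assert lower == pytest.approx(0.0625)
        assert upper == pytest.approx(0.49)

    def test_degenerate_supports_reproduce_limits(self, rng):
        for _ in range(20):
            lam = rng.uniform(0.1, 5)
            q = rng.uniform(0.05, 1)
            lower, upper = deterministic_envelope(lam, lam, q, q)
            assert lower == pytest.approx(upper, rel=1e-12)
            assert lower == pytest.approx(q * q * lam / 4, rel=1e-12)

    def test_invalid_supports_rejected(self):
        with pytest.raises(ValueError):
            deterministic_envelope(2, 1, 0.5, 0.7)
        with pytest.raises(ValueError):
            deterministic_envelope(1, 2, 0.7, 0.5)
        with pytest.raises(ValueError):
            deterministic_envelope(1, 2, 0.5, 1.2)


class TestConsistencyAcrossResults:
    def test_realized_bounds_tighten_toward_limit_in_homogeneous_case(self):
        # as n grows the homogeneous realized interval closes onto q^2 lam/4
        q = 0.5
        widths = []
        for n in (5, 20, 80):
            rep = realized_bounds_rates(np.ones(n + 1), q, q)
            widths.append(rep.upper - rep.lower)
            assert rep.lower == pytest.approx(q * q / 4, rel=1e-12)
        assert widths[0] > widths[1] > widths[2]

    def test_finite_interval_covers_realized_draws(self, rng):
        # Thm-level coherence: the probabilistic interval evaluated with
        # eps = 0 lower end always sits below the realized solver rate
        for _ in range(25):
            n = int(rng.integers(6, 20))
            lam = rng.uniform(1, 2, n + 1)
            q = np.full(n, 0.5)
            R = steady_rate(RFMDParams(lam, q)).R
            rep = finite_bounds_iid_rates(0.5, 0.5, 1.0, eps=0.0, s=2, n=n, a_eps=0.5)
            assert R >= rep.lower - 1e-12
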