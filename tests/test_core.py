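"""Unit tests for lagged coincidence counting and the Poisson test."""

import math

import numpy as np
import pytest

from cer import (
    EventSeries,
    bidirectional_scan,
    cer_test,
    count_er,
    er_profile,
    lower_limit,
    make_delay,
    poisson_cdf,
    simulate_network,
    two_node_config,
    upper_limit,
)

from conftest import count_er_oracle, poisson_cdf_oracle


def series(values, label=""):
    return EventSeries(np.array(values), label=label)


class TestEventSeries:
    def test_rejects_non_binary_values(self):
        with pytest.raises(ValueError, match="0 or 1"):
            series([0, 1, 2])

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            series([])

    def test_metadata(self):
        s = series([0, 1, 1], label="X")
        assert (s.n, s.label, s.event_count()) == (3, "X", 2)


class TestCountER:
    @pytest.mark.parametrize(
        "x, y, tau, expected",
        [
            ([0] * 10, [1, 0] * 5, 3, 0),            # no effect events
            ([1, 1, 1, 1], [1, 1, 1, 1], 0, 4),      # identity case
            ([0, 1, 0, 0, 1, 0, 1], [1, 0, 0, 1, 0, 1, 0], 1, 3),
        ],
    )
    def test_known_counts(self, x, y, tau, expected):
        assert count_er(series(x), series(y), tau) == expected

    def test_matches_brute_force(self, rng):
        x = (rng.random(200) < 0.4).astype(int)
        y = (rng.random(200) < 0.4).astype(int)
        for tau in (0, 1, 5, 50, 199):
            assert count_er(series(x), series(y), tau) == count_er_oracle(x, y, tau)

    def test_count_bounded_by_overlap(self, rng):
        x = series(np.ones(50, dtype=int))
        y = series(np.ones(50, dtype=int))
        for tau in range(50):
            assert count_er(x, y, tau) == 50 - tau

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="lengths differ"):
            count_er(series([0, 1]), series([0, 1, 1]), 0)

    def test_lag_out_of_range(self):
        s = series([0, 1, 0])
        with pytest.raises(ValueError, match="outside the valid range"):
            count_er(s, s, 3)
        with pytest.raises(ValueError):
            count_er(s, s, -1)


class TestPoissonCDF:
    def test_degenerate_mean(self):
        assert poisson_cdf(0, 0.0) == 1.0

    def test_closed_form(self):
        assert poisson_cdf(0, 1.0) == pytest.approx(math.exp(-1), abs=1e-12)

    def test_derived_value(self):
        # frozen from the decimal direct-summation oracle
        assert poisson_cdf(5, 3.0) == pytest.approx(0.9160820579686966, abs=1e-12)

    @pytest.mark.parametrize("k,lam", [(0, 5.0), (10, 0.5), (100, 100.0), (500, 450.0)])
    def test_agrees_with_oracle(self, k, lam):
        assert poisson_cdf(k, lam) == pytest.approx(poisson_cdf_oracle(k, lam), abs=1e-10)

    def test_rejects_negative_inputs(self):
        with pytest.raises(ValueError):
            poisson_cdf(-1, 1.0)
        with pytest.raises(ValueError):
            poisson_cdf(1, -1.0)


class TestLimits:
    def test_zero_reference(self):
        assert upper_limit(0, 0.005) == 0

    def test_derived_threshold(self):
        # frozen from an upward scan with the decimal CDF oracle
        assert upper_limit(100, 0.005) == 127

    def test_threshold_exceeds_reference(self):
        for k0 in (1, 2, 5, 17, 100, 1000):
            assert upper_limit(k0, 0.005) > k0

    def test_monotone_in_reference(self):
        thresholds = [upper_limit(k0, 0.005) for k0 in range(0, 300, 7)]
        assert thresholds == sorted(thresholds)

    def test_frequency_form(self):
        k, f = upper_limit(100, 0.005, n_eff=5000)
        assert (k, f) == (127, 127 / 5000)

    def test_lower_limit(self):
        lo = lower_limit(100, 0.005)
        assert poisson_cdf(lo, 100) < 0.005 <= poisson_cdf(lo + 1, 100)
        assert lower_limit(0, 0.005) is None

    def test_invalid_alpha(self):
        with pytest.raises(ValueError, match="alpha"):
            upper_limit(10, 0.7)


class TestERProfile:
    def test_constant_ones_counts(self):
        s = series([1] * 30)
        prof = er_profile(s, s, tau_max=5)
        assert list(prof.counts) == [30 - t for t in range(6)]
        assert prof.k0 == 30

    def test_frequencies_use_overlap_length(self, random_pair):
        x, y = random_pair(n=400)
        prof = er_profile(x, y, tau_max=10)
        np.testing.assert_allclose(prof.frequencies, prof.counts / (400 - prof.lags))
        assert ((prof.frequencies >= 0) & (prof.frequencies <= 1)).all()

    def test_threshold_relation(self, random_pair):
        x, y = random_pair()
        prof = er_profile(x, y, tau_max=10, alpha=0.005)
        assert prof.upper_count > prof.k0 > 0


class TestCERTest:
    def test_fixed_delay_recovers_lag(self):
        cfg = two_node_config(0.6, make_delay("fixed", tau=4), seed=1)
        sim = simulate_network(cfg)
        result = cer_test(sim.series["X"], sim.series["Y"], tau_max=20, alpha=0.005)
        assert result.status == "tested"
        assert set(result.significant_lags) == {4}
        assert result.significant_lags[4] == +1

    def test_bi_delay_recovers_both_lags(self):
        cfg = two_node_config(0.6, make_delay("bimodal", taus=(2, 5)), seed=2)
        sim = simulate_network(cfg)
        result = cer_test(sim.series["X"], sim.series["Y"], tau_max=20, alpha=0.005)
        assert set(result.significant_lags) == {2, 5}

    def test_all_zero_effect_is_insufficient(self):
        x = series([0] * 100)
        y = series([0, 1] * 50)
        result = cer_test(x, y, tau_max=5)
        assert result.status == "insufficient-events"
        assert result.significant_lags == {}

    def test_decrease_tail_flags_low_counts(self):
        # effect silenced wherever the cause fired 2 steps earlier
        rng = np.random.default_rng(3)
        y = (rng.random(5000) < 0.4).astype(int)
        x = (rng.random(5000) < 0.4).astype(int)
        x[2:][y[:-2] == 1] = 0
        result = cer_test(series(x), series(y), tau_max=10, alpha=0.005, tail="decrease")
        assert result.significant_lags.get(2) == -1

    def test_rethreshold_matches_fresh_run(self):
        cfg = two_node_config(0.6, make_delay("fixed", tau=4), seed=5)
        sim = simulate_network(cfg)
        x, y = sim.series["X"], sim.series["Y"]
        loose = cer_test(x, y, tau_max=20, alpha=0.05)
        tight = cer_test(x, y, tau_max=20, alpha=0.0005)
        assert loose.rethreshold(0.0005).significant_lags == tight.significant_lags

    def test_invalid_tail(self, random_pair):
        x, y = random_pair(n=100)
        with pytest.raises(ValueError, match="tail"):
            cer_test(x, y, tau_max=5, tail="sideways")


class TestBidirectionalScan:
    def test_identical_inputs_give_mirror_profile(self):
        rng = np.random.default_rng(7)
        a = series((rng.random(1000) < 0.3).astype(int), label="A")
        b = series(a.values.copy(), label="B")
        scan = bidirectional_scan(a, b, tau_max=10)
        lags, counts = scan.combined_profile()
        np.testing.assert_array_equal(counts, counts[::-1])
        assert scan.forward.k0 == scan.reverse.k0

    def test_directed_link_flags_only_cause_leads_side(self):
        cfg = two_node_config(0.6, make_delay("fixed", tau=4), seed=9)
        sim = simulate_network(cfg)
        scan = bidirectional_scan(sim.series["Y"], sim.series["X"], tau_max=20)
        assert scan.forward.direction == ("Y", "X")
        assert scan.forward.detected
        assert not scan.reverse.detected

    def test_zero_lag_diagnostic_on_synchronous_link(self):
        # a copy-with-jitter pair: joint mass concentrates at lag 0
        rng = np.random.default_rng(13)
        a = (rng.random(5000) < 0.3).astype(int)
        b = np.where(rng.random(5000) < 0.9, a, 0)
        scan = bidirectional_scan(
            series(a, "A"), series(b, "B"), tau_max=10, zero_lag_diagnostic=True
        )
        assert scan.zero_lag_related is True
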