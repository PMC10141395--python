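"""Generators: exact fGn, binomial cascade, Markov gating, protocol assembly."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from mfpatch import (
    CascadeSpec,
    FgnSpec,
    GatingSpec,
    ParameterError,
    ProtocolSpec,
    assemble_protocol_recording,
    binary_dwells,
    cascade_alpha_theory,
    cascade_hurst_theory,
    fgn_autocovariance,
    simulate_cascade,
    simulate_channel_current,
    simulate_fgn,
)


class TestFgn:
    def test_same_seed_is_bit_identical(self):
        spec = FgnSpec(hurst=0.7, n_samples=1024, seed=42)
        assert np.array_equal(simulate_fgn(spec), simulate_fgn(spec))

    def test_h_half_is_uncorrelated(self):
        # H=0.5 is i.i.d. Gaussian: lag-1 autocorrelation ~ 0
        r1 = []
        for seed in range(20):
            x = simulate_fgn(FgnSpec(hurst=0.5, n_samples=4096, seed=seed))
            x = x - x.mean()
            r1.append(np.dot(x[:-1], x[1:]) / np.dot(x, x))
        assert abs(np.mean(r1)) < 0.05

    def test_autocovariance_matches_closed_form(self):
        # mean sample autocovariance at lags 1..10 vs gamma(k), 20 seeds
        hurst, n, lags = 0.7, 65536, np.arange(1, 11)
        acov = np.empty((20, lags.size))
        for seed in range(20):
            x = simulate_fgn(FgnSpec(hurst=hurst, n_samples=n, seed=seed))
            d = x - x.mean()
            acov[seed] = [np.dot(d[:-k], d[k:]) / n for k in lags]
        mean = acov.mean(axis=0)
        se = acov.std(axis=0, ddof=1) / np.sqrt(20)
        gamma = fgn_autocovariance(hurst, lags)
        assert np.all(np.abs(mean - gamma) < 3 * se)

    def test_sample_variance_approaches_sigma_squared(self):
        sigma = 2.0
        var = [
            simulate_fgn(FgnSpec(hurst=0.6, n_samples=2**14, sigma=sigma, seed=s)).var()
            for s in range(20)
        ]
        se = np.std(var, ddof=1) / np.sqrt(20)
        assert abs(np.mean(var) - sigma**2) < 3 * se

    @pytest.mark.parametrize("hurst", [0.0, 1.0, -0.2, 1.5])
    def test_hurst_outside_unit_interval_rejected(self, hurst):
        with pytest.raises(ParameterError):
            FgnSpec(hurst=hurst, n_samples=100)

    def test_embedding_nonnegative_across_hurst_range(self):
        # exactness precondition: the circulant eigenvalues stay >= 0
        for hurst in (0.05, 0.3, 0.5, 0.7, 0.95):
            x = simulate_fgn(FgnSpec(hurst=hurst, n_samples=2**12, seed=0))
            assert np.all(np.isfinite(x))


class TestCascade:
    def test_symmetric_split_is_constant(self):
        x = simulate_cascade(CascadeSpec(a=0.5, k_levels=8))
        assert np.allclose(x, 2.0**-8, rtol=0, atol=1e-15)

    @given(
        a=st.floats(0.05, 0.95),
        k=st.integers(4, 12),
        shuffle=st.booleans(),
    )
    def test_mass_conservation_and_positivity(self, a, k, shuffle):
        x = simulate_cascade(CascadeSpec(a=a, k_levels=k, seed=7, shuffle=shuffle))
        assert x.size == 2**k
        assert np.all(x > 0)
        assert abs(x.sum() - 1.0) < 1e-12

    def test_closed_form_hurst_at_q2(self):
        # H(2) = 0.5 - log2(0.625)/2 for a = 0.75
        expected = 0.5 - np.log2(0.75**2 + 0.25**2) / 2
        assert cascade_hurst_theory(0.75, 2.0) == pytest.approx(expected)
        assert cascade_hurst_theory(0.75, 2.0) == pytest.approx(0.8390, abs=1e-4)

    def test_closed_form_continuous_at_q0(self):
        eps = 1e-6
        h0 = cascade_hurst_theory(0.7, 0.0)
        assert cascade_hurst_theory(0.7, eps) == pytest.approx(h0, abs=1e-5)
        assert cascade_hurst_theory(0.7, -eps) == pytest.approx(h0, abs=1e-5)

    def test_alpha_theory_at_q0(self):
        # apex of the spectrum: alpha(0) = -(log2 a + log2(1-a)) / 2
        assert cascade_alpha_theory(0.75, 0.0) == pytest.approx(1.2075, abs=1e-4)

    def test_invalid_a_rejected(self):
        with pytest.raises(ParameterError):
            CascadeSpec(a=1.0, k_levels=8)

    def test_shuffle_permutes_but_preserves_values(self):
        base = simulate_cascade(CascadeSpec(a=0.7, k_levels=10))
        shuf = simulate_cascade(CascadeSpec(a=0.7, k_levels=10, seed=3, shuffle=True))
        assert not np.array_equal(base, shuf)
        assert np.allclose(np.sort(base), np.sort(shuf))


class TestGating:
    def test_closed_absorbing_when_open_rate_zero(self):
        g = GatingSpec(open_rate=0.0, close_rate=100.0, baseline_current=5e-12, seed=1)
        n = 20000
        x = simulate_channel_current(g, n)
        assert abs(x.mean() - 5e-12) < 3 * g.noise_sd / np.sqrt(n)

    def test_stationary_open_probability(self):
        # p_open = 50 / (50 + 150) = 0.25
        g_kwargs = dict(open_rate=50.0, close_rate=150.0, noise_sd=0.0, dt=5e-5)
        fractions = []
        for seed in range(20):
            _, states = simulate_channel_current(
                GatingSpec(seed=seed, **g_kwargs), 80_000, return_states=True
            )
            fractions.append(states.mean())
        # replicate-to-replicate scatter is large (dwells are ~ms long);
        # bound the mean by 3 standard errors across seeds
        se = np.std(fractions, ddof=1) / np.sqrt(len(fractions))
        assert abs(np.mean(fractions) - 0.25) < 3 * se

    def test_open_dwell_times_exponential(self):
        g = GatingSpec(open_rate=200.0, close_rate=150.0, dt=5e-5, seed=5)
        _, states = simulate_channel_current(g, 400_000, return_states=True)
        _, open_dwells = binary_dwells(states)
        assert open_dwells.size >= 500
        dwell_s = open_dwells * g.dt
        mean_expected = 1.0 / g.close_rate
        se = dwell_s.std(ddof=1) / np.sqrt(dwell_s.size)
        assert abs(dwell_s.mean() - mean_expected) < 3 * se

    def test_dwell_histogram_kolmogorov_smirnov(self):
        # geometric dwells at dt*rate << 1 are exponential in distribution
        passed = 0
        for seed in range(20):
            g = GatingSpec(open_rate=200.0, close_rate=150.0, dt=5e-5, seed=seed)
            _, states = simulate_channel_current(g, 300_000, return_states=True)
            _, open_dwells = binary_dwells(states)
            if open_dwells.size < 500:
                continue
            p = stats.kstest(
                open_dwells * g.dt, "expon", args=(0, 1.0 / g.close_rate)
            ).pvalue
            passed += p > 0.01
        assert passed >= 19

    def test_discretisation_warning(self):
        g = GatingSpec(open_rate=5000.0, close_rate=150.0, dt=5e-5, seed=0)
        with pytest.warns(UserWarning, match="discretisation"):
            simulate_channel_current(g, 100)

    def test_negative_rate_rejected(self):
        with pytest.raises(ParameterError):
            GatingSpec(open_rate=-1.0, close_rate=100.0)


class TestProtocolAssembly:
    def _specs(self, dt=5e-5, seed=0):
        g_hold = GatingSpec(open_rate=5.0, close_rate=150.0, dt=dt, seed=seed)
        g_test = GatingSpec(open_rate=50.0, close_rate=150.0, dt=dt, seed=seed + 1)
        return g_hold, g_test

    def test_default_protocol_has_80000_samples(self):
        p = ProtocolSpec(test_voltage=-100.0)
        rec = assemble_protocol_recording(p, *self._specs())
        assert rec.n_samples == 80_000
        assert rec.duration == pytest.approx(4.0)

    def test_zero_holding_gives_pure_test_phase(self):
        p = ProtocolSpec(test_voltage=60.0, holding_duration=0.0)
        rec = assemble_protocol_recording(p, *self._specs())
        assert rec.n_samples == p.n_test

    def test_mismatched_dt_rejected(self):
        p = ProtocolSpec(test_voltage=60.0)
        g_hold, _ = self._specs()
        g_test_bad = GatingSpec(open_rate=50.0, close_rate=150.0, dt=1e-4)
        with pytest.raises(ParameterError, match="sampling interval"):
            assemble_protocol_recording(p, g_hold, g_test_bad)

    def test_replicates_distinct_traces_shared_metadata(self):
        p = ProtocolSpec(test_voltage=100.0)
        recs = []
        for rep in range(1, 6):
            g_hold, g_test = self._specs(seed=rep * 10)
            recs.append(
                assemble_protocol_recording(p, g_hold, g_test, replicate=rep)
            )
        for a, b in zip(recs, recs[1:]):
            assert not np.array_equal(a.values, b.values)
        assert {r.voltage_mV for r in recs} == {100.0}
        assert [r.replicate for r in recs] == [1, 2, 3, 4, 5]
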