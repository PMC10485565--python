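"""Coupling statistics: theta phase, circular tests, band power,
event-triggered profiles, indices, PETHs, SDR, episode-duration model."""
import numpy as np
import pytest
from scipy import special, stats as spstats

from pwavekit import synth
from pwavekit.core import NREM, REM, WAKE, EventTable, SignalTrace, SpikeTrain, StateEpisode
from pwavekit.coupling import (
    asymmetry_index, band_power_trace, episode_duration_model,
    episode_quartile_profile, event_power_xcorr, modulation_index, peth,
    phase_locking, profile_similarity, rayleigh_test, sdr, theta_phase,
    theta_power_windows,
)

RATE = 1000.0


def _cosine_trace(freq=7.0, dur=60.0, rate=RATE):
    t = np.arange(0, dur, 1 / rate)
    return SignalTrace(np.cos(2 * np.pi * freq * t), rate, "lfp"), t


class TestThetaPhase:
    def test_events_at_peaks_have_zero_phase(self):
        tr, t = _cosine_trace()
        phase = theta_phase(tr)
        peaks = np.arange(5.0, 55.0, 1.0 / 7.0 * 7)  # whole-second peaks of 7 Hz
        res = phase_locking(phase, peaks)
        assert res.r > 0.99
        assert abs(res.mean_phase) < 0.05

    def test_events_at_troughs_have_pi_phase(self):
        tr, t = _cosine_trace()
        phase = theta_phase(tr)
        troughs = np.arange(5.0, 55.0, 1.0) + 1.0 / 14.0  # half a cycle later
        res = phase_locking(phase, troughs)
        assert res.r > 0.99
        assert abs(abs(res.mean_phase) - np.pi) < 0.05

    def test_uniform_event_times_uniform_phases(self):
        tr, t = _cosine_trace(dur=120.0)
        phase = theta_phase(tr)
        rng = np.random.default_rng(0)
        events = np.sort(rng.uniform(5, 115, 300))
        res = phase_locking(phase, events)
        assert res.r < 0.15
        assert res.p > 0.05

    def test_differential_input_subtracts(self):
        tr, t = _cosine_trace()
        half = SignalTrace(0.5 * tr.samples, RATE, "b")
        phase_diff = theta_phase(tr, half)  # 0.5x amplitude, same phase
        res = phase_locking(phase_diff, np.arange(5.0, 55.0, 1.0))
        assert abs(res.mean_phase) < 0.05

    def test_too_short_trace_rejected(self):
        tr = SignalTrace(np.zeros(500), RATE)
        with pytest.raises(ValueError, match="filter"):
            theta_phase(tr)


class TestPhaseLocking:
    def test_degenerate_cases(self):
        phase = SignalTrace(np.full(1000, 0.7), RATE)
        res = phase_locking(phase, [0.1, 0.2, 0.3])
        assert res.r == pytest.approx(1.0)
        with pytest.raises(ValueError, match="events"):
            phase_locking(phase, [])

    def test_orthogonal_phases_cancel(self):
        phases = np.array([0.0, np.pi / 2, np.pi, 3 * np.pi / 2])
        tr = SignalTrace(phases, 1.0)
        res = phase_locking(tr, [0.0, 1.0, 2.0, 3.0])
        assert res.r == pytest.approx(0.0, abs=1e-12)

    def test_von_mises_resultant_bessel_ratio(self):
        # r -> I1(kappa)/I0(kappa) for large n
        rng = np.random.default_rng(1)
        kappa, mu = 2.0, 1.0
        draws = rng.vonmises(mu, kappa, 10_000)
        tr = SignalTrace(draws, 1.0)
        res = phase_locking(tr, np.arange(len(draws), dtype=float))
        expected = special.iv(1, kappa) / special.iv(0, kappa)
        assert abs(res.r - expected) < 0.01
        assert abs(res.mean_phase - mu) < 0.02

    def test_r_matches_brute_force_phasor_sum(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            ph = rng.uniform(-np.pi, np.pi, rng.integers(1, 200))
            tr = SignalTrace(ph, 1.0)
            res = phase_locking(tr, np.arange(len(ph), dtype=float))
            # independent oracle: explicit phasor accumulation
            sx = sum(np.cos(p) for p in ph) / len(ph)
            sy = sum(np.sin(p) for p in ph) / len(ph)
            assert res.r == pytest.approx(np.hypot(sx, sy), abs=1e-12)

    def test_rayleigh_p_uniform_under_null(self):
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(1000):
            _, p = rayleigh_test(rng.uniform(-np.pi, np.pi, 50))
            ps.append(p)
        stat, ks_p = spstats.kstest(ps, "uniform")
        assert ks_p > 0.01

    def test_nan_phases_dropped_and_counted(self):
        x = np.full(1000, np.nan)
        x[500:] = 0.3
        tr = synth._phase_trace(x, RATE)
        res = phase_locking(tr, [0.1, 0.7, 0.8])
        assert res.n_dropped == 1
        assert len(res.phases) == 2


class TestBandPower:
    def test_sinusoid_power_closed_form(self):
        t = np.arange(0, 10, 1 / RATE)
        tr = SignalTrace(2.0 * np.sin(2 * np.pi * 150 * t), RATE)
        p = band_power_trace(tr, None, (80, 250))
        assert np.allclose(p.samples[2000:-2000], 4.0 / 2, rtol=0.05)

    def test_out_of_band_rejected_and_nonnegative(self):
        t = np.arange(0, 10, 1 / RATE)
        tr = SignalTrace(np.sin(2 * np.pi * 2 * t), RATE)
        p = band_power_trace(tr, None, (80, 250))
        assert (p.samples >= 0).all()
        assert p.samples[2000:-2000].max() < 1e-4


class TestEventPowerXcorr:
    def test_null_profile_flat(self):
        rng = np.random.default_rng(4)
        power = SignalTrace(1.0 + 0.1 * rng.standard_normal(600_000), RATE)
        events = np.sort(rng.uniform(10, 590, 150))
        lags, z, mean = event_power_xcorr(power, events)
        assert np.mean(np.abs(z) < 3) > 0.99

    def test_baseline_zscore_construction(self):
        rng = np.random.default_rng(5)
        power = SignalTrace(1.0 + 0.1 * rng.standard_normal(200_000), RATE)
        events = np.sort(rng.uniform(10, 190, 50))
        lags, z, mean = event_power_xcorr(power, events)
        bmask = (lags >= -3.0) & (lags <= -2.0)
        assert abs(z[bmask].mean()) < 1e-9
        assert z[bmask].std() == pytest.approx(1.0, abs=1e-9)

    def test_injected_post_event_dip_is_negative(self):
        rng = np.random.default_rng(6)
        power = 1.0 + 0.05 * rng.standard_normal(400_000)
        events = np.sort(rng.uniform(10, 390, 80))
        for t in events:
            i = int(t * RATE)
            power[i:i + 400] -= 0.5  # suppression in the 400 ms after events
        lags, z, mean = event_power_xcorr(SignalTrace(power, RATE), events)
        post = z[(lags > 0.05) & (lags < 0.35)]
        assert post.mean() < -3

    def test_no_complete_window_errors(self):
        power = SignalTrace(np.ones(1000), RATE)
        with pytest.raises(ValueError, match="window"):
            event_power_xcorr(power, [0.5])


class TestIndices:
    def test_closed_form_cases(self):
        # pre == post -> 0
        tr = SignalTrace(np.ones(10_000), RATE)
        res = asymmetry_index(tr, [5.0])
        assert res.index == pytest.approx(0.0)
        # post = 0, pre > 0 -> -1
        x = np.ones(10_000)
        x[5000:] = 0.0
        res = asymmetry_index(SignalTrace(x, RATE), [5.0])
        assert res.index == pytest.approx(-1.0, abs=1e-3)
        # pre = 1, post = 3 -> 0.5
        x = np.ones(10_000)
        x[5001:] = 3.0
        res = asymmetry_index(SignalTrace(x, RATE), [5.0])
        assert res.index == pytest.approx(0.5, abs=1e-3)

    def test_zero_power_undefined(self):
        res = asymmetry_index(SignalTrace(np.zeros(10_000), RATE), [5.0])
        assert np.isnan(res.index)

    def test_modulation_index_per_unit(self):
        events = [10.0, 20.0, 30.0]
        # unit firing only before events; another firing only after
        pre_unit = SpikeTrain("pre", sorted(t - 0.1 for t in events))
        post_unit = SpikeTrain("post", sorted(t + 0.1 for t in events))
        out = modulation_index([pre_unit, post_unit], events)
        assert out[0].index == pytest.approx(-1.0)
        assert out[1].index == pytest.approx(1.0)
        assert out[0].unit_id == "pre"

    def test_index_bounds(self):
        rng = np.random.default_rng(7)
        tr = SignalTrace(np.abs(rng.standard_normal(100_000)), RATE)
        events = np.sort(rng.uniform(5, 95, 30))
        res = asymmetry_index(tr, events)
        assert -1.0 <= res.index <= 1.0


class TestThetaPowerWindows:
    def test_stationary_power_equal_means(self):
        rng = np.random.default_rng(8)
        tr = SignalTrace(2.0 + 0.05 * rng.standard_normal(200_000), RATE)
        events = np.sort(rng.uniform(5, 195, 60))
        far, near = theta_power_windows(tr, events)
        assert abs(far - near) < 0.02

    def test_single_event_flat_power(self):
        tr = SignalTrace(np.full(20_000, 3.7), RATE)
        far, near = theta_power_windows(tr, [10.0])
        assert far == pytest.approx(3.7) and near == pytest.approx(3.7)

    def test_ramped_theta_center_window_larger(self):
        rng = np.random.default_rng(9)
        power = 1.0 + 0.02 * rng.standard_normal(400_000)
        events = np.sort(rng.uniform(10, 390, 60))
        for t in events:
            i = int(t * RATE)
            power[i - 300:i + 300] += 0.5  # elevation around events
        far, near = theta_power_windows(SignalTrace(power, RATE), events)
        assert near > far + 0.3


class TestPeth:
    def test_homogeneous_poisson_flat(self):
        rng = np.random.default_rng(10)
        spikes = [SpikeTrain("u", np.sort(rng.uniform(0, 600, 6000)))]
        events = np.sort(rng.uniform(5, 595, 100))
        res = peth(spikes, events)
        assert abs(res.z[0].mean()) < 0.2

    def test_latency_peak_recovered(self):
        events = np.arange(5.0, 500.0, 5.0)
        spikes = [SpikeTrain("lat50", np.sort(events + 0.05))]
        res = peth(spikes, events)
        peak_lag = res.lags[np.argmax(res.z[0])]
        assert abs(peak_lag - 0.05) < 0.015

    def test_identical_units_adjacent_in_sorts(self):
        rng = np.random.default_rng(11)
        events = np.arange(5.0, 500.0, 5.0)
        t1 = np.sort(events + 0.05)
        spikes = [SpikeTrain("a", t1), SpikeTrain("b", t1.copy()),
                  SpikeTrain("c", np.sort(events - 0.2))]
        res = peth(spikes, events, smooth_sd=None)
        ia, ib = list(res.order_peak).index(0), list(res.order_peak).index(1)
        assert abs(ia - ib) == 1
        ia, ib = list(res.order_pc).index(0), list(res.order_pc).index(1)
        assert abs(ia - ib) == 1

    def test_silent_unit_flagged_zero_row(self):
        events = [10.0, 20.0]
        spikes = [SpikeTrain("quiet", [500.0])]
        res = peth(spikes, events)
        assert res.silent_units == ["quiet"]
        assert np.all(res.z[0] == 0)

    def test_z_normalization_per_unit(self):
        rng = np.random.default_rng(12)
        spikes = [SpikeTrain("u", np.sort(rng.uniform(0, 300, 3000)))]
        events = np.sort(rng.uniform(5, 295, 60))
        res = peth(spikes, events)
        assert res.z[0].mean() == pytest.approx(0.0, abs=1e-9)
        assert res.z[0].std() == pytest.approx(1.0, abs=1e-6)


class TestProfileSimilarity:
    def test_identity_gives_unit_correlation(self):
        rng = np.random.default_rng(13)
        a = rng.standard_normal((10, 50))
        rs, t, p, excl = profile_similarity(a, a)
        assert np.allclose(rs, 1.0)

    def test_independent_profiles_near_zero(self):
        rng = np.random.default_rng(14)
        a = rng.standard_normal((200, 50))
        b = rng.standard_normal((200, 50))
        rs, t, p, excl = profile_similarity(a, b)
        assert abs(np.mean(rs)) < 0.05

    def test_shared_template_significant(self):
        rng = np.random.default_rng(15)
        template = np.sin(np.linspace(0, 3, 50))
        a = template + 0.5 * rng.standard_normal((30, 50))
        b = template + 0.5 * rng.standard_normal((30, 50))
        rs, t, p, excl = profile_similarity(a, b)
        assert np.mean(rs) > 0.2
        assert p < 0.001

    def test_zero_variance_excluded(self):
        a = np.vstack([np.zeros(20), np.arange(20.0)])
        b = np.vstack([np.arange(20.0), np.arange(20.0)])
        rs, t, p, excl = profile_similarity(a, b)
        assert excl == 1 and len(rs) == 1


class TestEpisodeQuartiles:
    def test_uniform_rate_equal_bins(self):
        eps = [StateEpisode(REM, 0.0, 100.0)]
        ev = EventTable.from_arrays(np.linspace(0.5, 99.5, 200))
        prof = episode_quartile_profile(ev, eps, REM)
        assert np.allclose(prof, prof[0], rtol=0.05)

    def test_final_quarter_only(self):
        eps = [StateEpisode(REM, 0.0, 100.0)]
        ev = EventTable.from_arrays(np.linspace(76.0, 99.0, 50))
        prof = episode_quartile_profile(ev, eps, REM)
        assert prof[0] == prof[1] == prof[2] == 0
        assert prof[3] > 0

    def test_ramped_generator_monotone_profile(self):
        cfg = synth.SessionConfig(duration=1500.0, seed=51)
        cfg.pwave.rem_ramp = 1.6
        cfg.pwave.doublet_prob = 0.0
        cfg.states.mean_durations = {WAKE: 40.0, NREM: 60.0, REM: 200.0}
        ses = synth.generate_session(cfg)
        ev = EventTable.from_arrays(ses.truth.pwave_times)
        prof = episode_quartile_profile(ev, ses.hypnogram.episodes(), REM)
        assert prof[0] < prof[1] < prof[3]
        assert prof[0] < prof[2] <= prof[3] * 1.2

    def test_missing_state_errors(self):
        eps = [StateEpisode(NREM, 0.0, 40.0)]
        with pytest.raises(ValueError, match="REM"):
            episode_quartile_profile(EventTable.empty(), eps, REM)


class TestSDR:
    def test_identical_traces_exactly_unity(self):
        x, _, _ = synth.generate_coupled_pair(([1.0], [1.0]), 8000, seed=0, noise_sd=0.0)
        df, summary = sdr(x, x, np.arange(0.5, 7.5, 0.5))
        assert np.all(df["rho_xy"] == 1.0)
        assert np.all(df["rho_yx"] == 1.0)

    def test_scale_invariance(self):
        x, y, _ = synth.generate_coupled_pair(([1.0, 0.4], [1.0, -0.5]), 20_000,
                                              seed=1, noise_sd=0.1)
        events = np.arange(1.0, 19.0, 1.0)
        df1, _ = sdr(x, y, events)
        xs = SignalTrace(x.samples * 7.3, x.rate, "xs")
        ys = SignalTrace(y.samples * 0.02, y.rate, "ys")
        df2, _ = sdr(xs, ys, events)
        assert np.allclose(df1["rho_xy"], df2["rho_xy"])
        assert np.allclose(df1["rho_yx"], df2["rho_yx"])

    def test_directionality_preferred_for_filtered_pairs(self):
        wins = 0
        for seed in range(25):
            x, y, _ = synth.generate_coupled_pair(([1.0, 0.5, 0.2], [1.0, -0.6]),
                                                  20_000, seed=seed, noise_sd=0.2)
            _, summary = sdr(x, y, np.arange(1.0, 19.0, 0.75))
            wins += summary["mean_rho_xy"] > summary["mean_rho_yx"]
        assert wins > 20

    def test_independent_noise_no_preference(self):
        rng = np.random.default_rng(2)
        x = SignalTrace(rng.standard_normal(20_000), RATE, "x")
        y = SignalTrace(rng.standard_normal(20_000), RATE, "y")
        df, summary = sdr(x, y, np.arange(1.0, 19.0, 0.75))
        assert abs(summary["mean_rho_xy"] - summary["mean_rho_yx"]) < 0.1


class TestEpisodeDurationModel:
    def test_exact_fit_without_noise(self):
        x = np.tile(np.linspace(0.1, 1.0, 10), 4)
        g = np.repeat(np.arange(4), 10)
        y = 60.0 * x + 5.0
        res = episode_duration_model(y, x, g)
        assert res.beta == pytest.approx(60.0, abs=1e-6)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            episode_duration_model([1, 2, 3, 4], [0.5] * 4, [0, 0, 1, 1])

    def test_parameter_recovery_with_random_intercepts(self):
        hits = 0
        for s in range(25):
            rng = np.random.default_rng(s)
            rows = []
            for rec in range(8):
                b = rng.normal(0, 10)
                x = rng.uniform(0.2, 1.2, 20)
                y = 60.0 * x + b + rng.normal(0, 5, 20)
                rows.extend(zip(y, x, [rec] * 20))
            y, x, g = map(np.array, zip(*rows))
            res = episode_duration_model(y, x, g)
            hits += res.ci_low <= 60.0 <= res.ci_high
        assert hits >= 22  # 95% CI coverage


class TestEventPowerXcorrSymmetry:
    def test_time_reversal_mirrors_profile(self):
        rng = np.random.default_rng(16)
        n = 400_000
        power = 1.0 + 0.05 * rng.standard_normal(n)
        events = np.sort(rng.uniform(10, 390, 60))
        for t in events:
            i = int(t * RATE)
            power[i:i + 300] -= 0.4
        tr = SignalTrace(power, RATE)
        lags, z, mean = event_power_xcorr(tr, events, window=(-3, 3), baseline=(-3, -2.5))
        rev = SignalTrace(power[::-1].copy(), RATE)
        ev_rev = np.sort((n - 1) / RATE - events)
        lags_r, z_r, mean_r = event_power_xcorr(rev, ev_rev, window=(-3, 3),
                                                baseline=(2.5, 3.0))
        assert np.allclose(mean_r[::-1], mean, atol=1e-6)
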