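"""Laminar branch: band-pass, spike detection, PSTH, current source density."""

import numpy as np
import pytest

import sepmap.laminar as lam
import sepmap.preprocessing as pp
import sepmap.synthetic as syn
from sepmap.containers import AveragedResponse, Recording
from sepmap.geometry import ProbeGeometry


def probe_recording(data, fs=20000.0, events=(1.0,), n_sites=None):
    n_sites = n_sites or data.shape[0]
    return Recording(data=np.asarray(data, dtype=float), fs=fs,
                     geometry=ProbeGeometry(n_sites=n_sites),
                     event_times=np.asarray(events))


class TestBandpass:
    def test_in_band_tone_passes_unscathed(self):
        fs = 20000.0
        t = np.arange(int(fs)) / fs
        tone = np.sin(2 * np.pi * 1000.0 * t)
        rec = probe_recording(np.tile(tone, (3, 1)), fs=fs)
        out = lam.bandpass_mua(rec)
        gain = np.abs(out.data[0, 5000:-5000]).max()
        assert gain == pytest.approx(1.0, abs=0.05)

    def test_out_of_band_tone_heavily_attenuated(self):
        fs = 20000.0
        t = np.arange(int(fs * 2)) / fs
        tone = np.sin(2 * np.pi * 50.0 * t)
        rec = probe_recording(np.tile(tone, (3, 1)), fs=fs)
        out = lam.bandpass_mua(rec)
        atten_db = 20 * np.log10(np.abs(out.data[0, 5000:-5000]).max())
        assert atten_db < -40.0

    def test_dc_offset_removed(self):
        rec = probe_recording(np.full((3, 20000), 7.0))
        out = lam.bandpass_mua(rec)
        assert np.abs(out.data[:, 5000:-5000]).max() < 1e-6

    def test_insufficient_sampling_rate_rejected(self):
        rec = probe_recording(np.zeros((3, 1000)), fs=6000.0)
        with pytest.raises(ValueError, match="too low"):
            lam.bandpass_mua(rec)


class TestSpikeDetection:
    def test_injected_spikes_recovered_precisely(self, probe):
        """At high SNR every ground-truth spike is found within 0.2 ms and
        nothing else: zero false positives (threshold raised so the
        Gaussian-noise crossing probability is negligible)."""
        cfg = syn.ScenarioConfig(components=(), n_trials=4, noise_sd=2.0,
                                 rng_seed=31, laminar=syn.LaminarSpec())
        rec = syn.simulate_laminar_session(cfg, probe, 20000.0)
        trains = lam.detect_spikes(lam.bandpass_mua(rec), k=6.0)
        gt = rec.ground_truth["spike_times_s"]
        for train in trains:
            truth = np.asarray(gt[train.channel])
            # every detection corresponds to a real spike (no false positives)
            for t in train.times:
                assert np.min(np.abs(truth - t)) <= 0.2e-3
            # and every real spike is detected
            for t0 in truth:
                assert np.min(np.abs(train.times - t0)) <= 0.2e-3

    def test_false_positive_rate_on_pure_noise(self):
        """MAD thresholding at k = 4.5 stays below 0.1 false spikes per
        second on band-limited Gaussian noise (Monte-Carlo estimate)."""
        rng = np.random.default_rng(7)
        fs, dur = 20000.0, 120.0
        rec = probe_recording(rng.standard_normal((3, int(fs * dur))) * 10.0,
                              fs=fs)
        trains = lam.detect_spikes(lam.bandpass_mua(rec))
        pooled_rate = sum(t.n_spikes for t in trains) / (3 * dur)
        assert pooled_rate < 0.1

    def test_empty_signal_gives_empty_trains(self):
        rec = probe_recording(np.zeros((3, 20000)))
        trains = lam.detect_spikes(rec)
        assert all(t.n_spikes == 0 for t in trains)

    def test_refractory_spacing_enforced(self, laminar_session):
        trains = lam.detect_spikes(lam.bandpass_mua(laminar_session),
                                   refractory=1.0)
        for t in trains:
            if t.n_spikes > 1:
                assert np.diff(t.times).min() >= 1.0e-3 - 1e-9


class TestPSTH:
    @staticmethod
    def train(times, channel="D1"):
        return lam.SpikeTrain(times=np.asarray(times), channel=channel,
                              threshold_used=-10.0)

    def test_left_edge_spike_counts_in_its_bin(self):
        trains = [self.train([1.005])]  # exactly +5 ms after the event
        hist = lam.psth(trains, np.array([1.0]), bin_width=5.0,
                        window=(0.0, 20.0))
        assert hist.counts[1, 0] == 1
        assert hist.counts.sum() == 1

    def test_spikes_at_seven_ms_fall_in_5_10_bin(self):
        trains = [self.train([1.007, 2.007, 3.007])]
        hist = lam.psth(trains, np.array([1.0, 2.0, 3.0]), bin_width=5.0,
                        window=(0.0, 20.0))
        assert hist.counts[1, 0] == 3

    def test_total_counts_conserved(self, laminar_session):
        trains = lam.detect_spikes(lam.bandpass_mua(laminar_session))
        window = (-100.0, 300.0)
        hist = lam.psth(trains, laminar_session.event_times, bin_width=5.0,
                        window=window)
        expected = 0
        for t in trains:
            for ev in laminar_session.event_times:
                rel = (t.times - ev) * 1000.0
                expected += int(((rel >= window[0]) & (rel < window[1])).sum())
        assert hist.counts.sum() == expected

    def test_evoked_rate_peaks_near_sink_depth(self, laminar_session, probe):
        trains = lam.detect_spikes(lam.bandpass_mua(laminar_session))
        hist = lam.psth(trains, laminar_session.event_times)
        rates = hist.rate_hz()
        _, ch = np.unravel_index(int(np.argmax(rates)), rates.shape)
        sink = laminar_session.ground_truth["sink_depth_um"]
        # depth tuning scale (120 μm) spans >2 sites, so allow ±2 sites
        assert abs(probe.depths[ch] - sink) <= 2 * probe.site_spacing


class TestCSD:
    @staticmethod
    def avg_from_profile(profile, n_times=10, fs=2000.0):
        data = np.tile(np.asarray(profile, dtype=float)[:, None],
                       (1, n_times))
        return AveragedResponse(
            data=data, fs=fs, pre=1e-3 * n_times / 4, post=1e-3 * n_times,
            n_trials_averaged=1,
            geometry=ProbeGeometry(n_sites=len(profile)),
        )

    def test_linear_profile_has_zero_csd(self):
        avg = self.avg_from_profile([1.0, 2.0, 3.0, 4.0, 5.0])
        assert np.abs(lam.csd(avg).values).max() < 1e-12

    def test_three_site_example_forced_by_formula(self):
        avg = self.avg_from_profile([0.0, 1.0, 4.0])
        out = lam.csd(avg, spacing=1.0)
        assert np.allclose(out.values, -2.0)

    def test_matches_brute_force_second_difference(self, rng):
        phi = rng.normal(size=(16, 40))
        avg = AveragedResponse(data=phi, fs=2000.0, pre=0.01, post=0.01,
                               n_trials_averaged=1,
                               geometry=ProbeGeometry(n_sites=16))
        out = lam.csd(avg)
        h = 50.0
        for i in range(1, 15):
            for j in range(40):
                expected = -(phi[i - 1, j] - 2 * phi[i, j]
                             + phi[i + 1, j]) / h**2
                assert out.values[i - 1, j] == pytest.approx(expected)

    def test_linearity(self, rng):
        p1 = rng.normal(size=(8, 20))
        p2 = rng.normal(size=(8, 20))
        geom = ProbeGeometry(n_sites=8)

        def csd_of(p):
            avg = AveragedResponse(data=p, fs=2000.0, pre=0.005, post=0.005,
                                   n_trials_averaged=1, geometry=geom)
            return lam.csd(avg).values

        combined = csd_of(2.0 * p1 + 3.0 * p2)
        assert np.allclose(combined, 2.0 * csd_of(p1) + 3.0 * csd_of(p2))

    def test_depth_constant_offset_cancels(self, rng):
        """Volume-conducted (depth-uniform) signal leaves the CSD unchanged
        — the stated purpose of the transform."""
        phi = rng.normal(size=(8, 20))
        offset = rng.normal(size=(1, 20))  # same at every depth
        geom = ProbeGeometry(n_sites=8)
        a1 = AveragedResponse(data=phi, fs=2000.0, pre=0.005, post=0.005,
                              n_trials_averaged=1, geometry=geom)
        a2 = AveragedResponse(data=phi + offset, fs=2000.0, pre=0.005,
                              post=0.005, n_trials_averaged=1, geometry=geom)
        assert np.allclose(lam.csd(a1).values, lam.csd(a2).values)

    def test_compact_dipole_csd_sums_to_zero(self, probe):
        """Discrete conservation: total CSD of a compact profile vanishes
        up to edge truncation."""
        depths = probe.depths
        u = (depths - 425.0) / 80.0
        profile = -200.0 * (1 - u * u) * np.exp(-u * u / 2)
        avg = self.avg_from_profile(profile)
        vals = lam.csd(avg).values[:, 0]
        assert abs(vals.sum()) < 0.02 * np.abs(vals).sum()

    def test_sink_recovered_at_configured_depth(self, laminar_session):
        lfp = lam.extract_lfp(laminar_session)
        ep = pp.baseline_correct(pp.epoch(lfp, pre=0.5, post=1.0))
        csd_map = lam.csd(pp.average_epochs(ep))
        depth, t_ms = csd_map.sink()
        truth = laminar_session.ground_truth["sink_depth_um"]
        assert abs(depth - truth) <= 50.0  # within one site
        assert t_ms == pytest.approx(
            laminar_session.ground_truth["laminar"]["lfp_latency"], abs=3.0
        )

    def test_early_sink_precedes_superficial_n_component(self,
                                                         laminar_session):
        """The thalamorecipient sink leads the delayed surface-negative
        component in time."""
        lfp = lam.extract_lfp(laminar_session)
        ep = pp.baseline_correct(pp.epoch(lfp, pre=0.5, post=1.0))
        csd_map = lam.csd(pp.average_epochs(ep))
        _, sink_t = csd_map.sink()
        n_latency = syn.latency_at_age(syn.N_LATENCY_MODEL, 8)
        assert sink_t < n_latency

    def test_nonuniform_spacing_rejected(self, rng):
        class Wonky(ProbeGeometry):
            @property
            def depths(self):
                d = super().depths.copy()
                d[3] += 10.0
                return d

        avg = AveragedResponse(data=rng.normal(size=(16, 5)), fs=2000.0,
                               pre=0.001, post=0.0015, n_trials_averaged=1,
                               geometry=Wonky(n_sites=16))
        with pytest.raises(ValueError, match="uniformly spaced"):
            lam.csd(avg)
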