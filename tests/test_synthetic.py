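"""Statistical and determinism properties of the synthetic generators."""

import numpy as np
import pytest
from scipy import stats

from hdmea import (
    ArrayGeometry,
    StimulationProtocol,
    count_puncta,
    detect_spikes,
    granulometric_filter,
)
from hdmea import synthetic as syn
from hdmea.activity import detect_bursts


class TestSpontaneous:
    def test_degenerate_lognormal_gives_uniform_rates(self, small_geometry):
        """sigma=0 at 1 ev/s: observed mean rate within 3 SE over 600 s."""
        regime = syn.RegimeSpec(regime="tonic", rate_log10_mean=0.0, rate_log10_sd=0.0)
        ts, gt = syn.gen_spontaneous(small_geometry, regime, 600.0, seed=1)
        assert np.all(gt.true_rates == 1.0)
        n = small_geometry.n_electrodes
        mean_rate = ts.n_spikes / (n * 600.0)
        se = np.sqrt(1.0 / (n * 600.0))  # Poisson SE of the pooled mean rate
        assert abs(mean_rate - 1.0) < 3 * se

    def test_rates_converge_to_ground_truth(self, small_geometry):
        """Law of large numbers: per-electrode empirical rates near truth at 3 SE."""
        regime = syn.RegimeSpec(regime="tonic", rate_log10_mean=0.3, rate_log10_sd=0.2)
        dur = 600.0
        ts, gt = syn.gen_spontaneous(small_geometry, regime, dur, seed=2)
        emp = ts.rates()
        se = np.sqrt(gt.true_rates / dur)
        within = np.abs(emp - gt.true_rates) <= 3 * se
        assert within.mean() > 0.95

    def test_log_rates_pass_normality_at_4096(self, full_geometry):
        ts, gt = syn.gen_spontaneous(
            full_geometry, syn.RegimeSpec.tonic(), 10.0, seed=3
        )
        stat, p = stats.normaltest(np.log10(gt.true_rates))
        assert p > 0.01

    def test_bursting_ground_truth_recovered_by_detector(self):
        """Programmed bursts (6 spikes at 20 ms ISI) are all found per electrode."""
        g = ArrayGeometry(n_rows=4, n_cols=4)
        regime = syn.RegimeSpec(
            regime="bursting",
            rate_log10_mean=-1.3,  # negligible background
            rate_log10_sd=0.0,
            burst_rate_per_min=1.0,
            intra_burst_isi_ms=20.0,
            spikes_per_burst=6,
            sync_fraction=1.0,
        )
        ts, gt = syn.gen_spontaneous(g, regime, 600.0, seed=4)
        for e, epochs in gt.burst_epochs.items():
            found = detect_bursts(ts.trains[e], e)
            assert len(found) == len(epochs)

    def test_fixed_seed_is_deterministic(self, small_geometry):
        a, _ = syn.gen_spontaneous(small_geometry, syn.RegimeSpec.tonic(), 10.0, seed=7)
        b, _ = syn.gen_spontaneous(small_geometry, syn.RegimeSpec.tonic(), 10.0, seed=7)
        assert set(a.trains) == set(b.trains)
        for e in a.trains:
            np.testing.assert_array_equal(a.trains[e], b.trains[e])

    def test_nonfinite_regime_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            syn.RegimeSpec(rate_log10_mean=np.nan)


class TestRawTraces:
    def test_pure_noise_sd(self):
        g = ArrayGeometry(n_rows=1, n_cols=1)
        ts = syn.gen_spontaneous(g, syn.RegimeSpec(rate_log10_mean=-9.0, rate_log10_sd=0), 1.0, 1)[0]
        rec = syn.gen_raw_traces(ts, syn.RegimeSpec(noise_sd_uv=5.0), 7800.0, seed=2)
        assert abs(np.std(rec.traces[0]) - 5.0) / 5.0 < 0.05

    def test_single_injected_spike_detected_once(self):
        """One 12xSD spike at t=0.5 s found within +/-1 ms by the 9xSD rule."""
        from hdmea import SpikeTrainSet

        g = ArrayGeometry(n_rows=1, n_cols=1)
        ts = SpikeTrainSet(g, 1.0, {0: np.array([0.5])})
        regime = syn.RegimeSpec(noise_sd_uv=5.0, spike_amplitude_sd=12.0)
        rec = syn.gen_raw_traces(ts, regime, 7800.0, seed=3, unit_class={0: 0})
        det = detect_spikes(rec)
        assert len(det.trains.get(0, [])) == 1
        assert abs(det.trains[0][0] - 0.5) < 0.001

    def test_identical_seed_bit_identical(self, small_geometry):
        ts, gt = syn.gen_spontaneous(small_geometry, syn.RegimeSpec.sparse(), 1.0, 5)
        r1 = syn.gen_raw_traces(ts, syn.RegimeSpec.sparse(), 7800.0, 6, gt.unit_class)
        r2 = syn.gen_raw_traces(ts, syn.RegimeSpec.sparse(), 7800.0, 6, gt.unit_class)
        np.testing.assert_array_equal(r1.traces, r2.traces)

    def test_subthreshold_amplitude_warns(self, small_geometry):
        ts, _ = syn.gen_spontaneous(small_geometry, syn.RegimeSpec.sparse(), 1.0, 5)
        with pytest.warns(UserWarning, match="untestable"):
            syn.gen_raw_traces(
                ts, syn.RegimeSpec(spike_amplitude_sd=0.5), 7800.0, seed=6
            )


class TestWaveformBank:
    def test_pure_class_bank_is_uniformly_labelled(self):
        snippets, labels = syn.gen_waveform_bank((1, 0, 0, 0), 100, seed=1)
        assert np.all(labels == 0)
        assert snippets.shape == (100, round(0.004 * 7800))

    def test_one_exemplar_per_class(self):
        for cls in range(4):
            mix = [0.0] * 4
            mix[cls] = 1.0
            snippets, labels = syn.gen_waveform_bank(mix, 1, seed=2)
            assert labels[0] == cls

    def test_bad_mix_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            syn.gen_waveform_bank((0.5, 0.5, 0.5, 0.5), 10)


class TestEvoked:
    def test_zero_jitter_fast_site_hits_70ms_exactly(self):
        g = ArrayGeometry(n_rows=16, n_cols=16, stim_sites=((8, 8),))
        proto = StimulationProtocol.sequential([0], n_pulses=35)
        spec = syn.EvokedSpec(latency_jitter_s=0.0, background_rate=0.0, reliability=1.0)
        ts, gt = syn.gen_evoked_experiment(g, proto, {0: "fast"}, seed=1, spec=spec)
        for (site, e), lat in gt.first_spike_latencies.items():
            assert np.allclose(lat[np.isfinite(lat)], 0.070)

    def test_long_site_support_extends_beyond_300ms(self):
        g = ArrayGeometry(n_rows=16, n_cols=16, stim_sites=((8, 8),))
        proto = StimulationProtocol.sequential([0], n_pulses=35)
        spec = syn.EvokedSpec(background_rate=0.0, reliability=1.0)
        ts, gt = syn.gen_evoked_experiment(g, proto, {0: "long"}, seed=2, spec=spec)
        rel = np.concatenate(
            [ts.trains[e] - p for e in ts.trains for p in proto.pulse_times[0]]
        )
        rel = rel[(rel > 0) & (rel < 0.5)]
        assert rel.max() > 0.3

    def test_artifacts_confined_to_20um(self):
        g = ArrayGeometry(n_rows=16, n_cols=16, pitch=42.0, stim_sites=((8, 8),))
        proto = StimulationProtocol.sequential([0], n_pulses=35)
        ts, gt = syn.gen_evoked_experiment(g, proto, {0: "fast"}, seed=3)
        d = g.distances_to((8, 8)) * g.pitch
        for e in gt.artifact_events:
            assert d[e] <= 20.0


class TestPunctaImage:
    def test_blank_image_counts_zero(self):
        img, gt = syn.gen_puncta_image(0, seed=1)
        _, mask = granulometric_filter(img)
        assert count_puncta(mask, img).count == 0

    def test_same_seed_identical_pixels(self):
        a, _ = syn.gen_puncta_image(20, seed=9)
        b, _ = syn.gen_puncta_image(20, seed=9)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_impossible_density_raises(self):
        with pytest.raises(ValueError, match="density"):
            syn.gen_puncta_image(5000, shape=(64, 64))
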