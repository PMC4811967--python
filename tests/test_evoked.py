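"""Artifact removal, PSTH, response classification, latencies and rings."""

import numpy as np
import pandas as pd
import pytest

from hdmea import (
    AnalysisConfig,
    ArrayGeometry,
    RingSpec,
    SpikeTrainSet,
    StimulationProtocol,
    baseline_rate,
    classify_response,
    compute_psth,
    first_spike_latencies,
    latency_vs_distance,
    remove_artifacts,
    ring_area,
)
from hdmea import synthetic as syn
from hdmea.evoked import PSTH

G = ArrayGeometry(n_rows=16, n_cols=16, stim_sites=((8, 8),))
PROTO = StimulationProtocol.sequential([0], n_pulses=35)


class TestRingGeometry:
    def test_printed_region_sizes(self):
        # the printed region sizes ~50, ~700 and ~2827 equal pi r^2
        assert ring_area(4) == pytest.approx(50.27, rel=0.01)
        assert ring_area(15) == pytest.approx(700.0, rel=0.01)
        assert ring_area(30) == pytest.approx(2827.43, rel=0.01)

    def test_area_is_pi_r_squared_exactly(self):
        for r in (2, 4, 15, 26, 30):
            assert ring_area(r) == np.pi * r**2

    def test_rings_partition_disc_of_radius_30(self):
        g = ArrayGeometry(stim_sites=((32, 32),))
        d = g.distances_to((32, 32))
        rings = RingSpec()
        idx = rings.assign(d)
        inside = d <= 30
        assert np.all(idx[inside] >= 0)
        assert np.all(idx[~inside] == -1)
        # pairwise disjoint by construction (single index per electrode);
        # the union over rings is the full disc
        assert np.array_equal(np.flatnonzero(idx >= 0), np.flatnonzero(inside))

    def test_nonincreasing_radii_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            RingSpec(radii=(4, 4, 6))


class TestRemoveArtifacts:
    def test_events_in_discard_window_removed(self):
        times = np.sort(np.concatenate([PROTO.pulse_times[0] + 0.004]))
        ts = SpikeTrainSet(G, PROTO.end_time + 1, {0: times})
        out = remove_artifacts(ts, PROTO)
        assert out.n_spikes == 0

    def test_no_pulses_is_identity(self):
        empty = StimulationProtocol(site_order=(), pulse_times={})
        times = np.sort(np.random.default_rng(0).uniform(0, 10, 50))
        ts = SpikeTrainSet(G, 10.0, {3: times})
        out = remove_artifacts(ts, empty)
        np.testing.assert_array_equal(out.trains[3], times)

    def test_generator_artifacts_exactly_removed(self):
        spec = syn.EvokedSpec(background_rate=0.0)
        ts, gt = syn.gen_evoked_experiment(G, PROTO, {0: "fast"}, seed=1, spec=spec)
        out = remove_artifacts(ts, PROTO)
        # all artifact events gone...
        for e, art in gt.artifact_events.items():
            kept = out.trains.get(e, np.empty(0))
            assert not np.isin(art, kept).any()
        # ...and all genuine evoked spikes (latency > 10 ms by construction) kept
        n_genuine = sum(
            len(t) for e, t in gt.spike_times.items()
        ) - sum(len(a) for a in gt.artifact_events.values())
        assert out.n_spikes == n_genuine

    def test_hard_threshold_below_detection_rejected(self):
        ts = SpikeTrainSet(G, 10.0, {})
        with pytest.raises(ValueError, match="exceed"):
            remove_artifacts(ts, PROTO, hard_threshold_uv=30.0, detection_threshold_uv=45.0)


class TestComputePsth:
    def test_no_spikes_gives_zero_psth(self):
        ts = SpikeTrainSet(G, PROTO.end_time + 1, {})
        psth = compute_psth(ts, PROTO, 0)
        assert psth.mean.sum() == 0
        assert psth.n_trials == 35

    def test_hand_countable_single_spike_per_trial(self):
        """One spike at +30 ms per trial: first bin [10,35) has mean 1, rest 0."""
        times = np.sort(PROTO.pulse_times[0] + 0.030)
        ts = SpikeTrainSet(G, PROTO.end_time + 1, {5: times})
        psth = compute_psth(ts, PROTO, 0)
        assert psth.edges[0] == pytest.approx(0.010)
        assert np.allclose(np.diff(psth.edges), 0.025)
        assert psth.mean[0] == 1.0
        assert psth.mean[1:].sum() == 0.0

    def test_band_ordering(self):
        """The percentile bands are ordered, and the full (min/max) band
        always brackets the trial-mean."""
        spec = syn.EvokedSpec(background_rate=0.0)
        ts, _ = syn.gen_evoked_experiment(G, PROTO, {0: "fast"}, seed=2, spec=spec)
        clean = remove_artifacts(ts, PROTO)
        psth = compute_psth(clean, PROTO, 0)
        assert np.all(psth.lower <= psth.upper)
        full = compute_psth(
            clean, PROTO, 0, config=AnalysisConfig(percentile_band=(0.0, 100.0))
        )
        assert np.all(full.lower <= full.mean + 1e-12)
        assert np.all(full.mean <= full.upper + 1e-12)

    def test_count_conservation(self):
        """Binned counts equal the raw spike count in the union of windows."""
        ts, _ = syn.gen_evoked_experiment(G, PROTO, {0: "long"}, seed=3)
        clean = remove_artifacts(ts, PROTO)
        psth = compute_psth(clean, PROTO, 0)
        raw = 0
        for t in clean.trains.values():
            for p in PROTO.pulse_times[0]:
                raw += np.sum((t >= p + psth.edges[0]) & (t < p + psth.edges[-1]))
        assert psth.total_count == raw

    def test_fast_site_mass_within_100ms(self):
        spec = syn.EvokedSpec(background_rate=0.0)
        ts, _ = syn.gen_evoked_experiment(G, PROTO, {0: "fast"}, seed=4, spec=spec)
        psth = compute_psth(remove_artifacts(ts, PROTO), PROTO, 0)
        centers = 0.5 * (psth.edges[:-1] + psth.edges[1:])
        frac = psth.mean[centers < 0.100].sum() / psth.mean.sum()
        assert frac >= 0.95

    def test_unknown_site_rejected(self):
        ts = SpikeTrainSet(G, PROTO.end_time + 1, {})
        with pytest.raises(ValueError, match="no pulses"):
            compute_psth(ts, PROTO, 9)


class TestClassifyResponse:
    def _psth(self, mean, edges=None):
        n = len(mean)
        edges = (
            np.asarray(edges)
            if edges is not None
            else 0.010 + 0.025 * np.arange(n + 1)
        )
        mean = np.asarray(mean, dtype=float)
        return PSTH(
            site=0,
            edges=edges,
            mean=mean,
            lower=np.zeros(n),
            upper=mean,
            trial_counts=np.tile(mean, (35, 1)),
        )

    def test_supra_bins_only_before_85ms_is_fast(self):
        mean = np.zeros(19)
        mean[:3] = 5.0  # bins [10,85) ms
        c = classify_response(self._psth(mean), baseline=0.5)
        assert c.response_class == "fast"
        assert c.duration_ms == pytest.approx(85.0)

    def test_supra_bins_through_460ms_is_long_lasting(self):
        mean = np.ones(19) * 5.0
        mean[18] = 0.0
        c = classify_response(self._psth(mean), baseline=0.5)
        assert c.response_class == "long-lasting"
        assert c.duration_ms == pytest.approx(460.0)

    def test_no_supra_run_is_non_responsive(self):
        c = classify_response(self._psth(np.zeros(19)), baseline=0.5)
        assert c.response_class == "non-responsive"

    def test_late_run_outside_onset_window_ignored(self):
        mean = np.zeros(19)
        mean[10:13] = 5.0  # starts at 260 ms: not an evoked onset
        c = classify_response(self._psth(mean), baseline=0.5)
        assert c.response_class == "non-responsive"

    def test_missing_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            classify_response(self._psth(np.zeros(19)), baseline=np.nan)


class TestFirstSpikeLatencies:
    def test_deterministic_70ms_every_trial(self):
        times = np.sort(PROTO.pulse_times[0] + 0.070)
        ts = SpikeTrainSet(G, PROTO.end_time + 1, {7: times})
        lat = first_spike_latencies(ts, PROTO, 0)
        assert set(lat) == {7}
        assert np.allclose(lat[7], 0.070)

    def test_9_of_35_trials_excluded(self):
        times = np.sort(PROTO.pulse_times[0][:9] + 0.070)
        ts = SpikeTrainSet(G, PROTO.end_time + 1, {7: times})
        assert first_spike_latencies(ts, PROTO, 0) == {}

    def test_10_of_35_trials_kept(self):
        times = np.sort(PROTO.pulse_times[0][:10] + 0.070)
        ts = SpikeTrainSet(G, PROTO.end_time + 1, {7: times})
        assert 7 in first_spike_latencies(ts, PROTO, 0)

    def test_spike_at_10ms_or_before_not_counted(self):
        times = np.sort(PROTO.pulse_times[0] + 0.010)
        ts = SpikeTrainSet(G, PROTO.end_time + 1, {7: times})
        assert first_spike_latencies(ts, PROTO, 0) == {}

    def test_programmed_latencies_recovered(self):
        g2 = ArrayGeometry(n_rows=16, n_cols=16, stim_sites=((8, 8), (4, 4)))
        proto = StimulationProtocol.sequential([0, 1], n_pulses=35)
        spec = syn.EvokedSpec(background_rate=0.0, reliability=0.9)
        ts, gt = syn.gen_evoked_experiment(
            g2, proto, {0: "fast", 1: "long"}, seed=5, spec=spec
        )
        clean = remove_artifacts(ts, proto)
        for site, target in ((0, 70.0), (1, 120.0)):
            lat = first_spike_latencies(clean, proto, site)
            vals = np.concatenate([v[np.isfinite(v)] for v in lat.values()])
            assert abs(vals.mean() * 1000 - target) < 5.0


class TestLatencyVsDistance:
    def test_uniform_latency_is_flat_across_rings(self):
        g = ArrayGeometry(stim_sites=((32, 32),))
        proto = StimulationProtocol.sequential([0], n_pulses=35)
        d = g.distances_to((32, 32))
        trains = {
            int(e): np.sort(proto.pulse_times[0] + 0.080)
            for e in np.flatnonzero(d <= 30)[::7]
        }
        ts = SpikeTrainSet(g, proto.end_time + 1, trains)
        lat = first_spike_latencies(ts, proto, 0)
        table = latency_vs_distance(lat, g, 0)
        occupied = table.dropna(subset=["mean_latency_ms"])
        assert len(occupied) > 5
        assert np.allclose(occupied["mean_latency_ms"], 80.0)

    def test_empty_rings_flagged(self):
        g = ArrayGeometry(stim_sites=((32, 32),))
        table = latency_vs_distance({}, g, 0)
        assert (table["n_electrodes"] == 0).all()
        assert table["mean_latency_ms"].isna().all()

    def test_off_grid_site_rejected(self):
        g = ArrayGeometry(stim_sites=((32, 32),))
        with pytest.raises(ValueError, match="site"):
            latency_vs_distance({}, g, 3)
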