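"""Evoked responses: PSTH, response form, first-spike latency, distance rings.

Simulates two stimulation sites (one fast, one long-lasting response class,
35 biphasic pulses each at 0.2 Hz), removes artifacts and the 10 ms
post-stimulus window, and runs the full evoked pipeline.
"""

import numpy as np

import hdmea
from hdmea import synthetic as syn

geometry = hdmea.ArrayGeometry(stim_sites=((16, 16), (48, 48)))
protocol = hdmea.StimulationProtocol.sequential([0, 1], n_pulses=35)
spec = syn.EvokedSpec(background_rate=0.02)
trains, truth = syn.gen_evoked_experiment(
    geometry, protocol, {0: "fast", 1: "long"}, seed=4, spec=spec
)
clean = hdmea.remove_artifacts(trains, protocol)

for site, programmed in ((0, "fast"), (1, "long")):
    psth = hdmea.compute_psth(clean, protocol, site)
    base = hdmea.baseline_rate(clean, protocol, site)
    cls = hdmea.classify_response(psth, base)
    lat = hdmea.first_spike_latencies(clean, protocol, site)
    vals = np.concatenate([v[np.isfinite(v)] for v in lat.values()])
    print(
        f"site {site} (programmed {programmed:4s}): {cls.response_class:14s} "
        f"duration {cls.duration_ms:5.0f} ms, "
        f"first spike {vals.mean() * 1000:5.1f} ms over {len(lat)} reliable electrodes"
    )

rings = hdmea.latency_vs_distance(hdmea.first_spike_latencies(clean, protocol, 0), geometry, 0)
print(rings[["radius", "area", "n_electrodes", "mean_latency_ms"]].head(6).to_string(index=False))
# Fast sites stay supra-baseline for ~100 ms with first spikes near 70 ms;
# long-lasting sites extend toward 500 ms with onsets near 120 ms. The
# per-ring means are flat: latency does not depend on distance here.
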