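"""Synthetic recordings, spike trains, stimulation experiments and images.

Every generator returns, alongside its observable output, a
:class:`GroundTruth` record of the quantities the downstream analyses are
supposed to recover — true per-electrode rates, burst epochs, evoked-response
classes and first-spike latencies, puncta positions and sizes — so each
pipeline stage can be validated without real data.

Statistical structure emulated
------------------------------
* Per-electrode firing rates are lognormal across the array (Gaussian in
  log10 events/s), the population shape observed on these cultures.
* Development is captured as three regimes: *sparse* random spiking,
  *tonic* network-wide firing, and *bursting* with network-synchronized
  burst epochs superposed on background spiking.
* Evoked responses come in two forms: *fast* (first spikes near 70 ms,
  envelope confined to ~100 ms) and *long-lasting* (first spikes near
  120 ms, envelope up to ~500 ms), delivered over 35 trials/site at 0.2 Hz;
  stimulation artifacts are confined to electrodes within 20 μm of the site.
* Fluorescence fields carry small bright elliptical puncta on a smooth
  heterogeneous background with pixel noise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import ArrayGeometry, Recording, SpikeTrainSet, StimulationProtocol

__all__ = [
    "RegimeSpec",
    "EvokedSpec",
    "GroundTruth",
    "WAVEFORM_CLASSES",
    "gen_spontaneous",
    "gen_raw_traces",
    "gen_evoked_experiment",
    "gen_waveform_bank",
    "gen_puncta_image",
    "waveform_template",
]

#: The four extracellular spike-shape classes, in canonical order. The
#: default mix is the repertoire measured on mature cultures: 41% negative
#: monophasic, 15% negative biphasic, 26% negative triphasic, 18% positive
#: biphasic.
WAVEFORM_CLASSES = ("neg-mono", "neg-bi", "neg-tri", "pos-bi")
DEFAULT_CLASS_MIX = (0.41, 0.15, 0.26, 0.18)


@dataclass(frozen=True)
class RegimeSpec:
    """Statistical description of one developmental activity regime.

    Rates are lognormal: ``log10(rate) ~ Normal(rate_log10_mean,
    rate_log10_sd)``. In the *bursting* regime, network-synchronized bursts
    (onsets shared across electrodes, per-electrode participation
    ``sync_fraction``) are superposed on that background.
    """

    regime: str = "sparse"  # sparse | tonic | bursting
    rate_log10_mean: float = -1.0  # log10 events/s
    rate_log10_sd: float = 0.3
    burst_rate_per_min: float = 6.0
    intra_burst_isi_ms: float = 20.0
    spikes_per_burst: int = 6
    sync_fraction: float = 0.6
    noise_sd_uv: float = 5.0  # raw-trace Gaussian noise SD, μV
    spike_amplitude_sd: float = 12.0  # spike peak amplitude in noise-SD units
    class_mix: tuple[float, float, float, float] = DEFAULT_CLASS_MIX

    def __post_init__(self) -> None:
        if self.regime not in ("sparse", "tonic", "bursting"):
            raise ValueError(f"unknown regime {self.regime!r}")
        for name in ("rate_log10_mean", "rate_log10_sd", "burst_rate_per_min"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.rate_log10_sd < 0:
            raise ValueError("rate_log10_sd must be non-negative")
        if self.noise_sd_uv <= 0:
            raise ValueError("noise_sd_uv must be positive")
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class_mix proportions must sum to 1")

    @classmethod
    def sparse(cls, **kw) -> "RegimeSpec":
        """Young-culture regime: sparse independent random spikes (~0.1 ev/s)."""
        return cls(regime="sparse", rate_log10_mean=-1.0, rate_log10_sd=0.3, **kw)

    @classmethod
    def tonic(cls, **kw) -> "RegimeSpec":
        """Mid-development regime: tonic network-wide firing (~0.66 ev/s)."""
        return cls(regime="tonic", rate_log10_mean=-0.18, rate_log10_sd=0.35, **kw)

    @classmethod
    def bursting(cls, **kw) -> "RegimeSpec":
        """Mature regime: synchronized network bursts on tonic background."""
        kw.setdefault("rate_log10_mean", -0.6)
        kw.setdefault("rate_log10_sd", 0.35)
        return cls(regime="bursting", **kw)


@dataclass(frozen=True)
class EvokedSpec:
    """Free parameters of the evoked-response generator.

    The source measurements constrain latencies and envelope durations but
    not the responding-electrode fraction or trial reliability; those are
    scenario parameters here.
    """

    fast_latency_s: float = 0.070
    long_latency_s: float = 0.120
    latency_jitter_s: float = 0.010
    fast_envelope_s: float = 0.100  # 95% of fast-response mass within this
    long_envelope_s: float = 0.500  # long-lasting support extends up to this
    extra_spikes_fast: float = 2.0  # Poisson mean of post-first spikes/trial
    extra_spikes_long: float = 4.0
    respond_prob_near: float = 0.5  # responder probability next to the site
    respond_decay_pitch: float = 12.0  # e-fold distance of that probability
    reliability: float = 0.9  # fraction of the 35 trials answered
    unreliable_fraction: float = 0.0  # responders programmed below the 10/35 rule
    unreliable_trials: int = 7  # trial count assigned to those responders
    background_rate: float = 0.05  # spontaneous events/s per electrode
    artifact_amplitude_uv: float = 2000.0
    artifact_radius_um: float = 20.0


@dataclass
class GroundTruth:
    """Everything a generator knows that the analyses should recover."""

    true_rates: np.ndarray | None = None  # events/s per electrode
    spike_times: dict[int, np.ndarray] | None = None
    unit_class: dict[int, int] | None = None  # electrode -> waveform class idx
    burst_epochs: dict[int, list[tuple[float, float, int]]] | None = None
    response_class: dict[int, str] | None = None  # site -> fast | long
    first_spike_latencies: dict[tuple[int, int], np.ndarray] | None = None
    responding_trials: dict[tuple[int, int], np.ndarray] | None = None
    artifact_events: dict[int, np.ndarray] | None = None
    puncta_centers_um: np.ndarray | None = None  # (n, 2) row/col in μm
    puncta_axes_um: np.ndarray | None = None  # (n,) major axes

    @property
    def n_bursts(self) -> int:
        if self.burst_epochs is None:
            return 0
        return sum(len(v) for v in self.burst_epochs.values())


# ---------------------------------------------------------------------------
# spontaneous activity


def _poisson_train(rng, rate: float, duration: float) -> np.ndarray:
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0.0, duration, n))


def gen_spontaneous(
    geometry: ArrayGeometry,
    regime: RegimeSpec,
    duration: float,
    seed: int,
) -> tuple[SpikeTrainSet, GroundTruth]:
    """Generate spontaneous activity for one developmental regime.

    Background spiking is homogeneous Poisson per electrode at a rate drawn
    from the regime's lognormal; the bursting regime adds network bursts
    whose onsets are sampled globally (jittered grid, so bursts stay
    separated) with per-electrode participation ``sync_fraction``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n_elec = geometry.n_electrodes
    log_rates = regime.rate_log10_mean + regime.rate_log10_sd * rng.standard_normal(
        n_elec
    )
    rates = 10.0**log_rates

    trains: dict[int, np.ndarray] = {}
    burst_epochs: dict[int, list[tuple[float, float, int]]] = {}

    burst_onsets = np.empty(0)
    if regime.regime == "bursting" and regime.burst_rate_per_min > 0:
        # Jittered grid keeps consecutive bursts separated by more than a
        # burst span + the 100 ms burst-joining scale.
        period = 60.0 / regime.burst_rate_per_min
        span = regime.spikes_per_burst * regime.intra_burst_isi_ms / 1000.0
        n_slots = int(duration // period)
        jitter = max(period - span - 0.3, 0.0)
        burst_onsets = (
            np.arange(n_slots) * period + 0.05 + rng.uniform(0.0, jitter, n_slots)
        )
        burst_onsets = burst_onsets[burst_onsets + span < duration]

    isi = regime.intra_burst_isi_ms / 1000.0
    for e in range(n_elec):
        times = _poisson_train(rng, rates[e], duration)
        epochs: list[tuple[float, float, int]] = []
        if burst_onsets.size:
            take = rng.uniform(size=burst_onsets.size) < regime.sync_fraction
            for onset in burst_onsets[take]:
                onset_e = onset + rng.uniform(0.0, 0.010)
                isis = isi * rng.uniform(0.8, 1.2, regime.spikes_per_burst - 1)
                burst_times = onset_e + np.concatenate(([0.0], np.cumsum(isis)))
                burst_times = burst_times[burst_times < duration]
                if len(burst_times) >= 2:
                    times = np.concatenate([times, burst_times])
                    epochs.append(
                        (float(burst_times[0]), float(burst_times[-1]), len(burst_times))
                    )
        times = np.unique(times)
        if times.size:
            trains[e] = times
        if epochs:
            burst_epochs[e] = epochs

    unit_class = {
        e: int(c)
        for e, c in enumerate(rng.choice(len(WAVEFORM_CLASSES), n_elec, p=regime.class_mix))
    }
    trainset = SpikeTrainSet(geometry=geometry, duration=float(duration), trains=trains)
    truth = GroundTruth(
        true_rates=rates,
        spike_times={e: t.copy() for e, t in trains.items()},
        unit_class=unit_class,
        burst_epochs=burst_epochs,
    )
    return trainset, truth


# ---------------------------------------------------------------------------
# waveform templates and raw traces


def _gauss(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def waveform_template(
    class_idx: int,
    sampling_rate: float,
    amplitude: float = 1.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """A 4 ms spike template of the given class, peak-centred at 2 ms.

    With ``rng`` the side-phase amplitudes and phase widths are randomized
    within class constraints (side phases 25–60% of the dominant peak);
    without it the canonical mid-range shape is returned. ``amplitude`` is
    the absolute amplitude of the dominant peak.
    """
    n = round(0.004 * sampling_rate)
    t = np.arange(n) / sampling_rate * 1000.0  # ms
    c = 1000.0 * (n // 2) / sampling_rate  # peak sample instant

    def u(lo, hi):
        return rng.uniform(lo, hi) if rng is not None else 0.5 * (lo + hi)

    w0 = u(0.15, 0.30)  # dominant-phase width, ms
    side = u(0.25, 0.60)
    side2 = u(0.25, 0.60)
    ws = u(0.25, 0.45)
    d = u(0.55, 0.90)  # side-phase offset, ms
    name = WAVEFORM_CLASSES[class_idx]
    if name == "neg-mono":
        wf = -_gauss(t, c, w0)
    elif name == "neg-bi":
        wf = -_gauss(t, c, w0) + side * _gauss(t, c + d, ws)
    elif name == "neg-tri":
        wf = (
            side * _gauss(t, c - d, ws)
            - _gauss(t, c, w0)
            + side2 * _gauss(t, c + d, ws)
        )
    elif name == "pos-bi":
        wf = _gauss(t, c, w0) - side * _gauss(t, c + d, ws)
    else:  # pragma: no cover
        raise ValueError(f"unknown class index {class_idx}")
    wf *= amplitude / np.max(np.abs(wf))
    # exact peak on the centre sample
    peak = n // 2
    dom = np.argmax(np.abs(wf))
    wf = np.roll(wf, peak - dom)
    return wf


def gen_raw_traces(
    trains: SpikeTrainSet,
    regime: RegimeSpec,
    sampling_rate: float,
    seed: int,
    unit_class: dict[int, int] | None = None,
) -> Recording:
    """Render spike trains into raw voltage traces.

    Gaussian background noise of ``regime.noise_sd_uv`` with one spike
    template per electrode (class from ``unit_class`` or drawn from the
    regime's class mix) inserted at each true spike time, dominant peak
    amplitude ``regime.spike_amplitude_sd`` times the noise SD.
    """
    if sampling_rate < 7000:
        raise ValueError("sampling_rate must be at least 7 kHz")
    if regime.spike_amplitude_sd < 1.0:
        warnings.warn(
            "spike amplitude below 1 noise SD: detection is untestable",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    n_elec = trains.geometry.n_electrodes
    n_samples = round(trains.duration * sampling_rate)
    traces = np.empty((n_elec, n_samples), dtype=np.float32)
    sd = regime.noise_sd_uv
    amp = regime.spike_amplitude_sd * sd
    half = round(0.004 * sampling_rate) // 2
    for e in range(n_elec):
        x = rng.normal(0.0, sd, n_samples)
        times = trains.trains.get(e)
        if times is not None and times.size:
            cls = (
                unit_class[e]
                if unit_class is not None and e in unit_class
                else int(rng.choice(len(WAVEFORM_CLASSES), p=regime.class_mix))
            )
            tmpl = waveform_template(cls, sampling_rate, amplitude=amp, rng=rng)
            for t0 in times:
                peak = round(t0 * sampling_rate)
                lo, hi = peak - half, peak - half + len(tmpl)
                s0, s1 = max(lo, 0), min(hi, n_samples)
                if s0 < s1:
                    x[s0:s1] += tmpl[s0 - lo : s1 - lo]
        traces[e] = x
    return Recording(
        geometry=trains.geometry, sampling_rate=float(sampling_rate), traces=traces
    )


# ---------------------------------------------------------------------------
# evoked experiments


def gen_evoked_experiment(
    geometry: ArrayGeometry,
    protocol: StimulationProtocol,
    response_classes: dict[int, str],
    seed: int,
    spec: EvokedSpec = EvokedSpec(),
    reliability_map: dict[tuple[int, int], int] | None = None,
) -> tuple[SpikeTrainSet, GroundTruth]:
    """Generate a multi-site stimulation experiment with known responses.

    For every site, responder electrodes are drawn with probability
    decaying with distance from the site. Each responder answers a fixed
    number of its 35 trials (``round(reliability * n_trials)``, drawn
    without replacement, or an explicit per-(site, electrode) count via
    ``reliability_map``) with a first spike at latency ``N(70 ms | 120 ms,
    jitter)`` followed by a Poisson number of envelope spikes confined to
    ~100 ms (fast) or up to ~500 ms (long-lasting). Stimulation artifacts
    (saturating ±2 mV deflections) appear on electrodes within 20 μm of the
    site during the first 2 ms after each pulse.
    """
    for site in response_classes:
        if response_classes[site] not in ("fast", "long"):
            raise ValueError("response class must be 'fast' or 'long'")
        if site >= len(geometry.stim_sites):
            raise ValueError(f"site {site} not defined in geometry.stim_sites")
    window = (
        spec.long_envelope_s
        if "long" in response_classes.values()
        else spec.fast_envelope_s
    )
    if window >= 1.0 / protocol.rate:
        raise ValueError(
            "response window must be shorter than the inter-stimulus interval"
        )

    rng = np.random.default_rng(seed)
    duration = protocol.end_time + 1.0
    n_elec = geometry.n_electrodes
    events: dict[int, list] = {e: [] for e in range(n_elec)}
    amps: dict[int, list] = {e: [] for e in range(n_elec)}

    # spontaneous background
    if spec.background_rate > 0:
        for e in range(n_elec):
            bg = _poisson_train(rng, spec.background_rate, duration)
            events[e].extend(bg)
            amps[e].extend(rng.normal(60.0, 8.0, bg.size))

    latencies: dict[tuple[int, int], np.ndarray] = {}
    responding: dict[tuple[int, int], np.ndarray] = {}
    artifacts: dict[int, list] = {}

    for site, cls in response_classes.items():
        pulses = protocol.pulse_times[site]
        n_trials = len(pulses)
        pos = geometry.stim_sites[site]
        dists = geometry.distances_to(pos)
        p_resp = spec.respond_prob_near * np.exp(-dists / spec.respond_decay_pitch)
        responders = np.flatnonzero(rng.uniform(size=n_elec) < p_resp)
        mean_lat = spec.fast_latency_s if cls == "fast" else spec.long_latency_s
        env_end = spec.fast_envelope_s if cls == "fast" else spec.long_envelope_s
        n_extra_mean = (
            spec.extra_spikes_fast if cls == "fast" else spec.extra_spikes_long
        )
        tau = (env_end - mean_lat) / 4.0  # Gamma(2, tau): ~95% mass in 4.7 tau
        for e in responders:
            if reliability_map is not None and (site, e) in reliability_map:
                k = int(reliability_map[(site, e)])
            elif spec.unreliable_fraction > 0 and rng.uniform() < spec.unreliable_fraction:
                k = int(spec.unreliable_trials)
            else:
                k = int(round(spec.reliability * n_trials))
            k = min(k, n_trials)
            trial_idx = np.sort(rng.choice(n_trials, size=k, replace=False))
            lat = np.full(n_trials, np.nan)
            for ti in trial_idx:
                first = rng.normal(mean_lat, spec.latency_jitter_s)
                first = float(np.clip(first, 0.012, env_end - 0.005))
                lat[ti] = first
                spk = [pulses[ti] + first]
                for _ in range(rng.poisson(n_extra_mean)):
                    dt = rng.gamma(2.0, tau)
                    if first + dt < env_end:
                        spk.append(pulses[ti] + first + dt)
                events[e].extend(spk)
                amps[e].extend(rng.normal(60.0, 8.0, len(spk)))
            latencies[(site, int(e))] = lat
            responding[(site, int(e))] = trial_idx
        # artifacts confined to < 20 μm from the site
        near = np.flatnonzero(dists * geometry.pitch <= spec.artifact_radius_um)
        for e in near:
            art = pulses + 0.0005
            events[e].extend(art)
            amps[e].extend(np.full(art.size, spec.artifact_amplitude_uv))
            artifacts.setdefault(int(e), []).extend(art)

    trains: dict[int, np.ndarray] = {}
    amplitudes: dict[int, np.ndarray] = {}
    for e in range(n_elec):
        if not events[e]:
            continue
        t = np.asarray(events[e])
        a = np.asarray(amps[e])
        order = np.argsort(t)
        t, a = t[order], a[order]
        keep = np.concatenate(([True], np.diff(t) > 0))
        trains[e] = t[keep]
        amplitudes[e] = a[keep]

    trainset = SpikeTrainSet(
        geometry=geometry,
        duration=float(duration),
        trains=trains,
        amplitudes=amplitudes,
    )
    truth = GroundTruth(
        spike_times={e: t.copy() for e, t in trains.items()},
        response_class=dict(response_classes),
        first_spike_latencies=latencies,
        responding_trials=responding,
        artifact_events={e: np.asarray(v) for e, v in artifacts.items()},
    )
    return trainset, truth


# ---------------------------------------------------------------------------
# waveform bank


def gen_waveform_bank(
    class_mix,
    n: int,
    sampling_rate: float = 7800.0,
    seed: int = 0,
    noise_sd: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate ``n`` labelled 4 ms snippets from the four phase classes.

    ``noise_sd`` is the additive Gaussian noise SD relative to the dominant
    peak amplitude (amplitudes themselves vary 3x across snippets).
    Returns ``(snippets, labels)`` with snippets of shape ``(n, snippet_len)``.
    """
    class_mix = np.asarray(class_mix, dtype=float)
    if abs(class_mix.sum() - 1.0) > 1e-9:
        raise ValueError("class_mix must sum to 1")
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    labels = rng.choice(len(WAVEFORM_CLASSES), size=n, p=class_mix)
    length = round(0.004 * sampling_rate)
    snippets = np.empty((n, length))
    for i, cls in enumerate(labels):
        amp = rng.uniform(30.0, 90.0)  # μV
        wf = waveform_template(int(cls), sampling_rate, amplitude=amp, rng=rng)
        snippets[i] = wf + rng.normal(0.0, noise_sd * amp, length)
    return snippets, labels


# ---------------------------------------------------------------------------
# puncta images


def gen_puncta_image(
    n_puncta: int,
    axis_range_um: tuple[float, float] = (0.5, 1.0),
    scale_um_per_px: float = 0.077,
    shape: tuple[int, int] = (512, 512),
    background: tuple[float, float, float] = (0.04, 0.02, 0.01),
    peak_intensity: tuple[float, float] = (0.4, 0.7),
    seed: int = 0,
):
    """Generate a fluorescence field with known puncta.

    Puncta are ellipses of the requested major axis (minor axis 60–100% of
    the major), rendered as slightly smoothed uniform-intensity ellipses so
    the measured major axis matches the programmed one; they are placed
    without overlap on a smooth heterogeneous background (``background`` =
    (mean, large-scale modulation SD, pixel-noise SD)).

    Returns ``(PunctaImage, GroundTruth)``; the image type is defined in
    :mod:`hdmea.puncta` and imported lazily to avoid a cycle.
    """
    from .puncta import PunctaImage

    if scale_um_per_px <= 0:
        raise ValueError("scale must be positive")
    if axis_range_um[0] / scale_um_per_px < 2:
        raise ValueError("puncta must span at least 2 pixels at this scale")
    rng = np.random.default_rng(seed)
    h, w = shape
    mean_bg, mod_sd, noise_sd = background
    field_ = gaussian_filter(rng.standard_normal(shape), sigma=min(h, w) / 8.0)
    img = mean_bg + mod_sd * field_ / max(field_.std(), 1e-12)

    centers_arr = np.empty((0, 2))
    axes: list[float] = []
    margin = axis_range_um[1] / scale_um_per_px
    if 2 * margin >= min(h, w):
        raise ValueError("requested puncta density too high to place without overlap")
    max_tries = 200 * max(n_puncta, 1)
    tries = 0
    min_sep2 = (3 * margin) ** 2
    # packing bound: refuse requests that cannot fit even at ~2x ideal packing
    if n_puncta * min_sep2 * np.pi / 4 > 2.0 * (h - 2 * margin) * (w - 2 * margin):
        raise ValueError("requested puncta density too high to place without overlap")
    bumps = np.zeros(shape)
    patch = int(np.ceil(margin)) + 2
    while len(axes) < n_puncta:
        tries += 1
        if tries > max_tries:
            raise ValueError("requested puncta density too high to place without overlap")
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        if centers_arr.size and np.any(
            (centers_arr[:, 0] - cy) ** 2 + (centers_arr[:, 1] - cx) ** 2 < min_sep2
        ):
            continue
        major = rng.uniform(*axis_range_um)
        minor = major * rng.uniform(0.6, 1.0)
        theta = rng.uniform(0, np.pi)
        a = major / 2 / scale_um_per_px  # semi-axes in px
        b = minor / 2 / scale_um_per_px
        y0, y1 = max(int(cy) - patch, 0), min(int(cy) + patch + 1, h)
        x0, x1 = max(int(cx) - patch, 0), min(int(cx) + patch + 1, w)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        amp = rng.uniform(*peak_intensity)
        bumps[y0:y1, x0:x1][mask] = amp
        centers_arr = np.vstack([centers_arr, [cy, cx]])
        axes.append(major)
    # blur is linear, so one pass over the accumulated bumps suffices
    img += gaussian_filter(bumps, sigma=0.7)
    img += rng.normal(0.0, noise_sd, shape)
    centers = centers_arr
    img = np.clip(img, 0.0, 1.0)
    image = PunctaImage(pixels=img, scale_um_per_px=scale_um_per_px)
    truth = GroundTruth(
        puncta_centers_um=np.asarray(centers, dtype=float) * scale_um_per_px,
        puncta_axes_um=np.asarray(axes, dtype=float),
    )
    return image, truth
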