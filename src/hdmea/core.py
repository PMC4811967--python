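"""Shared domain types for high-density MEA analysis.

The central objects are :class:`ArrayGeometry` (the electrode grid),
:class:`Recording` (raw multi-channel voltage traces), :class:`SpikeTrainSet`
(per-electrode spike times, the main intermediate of every analysis stage),
:class:`StimulationProtocol` (pulse schedule of the on-chip stimulation
sites) and :class:`AnalysisConfig` (every tunable numeric parameter in one
place).

Conventions
-----------
* Times are seconds internally; report tables convert to ms where customary.
* Electrodes are addressed row-major, 0-based: ``index = row * n_cols + col``.
* Distances between electrodes are expressed in pitch units (inter-electrode
  spacings) computed from grid coordinates; multiply by ``pitch`` for μm.
* Voltages are μV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "SchemaError",
    "ArrayGeometry",
    "Recording",
    "SpikeTrainSet",
    "StimulationProtocol",
    "AnalysisConfig",
    "DEFAULT_GEOMETRY",
]

#: Sampling rates of the acquisition system: 7.8 kHz full-frame (4096
#: electrodes) or 22 kHz for a 1024-electrode region of interest.
STANDARD_SAMPLING_RATES = (7800.0, 22000.0)


class SchemaError(ValueError):
    """A container file or in-memory object violates the documented schema."""


@dataclass(frozen=True)
class ArrayGeometry:
    """Layout of the recording-electrode grid and on-chip stimulation sites.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions (64 x 64 = 4096 electrodes for the full array).
    pitch
        Centre-to-centre electrode spacing in μm (42 for the recording-only
        chip, 81 for the variant with interleaved stimulation electrodes).
    electrode_size
        Electrode side length in μm (21).
    stim_sites
        Grid positions ``(row, col)`` of up to 16 stimulation sites.
    """

    n_rows: int = 64
    n_cols: int = 64
    pitch: float = 42.0
    electrode_size: float = 21.0
    stim_sites: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")
        if len(self.stim_sites) > 16:
            raise ValueError("at most 16 stimulation sites are supported")
        object.__setattr__(
            self, "stim_sites", tuple((int(r), int(c)) for r, c in self.stim_sites)
        )
        for r, c in self.stim_sites:
            if not (0 <= r < self.n_rows and 0 <= c < self.n_cols):
                raise ValueError(f"stimulation site {(r, c)} lies outside the grid")

    @property
    def n_electrodes(self) -> int:
        return self.n_rows * self.n_cols

    def index(self, row: int, col: int) -> int:
        """Row-major electrode index of grid position ``(row, col)``."""
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"position {(row, col)} outside the grid")
        return row * self.n_cols + col

    def position(self, index: int) -> tuple[int, int]:
        """Grid position ``(row, col)`` of a row-major electrode index."""
        if not 0 <= index < self.n_electrodes:
            raise ValueError(f"electrode index {index} out of range")
        return divmod(int(index), self.n_cols)

    def distances_to(self, site: tuple[int, int]) -> np.ndarray:
        """Euclidean distance of every electrode to ``site`` in pitch units."""
        rows, cols = np.divmod(np.arange(self.n_electrodes), self.n_cols)
        return np.hypot(rows - site[0], cols - site[1])


DEFAULT_GEOMETRY = ArrayGeometry()


@dataclass
class Recording:
    """Raw per-electrode extracellular voltage traces.

    ``traces`` has shape ``(n_electrodes, n_samples)`` in μV. ``roi``
    optionally names a sub-grid ``(row0, col0, n_rows, n_cols)`` when the
    recording covers a region of interest rather than the full array.
    """

    geometry: ArrayGeometry
    sampling_rate: float
    traces: np.ndarray
    roi: tuple[int, int, int, int] | None = None

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces)
        if self.traces.ndim != 2:
            raise SchemaError("traces must be a 2-D (n_electrodes, n_samples) array")
        if self.traces.shape[0] != self.geometry.n_electrodes:
            raise SchemaError(
                f"traces has {self.traces.shape[0]} rows but the geometry "
                f"defines {self.geometry.n_electrodes} electrodes"
            )
        if self.sampling_rate <= 0:
            raise SchemaError("sampling_rate must be positive")
        if self.sampling_rate not in STANDARD_SAMPLING_RATES:
            warnings.warn(
                f"sampling rate {self.sampling_rate} Hz is non-standard "
                f"(acquisition system uses {STANDARD_SAMPLING_RATES})",
                stacklevel=2,
            )

    @property
    def n_samples(self) -> int:
        return self.traces.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate


def _validate_train(times: np.ndarray, duration: float, electrode: int) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1:
        raise SchemaError(f"electrode {electrode}: spike times must be 1-D")
    if times.size and (times[0] < 0 or times[-1] > duration):
        raise SchemaError(
            f"electrode {electrode}: spike times outside [0, {duration}]"
        )
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise SchemaError(f"electrode {electrode}: spike times not strictly increasing")
    return times


@dataclass
class SpikeTrainSet:
    """Electrode-indexed spike times with optional waveform snippets.

    ``trains`` maps electrode index to a strictly increasing array of spike
    times (s). ``waveforms`` optionally maps electrode index to an array of
    shape ``(n_spikes, snippet_len)`` holding 4 ms peak-centred snippets (μV),
    aligned one-to-one with the spike times; ``amplitudes`` optionally holds
    the per-spike peak absolute amplitude (μV), a light-weight alternative
    when full snippets are not needed (e.g. artifact screening).
    """

    geometry: ArrayGeometry
    duration: float
    trains: dict[int, np.ndarray]
    waveforms: dict[int, np.ndarray] | None = None
    amplitudes: dict[int, np.ndarray] | None = None
    sampling_rate: float | None = None

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise SchemaError("duration must be non-negative")
        self.trains = {
            int(e): _validate_train(t, self.duration, e) for e, t in self.trains.items()
        }
        if self.waveforms is not None:
            if self.sampling_rate is None:
                raise SchemaError("waveforms require a sampling_rate")
            snip = round(0.004 * self.sampling_rate)
            for e, w in self.waveforms.items():
                w = np.asarray(w)
                if w.shape != (len(self.trains.get(e, ())), snip):
                    raise SchemaError(
                        f"electrode {e}: waveform array shape {w.shape} does not "
                        f"match ({len(self.trains.get(e, ()))}, {snip})"
                    )
        if self.amplitudes is not None:
            for e, a in self.amplitudes.items():
                if len(a) != len(self.trains.get(e, ())):
                    raise SchemaError(f"electrode {e}: amplitude count mismatch")

    @property
    def n_spikes(self) -> int:
        return sum(len(t) for t in self.trains.values())

    def rates(self) -> np.ndarray:
        """Mean firing rate (events/s) of every electrode, zeros included."""
        if self.duration == 0:
            raise ValueError("rates undefined for zero-duration set")
        out = np.zeros(self.geometry.n_electrodes)
        for e, t in self.trains.items():
            out[e] = len(t) / self.duration
        return out

    def subset(self, electrodes) -> "SpikeTrainSet":
        keep = set(int(e) for e in electrodes)
        return SpikeTrainSet(
            geometry=self.geometry,
            duration=self.duration,
            trains={e: t for e, t in self.trains.items() if e in keep},
            waveforms=None
            if self.waveforms is None
            else {e: w for e, w in self.waveforms.items() if e in keep},
            amplitudes=None
            if self.amplitudes is None
            else {e: a for e, a in self.amplitudes.items() if e in keep},
            sampling_rate=self.sampling_rate,
        )


@dataclass
class StimulationProtocol:
    """Schedule of biphasic current pulses delivered from on-chip sites.

    The standard protocol delivers low-frequency (0.2 Hz) trains of 35
    biphasic pulses per site (300 μs per phase, positive phase first,
    300 μA peak-to-peak).
    """

    site_order: tuple[int, ...]
    pulse_times: dict[int, np.ndarray]
    rate: float = 0.2
    n_pulses_per_site: int = 35
    phase_duration: float = 300e-6
    amplitude: float = 300.0
    polarity: str = "positive-first"

    def __post_init__(self) -> None:
        self.site_order = tuple(int(s) for s in self.site_order)
        self.pulse_times = {
            int(s): np.sort(np.asarray(t, dtype=float))
            for s, t in self.pulse_times.items()
        }
        period = 1.0 / self.rate
        for s, t in self.pulse_times.items():
            if len(t) != self.n_pulses_per_site:
                raise SchemaError(
                    f"site {s}: {len(t)} pulses, expected {self.n_pulses_per_site}"
                )
            if len(t) > 1 and not np.allclose(np.diff(t), period, atol=1e-6):
                raise SchemaError(f"site {s}: pulses not spaced by 1/rate = {period} s")

    @classmethod
    def regular(
        cls,
        sites,
        rate: float = 0.2,
        n_pulses: int = 35,
        start: float = 1.0,
        stagger: float | None = None,
    ) -> "StimulationProtocol":
        """Regular interleaved trains: every site pulses at ``rate`` with the
        site onsets staggered evenly inside one inter-pulse period."""
        sites = tuple(int(s) for s in sites)
        period = 1.0 / rate
        if stagger is None:
            stagger = period / max(len(sites), 1)
        times = {
            s: start + i * stagger + period * np.arange(n_pulses)
            for i, s in enumerate(sites)
        }
        return cls(
            site_order=sites, pulse_times=times, rate=rate, n_pulses_per_site=n_pulses
        )

    @classmethod
    def sequential(
        cls,
        sites,
        rate: float = 0.2,
        n_pulses: int = 35,
        start: float = 1.0,
        gap: float = 1.0,
    ) -> "StimulationProtocol":
        """One full train per site, sites in consecutive blocks.

        Keeps response windows of different sites disjoint, which the
        interleaved :meth:`regular` schedule does not guarantee for
        long-lasting responses.
        """
        sites = tuple(int(s) for s in sites)
        period = 1.0 / rate
        block = n_pulses * period + gap
        times = {
            s: start + i * block + period * np.arange(n_pulses)
            for i, s in enumerate(sites)
        }
        return cls(
            site_order=sites, pulse_times=times, rate=rate, n_pulses_per_site=n_pulses
        )

    @property
    def end_time(self) -> float:
        if not self.pulse_times:
            return 0.0
        return max(float(t[-1]) for t in self.pulse_times.values())


@dataclass
class AnalysisConfig:
    """Every numeric analysis parameter, with the standard defaults.

    Attributes
    ----------
    detection_threshold : float
        Spike-detection threshold, multiples of the per-electrode noise SD (9).
    active_rate_bounds : tuple
        Inclusive firing-rate band (events/s) defining an "active electrode"
        (0.05, 10).
    burst_min_spikes, burst_max_isi_ms : int, float
        Burst rule: at least 5 consecutive spikes with every ISI < 100 ms.
    psth_bin_ms, psth_discard_ms, psth_window_s : float
        PSTH binning (25 ms), post-stimulus discard (10 ms) and response
        window (0.5 s).
    ring_radii : tuple
        Circular-region radii around the stimulation site in electrode
        (pitch) units: 4, 6, ..., 30.
    reliability_min_trials, n_trials : int
        An electrode is "reliable" when it responds in at least 10 of the
        35 stimulation trials.
    response_boundary_ms : float
        Fast vs long-lasting response boundary on PSTH response duration.
    response_onset_ms : float
        A supra-baseline run must start within this many ms to count as the
        evoked response.
    puncta_offset : float
        Intensity offset above which filtered fluorescence counts as a
        punctum (0.07, normalized units).
    puncta_axis_bounds_um : tuple
        Accepted major-axis range for puncta, μm (0.3, 1.3).
    seed : int
        Global random seed propagated to every stochastic stage.
    """

    detection_threshold: float = 9.0
    noise_estimator: str = "mad"
    active_rate_bounds: tuple[float, float] = (0.05, 10.0)
    burst_min_spikes: int = 5
    burst_max_isi_ms: float = 100.0
    psth_bin_ms: float = 25.0
    psth_discard_ms: float = 10.0
    psth_window_s: float = 0.5
    ring_radii: tuple[int, ...] = tuple(range(4, 31, 2))
    reliability_min_trials: int = 10
    n_trials: int = 35
    response_boundary_ms: float = 150.0
    response_onset_ms: float = 100.0
    percentile_band: tuple[float, float] = (5.0, 95.0)
    puncta_offset: float = 0.07
    puncta_axis_bounds_um: tuple[float, float] = (0.3, 1.3)
    seed: int = 0

    def __post_init__(self) -> None:
        pairs = {
            "active_rate_bounds": self.active_rate_bounds,
            "puncta_axis_bounds_um": self.puncta_axis_bounds_um,
            "percentile_band": self.percentile_band,
        }
        for name, (lo, hi) in pairs.items():
            if not lo < hi:
                raise ValueError(f"{name}: lower bound must be below upper bound")
        positive = {
            "detection_threshold": self.detection_threshold,
            "burst_min_spikes": self.burst_min_spikes,
            "burst_max_isi_ms": self.burst_max_isi_ms,
            "psth_bin_ms": self.psth_bin_ms,
            "psth_window_s": self.psth_window_s,
            "response_boundary_ms": self.response_boundary_ms,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive")
        if self.psth_discard_ms < 0:
            raise ValueError("psth_discard_ms must be non-negative")

    def to_yaml(self, path) -> None:
        data = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        tuple_fields = {
            "active_rate_bounds",
            "ring_radii",
            "percentile_band",
            "puncta_axis_bounds_um",
        }
        kwargs = {
            k: (tuple(v) if k in tuple_fields else v) for k, v in data.items()
        }
        return cls(**kwargs)
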