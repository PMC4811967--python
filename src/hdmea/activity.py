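"""Network-wide spontaneous-activity statistics.

Definitions
-----------
active electrode
    Firing rate within [0.05, 10] events/s over the recording phase
    (bounds inclusive).
burst
    A maximal run of at least five consecutive spikes on one electrode with
    every inter-spike interval strictly below 100 ms.
network summary
    Totals computed over active electrodes only: total spikes (reported per
    10 min phase), number of active electrodes, mean firing rate
    = total spikes / (n_active * duration), burst count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AnalysisConfig, SpikeTrainSet

__all__ = [
    "BurstEvent",
    "NetworkSummary",
    "classify_active_electrodes",
    "detect_bursts",
    "summarize_network",
    "pre_post_comparison",
]

PHASE_S = 600.0  # reporting phase for total-spike counts (10 min)


@dataclass(frozen=True)
class BurstEvent:
    electrode: int
    start: float
    end: float
    n_spikes: int


@dataclass(frozen=True)
class NetworkSummary:
    n_active_electrodes: int
    total_spikes: int  # over active electrodes, per 10 min phase (scaled if flagged)
    mean_firing_rate: float  # events/s over active electrodes
    n_bursts: int
    duration: float
    div_label: str | None = None
    scaled_to_phase: bool = False


def classify_active_electrodes(
    trains: SpikeTrainSet, config: AnalysisConfig = AnalysisConfig()
) -> np.ndarray:
    """Boolean mask over electrodes: rate within the active band (inclusive)."""
    if trains.duration <= 0:
        raise ValueError("duration must be positive to compute rates")
    lo, hi = config.active_rate_bounds
    rates = trains.rates()
    return (rates >= lo) & (rates <= hi)


def detect_bursts(
    times: np.ndarray,
    electrode: int = 0,
    min_spikes: int = 5,
    max_isi_ms: float = 100.0,
) -> list[BurstEvent]:
    """Maximal runs of >= ``min_spikes`` consecutive spikes, all ISIs < ``max_isi_ms``."""
    times = np.asarray(times, dtype=float)
    if times.size > 1 and np.any(np.diff(times) < 0):
        raise ValueError("spike times must be sorted")
    if times.size < min_spikes:
        return []
    short = np.diff(times) < max_isi_ms / 1000.0
    bursts: list[BurstEvent] = []
    # runs of consecutive short ISIs; a run of k short ISIs spans k+1 spikes
    boundaries = np.flatnonzero(np.diff(short.astype(int)))
    starts = [0] if short[0] else []
    starts += [b + 1 for b in boundaries if short[b + 1]]
    ends = [b + 1 for b in boundaries if short[b]]
    if short[-1]:
        ends.append(len(short))
    for s, e in zip(starts, ends):
        n = e - s + 1
        if n >= min_spikes:
            bursts.append(
                BurstEvent(
                    electrode=electrode,
                    start=float(times[s]),
                    end=float(times[e]),
                    n_spikes=int(n),
                )
            )
    return bursts


def summarize_network(
    trains: SpikeTrainSet,
    div_label: str | None = None,
    config: AnalysisConfig = AnalysisConfig(),
    scale_to_phase: bool = False,
) -> NetworkSummary:
    """Network summary over active electrodes only.

    Spikes on inactive electrodes are excluded from all totals. Total spike
    counts refer to the recording as-is; pass ``scale_to_phase=True`` to
    rescale them to the standard 10 min phase (never done silently).
    """
    active = classify_active_electrodes(trains, config)
    idx = np.flatnonzero(active)
    total = int(sum(len(trains.trains.get(e, ())) for e in idx))
    n_bursts = sum(
        len(
            detect_bursts(
                trains.trains[e],
                e,
                config.burst_min_spikes,
                config.burst_max_isi_ms,
            )
        )
        for e in idx
        if e in trains.trains
    )
    if idx.size == 0:
        warnings.warn("no active electrodes; summary is all zeros", stacklevel=2)
        mfr = 0.0
    else:
        mfr = total / (idx.size * trains.duration)
    reported = total
    if scale_to_phase and trains.duration > 0:
        reported = int(round(total * PHASE_S / trains.duration))
    return NetworkSummary(
        n_active_electrodes=int(idx.size),
        total_spikes=reported,
        mean_firing_rate=float(mfr),
        n_bursts=int(n_bursts),
        duration=trains.duration,
        div_label=div_label,
        scaled_to_phase=bool(scale_to_phase),
    )


def pre_post_comparison(pre, post) -> pd.DataFrame:
    """Per-metric pre/post deltas with SEM across replicate cultures.

    ``pre`` and ``post`` are :class:`NetworkSummary` or sequences of them
    (replicates). Metrics with mismatched durations are compared as rates.
    Returns a table with mean delta, ratio and SEMs; with a single replicate
    the SEM columns are NaN and ``sem_defined`` is False.
    """
    pre = [pre] if isinstance(pre, NetworkSummary) else list(pre)
    post = [post] if isinstance(post, NetworkSummary) else list(post)

    def metric_rows(name, fa, fb):
        a = np.array([fa(s) for s in pre], dtype=float)
        b = np.array([fb(s) for s in post], dtype=float)
        delta = b - a
        ratio = np.divide(b, a, out=np.full_like(b, np.nan), where=a != 0)
        n = len(delta)
        sem = lambda v: float(np.std(v, ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        return {
            "metric": name,
            "pre_mean": float(a.mean()),
            "post_mean": float(b.mean()),
            "delta_mean": float(delta.mean()),
            "delta_sem": sem(delta),
            "ratio_mean": float(np.nanmean(ratio)) if np.isfinite(ratio).any() else np.nan,
            "ratio_sem": sem(ratio[~np.isnan(ratio)]) if np.isfinite(ratio).any() else np.nan,
            "sem_defined": n > 1,
        }

    same_duration = all(
        abs(a.duration - b.duration) < 1e-9 for a, b in zip(pre, post)
    )
    spikes = (
        (lambda s: s.total_spikes)
        if same_duration
        else (lambda s: s.total_spikes / s.duration)
    )
    rows = [
        metric_rows("n_active_electrodes", lambda s: s.n_active_electrodes, lambda s: s.n_active_electrodes),
        metric_rows("total_spikes" if same_duration else "spike_rate", spikes, spikes),
        metric_rows("mean_firing_rate", lambda s: s.mean_firing_rate, lambda s: s.mean_firing_rate),
        metric_rows("n_bursts", lambda s: s.n_bursts, lambda s: s.n_bursts),
    ]
    return pd.DataFrame(rows)
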