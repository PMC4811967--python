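# Methods

This note documents the models, parameter choices and numerical decisions
behind `hdmea`, and what the synthetic-data generators do and do not
emulate.

## Conventions

Times are seconds internally (report tables use ms where customary),
voltages μV, electrode addresses row-major `(row, col)` on the grid, and
inter-electrode distances Euclidean in *pitch units* (multiply by the pitch,
42 or 81 μm, for physical distance). One `AnalysisConfig` object carries
every numeric parameter; a single seed propagates to all stochastic stages.

## Spike detection

The detector is a peak-to-peak differential threshold detector: per
electrode, the noise SD σ is estimated and an event is emitted wherever
`max − min` within a sliding window (default 1 ms) exceeds `k·σ` with
`k = 9`. Event time is the extremum of the dominant phase; events closer
than the refractory period (1 ms) merge, keeping the larger excursion;
4 ms snippets are extracted peak-centred and zero-padded at trace edges.
This is a documented surrogate for precise-timing detectors whose full
internals live in vendor software; only the 9×SD rule and the 4 ms snippet
length are fixed by the measurement convention, and whether the threshold
applies to a raw or differential quantity is not specified there — the
peak-to-peak reading is this package's choice.

σ defaults to the robust MAD estimate `median(|x − median(x)|)/0.6745`
computed over the whole recording (stationarity assumed at this scale).
The plain SD is selectable but inflates under spike contamination: with 1%
of samples at 20σ the MAD estimate stays within 5% of the true noise SD
while the plain SD rises by > 50% (tested). A constant trace yields σ = 0
with a warning and no events.

At 12σ spike amplitude the detector recovers ≥ 95% (measured ≈ 99.5%) of
injected spikes with ≤ 1 sample timing error at 7.8 kHz, with < 0.1
false events/s on pure noise — the max–min of ~8 Gaussian samples has
negligible mass beyond 9σ.

## Activity metrics

*Active electrode*: rate within [0.05, 10] events/s, **bounds inclusive**
("between" read inclusively; the boundary cases 30 and 6000 spikes in
600 s are tested). *Burst*: a maximal run of ≥ 5 consecutive spikes with
every ISI **strictly** below 100 ms; maximality means no extension in
either direction. The implementation is validated by exact equivalence
against a brute-force maximal-run scan on 1000 random trains. Network
summaries count only active electrodes (the interaction between the active
filter and total-spike counts is not otherwise defined; exclusion is this
package's documented choice), report totals per 10 min phase (shorter
recordings are rescaled only on an explicit flag), and define the mean
firing rate as `total_spikes / (n_active · duration)`. Bursts are
per-electrode; no cross-electrode network-burst rule is imposed.

## Rate distributions

Rates of active electrodes are binned on a fixed log₁₀ grid — 0.1-decade
bins over [−1.5, 1.1], covering the active band — and density-normalized.
A Gaussian `A·exp(−(x−μ)²/2σ²)` is fitted by least squares
(`scipy.optimize.curve_fit`, moment-based initial values, σ bounded
positive); 95% CIs come from the fit covariance and R² < 0.8 flags a poor
(e.g. bimodal) fit. Least squares on the density histogram, rather than
MLE, matches the "Gaussian fit to the distribution" convention; the fixed
grid keeps fits comparable across time-points (the original binning
procedure is described only in external work, so the grid here is a
documented stand-in). Fold-shift between fits is `10^(μ_a − μ_b)` with
the earlier time-point first; a fold > 1 reads "toward low firing rates".
Median recovery error on 4096-rate samples is < 0.01 log₁₀-units for both
μ and σ, well inside the 0.05 tolerance asserted.

## Evoked analysis

Artifact handling: events within 10 ms after any pulse are discarded, and
events whose snippet amplitude exceeds a hard threshold (default 450 μV,
~10× a typical detection threshold; configurable, must exceed the
detection threshold) are removed as stimulation artifacts — artifacts
saturate near ±2 mV and are spatially confined to < 20 μm from the site.

PSTHs bin spikes of all electrodes in 25 ms bins from +10 ms, per trial;
mean and percentile bands (default 5th/95th) are taken across the 35
trials. Note that a 5th/95th band does not bracket the *mean* when
responses are rare (the mean of mostly-zero counts exceeds their 95th
percentile); the min/max band (percentiles 0/100) always does, and the
test suite asserts exactly that.

Classification: the response duration is the end of the last contiguous
supra-baseline bin run starting within 100 ms of the stimulus; fast if
≤ 150 ms, long-lasting if longer, non-responsive if no qualifying run. The
150 ms boundary is configurable — the two observed forms sit near ~100 ms
and up to ~500 ms, so any boundary between them separates the classes; the
onset window is likewise a parameter. Baseline = mean per-bin count over
the 1 s preceding each pulse (no baseline rule is prescribed elsewhere).

First-spike latencies take, per trial, the first spike in (10, 500] ms
post-pulse; electrodes responding in < 10 of 35 trials are excluded as
unreliable. Latency-vs-distance uses concentric regions of radius
4, 6, …, 30 electrodes around the site: the innermost disc plus annuli
between consecutive radii, which partition the disc of radius 30. The
region size is π·r² in squared electrode units (50.3, 706.9, 2827.4 for
r = 4, 15, 30); the "μm" labels sometimes attached to these numbers equal
π·r² in electrode units rather than any physical distance at the stated
pitches, and are treated here as a suspected erratum.

## Waveform taxonomy

Unit isolation replaces a proprietary t-distribution E-M sorter with PCA
(≤ 3 components) + Gaussian mixtures of 1–3 components selected by BIC —
standard, reproducible, and respecting the 1–3 unit range; < 20 snippets
fall back to a single unit with a warning. Classification subtracts a
baseline (mean of the first 0.5 ms), takes the dominant polarity from the
larger |extremum|, and counts side phases as present at ≥ α = 0.2 of the
dominant amplitude (α configurable; no quantitative "small amplitude"
criterion is given elsewhere). Negative-dominant waveforms with 0/1/2
significant positive phases map to mono/bi/triphasic (triphasic requires
positive phases on *both* sides of the trough); positive-dominant
waveforms are positive biphasic. Classification is applied to per-unit
mean waveforms by default (per-spike available by calling it directly).
Class proportions are exhaustive and sum to 1 by construction; on a
2000-snippet bank at the 41/15/26/18% repertoire the classifier recovers
each class within 3 percentage points and a negative total near 82%.

## Puncta quantification

Granulometric filtering is implemented as a grayscale **white top-hat**
with a disc footprint slightly larger than the maximum punctum radius
(1.3 μm at the image scale): the opening estimates everything larger than
a punctum — the heterogeneous background — and subtracting it leaves the
small bright grains. The binary mask keeps pixels where the filtered
intensity exceeds `max(threshold, offset)`; the threshold defaults to
Otsu's method (the original manual value being unstated) with a manual
override, and the offset defaults to 0.07 normalized units. Connected
components are measured with best-fit ellipses; only major axes within
0.3–1.3 μm survive; density is count per μm² of field area (standard
field ~79 × 79 μm from 1024 × 1024 px, 0.077 μm/px; tests use smaller
fields at the same scale). Condition fold-changes use
`mean(a)/mean(b)` with first-order SEM propagation and a Mann-Whitney
rank test (delegated to scipy); the V-GLUT/V-GAT ratio is the per-field
count ratio averaged over fields, excluding zero-V-GAT fields with a
warning.

## Synthetic generators

The generators emulate the statistical structure the analyses assume, not
the biophysics:

* **Rates** are lognormal across electrodes (Gaussian in log₁₀ events/s).
  Regime defaults: sparse μ = −1.0, σ = 0.3 (young cultures, ~0.1 ev/s);
  tonic μ = −0.18, σ = 0.35 (~0.66 ev/s, the scale of mature-network mean
  rates); bursting background μ = −0.6, σ = 0.35 with network bursts.
* **Spiking** outside bursts is homogeneous Poisson per electrode — the
  simplest model consistent with "random spiking". **Network bursts**
  sample onsets on a jittered global grid (keeping consecutive bursts
  separated by more than the 100 ms joining scale) with per-electrode
  participation probability (default 0.6), 6 spikes per burst at ~20 ms
  ISI. No synaptic or network mechanism is modelled.
* **Raw traces** are Gaussian noise (5 μV SD) plus one spike template per
  electrode at 12× the noise SD by default; templates are sums of Gaussian
  phases parameterized per class (side phases 25–60% of the dominant
  peak). Electrode crosstalk, drift, line noise and overlapping spikes are
  *not* modelled, so detection results here bound performance from above.
* **Evoked responses**: responder electrodes are drawn with probability
  decaying exponentially with distance from the site (free parameters —
  no responding fraction is reported for the real preparations); each
  responder answers a programmed number k of its 35 trials (k drawn
  without replacement, so reliability is exact); first-spike latencies are
  Normal(70 ms | 120 ms, 10 ms) for fast | long-lasting sites, followed by
  a Poisson number of envelope spikes at Gamma(2, τ) offsets with τ set so
  ~95% of the envelope falls within 100 ms (fast) or 500 ms
  (long-lasting) — an alpha-function-shaped rate profile. Artifacts are
  ±2 mV markers during the first 2 ms on electrodes within 20 μm.
* **Puncta images**: ellipses with the programmed major axis (minor axis
  60–100% of it), rendered as uniform-intensity ellipses blurred by
  σ ≈ 0.7 px so the measured major axis matches the programmed one
  (small blurred objects are approximately Gaussian-profile), placed
  without overlap by rejection sampling on a smooth heterogeneous
  background (large-scale Gaussian random field) with pixel noise.
  Overlapping puncta, z-blur and photobleaching gradients are not
  emulated.

Because the generators realize exactly the assumptions of the analyses,
passing tests demonstrate correctness of the implementations and
recoverability of programmed effects — not robustness to real-data
pathologies (electrode drift, overlapping units, out-of-focus puncta).

## Problem sizes and tolerances

The test suite runs the detection benchmark at 1024 electrodes × 60 s ×
7.8 kHz (streamed one electrode at a time), burst-oracle equivalence on
1000 × 600 s random trains, lognormal recovery over 100 seeds × 4096
rates, the evoked scenario at 16 sites × 35 trials on the full 64×64
grid, and puncta recovery on 512×512 px fields; the acceptance script uses
the same scenarios (512 electrodes for detection). Numerical tolerances:
fit recovery 0.05 log₁₀-units (median), latency recovery ±5 ms on group
means, puncta counts ±5%, exact equality for burst sets and PSTH count
conservation.

## Known limitations

* The HDF5 container is a documented stand-in, not a vendor format.
* No streaming/online detection; recordings are processed in memory
  per electrode.
* Edge snippets are zero-padded but not separately flagged per spike.
* Network-level burst synchrony is not analyzed beyond per-electrode
  bursts.
* Statistical significance testing (ANOVA/Tukey, Kruskal-Wallis) is
  delegated to standard libraries by the caller; only the rank test inside
  `condition_comparison` is bundled.
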