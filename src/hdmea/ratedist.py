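"""Firing-frequency distributions across electrodes and their lognormal fit.

Across a mature network the per-electrode firing rates are approximately
lognormal, so the density histogram of log10(rate) is approximately Gaussian
and is summarized by a least-squares Gaussian fit
``A * exp(-(x - mu)^2 / (2 sigma^2))`` on the log axis. Developmental shifts
are quantified by the fitted mean: a difference of ``d`` log10-units between
two time-points is a ``10**d``-fold shift of the distribution.

Binning uses a fixed grid (0.1 log10-unit bins over [-1.5, 1.1], covering
the active-electrode band 0.05-10 events/s) so fits are comparable across
time-points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .core import AnalysisConfig, SpikeTrainSet
from .activity import classify_active_electrodes

__all__ = [
    "RateDistributionFit",
    "rate_histogram",
    "fit_lognormal",
    "compare_fits",
    "BIN_EDGES",
]

BIN_WIDTH = 0.1
BIN_EDGES = np.round(np.arange(-1.5, 1.1 + BIN_WIDTH / 2, BIN_WIDTH), 10)


@dataclass(frozen=True)
class RateDistributionFit:
    edges: np.ndarray  # log10 events/s
    density: np.ndarray  # normalized histogram heights
    mu: float  # fitted mean, log10 events/s
    sigma: float  # fitted SD, log10-units
    amplitude: float
    mu_ci: tuple[float, float]  # 95% CI from the fit covariance
    sigma_ci: tuple[float, float]
    r_squared: float
    good_fit: bool  # flagged False when R^2 < 0.8 (e.g. bimodal input)


def _gaussian(x, amplitude, mu, sigma):
    return amplitude * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def rate_histogram(
    trains_or_rates,
    config: AnalysisConfig = AnalysisConfig(),
    edges: np.ndarray = BIN_EDGES,
) -> tuple[np.ndarray, np.ndarray]:
    """Density histogram of log10 firing rate over active electrodes.

    Accepts a :class:`SpikeTrainSet` (active-electrode filter applied) or a
    plain array of positive rates. Returns ``(edges, density)`` with
    ``sum(density * diff(edges)) == 1``.
    """
    if isinstance(trains_or_rates, SpikeTrainSet):
        mask = classify_active_electrodes(trains_or_rates, config)
        rates = trains_or_rates.rates()[mask]
    else:
        rates = np.asarray(trains_or_rates, dtype=float)
        rates = rates[rates > 0]
    if rates.size < 10:
        raise ValueError(
            f"only {rates.size} active electrodes; record longer to build a "
            "rate distribution (need >= 10)"
        )
    density, edges = np.histogram(np.log10(rates), bins=edges, density=True)
    return edges, density


def fit_lognormal(
    edges: np.ndarray, density: np.ndarray, min_occupied_bins: int = 5
) -> RateDistributionFit:
    """Least-squares Gaussian fit to a log-rate density histogram."""
    edges = np.asarray(edges, dtype=float)
    density = np.asarray(density, dtype=float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    occupied = density > 0
    if occupied.sum() < min_occupied_bins:
        raise ValueError(
            f"only {int(occupied.sum())} occupied bins (need >= {min_occupied_bins})"
        )
    mass = density * np.diff(edges)
    mu0 = float(np.sum(centers * mass) / mass.sum())
    sigma0 = float(np.sqrt(np.sum((centers - mu0) ** 2 * mass) / mass.sum())) or 0.1
    amp0 = float(density.max())
    try:
        popt, pcov = curve_fit(
            _gaussian,
            centers,
            density,
            p0=(amp0, mu0, sigma0),
            bounds=((0.0, centers[0] - 1, 1e-4), (np.inf, centers[-1] + 1, 10.0)),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"Gaussian fit did not converge (p0={(amp0, mu0, sigma0)}, "
            f"{int(occupied.sum())} occupied bins, total mass {mass.sum():.3g})"
        ) from exc
    amplitude, mu, sigma = popt
    resid = density - _gaussian(centers, *popt)
    ss_tot = float(np.sum((density - density.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    err = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    return RateDistributionFit(
        edges=edges,
        density=density,
        mu=float(mu),
        sigma=float(abs(sigma)),
        amplitude=float(amplitude),
        mu_ci=(float(mu - 1.96 * err[1]), float(mu + 1.96 * err[1])),
        sigma_ci=(float(sigma - 1.96 * err[2]), float(sigma + 1.96 * err[2])),
        r_squared=r2,
        good_fit=r2 >= 0.8,
    )


def compare_fits(fit_a: RateDistributionFit, fit_b: RateDistributionFit) -> dict:
    """Shift between two fitted distributions.

    Convention: ``fit_a`` is the earlier time-point. ``fold_shift =
    10**(mu_a - mu_b)``; a fold > 1 means the later distribution moved
    toward low firing rates.
    """
    for name, fit in (("a", fit_a), ("b", fit_b)):
        if not fit.good_fit:
            raise ValueError(f"fit {name} is flagged as poor (R^2 = {fit.r_squared:.3f})")
    fold = 10.0 ** (fit_a.mu - fit_b.mu)
    return {
        "fold_shift": float(fold),
        "peak_height_ratio": float(fit_b.amplitude / fit_a.amplitude),
        "direction": "toward low firing rates"
        if fold > 1
        else ("toward high firing rates" if fold < 1 else "no shift"),
    }
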