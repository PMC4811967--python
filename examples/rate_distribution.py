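"""Lognormal firing-rate distributions and developmental shifts.

Draws two populations of 4096 per-electrode rates whose log10 means differ
by log10(5), fits the Gaussian on the log axis to each density histogram,
and quantifies the shift as 10**(mu_early - mu_late).
"""

import numpy as np

import hdmea

early = 10 ** np.random.default_rng(1).normal(0.35, 0.25, 4096)
late = 10 ** np.random.default_rng(2).normal(0.35 - np.log10(5), 0.25, 4096)

fits = {}
for label, rates in (("81 DIV", early), ("90 DIV", late)):
    edges, density = hdmea.rate_histogram(rates)
    fits[label] = hdmea.fit_lognormal(edges, density)
    f = fits[label]
    print(f"{label}: mu = {f.mu:+.3f} log10(ev/s), sigma = {f.sigma:.3f}, R^2 = {f.r_squared:.3f}")

shift = hdmea.compare_fits(fits["81 DIV"], fits["90 DIV"])
print(f"fold shift        : {shift['fold_shift']:.2f} ({shift['direction']})")
# The fitted means recover the programmed log10(5) separation, i.e. a
# ~5-fold shift of the distribution toward low firing rates.
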